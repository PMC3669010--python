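"""Comparator estimators: fixed-value substitution + OLS, and Tobit.

Substitution replaces each censored replicate with a fixed copy number
(0 through the LOQ), averages the triplicates, back-calculates to log10
copies per gram and runs ordinary least squares on the risk factor.
Tobit regression instead keeps the censoring in the likelihood: sample
log10 quantities below the back-calculated LOQ contribute the normal
CDF rather than the density.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import statsmodels.api as sm
from scipy import optimize, stats
from statsmodels.tools.numdiff import approx_hess

from .simulate import CensoredDataset

__all__ = [
    "ComparatorResult",
    "substitute",
    "back_calculate_log10_per_gram",
    "ols_regress",
    "tobit_fit",
    "tobit_view",
    "zero_floor_copies_per_reaction",
]


class OptimizationError(RuntimeError):
    """Raised when the Tobit likelihood optimiser fails to converge."""


@dataclass
class ComparatorResult:
    """Point estimates, standard errors and 95% CIs for one method."""

    method_label: str
    beta0_hat: float
    beta1_hat: float
    se_beta0: float
    se_beta1: float
    ci_beta0: tuple[float, float]
    ci_beta1: tuple[float, float]
    n_samples_all_censored: int = 0
    sigma_hat: float | None = None

    def __post_init__(self) -> None:
        for lo, hi in (self.ci_beta0, self.ci_beta1):
            if not lo < hi:
                raise ValueError("confidence interval bounds must satisfy lo < hi")


def back_calculate_log10_per_gram(
    mean_copies_per_reaction: float,
    q: float = 0.65,
    extract_volume_ul: float = 1000.0,
    aliquot_volume_ul: float = 5.0,
) -> float:
    """Convert mean copies per reaction to log10 copies per gram.

    Scales by the extract/aliquot volume ratio and divides by the
    extraction efficiency q.  A zero mean has no defined logarithm; the
    caller must first apply the all-censored floor
    (:func:`zero_floor_copies_per_reaction`).
    """
    if mean_copies_per_reaction <= 0:
        raise ValueError(
            "mean copies per reaction must be > 0; a zero mean back-calculates "
            "to an undefined log10 quantity (apply the all-censored floor first)"
        )
    scale = extract_volume_ul / aliquot_volume_ul
    return float(np.log10(mean_copies_per_reaction * scale / q))


def zero_floor_copies_per_reaction(
    q: float = 0.65,
    extract_volume_ul: float = 1000.0,
    aliquot_volume_ul: float = 5.0,
) -> float:
    """Mean copies/reaction equivalent to 1 copy per gram (0 on log10).

    With the default assay constants this is 0.65 * 5/1000 = 0.00325:
    substituting it for an all-censored sample's zero mean makes the
    back-calculated quantity exactly 0 log10 copies per gram.
    """
    return q * aliquot_volume_ul / extract_volume_ul


def substitute(dataset: CensoredDataset, value: int) -> np.ndarray:
    """Complete the dataset by substituting ``value`` for censored cells.

    Each censored replicate is set to ``value`` (0..LOQ), triplicates
    are averaged and back-calculated to log10 copies per gram.  When
    ``value`` is 0 and every replicate of a sample is censored the mean
    would be zero and its log undefined, so the mean is floored at the
    copies-per-reaction equivalent of 1 copy per gram (0 log10).
    """
    cfg = dataset.config
    if not 0 <= value <= cfg.loq:
        raise ValueError(f"substitution value must be in 0..{cfg.loq}")
    counts, censored, _ = dataset.to_arrays()
    filled = np.where(censored, float(value), counts)
    means = filled.mean(axis=1)
    floor = zero_floor_copies_per_reaction(
        cfg.extraction_efficiency, cfg.extract_volume_ul, cfg.aliquot_volume_ul
    )
    means = np.where(means == 0.0, floor, means)
    scale = cfg.extract_volume_ul / cfg.aliquot_volume_ul
    return np.log10(means * scale / cfg.extraction_efficiency)


def ols_regress(
    log10_quantities: np.ndarray,
    risk_indicators: np.ndarray,
    method_label: str = "ols",
    n_samples_all_censored: int = 0,
) -> ComparatorResult:
    """Ordinary least squares of log10 quantity on the binary risk factor.

    Classical standard errors and t-based 95% confidence intervals.
    """
    y = np.asarray(log10_quantities, dtype=float)
    x = np.asarray(risk_indicators, dtype=float)
    if np.all(x == x[0]):
        raise ValueError("risk factor is constant; both groups must be present")
    X = sm.add_constant(x)
    res = sm.OLS(y, X).fit()
    ci = res.conf_int(alpha=0.05)
    return ComparatorResult(
        method_label=method_label,
        beta0_hat=float(res.params[0]),
        beta1_hat=float(res.params[1]),
        se_beta0=float(res.bse[0]),
        se_beta1=float(res.bse[1]),
        ci_beta0=(float(ci[0, 0]), float(ci[0, 1])),
        ci_beta1=(float(ci[1, 0]), float(ci[1, 1])),
        n_samples_all_censored=n_samples_all_censored,
        sigma_hat=float(np.sqrt(res.mse_resid)),
    )


def tobit_view(
    dataset: CensoredDataset,
) -> tuple[np.ndarray, np.ndarray, float, np.ndarray]:
    """Collapse replicate-level censoring to one value per sample.

    Each sample's value is the back-calculated mean of its uncensored
    replicates.  The left-censoring limit is the back-calculated LOQ
    (log10(LOQ * volume ratio / q), ~3.488 with the default assay
    constants), and — as a Tobit left limit is conventionally applied —
    every sample whose value falls at or below the limit is treated as
    censored there, which automatically covers samples with all
    replicates censored.  Returns (log10 quantities, censored flags,
    censor limit, risk indicators); censored samples carry the limit as
    their value.
    """
    cfg = dataset.config
    counts, censored, risk = dataset.to_arrays()
    if cfg.loq <= 0:  # censoring impossible: no finite left limit
        limit = -np.inf
    else:
        limit = back_calculate_log10_per_gram(
            float(cfg.loq),
            cfg.extraction_efficiency,
            cfg.extract_volume_ul,
            cfg.aliquot_volume_ul,
        )
    obs = np.where(censored, 0.0, counts)
    n_obs = (~censored).sum(axis=1)
    means = obs.sum(axis=1) / np.maximum(n_obs, 1)  # all-censored rows unused
    # observed all-zero counts (possible only when loq == 0) get the
    # 1-copy-per-gram floor, matching the substitution convention
    floor = zero_floor_copies_per_reaction(
        cfg.extraction_efficiency, cfg.extract_volume_ul, cfg.aliquot_volume_ul
    )
    means = np.where(means == 0.0, floor, means)
    scale = cfg.extract_volume_ul / cfg.aliquot_volume_ul
    y = np.full(len(means), limit)
    ok = n_obs > 0
    y[ok] = np.log10(means[ok] * scale / cfg.extraction_efficiency)
    cens_flags = y <= limit
    y = np.where(cens_flags, limit, y)
    return y, cens_flags, limit, risk


def _tobit_negll(params, y, cens, limit, x):
    b0, b1, log_sigma = params
    sigma = np.exp(log_sigma)
    mu = b0 + b1 * x
    ll = stats.norm.logpdf(y[~cens], mu[~cens], sigma).sum()
    if cens.any():
        ll += stats.norm.logcdf((limit - mu[cens]) / sigma).sum()
    return -ll


def tobit_fit(
    log10_quantities: np.ndarray,
    censored_indicators: np.ndarray,
    censor_limit: float,
    risk_indicators: np.ndarray,
    method_label: str = "tobit",
) -> ComparatorResult:
    """Left-censored normal (Tobit) maximum-likelihood regression.

    Uncensored samples contribute the normal density, censored samples
    the normal CDF at the censoring limit.  Standard errors come from
    the observed information (numerical Hessian at the MLE) and CIs are
    Wald intervals.
    """
    y = np.asarray(log10_quantities, dtype=float)
    cens = np.asarray(censored_indicators, dtype=bool)
    x = np.asarray(risk_indicators, dtype=float)
    if cens.all():
        raise ValueError("all samples censored: Tobit parameters not identifiable")

    uncens = ~cens
    b0 = float(y[uncens].mean())
    b1 = 0.0
    s0 = float(y[uncens].std(ddof=1)) if uncens.sum() > 1 else 1.0
    start = np.array([b0, b1, np.log(max(s0, 0.1))])
    res = optimize.minimize(
        _tobit_negll,
        start,
        args=(y, cens, censor_limit, x),
        method="BFGS",
        options={"gtol": 1e-7, "maxiter": 500},
    )
    if not np.all(np.isfinite(res.x)):
        raise OptimizationError(f"Tobit optimisation diverged: {res.message}")

    b0_hat, b1_hat, log_sigma_hat = res.x
    sigma_hat = float(np.exp(log_sigma_hat))

    # observed information in the (b0, b1, sigma) parameterisation
    def negll_sigma(params):
        b0_, b1_, sigma_ = params
        return _tobit_negll(
            np.array([b0_, b1_, np.log(sigma_)]), y, cens, censor_limit, x
        )

    hess = approx_hess(np.array([b0_hat, b1_hat, sigma_hat]), negll_sigma)
    try:
        cov = np.linalg.inv(hess)
    except np.linalg.LinAlgError as exc:
        raise OptimizationError(f"singular observed information: {exc}") from exc
    if np.any(np.diag(cov)[:2] <= 0):
        raise OptimizationError("observed information is not positive definite")
    se = np.sqrt(np.diag(cov)[:2])
    zcrit = stats.norm.ppf(0.975)
    return ComparatorResult(
        method_label=method_label,
        beta0_hat=float(b0_hat),
        beta1_hat=float(b1_hat),
        se_beta0=float(se[0]),
        se_beta1=float(se[1]),
        ci_beta0=(float(b0_hat - zcrit * se[0]), float(b0_hat + zcrit * se[0])),
        ci_beta1=(float(b1_hat - zcrit * se[1]), float(b1_hat + zcrit * se[1])),
        n_samples_all_censored=int(cens.sum()),
        sigma_hat=sigma_hat,
    )
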