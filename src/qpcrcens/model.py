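"""Hierarchical Bayesian Poisson model for left-censored qPCR replicates.

Each sample j has an unknown log10 gene quantity per gram, y_j, modelled
as Normal(beta0 + beta1 * risk_j, sigma).  Extraction recovers a fixed
fraction q of the copies, and each replicate reaction receives a random
proportion p_j ~ Beta (centred on the pipetted volume fraction) of the
extract, so replicate counts are Poisson with rate

    lambda_j = q * 10**y_j * p_j   (copies per reaction).

Replicates below the limit of quantification (LOQ) are left-censored:
their latent counts z_ij live on {0, ..., LOQ-1} and are imputed each
MCMC sweep from the exact truncated Poisson.  Regression parameters get
flat-ish normal priors and the precision 1/sigma**2 a diffuse gamma
prior, so posterior inference is driven by the data.

The sampler is Metropolis-within-Gibbs: exact inverse-CDF imputation of
z_ij, random-walk Metropolis on y_j and logit(p_j) (independent across
samples, hence vectorised), and conjugate draws for (beta0, beta1) and
the precision given {y_j}.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import gammaln

from .simulate import CensoredDataset

__all__ = [
    "PriorSpec",
    "MCMCConfig",
    "LatentState",
    "PosteriorDraws",
    "FitSummary",
    "replicate_rate",
    "poisson_validity_flag",
    "truncated_poisson_draw",
    "log_likelihood",
    "fit",
    "gelman_rubin",
    "posterior_summary",
]

logger = logging.getLogger(__name__)

_LN10 = np.log(10.0)
# reject y proposals implying a per-reaction rate above this: the Poisson
# pmf overflows and such rates are physically absurd for qPCR reactions
_LAMBDA_GUARD = 1e12


@dataclass(frozen=True)
class PriorSpec:
    """Priors for the hierarchical model.

    ``beta_mean``/``beta_variance`` parameterise independent normal
    priors on the regression coefficients (default variance 1e6, i.e.
    effectively noninformative on the log10 scale).  The precision
    1/sigma**2 gets a Gamma(shape, rate) prior.  The per-sample aliquot
    proportion p_j gets a Beta prior parameterised by its mean and
    concentration: mean 0.005 with concentration 1000 is Beta(5, 995).
    """

    beta_mean: float = 0.0
    beta_variance: float = 1e6
    precision_shape: float = 0.001
    precision_rate: float = 0.001
    p_prior_mean: float = 0.005
    p_prior_concentration: float = 1000.0

    def __post_init__(self) -> None:
        if self.beta_variance <= 0:
            raise ValueError("beta_variance must be > 0")
        if self.precision_shape <= 0 or self.precision_rate <= 0:
            raise ValueError("gamma prior parameters must be > 0")
        if not 0 < self.p_prior_mean < 1:
            raise ValueError("p_prior_mean must be in (0, 1)")
        if self.p_prior_concentration <= 0:
            raise ValueError("p_prior_concentration must be > 0")

    @property
    def p_alpha(self) -> float:
        return self.p_prior_mean * self.p_prior_concentration

    @property
    def p_beta(self) -> float:
        return (1.0 - self.p_prior_mean) * self.p_prior_concentration


@dataclass(frozen=True)
class MCMCConfig:
    """Sampler settings.

    Defaults follow the protocol used for the simulation study: 5000
    iterations with a 1000-iteration burn-in and a single chain (three
    chains for convergence diagnostics).  Proposal scales apply to the
    random-walk updates of y_j and logit(p_j); with ``adapt`` they are
    tuned per sample during burn-in (target acceptance 0.2-0.5) and
    frozen afterwards so detailed balance holds for the retained draws.
    """

    n_iter: int = 5000
    burn_in: int = 1000
    n_chains: int = 1
    proposal_scale_y: float = 0.6
    proposal_scale_logit_p: float = 0.15
    adapt: bool = True
    store_latents: bool = False
    seed: int | None = None

    def __post_init__(self) -> None:
        if not 0 <= self.burn_in < self.n_iter:
            raise ValueError("burn_in must satisfy 0 <= burn_in < n_iter")
        if self.n_chains < 1:
            raise ValueError("n_chains must be >= 1")
        if self.proposal_scale_y <= 0 or self.proposal_scale_logit_p <= 0:
            raise ValueError("proposal scales must be > 0")


@dataclass
class LatentState:
    """Latent variables for one MCMC state.

    ``z`` is a samples x replicates float array holding the imputed
    counts at censored positions and NaN elsewhere (observed replicates
    are never altered).
    """

    y: np.ndarray
    p: np.ndarray
    z: np.ndarray

    def lambda_(self, q: float) -> np.ndarray:
        """Per-reaction Poisson rate q * 10**y * p for each sample."""
        return replicate_rate(self.y, self.p, q)


@dataclass
class PosteriorDraws:
    """Retained MCMC draws, shaped (n_chains, n_kept)."""

    beta0: np.ndarray
    beta1: np.ndarray
    sigma: np.ndarray
    y_post_mean: np.ndarray | None = None
    z_post_mean: np.ndarray | None = None
    y_draws: np.ndarray | None = None
    acceptance_y: float | None = None
    acceptance_p: float | None = None
    n_lambda_guard: int = 0

    @property
    def n_chains(self) -> int:
        return self.beta0.shape[0]

    @property
    def n_kept(self) -> int:
        return self.beta0.shape[1]

    def as_dict(self) -> dict[str, np.ndarray]:
        return {"beta0": self.beta0, "beta1": self.beta1, "sigma": self.sigma}


@dataclass
class FitSummary:
    """Posterior summary table: mean, sd, central 95% interval, R-hat."""

    table: pd.DataFrame

    def interval(self, quantity: str) -> tuple[float, float]:
        row = self.table.loc[quantity]
        return float(row["q2.5"]), float(row["q97.5"])

    def __getitem__(self, quantity: str) -> pd.Series:
        return self.table.loc[quantity]


def replicate_rate(y, p, q):
    """Expected copies per reaction: lambda = q * 10**y * p."""
    return q * np.power(10.0, y) * p


def poisson_validity_flag(y, p, q):
    """True where the Poisson approximation to the binomial is adequate.

    The approximation holds for large copy number and small aliquot
    proportion provided the product (the per-reaction rate) stays below
    10 copies; at 10**3.5 copies/gram with q = 0.65 and p = 0.005 the
    rate is 10.28 and the flag turns False.
    """
    return np.asarray(replicate_rate(y, p, q) < 10.0)


def _truncated_poisson_matrix(
    lam: np.ndarray, upper: int, rng: np.random.Generator
) -> np.ndarray:
    """Vectorised exact inverse-CDF draw from Poisson(lam) on {0..upper}."""
    lam = np.asarray(lam, dtype=float)
    ks = np.arange(upper + 1)
    with np.errstate(divide="ignore", invalid="ignore"):
        log_w = ks * np.log(lam)[..., None] - gammaln(ks + 1)
    # lam == 0 puts all mass at k = 0
    zero = lam == 0
    if np.any(zero):
        log_w[zero] = -np.inf
        log_w[zero, 0] = 0.0
    log_w -= log_w.max(axis=-1, keepdims=True)
    cdf = np.cumsum(np.exp(log_w), axis=-1)
    u = rng.random(lam.shape) * cdf[..., -1]
    return (cdf < u[..., None]).sum(axis=-1)


def truncated_poisson_draw(lam, upper: int, rng: np.random.Generator):
    """Draw from a Poisson(lam) distribution truncated to {0, ..., upper}.

    Uses exact inverse-CDF sampling on the (small) support — no
    rejection loop, so arbitrarily large rates simply concentrate the
    draw at ``upper``.  Accepts a scalar or array ``lam``.
    """
    lam_arr = np.asarray(lam, dtype=float)
    if not np.all(np.isfinite(lam_arr)):
        raise ValueError("lambda must be finite")
    if np.any(lam_arr < 0):
        raise ValueError("lambda must be >= 0")
    if upper < 0:
        raise ValueError("upper must be >= 0")
    draws = _truncated_poisson_matrix(np.atleast_1d(lam_arr), upper, rng)
    if np.isscalar(lam) or lam_arr.ndim == 0:
        return int(draws[0])
    return draws


def truncated_poisson_pmf(upper: int, lam: float) -> np.ndarray:
    """Analytic pmf of Poisson(lam) truncated to {0, ..., upper}."""
    ks = np.arange(upper + 1)
    if lam == 0:
        pmf = np.zeros(upper + 1)
        pmf[0] = 1.0
        return pmf
    log_w = ks * np.log(lam) - gammaln(ks + 1)
    log_w -= log_w.max()
    w = np.exp(log_w)
    return w / w.sum()


def log_likelihood(
    dataset: CensoredDataset,
    state: LatentState,
    params: tuple[float, float, float],
) -> float:
    """Replicate-level Poisson log likelihood at the given latent state.

    Observed counts enter directly; censored replicates enter through
    their imputed z_ij.  ``params`` is accepted for interface symmetry
    (the regression parameters act on y_j through its prior, not here).
    """
    counts, censored, _ = dataset.to_arrays()
    loq = dataset.config.loq
    z = state.z
    if np.any(censored & ~np.isfinite(z)):
        raise ValueError("state is missing an imputed z for a censored replicate")
    zc = z[censored]
    if zc.size and (np.any(zc < 0) or np.any(zc > loq - 1)):
        raise ValueError(f"imputed z outside [0, {loq - 1}]")
    full = np.where(censored, z, counts)
    lam = state.lambda_(dataset.config.extraction_efficiency)[:, None]
    lam = np.broadcast_to(lam, full.shape)
    ll = full * np.log(lam) - lam - gammaln(full + 1)
    return float(ll.sum())


def _initial_state(
    counts: np.ndarray,
    censored: np.ndarray,
    risk: np.ndarray,
    config,
    priors: PriorSpec,
    rng: np.random.Generator,
) -> tuple[np.ndarray, np.ndarray, np.ndarray, float]:
    """Crude initial values: back-calculated y, prior-mean p, OLS betas."""
    filled = np.where(censored, config.loq / 2.0, counts)
    mean_per_rxn = np.clip(filled.mean(axis=1), 0.05, None)
    scale = config.extract_volume_ul / config.aliquot_volume_ul
    y0 = np.log10(mean_per_rxn * scale / config.extraction_efficiency)
    y0 = y0 + rng.normal(0.0, 0.1, size=y0.shape)
    p0 = np.full(y0.shape, priors.p_prior_mean)
    X = np.column_stack([np.ones_like(risk, dtype=float), risk])
    beta, *_ = np.linalg.lstsq(X, y0, rcond=None)
    resid = y0 - X @ beta
    sigma0 = max(float(resid.std(ddof=2)), 0.1)
    return y0, p0, beta, sigma0


def _run_chain(
    counts: np.ndarray,
    censored: np.ndarray,
    risk: np.ndarray,
    config,
    priors: PriorSpec,
    mcmc: MCMCConfig,
    rng: np.random.Generator,
    store_latents: bool,
):
    n, r = counts.shape
    q = config.extraction_efficiency
    loq = config.loq
    log_q = np.log(q)
    a_p, b_p = priors.p_alpha, priors.p_beta
    X = np.column_stack([np.ones(n), risk.astype(float)])
    XtX = X.T @ X
    prior_prec_beta = 1.0 / priors.beta_variance

    y, p, beta, sigma = _initial_state(counts, censored, risk, config, priors, rng)
    logit_p = np.log(p) - np.log1p(-p)
    cens_rows, cens_cols = np.nonzero(censored)
    any_censored = cens_rows.size > 0
    obs_counts = np.where(censored, 0.0, counts)
    obs_sum = obs_counts.sum(axis=1)
    n_cens_per_sample = censored.sum(axis=1).astype(float)

    n_kept = mcmc.n_iter - mcmc.burn_in
    out_beta0 = np.empty(n_kept)
    out_beta1 = np.empty(n_kept)
    out_sigma = np.empty(n_kept)
    y_sum = np.zeros(n)
    z_sum = np.zeros(cens_rows.size)
    y_draws = np.empty((n_kept, n)) if store_latents else None

    scale_y = np.full(n, mcmc.proposal_scale_y)
    scale_p = np.full(n, mcmc.proposal_scale_logit_p)
    acc_y = np.zeros(n)
    acc_p = np.zeros(n)
    acc_y_total = 0.0
    acc_p_total = 0.0
    n_guard = 0
    adapt_window = 50

    z = np.zeros(cens_rows.size)
    mu = X @ beta

    for it in range(mcmc.n_iter):
        lam = np.exp(log_q + y * _LN10 + np.log(p))

        # -- impute censored counts from the truncated Poisson
        if any_censored:
            z = _truncated_poisson_matrix(lam[cens_rows], loq - 1, rng).astype(float)
            z_row_sum = np.bincount(cens_rows, weights=z, minlength=n)
        else:
            z_row_sum = 0.0
        S = obs_sum + z_row_sum  # total counts per sample

        # -- random-walk Metropolis on logit(p_j), vectorised over samples
        lp_new = logit_p + scale_p * rng.standard_normal(n)
        p_new = 1.0 / (1.0 + np.exp(-lp_new))
        base = q * np.power(10.0, y)  # rate per unit p
        logpost_p = (a_p + S) * np.log(p) + b_p * np.log1p(-p) - r * base * p
        logpost_p_new = (
            (a_p + S) * np.log(p_new) + b_p * np.log1p(-p_new) - r * base * p_new
        )
        accept = np.log(rng.random(n)) < logpost_p_new - logpost_p
        p = np.where(accept, p_new, p)
        logit_p = np.where(accept, lp_new, logit_p)
        acc_p += accept
        acc_p_total += accept.sum()

        # -- random-walk Metropolis on y_j
        y_new = y + scale_y * rng.standard_normal(n)
        log10_lam_new = np.log10(q) + y_new + np.log10(p)
        guarded = log10_lam_new > 12.0  # Poisson pmf overflow guard
        n_guard += int(guarded.sum())
        lam_y = q * np.power(10.0, y) * p
        lam_y_new = q * np.power(10.0, np.where(guarded, y, y_new)) * p
        logpost_y = S * y * _LN10 - r * lam_y - 0.5 * ((y - mu) / sigma) ** 2
        logpost_y_new = (
            S * y_new * _LN10 - r * lam_y_new - 0.5 * ((y_new - mu) / sigma) ** 2
        )
        accept = (np.log(rng.random(n)) < logpost_y_new - logpost_y) & ~guarded
        y = np.where(accept, y_new, y)
        acc_y += accept
        acc_y_total += accept.sum()

        # -- conjugate normal draw for (beta0, beta1) | y, sigma
        prec = XtX / sigma**2 + prior_prec_beta * np.eye(2)
        cov = np.linalg.inv(prec)
        mean = cov @ (X.T @ y / sigma**2 + prior_prec_beta * priors.beta_mean)
        beta = rng.multivariate_normal(mean, cov, method="cholesky")
        mu = X @ beta

        # -- conjugate gamma draw for the precision 1/sigma**2
        resid = y - mu
        tau = rng.gamma(
            priors.precision_shape + 0.5 * n,
            1.0 / (priors.precision_rate + 0.5 * float(resid @ resid)),
        )
        sigma = float(tau**-0.5)

        # -- adapt proposal scales during burn-in only
        if mcmc.adapt and it < mcmc.burn_in and (it + 1) % adapt_window == 0:
            rate_y = acc_y / adapt_window
            rate_p = acc_p / adapt_window
            scale_y *= np.where(rate_y < 0.2, 0.7, np.where(rate_y > 0.5, 1.4, 1.0))
            scale_p *= np.where(rate_p < 0.2, 0.7, np.where(rate_p > 0.5, 1.4, 1.0))
            scale_y = np.clip(scale_y, 1e-3, 10.0)
            scale_p = np.clip(scale_p, 1e-3, 10.0)
            acc_y[:] = 0.0
            acc_p[:] = 0.0

        if it >= mcmc.burn_in:
            k = it - mcmc.burn_in
            out_beta0[k] = beta[0]
            out_beta1[k] = beta[1]
            out_sigma[k] = sigma
            y_sum += y
            if any_censored:
                z_sum += z
            if store_latents:
                y_draws[k] = y

    return {
        "beta0": out_beta0,
        "beta1": out_beta1,
        "sigma": out_sigma,
        "y_mean": y_sum / n_kept,
        "z_mean": z_sum / n_kept if any_censored else None,
        "cens_idx": (cens_rows, cens_cols),
        "y_draws": y_draws,
        "acc_y": acc_y_total / (mcmc.n_iter * n),
        "acc_p": acc_p_total / (mcmc.n_iter * n),
        "n_guard": n_guard,
    }


def fit(
    dataset: CensoredDataset,
    priors: PriorSpec | None = None,
    mcmc: MCMCConfig | None = None,
    rng: np.random.Generator | None = None,
) -> PosteriorDraws:
    """Fit the hierarchical model by Metropolis-within-Gibbs MCMC.

    Each sweep imputes the censored counts z_ij exactly from their
    truncated Poisson full conditional, updates p_j and y_j by
    random-walk Metropolis, and draws (beta0, beta1) and the precision
    from their conjugate full conditionals.  Draws after burn-in are
    returned per chain.

    Parameters
    ----------
    dataset : CensoredDataset
        Replicate counts with censoring flags and a risk covariate.
    priors, mcmc : PriorSpec, MCMCConfig
        Priors and sampler settings; defaults follow the module
        docstring.
    rng : numpy Generator, optional
        Overrides ``mcmc.seed``.
    """
    priors = priors or PriorSpec()
    mcmc = mcmc or MCMCConfig()
    if rng is None:
        rng = np.random.default_rng(mcmc.seed)

    counts, censored, risk = dataset.to_arrays()
    groups = np.unique(risk)
    if len(groups) > 1:
        for g in groups:
            if (risk == g).sum() < 2:
                raise ValueError(
                    "each covariate group needs at least 2 samples"
                )
    if censored.all():
        logger.warning(
            "every replicate of every sample is censored; the regression "
            "parameters are only weakly identified by the priors"
        )

    chains = []
    for _ in range(mcmc.n_chains):
        chains.append(
            _run_chain(
                counts,
                censored,
                risk,
                dataset.config,
                priors,
                mcmc,
                rng,
                mcmc.store_latents,
            )
        )

    n = counts.shape[0]
    z_post = None
    if chains[0]["z_mean"] is not None:
        rows, cols = chains[0]["cens_idx"]
        z_post = np.full(counts.shape, np.nan)
        z_post[rows, cols] = np.mean([c["z_mean"] for c in chains], axis=0)
    y_draws = None
    if mcmc.store_latents:
        y_draws = np.stack([c["y_draws"] for c in chains])
    return PosteriorDraws(
        beta0=np.stack([c["beta0"] for c in chains]),
        beta1=np.stack([c["beta1"] for c in chains]),
        sigma=np.stack([c["sigma"] for c in chains]),
        y_post_mean=np.mean([c["y_mean"] for c in chains], axis=0),
        z_post_mean=z_post,
        y_draws=y_draws,
        acceptance_y=float(np.mean([c["acc_y"] for c in chains])),
        acceptance_p=float(np.mean([c["acc_p"] for c in chains])),
        n_lambda_guard=int(sum(c["n_guard"] for c in chains)),
    )


def gelman_rubin(chains: np.ndarray) -> float:
    """Potential scale reduction factor (R-hat) for one parameter.

    ``chains`` is an (m, n) array of m >= 2 equal-length chains.  R-hat
    compares the between-chain variance of the chain means with the
    pooled within-chain variance and approaches 1 at convergence.
    """
    chains = np.asarray(chains, dtype=float)
    if chains.ndim != 2 or chains.shape[0] < 2:
        raise ValueError("gelman_rubin requires >= 2 chains of equal length")
    m, n = chains.shape
    chain_means = chains.mean(axis=1)
    W = chains.var(axis=1, ddof=1).mean()
    B = n * chain_means.var(ddof=1)
    var_plus = (n - 1) / n * W + B / n
    if W == 0:
        return 1.0
    return float(np.sqrt(var_plus / W))


def posterior_summary(draws: PosteriorDraws) -> FitSummary:
    """Summarise the retained draws for beta0, beta1 and sigma.

    Means, standard deviations and central 95% credible intervals
    (2.5/97.5 linear-interpolation percentiles) pool all chains; R-hat
    is reported when more than one chain was run.
    """
    rows = {}
    for name, arr in draws.as_dict().items():
        flat = arr.reshape(-1)
        if flat.size == 0:
            raise ValueError("draws are empty")
        lo, hi = np.percentile(flat, [2.5, 97.5])
        rows[name] = {
            "mean": float(flat.mean()),
            "sd": float(flat.std(ddof=1)) if flat.size > 1 else 0.0,
            "q2.5": float(lo),
            "q97.5": float(hi),
            "rhat": gelman_rubin(arr) if arr.shape[0] > 1 else np.nan,
        }
    return FitSummary(table=pd.DataFrame(rows).T)
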