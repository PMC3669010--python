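"""Hierarchical model: rates, truncated imputation, sampler, diagnostics."""

import numpy as np
import pytest
from scipy import stats

from qpcrcens import (
    MCMCConfig,
    ScenarioConfig,
    fit,
    gelman_rubin,
    log_likelihood,
    poisson_validity_flag,
    posterior_summary,
    replicate_rate,
    simulate_dataset,
    truncated_poisson_draw,
)
from qpcrcens.comparators import ols_regress
from qpcrcens.model import LatentState, PosteriorDraws, PriorSpec, truncated_poisson_pmf
from qpcrcens.simulate import CensoredDataset, SampleRecord


@pytest.mark.parametrize(
    "y, p, q, expected",
    [(3.5, 0.005, 0.65, 10.28), (3.0, 0.005, 0.65, 3.25), (2.0, 0.0, 0.65, 0.0)],
)
def test_replicate_rate(y, p, q, expected):
    assert replicate_rate(y, p, q) == pytest.approx(expected, abs=0.005)


@pytest.mark.parametrize(
    "y, expected",
    [(3.5, False), (3.4, True), (-50.0, True)],
)
def test_poisson_validity_threshold(y, expected):
    # approximation valid while the per-reaction rate stays below 10 copies
    assert bool(poisson_validity_flag(y, 0.005, 0.65)) is expected


class TestTruncatedPoisson:
    def test_zero_rate_always_zero(self, rng):
        assert all(truncated_poisson_draw(0.0, 9, rng) == 0 for _ in range(100))

    def test_huge_rate_concentrates_at_upper(self, rng):
        pmf = truncated_poisson_pmf(9, 1000.0)
        assert pmf[9] > 0.99
        draws = truncated_poisson_draw(np.full(2000, 1000.0), 9, rng)
        assert np.mean(draws == 9) > 0.98

    @pytest.mark.parametrize("lam", [0.1, 1.0, 4.0, 20.0])
    def test_matches_analytic_pmf(self, lam):
        rng = np.random.default_rng(2024)
        n = 100_000
        draws = truncated_poisson_draw(np.full(n, lam), 9, rng)
        observed = np.bincount(draws, minlength=10)
        expected = truncated_poisson_pmf(9, lam) * n
        keep = expected > 5  # chi-square validity
        chi2 = ((observed[keep] - expected[keep]) ** 2 / expected[keep]).sum()
        pvalue = stats.chi2.sf(chi2, keep.sum() - 1)
        assert pvalue > 1e-4

    def test_rejects_nonfinite_rate(self, rng):
        with pytest.raises(ValueError):
            truncated_poisson_draw(np.inf, 9, rng)
        with pytest.raises(ValueError):
            truncated_poisson_draw(np.nan, 9, rng)


def _single_sample_dataset(x, censored, n_replicates, loq=10):
    cfg = ScenarioConfig(
        beta0=3.0, beta1=0.5, sigma=1.5, n_samples=1, n_replicates=n_replicates, loq=loq
    )
    rec = SampleRecord(
        sample_id="s1",
        risk_indicator=0,
        replicate_counts=tuple(x),
        censored_flags=tuple(censored),
    )
    return CensoredDataset(records=[rec], config=cfg)


def _state_for_lambda(lam, q=0.65, p=0.005, n=1, r=1):
    # choose y so that q * 10**y * p equals the requested rate
    y = np.log10(lam / (q * p))
    return LatentState(
        y=np.full(n, y), p=np.full(n, p), z=np.full((n, r), np.nan)
    )


class TestLogLikelihood:
    def test_zero_count_unit_rate(self):
        # log P(X=0 | lambda=1) = -1
        ds = _single_sample_dataset([0], [False], 1, loq=0)
        state = _state_for_lambda(1.0)
        assert log_likelihood(ds, state, (3.0, 0.5, 1.5)) == pytest.approx(-1.0)

    def test_direct_pmf_value(self):
        ds = _single_sample_dataset([2], [False], 1, loq=0)
        state = _state_for_lambda(2.0)
        assert log_likelihood(ds, state, (3.0, 0.5, 1.5)) == pytest.approx(
            np.log(2.0) - 2.0, abs=1e-9
        )

    def test_additivity_under_duplication(self):
        ds1 = _single_sample_dataset([12, 15, None], [False, False, True], 3)
        cfg = ScenarioConfig(
            beta0=3.0, beta1=0.5, sigma=1.5, n_samples=2, n_replicates=3
        )
        ds2 = CensoredDataset(records=ds1.records * 2, config=cfg)
        s1 = _state_for_lambda(13.0, r=3)
        s1.z[0, 2] = 4.0
        s2 = LatentState(
            y=np.repeat(s1.y, 2), p=np.repeat(s1.p, 2), z=np.vstack([s1.z, s1.z])
        )
        assert log_likelihood(ds2, s2, (3, 0.5, 1.5)) == pytest.approx(
            2 * log_likelihood(ds1, s1, (3, 0.5, 1.5))
        )

    def test_rejects_out_of_support_imputation(self):
        ds = _single_sample_dataset([12, 15, None], [False, False, True], 3)
        state = _state_for_lambda(13.0, r=3)
        state.z[0, 2] = 10.0  # outside {0..9}
        with pytest.raises(ValueError):
            log_likelihood(ds, state, (3, 0.5, 1.5))


class TestGelmanRubin:
    def test_identical_chains(self):
        # B = 0, so R-hat = sqrt((n-1)/n) -> 1 as the chains lengthen
        chain = np.sin(np.arange(10_000.0))
        assert gelman_rubin(np.stack([chain, chain])) == pytest.approx(1.0, abs=1e-3)

    def test_separated_chains_flagged(self):
        rng = np.random.default_rng(0)
        chains = np.stack([rng.normal(0, 1, 500), rng.normal(100, 1, 500)])
        assert gelman_rubin(chains) > 10

    def test_matches_textbook_formula(self):
        chains = np.array(
            [
                [1.2, 0.8, 1.5, 0.9, 1.1, 1.3, 0.7, 1.0, 1.4, 0.6],
                [2.1, 1.9, 2.4, 1.6, 2.2, 1.8, 2.0, 2.3, 1.7, 2.5],
            ]
        )
        m, n = chains.shape
        means = chains.mean(axis=1)
        W = chains.var(axis=1, ddof=1).mean()
        B = n * means.var(ddof=1)
        expected = np.sqrt(((n - 1) / n * W + B / n) / W)
        assert gelman_rubin(chains) == pytest.approx(expected, abs=1e-10)

    def test_single_chain_rejected(self):
        with pytest.raises(ValueError):
            gelman_rubin(np.ones((1, 100)))


class TestPosteriorSummary:
    def test_constant_draws(self):
        draws = PosteriorDraws(
            beta0=np.full((1, 50), 2.0),
            beta1=np.full((1, 50), 0.5),
            sigma=np.full((1, 50), 1.5),
        )
        row = posterior_summary(draws).table.loc["beta0"]
        assert row["mean"] == 2.0
        assert (row["q2.5"], row["q97.5"]) == (2.0, 2.0)

    def test_percentile_interpolation(self):
        vals = np.arange(1.0, 101.0)
        draws = PosteriorDraws(
            beta0=vals[None, :], beta1=vals[None, :], sigma=vals[None, :]
        )
        summary = posterior_summary(draws)
        assert summary.interval("beta0") == pytest.approx((3.475, 97.525))

    def test_interval_ordering(self, small_dataset):
        draws = fit(
            small_dataset,
            mcmc=MCMCConfig(n_iter=300, burn_in=100, seed=3),
        )
        table = posterior_summary(draws).table
        assert (table["q2.5"] <= table["mean"]).all()
        assert (table["mean"] <= table["q97.5"]).all()


class TestFit:
    def test_uncensored_limit_agrees_with_ols(self):
        # with no censoring and large counts the posterior should match
        # OLS on back-calculated log10 quantities within 2 posterior sd
        cfg = ScenarioConfig(beta0=4.0, beta1=0.5, sigma=1.0, n_samples=80, loq=0)
        ds = simulate_dataset(cfg, np.random.default_rng(5))
        counts, _, risk = ds.to_arrays()
        ylog = np.log10(np.maximum(counts.mean(axis=1), 0.5) * 200 / 0.65)
        ols = ols_regress(ylog, risk)
        draws = fit(ds, mcmc=MCMCConfig(n_iter=1500, burn_in=500, seed=6))
        table = posterior_summary(draws).table
        for param, ols_val in (("beta0", ols.beta0_hat), ("beta1", ols.beta1_hat)):
            post = table.loc[param]
            assert abs(post["mean"] - ols_val) < 2 * post["sd"]

    def test_observed_replicates_never_altered(self, small_dataset):
        draws = fit(small_dataset, mcmc=MCMCConfig(n_iter=400, burn_in=100, seed=7))
        _, censored, _ = small_dataset.to_arrays()
        # imputed means exist exactly at censored positions, within support
        assert np.isnan(draws.z_post_mean[~censored]).all()
        imputed = draws.z_post_mean[censored]
        assert ((imputed >= 0) & (imputed <= small_dataset.config.loq - 1)).all()

    def test_imputation_tracks_estimated_rate(self):
        cfg = ScenarioConfig(beta0=3.0, beta1=0.5, sigma=1.5, n_samples=150)
        ds = simulate_dataset(cfg, np.random.default_rng(9))
        draws = fit(ds, mcmc=MCMCConfig(n_iter=1000, burn_in=300, seed=10))
        _, censored, _ = ds.to_arrays()
        n_cens = censored.sum(axis=1)
        # a censored replicate alongside two quantified ones sits near the
        # top of the censored range; all-censored samples, whose rate is
        # informed only by "every count was below 10", are imputed low
        mean_z = {
            k: np.nanmean(draws.z_post_mean[n_cens == k])
            for k in (1, 2, 3)
            if (n_cens == k).any()
        }
        assert mean_z[1] > 6.0
        assert mean_z[1] > mean_z[2] > mean_z[3]
        assert mean_z[3] < 3.0

    def test_sample_order_invariance(self):
        cfg = ScenarioConfig(beta0=3.0, beta1=0.5, sigma=1.5, n_samples=80)
        ds = simulate_dataset(cfg, np.random.default_rng(11))
        perm = np.random.default_rng(1).permutation(len(ds.records))
        ds_perm = CensoredDataset(
            records=[ds.records[i] for i in perm], config=cfg
        )
        mcmc = MCMCConfig(n_iter=1200, burn_in=400, seed=12)
        t1 = posterior_summary(fit(ds, mcmc=mcmc)).table
        t2 = posterior_summary(fit(ds_perm, mcmc=mcmc)).table
        for param in ("beta0", "beta1", "sigma"):
            mc_err = t1.loc[param, "sd"] / np.sqrt(30)  # generous ESS floor
            assert abs(t1.loc[param, "mean"] - t2.loc[param, "mean"]) < 6 * mc_err

    def test_all_censored_flags_weak_identifiability(self, caplog):
        recs = [
            SampleRecord(f"s{j}", j % 2, (None, None, None), (True, True, True))
            for j in range(10)
        ]
        cfg = ScenarioConfig(beta0=1.0, beta1=0.5, sigma=1.5, n_samples=10)
        ds = CensoredDataset(records=recs, config=cfg)
        with caplog.at_level("WARNING", logger="qpcrcens.model"):
            draws = fit(ds, mcmc=MCMCConfig(n_iter=200, burn_in=50, seed=13))
        assert "weakly identified" in caplog.text
        assert np.isfinite(draws.beta0).all()

    def test_multichain_rhat_near_one(self, small_dataset):
        draws = fit(
            small_dataset,
            mcmc=MCMCConfig(n_iter=800, burn_in=300, n_chains=3, seed=14),
        )
        table = posterior_summary(draws).table
        assert (table["rhat"] < 1.2).all()

    def test_config_validation(self):
        with pytest.raises(ValueError):
            MCMCConfig(n_iter=100, burn_in=100)
        with pytest.raises(ValueError):
            PriorSpec(p_prior_mean=1.5)
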