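# Methods

## Model

The package targets absolute quantification of a low-abundance gene in
community DNA by qPCR, where the analysis goal is a population-level
regression rather than per-sample precision. One gram of sample is
extracted into `extract_volume_ul` (default 1000 µl) of DNA solution
with efficiency `q` (default 0.65, the fraction of copies recovered —
a fixed constant here; if it is uncertain, a distribution could be
placed on it instead). Each of `n_replicates` (default 3) reactions
receives `aliquot_volume_ul` (default 5 µl), so a copy enters a given
reaction with probability near `p = 5/1000 = 0.005`.

With `y_j` the log10 copies per gram of sample *j* and `r_j` its binary
risk factor,

    y_j  ~ Normal(beta0 + beta1 * r_j, sigma^2)
    p_j  ~ Beta(a, b),  a = 0.005 c,  b = 0.995 c   (c = 1000 by default)
    x_ij ~ Poisson(lambda_j),  lambda_j = q * 10^{y_j} * p_j

Counts below the LOQ (default 10 copies/reaction) are left-censored;
the latent count `z_ij` of a censored replicate lives on {0, ..., LOQ-1}.
The Poisson law stands in for the Binomial(n_j, p_j) subsampling of the
n_j = q·10^{y_j} extract copies; the approximation is adequate while
`lambda_j < 10`, i.e. below roughly 3.5 log10 copies/g at the default
constants, and `poisson_validity_flag` reports where it degrades.
Regression priors are Normal(0, 1e6); the precision `1/sigma^2` gets
Gamma(0.001, 0.001). We read "a diffuse gamma prior on the inverse of
the scale" as acting on the precision (the usual conjugate convention
in BUGS-family software); a Gamma on `1/sigma` itself would be a
one-line change in the precision update and was not pursued.

## Sampler

Metropolis-within-Gibbs, vectorised across samples (all per-sample
conditionals are independent given the regression parameters):

1. **Imputation.** Each censored `z_ij` is drawn exactly from
   Poisson(lambda_j) truncated to {0..LOQ-1} by inverse-CDF sampling on
   the (small) support, with the log-pmf normalised by its row maximum
   so arbitrarily large rates are handled without overflow or rejection
   loops. Observed replicates are never altered.
2. **p_j.** Random-walk Metropolis on logit(p_j); the Beta prior and
   Poisson likelihood are evaluated in log space.
3. **y_j.** Random-walk Metropolis; proposals implying
   `lambda > 1e12` copies/reaction are rejected outright and counted
   (`n_lambda_guard`) — the Poisson pmf would overflow and such rates
   are physically meaningless.
4. **(beta0, beta1).** Conjugate bivariate-normal draw given {y_j} and
   sigma.
5. **Precision.** Conjugate gamma draw given the regression residuals.

Proposal scales are tuned per sample during burn-in only (multiplied by
0.7/1.4 every 50 sweeps when acceptance leaves [0.2, 0.5]) and frozen
afterwards, so detailed balance holds for every retained draw. Initial
values come from back-calculated naive estimates (censored cells at
LOQ/2) with small jitter, OLS for the betas, and the residual sd for
sigma; chains of a multi-chain run differ through the jitter. Defaults
follow the study protocol — 5000 iterations, 1000 burn-in, one chain
(three for convergence checks via the Gelman-Rubin statistic, computed
from the standard between/within-chain variance ratio).

Summaries are posterior means, sds and central 95% credible intervals
(2.5/97.5 linear-interpolation percentiles) pooled over chains.

## Simulator

The generator mirrors the assay physics rather than the inference
model: extract copies `round(q * 10^y)` are partitioned into the three
aliquots plus remainder by a **Dirichlet-multinomial** with mean
probabilities (0.005, 0.005, 0.005, 0.985) and total concentration
`dirichlet_concentration`. A finite concentration makes replicate
counts overdispersed relative to a fixed-p multinomial, as real
triplicates are; the multinomial is recovered as the concentration
grows. The default concentration of 1000 (Dirichlet(5, 5, 5, 985))
produces the censoring profile the three scenario configurations are
known for (≈57% / 79% / 93% of replicates censored at intercepts
3/2/1, with roughly half the scenario-1 samples fully censored) — the
acceptance script recomputes these from scratch. The risk factor is
Bernoulli(0.5) per sample ("approximately half"), not an exact split.
Rounding of `q * 10^y` is half-away-from-zero, since a multinomial size
must be an integer. Censored cells are stored as missing values plus a
flag, never as sentinel numbers, so they cannot leak into arithmetic.

What the simulator does **not** emulate: fluorescence (Cq) curves,
amplification-efficiency variation, standard-curve calibration error,
inter-run effects, or true-zero samples (every sample carries a
positive quantity drawn from the normal). Passing tests therefore
validate the estimators under idealised assay noise, not under
calibration or matrix effects present in real extracts.

## Comparators

**Substitution + OLS.** Each censored replicate is replaced by a fixed
value in 0..LOQ, triplicates are averaged, and the mean is
back-calculated to `log10(mean * (V_extract / V_aliquot) / q)` copies
per gram. A fully censored sample under substitution of zero has mean
zero, whose log is undefined; its mean is floored at
`q * V_aliquot / V_extract` copies/reaction (0.00325 with the default
constants), the quantity that back-calculates to exactly 1 copy per
gram, i.e. 0 log10. The floor is derived from the assay constants, not
hard-coded, so it adapts to non-default volumes. OLS (via statsmodels)
supplies classical SEs and t-based 95% CIs.

**Tobit.** One value per sample: the back-calculated mean of its
uncensored replicates. The left limit is the back-calculated LOQ
(≈3.488 log10 copies/g by default), and — as a Tobit left limit is
conventionally applied, e.g. by `censReg` — *every* sample at or below
the limit is treated as censored there, which automatically includes
fully censored samples. Two alternatives were examined and rejected:
flagging only fully censored samples (it inflates the intercept,
because partially censored samples whose uncensored-replicate mean
falls below the LOQ-equivalent are kept as exact observations), and a
replicate-level Tobit on all 1500 observations (it conflates
within-sample Poisson noise with the between-sample normal scale). The
likelihood is maximised over (beta0, beta1, log sigma) by BFGS; SEs
come from the numerical observed information at the MLE in the
(beta0, beta1, sigma) parameterisation, with Wald 95% CIs.

## Evaluation driver

`run_scenario` simulates `n_datasets` datasets, applies each requested
method, and aggregates bias `mean(est) - truth`, MSE
`mean((est - truth)^2)` and the fraction of 95% intervals covering the
truth, per method and parameter. Per-dataset seeds derive from the
master seed by a counter-based spawn scheme, so any single dataset is
reproducible in isolation; the simulation and fitting streams are
separate. A failed fit is logged, counted and excluded — never silently
dropped. The per-dataset estimate table is returned (and written by the
CLI) so the aggregate metrics can be recomputed exactly.

Desk-scale defaults used by the tests and the acceptance script: 100
datasets for censoring summaries and for the MCMC operating-
characteristics study (2000 iterations / 500 burn-in, one chain), 200
datasets for the Tobit and substitution studies. The original protocol
used 500 datasets and 5000/1000 iterations; at these reduced sizes the
Monte-Carlo standard errors quoted by the tests absorb the difference.

## Known limitations

* Extraction efficiency is a fixed constant; its uncertainty is not
  propagated.
* The model assumes one shared aliquot-proportion `p_j` per sample,
  while the generator gives each replicate its own (negatively
  correlated) proportion from a single Dirichlet draw — deliberate, so
  that the inference model is a simplification of the data-generating
  process, as it would be for real data.
* The operating characteristics of the intercept estimate are sensitive
  to the Beta-prior concentration on `p_j` relative to the aliquot
  overdispersion actually present: a prior more diffuse than the truth
  inflates the upward intercept bias and collapses its interval
  coverage, a tighter prior does the reverse. The default (1000)
  matches the generator's default, making the model nearly
  well-specified in simulation; with real data this match is unknown.
* Single-level regression only: no random effects for repeated
  measures or clustering, no negative-binomial replicate model.
* The Poisson approximation degrades above ~3.5 log10 copies/g
  (rate ≥ 10 copies/reaction); very high-abundance samples are
  under-shrunk, though such genes rarely need censoring-aware analysis
  at all.
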