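# qpcrcens

Hierarchical Bayesian analysis of left-censored quantitative real-time
PCR (qPCR) data.

## The problem

qPCR assays quantify a target gene only within their linear dynamic
range; replicate reactions yielding fewer copies than the limit of
quantification (LOQ — 10 copies per reaction for the assays modelled
here) are **left-censored**: all that is known is that the count was
somewhere in 0–9. In epidemiological applications — e.g. relating
antibiotic-resistance gene load in fecal community DNA to a risk
factor — censoring routinely affects half or more of the technical
replicates, and the common fixes (deleting censored replicates, or
substituting a fixed value before log-transforming) bias the regression
estimates that are the actual object of interest.

`qpcrcens` provides, for exactly this setting:

* a **generative simulator** of triplicate qPCR counts with
  Dirichlet-multinomial aliquoting and LOQ censoring,
* the **hierarchical Bayesian Poisson model** fitted by
  Metropolis-within-Gibbs MCMC, which imputes each censored replicate
  from its exact truncated-Poisson conditional,
* the comparator estimators: **fixed-value substitution + OLS** (values
  0–10) and **Tobit** (left-censored normal ML) regression,
* an **evaluation driver** measuring bias, MSE and 95%-interval
  coverage of every estimator over repeated simulated datasets.

## The model

For sample *j* with binary risk factor *r<sub>j</sub>* and unknown
log10 gene quantity per gram *y<sub>j</sub>*:

```
y_j  ~  Normal(β0 + β1 r_j, σ²)
p_j  ~  Beta(mean 0.005, concentration 1000)        aliquot proportion
λ_j  =  q · 10^{y_j} · p_j                          copies per reaction
x_ij ~  Poisson(λ_j)          i = 1..3 technical replicates
x_ij observed if x_ij ≥ LOQ, otherwise censored (latent z_ij ∈ {0..9})
```

`q = 0.65` is the DNA-extraction efficiency and `0.005 = 5 µl / 1000 µl`
the volume fraction pipetted into each reaction. The Poisson law is the
standard approximation to the binomial subsampling of extract copies,
adequate while `λ_j < 10` (i.e. below ~3.5 log10 copies/g at the default
constants). Priors on (β0, β1) are Normal(0, 10⁶) and on the precision
1/σ² Gamma(0.001, 0.001). Each MCMC sweep imputes the censored
z<sub>ij</sub> exactly by inverse-CDF truncated-Poisson draws, updates
y<sub>j</sub> and logit(p<sub>j</sub>) by adaptive random-walk
Metropolis, and draws (β0, β1) and 1/σ² from their conjugate
conditionals.

## Worked example

```python
import numpy as np
from qpcrcens import (ScenarioConfig, simulate_dataset, censoring_summary,
                      fit, posterior_summary, MCMCConfig)

cfg = ScenarioConfig(beta0=3.0, beta1=0.5, sigma=1.5, seed=7)   # 500 samples
ds = simulate_dataset(cfg)
frac, levels = censoring_summary(ds)
print(f"censored fraction: {frac:.3f}")
print(f"samples by number of censored replicates (0,1,2,3): {levels}")

draws = fit(ds, mcmc=MCMCConfig(n_iter=2000, burn_in=500, seed=1))
print(posterior_summary(draws).table.round(3))
```

prints

```
censored fraction: 0.599
samples by number of censored replicates (0,1,2,3): (168, 34, 30, 268)
        mean     sd   q2.5  q97.5  rhat
beta0  3.074  0.112  2.851  3.289   NaN
beta1  0.340  0.149  0.047  0.627   NaN
sigma  1.419  0.070  1.283  1.560   NaN
```

Even with 60% of replicates censored (268 of 500 samples had *no*
quantifiable replicate), the posterior recovers the generating values
β0 = 3, β1 = 0.5, σ = 1.5: every 95% credible interval covers the
truth. `rhat` is reported when `n_chains > 1`.

The same workflow is available from the shell:

```sh
qpcrcens simulate --config scenario.yaml --out data.csv --seed 7
qpcrcens fit --data data.csv --iters 2000 --burnin 500 --seed 1
qpcrcens compare --data data.csv --methods substitute:0..10,tobit
qpcrcens evaluate --scenario scenario.yaml --methods hier,tobit,substitute:0 \
    --n-datasets 100 --out results/
```

where `scenario.yaml` contains e.g.
`scenario: {beta0: 3.0, beta1: 0.5, sigma: 1.5}`.

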