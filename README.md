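# microjoint

Joint models for longitudinal microbiome count data and time-to-event
outcomes.

Longitudinal microbiome studies ask whether the trajectory of a taxon's
abundance is associated with the time to a clinical event — preterm
delivery, infection onset, relapse.  Standard tools fit poorly on both
sides: sequence read counts are overdispersed, library sizes vary
sample-to-sample, and a taxon's abundance is an *endogenous*
time-dependent covariate that a Cox model cannot legitimately carry.
`microjoint` links the two processes in a single Bayesian model, for
biostatisticians and microbiome researchers working from a taxa-by-sample
count table, per-sample metadata, and a per-subject event table.

## The model

Counts of a focal taxon follow a negative-binomial mixed model with a
library-size offset:

    y_ij ~ NB(mu_ij, theta),   log mu_ij = x_ij'beta + z_ij'b_i + log C_ij,

with `E[y] = mu`, `Var(y) = mu + mu^2/theta`, subject random effects
`b_i ~ MVN(0, D)` and `C_ij` the total reads in the sample (no
rarefaction).  The model-implied *relative abundance*
`p_i(t) = exp(x'beta + z'b_i)` enters a proportional hazard scaled by a
fixed constant `phi`:

    h_i(t) = h0(t) exp(gamma'w_i + alpha * phi * p_i(t)),

so with `phi = 10`, `exp(alpha)` is the hazard ratio per 10% increase in
relative abundance.  Both submodels share `beta` and `b_i` and are
estimated simultaneously by Hamiltonian Monte Carlo with analytic
gradients.  The package also ships a simulator for linked count/event
data (event times inverted from the quadrature cumulative hazard by root
finding), dynamic event-free prediction, and an evaluation harness with
Cox and Gaussian-joint-model comparators.  See `docs/methods.md` for the
full model account.

## Worked example

```python
import warnings
from microjoint import (SimulationConfig, simulate_joint_dataset,
                        fit_joint, summarize_hazard_ratios)

config = SimulationConfig(n_subjects=150, k_samples=6)   # alpha = 0.5
dataset, truth = simulate_joint_dataset(config, seed=7)
with warnings.catch_warnings():
    warnings.simplefilter("ignore", RuntimeWarning)
    posterior = fit_joint(dataset, chains=2, warmup=700, draws=400, seed=3)
print(posterior.summary(probs=(0.95,)).round(3).to_string(index=False))
```

prints (abridged):

```
        parameter  median  hdi95_lo  hdi95_hi  rhat     ess
beta[(Intercept)]  -6.819    -6.971    -6.661 1.001 270.760
         beta[X1]   3.047     2.850     3.269 1.002 258.179
       beta[Time]   0.261     0.227     0.299 1.004 205.702
    beta[X1:Time]   0.137     0.084     0.185 1.008 193.604
        gamma[W1]  -1.069    -1.511    -0.570 1.004 236.858
        gamma[W2]  -0.587    -1.171    -0.118 1.006 245.197
            alpha   0.503     0.365     0.639 1.002 266.612
           lambda   0.088     0.059     0.133 1.012 231.117
            theta   1.977     1.787     2.177 1.000 528.286
```

The dataset was generated with `alpha = 0.5`, `lambda = 0.1`,
`theta = 2`, `beta = (-6.75, 3.0, 0.25, 0.15)` and `gamma = (-1.2, -0.8)`:
every generating value sits inside its 95% HDI.
`summarize_hazard_ratios(posterior)` reports `exp(alpha)` ≈ 1.65 — a
1.7-fold hazard increase per 10% abundance increase.  The
`examples/` directory has one short script per capability: simulation,
fitting, dynamic prediction, model comparison.

A thin CLI wraps the same functions
(`microjoint simulate|fit|predict|evaluate`, each taking `--config`,
`--seed` and an output location).

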