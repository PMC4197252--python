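# geosurv

Multilevel discrete-time and Bayesian spatial random-effects survival
models for studying **geographical inequalities in cancer survival**
across small administrative areas.

Population-based cancer registries record, for each patient, an area of
residence, individual covariates (age, sex, stage, ...), area-level
covariates (remoteness, socioeconomic disadvantage) and a censored
all-cause survival time.  Two modelling traditions answer the question
"how much does survival vary between areas, and why?":

1. **Multilevel discrete-time survival.**  Follow-up is cut into annual
   intervals and each survived year of each patient becomes one row of a
   *person-period file* with a binary death response.  The discrete hazard
   `h_tij` — the probability that patient *i* in area *j* dies during year
   *t* given survival to *t−1* — follows a random-intercept logistic model

   ```
   logit(h_tij) = f(t) + x_ij' β + u_j ,   u_j ~ N(0, σ²_u)
   f(t) = f1 D1 + ... + f5 D5            (a dummy per follow-up year)
   ```

   Areas are treated as independent.  Between-area heterogeneity is
   reported as the **median odds ratio**,
   `MOR = exp(√(2 σ²_u) · z_0.75)` with `z_0.75 = 0.6745`: the median
   odds ratio between the higher- and lower-risk area of two randomly
   chosen areas, for identical patients (≥ 1 by construction).

2. **Bayesian spatial piecewise-exponential survival.**  Deaths `d_mtj`
   and person-time `y_mtj`, aggregated by covariate stratum *m* × year
   *t* × area *j*, follow a Poisson model with offset

   ```
   d_mtj ~ Poisson(μ_mtj),   μ_mtj = y_mtj · exp(α_t + x_m' β + u_j + v_j)
   ```

   with the classic convolution of area effects: `u_j` spatially
   structured under an intrinsic conditional autoregressive (ICAR) prior
   over the area adjacency graph, `v_j` exchangeable `N(0, σ²_v)`.
   `exp(u_j + v_j)` is the area's **smoothed relative risk** of death;
   the **spatial fraction** `Ψ = σ²_u(m) / (σ²_u(m) + σ²_v)` (marginal
   spatial variance over total area-level variance) measures how much of
   the residual heterogeneity is spatially structured.

Both backends are estimated by Metropolis-within-Gibbs MCMC with
conjugate Gamma updates for the precisions, and share Geweke convergence
diagnostics, DIC model comparison, a hyperprior sensitivity grid, and a
model-ladder driver that grows the covariate set stepwise and tabulates
how the area-level variance shrinks.  Because the registry data such
studies use are not public, the package ships a synthetic-cohort
generator with known ground truth (lattice maps, Table-style covariate
frequencies, ICAR + independent area frailties, hazards calibrated to a
target five-year survival) that every statistical claim in the test
suite is checked against.

## Worked example

Generate a 100-area cohort of 20,000 patients whose area frailty is
three-quarters spatial, then fit both backends:

```python
import numpy as np, geosurv as gs

adj = gs.lattice_adjacency(10, 10)
mf = gs.icar_marginal_factor(adj)          # marginal/conditional ICAR ratio
cfg = gs.SyntheticCohortConfig(
    n_areas=100, lattice_dims=(10, 10), n_patients=20_000,
    covariate_levels={"stage": ["early", "late"]},
    covariate_freqs={"stage": [0.7, 0.3]},
    covariate_effects={"stage": [0.0, np.log(2.0)]},
    sigma2_u=0.018 / mf, sigma2_v=0.006,    # marginal spatial var ≈ 0.018
    target_5yr_survival=0.581, seed=1,
)
cohort, truth = gs.generate_cohort(cfg, adj)

pp = gs.expand_person_period(cohort)
ml = gs.DiscreteTimeMultilevel(pp, ["stage"], n_areas=100).fit(
    n_iter=4000, burn_in=2000, seed=1)
print(ml.summary())

strata = gs.aggregate_strata(cohort, ["stage"])
sp = gs.SpatialPoissonModel(strata, adj, ["stage"]).fit(
    n_iter=4000, burn_in=3000, seed=1)
print(sp.summary())
```

The multilevel summary ends with

```
stage[late]  0.7107  0.7108  0.0229   0.6641    0.7550
sigma2_u     0.0106  0.0110  0.0037   0.0044    0.0191

MOR: 1.10 (95% CrI 1.07, 1.14)
Wald test of area variance: chi2 = 8.59, p = 0.00337
DIC: 52631.1 (pD = 49.7)
```

— the stage effect is recovered as an odds ratio `exp(0.711) = 2.04`
against a generating value of 2.0, and the residual area variance 0.011
translates to a median odds ratio of 1.10: two otherwise-identical
patients from two random areas differ in their odds of death by a median
10%.  The spatial summary for the same cohort prints

```
stage[late]  0.6676  0.6675  0.0225   0.6229    0.7101

Variance components:
                      median  cri_2.5  cri_97.5
sigma2_u_conditional  0.0084   0.0022    0.0286
sigma2_u_marginal     0.0047   0.0012    0.0126
sigma2_v              0.0071   0.0025    0.0147
total                 0.0124   0.0067    0.0200
Spatial fraction Psi: 0.40 (95% CrI 0.10, 0.79)
DIC: 4903.5 (pD = 55.3)
```

— on the rate scale the same effect is `exp(0.668) = 1.95`, within 5% of
the multilevel odds ratio (the rare-event regime: annual hazards are
below 0.1), and the wide spatial-fraction interval shows how weakly a
100-area map separates spatial from unstructured heterogeneity.

The same workflow is available from the shell:

```sh
geosurv simulate --out demo --seed 1
geosurv expand    --cohort demo_cohort.csv --out pp.csv
geosurv aggregate --cohort demo_cohort.csv --covariates stage --out strata.csv
geosurv multilevel --cohort demo_cohort.csv --out post --seed 1
geosurv spatial   --strata strata.csv --adj demo_map.adj --out spost --seed 1
geosurv diagnose  --posterior post
geosurv ladder    --cohort demo_cohort.csv --adj demo_map.adj --out report/
```

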