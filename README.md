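# geoaft

Geospatial survival analysis for cancer-registry cohorts: Bayesian
accelerated failure time (AFT) models with county-level spatial frailties,
plus the surrounding registry pipeline — cohort construction,
age-standardized incidence with gamma-method confidence intervals,
Kaplan–Meier / log-rank survival, and a secondary assessment linking
county-level health and environmental factors to the estimated spatial
field.

It is written for epidemiologists and biostatisticians studying geographic
disparities in cancer-specific mortality from registry-style individual
records (one row per case: demographics, tumor variables, follow-up time,
event type, county of residence). Because real registry data are usually
restricted, the package ships a synthetic-data generator that reproduces
the statistical structure of such a cohort with full ground truth, so every
stage is runnable and testable out of the box.

## The model

For case *i* residing in county *c(i)*,

```
log T_i = μ + x_i'β + W_{c(i)} + σ ε_i
```

where *T_i* is the disease-specific survival time (months), *x_i* are
dummy-coded individual risk factors, and ε is standard normal (log-normal
AFT, the default) or standard minimum extreme value (Weibull option).
Other-cause deaths and administrative end of study are right-censored.
Coefficients act on log time: `exp(β)` is the **acceleration factor**, so
β = −0.221 means a `1 − exp(−0.221) ≈ 20%` shorter average survival time.

The county frailty field *W* has an intrinsic conditional autoregressive
(ICAR) prior with precision τ over the county adjacency graph,

```
p(W) ∝ exp( −τ/2 · Σ_{c~d} (W_c − W_d)² ),
```

identified by sum-to-zero centering (per connected component). Higher
frailty means longer survival in that county. Inference is by Gibbs
sampling with truncated-normal data augmentation for censored log-times;
model comparison uses the deviance information criterion
DIC = D̄ + p_D. The secondary assessment classifies counties into frailty
quartiles and fits, per county-level factor,

```
factor_c = α + γ·1[c ∈ Q4] + u_c + e_c
```

with an ICAR random effect *u* over the Q1∪Q4 subgraph: γ > 0 means the
factor is elevated where survival is longest.

## Worked example

```python
import numpy as np
from geoaft import make_county_graph
from geoaft.simulate import SimulationTruth, simulate_registry
from geoaft.aft import AFTModelSpec, build_design, fit_spatial_aft, summarize_posterior

graph = make_county_graph(16, "grid", seed=0)
truth = SimulationTruth(beta=np.array([-0.5, 0.8]), sigma=1.0, tau=4.0,
                        mu=4.0, target_censor_frac=0.30, seed=5)
cases, echo = simulate_registry(
    graph, truth, 5000,
    covariate_spec={"exposure": (["no", "yes"], [0.5, 0.5]),
                    "therapy": (["none", "given"], [0.5, 0.5])})

spec = AFTModelSpec(covariates={"exposure": "no", "therapy": "none"})
draws = fit_spatial_aft(build_design(cases, graph, spec), graph, spec,
                        n_iter=6000, burn_in=1000, thin=2, seed=1)
print(summarize_posterior(draws))
```

prints (run `python examples/05_spatial_aft.py` for the full script)

```
         term     mean    lower    upper  significant      ess
    intercept    3.992    3.940    4.042         True 2500.000
 exposure:yes   -0.503   -0.562   -0.442         True 2500.000
therapy:given    0.843    0.781    0.905         True 2199.804
        sigma    1.014    0.990    1.040        False 1891.464
          tau    5.466    2.234   10.058        False 2500.000
exposure acceleration factor 0.60 (40% reduction in survival time)
Spearman(true frailty, estimated frailty) = 0.93
DIC: {'Dbar': 37417.0, 'D_at_mean': 37398.6, 'pD': 18.4, 'DIC': 37435.4}
```

The posterior means sit on the generative values (−0.5, +0.8, σ = 1): a
−0.50 log-time coefficient is an acceleration factor of 0.60, i.e. exposed
cases live on average 40% shorter; the estimated county field recovers the
true spatial pattern (rank correlation 0.93).

The `examples/` directory has one short script per capability (simulation,
cohort construction, incidence, Kaplan–Meier, the spatial fit, secondary
assessment, map export). A thin CLI chains the stages from the shell:

```
geoaft simulate --seed 7 --out sim
geoaft cohort   --cases sim/cases.csv --adjacency sim/adjacency.txt \
                --attrs sim/county_attrs.csv --out coh
geoaft fit-aft  --cases coh/eligible.csv --adjacency sim/adjacency.txt \
                --attrs sim/county_attrs.csv --out fit --seed 7
```

Each step writes its outputs plus a `manifest.json` (inputs, seed,
versions) and is byte-reproducible under a fixed seed.

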