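# carmap

Small-area disease mapping for treated-prevalence count data: indirect
standardization, ecological indices, frequentist count-model diagnostics,
conditional-autoregressive (CAR) Bayesian smoothing by MCMC, and
exceedance-probability hotspot detection.

The package is aimed at psychiatric and spatial epidemiologists analysing
per-neighbourhood case counts (here: treated non-affective psychotic
disorders over census micro-areas of ~2000 residents) against ecological
covariates — economic deprivation, migrant density, social fragmentation —
when counts are too small and too spatially structured for a plain Poisson
regression to be valid.

## The model

Counts are modelled on the rate scale with a log-population offset:

    y_k ~ Poisson(mu_k),   log mu_k = log n_k + x_k' beta + phi_k (+ theta_k)

where `n_k` is the adult population at risk of area `k`, `x_k` holds the
confounder proportions (age/gender strata, 55+ as reference) and the
ecological Z-score indices, and the random effects carry the extra-Poisson
variation.  Four prior structures are available for the effects:

| structure | prior precision of the field | interpretation |
|-----------|------------------------------|----------------|
| IND | `sigma2^-1 I` | exchangeable; shrinks area risks to the overall mean |
| IAR | `tau2^-1 (D - W)` | intrinsic autoregressive; shrinks to the neighbour mean |
| BYM | IAR + IND convolution | structured + unstructured components |
| LER | `tau2^-1 [rho(D - W) + (1 - rho) I]` | Leroux: one mixing parameter `rho` interpolating between IND (rho=0) and IAR (rho=1) |

`W` is the binary contiguity matrix, `D` its degree diagonal.  Inference is
Metropolis-within-Gibbs (non-conjugate Poisson likelihood), model choice is
by DIC (AIC on the frequentist side), convergence is monitored with Geweke
Z-scores, and areas whose smoothed relative risk `mu_k / E_k` exceeds 1
with posterior probability above 0.75 are flagged as hotspots.  `E_k` is
the indirectly standardized expected count: catchment-wide stratum
prevalences applied to each area's stratum denominators, so that
`sum(E) == sum(y)` exactly.

The escalation logic mirrors sound applied practice: fit Poisson first;
move to the negative binomial only if Dean's score test shows
overdispersion; move to the spatial Bayesian models only if Moran's I shows
residual autocorrelation (or the analyst forces it); compare paradigms by
r² and RMSD between observed and fitted counts.

A synthetic-data generator (`carmap.synthetic`) reproduces these study
conditions with known parameters — 56 grid areas, populations 2064 ± 705,
crude prevalence 358/109 397, a deprivation log-rate-ratio of 0.12 per SD,
Leroux field with rho = 0.8, tau2 = 0.3 — so every stage is testable
end-to-end without access to the (unpublished) per-area data.  The real
catchment's gender × age-band aggregates are packaged as a fixture.

## Worked example

```python
from carmap.compare import run_pipeline

config = {
    "simulate": {"rho": 0.8, "tau2": 0.3},       # Leroux-field synthetic catchment
    "force_bayesian": True,
    "moran_permutations": 999,
    "mcmc": {"n_burnin": 2000, "n_keep": 3000, "thin": 2},
}
res = run_pipeline(config, seed=1, out_dir="out")
print(res.summary)
```

prints (abridged):

```
dataset ready: 56 areas, 392 cases
Poisson selection kept ('MIG',) (AIC 312.61)
Dean's test: statistic 3.61, overdispersed
negative binomial selection kept ('nothing',) (AIC 303.94)
Moran's I on residuals: 0.005 (p = 0.396)
CAR IND: kept ('FRAG',) (DIC 290.99)
CAR IAR: kept ('nothing',) (DIC 296.84)
CAR BYM: kept ('ECON',) (DIC 291.93)
CAR LER: kept ('nothing',) (DIC 291.10)
comparison: r2 0.87 (Bayes) vs 0.39 (freq)
hotspots: 11 area(s) above 0.75 exceedance
```

Reading: the synthetic counts are overdispersed (Dean 3.61, one-sided
normal reference), so the Poisson stage is rejected; the four CAR
structures land within ~1 DIC point of each other except IAR; the Bayesian
fit explains far more per-area variance than the best frequentist fit
(r² 0.87 vs 0.39) because the random effects absorb the simulated spatial
field; 11 areas carry a smoothed relative risk above 1 with more than 75 %
posterior probability — genuine raised-risk areas of the simulated field.
`out/` receives the selection traces, effect tables, chains, hotspot CSV +
GeoJSON, run log and a machine-readable `summary.json`.

The same stages are scriptable from a shell:

```
carmap simulate --seed 4 --out data/
carmap fit-freq --areas data/areas.csv --adjacency data/adjacency.csv --family poisson --out fits/
carmap run --seed 1 --config config.yaml --out out/
```

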