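# mctkit

Statistical design and analysis of **mouse clinical trials** (MCTs) —
preclinical oncology trials in which a panel of mouse tumor models (PDX,
CDX or syngeneic), each with one or more mice per arm, is treated to
measure a drug's efficacy across a heterogeneous tumor population.

MCTs look like human trials but are not: every tumor model places mice in
*both* arms, volumes are measured twice a week, and mice are clustered
within models that share tumor genetics.  mctkit implements the endpoint
definitions and the clustered statistical models this structure calls for,
for biostatisticians and pharmacologists designing or analyzing such
trials:

* **Categorical endpoints** — RECIST-style, 3-category, mRECIST and
  5-category response classifiers on relative tumor volume
  (RTV = TV_d/TV_0), per-model majority calls, objective response rates.
* **Continuous endpoints** — PFS (volume doubling time, interpolated as
  t = d₁ + (d₂−d₁)(2·TV₀−TV₁)/(TV₂−TV₁)), RTV ratio, tumor growth
  inhibition TGI = 1 − RTV_t/RTV_c (or 1 − ΔT/ΔC), growth-rate ratio
  k_t/k_c from log-linear fits, and an AUC ratio that reduces to k_t/k_c
  under exponential kinetics.
* **Subsampling accuracy** — how categorical-call accuracy and continuous-
  endpoint error shrink as mice per model increase.
* **Three-level linear mixed model** — log TV_tij = β₀ + β₁·Day +
  β₂·Day·Treat + u₀ⱼ + u₁ⱼ·Day + u₀ᵢ|ⱼ + u₁ᵢ|ⱼ·Day + ε_tij, REML-fitted
  with unstructured intercept+slope covariances at the model and
  mouse-within-model levels; covariate slopes and slope-by-treatment
  interactions support trial analysis and single-gene biomarker scans.
* **Survival analysis** — doubling/tripling event times, Cox (lifelines)
  and an additive frailty model
  h_ij(t) = h₀(t)·exp(uᵢ + (w + vᵢ)T_ij + βᵀXᵢ) with Weibull baseline and
  bivariate normal frailties, fitted by adaptive Gauss–Hermite quadrature.
* **Power analysis** — simulation-based power for n:n designs under both
  engines.
* **Synthetic trials** — a generator for clustered longitudinal volumes,
  expression matrices with a planted biomarker, and clustered survival
  data, with full ground-truth records.

There is no command-line tool: the package is a library, used from Python.
The `examples/` directory holds one short narrative script per capability.

## Worked example

```python
from mctkit import SimConfig, generate_mct, fit_lmm

dataset, truth = generate_mct(SimConfig(n_models=20, n_mice_per_arm=3), seed=1)
fit = fit_lmm(dataset)
print(fit.summary())
```

prints

```
               estimate        se        p_value
term
Intercept      5.155198  0.070632  2.225074e-308
Day            0.056275  0.003771   2.323304e-50
Day:Treatment -0.009999  0.002724   2.420715e-04
```

Vehicle tumors grow at 0.056/day on the log-volume scale (doubling in
about 12 days); the drug lowers that slope by 0.010/day — an 18% estimated
growth-rate reduction against a simulated truth of 20% (β₂ = −0.012),
detected at p ≈ 2×10⁻⁴ with just 20 models at 3:3.  The same dataset feeds
the classifiers, endpoint functions, survival fits and subsampling
procedures; see `examples/` for each.

For the clustered-survival side (`examples/survival_frailty.py`): on data
simulated with a true hazard ratio of 0.5 and real between-model
heterogeneity, the naive Cox estimate lands at 0.52 while the frailty
model recovers 0.44 with both frailty variances detectably positive — the
attenuation that makes clustering impossible to ignore.

## Acceptance script

```bash
python scripts/acceptance.py --seed 1 --out results/acceptance.json
```

recomputes the package's main pipeline from scratch under the given seed —
simulating a reference trial, computing response calls and continuous
endpoints, fitting the mixed model and a biomarker scan, fitting Cox and
frailty survival models, and running subsampling-accuracy and power cells —
printing each result and writing the results JSON to `--out`.

## Layout

```
src/mctkit/        library (datamodel, io, growth, categorical, continuous,
                   resampling, lmm, survival, power, simulate)
examples/          one narrative script per capability
tests/             pytest suite; test_acceptance.py = statistical validation
scripts/acceptance.py
docs/methods.md    models, defaults, numerical choices, limitations
```
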