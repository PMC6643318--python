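# Methods

This note documents the statistical models behind mctkit, the defaults that
matter, what the synthetic-trial generator does and does not emulate, and
the numerical choices a user analyzing a real mouse clinical trial (MCT)
should know about.

## The data and the growth model

An MCT follows G mouse tumor models (PDX/CDX/syngeneic); each model
contributes n mice to a vehicle arm and n to a treatment arm (the balanced
n:n design; unbalanced data are accepted everywhere, only the power engines
assume balance).  Tumor volume is measured by caliper roughly twice a week
from treatment initiation (day 0) until study end or until the tumor reaches
the euthanasia threshold of 3000 mm³.  Subcutaneous tumor growth is treated
as exponential, TV_d = TV_0·e^{kd}, so analyses run on log volume, where
growth is linear in day and treatment effects are slope changes.  Gompertz
or logistic refinements are deliberately out of scope: over a 3-week window
the exponential model fits the large majority of mice and keeps every
downstream model linear.

Zero recorded volume means "no measurable tumor mass".  Zero-volume points
are excluded from log-scale fitting (their count is retained on the fit
object); they are meaningful to the categorical classifiers, where RTV = 0
defines complete response.  An optional volume floor reproducing the older
TV < 0.10 cm³ CR convention exists but is off by default.

## Interpolation conventions

Two different interpolation rules coexist, on purpose:

* `volume_at` interpolates **linearly in log volume** (geometric
  interpolation), matching exponential kinetics; it falls back to linear
  interpolation of the raw volume when a flanking volume is 0.
* `time_to_multiple` (doubling time = PFS, tripling time = OS) interpolates
  the crossing **linearly in volume** between flanking days:
  t = d₁ + (d₂−d₁)(f·TV₀−TV₁)/(TV₂−TV₁).  This is the standard printed
  doubling-time rule, and PFS values would silently change if the log-scale
  rule were used instead.  Curves that never cross are censored at the last
  measured day (the field has no fixed convention; ours is explicit).

## Categorical endpoints

All four classifiers act on relative tumor volume RTV = TV_d/TV_0:

| method | rule |
| --- | --- |
| RECIST-style | CR: RTV = 0; PR: ≤ 0.657; SD: ≤ 1.728; PD: above |
| 3-category | OR: ≤ 0.65; PD: ≥ 1.35; SD: between |
| mRECIST | thresholds on best response (min RTV over days ≥ 10) and best average response (min running-mean RTV over days ≥ 10), tested CR → PR → SD → PD |
| 5-category | MCR: RTV = 0 at end; CR: RTV = 0 ever; PR: RTV ≤ 0.50 ever; SD: end RTV ≤ 1.25; PD: otherwise |

The mRECIST numeric cutoffs are not standardized in print; we adopt the
widely used Gao-style cutoffs expressed on the RTV scale — CR 0.05/0.60,
PR 0.50/0.80, SD 1.35/1.30 (best / best-average upper bounds, strict
inequalities) — as configurable constants.  The running average makes
mRECIST remember early growth: a tumor that grows through day 14 and then
disappears entirely is still PD, a classification anomaly the test suite
pins down.  The 5-category "during the study" window excludes day 0 (where
RTV ≡ 1; this only matters for PR).

A model's call is the majority call of its mice; ties break toward the more
progressive category (PD > SD > PR/OR > CR > MCR), a conservative efficacy
convention (configurable).  Evaluation day defaults to the mice's last
common measured day.  Baseline volumes outside the admissible 50–300 mm³
enrollment range trigger warnings, not failures.

## Continuous endpoints

RTV ratio and TGI (1 − RTV_t/RTV_c, or 1 − ΔT/ΔC on raw volume changes)
are day-specific; group RTV is the arithmetic mean of per-mouse RTVs
(median available).  The growth-rate ratio k_t/k_c uses a common-slope
regression with per-mouse intercepts in each arm ("mean of per-mouse
slopes" available).  The AUC ratio is defined here as the ratio of
trapezoid areas under the per-arm mean log-RTV curves over the largest day
window covered by every mouse; on the log scale this reduces *exactly* to
k_t/k_c under exponential kinetics (each area is kT²/2) while remaining
defined for any growth shape.  The raw-volume alternative would not have
that limit and is not offered.  TGI's day dependence versus the
day-freeness of the two trajectory ratios is demonstrated in the test
suite; choosing a reporting day for TGI remains the user's burden.

## Subsampling accuracy

Categorical: for each model, draw n mice **without replacement** (with-
replacement available) from the treated arm, take the subsample majority
with the same tie-break, and score agreement with the full-group majority
over 1000 draws; report per-actual-majority-category means ± sd and their
unweighted average.  Continuous: recompute the endpoint (PFS = median
per-mouse doubling time, censored times entering at their censoring value;
or RTV ratio with n drawn per arm) and record |sub − full|/full·100 (or the
absolute error) per replication; models need ≥ 10 mice per relevant arm to
enter.  Undefined subsample endpoints are recorded as missing and counted.
Seeds are mandatory arguments; results are bit-reproducible.

## The three-level linear mixed model

Log volume for observation t of mouse i in model j:

    log TV_tij = β₀ + β₁·Day + Σ_c β_c·Day·c_j [+ β_T·Day·Treat_ij]
                 [+ Σ_c β_{cT}·Day·c_j·Treat_ij]
                 + u_{0j} + u_{1j}·Day + u_{0i|j} + u_{1i|j}·Day + ε_tij

with unstructured 2×2 covariances for the (intercept, slope) pairs at the
model level and the mouse-within-model level, independence across levels,
iid residuals, and REML estimation.  Model-level covariates act on the
slope because that is where biology acts under exponential growth;
categorical covariates expand to dummies against a reference level.

The fitter is implemented in-package: σ² is profiled out, the remaining six
relative-scale Cholesky parameters are optimized by L-BFGS-B (three
deterministic restarts on failure), and each likelihood evaluation factors
the per-cluster covariance with the Woodbury identity around the
block-diagonal mouse level — one small Cholesky per distinct
measurement-day pattern plus 2×2 cluster algebra, vectorized across mice.
A fit of a 20-model 3:3 trial takes ~0.1 s, which is what makes the
1000-replicate calibration checks and genome scans tractable.  statsmodels'
MixedLM cannot express correlated intercept+slope pairs at both levels and
serves instead as the independent two-level oracle in the tests.

Inference uses large-sample Wald z tests; no Satterthwaite/Kenward–Roger
degree-of-freedom correction is applied.  This is a documented limitation:
with very few models the tests run liberal.  The simulation suite verifies
calibration (type-I error within [0.03, 0.07]; 95% interval coverage
≥ 0.93) at the 20-model scale.

### Biomarker scanning

For each gene, its value (standardized across models by default) enters as
a Day-slope covariate and a Day×Gene×Treatment interaction; the interaction
coefficient is the predictive effect and is ranked by Wald p-value, with
Benjamini–Hochberg adjusted p-values reported alongside.  Constant genes
are skipped and flagged.  Variance parameters are warm-started from the
previous gene's fit (~30 ms per gene).  The naive comparator correlates
expression with per-model TGI (Spearman, ranked by |ρ|).
`interpret_gene_effects` separates a gene's prognostic role (Day:Gene) from
its predictive role (Day:Gene:Treatment); opposite-signed effects of
comparable magnitude are the configuration that lets marker-stratified
trials in different populations reach conflicting conclusions.

## Survival: Cox and the additive frailty model

Event times are volume doubling (PFS) or tripling (OS) times.  The naive
Cox model (lifelines, Breslow ties) ignores the clustering of mice within
models; its treatment hazard ratio is a population-averaged quantity
attenuated toward 1 when real between-model heterogeneity exists.  The
additive frailty model puts the hazard for mouse j of model i at

    h_ij(t) = h₀(t)·exp(u_i + (w + v_i)·T_ij + βᵀX_i),

(u_i, v_i) bivariate normal with variances σ², τ² and correlation ρ;
h₀(t) = (shape/scale)·(t/scale)^(shape−1) (Weibull; this parameterization
is stated because conventions differ).  The marginal likelihood integrates
the frailty pair per cluster by adaptive Gauss–Hermite quadrature (9 nodes
per dimension by default; posterior modes found by damped Newton, nodes
centered and scaled by the mode's Hessian; a Laplace fallback is
selectable).  The tests verify the log-likelihood is stable to < 1e-4 when
moving from 9 to 15 nodes, that the score vanishes at the optimum, and
time-rescaling equivariance.

Variance inference: parameters are estimated on the log-variance scale;
the Wald test for σ² > 0 (and τ² > 0) is the one-sided z test of
σ̂²/SE(σ̂²) with SE via the delta method.  This is a pragmatic boundary
test, not a formal mixture test — estimates at the variance floor are
flagged and their p-value set to 1.  ρ is estimated by default; fixing
ρ = 0 (`fix_rho=0`) is recommended below ~50 clusters and is what the
simulation suites use (their generator has ρ = 0).  Cluster-level frailty
BLUPs (posterior modes) are returned; the baseline frailty û_i correlates
positively with the model's vehicle-arm growth rate when growth drives
hazard, which `frailty_growth_correlation` quantifies.

## Power analysis

Both engines simulate trials on the reference schedule — a 21-day trial
measured on days 0, 3, 6, 9, 12, 15, 18, 21 (8 points, twice-weekly;
configurable) — fit the corresponding model, and report the rejection rate
of the two-sided Wald test at α = 0.05 with a binomial Monte-Carlo CI.
Failed fits count as non-rejections (conservative) and the failure rate is
reported per cell.  Effects are specified as β₂/β₁ growth-rate reduction
ratios (longitudinal) or hazard ratios (survival).  Default 500
replications per cell at desk scale; 1000+ recommended for final curves.
The design-level finding the suite verifies: power is governed mostly by
the total mouse count, so 40×1:1, 20×2:2 and 13×3:3 land within a few
points of each other — the choice among them is about breadth of tumor
heterogeneity versus per-model precision, not statistics.

## The synthetic world, and what a green test establishes

`SimConfig` defaults ("cisplatin-like" preset):

| parameter | default | why |
| --- | --- | --- |
| β₀ | ln 150 | center of the 100–300 mm³ dosing-start range |
| β₁ | 0.06 /day | typical PDX log-growth rate (≈ 12-day doubling) |
| β₂ | −0.012 /day | a 20% growth-rate reduction |
| model (intercept, slope) sd | 0.25, 0.015 | between-model heterogeneity |
| mouse (intercept, slope) sd | 0.10, 0.014 | within-model heterogeneity |
| residual sd | 0.12 | caliper measurement noise on log volume |
| initial volumes | log-uniform 100–300 mm³ | dosing-start rule |
| dropout threshold | 3000 mm³ | euthanasia rule; later points truncated |
| Weibull shape, scale | 2.0, 12 days | accelerating hazard, ~12-day tripling |
| frailty σ², τ², ρ | 0.5, 0.2, 0 | strong growth, moderate response heterogeneity |
| planted gene effects | −0.02 / +0.02 per SD | clearly detectable prognostic/predictive pair |

The mouse-level slope sd (0.014) was sized so that a 1:1 design with ~36
models reaches ~90% power at a 20% growth-rate reduction, anchoring the
power curves to the published design scale for cisplatin-class effects.
The intercept random effects act through and on top of the log-uniform
baseline draw (the baseline carries measurement noise like any other
observation).  Dropout truncates a mouse's later measurements rather than
deleting the mouse, mirroring euthanasia at threshold; by construction it
is missing-at-random given the latent trajectory, which is exactly the
mechanism mixed models tolerate — the suite's green fits on truncated data
establish robustness to *this* mechanism, not to informative missingness
(e.g. toxicity-driven sacrifice correlated with response).

Other things the generator does not emulate: non-exponential growth
phases, measurement-day jitter between mice, correlated gene-gene
expression structure, and the polarized per-mouse responses of syngeneic
models under immunotherapy.  Consequences worth knowing: with iid noise
genes, the naive Spearman scan loses to the longitudinal scan in *false
positives on real, correlated transcriptomes*, but on the synthetic world
both methods find a strongly planted gene — the suite checks the scan's
ranking power and calibration, not the full real-data contrast.

## Numerical conventions and degenerate inputs

* R² of a constant log-volume series is reported as 0.
* Group endpoints raise typed errors on undefined inputs (zero baseline,
  zero vehicle RTV/area/slope) rather than returning NaN.
* REML criterion is non-finite off the feasible set (non-PSD covariances);
  the optimizer simply avoids it.  Three deterministic restarts; a
  ConvergenceError carries the start/criterion trace.
* Frailty variance floor 1e-6 (log-scale bound); hitting it flags the fit.
* All stochastic procedures require explicit seeds and are bit-reproducible
  under them; derived seeds stay below 2³¹.
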