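# Methods

## Density measures

A density map assigns each pixel a dense-tissue height h ≥ 0 (mm) inside a
breast mask.  For a threshold t (mm):

* dense volume above t: `a · Σ {h : h > t, in mask}` (a = pixel area,
  mm² → cm³);
* breast volume: `a · T · n_mask` with T the recorded compressed-breast
  thickness, treated as a uniform slab.  Volumetric density software
  estimates breast volume internally and may model the thinner breast
  periphery; that calibration is proprietary, so the uniform-slab
  definition is used here and stated wherever volumes are reported.  A
  per-pixel thickness grid is deliberately out of scope.
* VPD(t) = 100·dense_volume/breast_volume; APD(t) = 100·(count of in-mask
  pixels with h > t)/n_mask.

The inequality is strict (`h > t`), so at t = 0 genuinely zero-height
(purely fatty) pixels are not counted dense and APD(0) is well defined.
Both measures are nonincreasing in t and bounded in [0, 100] whenever
in-mask heights do not exceed T; these are tested properties, with a
per-pixel loop oracle on tiny maps.

Thresholds live on a grid within [0, 25] mm; the default grid is integer
millimetres 0..25 (the step is configurable — analyses state a range, not
a step).  Ties in best-AIC selection break toward the smaller threshold,
then volumetric before areal, so reports are deterministic.

Rasters are stored as 16-bit unsigned TIFF (PGM accepted) in 0.01 mm
units with an 8-bit 0/255 mask raster and a JSON sidecar
(`subject_id`, `pixel_area_mm2`, `breast_thickness_mm`,
`height_scale_mm_per_unit`); round trips are exact at the stored
quantization.

## Conditional logistic regression

Matched sets contain one case and m controls sharing the four matching
variables (age band, BMI band, HRT use, menopausal status).  Conditioning
on one case per set gives the softmax likelihood
ℓ(β) = Σ_s [x_case·β − log Σ_{j∈s} exp(x_j·β)], evaluated with within-set
max subtraction so linear predictors up to ~±700 stay finite.  Because
every set has exactly one case, no tie-handling (Breslow/Efron) arises.

Fitting is Newton–Raphson with analytic score and observed information,
step-halving if a step would decrease the likelihood, convergence at
max|score| < 1e-8 or relative log-likelihood change < 1e-12, at most 50
iterations; the covariance is the inverse observed information at the
optimum.  Perfect separation is detected either by a diverging
standardized coefficient (|β·sd| > 50) or by the log-likelihood
approaching its separation supremum of zero (ℓ > −1e-6·n_sets) — with
well-scaled predictors the score can meet its tolerance before any
coefficient grows large, so the likelihood criterion is the operative
one.  Failures raise naming the offending column; fits that merely hit
the iteration cap return `converged=False` and are excluded from model
selection.  The engine is cross-checked against an independent
conditional-logit implementation (statsmodels) and a fine grid-search
oracle in the tests.

Reported effects are standardized odds ratios exp(β_j·sd_j) with Wald 95%
CIs exp((β_j ± 1.96·se_j)·sd_j).  SDs are computed over all analyzed
subjects, cases and controls pooled (the convention is recorded in every
serialized fit, since other conventions — controls only, per-study —
exist).  AIC = 2k − 2ℓ̂ exactly; the model chi-square is 2(ℓ̂ − ℓ₀) against
β = 0, and nested models are compared by the likelihood-ratio test with an
upper-tail chi-square p-value.

The screen/interval analysis fits (x, x·I[interval]) where the indicator
is constant within a set (a set is one woman's case plus her controls, and
the mode of detection is the case's).  The screen log-OR is β₁, the
interval log-OR β₁+β₂ with SE from the full covariance, and the
interaction is tested by LR against the single-predictor model.

## Matched concordance and bootstrap

Per set with case score c and control scores u_j, concordance is
(#{u_j < c} + 0.5·#{u_j = c})/m; mC is the unweighted mean over sets
(sets here have constant size, so weighting is moot).  mC is invariant to
strictly increasing transforms and flips to 1−mC under negation when
tie-free.

Two scores are compared by resampling *sets* with replacement — the set is
the sampling unit because matching makes it the independent unit — with
B = 10,000 replicates by default.  The two-sided p is the percentile-style
count 2·min((1+#{Δ*≤0})/(B+1), (1+#{Δ*≥0})/(B+1)) capped at 1; the add-one
correction avoids a Monte-Carlo p of exactly zero.  (Whether the original
analyses used percentile, normal-approximation or studentized bootstrap is
not documented; percentile counting is implemented and labelled.)  mC
confidence intervals use the same set-bootstrap at percentiles 2.5/97.5.

## Demographic tables

Case/control category tables are tested with the likelihood-ratio
chi-square G² = 2 Σ O·ln(O/E), E from the product of margins, zero cells
contributing nothing, df = (rows−1)(cols−1).  Rows labelled exactly
"Unknown" are excluded before testing — this convention reproduces the
published HRT, ethnicity and parity p-values from the two screening
studies to the fourth decimal place (one of the five, HRT in the second
study, computes to 0.93195 where 0.9320 was printed — agreement within one
unit in the last digit); "Other/unknown" ethnicity is a substantive
category and is retained.  The published age and menopausal-status
p-values are *not* reproduced by any convention tried and are not used as
checks.  Medians/IQRs of continuous measures use linear-interpolation
quantiles (the upstream convention is unknown; these are display-only).

## Synthetic data

The generator emulates the data at the level the analysis consumes.

**Height maps.**  The breast mask is a half-ellipse flush against one
image edge (craniocaudal-view-like), default 80×60 pixels of 4 mm²
(2 mm spacing), semi-axes 36×54 px, T = 55 mm.  In-mask heights are
`clip(exp(μ_i + σ_i·G) − 0.5, 0, T)` where G is unit-variance Gaussian
noise smoothed to a 3-px correlation length; the 0.5 mm shift creates
exact-zero fatty pixels so APD(0) < 100 and varies.  Subjects differ via
μ_i ~ N(0.60, 0.40²) and log σ_i ~ N(log 1.15, 0.12²).  The defaults were
calibrated once so the population of simulated VPD(0) matches published
screening controls — median ≈ 5.0% with IQR ≈ 3.6–7.7% against the
published 4.90 (3.63–7.19) — and are not study-size dials.  The
two-dimensional (location *and* shape) subject heterogeneity matters:
with location-only heterogeneity every threshold's measure would be a
monotone function of a single latent variable and thresholds could not be
distinguished by fit.

**Fast measure sampling.**  When maps themselves are not needed,
`simulate_measures` draws each subject's height distribution at 96
independent points — roughly the number of effectively independent
patches of the default correlated map — and computes VPD/APD from those
samples exactly as the map pipeline would.  This preserves the sampling
noise and cross-threshold correlation structure that drive threshold
identifiability, at a small fraction of the cost; large simulation
studies use it, map-level tests and the varying-threshold analysis use
real maps.

**Subjects and matching.**  Covariates are independent multinomials whose
default frequencies are the two studies' printed control-arm
distributions.  Matching is exact on the four bands (the originating
studies matched "approximately"; exactness simplifies validation and is a
stand-in, not a claim about the original matching algorithm).  Within
each stratum, disjoint groups of m+1 are formed and one member is
labelled the case with probability exp(β·x_i)/Σ_j exp(β·x_j) on the
standardized designated predictor.  This within-group softmax — rather
than a marginal logistic model plus post-hoc matching — makes the
conditional likelihood exactly the true likelihood, so parameter-recovery
checks have a clean target.  Study-2-style cohorts first designate each
set screen or interval (default split 50/50) and use the mode-specific β.
Leftover subjects in a stratum are unused; strata smaller than m+1 are
skipped with a count reported in the error if nothing can be formed.

**What the generator does not emulate:** mammographic texture, lesions,
pectoral muscle, scanner effects, informative missingness, approximate or
caliper matching, correlation between demographics and density, or
risk-model scores.  Passing tests therefore demonstrate the statistical
machinery is correct under its own assumptions, not that the thresholded
measures are validated on real mammograms.

## Varying-threshold sensitivity analysis

Each woman's threshold is t_i = clip(γ₀ + γ₁·age + γ₂·BMI + γ₃·T_i +
γ₄·V_i, 0, 25) with covariates standardized; age and BMI enter as band
midpoints (47, 52, 57, 62, 67, 72 and 22.5, 27, 33), thickness and breast
volume come from the map.  γ is found by coordinate descent over fixed
grids (intercept 0–12 mm by 2; slopes ±3, ±1.5, 0 per SD), minimizing the
one-predictor conditional-logit AIC with the measure re-evaluated from
each woman's map at her own threshold (sorted heights + suffix sums make
that O(log n_pixels) per evaluation).  No estimation method is documented
for this analysis upstream; the grid search is a labelled, deterministic
stand-in with no claim of global optimality.  With all slope grids {0} it
reduces exactly to the fixed-threshold sweep.

## Problem sizes and seeds

Simulation studies in the tests and the acceptance script use 1,000
matched sets × 200 replicates for parameter recovery, 1,000 sets × 50 for
threshold recovery, 900 sets × 200 for per-mode OR recovery, 300 sets ×
1,000 for interaction null calibration, 250 sets × 200 cohorts × B=500
for bootstrap null calibration, and 1,000 small maps for measure
properties — sizes chosen to keep Monte-Carlo error small relative to the
bands being checked while remaining a desk-scale computation.  Every
stochastic operation takes an explicit seed; a master seed fans out
through `numpy.random.SeedSequence` (`spawn_seeds`), and the CLI records
all stage seeds plus the package version in a run manifest.

## Known limitations

* Breast volume is a uniform slab; peripheral thinning is ignored.
* "Unknown" handling in the G² tests is a reconstruction that matches
  most, not all, published p-values (see above).
* The bootstrap p convention and the χ² definition (2(ℓ̂−ℓ₀)) are the
  standard choices but are labelled assumptions, not documented facts
  about the original analyses.
* Real-data effect sizes appear only as generating parameters for
  simulations; nothing here reproduces the original cohorts' fitted
  values, which would require the undeposited mammograms.
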