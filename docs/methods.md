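# Methods

`ngdwi` implements a complete analysis chain for multi-b-value
diffusion-weighted MRI (DWI) of tumors: voxel-wise fitting of one Gaussian
and five non-Gaussian diffusion signal models, whole-VOI first-order
histogram features, a two-rater reproducibility filter, LASSO + logistic
diagnostic-model construction, and discrimination/calibration/clinical-utility
evaluation.  A synthetic phantom-cohort generator supplies ground truth for
every stage, so the full chain is testable without patient data.

## Signal models

All models act on the scalar b-value axis (no directional encoding).  With
S₀ the unweighted signal and b in s/mm²:

| model | equation | parameters |
|---|---|---|
| mono-exponential | S₀·exp(−b·ADC) | ADC |
| IVIM | S₀·[f·exp(−b·D*) + (1−f)·exp(−b·D)] | f, D, D* |
| DKI | S₀·exp[−bD + (1/6)·K·(bD)²] | D, K |
| SEM | S₀·exp[−(b·DDC)^α] | DDC, α |
| FROC | S₀·exp[−D·μ^{2(β−1)}·(γG_dδ)^{2β}·(Δ − ((2β−1)/(2β+1))δ)] | D, β, μ |
| CTRW | S₀·E_α[−(bD)^β] | D, α, β |

Diffusivities are carried internally in mm²/s and reported on maps in
10⁻³ mm²/s (μm²/ms), the scale on which such maps are conventionally
printed.  Every non-Gaussian model reduces exactly to the mono-exponential
at its Gaussian limit (f = 0, K = 0, α = 1, β = 1); this is enforced by
tests at 10⁻¹² relative tolerance and anchors the FROC timing convention
(below).

### FROC timing and identifiability

The FROC exponent involves the gradient duration δ, separation Δ, and the
per-b product γG_dδ.  Acquisition protocols vary gradient amplitude at
fixed timing, so the package derives γG_dδ per b from the Stejskal-Tanner
relation b = (γG_dδ)²(Δ − δ/3) with defaults δ = 20 ms, Δ = 40 ms
(overridable).  This makes β = 1 collapse exactly onto exp(−bD).

A consequence worth stating explicitly: under this (physically standard)
convention the FROC exponent is −[D·μ^{2β−2}·T(β)/T_diff^β]·b^β, so D and μ
enter the decay only through a single composite amplitude.  They are
**exactly jointly unidentifiable** from scalar-b data; fitted μ values ride
a flat likelihood ridge anchored near the initialization (5 μm is used).
Accuracy claims for FROC are therefore made for S₀, β and the composite
D·μ^{2(β−1)}.  Published voxel-wise μ maps from scalar-b protocols should
be read with the same caveat.

### Mittag-Leffler numerics

The CTRW model needs E_α(z) only on the completely monotone branch
(0 < α ≤ 1, z ≤ 0).  The implementation uses:

* the defining power series for |z| ≤ 0.5 (no cancellation there);
* numerical inversion of the Laplace transform s^{α−1}/(s^α + x) on a
  64-node Talbot contour otherwise.  For x > 0 the integrand is analytic on
  the cut plane (the zeros of s^α + x lie off the principal branch), so the
  trapezoid rule converges geometrically and delivers ≤10⁻⁸ relative error
  over α ∈ [0.3, 1], z ∈ [−50, 0] — verified against an mpmath
  extended-precision series/spectral-integral reference in the tests.

The textbook alternative — power series plus the asymptotic expansion
−Σ z^{−k}/Γ(1−αk) for large |z| — was rejected: the asymptotic series'
optimal truncation error is ~10⁻⁴ for α ≈ 0.9 at z ≈ −10, orders of
magnitude short of the accuracy target, and the plain series loses all
precision to cancellation for moderately large |z|.

## Voxel-wise fitting

Each voxel is fitted by bounded nonlinear least squares on a normalized
signal (divided by the voxel's maximum), with diffusivities optimized in
10⁻³ mm²/s so all parameters are O(0.1-10):

* initialization: weighted log-linear mono-exponential fit (weights ∝
  signal, approximating unweighted NLLS on the linear scale); a weighted
  quadratic log fit for DKI; a segmented start for IVIM (log-linear D on
  b ≥ 200 s/mm², f from the extrapolated intercept); shape parameters at
  α = β = 0.9, K = 0.5, f = 0.1, μ = 5 μm, D* = 15 μm²/ms;
* bounds: ADC/D/DDC ∈ (10⁻³, 5), D* ∈ (3, 100) (all 10⁻³ mm²/s),
  f ∈ [0, 0.5], K ∈ [0, 3], α, β ∈ (0.01, 1], μ ∈ (10⁻⁴, 0.02) mm —
  physiologic ranges that also prevent exchange of the D/D* roles;
* solver: models with closed-form Jacobians (ADC, IVIM, DKI, SEM) run
  through a batched, bounds-projected Levenberg-Marquardt engine that
  assembles the per-voxel normal equations as one stacked array and solves
  all voxels of a volume per iteration (per-voxel damping grows/shrinks on
  rejected/accepted steps, trust-region style).  FROC and CTRW use scipy's
  trust-region-reflective solver per voxel with finite-difference
  Jacobians.  Single-voxel fits are the n = 1 case of the same code path,
  so per-voxel and per-volume results agree exactly;
* non-converged voxels are retried up to 3 times from seeded random
  initializations within bounds; everything is deterministic given the
  seed;
* IVIM uses b ≤ 1000 s/mm² by default to limit kurtosis contamination at
  high b; other models use all b-values (configurable).

Degenerate voxels — non-positive S(0), all-zero series, or decays whose
upper-half-b mean exceeds the lower-half mean — are flagged, carry
bounds-midpoint parameters, and are excluded from histogram analysis.

Measured accuracy under the default 11-b scheme (0-2500 s/mm²): noiseless
round-trips recover parameters to ≤0.1%; with Rician noise at SNR 50 and
1000 voxels, the median relative bias is ≤5% for rate parameters and ≤10%
for shape parameters (the acceptance suite recomputes both).

## Histogram features

Eighteen first-order statistics per metric map over the VOI (after
removing excluded sub-regions such as necrosis, and degenerate-fit voxels):
energy, total energy (voxel volume × energy), entropy, minimum, 10th/90th
percentile, maximum, mean, median, interquartile range, range, mean
absolute deviation, robust MAD (on the 10-90 percentile core), RMS,
skewness, kurtosis, variance, uniformity.  Conventions: percentiles use
linear interpolation between closest ranks; skewness/kurtosis use
population moments (kurtosis non-excess — a normal distribution scores 3;
zero-variance input scores 0 for both); entropy/uniformity use a fixed
64-bin discretization spanning the in-VOI min-max, which is scale-free
across metrics with heterogeneous units.  The exact 18-feature list is a
documented choice following the standard radiomics first-order set
(standard deviation omitted as redundant with variance); with 14 maps
(ADC + 13 non-Gaussian metrics) it yields 252 features per participant.

## Reliability filter

Features are extracted twice, once per rater's VOI, and screened with the
two-way random-effects, absolute-agreement, single-measurement ICC —
ICC(2,1).  Absolute agreement (rather than consistency) is the defensible
default for segmentation reproducibility because systematic offsets between
raters should count against a feature.  Features with ICC < 0.80 are
dropped before any supervised step.

## Diagnostic models

Per diffusion model: L1-penalized logistic regression over a 100-point
log-spaced λ grid from λ_max = max|Xᵀ(y−ȳ)|/n down to 10⁻³λ_max, features
standardized inside each of 10 stratified CV folds, selecting the λ that
minimizes mean CV binomial deviance (λ_min rather than the 1-SE rule; the
grid walk stops early once the CV deviance has not improved for 30
consecutive λ, which cannot change the argmin).  Selected features are
refit by unpenalized maximum-likelihood logistic regression on the raw
scale with Wald p-values; perfect separation falls back to a lightly
ridge-stabilized IRLS fit, flagged.  Significant features (p < 0.05) are
pooled across models; of every pair with |Spearman ρ| > 0.70 the lower-ICC
member is dropped (greedy, most-correlated pair first, with an audit
trail); the survivors form the combined model.  Two task labelings are
supported, mirroring the clinical questions: invasion (class 1 =
muscle-invasive-like) and grade (class 1 = high-grade-like, within the
non-invasive subset).

## Evaluation

* AUC: Mann-Whitney pairwise estimate (ties half-weighted), exactly equal
  to brute-force pair counting.
* DeLong structural components give the AUC variance (CI on the AUC scale,
  clipped to [0, 1]) and the paired z-test between two markers on the same
  subjects.
* Operating point: threshold from the observed score set maximizing
  Youden's J, ties broken toward sensitivity.
* Decision curves: NB(pt) = TP/N − (FP/N)·pt/(1−pt) on a 0.01-0.99 grid,
  with treat-all and treat-none references.
* Hosmer-Lemeshow: equal-count deciles of predicted risk, df = g − 2.
  Note this reference distribution is derived for probabilities *fitted*
  on the same data; applied to externally specified true probabilities the
  statistic is ~χ²_g and the test over-rejects (~11% at α = 0.05 with
  g = 10) — the package's calibration simulations therefore fit the
  logistic model per replicate.
* Calibration error: bootstrap-averaged MAE between an equal-count-binned,
  linearly interpolated observed-frequency curve and the identity,
  evaluated at the observed predicted probabilities.  This is a documented
  analogue of smoother-based calibration MAE, not a reimplementation of
  any specific package's smoother.
* Cohort balance: Mann-Whitney U (tie-corrected normal approximation,
  no continuity correction) for continuous variables; chi-square without
  continuity correction for categorical, switching to Fisher's exact for
  2×2 tables with any expected cell < 5.

## Synthetic cohorts

The phantom generator emulates the study design the chain targets:

* 11 b-values (0, 50, 100, 150, 200, 500, 800, 1000, 1500, 2000,
  2500 s/mm²);
* ellipsoidal tumors (default semi-axes 2.5-4 voxels on a 20×20×10 grid of
  2 mm voxels — desk-scale sizes chosen so the full pipeline runs in
  minutes; tests use 1.5-2.5 on 14×14×8) with optional interior "necrosis"
  ellipsoids exported as exclusion masks;
* per-patient parameter means drawn from class-conditional distributions
  (normal/lognormal/beta), within-tumor texture from a smoothed Gaussian
  field (σ = 1 voxel, CV 5%), and an optional two-component mixture that
  shifts a random subset of voxels upward to inject positive skewness —
  the mechanism that makes skewness features discriminative;
* class contrasts: the invasion-like preset lowers tissue diffusivity by
  30% and raises the skew-mixture weight (0.25 vs 0.05) in class 1; the
  grade-like preset raises the IVIM perfusion fraction (0.18 vs 0.10) and
  lowers D;
* Rician noise √((S+σε₁)² + (σε₂)²) with σ = S₀/SNR, SNR 50 by default
  (a reasonable body-DWI figure; chosen once, stated here because no
  empirical value was available to copy);
* a second-rater mask from random boundary erosion/dilation with a Dice
  floor of 0.85.

What the phantoms do **not** emulate: anatomy (bladder wall, lumen,
neighboring organs), partial-volume effects at the tumor boundary, scanner
artifacts (distortion, ghosting, eddy currents), background tissue outside
the VOI (rater-B voxels beyond the phantom see pure noise and are caught by
the degenerate-voxel flag rather than by realistic adjacent tissue), or
between-scanner differences beyond independent noise realizations.
Passing end-to-end tests therefore demonstrates that the chain recovers
designed contrasts and stays calibrated under its own assumptions — not
that any particular clinical AUC would be reproduced.

## Problem sizes

The end-to-end controls use 100 training and 25 testing patients per class
(mirroring a realistic two-scanner cohort split at roughly 4:1), tumors of
~15-60 voxels, and two fitted models (ADC + DKI) as the pipeline carrier;
the noise-recovery studies use 1000 voxels per model; resampling studies
use 500 replicates.  These sizes are the package's chosen desk-scale study
conditions and are stated in the relevant docstrings.

## Known limitations

* FROC μ is not separately identifiable (see above).
* The IVIM perfusion compartment is weakly determined at SNR 50 with a
  single signal average; convergence flags are honest about this (~90%
  under noise) and estimates remain usable (median bias within bounds).
* The combined model falls back to intercept-only when no feature is
  significant in any per-model fit (expected and correct on null cohorts).
* Decision-curve and calibration outputs carry no confidence bands.
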