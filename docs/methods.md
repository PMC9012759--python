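# Methods

`sertpet` implements the quantitative core of a serotonin-transporter PET
study design: dynamic [11C]DASB scans are reduced to regional
non-displaceable binding potential (BP_ND) with reference-tissue kinetic
models, regional values are compared across groups and correlated with
clinical covariates, and a multivariate disease pattern is sought with
scaled-subprofile-model PCA (SSM/PCA). Because patient data of this kind is
not publicly distributable, the package includes a first-class synthetic
cohort generator that reproduces the statistical structure such a study
assumes, so every stage is exercised end to end by tests.

## Kinetic models

The simplified reference tissue model (SRTM) writes the target-tissue
concentration as

    C_T(t) = R1 · C_R(t) + (k2 − R1·k2a) · C_R(t) ⊗ exp(−k2a·t),

with R1 = K1/K1′ the delivery ratio, k2 the target efflux rate (1/min) and
k2a = k2/(1 + BP_ND) the apparent efflux, so BP_ND = k2/k2a − 1. SRTM2
fixes the reference-region efflux k2′ = k2/R1 at a value estimated once
from a high-binding region (the striatum for [11C]DASB; the cerebellum
excluding vermis is the reference), reducing each target fit to two free
parameters:

    C_T(t) = R1 · C_R(t) + R1·(k2′ − k2a) · C_R(t) ⊗ exp(−k2a·t),
    BP_ND = R1·k2′/k2a − 1.

Both models are solved by **basis functions**: for fixed k2a the model is
linear in the remaining coefficients, so the fit is a 1-D search over a
log-spaced k2a grid (default 0.006–0.6 /min, 128 points) with weighted
linear least squares per grid point, followed by bounded scalar
minimisation between the neighbours of the best grid point. Frame-duration
weights are the default (uniform weights available); duration weighting is
the common convention for framed PET data. The basis-function optimum is
verified in tests against a 10× denser brute-force grid.

### Numerics

* Convolutions are evaluated on a fine uniform grid (default 0.05 min) with
  the exact piecewise-linear exponential update, so no quadrature error
  accrues beyond the linear representation of the input curve.
* Measured TACs are frame averages, not point samples. For fitting, the
  continuous reference curve is reconstructed as the piecewise-linear curve
  through the frame mid-times whose frame averages reproduce the measured
  values exactly (a small linear system). Because the model is linear in
  C_R and the frame-averaging operator is linear, average-matching makes
  the reconstruction error nearly orthogonal to the fit: noiseless
  forward-simulated parameters are recovered to better than 0.05% across
  BP_ND ∈ [0.25, 4] and R1 ∈ [0.7, 1.3].
* Negative BP_ND estimates are clamped to zero and counted; the count is
  logged in run reports. Clamping keeps downstream square-root transforms
  and pattern analysis on their intended domain.
* Voxel-wise maps use the same basis grid plus a parabolic refinement of
  log k2a from the three bracketing grid points, then one exact re-solve at
  the refined k2a per voxel; noiseless phantom medians recover truth within
  1%.

## Synthetic data

The generator emulates the cohort structure of a three-group study:
dopa-responsive dystonia (DRD, n = 10), cervical dystonia (CD, n = 14) and
healthy controls (n = 12); 13 bilateral VOIs plus four raphe VOIs
(subject- and atlas-defined dorsal/median raphe); clinical instruments
(BAI, BDI, ESS, FSS, PSQI, CGI, BFMDRS, age) on their integer scales with
group medians taken from the study's demographics table; psychiatric
lifetime-diagnosis prevalence 60/79/33% per group; levodopa use in 80% of
DRD subjects (median 150 mg/day, range 100–400).

* **Reference input.** Real studies measure the cerebellum curve; the
  generator needs an analytic stand-in. We use a saturating bolus with
  bi-exponential washout, C_R(t) ∝ (1 − e^(−t/τ))^α (w₁e^(−μ₁t) +
  (1−w₁)e^(−μ₂t)), peaking near 3 min at 50 kBq/mL — smooth, realistic and
  cheap to evaluate.
* **Frame schedule.** The 23-frame [11C]DASB framing (7×10 s, 2×30 s,
  3×1 min, 2×2 min, 2×3 min, 5×5 min, 2×10 min). The printed products sum
  to 3610 s rather than a round 60 min; the generator follows the printed
  schedule.
* **Noise.** Additive zero-mean Gaussian with per-frame SD ∝
  √(value/duration), the standard count-statistics surrogate for TAC
  noise. The true noise magnitude of the scanner protocol is not
  specified, so the scale is a free configuration parameter (pipeline
  default 0.3, giving a few percent error on late frames).
* **Dependence.** Cross-variable structure is a Gaussian copula: latent
  multivariate-normal draws with Pearson correlation 2·sin(πρ_s/6) for a
  requested Spearman ρ_s, pushed through each marginal (normal for BP_ND;
  rounded, clipped normal for integer instrument scores; thresholded for
  binary flags). Defaults: PSQI↔sDRN ρ_s = +0.45 (worse sleep, higher
  dorsal-raphe binding) and FSS↔sMRN ρ_s = −0.45 (more fatigue, lower
  median-raphe binding; chosen weaker than the within-patient-group value
  such a study reports, since it is applied cohort-wide), plus a −0.08
  hippocampal BP_ND shift in psychiatrically flagged subjects. Requested
  rank correlations are reproduced within ±0.05 at n = 2000. Zeroing these
  fields (`CohortConfig.null()`) yields exchangeable groups.
* **Pattern embedding.** For pattern-recovery experiments,
  `embed_pattern_maps` rebuilds the profile as baseline + score·weights +
  noise with expression scores N(gap, 1) in the disease group and N(0, 1)
  elsewhere, so `gap` is the group separation in within-group score SDs.

What the generator does **not** emulate: spatial autocorrelation and
partial-volume effects of real parametric maps, scanner- and
reconstruction-specific noise spectra, frame-to-frame motion, arterial
input variability, or non-Gaussian tails of clinical scores. Passing tests
therefore establish that the estimators and statistics behave correctly on
data with the assumed structure — not that a specific clinical finding
would replicate.

## VOI statistics

* Homologous left/right regions are combined by volume-weighted averaging.
* The subject-based raphe VOI keeps the ⌈0.8·N⌉ highest-uptake voxels
  within a sphere; ties break by distance to the centre, then lexicographic
  voxel index, making the mask deterministic. The atlas-based raphe VOI is
  a fixed sphere at given coordinates.
* Group comparisons are two-sided Mann–Whitney U tests: exact enumeration
  when both groups have ≤ 10 observations and no ties, otherwise the tie-
  and continuity-corrected normal approximation. The Bonferroni family is
  the 13 bilateral VOIs (threshold 0.05/13 ≈ 0.004); raphe VOIs are
  correlation targets, not part of this family.
* Clinical correlations are Spearman rank correlations; the
  Benjamini–Hochberg family is all (score × VOI) pairs tested in one call,
  making the family explicit and configurable. Constant inputs yield a
  flagged undefined ρ rather than silent omission.
* The ANCOVA fits sqrt(BP_ND) ~ group + psychiatric flag (OLS, type-II
  partial F for the group effect). The square root is defined because
  kinetics clamps BP_ND at zero upstream. A flag perfectly confounded with
  group is reported as a flagged singular design.
* Two-sided p-values throughout; sidedness is not configurable.

## SSM/PCA

The subjects × regions profile is double-centered —
r_ij = x_ij − rowmean_i − colmean_j + grandmean — and decomposed through
the subject-by-subject covariance matrix (eigenvectors projected back to
region space and unit-normalised; double centering leaves at most
min(n, p) − 1 components). The leading components covering 50% of the
variance enter a forward stepwise search: at each step the candidate
component minimising the AIC of a logistic regression of class on subject
component scores is added. Design choices made where the method family
leaves them open:

* **No log transform by default.** The classic SSM log step is provided as
  an option with a configurable positive offset, but BP_ND values near
  zero make it fragile, so the default operates on raw BP_ND.
* **Logistic AIC.** AIC needs a likelihood; logistic regression of class
  on scores is the established choice for two-group pattern derivation.
  Perfect separation triggers a bias-reduced (Jeffreys-penalised, Firth)
  fallback, flagged in the pattern metadata.
* **At least one component.** The first component (the single-PC model
  with the lowest AIC) is always included even when it does not beat the
  intercept-only model, because the method must always produce a pattern —
  a study reports a pattern and its (possibly chance-level) discrimination
  rather than "no pattern". Further components are added only while AIC
  strictly decreases; ties break toward the smaller model.
* **Sign convention.** The pattern is oriented so the disease class has
  the higher mean expression score; PC signs are otherwise arbitrary.
* **Masking.** Features with zero variance, or mean below a configurable
  BP_ND floor, are dropped before centering.

Expression scores are inner products of the pattern with the subject's
residual profile, centered against the **derivation-set** feature means
(prospective convention — scoring a new subject uses no information about
other test subjects). Leave-one-out cross-validation re-derives the whole
chain (centering, PCA, selection, stepwise search) on each fold of n − 1
subjects, aligns the fold pattern's sign to the full-data pattern
(positive correlation) and scores the held-out subject prospectively. ROC
curves use a full threshold sweep; the trapezoidal AUC equals the
Mann–Whitney U statistic divided by n₁·n₂ (ties contribute one half), an
identity asserted exactly in tests. Run reports carry both raw and
z-scored subject scores, since the score normalisation convention differs
between SSM implementations.

Under the null (no group effect), the LOOCV AUC of this procedure is close
to, but not exactly, 1/2: the fold-pattern sign alignment uses the
full-data pattern, whose orientation was fixed on all subjects including
the held-out one, giving a small optimistic bias (mean ≈ 0.54 for groups
of 10 and 12 over 13 features), while orienting each fold only on its own
derivation set biases the other way (≈ 0.46). The alignment convention
follows the cross-validation design above; the calibration suite checks
the mean stays within [0.45, 0.55].

## Problem sizes

Tests and the acceptance script are Monte-Carlo experiments with fixed
seeds. The null-calibration experiments use 100 replicates in the test
suite and 9000 in the acceptance script (per-replicate LOOCV AUC on 22
subjects has an SD near 0.15, so the replicate count pins the mean to
±0.0016);
type-I-error checks use 1000 replicates; stepwise-vs-exhaustive AIC
comparisons use 200 random instances with ≤ 5 candidate components;
copula calibration uses n = 2000 subjects. Pattern-recovery
demonstrations embed an expression gap of 2.5 within-group SDs with
feature noise SD 0.05.

## Known limitations

* SRTM2 equivalence with any proprietary vendor implementation (voxel
  weighting, spatial constraints on k2a) is not claimed.
* Voxel-wise statistical mapping (SPM-style t-maps with cluster-level
  family-wise-error correction) is out of scope; group inference here is
  VOI-level only.
* The generator produces regionally independent noise; statistics that
  depend on spatial covariance of real maps are not represented.
* Arterial-input models, Logan graphical analysis, partial-volume and
  motion correction are not implemented.
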