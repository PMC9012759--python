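# sertpet

Serotonin-transporter PET analysis in Python: reference-tissue kinetic
modelling of dynamic [11C]DASB scans to non-displaceable binding potential
(BP_ND), VOI-level group statistics and clinical correlations, and
scaled-subprofile-model PCA (SSM/PCA) disease-pattern derivation with
leave-one-out cross-validation and ROC analysis.

The package targets researchers analysing regional serotonergic binding in
clinical cohorts — for example dystonia patients versus controls — where
the pipeline runs from per-frame time–activity curves (TACs) to a tested
statistical report. Because such patient data cannot be redistributed, a
synthetic cohort generator with the same statistical structure (three
groups, 13 bilateral VOIs plus raphe nuclei, clinical covariates,
configurable effects) is part of the package, and every stage of the
pipeline is validated against it.

## The models

**SRTM / SRTM2.** The simplified reference tissue model describes a target
region by

    C_T(t) = R1·C_R(t) + (k2 − R1·k2a)·C_R(t) ⊗ e^(−k2a·t),   k2a = k2/(1+BP_ND)

with cerebellum as reference region C_R. SRTM2 fixes the reference efflux
k2′ = k2/R1 from a single striatal fit and re-fits every region (or voxel)
with two free parameters, BP_ND = R1·k2′/k2a − 1. Fits use basis functions
in k2a (log-spaced grid + local refinement) with frame-duration weights.

**SSM/PCA.** Subject × region BP_ND profiles are double-centered, the
subject-covariance PCA components covering 50% of variance enter a forward
stepwise search minimising the AIC of a logistic regression of group on
subject scores, and the lowest-AIC combination is the disease pattern.
Subjects express the pattern as the inner product with their residual
profile; LOOCV re-derives the pattern per fold and an ROC/AUC summarises
discrimination.

**Statistics.** Mann–Whitney U group comparisons with a Bonferroni
threshold over the 13-VOI family (0.05/13 ≈ 0.004), Spearman clinical
correlations with Benjamini–Hochberg adjustment, a psychiatric-subgroup
comparison, and an ANCOVA on √BP_ND adjusting for psychiatric
co-morbidity.

## Worked example

```python
import numpy as np
from sertpet import (
    make_frame_schedule, DASB_FRAMING, simulate_reference_tac,
    simulate_target_tac, KineticParams, estimate_k2prime, fit_srtm2,
    simulate_cohort, CohortConfig, derive_pattern, loocv_patterns, roc,
)
from sertpet.tac import TimeActivityCurve

# 1. kinetics: simulate a striatal TAC and recover its parameters
sched = make_frame_schedule(DASB_FRAMING)          # 23 frames, 60.2 min
ref = simulate_reference_tac(sched)                # cerebellum curve
truth = KineticParams(r1=0.95, k2=0.95 * 0.07, bp_nd=2.0)
tac = simulate_target_tac(ref, truth)
ref_m = TimeActivityCurve(sched, ref.values, "cerebellum")
tac_m = TimeActivityCurve(sched, tac.values, "putamen")
k2p = estimate_k2prime(tac_m, ref_m)
fit = fit_srtm2(tac_m, ref_m, k2p)
print(f"k2' = {k2p:.4f} /min; SRTM2: R1 = {fit.params.r1:.3f}, "
      f"BP_ND = {fit.params.bp_nd:.3f}")

# 2. cohort: a null study (no group effects) and its disease pattern
cohort = simulate_cohort(CohortConfig().null(), seed=0)
mask = cohort.groups.isin(["DRD", "control"])
profile = cohort.profile.loc[mask, cohort.profile.columns[:13]]
labels = cohort.groups.loc[mask]
pattern = derive_pattern(profile, labels, "DRD")
scores = loocv_patterns(profile, labels, "DRD")
print("included PCs:", pattern.included_pcs,
      f"LOOCV AUC = {roc(scores, 'DRD').auc:.3f}")
```

prints

```
k2' = 0.0700 /min; SRTM2: R1 = 0.950, BP_ND = 2.000
included PCs: (1,) LOOCV AUC = 0.275
```

The kinetic fit recovers the simulated parameters essentially exactly
(noiseless data). The pattern analysis on a null cohort still produces a
pattern — the method always returns its best combination — but the
cross-validated AUC is uninformative, which is exactly what it should be
when no group difference exists: single null cohorts scatter widely around
chance, and averaged over many null cohorts the LOOCV AUC is ~0.5 (see
below).

Short narrative scripts, one per capability, live in `examples/`; the
`sertpet` console command (`simulate`, `fit`, `voi-stats`, `pattern`,
`run-study`) exposes the same pipeline from the shell.

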