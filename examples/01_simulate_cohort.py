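"""Simulate a three-group study cohort and inspect its structure.

Draws 10 DRD, 14 CD and 12 control subjects with BP_ND over 13 bilateral
VOIs plus four raphe VOIs, integer clinical scores, and the configured
effects (hippocampal shift with psychiatric history, sleep-raphe and
fatigue-raphe rank correlations).
"""

from scipy.stats import spearmanr

from sertpet import CohortConfig, simulate_cohort

cohort = simulate_cohort(CohortConfig(), seed=0)

print("groups:", cohort.groups.value_counts().to_dict())
print("\nBP_ND means per VOI (high binding in striatum/thalamus/raphe):")
print(cohort.profile.mean().round(2).to_string())

rho, p = spearmanr(cohort.clinical["PSQI"], cohort.profile["sDRN"])
print(f"\nsleep quality (PSQI) vs dorsal raphe binding: rho = {rho:.2f} "
      "(configured +0.45; small-sample estimate)")

flags = cohort.clinical["psychiatric_lifetime"]
print("hippocampal BP_ND median, psychiatric vs not: "
      f"{cohort.profile.loc[flags, 'hippocampus'].median():.2f} vs "
      f"{cohort.profile.loc[~flags, 'hippocampus'].median():.2f} "
      "(configured shift -0.08)")
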