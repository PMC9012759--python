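"""Derive an SSM/PCA disease pattern and validate it by LOOCV/ROC.

Embeds a known covariance pattern into a null cohort with a 2.5-SD
expression gap, re-derives it (double-centering, covariance PCA,
50%-variance selection, forward-AIC stepwise combination), and checks
recovery and cross-validated discrimination.
"""

import numpy as np

from sertpet import (
    CohortConfig, derive_pattern, embed_pattern_maps, loocv_patterns, roc,
    simulate_cohort,
)
from sertpet.synth import BILATERAL_VOIS

cfg = CohortConfig(group_sizes={"DRD": 10, "control": 12},
                   vois=dict(BILATERAL_VOIS)).null()
cohort = simulate_cohort(cfg, seed=42)

rng = np.random.default_rng(7)
weights = rng.standard_normal(13)
weights /= np.linalg.norm(weights)
emb = embed_pattern_maps(cohort, weights, expression_gap=2.5, seed=3,
                         noise_sd=0.02)

pattern = derive_pattern(emb.profile, emb.groups, "DRD")
r = np.corrcoef(pattern.weights.to_numpy(), weights)[0, 1]
print(f"included PCs: {pattern.included_pcs}, AIC = {pattern.aic:.2f}")
print(f"correlation of derived pattern with embedded weights: r = {r:.3f}")

scores = loocv_patterns(emb.profile, emb.groups, "DRD")
auc = roc(scores, "DRD").auc
print(f"LOOCV ROC AUC = {auc:.3f}  (> 0.9 means the pattern generalises "
      "across held-out subjects)")
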