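"""VOI construction and univariate statistics for BP_ND profiles.

Covers the study's region-level analysis: volume-weighted bilateral
averaging, subject-based raphe VOIs (the 80% highest-uptake voxels within a
sphere) and atlas-based raphe VOIs at fixed coordinates, Mann-Whitney group
comparisons with a Bonferroni threshold over the 13-VOI family,
Spearman clinical correlations with Benjamini-Hochberg adjustment, the
psychiatric-subgroup comparison, an ANCOVA on square-root-transformed
BP_ND adjusting for psychiatric co-morbidity, and confounder screens
(levodopa dose, age, genotype).

All tabular results are tidy DataFrames with columns
(feature, statistic, p, p_adj, method, ...); two-sided p-values throughout.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
import statsmodels.api as sm
import statsmodels.formula.api as smf
from statsmodels.stats.multitest import multipletests

__all__ = [
    "VOIDefinition",
    "bilateral_average",
    "sphere_indices",
    "raphe_voi_subject",
    "raphe_voi_atlas",
    "voi_mean",
    "bonferroni_threshold",
    "compare_groups",
    "correlate_clinical",
    "compare_by_psychiatry",
    "ancova_sqrt",
    "confounder_screen",
    "VOI_FAMILY_SIZE",
]

#: Size of the Bonferroni family: the 13 bilateral VOIs.  Raphe VOIs are
#: correlation targets under the BH family, not part of this count.
VOI_FAMILY_SIZE = 13


@dataclass
class VOIDefinition:
    """A volume of interest: named voxel set on a 3-D grid."""

    name: str
    indices: np.ndarray  # (n, 3) integer voxel indices
    voxel_volume_mm3: float = 8.0  # 2-mm isotropic default
    laterality: str = "none"  # left | right | bilateral | none

    def __post_init__(self) -> None:
        self.indices = np.atleast_2d(np.asarray(self.indices, dtype=int))
        if self.indices.size == 0:
            raise ValueError(f"VOI {self.name!r} is empty")

    @property
    def n_voxels(self) -> int:
        return self.indices.shape[0]

    @property
    def volume_mm3(self) -> float:
        return self.n_voxels * self.voxel_volume_mm3

    def mask(self, shape: tuple[int, int, int]) -> np.ndarray:
        m = np.zeros(shape, dtype=bool)
        m[tuple(self.indices.T)] = True
        return m


def bilateral_average(
    left_value: float, right_value: float, left_volume: float, right_volume: float
) -> float:
    """Volume-weighted average of homologous left/right region values."""
    if left_volume <= 0 or right_volume <= 0:
        raise ValueError("region volumes must be positive")
    return (left_volume * left_value + right_volume * right_value) / (
        left_volume + right_volume
    )


def sphere_indices(
    shape: tuple[int, int, int], center: tuple[float, float, float], radius: float
) -> np.ndarray:
    """Voxel indices within a sphere (voxel units), clipped to the grid."""
    lo = [max(int(np.floor(c - radius)), 0) for c in center]
    hi = [min(int(np.ceil(c + radius)), s - 1) for c, s in zip(center, shape)]
    if any(l > h for l, h in zip(lo, hi)):
        raise ValueError("sphere does not intersect the grid")
    gx, gy, gz = np.mgrid[lo[0] : hi[0] + 1, lo[1] : hi[1] + 1, lo[2] : hi[2] + 1]
    pts = np.column_stack([gx.ravel(), gy.ravel(), gz.ravel()])
    d2 = ((pts - np.asarray(center)) ** 2).sum(axis=1)
    inside = pts[d2 <= radius**2 + 1e-9]
    if inside.size == 0:
        raise ValueError("sphere contains no voxels")
    return inside


def raphe_voi_subject(
    image: np.ndarray,
    center: tuple[float, float, float],
    radius: float,
    *,
    name: str = "sDRN",
    fraction: float = 0.8,
    voxel_volume_mm3: float = 8.0,
) -> VOIDefinition:
    """Subject-based raphe VOI: the ceil(fraction * N) highest-uptake voxels
    among the N sphere voxels.  Ties break by distance to the center, then
    by lexicographic voxel index, so the mask is deterministic."""
    pts = sphere_indices(image.shape, center, radius)
    vals = image[tuple(pts.T)]
    dist = np.sqrt(((pts - np.asarray(center)) ** 2).sum(axis=1))
    flat = np.ravel_multi_index(tuple(pts.T), image.shape)
    order = np.lexsort((flat, dist, -vals))  # primary: value desc
    k = int(np.ceil(fraction * len(pts)))
    return VOIDefinition(
        name=name, indices=pts[order[:k]], voxel_volume_mm3=voxel_volume_mm3,
    )


def raphe_voi_atlas(
    shape: tuple[int, int, int],
    center: tuple[float, float, float],
    radius: float,
    *,
    name: str = "aDRN",
    voxel_volume_mm3: float = 8.0,
) -> VOIDefinition:
    """Atlas-based raphe VOI: a fixed sphere at given grid coordinates,
    independent of image intensities.  radius 0 selects the nearest voxel."""
    if any(not 0 <= c <= s - 1 for c, s in zip(center, shape)):
        raise ValueError("center outside the grid")
    if radius == 0:
        idx = np.array([[int(round(c)) for c in center]])
        return VOIDefinition(name=name, indices=idx, voxel_volume_mm3=voxel_volume_mm3)
    return VOIDefinition(
        name=name,
        indices=sphere_indices(shape, center, radius),
        voxel_volume_mm3=voxel_volume_mm3,
    )


def voi_mean(image: np.ndarray, voi: VOIDefinition) -> float:
    return float(image[tuple(voi.indices.T)].mean())


# ---------------------------------------------------------------------------
# statistics
# ---------------------------------------------------------------------------

def bonferroni_threshold(alpha: float = 0.05, family_size: int = VOI_FAMILY_SIZE) -> float:
    """Per-test significance threshold alpha / family size (0.05/13 ~ 0.004)."""
    if family_size < 1:
        raise ValueError("family size must be >= 1")
    return alpha / family_size


def _mannwhitney(x: np.ndarray, y: np.ndarray) -> tuple[float, float, str]:
    """Two-sided Mann-Whitney U: exact enumeration when both samples are
    small and tie-free, else the tie- and continuity-corrected normal
    approximation."""
    has_ties = len(np.unique(np.concatenate([x, y]))) < len(x) + len(y)
    if len(x) <= 10 and len(y) <= 10 and not has_ties:
        res = stats.mannwhitneyu(x, y, alternative="two-sided", method="exact")
        return float(res.statistic), float(res.pvalue), "mannwhitney-exact"
    res = stats.mannwhitneyu(
        x, y, alternative="two-sided", method="asymptotic", use_continuity=True
    )
    return float(res.statistic), float(res.pvalue), "mannwhitney-asymptotic"


def compare_groups(
    profile: pd.DataFrame,
    labels: pd.Series,
    pair: tuple[str, str],
    *,
    alpha: float = 0.05,
    family_size: int | None = None,
    features: list[str] | None = None,
) -> pd.DataFrame:
    """Per-feature Mann-Whitney comparison of two named groups.

    The Bonferroni threshold alpha / family size is reported alongside each
    raw p-value; by default the family is the declared feature list.
    """
    g1, g2 = pair
    labels = labels.loc[profile.index]
    for g in pair:
        if (labels == g).sum() < 2:
            raise ValueError(f"group {g!r} missing or has fewer than 2 subjects")
    features = features or list(profile.columns)
    m = family_size if family_size is not None else len(features)
    thresh = bonferroni_threshold(alpha, m)
    rows = []
    for f in features:
        x = profile.loc[labels == g1, f].to_numpy(dtype=float)
        y = profile.loc[labels == g2, f].to_numpy(dtype=float)
        u, p, method = _mannwhitney(x, y)
        rows.append(
            dict(
                feature=f,
                statistic=u,
                p=p,
                p_threshold=thresh,
                significant=p < thresh,
                median_1=float(np.median(x)),
                median_2=float(np.median(y)),
                group_1=g1,
                group_2=g2,
                method=method,
            )
        )
    return pd.DataFrame(rows)


def correlate_clinical(
    profile: pd.DataFrame,
    clinical: pd.DataFrame,
    score_names: list[str],
    *,
    features: list[str] | None = None,
    adjust: str = "fdr_bh",
) -> pd.DataFrame:
    """Spearman correlations between clinical scores and VOI BP_ND.

    The multiple-testing family is all (score x VOI) pairs tested in this
    call; p-values are Benjamini-Hochberg adjusted (step-up, with the usual
    monotonicity enforcement).  Constant inputs yield an undefined rho,
    flagged rather than dropped.
    """
    features = features or list(profile.columns)
    clinical = clinical.loc[profile.index]
    rows = []
    for s in score_names:
        sv = pd.to_numeric(clinical[s]).to_numpy(dtype=float)
        for f in features:
            fv = profile[f].to_numpy(dtype=float)
            if np.std(sv) == 0 or np.std(fv) == 0:
                rows.append(dict(score=s, feature=f, rho=np.nan, p=np.nan,
                                 method="spearman", note="constant input"))
                continue
            rho, p = stats.spearmanr(sv, fv)
            rows.append(dict(score=s, feature=f, rho=float(rho), p=float(p),
                             method="spearman", note=""))
    out = pd.DataFrame(rows)
    ok = out["p"].notna()
    out["p_adj"] = np.nan
    if ok.any():
        out.loc[ok, "p_adj"] = multipletests(out.loc[ok, "p"], method=adjust)[1]
    return out


def compare_by_psychiatry(
    profile: pd.DataFrame, psychiatric_flags: pd.Series, feature: str
) -> pd.Series:
    """Mann-Whitney comparison of one feature between subjects with and
    without a lifetime psychiatric diagnosis, with per-level medians."""
    flags = psychiatric_flags.loc[profile.index].astype(bool)
    if flags.nunique() < 2:
        raise ValueError("both psychiatric-flag levels must be present")
    x = profile.loc[flags, feature].to_numpy(dtype=float)
    y = profile.loc[~flags, feature].to_numpy(dtype=float)
    u, p, method = _mannwhitney(x, y)
    return pd.Series(
        dict(
            feature=feature,
            statistic=u,
            p=p,
            median_flagged=float(np.median(x)),
            median_unflagged=float(np.median(y)),
            n_flagged=len(x),
            n_unflagged=len(y),
            method=method,
        )
    )


def ancova_sqrt(
    profile: pd.DataFrame,
    labels: pd.Series,
    covariate_flags: pd.Series,
    feature: str,
) -> pd.Series:
    """Group effect on sqrt(BP_ND) adjusted for the psychiatric flag.

    Linear model sqrt(BP_ND) ~ group + flag; the group effect is the
    partial F-test.  A design in which the flag is confounded with group
    (rank-deficient) is returned flagged with NaN statistics.
    """
    vals = profile[feature].to_numpy(dtype=float)
    if np.any(vals < 0):
        raise ValueError("BP_ND must be non-negative for the sqrt transform")
    df = pd.DataFrame(
        {
            "y": np.sqrt(vals),
            "group": pd.Categorical(labels.loc[profile.index]),
            "flag": covariate_flags.loc[profile.index].astype(int),
        }
    )
    if df["group"].nunique() < 2:
        raise ValueError("need at least 2 groups")
    X = pd.get_dummies(df[["group", "flag"]], columns=["group"], drop_first=True, dtype=float)
    if np.linalg.matrix_rank(sm.add_constant(X).to_numpy()) < X.shape[1] + 1:
        return pd.Series(dict(feature=feature, statistic=np.nan, p=np.nan,
                              method="ancova-sqrt", note="singular design"))
    model = smf.ols("y ~ C(group) + flag", data=df).fit()
    an = sm.stats.anova_lm(model, typ=2)
    return pd.Series(
        dict(
            feature=feature,
            statistic=float(an.loc["C(group)", "F"]),
            p=float(an.loc["C(group)", "PR(>F)"]),
            method="ancova-sqrt",
            note="",
        )
    )


def confounder_screen(
    profile: pd.DataFrame,
    clinical: pd.DataFrame,
    covariates: tuple[str, ...] = ("levodopa_mg_per_day", "age", "genotype_LaLa"),
    *,
    features: list[str] | None = None,
) -> pd.DataFrame:
    """Spearman screen of candidate confounders against VOI BP_ND (binary
    genotype enters as a two-level rank variable)."""
    clin = clinical.loc[profile.index].copy()
    for c in covariates:
        if clin[c].dtype == bool:
            clin[c] = clin[c].astype(int)
    return correlate_clinical(profile, clin, list(covariates), features=features)
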