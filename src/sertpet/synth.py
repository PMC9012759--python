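"""Synthetic dynamic PET data and cohort profiles.

Emulates the structure of a three-group [11C]DASB study — dopa-responsive
dystonia (DRD, n=10), cervical dystonia (CD, n=14) and healthy controls
(n=12) — over 13 bilateral volumes of interest plus four raphe VOIs, with
clinical covariates on each instrument's integer scale and configurable
effects: a hippocampal BP_ND shift in subjects with a lifetime psychiatric
diagnosis and rank correlations between sleep quality and dorsal-raphe
binding (positive) and fatigue and median-raphe binding (negative).

Cross-variable dependence is induced through a Gaussian copula: latent
multivariate-normal draws with the Pearson correlation 2*sin(pi*rho_s/6)
that maps to a requested Spearman rho_s, pushed through each variable's
marginal (normal for BP_ND, rounded/clipped normal for integer instrument
scores, thresholded for binary flags).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.stats import norm

from .kinetics import KineticParams, exp_conv, frame_average_matrix, DEFAULT_DT
from .tac import DASB_FRAMING, FrameSchedule, TimeActivityCurve, make_frame_schedule

__all__ = [
    "ReferenceInput",
    "GroundTruth",
    "CohortConfig",
    "CohortDataset",
    "simulate_reference_tac",
    "simulate_target_tac",
    "add_noise",
    "simulate_cohort",
    "embed_pattern_maps",
    "make_ground_truth",
    "simulate_subject_tacs",
    "make_voxel_maps",
    "GROUPS",
    "BILATERAL_VOIS",
    "RAPHE_VOIS",
]

GROUPS = ("DRD", "CD", "control")

#: The 13 bilateral VOIs of the statistical family, with typical [11C]DASB
#: BP_ND population means and between-subject SDs (high binding in striatum,
#: thalamus and midbrain; low cortical binding; hippocampus near 0.45).
BILATERAL_VOIS: dict[str, tuple[float, float]] = {
    "caudate": (1.30, 0.20),
    "putamen": (1.50, 0.22),
    "pallidum": (1.20, 0.20),
    "thalamus": (1.60, 0.24),
    "midbrain": (2.00, 0.30),
    "hippocampus": (0.46, 0.10),
    "amygdala": (1.00, 0.18),
    "insula": (0.90, 0.15),
    "anterior_cingulate": (0.70, 0.12),
    "posterior_cingulate": (0.60, 0.11),
    "frontal_cortex": (0.35, 0.08),
    "temporal_cortex": (0.50, 0.10),
    "occipital_cortex": (0.30, 0.08),
}

#: Raphe VOIs (subject-based and atlas-based dorsal/median raphe).
RAPHE_VOIS: dict[str, tuple[float, float]] = {
    "sDRN": (2.20, 0.35),
    "sMRN": (1.80, 0.30),
    "aDRN": (2.00, 0.35),
    "aMRN": (1.60, 0.30),
}

#: Clinical instruments: (low, high, {group: median}, SD).  Medians follow
#: the cohort's demographics table; SDs are chosen to respect the printed
#: ranges.
CLINICAL_INSTRUMENTS: dict[str, tuple[float, float, dict[str, float], float]] = {
    "BAI": (0, 63, {"DRD": 6.5, "CD": 8, "control": 3}, 4.5),
    "BDI": (0, 63, {"DRD": 5, "CD": 11, "control": 2}, 4.5),
    "ESS": (0, 24, {"DRD": 10.5, "CD": 12.5, "control": 4.5}, 4.5),
    "FSS": (9, 63, {"DRD": 31.5, "CD": 36, "control": 22.5}, 10.0),
    "PSQI": (0, 21, {"DRD": 8.5, "CD": 8, "control": 4.5}, 3.5),
    "CGI": (1, 7, {"DRD": 2, "CD": 4.5, "control": 1}, 1.2),
    "BFMDRS": (0, 120, {"DRD": 6.5, "CD": 5.3, "control": 0}, 4.0),
    "age": (18, 90, {"DRD": 46.5, "CD": 55.0, "control": 53.5}, 10.0),
}


# ---------------------------------------------------------------------------
# dynamic TAC simulation
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ReferenceInput:
    """Analytic reference-region curve: a saturating bolus uptake with
    bi-exponential washout,

        C_R(t) = A_norm * (1 - exp(-t/tau))**alpha
                 * (w1*exp(-mu1*t) + (1-w1)*exp(-mu2*t)),

    normalised so the peak equals ``peak_amplitude`` (kBq/mL).  With the
    defaults the peak falls near 3 min, as measured cerebellum TACs do.
    """

    peak_amplitude: float = 50.0
    rise_time: float = 0.6  # min, bolus uptake time constant tau
    alpha: float = 3.0
    fast_rate: float = 0.12  # 1/min
    slow_rate: float = 0.015  # 1/min
    fast_fraction: float = 0.5

    def __post_init__(self) -> None:
        if self.peak_amplitude < 0:
            raise ValueError("peak_amplitude must be non-negative")
        if min(self.fast_rate, self.slow_rate, self.alpha, self.rise_time) <= 0:
            raise ValueError("descriptor rates, alpha and rise_time must be positive")
        if not 0 <= self.fast_fraction <= 1:
            raise ValueError("fast_fraction must lie in [0, 1]")

    def _shape(self, t: np.ndarray) -> np.ndarray:
        t = np.maximum(np.asarray(t, dtype=float), 0.0)
        rise = (1.0 - np.exp(-t / self.rise_time)) ** self.alpha
        wash = self.fast_fraction * np.exp(-self.fast_rate * t) + (
            1 - self.fast_fraction
        ) * np.exp(-self.slow_rate * t)
        return rise * wash

    def __call__(self, t: np.ndarray) -> np.ndarray:
        tt = np.linspace(0.0, 90.0, 9001)
        peak = self._shape(tt).max()
        if peak == 0:
            return np.zeros_like(np.asarray(t, dtype=float))
        return self.peak_amplitude / peak * self._shape(t)


@dataclass
class GroundTruth:
    """True kinetic parameters per region plus the reference input used."""

    params_by_region: dict[str, KineticParams]
    ref_input: ReferenceInput

    def __post_init__(self) -> None:
        for name, p in self.params_by_region.items():
            if p.bp_nd < 0 or p.k2 <= 0 or p.r1 <= 0:
                raise ValueError(f"invalid ground-truth parameters for {name!r}")


def simulate_reference_tac(
    schedule: FrameSchedule,
    ref_input: ReferenceInput | None = None,
    dt: float = DEFAULT_DT,
) -> TimeActivityCurve:
    """Frame-averaged reference-region TAC from the analytic input curve."""
    ref_input = ref_input or ReferenceInput()
    t = schedule.fine_grid(dt)
    fine = ref_input(t)
    A = frame_average_matrix(schedule, dt)
    return TimeActivityCurve(schedule, A @ fine, "reference", fine=(t, fine))


def simulate_target_tac(
    ref: TimeActivityCurve, params: KineticParams, dt: float = DEFAULT_DT
) -> TimeActivityCurve:
    """Forward SRTM model: frame-averaged target TAC for given kinetics.

    C_T(t) = R1*C_R(t) + (k2 - R1*k2a) * C_R (x) exp(-k2a t), evaluated on a
    fine grid (the reference's attached fine curve when present, otherwise
    the average-matching reconstruction) and averaged within frames.
    """
    from .kinetics import reconstruct_continuous

    t = ref.schedule.fine_grid(dt)
    if ref.fine is not None:
        r_fine = np.interp(t, ref.fine[0], ref.fine[1])
    else:
        r_fine = reconstruct_continuous(ref, dt)
    conv = exp_conv(r_fine, dt, params.k2a)
    fine = params.r1 * r_fine + (params.k2 - params.r1 * params.k2a) * conv
    A = frame_average_matrix(ref.schedule, dt)
    return TimeActivityCurve(ref.schedule, A @ fine, "target", fine=(t, fine))


def add_noise(
    tac: TimeActivityCurve, scale: float, seed: int | np.random.Generator
) -> TimeActivityCurve:
    """Additive zero-mean Gaussian noise with per-frame SD proportional to
    sqrt(value / frame duration), the usual count-statistics surrogate."""
    if scale < 0:
        raise ValueError("noise scale must be non-negative")
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    sd = scale * np.sqrt(np.maximum(tac.values, 0.0) / tac.schedule.frame_durations)
    noisy = tac.values + rng.normal(0.0, 1.0, tac.values.shape) * sd
    noisy[0] = max(noisy[0], 0.0)
    return TimeActivityCurve(tac.schedule, noisy, tac.label, fine=tac.fine)


# ---------------------------------------------------------------------------
# cohort simulation
# ---------------------------------------------------------------------------

@dataclass
class CohortConfig:
    """Population parameters of the synthetic cohort.

    Defaults reproduce the study conditions: group sizes 10/14/12, the
    13-VOI + 4-raphe feature set, psychiatric-diagnosis prevalence of
    60/79/33% per group, a -0.08 hippocampal BP_ND shift in flagged
    subjects, and rank correlations PSQI<->sDRN = +0.45 and
    FSS<->sMRN = -0.45.  Zeroing the effect fields yields a null cohort.
    """

    group_sizes: dict[str, int] = field(
        default_factory=lambda: {"DRD": 10, "CD": 14, "control": 12}
    )
    vois: dict[str, tuple[float, float]] = field(
        default_factory=lambda: {**BILATERAL_VOIS, **RAPHE_VOIS}
    )
    group_offsets: dict[str, dict[str, float]] = field(default_factory=dict)
    psych_prevalence: dict[str, float] = field(
        default_factory=lambda: {"DRD": 0.60, "CD": 0.79, "control": 0.33}
    )
    hippocampus_psych_shift: float = -0.08
    rho_sleep_drn: float = 0.45  # Spearman target, PSQI <-> sDRN
    rho_fatigue_mrn: float = -0.45  # Spearman target, FSS <-> sMRN
    genotype_lala_prevalence: dict[str, float] = field(
        default_factory=lambda: {"DRD": 0.40, "CD": 0.21, "control": 0.42}
    )
    levodopa_user_fraction: float = 0.8  # within the DRD group
    clinical: dict[str, tuple[float, float, dict[str, float], float]] = field(
        default_factory=lambda: dict(CLINICAL_INSTRUMENTS)
    )

    def validate(self) -> None:
        for g, n in self.group_sizes.items():
            if n < 1:
                raise ValueError(f"group size for {g!r} must be >= 1")
        for name, (mean, sd) in self.vois.items():
            if sd <= 0:
                raise ValueError(f"non-positive SD for VOI {name!r}")
        for rho in (self.rho_sleep_drn, self.rho_fatigue_mrn):
            if abs(rho) >= 1:
                raise ValueError(f"|rho| must be < 1, got {rho}")
        for g, p in self.psych_prevalence.items():
            if not 0 <= p <= 1:
                raise ValueError(f"prevalence for {g!r} outside [0, 1]")

    def null(self) -> "CohortConfig":
        """Copy with every configured effect removed (identical groups)."""
        cfg = replace(
            self,
            group_offsets={},
            hippocampus_psych_shift=0.0,
            rho_sleep_drn=0.0,
            rho_fatigue_mrn=0.0,
        )
        return cfg


@dataclass
class CohortDataset:
    """Synthetic study: BP_ND profile, clinical table, group labels."""

    profile: pd.DataFrame  # subjects x VOI features (true BP_ND)
    clinical: pd.DataFrame  # subjects x covariates, includes 'group'
    config: CohortConfig
    seed: int | None = None
    fitted_profile: pd.DataFrame | None = None
    voxel_maps: dict[str, np.ndarray] | None = None

    def __post_init__(self) -> None:
        if not self.profile.index.equals(self.clinical.index):
            raise ValueError("profile and clinical tables must share subject ids")
        bad = set(self.clinical["group"]) - set(GROUPS)
        if bad:
            raise ValueError(f"unknown group labels: {sorted(bad)}")

    @property
    def groups(self) -> pd.Series:
        return self.clinical["group"]


def _spearman_to_pearson(rho_s: float) -> float:
    return 2.0 * math.sin(math.pi * rho_s / 6.0)


def simulate_cohort(config: CohortConfig | None = None, seed: int = 0) -> CohortDataset:
    """Draw a cohort whose population parameters equal the configuration."""
    config = config or CohortConfig()
    config.validate()
    rng = np.random.default_rng(seed)

    voi_names = list(config.vois)
    score_names = list(config.clinical)
    aux_names = ["_psych", "_genotype", "_levodopa_user", "_levodopa_dose"]
    dims = voi_names + score_names + aux_names
    idx = {name: i for i, name in enumerate(dims)}

    corr = np.eye(len(dims))
    pairs = []
    if "PSQI" in idx and "sDRN" in idx and config.rho_sleep_drn != 0:
        pairs.append(("PSQI", "sDRN", config.rho_sleep_drn))
    if "FSS" in idx and "sMRN" in idx and config.rho_fatigue_mrn != 0:
        pairs.append(("FSS", "sMRN", config.rho_fatigue_mrn))
    for a, b, rho in pairs:
        r = _spearman_to_pearson(rho)
        corr[idx[a], idx[b]] = corr[idx[b], idx[a]] = r
    L = np.linalg.cholesky(corr)

    rows_profile, rows_clin, ids = [], [], []
    counter = 0
    for group in config.group_sizes:
        n = config.group_sizes[group]
        offsets = config.group_offsets.get(group, {})
        for _ in range(n):
            counter += 1
            sid = f"S{counter:03d}"
            z = L @ rng.standard_normal(len(dims))
            bp = {}
            for name in voi_names:
                mean, sd = config.vois[name]
                bp[name] = max(mean + offsets.get(name, 0.0) + sd * z[idx[name]], 0.01)
            clin: dict[str, object] = {"group": group}
            for name in score_names:
                lo, hi, med, sd = config.clinical[name]
                clin[name] = int(round(min(max(med[group] + sd * z[idx[name]], lo), hi)))
            psych = bool(z[idx["_psych"]] < norm.ppf(config.psych_prevalence[group]))
            if psych and "hippocampus" in bp:
                bp["hippocampus"] = max(
                    bp["hippocampus"] + config.hippocampus_psych_shift, 0.01
                )
            clin["psychiatric_lifetime"] = psych
            clin["genotype_LaLa"] = bool(
                z[idx["_genotype"]] < norm.ppf(config.genotype_lala_prevalence[group])
            )
            if group == "DRD" and z[idx["_levodopa_user"]] < norm.ppf(
                config.levodopa_user_fraction
            ):
                dose = 150.0 * math.exp(0.45 * z[idx["_levodopa_dose"]])
                clin["levodopa_mg_per_day"] = float(
                    50 * round(min(max(dose, 100.0), 400.0) / 50)
                )
            else:
                clin["levodopa_mg_per_day"] = 0.0
            rows_profile.append(bp)
            rows_clin.append(clin)
            ids.append(sid)

    profile = pd.DataFrame(rows_profile, index=pd.Index(ids, name="subject_id"))[voi_names]
    clinical = pd.DataFrame(rows_clin, index=pd.Index(ids, name="subject_id"))
    return CohortDataset(profile=profile, clinical=clinical, config=config, seed=seed)


def embed_pattern_maps(
    cohort: CohortDataset,
    pattern_weights: np.ndarray,
    expression_gap: float,
    seed: int,
    *,
    disease_group: str = "DRD",
    pattern_scale: float = 0.25,
    noise_sd: float = 0.05,
) -> CohortDataset:
    """Rebuild the profile as baseline + score * weights + noise.

    Expression scores are drawn per group as N(expression_gap, 1) for the
    disease group and N(0, 1) otherwise, so ``expression_gap`` is the group
    separation in units of the within-group score SD.  Used to verify that
    the pattern-derivation pipeline recovers a known covariance pattern.
    """
    w = np.asarray(pattern_weights, dtype=float)
    if w.shape != (cohort.profile.shape[1],):
        raise ValueError(
            f"weight length {w.size} != feature count {cohort.profile.shape[1]}"
        )
    if not np.all(np.isfinite(w)):
        raise ValueError("pattern weights must be finite")
    rng = np.random.default_rng(seed)
    baseline = cohort.profile.mean(axis=0).to_numpy()
    groups = cohort.groups.to_numpy()
    scores = rng.standard_normal(len(groups)) + np.where(
        groups == disease_group, expression_gap, 0.0
    )
    noise = rng.normal(0.0, noise_sd, cohort.profile.shape) if noise_sd > 0 else 0.0
    values = baseline[None, :] + pattern_scale * scores[:, None] * w[None, :] + noise
    profile = pd.DataFrame(values, index=cohort.profile.index, columns=cohort.profile.columns)
    return CohortDataset(
        profile=profile,
        clinical=cohort.clinical.copy(),
        config=cohort.config,
        seed=cohort.seed,
    )


# ---------------------------------------------------------------------------
# per-subject dynamic data
# ---------------------------------------------------------------------------

def make_ground_truth(
    bp_by_region: dict[str, float],
    ref_input: ReferenceInput | None = None,
    k2prime: float = 0.07,
    rng: np.random.Generator | int | None = None,
) -> GroundTruth:
    """Kinetic ground truth for one subject: R1 drawn around 0.95 per region,
    k2 = R1 * k2', BP_ND from the cohort profile."""
    rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng
    params = {}
    for region, bp in bp_by_region.items():
        r1 = float(np.clip(rng.normal(0.95, 0.05), 0.75, 1.25))
        params[region] = KineticParams(r1=r1, k2=r1 * k2prime, bp_nd=max(bp, 0.0))
    return GroundTruth(params_by_region=params, ref_input=ref_input or ReferenceInput())


def simulate_subject_tacs(
    truth: GroundTruth,
    schedule: FrameSchedule | None = None,
    noise_scale: float = 0.0,
    rng: np.random.Generator | int | None = None,
) -> dict[str, TimeActivityCurve]:
    """Reference ('cerebellum') plus per-region target TACs for one subject."""
    schedule = schedule or make_frame_schedule(DASB_FRAMING)
    rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng
    ref = simulate_reference_tac(schedule, truth.ref_input)
    out = {"cerebellum": ref if noise_scale == 0 else add_noise(ref, noise_scale, rng)}
    for region, params in truth.params_by_region.items():
        tac = simulate_target_tac(ref, params)
        tac.label = region
        out[region] = tac if noise_scale == 0 else add_noise(tac, noise_scale, rng)
    return out


def make_voxel_maps(
    cohort: CohortDataset,
    label_img: np.ndarray,
    legend: dict[int, str],
    noise_sd: float = 0.05,
    seed: int = 0,
) -> dict[str, np.ndarray]:
    """Per-subject 3-D BP_ND maps: each labelled region filled with the
    subject's VOI value plus voxel noise (unlabelled voxels are zero)."""
    rng = np.random.default_rng(seed)
    maps = {}
    for sid, row in cohort.profile.iterrows():
        img = np.zeros(label_img.shape)
        for label, voi in legend.items():
            if voi not in row.index:
                continue
            mask = label_img == label
            img[mask] = row[voi] + rng.normal(0.0, noise_sd, int(mask.sum()))
        maps[str(sid)] = img
    return maps
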