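"""Run configuration: one schema covering simulation, statistics and the
pattern analysis, loadable from YAML and hashable for provenance."""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field, fields

from .synth import BILATERAL_VOIS, CohortConfig
from .tac import DASB_FRAMING

__all__ = ["PatternOptions", "KineticsOptions", "StatsOptions", "RunConfig"]


@dataclass
class PatternOptions:
    cumulative_fraction: float = 0.5
    log_transform: bool = False
    log_offset: float = 0.0
    mask_floor: float | None = None
    disease_group: str = "DRD"
    control_group: str = "control"


@dataclass
class KineticsOptions:
    enabled: bool = True
    noise_scale: float = 0.3  # TAC noise scale (count-statistics surrogate)
    k2prime_region: str = "putamen"  # striatal high-binding region
    dt: float = 0.05


@dataclass
class StatsOptions:
    alpha: float = 0.05
    voi_family: tuple[str, ...] = tuple(BILATERAL_VOIS)
    bh_scores: tuple[str, ...] = ("BDI", "BAI", "ESS", "FSS", "PSQI", "CGI", "BFMDRS")
    psychiatry_feature: str = "hippocampus"


@dataclass
class RunConfig:
    seed: int = 0
    framing: tuple[tuple[int, float], ...] = DASB_FRAMING
    cohort: CohortConfig = field(default_factory=CohortConfig)
    kinetics: KineticsOptions = field(default_factory=KineticsOptions)
    stats: StatsOptions = field(default_factory=StatsOptions)
    pattern: PatternOptions = field(default_factory=PatternOptions)

    def to_dict(self) -> dict:
        return asdict(self)

    def hash(self) -> str:
        blob = json.dumps(self.to_dict(), sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()[:16]

    @classmethod
    def from_dict(cls, data: dict) -> "RunConfig":
        kwargs: dict = {}
        for f in fields(cls):
            if f.name not in data:
                continue
            value = data[f.name]
            if f.name == "cohort":
                sub = dict(value)
                if "vois" in sub:
                    sub["vois"] = {k: tuple(v) for k, v in sub["vois"].items()}
                if "clinical" in sub:
                    sub["clinical"] = {
                        k: (v[0], v[1], dict(v[2]), v[3]) for k, v in sub["clinical"].items()
                    }
                kwargs["cohort"] = CohortConfig(**sub)
            elif f.name == "kinetics":
                kwargs["kinetics"] = KineticsOptions(**value)
            elif f.name == "stats":
                sub = dict(value)
                for key in ("voi_family", "bh_scores"):
                    if key in sub:
                        sub[key] = tuple(sub[key])
                kwargs["stats"] = StatsOptions(**sub)
            elif f.name == "pattern":
                kwargs["pattern"] = PatternOptions(**value)
            elif f.name == "framing":
                kwargs["framing"] = tuple((int(c), float(d)) for c, d in value)
            else:
                kwargs[f.name] = value
        return cls(**kwargs)
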