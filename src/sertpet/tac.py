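"""Frame schedules and time–activity curves for dynamic PET.

All times are in minutes and activity concentrations in kBq/mL; curves are
assumed decay-corrected.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

__all__ = ["FrameSchedule", "TimeActivityCurve", "make_frame_schedule", "DASB_FRAMING"]

#: Framing of the 60-min [11C]DASB acquisition: (frame count, duration in minutes).
#: The printed products sum to 3610 s; the schedule below follows them as printed.
DASB_FRAMING: tuple[tuple[int, float], ...] = (
    (7, 10 / 60),
    (2, 30 / 60),
    (3, 1.0),
    (2, 2.0),
    (2, 3.0),
    (5, 5.0),
    (2, 10.0),
)


@dataclass(frozen=True)
class FrameSchedule:
    """Contiguous, non-overlapping acquisition frames starting at t = 0.

    Parameters
    ----------
    frame_starts : array of frame start times (min)
    frame_durations : array of frame durations (min), all > 0
    """

    frame_starts: np.ndarray
    frame_durations: np.ndarray

    def __post_init__(self) -> None:
        starts = np.asarray(self.frame_starts, dtype=float)
        durs = np.asarray(self.frame_durations, dtype=float)
        object.__setattr__(self, "frame_starts", starts)
        object.__setattr__(self, "frame_durations", durs)
        if starts.ndim != 1 or starts.size < 1 or starts.shape != durs.shape:
            raise ValueError("frame_starts and frame_durations must be equal-length 1-D arrays")
        if np.any(durs <= 0):
            raise ValueError("frame durations must be positive")
        ends = starts + durs
        if not np.allclose(starts[1:], ends[:-1], rtol=0, atol=1e-9):
            raise ValueError("frames must be contiguous and non-overlapping")

    @property
    def n_frames(self) -> int:
        return int(self.frame_starts.size)

    @property
    def frame_ends(self) -> np.ndarray:
        return self.frame_starts + self.frame_durations

    @property
    def mid_times(self) -> np.ndarray:
        return self.frame_starts + self.frame_durations / 2

    @property
    def total_duration(self) -> float:
        return float(self.frame_ends[-1] - self.frame_starts[0])

    def fine_grid(self, dt: float = 0.05) -> np.ndarray:
        """Uniform time grid from 0 to the end of the last frame, step ``dt`` min."""
        if dt <= 0:
            raise ValueError("dt must be positive")
        n = int(np.ceil(self.frame_ends[-1] / dt)) + 1
        return np.arange(n) * dt

    def frame_average(self, t: np.ndarray, values: np.ndarray) -> np.ndarray:
        """Average a finely sampled curve within each frame (trapezoidal mean)."""
        t = np.asarray(t, dtype=float)
        values = np.asarray(values, dtype=float)
        out = np.empty(self.n_frames)
        for i, (a, b) in enumerate(zip(self.frame_starts, self.frame_ends)):
            grid = np.unique(np.concatenate(([a], t[(t > a) & (t < b)], [b])))
            v = np.interp(grid, t, values)
            out[i] = np.trapezoid(v, grid) / (b - a)
        return out


@dataclass
class TimeActivityCurve:
    """Per-frame activity concentration (kBq/mL) for one region or voxel.

    ``fine`` optionally carries the underlying continuous curve as
    ``(t, values)`` on a fine grid; simulators attach it so forward models
    need not re-interpolate, while measured data leaves it ``None``.
    """

    schedule: FrameSchedule
    values: np.ndarray
    label: str = ""
    fine: tuple[np.ndarray, np.ndarray] | None = field(default=None, repr=False, compare=False)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (self.schedule.n_frames,):
            raise ValueError(
                f"values length {self.values.size} != frame count {self.schedule.n_frames}"
            )
        if not np.all(np.isfinite(self.values)):
            raise ValueError("TAC values must be finite")
        if self.values[0] < -1e-12:
            raise ValueError("first-frame value must be non-negative")

    def scaled(self, factor: float) -> "TimeActivityCurve":
        return TimeActivityCurve(self.schedule, self.values * factor, self.label)


def make_frame_schedule(spec: Sequence[tuple[int, float]]) -> FrameSchedule:
    """Build a contiguous schedule from (count, duration_min) blocks.

    >>> make_frame_schedule(DASB_FRAMING).n_frames
    23
    """
    durations: list[float] = []
    for count, dur in spec:
        if count < 1:
            raise ValueError(f"frame count must be >= 1, got {count}")
        if dur <= 0:
            raise ValueError(f"frame duration must be positive, got {dur}")
        durations.extend([float(dur)] * int(count))
    durs = np.array(durations)
    starts = np.concatenate(([0.0], np.cumsum(durs)[:-1]))
    return FrameSchedule(starts, durs)
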