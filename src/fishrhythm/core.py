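"""Core in-memory containers shared across the pipeline.

Conventions
-----------
* All times are seconds from recording start; zeitgeber conversion happens
  only when binning (see :mod:`fishrhythm.metrics`).
* The canonical length unit is mm; speed thresholds are mm/s (the adult
  4 cm/s cutoff is stored as 40 mm/s).
* A sample at index ``i`` of a uniform grid represents the frame *interval*
  ``((i-1)/fps, i/fps]``; a trajectory of ``n`` samples therefore spans
  ``(n-1)/fps`` seconds of observed motion.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np

__all__ = [
    "STAGES",
    "SPEED_THRESHOLDS_MM_S",
    "Trajectory",
    "EthogramEvents",
    "SpeedSeries",
    "RestBout",
    "HourlyProfile",
    "RhythmIndices",
]

STAGES = ("juvenile", "adult")

#: Empirically determined cutoffs separating passive drift from active
#: swimming: 12 mm/s for juveniles, 4 cm/s (= 40 mm/s) for adults.
SPEED_THRESHOLDS_MM_S = {"juvenile": 12.0, "adult": 40.0}


def _check_stage(stage: str) -> str:
    if stage not in STAGES:
        raise ValueError(f"stage must be one of {STAGES}, got {stage!r}")
    return stage


@dataclass
class Trajectory:
    """One subject's positional time series on a uniform frame grid.

    ``valid`` marks frames where tracking succeeded; x/y are NaN on invalid
    frames and must be finite elsewhere.
    """

    subject_id: str
    t: np.ndarray  # s from recording start, uniform grid
    x: np.ndarray  # mm
    y: np.ndarray  # mm
    stage: str = "adult"
    valid: Optional[np.ndarray] = None

    def __post_init__(self) -> None:
        _check_stage(self.stage)
        self.t = np.asarray(self.t, dtype=float)
        self.x = np.asarray(self.x, dtype=float)
        self.y = np.asarray(self.y, dtype=float)
        if self.valid is None:
            self.valid = np.ones(self.t.shape, dtype=bool)
        else:
            self.valid = np.asarray(self.valid, dtype=bool)
        n = len(self.t)
        if not (len(self.x) == len(self.y) == len(self.valid) == n):
            raise ValueError("t, x, y, valid must have equal length")
        if n >= 2:
            dt = np.diff(self.t)
            if np.any(dt <= 0):
                raise ValueError(f"{self.subject_id}: time must be strictly increasing")
            if not np.allclose(dt, dt[0], rtol=0, atol=0.5 * dt[0]):
                raise ValueError(f"{self.subject_id}: time grid is not uniform")
        bad = self.valid & ~(np.isfinite(self.x) & np.isfinite(self.y))
        if np.any(bad):
            raise ValueError(
                f"{self.subject_id}: non-finite coordinates on {int(bad.sum())} valid frames"
            )

    @property
    def n_frames(self) -> int:
        return len(self.t)

    @property
    def dt(self) -> float:
        """Frame interval in seconds."""
        if self.n_frames < 2:
            raise ValueError("need >= 2 samples to define a frame interval")
        return float(np.median(np.diff(self.t)))

    @property
    def fps(self) -> float:
        return 1.0 / self.dt

    @property
    def duration_s(self) -> float:
        """Observed span: (n-1) frame intervals."""
        return float(self.t[-1] - self.t[0])


@dataclass
class EthogramEvents:
    """Manually scored state-event intervals for one subject and behavior.

    ``intervals`` is an (m, 2) array of (start_s, stop_s) rows, normalized:
    sorted, stop > start, non-overlapping, touching intervals merged.
    """

    subject_id: str
    behavior: str
    intervals: np.ndarray

    def __post_init__(self) -> None:
        iv = np.asarray(self.intervals, dtype=float).reshape(-1, 2)
        self.intervals = normalize_intervals(iv)

    @property
    def total_duration_s(self) -> float:
        if len(self.intervals) == 0:
            return 0.0
        return float(np.sum(self.intervals[:, 1] - self.intervals[:, 0]))


def normalize_intervals(intervals: np.ndarray) -> np.ndarray:
    """Sort intervals and merge any that overlap or touch.

    Raises on intervals with stop <= start (callers filter those first).
    """
    iv = np.asarray(intervals, dtype=float).reshape(-1, 2)
    if len(iv) == 0:
        return iv
    if np.any(iv[:, 1] <= iv[:, 0]):
        raise ValueError("intervals must satisfy stop > start")
    iv = iv[np.argsort(iv[:, 0])]
    merged = [iv[0].copy()]
    for start, stop in iv[1:]:
        if start <= merged[-1][1]:  # overlap or touch
            merged[-1][1] = max(merged[-1][1], stop)
        else:
            merged.append(np.array([start, stop]))
    return np.array(merged)


@dataclass
class SpeedSeries:
    """Per-frame swimming speed (mm/s) on a uniform grid.

    ``speed[i]`` is the speed over the frame interval ending at ``t[i]``;
    ``valid[i]`` is False where either endpoint of that interval was lost.
    """

    subject_id: str
    t: np.ndarray
    speed: np.ndarray
    valid: Optional[np.ndarray] = None
    dt: Optional[float] = None

    def __post_init__(self) -> None:
        self.t = np.asarray(self.t, dtype=float)
        self.speed = np.asarray(self.speed, dtype=float)
        if self.valid is None:
            self.valid = np.ones(self.t.shape, dtype=bool)
        else:
            self.valid = np.asarray(self.valid, dtype=bool)
        if not (len(self.t) == len(self.speed) == len(self.valid)):
            raise ValueError("t, speed, valid must have equal length")
        if self.dt is None:
            if len(self.t) < 2:
                raise ValueError("dt must be given for series with < 2 samples")
            self.dt = float(np.median(np.diff(self.t)))
        if np.any(self.speed[self.valid] < 0):
            raise ValueError("speed must be non-negative where valid")


@dataclass(frozen=True)
class RestBout:
    """A maximal run of sub-threshold speed lasting at least the minimum
    duration (default 60 s)."""

    start_s: float
    stop_s: float

    @property
    def duration_s(self) -> float:
        return self.stop_s - self.start_s


@dataclass
class HourlyProfile:
    """24 zeitgeber-hour bins of locomotion and rest for one subject/group.

    ``locomotion`` is mm per hour (NaN for ethogram-only pathways, which
    carry no displacement information); ``active_minutes`` is time spent in
    the active state per hour (min); ``rest_minutes`` is rest-bout overlap
    per hour (min). Multi-day recordings hold per-ZT-bin means across days.
    """

    subject_id: str
    locomotion: np.ndarray  # mm per hour, len 24, indexed by ZT bin
    rest_minutes: np.ndarray  # min per hour, len 24
    active_minutes: Optional[np.ndarray] = None  # min per hour, len 24
    n_days: int = 1
    n_subjects: int = 1  # >1 for group averages

    def __post_init__(self) -> None:
        self.locomotion = np.asarray(self.locomotion, dtype=float)
        self.rest_minutes = np.asarray(self.rest_minutes, dtype=float)
        if self.active_minutes is not None:
            self.active_minutes = np.asarray(self.active_minutes, dtype=float)
            if self.active_minutes.shape != (24,):
                raise ValueError("active_minutes must have 24 bins")
        if self.locomotion.shape != (24,) or self.rest_minutes.shape != (24,):
            raise ValueError("hourly profiles must have exactly 24 ZT bins")
        with np.errstate(invalid="ignore"):
            if np.any(self.rest_minutes < -1e-9) or np.any(self.rest_minutes > 60 + 1e-9):
                raise ValueError("rest_minutes must lie in [0, 60] per bin")

    @property
    def zt_hours(self) -> np.ndarray:
        return np.arange(24)

    def channel(self, name: str) -> np.ndarray:
        """Return one of the profile channels by name.

        ``"locomotion"`` (mm/h), ``"active_minutes"`` or ``"rest_minutes"``.
        """
        if name == "locomotion":
            return self.locomotion
        if name == "active_minutes":
            if self.active_minutes is None:
                raise ValueError(f"{self.subject_id}: no active_minutes channel")
            return self.active_minutes
        if name == "rest_minutes":
            return self.rest_minutes
        raise ValueError(f"unknown profile channel {name!r}")


@dataclass(frozen=True)
class RhythmIndices:
    """Diurnality and crepuscularity indices with their component terms.

    A_R = (D - N)/(D + N): +1 fully diurnal, -1 fully nocturnal; undefined
    (None) when D + N = 0 — a motionless fish has no diurnality, not zero.
    C_R = C/NC - 1: 0 means no activity change after light transitions, 1 a
    100% increase; undefined when NC = 0.
    """

    subject_id: str
    D: float  # mean hourly activity, light phase
    N: float  # mean hourly activity, dark phase
    A_R: Optional[float]
    C: float  # mean activity in post-transition (dawn/dusk) hours
    NC: float  # mean activity over the remaining hours
    C_R: Optional[float]
    channel: str = "locomotion"
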