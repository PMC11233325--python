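"""Frame-wise speed, activity/rest classification and rest-bout extraction.

Rest is operationalized as in the study system: a frame is *inactive*
when its swimming speed is strictly below a stage-specific threshold
(12 mm/s for juveniles, 40 mm/s for adults), and a maximal run of
inactive frames lasting at least 60 s (inclusive) is a *rest bout*. The
rule deliberately stops short of calling this sleep.

Accounting is exact: every frame interval of a recording is classified as
active, in-bout rest, sub-minimum inactivity, or tracking gap, and the
four classes partition the recording span.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .core import (
    SPEED_THRESHOLDS_MM_S,
    EthogramEvents,
    RestBout,
    SpeedSeries,
    Trajectory,
)

__all__ = [
    "compute_speed",
    "detect_rest_bouts",
    "ethogram_to_rest",
    "time_accounting",
    "TimeAccounting",
    "threshold_for_stage",
    "bouts_table",
    "MIN_REST_DURATION_S",
]

logger = logging.getLogger(__name__)

#: Minimum inactive-run length counted as rest ("1 min or longer").
MIN_REST_DURATION_S = 60.0

_TOL = 1e-9  # absolute slack for duration comparisons on float time grids


def threshold_for_stage(stage: str) -> float:
    """Stage-resolved inactivity threshold, mm/s."""
    return SPEED_THRESHOLDS_MM_S[stage]


def compute_speed(traj: Trajectory, smooth_window: int = 0) -> SpeedSeries:
    """Per-frame speed from consecutive positions.

    ``speed[i]`` is the Euclidean displacement from sample ``i`` to
    ``i+1`` divided by the frame interval, assigned to the later sample;
    it is invalid wherever either endpoint was a tracking gap.

    ``smooth_window`` (frames) applies an optional centered boxcar to the
    speed series; off (0) by default.
    """
    if traj.n_frames < 2:
        raise ValueError(f"{traj.subject_id}: need >= 2 samples to compute speed")
    dt = traj.dt
    disp = np.hypot(np.diff(traj.x), np.diff(traj.y))
    valid = traj.valid[1:] & traj.valid[:-1]
    speed = np.where(valid, disp / dt, np.nan)
    if not valid.any():
        logger.warning("%s: no consecutive valid samples; speed series is empty",
                       traj.subject_id)
    if smooth_window and smooth_window > 1:
        kernel = np.ones(smooth_window) / smooth_window
        padded = np.where(valid, speed, 0.0)
        norm = np.convolve(valid.astype(float), kernel, mode="same")
        smoothed = np.convolve(padded, kernel, mode="same")
        with np.errstate(invalid="ignore", divide="ignore"):
            speed = np.where(valid & (norm > 0), smoothed / norm, np.nan)
    return SpeedSeries(
        subject_id=traj.subject_id, t=traj.t[1:], speed=np.where(valid, speed, np.nan),
        valid=valid, dt=dt,
    )


def _inactive_runs(speed: SpeedSeries, threshold: float) -> list[tuple[int, int]]:
    """Maximal runs [a, b] (inclusive indices) of valid sub-threshold frames."""
    with np.errstate(invalid="ignore"):
        below = speed.valid & (speed.speed < threshold)
    if not below.any():
        return []
    padded = np.concatenate([[False], below, [False]])
    d = np.diff(padded.astype(np.int8))
    starts = np.flatnonzero(d == 1)
    stops = np.flatnonzero(d == -1) - 1
    return list(zip(starts, stops))


def detect_rest_bouts(
    speed: SpeedSeries,
    threshold: float,
    min_duration_s: float = MIN_REST_DURATION_S,
) -> list[RestBout]:
    """Extract rest bouts from a speed series.

    A bout is a maximal run of valid frames with ``speed < threshold``
    (strict) whose span is at least ``min_duration_s`` (inclusive). Runs
    interrupted by tracking gaps are split — gap frames belong to no bout.
    A frame's interval is the ``dt`` seconds ending at its timestamp, so a
    run over frames ``a..b`` spans ``t[a] - dt`` to ``t[b]``.
    """
    if threshold <= 0:
        raise ValueError("threshold must be > 0")
    if min_duration_s <= 0:
        raise ValueError("min_duration_s must be > 0")
    dt = speed.dt
    bouts = []
    for a, b in _inactive_runs(speed, threshold):
        duration = (b - a + 1) * dt
        if duration >= min_duration_s - _TOL:
            bouts.append(RestBout(start_s=speed.t[a] - dt, stop_s=speed.t[b]))
    return bouts


def ethogram_to_rest(
    events: EthogramEvents,
    recording_span: tuple[float, float],
    min_duration_s: float = MIN_REST_DURATION_S,
) -> list[RestBout]:
    """Rest bouts implied by scored active-swimming intervals.

    The complement of the (normalized) active intervals within the
    recording span is scanned for gaps of at least ``min_duration_s``
    (inclusive). Intervals reaching outside the span are clipped with a
    logged warning.
    """
    start, stop = recording_span
    if stop <= start:
        raise ValueError("recording_span must satisfy stop > start")
    iv = events.intervals
    if len(iv):
        outside = (iv[:, 0] < start - _TOL) | (iv[:, 1] > stop + _TOL)
        if outside.any():
            logger.warning(
                "%s: clipped %d interval(s) outside the recording span",
                events.subject_id, int(outside.sum()),
            )
        iv = np.clip(iv, start, stop)
        iv = iv[iv[:, 1] > iv[:, 0]]
    # complement of active coverage within the span
    edges = [start] + list(iv.ravel()) + [stop]
    gaps = np.array(edges).reshape(-1, 2)
    bouts = []
    for g0, g1 in gaps:
        if g1 - g0 >= min_duration_s - _TOL:
            bouts.append(RestBout(start_s=float(g0), stop_s=float(g1)))
    return bouts


@dataclass(frozen=True)
class TimeAccounting:
    """Exact partition of a recording's frame intervals.

    Frame counts sum to the total number of frame intervals; the seconds
    fields are counts times the frame interval.
    """

    n_frames: int
    active_frames: int
    rest_frames: int
    submin_inactive_frames: int
    gap_frames: int
    dt: float

    @property
    def total_s(self) -> float:
        return self.n_frames * self.dt

    @property
    def active_s(self) -> float:
        return self.active_frames * self.dt

    @property
    def rest_s(self) -> float:
        return self.rest_frames * self.dt

    @property
    def submin_inactive_s(self) -> float:
        return self.submin_inactive_frames * self.dt

    @property
    def gap_s(self) -> float:
        return self.gap_frames * self.dt


def time_accounting(
    speed: SpeedSeries,
    threshold: float,
    min_duration_s: float = MIN_REST_DURATION_S,
) -> TimeAccounting:
    """Classify every frame interval and account for the full recording."""
    dt = speed.dt
    n = len(speed.speed)
    gap = int((~speed.valid).sum())
    with np.errstate(invalid="ignore"):
        active = int((speed.valid & (speed.speed >= threshold)).sum())
    rest = 0
    for a, b in _inactive_runs(speed, threshold):
        if (b - a + 1) * dt >= min_duration_s - _TOL:
            rest += b - a + 1
    submin = n - gap - active - rest
    return TimeAccounting(
        n_frames=n, active_frames=active, rest_frames=rest,
        submin_inactive_frames=submin, gap_frames=gap, dt=dt,
    )


def bouts_table(bouts_by_subject: dict[str, Sequence[RestBout]]) -> pd.DataFrame:
    """Tidy export: one row per rest bout (subject, start_s, stop_s, duration_s)."""
    rows = [
        (subject, b.start_s, b.stop_s, b.duration_s)
        for subject, bouts in bouts_by_subject.items()
        for b in bouts
    ]
    return pd.DataFrame(rows, columns=["subject", "start_s", "stop_s", "duration_s"])
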