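"""Zeitgeber hourly profiles and rest-activity rhythm indices.

Locomotion is binned into 24 one-hour zeitgeber bins with no smoothing;
bin k covers [ZT k, ZT k+1). From a profile the module derives:

* ``D`` and ``N`` — mean hourly activity over the light- and dark-phase
  bins (14 and 10 bins on the default schedule);
* the diurnality *activity change ratio* ``A_R = (D - N) / (D + N)``,
  +1 for fully diurnal, -1 for fully nocturnal animals;
* the crepuscularity index ``C_R = C / NC - 1``, where ``C`` is the mean
  activity in the hour(s) following the two light transitions and ``NC``
  the mean over the remaining hours; 0 means no post-transition change,
  1 a 100% increase.

Both indices are undefined (returned as ``None``, never silently 0) when
their denominator vanishes: a motionless subject has no diurnality.
"""

from __future__ import annotations

import logging
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .core import HourlyProfile, RestBout, RhythmIndices, SpeedSeries, Trajectory
from .kinematics import compute_speed, threshold_for_stage
from .schedule import LightSchedule

__all__ = [
    "bin_hourly",
    "bin_hourly_events",
    "day_night_means",
    "diurnality_index",
    "crepuscularity_index",
    "rhythm_indices",
    "group_average",
    "profiles_table",
    "indices_table",
]

logger = logging.getLogger(__name__)

_DAY_S = 86400.0


def _whole_days(duration_s: float) -> int:
    if duration_s < 3600.0:
        raise ValueError("recording shorter than 1 h cannot be binned hourly")
    n_days = duration_s / _DAY_S
    if abs(n_days - round(n_days)) > 1e-6 or round(n_days) < 1:
        raise ValueError(
            f"recording spans {duration_s / 3600:.2f} h; hourly profiles require "
            "whole 24 h days (partial days are rejected, not guessed)"
        )
    return int(round(n_days))


def _hour_overlap_minutes(intervals: np.ndarray, schedule: LightSchedule) -> np.ndarray:
    """Overlap of (start, stop) intervals with each ZT hour bin, in minutes
    summed over all recording days."""
    out = np.zeros(24)
    for s0, s1 in intervals:
        k0 = int(np.floor(s0 / 3600.0))
        k1 = int(np.ceil(s1 / 3600.0))
        for k in range(k0, k1):
            lo, hi = k * 3600.0, (k + 1) * 3600.0
            overlap = min(s1, hi) - max(s0, lo)
            if overlap > 0:
                zt_bin = int((schedule.recording_start_zt + k) % 24)
                out[zt_bin] += overlap / 60.0
    return out


def bin_hourly(
    traj: Trajectory,
    bouts: Sequence[RestBout],
    schedule: LightSchedule,
    speed: Optional[SpeedSeries] = None,
    threshold: Optional[float] = None,
) -> HourlyProfile:
    """Hourly zeitgeber profile of locomotion, rest and active time.

    Each frame interval is assigned to the ZT hour containing its
    midpoint; per-bin locomotion is the summed frame displacement (mm),
    so the bins over one day add up exactly to that day's path length
    (gap frames excluded). Rest bouts are split pro rata across the bins
    they span. Multi-day recordings are averaged per ZT bin across days.
    """
    n_days = _whole_days(traj.duration_s)
    if speed is None:
        speed = compute_speed(traj)
    if threshold is None:
        threshold = threshold_for_stage(traj.stage)
    dt = speed.dt
    mid = (speed.t - traj.t[0]) - 0.5 * dt
    bins = schedule.zt_bin(mid)

    disp = np.where(speed.valid, speed.speed * dt, 0.0)
    locomotion = np.zeros(24)
    np.add.at(locomotion, bins, disp)

    with np.errstate(invalid="ignore"):
        active = speed.valid & (speed.speed >= threshold)
    active_minutes = np.zeros(24)
    np.add.at(active_minutes, bins[active], dt / 60.0)

    bout_iv = np.array([[b.start_s, b.stop_s] for b in bouts]).reshape(-1, 2)
    rest_minutes = _hour_overlap_minutes(bout_iv, schedule)

    return HourlyProfile(
        subject_id=traj.subject_id,
        locomotion=locomotion / n_days,
        rest_minutes=rest_minutes / n_days,
        active_minutes=active_minutes / n_days,
        n_days=n_days,
    )


def bin_hourly_events(
    events, bouts: Sequence[RestBout], schedule: LightSchedule, duration_s: float
) -> HourlyProfile:
    """Hourly profile from a scored ethogram.

    The ethogram carries no displacement information, so the locomotion
    channel is NaN; activity is quantified as time in the active state
    per hour (min), the quantity the manual-scoring pathway measures.
    """
    n_days = _whole_days(duration_s)
    active_minutes = _hour_overlap_minutes(events.intervals, schedule)
    bout_iv = np.array([[b.start_s, b.stop_s] for b in bouts]).reshape(-1, 2)
    rest_minutes = _hour_overlap_minutes(bout_iv, schedule)
    return HourlyProfile(
        subject_id=events.subject_id,
        locomotion=np.full(24, np.nan),
        rest_minutes=rest_minutes / n_days,
        active_minutes=active_minutes / n_days,
        n_days=n_days,
    )


def day_night_means(
    profile: HourlyProfile, schedule: LightSchedule, channel: str = "locomotion"
) -> tuple[float, float]:
    """Mean hourly activity over the light (D) and dark (N) phase bins."""
    vals = profile.channel(channel)
    D = float(np.mean(vals[schedule.light_bins]))
    N = float(np.mean(vals[schedule.dark_bins]))
    return D, N


def diurnality_index(D: float, N: float) -> Optional[float]:
    """Activity change ratio (D - N)/(D + N); None when D + N = 0."""
    if D < 0 or N < 0:
        raise ValueError("phase activity means must be non-negative")
    total = D + N
    if total == 0:
        return None
    return (D - N) / total


def crepuscularity_index(
    profile: HourlyProfile,
    schedule: LightSchedule,
    window_h: int = 1,
    channel: str = "locomotion",
) -> Optional[float]:
    """Crepuscularity index C/NC - 1; None when NC = 0."""
    _, _, cr = _crepuscular_terms(profile, schedule, window_h, channel)
    return cr


def _crepuscular_terms(profile, schedule, window_h, channel):
    vals = profile.channel(channel)
    crep = schedule.crepuscular_bins(window_h)
    others = np.setdiff1d(np.arange(24), crep)
    C = float(np.mean(vals[crep]))
    NC = float(np.mean(vals[others]))
    if NC == 0:
        return C, NC, None
    return C, NC, C / NC - 1.0


def rhythm_indices(
    profile: HourlyProfile,
    schedule: LightSchedule,
    window_h: int = 1,
    channel: str = "locomotion",
) -> RhythmIndices:
    """Diurnality and crepuscularity indices with their component terms."""
    D, N = day_night_means(profile, schedule, channel)
    C, NC, cr = _crepuscular_terms(profile, schedule, window_h, channel)
    return RhythmIndices(
        subject_id=profile.subject_id,
        D=D, N=N, A_R=diurnality_index(D, N),
        C=C, NC=NC, C_R=cr,
        channel=channel,
    )


def group_average(profiles: Sequence[HourlyProfile], group_id: str = "group") -> HourlyProfile:
    """Per-bin arithmetic mean across subjects (group-recording analysis).

    Used when individual identities cannot be maintained over a recording
    and only the average locomotion within each group is analyzed.
    """
    if len(profiles) == 0:
        raise ValueError("group_average requires at least one profile")
    n_days = profiles[0].n_days
    if any(p.n_days != n_days for p in profiles):
        raise ValueError("profiles have mismatched day counts")
    locomotion = np.mean([p.locomotion for p in profiles], axis=0)
    rest = np.mean([p.rest_minutes for p in profiles], axis=0)
    if all(p.active_minutes is not None for p in profiles):
        active = np.mean([p.active_minutes for p in profiles], axis=0)
    else:
        active = None
    return HourlyProfile(
        subject_id=group_id,
        locomotion=locomotion,
        rest_minutes=rest,
        active_minutes=active,
        n_days=n_days,
        n_subjects=int(np.sum([p.n_subjects for p in profiles])),
    )


def profiles_table(profiles: Sequence[HourlyProfile]) -> pd.DataFrame:
    """Tidy export: one row per subject per ZT bin."""
    rows = []
    for p in profiles:
        for k in range(24):
            rows.append(
                (
                    p.subject_id, k, p.locomotion[k], p.rest_minutes[k],
                    np.nan if p.active_minutes is None else p.active_minutes[k],
                    p.n_days,
                )
            )
    return pd.DataFrame(
        rows,
        columns=["subject", "zt_hour", "locomotion_mm", "rest_min", "active_min", "n_days"],
    )


def indices_table(indices: Sequence[RhythmIndices]) -> pd.DataFrame:
    """Tidy export: one row of index terms per subject.

    Undefined indices are exported as NaN; the count of undefined entries
    is logged so they are excluded from group statistics explicitly, not
    silently zeroed.
    """
    n_undef = sum(1 for ix in indices if ix.A_R is None or ix.C_R is None)
    if n_undef:
        logger.info("indices_table: %d subject(s) with undefined indices", n_undef)
    rows = [
        (
            ix.subject_id, ix.channel, ix.D, ix.N,
            np.nan if ix.A_R is None else ix.A_R,
            ix.C, ix.NC,
            np.nan if ix.C_R is None else ix.C_R,
        )
        for ix in indices
    ]
    return pd.DataFrame(
        rows, columns=["subject", "channel", "D", "N", "A_R", "C", "NC", "C_R"]
    )
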