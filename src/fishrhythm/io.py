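"""Reading and writing the pipeline's delimited-text exchange formats.

Two CSV dialects are supported, mirroring what video trackers and
interactive scoring tools export:

* positional tables with columns ``time_s, subject, x, y`` (one row per
  frame per subject); delimiter auto-detected among comma/semicolon/tab;
* "aggregated events"-style ethogram tables with columns
  ``subject, behavior, start_s, stop_s``.

Parsers are total on well-formed files and account for every row read
(kept + rejected), logging the split.
"""

from __future__ import annotations

import logging
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .core import EthogramEvents, Trajectory, _check_stage

__all__ = [
    "FormatError",
    "read_positions",
    "write_positions",
    "read_ethogram",
    "write_ethogram",
]

logger = logging.getLogger(__name__)

POSITION_COLUMNS = ["time_s", "subject", "x", "y"]
ETHOGRAM_COLUMNS = ["subject", "behavior", "start_s", "stop_s"]


class FormatError(ValueError):
    """Raised when an input table does not match the expected dialect."""


def _read_table(path, required: Sequence[str]) -> pd.DataFrame:
    df = pd.read_csv(path, sep=None, engine="python")
    missing = [c for c in required if c not in df.columns]
    if missing:
        unknown = [c for c in df.columns if c not in required]
        raise FormatError(
            f"{path}: missing required column(s) {missing}; "
            f"found unrecognized header(s) {unknown}"
        )
    return df


def read_positions(path, stage: str = "adult", scale: float = 1.0) -> list[Trajectory]:
    """Parse a positional tracking export into per-subject trajectories.

    Parameters
    ----------
    path : str or Path
        Delimited table with columns ``time_s, subject, x, y``.
    stage : {"juvenile", "adult"}
        Life stage of the recorded subjects (selects default analysis
        thresholds downstream).
    scale : float
        mm per coordinate unit; coordinates are multiplied by this on read.

    Dropped frames (times missing from the uniform grid, or rows with
    empty/non-finite coordinates) are flagged in the validity mask, never
    interpolated.
    """
    _check_stage(stage)
    if scale <= 0:
        raise ValueError("scale must be > 0 mm per unit")
    df = _read_table(path, POSITION_COLUMNS)
    trajectories = []
    for subject, sub in df.groupby("subject", sort=True):
        t = sub["time_s"].to_numpy(dtype=float)
        if np.any(np.diff(t) <= 0):
            raise FormatError(f"{path}: non-monotone time for subject {subject!r}")
        x = sub["x"].to_numpy(dtype=float) * scale
        y = sub["y"].to_numpy(dtype=float) * scale
        present = np.isfinite(x) & np.isfinite(y)
        if len(t) >= 2:
            # dropped frames leave diffs at multiples of the frame interval,
            # so the smallest diff is the grid step
            dt = np.min(np.diff(t))
            grid = np.round((t - t[0]) / dt).astype(int)
            n = grid[-1] + 1
            tf = t[0] + np.arange(n) * dt
            xf = np.full(n, np.nan)
            yf = np.full(n, np.nan)
            mask = np.zeros(n, dtype=bool)
            xf[grid] = x
            yf[grid] = y
            mask[grid] = present
            xf[~mask] = np.nan
            yf[~mask] = np.nan
            n_gaps = int(n - present.sum())
            if n_gaps:
                logger.info("%s: subject %s has %d gap frame(s)", path, subject, n_gaps)
        else:
            tf, xf, yf, mask = t, x, y, present
        trajectories.append(
            Trajectory(subject_id=str(subject), t=tf, x=xf, y=yf, stage=stage, valid=mask)
        )
    logger.info(
        "%s: read %d rows -> %d trajectories", path, len(df), len(trajectories)
    )
    return trajectories


def write_positions(trajectories: Sequence[Trajectory], path) -> None:
    """Write trajectories in the positional CSV dialect (mm, comma-separated).

    Invalid frames are written with empty coordinate fields so the time
    grid round-trips exactly.
    """
    frames = []
    for traj in trajectories:
        frames.append(
            pd.DataFrame(
                {
                    "time_s": traj.t,
                    "subject": traj.subject_id,
                    "x": np.where(traj.valid, traj.x, np.nan),
                    "y": np.where(traj.valid, traj.y, np.nan),
                }
            )
        )
    out = pd.concat(frames, ignore_index=True)
    out.to_csv(path, index=False, float_format="%.17g")


def read_ethogram(path) -> list[EthogramEvents]:
    """Parse an aggregated-events ethogram export.

    Rows with ``stop_s <= start_s`` are rejected with a logged warning
    count; per subject+behavior the surviving intervals are sorted and
    merged where they overlap or touch. An empty table yields an empty
    list, not an error.
    """
    df = _read_table(path, ETHOGRAM_COLUMNS)
    ok = df["stop_s"] > df["start_s"]
    n_rejected = int((~ok).sum())
    if n_rejected:
        logger.warning(
            "%s: rejected %d row(s) with stop_s <= start_s (kept %d of %d)",
            path, n_rejected, int(ok.sum()), len(df),
        )
    df = df[ok]
    events = []
    for (subject, behavior), sub in df.groupby(["subject", "behavior"], sort=True):
        events.append(
            EthogramEvents(
                subject_id=str(subject),
                behavior=str(behavior),
                intervals=sub[["start_s", "stop_s"]].to_numpy(dtype=float),
            )
        )
    logger.info(
        "%s: read %d rows = %d kept + %d rejected -> %d event series",
        path, n_rejected + int(ok.sum()), int(ok.sum()), n_rejected, len(events),
    )
    return events


def write_ethogram(events: Sequence[EthogramEvents], path) -> None:
    """Write event series in the aggregated-events CSV dialect."""
    rows = []
    for ev in events:
        for start, stop in ev.intervals:
            rows.append((ev.subject_id, ev.behavior, start, stop))
    pd.DataFrame(rows, columns=ETHOGRAM_COLUMNS).to_csv(
        path, index=False, float_format="%.17g"
    )
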