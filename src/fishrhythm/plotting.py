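"""Small matplotlib helpers for 24 h zeitgeber profiles."""

from __future__ import annotations

from typing import Optional, Sequence

import numpy as np

from .core import HourlyProfile
from .schedule import LightSchedule

__all__ = ["plot_profile"]


def plot_profile(
    profile: HourlyProfile,
    schedule: LightSchedule,
    channel: str = "locomotion",
    ax=None,
    **plot_kwargs,
):
    """24 h activity trace with the dark period shaded.

    Bins are drawn at their centers (ZT k + 0.5). Returns the axes.
    """
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(6, 3))
    vals = profile.channel(channel)
    centers = np.arange(24) + 0.5
    ax.plot(centers, vals, marker="o", ms=3, **plot_kwargs)
    on = schedule.lights_on_duration
    ax.axvspan(on, 24, color="0.85", zorder=0, label="dark")
    ax.set_xlim(0, 24)
    ax.set_xticks(range(0, 25, 4))
    ax.set_xlabel("zeitgeber time (h)")
    unit = {"locomotion": "locomotion (mm/h)", "rest_minutes": "rest (min/h)",
            "active_minutes": "active (min/h)"}[channel]
    ax.set_ylabel(unit)
    ax.set_title(profile.subject_id)
    return ax
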