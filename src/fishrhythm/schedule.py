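"""Photoperiod geometry and zeitgeber-time bookkeeping.

Zeitgeber time (ZT) is clock time referenced to the light cycle: ZT0 is
lights-on, lights stay on for ``lights_on_duration`` hours and off for the
remainder of the 24 h day. All recording-internal times are seconds from
recording start; the schedule is the single place where they are mapped to
ZT hours, light/dark phase labels and hourly bins.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["LightSchedule"]

_DAY_H = 24.0


@dataclass(frozen=True)
class LightSchedule:
    """A periodic light:dark schedule anchored at lights-on (ZT0).

    Parameters
    ----------
    lights_on_duration : float
        Hours of light per day (default 14).
    lights_off_duration : float
        Hours of dark per day (default 10). Must sum with the light phase
        to 24 h.
    recording_start_zt : float
        Zeitgeber hour at which the recording's t = 0 falls (default 1,
        i.e. recordings start one hour after lights-on).
    """

    lights_on_duration: float = 14.0
    lights_off_duration: float = 10.0
    recording_start_zt: float = 1.0

    def __post_init__(self) -> None:
        if not np.isclose(self.lights_on_duration + self.lights_off_duration, _DAY_H):
            raise ValueError(
                "light and dark phases must sum to 24 h, got "
                f"{self.lights_on_duration} + {self.lights_off_duration}"
            )
        if not (0 < self.lights_on_duration < _DAY_H):
            raise ValueError("lights_on_duration must lie strictly inside (0, 24) h")
        if not (0 <= self.recording_start_zt < _DAY_H):
            raise ValueError("recording_start_zt must lie in [0, 24) h")

    # ------------------------------------------------------------------ #
    # time mappings

    def zt_hours(self, t_s):
        """Zeitgeber hour (float in [0, 24)) for time(s) in seconds from start."""
        return (self.recording_start_zt + np.asarray(t_s, dtype=float) / 3600.0) % _DAY_H

    def is_light(self, t_s):
        """True where the lights are on; ZT in [0, lights_on_duration)."""
        return self.zt_hours(t_s) < self.lights_on_duration

    def zt_bin(self, t_s):
        """Integer ZT hour bin (0..23); bin k covers [ZT k, ZT k+1)."""
        return np.minimum(np.floor(self.zt_hours(t_s)).astype(int), 23)

    # ------------------------------------------------------------------ #
    # bin geometry (assumes integer phase durations, as in hourly binning)

    @property
    def light_bins(self) -> np.ndarray:
        """ZT hour bins that fall in the light phase."""
        return np.arange(int(round(self.lights_on_duration)))

    @property
    def dark_bins(self) -> np.ndarray:
        """ZT hour bins that fall in the dark phase."""
        return np.arange(int(round(self.lights_on_duration)), 24)

    def crepuscular_bins(self, window_h: int = 1) -> np.ndarray:
        """ZT bins in the ``window_h`` hours after each light transition.

        Dawn (lights-on) is ZT0; dusk (lights-off) is ZT ``lights_on_duration``.
        """
        window_h = int(window_h)
        if window_h < 1:
            raise ValueError("window_h must be >= 1")
        on = int(round(self.lights_on_duration))
        off = 24 - on
        if window_h > min(on, off):
            raise ValueError(
                f"crepuscular window of {window_h} h overlaps the next transition "
                f"on a {on}:{off} schedule"
            )
        dawn = np.arange(window_h)
        dusk = on + np.arange(window_h)
        return np.concatenate([dawn, dusk])

    # ------------------------------------------------------------------ #
    # phase transitions, for the simulator

    def transition_times(self, duration_s: float) -> np.ndarray:
        """Times (s from recording start) of every light<->dark switch in
        (0, duration_s), in increasing order."""
        # switches occur when ZT crosses 0 (dawn) or lights_on_duration (dusk)
        switches_zt = np.array([0.0, self.lights_on_duration])
        out = []
        for zt in switches_zt:
            first = ((zt - self.recording_start_zt) % _DAY_H) * 3600.0
            times = np.arange(first, duration_s, _DAY_H * 3600.0)
            out.append(times[times > 0])
        times = np.concatenate(out)
        return np.sort(times)
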