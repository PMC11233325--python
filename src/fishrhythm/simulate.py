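"""Synthetic locomotor trajectories with known ground truth.

The generator emulates a 24 h light:dark recording of individually housed
fish: each subject alternates between an *active* state (swimming at a
phase-dependent mean speed) and a *rest* state (sub-threshold jitter),
with exponentially distributed dwell times whose hazards depend on the
light phase. This is a two-state semi-Markov process; its stationary
occupancy gives closed-form expected activity levels, so the downstream
analysis can be tested against known truth.

Model summary
-------------
* In phase p (light or dark), the active->rest hazard is ``rest_rate_p``
  and the rest->active hazard is ``wake_rate_p``; expected rest fraction
  is ``rest_rate_p / (rest_rate_p + wake_rate_p)``.
* Active frames displace by ``mean_active_speed_p / fps`` (boosted by the
  crepuscular multiplier during the first hour after each light
  transition); rest frames displace by a fixed jitter of 25% of the
  stage's analysis speed threshold, so simulated rest is unambiguously
  sub-threshold and simulated swimming unambiguously supra-threshold.
* Headings are isotropic; when a step would leave the arena the heading
  is redrawn until the step stays inside, which preserves the step
  magnitude exactly (a folded reflection would shorten the measured
  displacement and could push an active frame below the speed cutoff).
* Dwell times in progress are redrawn at light transitions (memoryless
  construction); the state itself carries over.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Optional

import numpy as np

from .core import SPEED_THRESHOLDS_MM_S, EthogramEvents, Trajectory, _check_stage
from .schedule import LightSchedule

__all__ = [
    "PhaseActivity",
    "SimulationParams",
    "GroundTruth",
    "simulate_trajectory",
    "simulate_ethogram",
    "species_preset",
    "params_with_expected_ar",
    "REST_JITTER_FRACTION",
]

#: Rest-state displacement magnitude as a fraction of the stage's analysis
#: speed threshold; fixed well below 1 so rest never straddles the cutoff.
REST_JITTER_FRACTION = 0.25

#: Hours after each light transition over which the crepuscular
#: multiplier boosts active swimming speed.
CREPUSCULAR_WINDOW_H = 1.0

_ARENA_DEFAULTS_MM = {
    # single well of a 6-well plate (juveniles, filmed from above)
    "juvenile": (35.0, 35.0),
    # side view of a small glass aquarium (adults, filmed from the side)
    "adult": (305.0, 203.0),
}


@dataclass(frozen=True)
class PhaseActivity:
    """Activity parameters for one light phase.

    mean_active_speed : mm/s swimming speed while in the active state.
    rest_rate : 1/s hazard of entering rest while active.
    wake_rate : 1/s hazard of waking while at rest.
    """

    mean_active_speed: float
    rest_rate: float
    wake_rate: float

    def __post_init__(self) -> None:
        for name in ("mean_active_speed", "rest_rate", "wake_rate"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be strictly positive")

    @property
    def rest_fraction(self) -> float:
        """Stationary probability of being at rest in this phase."""
        return self.rest_rate / (self.rest_rate + self.wake_rate)


@dataclass(frozen=True)
class SimulationParams:
    seed: int
    light: PhaseActivity
    dark: PhaseActivity
    duration_h: float = 24.0
    fps: float = 15.0
    stage: str = "juvenile"
    arena_width_mm: Optional[float] = None
    arena_height_mm: Optional[float] = None
    crepuscular_multiplier: float = 1.0
    n_subjects: int = 1

    def __post_init__(self) -> None:
        _check_stage(self.stage)
        if self.duration_h <= 0:
            raise ValueError("duration_h must be > 0")
        if self.fps < 1:
            raise ValueError("fps must be >= 1")
        if self.crepuscular_multiplier < 1:
            raise ValueError("crepuscular_multiplier must be >= 1")
        if self.n_subjects < 1:
            raise ValueError("n_subjects must be >= 1")
        w, h = self.arena_mm
        max_step = (
            max(self.light.mean_active_speed, self.dark.mean_active_speed)
            * self.crepuscular_multiplier
            / self.fps
        )
        # a step must fit inside the arena from any interior point with
        # non-vanishing probability; 0.35 of the diagonal leaves margin at
        # the arena centre, the worst-case position
        if max_step >= 0.35 * math.hypot(w, h):
            raise ValueError(
                f"arena ({w} x {h} mm) too small for a single displacement "
                f"step of {max_step:.1f} mm; lower the speed or raise fps"
            )
        thr = SPEED_THRESHOLDS_MM_S[self.stage]
        for name in ("light", "dark"):
            if getattr(self, name).mean_active_speed <= thr:
                raise ValueError(
                    f"{name} mean_active_speed must exceed the {self.stage} "
                    f"analysis threshold ({thr} mm/s) so simulated swimming "
                    "is unambiguously active"
                )

    @property
    def arena_mm(self) -> tuple[float, float]:
        default_w, default_h = _ARENA_DEFAULTS_MM[self.stage]
        return (
            self.arena_width_mm if self.arena_width_mm is not None else default_w,
            self.arena_height_mm if self.arena_height_mm is not None else default_h,
        )

    @property
    def jitter_speed(self) -> float:
        """Rest-state displacement speed, mm/s."""
        return REST_JITTER_FRACTION * SPEED_THRESHOLDS_MM_S[self.stage]

    @property
    def n_frames(self) -> int:
        """Samples per subject: duration * fps frame intervals plus the start."""
        return int(round(self.duration_h * 3600.0 * self.fps)) + 1


@dataclass(frozen=True)
class GroundTruth:
    """Closed-form expectations implied by the simulation parameters.

    Hourly distances include both components of real path length: active
    swimming, ``(1 - rest_fraction) * mean_active_speed`` (with the
    crepuscular hour's boost averaged into its phase), and rest jitter,
    ``rest_fraction * jitter_speed``.
    """

    expected_D: float  # mm/h, mean over light-phase hours
    expected_N: float  # mm/h, mean over dark-phase hours
    expected_AR: Optional[float]
    expected_rest_fraction: dict = field(default_factory=dict)  # per phase


def _phase_hourly_distance(phase: PhaseActivity, jitter_speed: float, multiplier: float) -> float:
    rf = phase.rest_fraction
    return 3600.0 * ((1.0 - rf) * phase.mean_active_speed * multiplier + rf * jitter_speed)


def ground_truth(params: SimulationParams, schedule: LightSchedule) -> GroundTruth:
    """Expected hourly activity per phase from stationary occupancy."""
    j = params.jitter_speed
    m = params.crepuscular_multiplier
    hours_light = schedule.lights_on_duration
    hours_dark = schedule.lights_off_duration

    def phase_mean(phase: PhaseActivity, hours: float) -> float:
        plain = _phase_hourly_distance(phase, j, 1.0)
        crep = _phase_hourly_distance(phase, j, m)
        # exactly one crepuscular hour falls in each phase (dawn in light,
        # dusk in dark) for the 1 h window
        return ((hours - CREPUSCULAR_WINDOW_H) * plain + CREPUSCULAR_WINDOW_H * crep) / hours

    D = phase_mean(params.light, hours_light)
    N = phase_mean(params.dark, hours_dark)
    ar = (D - N) / (D + N) if (D + N) > 0 else None
    return GroundTruth(
        expected_D=D,
        expected_N=N,
        expected_AR=ar,
        expected_rest_fraction={
            "light": params.light.rest_fraction,
            "dark": params.dark.rest_fraction,
        },
    )


# --------------------------------------------------------------------- #
# state process

_ACTIVE, _REST = 1, 0


def _state_segments(
    rng: np.random.Generator,
    duration_s: float,
    schedule: LightSchedule,
    light: PhaseActivity,
    dark: PhaseActivity,
) -> list[tuple[float, float, int]]:
    """Continuous-time state path as (t0, t1, state) segments covering
    [0, duration_s]. Dwells are redrawn (state kept) at phase switches."""
    boundaries = list(schedule.transition_times(duration_s)) + [math.inf]
    b_idx = 0
    t = 0.0
    phase = light if schedule.is_light(0.0) else dark
    # start from the stationary occupancy of the initial phase
    state = _REST if rng.random() < phase.rest_fraction else _ACTIVE
    segments: list[tuple[float, float, int]] = []
    while t < duration_s:
        while boundaries[b_idx] <= t:
            b_idx += 1
        phase = light if schedule.is_light(t) else dark
        hazard = phase.rest_rate if state == _ACTIVE else phase.wake_rate
        dwell = rng.exponential(1.0 / hazard)
        next_boundary = boundaries[b_idx]
        if t + dwell >= next_boundary and next_boundary < duration_s:
            segments.append((t, next_boundary, state))  # redraw at the switch
            t = next_boundary
        else:
            end = min(t + dwell, duration_s)
            segments.append((t, end, state))
            state = _ACTIVE if state == _REST else _REST
            t = end
    return segments


def _frame_states(params: SimulationParams, state_rng: np.random.Generator,
                  schedule: LightSchedule) -> np.ndarray:
    """Boolean active-state per frame interval (length n_frames - 1).

    Frame interval i covers ((i-1)dt, i*dt]; its state is the continuous
    process sampled at the interval midpoint, which avoids boundary ties.
    """
    duration_s = params.duration_h * 3600.0
    segs = _state_segments(state_rng, duration_s, schedule, params.light, params.dark)
    ends = np.array([s[1] for s in segs])
    states = np.array([s[2] for s in segs], dtype=np.int8)
    dt = 1.0 / params.fps
    mid = (np.arange(1, params.n_frames) - 0.5) * dt
    idx = np.minimum(np.searchsorted(ends, mid, side="left"), len(segs) - 1)
    return states[idx] == _ACTIVE


def _active_speed_per_frame(params: SimulationParams, schedule: LightSchedule) -> np.ndarray:
    """Deterministic active-state speed (mm/s) for each frame interval."""
    dt = 1.0 / params.fps
    mid = (np.arange(1, params.n_frames) - 0.5) * dt
    light = schedule.is_light(mid)
    speed = np.where(light, params.light.mean_active_speed, params.dark.mean_active_speed)
    if params.crepuscular_multiplier != 1.0:
        zt = schedule.zt_hours(mid)
        dawn = zt < CREPUSCULAR_WINDOW_H
        dusk = (zt >= schedule.lights_on_duration) & (
            zt < schedule.lights_on_duration + CREPUSCULAR_WINDOW_H
        )
        speed = np.where(dawn | dusk, speed * params.crepuscular_multiplier, speed)
    return speed


# --------------------------------------------------------------------- #
# arena walk

try:  # pragma: no cover - exercised implicitly
    from numba import njit

    _HAVE_NUMBA = True
except ImportError:  # pragma: no cover
    _HAVE_NUMBA = False


def _walk_py(x0, y0, steps, w, h, seed):
    rs = np.random.RandomState(seed)
    n = len(steps)
    xs = np.empty(n + 1)
    ys = np.empty(n + 1)
    xs[0], ys[0] = x0, y0
    for i in range(n):
        s = steps[i]
        while True:
            th = 2.0 * np.pi * rs.random_sample()
            nx = xs[i] + s * np.cos(th)
            ny = ys[i] + s * np.sin(th)
            if 0.0 <= nx <= w and 0.0 <= ny <= h:
                break
        xs[i + 1], ys[i + 1] = nx, ny
    return xs, ys


if _HAVE_NUMBA:

    @njit
    def _walk_nb(x0, y0, steps, w, h, seed):  # pragma: no cover - jitted
        np.random.seed(seed)
        n = steps.shape[0]
        xs = np.empty(n + 1)
        ys = np.empty(n + 1)
        xs[0] = x0
        ys[0] = y0
        for i in range(n):
            s = steps[i]
            while True:
                th = 2.0 * np.pi * np.random.random()
                nx = xs[i] + s * np.cos(th)
                ny = ys[i] + s * np.sin(th)
                if 0.0 <= nx <= w and 0.0 <= ny <= h:
                    break
            xs[i + 1] = nx
            ys[i + 1] = ny
        return xs, ys

    _walk = _walk_nb
else:  # pragma: no cover
    _walk = _walk_py


# --------------------------------------------------------------------- #
# public generators


def _subject_streams(params: SimulationParams):
    """Per-subject (state_rng, motion_rng, heading_seed) triples.

    The state stream is isolated so trajectory and ethogram generation
    consume identical randomness for the state path.
    """
    root = np.random.SeedSequence(params.seed)
    for child in root.spawn(params.n_subjects):
        c_state, c_motion = child.spawn(2)
        state_rng = np.random.default_rng(c_state)
        motion_rng = np.random.default_rng(c_motion)
        heading_seed = int(c_motion.generate_state(2, np.uint32)[1])
        yield state_rng, motion_rng, heading_seed


def simulate_trajectory(
    params: SimulationParams, schedule: LightSchedule
) -> tuple[list[Trajectory], GroundTruth]:
    """Simulate positional tracks for ``params.n_subjects`` subjects.

    Returns one :class:`Trajectory` per subject (deterministic given the
    seed) and the closed-form :class:`GroundTruth`.
    """
    w, h = params.arena_mm
    dt = 1.0 / params.fps
    active_speed = _active_speed_per_frame(params, schedule)
    trajectories = []
    for i, (state_rng, motion_rng, heading_seed) in enumerate(_subject_streams(params)):
        active = _frame_states(params, state_rng, schedule)
        steps = np.where(active, active_speed, params.jitter_speed) * dt
        x0 = motion_rng.uniform(0.0, w)
        y0 = motion_rng.uniform(0.0, h)
        xs, ys = _walk(x0, y0, steps, w, h, heading_seed)
        t = np.arange(params.n_frames) * dt
        trajectories.append(
            Trajectory(subject_id=f"sim{i:03d}", t=t, x=xs, y=ys, stage=params.stage)
        )
    return trajectories, ground_truth(params, schedule)


def simulate_ethogram(
    params: SimulationParams, schedule: LightSchedule
) -> list[EthogramEvents]:
    """Emit each subject's active-state intervals as a scored ethogram.

    Shares the state randomness with :func:`simulate_trajectory`: with the
    same params (incl. seed) the intervals delimit exactly the frames in
    which the trajectory is in the active state.
    """
    dt = 1.0 / params.fps
    events = []
    for i, (state_rng, _motion_rng, _hs) in enumerate(_subject_streams(params)):
        active = _frame_states(params, state_rng, schedule)
        intervals = _runs_to_intervals(active, dt)
        events.append(
            EthogramEvents(
                subject_id=f"sim{i:03d}", behavior="active swimming", intervals=intervals
            )
        )
    return events


def _runs_to_intervals(active: np.ndarray, dt: float) -> np.ndarray:
    """Maximal runs of True in the frame-interval state array, as (start, stop)
    seconds. Frame interval i (0-based here) covers (i*dt, (i+1)*dt]."""
    if len(active) == 0 or not active.any():
        return np.empty((0, 2))
    padded = np.concatenate([[False], active, [False]])
    d = np.diff(padded.astype(np.int8))
    starts = np.flatnonzero(d == 1)
    stops = np.flatnonzero(d == -1)
    return np.column_stack([starts * dt, stops * dt])


# --------------------------------------------------------------------- #
# presets

# Illustrative phenotype presets (juvenile scale, mm/s and 1/s). The study
# system spans diurnal, nocturnal, arrhythmic and crepuscular species; no
# per-species quantitative activity parameters are published, so these are
# qualitative archetypes, not calibrated species models.
_PRESETS_JUVENILE = {
    "diurnal": dict(
        light=PhaseActivity(30.0, 1 / 600, 1 / 120),
        dark=PhaseActivity(18.0, 1 / 180, 1 / 240),
        crepuscular_multiplier=1.0,
    ),
    "nocturnal": dict(
        light=PhaseActivity(18.0, 1 / 180, 1 / 240),
        dark=PhaseActivity(30.0, 1 / 600, 1 / 120),
        crepuscular_multiplier=1.0,
    ),
    "arrhythmic": dict(
        light=PhaseActivity(24.0, 1 / 300, 1 / 150),
        dark=PhaseActivity(24.0, 1 / 300, 1 / 150),
        crepuscular_multiplier=1.0,
    ),
    "crepuscular": dict(
        light=PhaseActivity(24.0, 1 / 300, 1 / 150),
        dark=PhaseActivity(24.0, 1 / 300, 1 / 150),
        crepuscular_multiplier=2.0,
    ),
}

#: Adult active speeds scale with the adult threshold (40 vs 12 mm/s).
_ADULT_SPEED_SCALE = 4.0


def species_preset(phenotype: str, stage: str = "juvenile", seed: int = 0,
                   **overrides) -> SimulationParams:
    """Simulation parameters for a qualitative activity phenotype.

    ``phenotype`` is one of ``diurnal``, ``nocturnal``, ``arrhythmic``,
    ``crepuscular``. Additional keyword arguments override any
    :class:`SimulationParams` field.
    """
    _check_stage(stage)
    try:
        base = _PRESETS_JUVENILE[phenotype]
    except KeyError:
        raise ValueError(
            f"unknown phenotype {phenotype!r}; expected one of {sorted(_PRESETS_JUVENILE)}"
        ) from None
    light, dark = base["light"], base["dark"]
    if stage == "adult":
        light = replace(light, mean_active_speed=light.mean_active_speed * _ADULT_SPEED_SCALE)
        dark = replace(dark, mean_active_speed=dark.mean_active_speed * _ADULT_SPEED_SCALE)
    kwargs = dict(
        seed=seed,
        light=light,
        dark=dark,
        stage=stage,
        crepuscular_multiplier=base["crepuscular_multiplier"],
    )
    kwargs.update(overrides)
    return SimulationParams(**kwargs)


def params_with_expected_ar(
    target_ar: float,
    seed: int = 0,
    stage: str = "juvenile",
    light: Optional[PhaseActivity] = None,
    dark_rest_rate: float = 1 / 150,
    dark_wake_rate: float = 1 / 120,
    **overrides,
) -> SimulationParams:
    """Parameters whose closed-form activity change ratio equals ``target_ar``.

    Holds the light phase and the dark-phase hazards fixed and solves the
    ground-truth formula for the dark-phase active speed. Only valid for
    crepuscular_multiplier = 1 (the default here).
    """
    if not (-1 < target_ar < 1):
        raise ValueError("target_ar must lie strictly inside (-1, 1)")
    _check_stage(stage)
    thr = SPEED_THRESHOLDS_MM_S[stage]
    j = REST_JITTER_FRACTION * thr
    if light is None:
        scale = _ADULT_SPEED_SCALE if stage == "adult" else 1.0
        light = PhaseActivity(30.0 * scale, 1 / 600, 1 / 120)
    D = _phase_hourly_distance(light, j, 1.0)
    N_target = D * (1.0 - target_ar) / (1.0 + target_ar)
    rf_d = dark_rest_rate / (dark_rest_rate + dark_wake_rate)
    v_dark = (N_target / 3600.0 - rf_d * j) / (1.0 - rf_d)
    if v_dark <= thr:
        raise ValueError(
            f"target_ar={target_ar} requires a dark active speed of "
            f"{v_dark:.2f} mm/s, at or below the {stage} threshold ({thr} mm/s); "
            "choose different hazards"
        )
    dark = PhaseActivity(v_dark, dark_rest_rate, dark_wake_rate)
    return SimulationParams(seed=seed, light=light, dark=dark, stage=stage, **overrides)
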