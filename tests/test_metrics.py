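import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

import fishrhythm as fr
from fishrhythm.core import HourlyProfile, RestBout, Trajectory
from fishrhythm.metrics import rhythm_indices


def _profile(values, rest=None, **kw):
    return HourlyProfile(
        subject_id="p",
        locomotion=np.asarray(values, dtype=float),
        rest_minutes=np.zeros(24) if rest is None else np.asarray(rest, dtype=float),
        **kw,
    )


def _constant_speed_trajectory(speed_mm_s=20.0, fps=1.0, days=1):
    n = int(86400 * days * fps) + 1
    t = np.arange(n) / fps
    return Trajectory("c", t=t, x=(speed_mm_s / fps) * np.arange(n), y=np.zeros(n),
                      stage="juvenile")


# ---------------------------------------------------------------- binning


def test_constant_speed_fills_all_bins_equally(schedule):
    tr = _constant_speed_trajectory(20.0)
    prof = fr.bin_hourly(tr, [], schedule)
    assert prof.locomotion == pytest.approx(np.full(24, 20.0 * 3600))
    # bin sum equals total path length
    assert prof.locomotion.sum() == pytest.approx(20.0 * 86400, rel=1e-9)


def test_rest_bout_split_pro_rata_across_bins(schedule):
    # 90 min bout starting exactly at a bin boundary (t=3600 is ZT2)
    tr = _constant_speed_trajectory(20.0)
    bouts = [RestBout(start_s=3600.0, stop_s=3600.0 + 90 * 60)]
    prof = fr.bin_hourly(tr, bouts, schedule)
    assert prof.rest_minutes[2] == pytest.approx(60.0)
    assert prof.rest_minutes[3] == pytest.approx(30.0)
    assert prof.rest_minutes.sum() == pytest.approx(90.0)


def test_multiday_profile_averages_single_day_binnings(schedule):
    params = fr.species_preset("diurnal", seed=21, fps=5.0, duration_h=72.0)
    (tr,), _ = fr.simulate_trajectory(params, schedule)
    sp = fr.compute_speed(tr)
    thr = fr.threshold_for_stage("juvenile")
    bouts = fr.detect_rest_bouts(sp, thr)
    prof = fr.bin_hourly(tr, bouts, schedule, speed=sp)
    assert prof.n_days == 3

    # independent per-day recomputation: slice each 24 h day and average
    n_day = int(86400 * params.fps)
    day_profiles = []
    for d in range(3):
        sl = slice(d * n_day, (d + 1) * n_day + 1)
        sub = Trajectory(tr.subject_id, t=tr.t[sl] - tr.t[sl][0], x=tr.x[sl],
                         y=tr.y[sl], stage=tr.stage, valid=tr.valid[sl])
        sub_sp = fr.compute_speed(sub)
        sub_bouts = fr.detect_rest_bouts(sub_sp, thr)
        day_profiles.append(fr.bin_hourly(sub, sub_bouts, schedule, speed=sub_sp))
    mean_loco = np.mean([p.locomotion for p in day_profiles], axis=0)
    assert prof.locomotion == pytest.approx(mean_loco, rel=1e-9)


def test_partial_day_recordings_are_rejected(schedule):
    tr = _constant_speed_trajectory(20.0)
    short = Trajectory("s", t=tr.t[:7200], x=tr.x[:7200], y=tr.y[:7200],
                       stage="juvenile")
    with pytest.raises(ValueError, match="whole 24 h days"):
        fr.bin_hourly(short, [], schedule)


def test_sub_hour_recording_is_an_error(schedule):
    tr = _constant_speed_trajectory(20.0)
    tiny = Trajectory("s", t=tr.t[:100], x=tr.x[:100], y=tr.y[:100], stage="juvenile")
    with pytest.raises(ValueError, match="1 h"):
        fr.bin_hourly(tiny, [], schedule)


# ---------------------------------------------------------------- D, N, A_R


def test_day_night_means_flat_profile(schedule):
    D, N = fr.day_night_means(_profile(np.full(24, 7.0)), schedule)
    assert D == N == pytest.approx(7.0)


def test_day_night_means_light_only(schedule):
    vals = np.zeros(24)
    vals[schedule.light_bins] = 10.0
    D, N = fr.day_night_means(_profile(vals), schedule)
    assert (D, N) == (10.0, 0.0)


def test_day_night_means_match_brute_force(schedule, rng):
    vals = rng.uniform(0, 100, 24)
    D, N = fr.day_night_means(_profile(vals), schedule)
    assert D == pytest.approx(np.mean([vals[k] for k in range(24) if k < 14]))
    assert N == pytest.approx(np.mean([vals[k] for k in range(24) if k >= 14]))


def test_diurnality_boundary_values():
    assert fr.diurnality_index(10.0, 0.0) == 1.0
    assert fr.diurnality_index(0.0, 10.0) == -1.0
    assert fr.diurnality_index(3.0, 1.0) == pytest.approx(0.5)
    assert fr.diurnality_index(0.0, 0.0) is None
    with pytest.raises(ValueError):
        fr.diurnality_index(-1.0, 1.0)


@given(st.floats(0, 1e6), st.floats(0, 1e6))
def test_diurnality_antisymmetry_and_bounds(D, N):
    ar = fr.diurnality_index(D, N)
    rev = fr.diurnality_index(N, D)
    if ar is None:
        assert rev is None
    else:
        assert -1.0 <= ar <= 1.0
        assert ar == pytest.approx(-rev)


# ---------------------------------------------------------------- C_R


def test_crepuscularity_doubled_transition_bins(schedule):
    vals = np.full(24, 5.0)
    vals[[0, 14]] = 10.0  # dawn and dusk bins carry double activity
    assert fr.crepuscularity_index(_profile(vals), schedule) == pytest.approx(1.0)


def test_crepuscularity_flat_profile(schedule):
    assert fr.crepuscularity_index(_profile(np.full(24, 5.0)), schedule) == pytest.approx(0.0)


def test_crepuscularity_silent_transitions(schedule):
    vals = np.full(24, 5.0)
    vals[[0, 14]] = 0.0
    assert fr.crepuscularity_index(_profile(vals), schedule) == pytest.approx(-1.0)


def test_crepuscularity_undefined_for_motionless_profile(schedule):
    assert fr.crepuscularity_index(_profile(np.zeros(24)), schedule) is None


def test_crepuscularity_window_2h(schedule):
    vals = np.full(24, 5.0)
    vals[[0, 1, 14, 15]] = 15.0
    assert fr.crepuscularity_index(_profile(vals), schedule, window_h=2) == pytest.approx(2.0)


@given(k=st.floats(0.01, 100))
def test_indices_scale_invariant(schedule, k):
    vals = np.array([float(3 + (i * 7) % 11) for i in range(24)])
    base = rhythm_indices(_profile(vals), schedule)
    scaled = rhythm_indices(_profile(vals * k), schedule)
    assert scaled.A_R == pytest.approx(base.A_R)
    assert scaled.C_R == pytest.approx(base.C_R)


# ---------------------------------------------------------------- groups


def test_group_average_identity_and_mean(schedule):
    a = _profile(np.full(24, 2.0), rest=np.full(24, 10.0))
    b = _profile(np.full(24, 4.0), rest=np.full(24, 30.0))
    single = fr.group_average([a])
    assert single.locomotion == pytest.approx(a.locomotion)
    both = fr.group_average([a, b], group_id="g")
    assert both.locomotion == pytest.approx(np.full(24, 3.0))
    assert both.rest_minutes == pytest.approx(np.full(24, 20.0))
    assert both.n_subjects == 2


def test_group_average_matches_brute_force(schedule, rng):
    profiles = [_profile(rng.uniform(0, 50, 24)) for _ in range(6)]
    avg = fr.group_average(profiles)
    brute = np.zeros(24)
    for p in profiles:
        brute += p.locomotion
    assert avg.locomotion == pytest.approx(brute / 6)


def test_group_average_rejects_mismatched_days(schedule):
    a = _profile(np.full(24, 2.0), n_days=1)
    b = _profile(np.full(24, 2.0), n_days=2)
    with pytest.raises(ValueError):
        fr.group_average([a, b])
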