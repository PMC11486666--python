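"""Motility metrics: velocity schemes, speeds, arrest, MSD, angles, filters."""

import numpy as np
import pytest

from hprw import (
    FILTER_PRESETS,
    TrackTable,
    apply_track_filters,
    arrest_coefficient,
    centered_velocities,
    forward_velocities,
    frame_speeds,
    mean_track_speed,
    msd_ensemble,
    net_displacement,
    sample_parameter_path,
    simulate_track,
    track_metrics,
    turning_angles,
)

from conftest import make_track, random_gapped_track


def linear_track(n=5, step=(1.0, 0.0, 0.0), track_id="lin"):
    pos = np.outer(np.arange(n), step)
    return make_track(np.arange(n), pos, track_id=track_id)


# --- velocities ---------------------------------------------------------


def test_centered_velocity_linear_motion(acq):
    t = linear_track(3)
    vs = centered_velocities(t, acq)
    assert vs.valid.tolist() == [False, True, False]
    assert np.allclose(vs.u[1], [2, 0, 0])  # 1 µm per 0.5 min step


def test_gap_invalidates_all_neighbors(acq):
    """Frames {0,1,3,4}: every interior slot misses a neighbor."""
    t = make_track([0, 1, 3, 4], np.zeros((4, 3)))
    vs = centered_velocities(t, acq)
    assert vs.n_valid == 0


def test_short_track_has_empty_mask(acq):
    t = make_track([0, 1], np.zeros((2, 3)))
    assert centered_velocities(t, acq).n_valid == 0


@pytest.mark.parametrize("seed", range(20))
def test_centered_velocities_brute_force_oracle(seed, acq):
    """Slot-by-slot recomputation agrees elementwise to 1e-12."""
    t = random_gapped_track(np.random.default_rng(seed))
    vs = centered_velocities(t, acq)
    lookup = {int(f): p for f, p in zip(t.frames, t.positions)}
    first, last = int(t.frames[0]), int(t.frames[-1])
    for slot in range(last - first + 1):
        f = first + slot
        if all(f + d in lookup for d in (-1, 0, 1)):
            expected = (lookup[f + 1] - lookup[f - 1]) / (2 * acq.frame_interval)
            assert vs.valid[slot]
            assert np.all(np.abs(vs.u[slot] - expected) < 1e-12)
        else:
            assert not vs.valid[slot]


def test_forward_velocities_recover_model_velocities(acq):
    """Per-frame displacement velocities equal the simulator's true u_t."""
    path = sample_parameter_path("constant", {"q": 0.5, "a": 2.0}, 50)
    track, u = simulate_track(path, acq, np.random.default_rng(0))
    vs = forward_velocities(track, acq)
    assert vs.valid[:-1].all() and not vs.valid[-1]
    assert np.allclose(vs.u[:-1], u[:-1])


# --- speeds and arrest --------------------------------------------------


def test_frame_speeds_and_gap_skipping(acq):
    t = make_track([0, 1, 3, 4], [[0, 0, 0], [1, 0, 0], [3, 0, 0], [4, 0, 0]])
    speeds = frame_speeds(t, acq)
    assert len(speeds) == 2  # pairs (0,1) and (3,4); (1,3) spans a gap
    assert np.allclose(speeds, 2.0)


def test_mean_track_speed_average(acq):
    t = make_track([0, 1, 2], [[0, 0, 0], [0, 0, 0], [2, 0, 0]])  # speeds 0, 4
    assert mean_track_speed(t, acq) == pytest.approx(2.0)


def test_mean_speed_undefined_for_single_point(acq):
    assert np.isnan(mean_track_speed(make_track([0], [[0, 0, 0]]), acq))


def test_arrest_coefficient_half(acq):
    # alternating 0.5 and 1.5 µm steps -> speeds 1 and 3 µm/min
    pos = np.cumsum([[0, 0, 0], [0.5, 0, 0], [1.5, 0, 0], [0.5, 0, 0], [1.5, 0, 0]], axis=0)
    t = make_track(np.arange(5), pos)
    assert arrest_coefficient(t, acq) == pytest.approx(50.0)


def test_arrest_all_and_strictness(acq):
    still = make_track(np.arange(4), np.zeros((4, 3)))
    assert arrest_coefficient(still, acq) == 100.0
    # steps of exactly 1 µm per 0.5 min = 2 µm/min: strict < leaves 0%
    t = linear_track(5)
    assert arrest_coefficient(t, acq) == 0.0


@pytest.mark.parametrize("seed", range(5))
def test_arrest_invariant_under_rigid_motion(seed, acq):
    rng = np.random.default_rng(seed)
    t = random_gapped_track(rng, gap_p=0.0)
    mat = np.linalg.qr(rng.normal(size=(3, 3)))[0]  # random rotation (or reflection)
    moved = make_track(t.frames, t.positions @ mat.T + rng.normal(size=3))
    assert arrest_coefficient(moved, acq) == pytest.approx(arrest_coefficient(t, acq))
    assert mean_track_speed(moved, acq) == pytest.approx(mean_track_speed(t, acq))


@pytest.mark.parametrize("seed", range(5))
def test_mean_speed_bounds_net_displacement_rate(seed, acq):
    """Path length >= chord: mean speed >= net displacement / duration."""
    t = random_gapped_track(np.random.default_rng(seed), gap_p=0.0)
    chord_rate = net_displacement(t) / t.duration(acq)
    assert mean_track_speed(t, acq) >= chord_rate - 1e-12


# --- MSD ----------------------------------------------------------------


def test_msd_ballistic_exact(acq):
    """Constant 3 µm/min motion: MSD(lag) = (3*lag)^2 at every lag."""
    t = make_track(np.arange(25), np.outer(np.arange(25), [1.5, 0, 0]))
    curve = msd_ensemble(TrackTable(tracks=[t], acquisition=acq), max_lag=5.0)
    assert np.allclose(curve.msd, (3.0 * curve.lags) ** 2)
    assert curve.msd[0] == 0.0


def test_msd_stationary_zero(acq):
    t = make_track(np.arange(25), np.zeros((25, 3)))
    curve = msd_ensemble(TrackTable(tracks=[t], acquisition=acq), max_lag=4.0)
    assert np.allclose(curve.msd, 0.0)


def test_msd_continuity_requirement(acq):
    """Tracks not continuously observed for 10 min are excluded."""
    short = make_track(np.arange(15), np.zeros((15, 3)), "short")  # 7 min
    gappy_frames = np.concatenate([np.arange(10), np.arange(11, 30)])  # gap at 10
    gappy = make_track(gappy_frames, np.zeros((29, 3)), "gappy")
    long = make_track(np.arange(25), np.zeros((25, 3)), "long")  # 12 min
    curve = msd_ensemble(TrackTable(tracks=[short, gappy, long], acquisition=acq),
                         max_lag=2.0)
    assert curve.n_tracks.max() == 1


def test_msd_rejects_non_grid_lag(acq):
    t = make_track(np.arange(25), np.zeros((25, 3)))
    with pytest.raises(ValueError, match="multiple"):
        msd_ensemble(TrackTable(tracks=[t], acquisition=acq), max_lag=1.3)


# --- turning angles -----------------------------------------------------


def test_turning_angle_geometry(acq):
    fwd = turning_angles(linear_track(4), acq)
    assert np.allclose(fwd, 0.0)
    rev = make_track([0, 1, 2], [[0, 0, 0], [1, 0, 0], [0, 0, 0]])
    assert np.allclose(turning_angles(rev, acq), 180.0)
    right = make_track([0, 1, 2], [[0, 0, 0], [1, 0, 0], [1, 1, 0]])
    assert np.allclose(turning_angles(right, acq), 90.0)


def test_turning_angle_min_step_floor(acq):
    """Sub-threshold steps contribute no angle (and no NaN)."""
    t = make_track([0, 1, 2], [[0, 0, 0], [0.05, 0, 0], [0.1, 0.05, 0]])
    assert turning_angles(t, acq, min_step=0.2).size == 0


# --- filters ------------------------------------------------------------


def fixture_cohort(acq):
    """Tracks with known durations, displacements and velocity counts."""
    tracks = [
        # 3.5 min: fails every duration filter
        make_track(np.arange(8), np.outer(np.arange(8), [2, 0, 0]), "short"),
        # 10 min, displacement 10 µm: fails only the 15 µm filter
        make_track(np.arange(21), np.outer(np.arange(21), [0.5, 0, 0]), "small-disp"),
        # 4.5 min continuous: 8 valid velocities -> fails clustering count
        make_track(np.arange(10), np.outer(np.arange(10), [2, 0, 0]), "few-vel"),
        # 4.5 min, passes everything except invivo's 5 min... except too few velocities
        make_track(np.arange(10), np.outer(np.arange(10), [2, 0, 0]) + 100, "borderline"),
        # 12 min continuous, 20 µm net: passes everything
        make_track(np.arange(25), np.outer(np.arange(25), [1, 0, 0]), "good"),
    ]
    return TrackTable(tracks=tracks, acquisition=acq)


@pytest.mark.parametrize(
    "preset,expected_excluded",
    [
        ("speed_2d3d", {"short", "small-disp"}),
        ("blebbistatin", {"short"}),
        ("clustering", {"short", "few-vel", "borderline"}),
        ("invivo", {"short", "few-vel", "borderline"}),
    ],
)
def test_filter_presets_exclusions(preset, expected_excluded, acq):
    table = fixture_cohort(acq)
    kept, log = apply_track_filters(table, preset)
    assert set(log["track_id"]) == expected_excluded
    assert len(kept) + len(log) == len(table)


def test_filter_log_reasons(acq):
    _, log = apply_track_filters(fixture_cohort(acq), "speed_2d3d")
    reasons = dict(zip(log["track_id"], log["reason"]))
    assert "duration<4min" in reasons["short"]
    assert "net_displacement<15um" in reasons["small-disp"]


def test_preset_thresholds():
    assert FILTER_PRESETS["speed_2d3d"].min_displacement == 15.0
    assert FILTER_PRESETS["clustering"].min_valid_velocities == 15
    assert FILTER_PRESETS["clustering"].min_duration == 4.0  # 240 s
    assert FILTER_PRESETS["invivo"].min_duration == 5.0


def test_track_metrics_table(acq):
    df = track_metrics(fixture_cohort(acq)).set_index("track_id")
    assert df.loc["good", "duration_min"] == 12.0
    assert df.loc["good", "mean_speed_um_min"] == pytest.approx(2.0)
    assert df.loc["good", "net_disp_um"] == pytest.approx(24.0)
    assert df.loc["few-vel", "n_valid_velocities"] == 8
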