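"""Synthetic-trial generator: minimum-jerk primitives, ground-truth
consistency, strategy presets, cohorts."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from reachkin.marker_io import write_trial
from reachkin.preprocess import tangential_speed
from reachkin.simulate import (
    CONTROL_RANGES,
    PATIENT_RANGES,
    PRESETS,
    StrategyConfig,
    compose_submovements,
    minimum_jerk_profile,
    simulate_cohort,
    simulate_trial,
)


def test_minimum_jerk_boundary_and_midpoint():
    prof = minimum_jerk_profile(200.0, 2.0, 60.0).values
    assert prof[0] == 0.0
    assert prof[-1] == pytest.approx(200.0)
    assert prof[len(prof) // 2] == pytest.approx(100.0)  # midtime symmetry


def test_minimum_jerk_peak_speed_factor():
    D, T, fs = 340.0, 1.24, 600.0  # fine sampling isolates the analytic factor
    v = np.gradient(minimum_jerk_profile(D, T, fs).values, 1 / fs)
    assert v.max() == pytest.approx(1.875 * D / T, rel=1e-3)


def test_zero_displacement_profile_is_zero():
    assert not minimum_jerk_profile(0.0, 1.0, 60.0).values.any()


def test_invalid_profile_duration_rejected():
    with pytest.raises(ValueError):
        minimum_jerk_profile(100.0, 0.0, 60.0)


def test_single_submovement_equals_plain_profile():
    a = compose_submovements(1, 300.0, 1.2, 60.0, seed=5).values
    b = minimum_jerk_profile(300.0, 1.2, 60.0).values
    np.testing.assert_allclose(a, b, atol=1e-12)


@given(st.integers(0, 10_000))
def test_composed_displacement_sums_exactly(seed):
    s = compose_submovements(4, 500.0, 2.0, 60.0, seed=seed).values
    assert s[-1] == pytest.approx(500.0, abs=1e-6)
    assert np.all(np.diff(s) >= -1e-9)  # monotone: submovements never reverse


def test_infeasible_submovement_count_rejected():
    with pytest.raises(ValueError, match="do not fit"):
        compose_submovements(10, 400.0, 1.0, 60.0)  # 10 x 0.1 s < 250 ms spacing


def test_five_submovements_produce_five_speed_peaks():
    s = compose_submovements(5, 400.0, 2.5, 60.0, seed=1).values
    traj = np.stack([s, np.zeros_like(s), np.zeros_like(s)], axis=1)
    speed = tangential_speed(traj, 60.0, presmooth_passes=0)
    above = speed > 50.0
    runs = np.diff(above.astype(int))
    assert (runs == 1).sum() == 5  # five excursions above the threshold


def test_config_validation_catches_inconsistencies():
    with pytest.raises(ValueError, match="sum to 100"):
        StrategyConfig(ae=50.0, tf=40.0, ta=5.0).validate()
    with pytest.raises(ValueError, match="mouth_return_fraction"):
        StrategyConfig(mouth_return_fraction=1.5).validate()
    with pytest.raises(ValueError, match="submovements"):
        StrategyConfig(k_rg=10, rg_s=1.0).validate()


@pytest.mark.parametrize("preset", sorted(PRESETS))
def test_ground_truth_is_internally_consistent(preset):
    cfg = PRESETS[preset]()
    cfg.seed = 4
    trial, gt = simulate_trial(cfg)
    trial.validate()
    assert gt.ae + gt.tf + gt.ta == pytest.approx(100.0, abs=1e-9)
    assert gt.md13 == pytest.approx(gt.md12 + gt.md23, abs=1e-9)
    t = gt.events.as_tuple()
    assert all(a < b for a, b in zip(t, t[1:]))
    assert t[-1] < trial.n_frames
    assert gt.nmu_total == gt.nmu_rg + gt.nmu_bgm
    assert sum(gt.durations.values()) == pytest.approx((t[-1] - t[0]) / trial.fs)


def test_same_seed_reproduces_identical_bytes(tmp_path):
    cfg = PRESETS["stroke-return"]()
    cfg.seed = 42
    t1, _ = simulate_trial(cfg)
    t2, _ = simulate_trial(cfg)
    p1, p2 = tmp_path / "a.tsv", tmp_path / "b.tsv"
    write_trial(t1, p1)
    write_trial(t2, p2)
    assert p1.read_bytes() == p2.read_bytes()


def test_different_seeds_differ():
    cfg = PRESETS["healthy"]()
    cfg.seed = 1
    a, _ = simulate_trial(cfg)
    cfg.seed = 2
    b, _ = simulate_trial(cfg)
    assert not np.array_equal(a.positions["HAND"], b.positions["HAND"])


def test_strategy_contrast_forward_posture_vs_trunk_return():
    """The trunk-return strategy recovers the mouth excursion while
    bringing; the forward-posture strategy barely does, at equal forward
    excursion."""
    fwd_cfg = PRESETS["stroke-forward-posture"]()
    ret_cfg = PRESETS["stroke-return"]()
    for cfg in (fwd_cfg, ret_cfg):
        cfg.noise_rms_mm = 0.0
        cfg.seed = 8
    _, fwd = simulate_trial(fwd_cfg)
    _, ret = simulate_trial(ret_cfg)
    assert fwd.md12 == pytest.approx(ret.md12, abs=1e-6)
    assert abs(ret.md23) > abs(fwd.md23)
    assert abs(ret.md23) == pytest.approx(ret.md12, rel=1e-6)


def test_left_sided_trial_is_valid_and_analyzable():
    cfg = PRESETS["healthy"]()
    cfg.side = "left"
    cfg.noise_rms_mm = 0.0
    trial, gt = simulate_trial(cfg)
    from reachkin.indexes import compute_trial_indexes
    from reachkin.segmentation import detect_events

    ti = compute_trial_indexes(trial, detect_events(trial))
    assert abs(ti.contributions.ae - gt.ae) < 0.5


def test_cohort_shape_metadata_and_determinism():
    trials, meta = simulate_cohort(2, 3, seed=5)
    assert len(trials) == (2 + 3) * 3
    assert sorted(meta["group"].value_counts().to_dict().items()) == [
        ("control", 3), ("stroke", 2),
    ]
    again, _ = simulate_cohort(2, 3, seed=5)
    np.testing.assert_array_equal(
        trials[0][0].positions["HAND"], again[0][0].positions["HAND"]
    )


def test_cohort_rejects_empty_group_and_inverted_ranges():
    with pytest.raises(ValueError):
        simulate_cohort(0, 6, seed=1)
    bad = dict(PATIENT_RANGES)
    bad["rg_s"] = (3.0, 1.0)
    with pytest.raises(ValueError, match="inverted"):
        simulate_cohort(1, 1, patient_ranges=bad, seed=1)


def test_cohort_parameters_fall_within_group_ranges():
    trials, meta = simulate_cohort(4, 4, seed=9)
    for _, row in meta.iterrows():
        ranges = PATIENT_RANGES if row["group"] == "stroke" else CONTROL_RANGES
        assert ranges["ae"][0] <= row["ae_true"] <= ranges["ae"][1]
        assert ranges["ta"][0] <= row["ta_true"] <= ranges["ta"][1]
        assert ranges["rg_s"][0] <= row["rg_s_true"] <= ranges["rg_s"][1]
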