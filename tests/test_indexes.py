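"""Per-trial index battery: contributions, elbow, mouth, arm, movement units."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from reachkin.indexes import (
    DegenerateMovementError,
    IndexConfig,
    arm_contribution,
    compute_trial_indexes,
    count_movement_units,
    elbow_angle,
    elbow_rom,
    mouth_displacements,
    reaching_contributions,
)
from reachkin.marker_io import mirror_trial
from reachkin.preprocess import tangential_speed
from reachkin.segmentation import TaskEvents, detect_events
from reachkin.simulate import PRESETS, compose_submovements, minimum_jerk_profile, simulate_trial


def _synthetic_reach(dh, dc7, dsh, n=80, t1=10, t2=70):
    """Trial whose X displacements between t1 and t2 are exactly as given."""
    from reachkin.marker_io import Trial

    ramp = np.zeros(n)
    ramp[t1:t2] = np.linspace(0, 1, t2 - t1)
    ramp[t2:] = 1.0

    def marker(x0, dx, y, z):
        return np.stack([x0 + dx * ramp, np.full(n, y), np.full(n, z)], axis=1)

    positions = {
        "HAND": marker(50, dh, -100, 30),
        "WRIST": marker(0, dh, -100, 40),
        "ELBOW": marker(-30, dh / 2, -150, 250),
        "SHOULDER": marker(-40, dsh, -180, 430),
        "C7": marker(-80, dc7, 0, 470),
        "MOUTH": marker(20, dc7, 0, 600),
        "GLASS_TOP": marker(400, 0, 0, 100),
        "GLASS_BOTTOM": marker(400, 0, 0, 0),
    }
    return Trial(positions=positions, fs=60.0)


def test_contribution_arithmetic_matches_definitions():
    # dh=400, dc7=150, dsh=190 -> AE=52.5, TF=37.5, TA=10.0
    trial = _synthetic_reach(400, 150, 190)
    cfg = IndexConfig(smoothing_passes=0)
    c = reaching_contributions(trial, TaskEvents(10, 70, 72, 74, 76), cfg)
    np.testing.assert_allclose([c.ae, c.tf, c.ta], [52.5, 37.5, 10.0], atol=1e-9)
    np.testing.assert_allclose(c.total, 100.0, atol=1e-9)


def test_pure_arm_reach_is_all_elongation():
    trial = _synthetic_reach(300, 0, 0)
    cfg = IndexConfig(smoothing_passes=0)
    c = reaching_contributions(trial, TaskEvents(10, 70, 72, 74, 76), cfg)
    np.testing.assert_allclose([c.ae, c.tf, c.ta], [100.0, 0.0, 0.0], atol=1e-12)


def test_degenerate_reach_rejected():
    trial = _synthetic_reach(30, 10, 10)  # below 50 mm minimum
    with pytest.raises(DegenerateMovementError):
        reaching_contributions(trial, TaskEvents(10, 70, 72, 74, 76), IndexConfig(smoothing_passes=0))


def test_elbow_angle_reference_configurations():
    s = np.array([0.0, 0.0, 100.0])
    e = np.zeros(3)
    np.testing.assert_allclose(elbow_angle(s, e, np.array([0.0, 0.0, -100.0])), 180.0)
    np.testing.assert_allclose(elbow_angle(s, e, np.array([100.0, 0.0, 0.0])), 90.0)
    with pytest.raises(ValueError, match="1 mm"):
        elbow_angle(s, e, np.array([0.0, 0.0, 0.5]))


@given(st.integers(0, 10_000))
def test_elbow_angle_rotation_invariant(seed):
    rng = np.random.default_rng(seed)
    pts = rng.uniform(-100, 100, size=(3, 3))
    if min(np.linalg.norm(pts[0] - pts[1]), np.linalg.norm(pts[2] - pts[1])) < 2.0:
        return
    q, _ = np.linalg.qr(rng.normal(size=(3, 3)))
    shift = rng.uniform(-500, 500, size=3)
    a1 = elbow_angle(*pts)
    a2 = elbow_angle(*(pts @ q.T + shift))
    np.testing.assert_allclose(a1, a2, atol=1e-7)


def test_frozen_arm_has_zero_rom():
    trial = _synthetic_reach(300, 100, 130)
    for m in ("SHOULDER", "ELBOW", "WRIST"):
        trial.positions[m] = np.tile(trial.positions[m][0], (trial.n_frames, 1))
    rom = elbow_rom(trial, TaskEvents(10, 70, 72, 74, 76), IndexConfig(smoothing_passes=0))
    assert rom == pytest.approx(0.0, abs=1e-9)


def test_mouth_displacement_example_and_identity():
    trial = _synthetic_reach(300, 190.33, 220)
    # mouth: forward 190.33 over reaching, then backward 90.33 by t3
    mouth = trial.positions["MOUTH"].copy()
    back = np.zeros(trial.n_frames)
    back[70:74] = np.linspace(0, 1, 4)
    back[74:] = 1.0
    mouth[:, 0] -= 90.33 * back
    trial.positions["MOUTH"] = mouth
    md = mouth_displacements(trial, TaskEvents(10, 70, 74, 76, 78), IndexConfig(smoothing_passes=0))
    assert md.md12 == pytest.approx(190.33, abs=1e-9)
    assert md.md23 == pytest.approx(-90.33, abs=1e-9)
    assert md.md13 == pytest.approx(100.0, abs=1e-9)
    assert md.md13 == md.md12 + md.md23  # telescoping, exact


def test_arm_contribution_limit_and_translation_invariance():
    trial = _synthetic_reach(300, 100, 130)
    ev = TaskEvents(2, 5, 70, 72, 76)  # BGM window covers the motion
    # shoulder frozen during BGM -> arm does everything
    frozen = trial.copy()
    frozen.positions["SHOULDER"] = np.tile(frozen.positions["SHOULDER"][0], (trial.n_frames, 1))
    cfg = IndexConfig(smoothing_passes=0)
    assert arm_contribution(frozen, ev, "BGM", cfg) == pytest.approx(100.0)
    shifted = trial.copy()
    for m in shifted.positions:
        shifted.positions[m] = shifted.positions[m] + np.array([123.0, -45.0, 67.0])
    np.testing.assert_allclose(
        arm_contribution(trial, ev, "BGM", cfg),
        arm_contribution(shifted, ev, "BGM", cfg),
        atol=1e-9,
    )


def _brute_force_nmu(speed, window, fs, threshold=50.0, prominence=10.0, min_sep_s=0.1):
    """Independent oracle: exhaustive scan applying the peak rules."""
    start, end = window
    seg = speed[start:end]
    accepted = []
    min_sep = max(1, round(min_sep_s * fs))
    for i in range(1, len(seg) - 1):
        # plateau peaks count once, at their first sample (zero-prominence
        # shoulder points are dropped by the prominence rule below)
        if not (seg[i] > seg[i - 1] and seg[i] >= seg[i + 1]):
            continue
        if seg[i] <= threshold:
            continue
        # prominence: walk out to the nearest higher sample on each side
        left = i
        lmin = seg[i]
        while left > 0 and seg[left - 1] <= seg[i]:
            left -= 1
            lmin = min(lmin, seg[left])
        lbase = lmin if left > 0 else min(lmin, seg[: i + 1].min())
        right = i
        rmin = seg[i]
        while right < len(seg) - 1 and seg[right + 1] <= seg[i]:
            right += 1
            rmin = min(rmin, seg[right])
        rbase = rmin if right < len(seg) - 1 else min(rmin, seg[i:].min())
        if seg[i] - max(lbase, rbase) < prominence:
            continue
        if accepted and i - accepted[-1] < min_sep:
            continue
        accepted.append(i)
    return len(accepted)


def test_single_minimum_jerk_movement_is_one_unit():
    fs = 60.0
    prof = minimum_jerk_profile(330.0, 1.0, fs).values  # peak ~620 mm/s
    traj = np.stack([prof, np.zeros_like(prof), np.zeros_like(prof)], axis=1)
    speed = tangential_speed(traj, fs)
    assert count_movement_units(speed, (0, len(speed)), fs) == 1


def test_subthreshold_motion_counts_zero():
    fs = 60.0
    prof = minimum_jerk_profile(20.0, 1.0, fs).values  # peak 37.5 mm/s < 50
    traj = np.stack([prof, np.zeros_like(prof), np.zeros_like(prof)], axis=1)
    speed = tangential_speed(traj, fs)
    assert count_movement_units(speed, (0, len(speed)), fs) == 0


@pytest.mark.parametrize("k", [2, 3, 5])
def test_commanded_submovement_count_recovered(k):
    fs = 60.0
    s = compose_submovements(k, 400.0, k * 0.5, fs, seed=3).values
    traj = np.stack([s, np.zeros_like(s), np.zeros_like(s)], axis=1)
    speed = tangential_speed(traj, fs)
    assert count_movement_units(speed, (0, len(speed)), fs) == k
    assert _brute_force_nmu(speed, (0, len(speed)), fs) == k


@given(st.integers(0, 500))
def test_movement_unit_count_matches_brute_force_oracle(seed):
    rng = np.random.default_rng(seed)
    n = 120
    # random smooth-ish positive signal with ripples around the threshold
    base = np.abs(np.cumsum(rng.normal(0, 18, n)))
    speed = np.convolve(base, np.ones(5) / 5, mode="same") + rng.uniform(0, 28, n)
    got = count_movement_units(speed, (0, n), 60.0)
    want = _brute_force_nmu(speed, (0, n), 60.0)
    assert got == want


def test_empty_window_rejected():
    with pytest.raises(ValueError):
        count_movement_units(np.ones(50), (20, 20), 60.0)


@pytest.mark.parametrize("preset", sorted(PRESETS))
def test_commanded_indexes_recovered_noise_free(preset):
    cfg = PRESETS[preset]()
    cfg.noise_rms_mm = 0.0
    cfg.seed = 7
    trial, gt = simulate_trial(cfg)
    ti = compute_trial_indexes(trial, detect_events(trial))
    assert abs(ti.contributions.ae - gt.ae) < 0.5
    assert abs(ti.contributions.tf - gt.tf) < 0.5
    assert abs(ti.contributions.ta - gt.ta) < 0.5
    assert abs(ti.elbow_rom - gt.elbow_rom) < 1.0
    assert abs(ti.mouth.md12 - gt.md12) < 2.0
    assert abs(ti.mouth.md23 - gt.md23) < 2.0
    assert (ti.nmu_rg, ti.nmu_bgm, ti.nmu_total) == (gt.nmu_rg, gt.nmu_bgm, gt.nmu_total)


def test_analysis_is_bitwise_deterministic(stroke_trial):
    trial, _ = stroke_trial
    ev = detect_events(trial)
    a = compute_trial_indexes(trial, ev).as_dict()
    b = compute_trial_indexes(trial, ev).as_dict()
    assert a == b


def test_indexes_invariant_under_mirroring(stroke_trial):
    trial, _ = stroke_trial
    a = compute_trial_indexes(trial, detect_events(trial)).as_dict()
    mirrored = mirror_trial(trial)
    b = compute_trial_indexes(mirrored, detect_events(mirrored)).as_dict()
    for key in a:
        np.testing.assert_allclose(a[key], b[key], atol=1e-9, err_msg=key)


def test_percentage_indexes_scale_invariant_mm_indexes_linear(healthy_trial):
    trial, _ = healthy_trial
    ev = detect_events(trial)
    base = compute_trial_indexes(trial, ev)
    scaled_trial = trial.copy()
    for m in scaled_trial.positions:
        scaled_trial.positions[m] = scaled_trial.positions[m] * 1.5
    scaled = compute_trial_indexes(scaled_trial, ev)
    np.testing.assert_allclose(scaled.contributions.ae, base.contributions.ae, atol=1e-9)
    np.testing.assert_allclose(scaled.arm_contrib_bgm, base.arm_contrib_bgm, atol=1e-9)
    np.testing.assert_allclose(scaled.mouth.md12, 1.5 * base.mouth.md12, atol=1e-9)
    np.testing.assert_allclose(
        scaled.contributions.hand_disp, 1.5 * base.contributions.hand_disp, atol=1e-9
    )
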