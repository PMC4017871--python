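"""Synthetic drinking-task trials with fully known ground truth.

The generator builds marker trajectories of a seated subject reaching
for a glass placed 400 mm from the table edge on the sagittal plane,
bringing it to the mouth, drinking (glass tilted to ~45 deg), and
putting it back.  Point-to-point transports are superpositions of
minimum-jerk submovements, the standard model of unimpaired reaches:
the displacement profile s(tau) = D (10 tau^3 - 15 tau^4 + 6 tau^5) has
zero boundary velocity/acceleration and a unimodal speed peaking at
1.875 D/T.  Jerky (post-stroke) movements are emulated by chaining k
non-overlapping submovements, which makes the commanded movement-unit
count exact by construction.

The reach decomposition is imposed directly: over the reaching phase the
C7 marker advances tf% and the shoulder (tf+ta)% of the commanded hand
forward displacement, so the generated trial's (AE, TF, TA) equal the
commanded contributions.  The mouth marker rides with C7 and returns by
a configurable fraction rho of its forward excursion during the
bringing phase: rho ~ 1 reproduces the strategy of an equal backward
trunk/mouth displacement while bringing, rho ~ 0 the strategy of
remaining in a forward-displaced head-and-trunk posture.

Anthropometry is a single fixed default skeleton: the indexes depend
only on displacements and angles, not absolute marker placement.  The
simulator is this package's oracle for testing the analysis pipeline,
not a biomechanical claim about patients.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from math import floor

import numpy as np
import pandas as pd
from scipy.optimize import brentq

from .marker_io import SubjectMeta, Trial
from .preprocess import ScalarSeries
from .segmentation import TaskEvents

__all__ = [
    "StrategyConfig",
    "GroundTruth",
    "PRESETS",
    "PATIENT_RANGES",
    "CONTROL_RANGES",
    "minimum_jerk_profile",
    "compose_submovements",
    "simulate_trial",
    "simulate_cohort",
]

#: Peak-speed factor of a minimum-jerk movement: v_max = 1.875 D / T.
MJ_PEAK_FACTOR = 1.875

#: Nominal per-submovement peak speed floor used when drawing amplitudes
#: (comfortably above the 50 mm/s movement-unit threshold).
MIN_SUBMOVEMENT_PEAK = 80.0

#: Minimum amplitude (mm) of the final reaching submovement, so that no
#: intermediate between-submovement stop falls within grasping distance
#: of the glass.
MIN_LAST_REACH_AMPLITUDE = 90.0

_GLASS_HEIGHT = 100.0  # mm, bottom marker to top-rim marker
_DRINK_TILT = 45.0  # deg, nominal drinking inclination
_TILT_RAMP_S = 0.3  # s, duration of the tilt up/down ramp


def _mj(tau: np.ndarray | float) -> np.ndarray | float:
    """Normalised minimum-jerk displacement, clipped outside [0, 1]."""
    t = np.clip(tau, 0.0, 1.0)
    return 10 * t**3 - 15 * t**4 + 6 * t**5


# tilt-ramp phase at which the inclination crosses the 30 deg detection
# entry criterion (solution of mj(tau) = 2/3; the downward crossing is at
# 1 - tau by symmetry)
_TAU_UP = brentq(lambda t: _mj(t) - 2.0 / 3.0, 0.0, 1.0)
_TAU_DOWN = 1.0 - _TAU_UP


@dataclass
class StrategyConfig:
    """Commanded parameters of one simulated trial."""

    # reach decomposition, percent of hand forward displacement (sum = 100)
    ae: float = 48.63
    tf: float = 37.39
    ta: float = 13.98
    # phase durations, seconds
    rg_s: float = 1.24
    bgm_s: float = 1.46
    dg_s: float = 1.0
    tbgt_s: float = 1.44
    # elbow included angle sweep during reaching, degrees
    elbow_start_deg: float = 90.0
    elbow_end_deg: float = 138.4
    # fraction of the mouth/trunk forward excursion recovered during bringing
    mouth_return_fraction: float = 0.85
    # commanded arm contribution (%) while putting the glass back: the trunk
    # leans forward again by the complementary share of the hand displacement
    arm_contrib_tbgt: float = 65.0
    # submovement counts per transport phase
    k_rg: int = 1
    k_bgm: int = 1
    k_tbgt: int = 1
    submovement_spacing_s: float = 0.25
    # geometry
    glass_distance_mm: float = 400.0
    hand_reach_mm: float = 260.0
    side: str = "right"
    # acquisition
    fs: float = 60.0
    pre_s: float = 0.5
    post_s: float = 0.5
    noise_rms_mm: float = 0.5  # 3-D radial RMS of added marker noise
    seed: int = 0

    def validate(self) -> "StrategyConfig":
        if abs(self.ae + self.tf + self.ta - 100.0) > 1e-9:
            raise ValueError(
                f"contributions must sum to 100%, got {self.ae + self.tf + self.ta}"
            )
        for name in ("rg_s", "bgm_s", "dg_s", "tbgt_s", "pre_s", "post_s"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")
        for name in ("k_rg", "k_bgm", "k_tbgt"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")
        if self.fs <= 0:
            raise ValueError("fs must be > 0")
        if not 0.0 <= self.mouth_return_fraction <= 1.0:
            raise ValueError("mouth_return_fraction must lie in [0, 1]")
        if self.side not in ("left", "right"):
            raise ValueError("side must be 'left' or 'right'")
        if self.hand_reach_mm <= MIN_LAST_REACH_AMPLITUDE:
            raise ValueError("hand_reach_mm too small for a graspable reach")
        if self.noise_rms_mm < 0:
            raise ValueError("noise_rms_mm must be >= 0")
        tilt_lead = _TAU_UP * _TILT_RAMP_S
        if self.bgm_s <= tilt_lead + 0.1:
            raise ValueError(f"bgm_s must exceed the tilt lead-in ({tilt_lead:.2f} s)")
        if self.dg_s < 0.3:
            raise ValueError("dg_s must be >= 0.3 s to fit the tilt ramps")
        for k, T, phase in (
            (self.k_rg, self.rg_s, "rg"),
            (self.k_bgm, self.bgm_s, "bgm"),
            (self.k_tbgt, self.tbgt_s, "tbgt"),
        ):
            if k > 1 and T / k < self.submovement_spacing_s:
                raise ValueError(
                    f"{k} submovements do not fit in {phase} ({T} s) at "
                    f"{self.submovement_spacing_s} s spacing"
                )
        return self


@dataclass
class GroundTruth:
    """True values of everything the analysis pipeline must recover."""

    events: TaskEvents
    durations: dict[str, float]
    ae: float
    tf: float
    ta: float
    hand_disp: float
    elbow_rom: float
    md12: float
    md23: float
    md13: float
    arm_contrib_bgm: float
    arm_contrib_tbgt: float
    nmu_rg: int
    nmu_bgm: int
    nmu_total: int
    config: StrategyConfig = field(repr=False, default=None)


# ---------------------------------------------------------------------------
# minimum-jerk primitives
# ---------------------------------------------------------------------------


def minimum_jerk_profile(D: float, T: float, fs: float) -> ScalarSeries:
    """Displacement profile of a single minimum-jerk movement.

    Sampled at fs over [0, T]; s(0) = 0, s(T) = D, boundary velocity and
    acceleration zero, unimodal speed with peak 1.875 D/T at midtime."""
    if T <= 0:
        raise ValueError(f"duration must be > 0, got {T}")
    if D < 0:
        raise ValueError(f"displacement must be >= 0, got {D}")
    if fs <= 0:
        raise ValueError(f"fs must be > 0, got {fs}")
    t = np.arange(round(T * fs) + 1) / fs
    return ScalarSeries(values=D * np.asarray(_mj(t / T)), fs=fs, unit="mm")


def _max_feasible_k(
    L: float, T: float, spacing: float, min_peak: float = MIN_SUBMOVEMENT_PEAK,
    min_last: float = 0.0,
) -> int:
    """Largest submovement count the amplitude/spacing constraints allow."""
    k = max(1, floor(T / spacing))
    while k > 1:
        seg = T / k
        min_amp = min_peak * seg / MJ_PEAK_FACTOR
        if max(min_last, min_amp) + (k - 1) * min_amp <= L:
            return k
        k -= 1
    return 1


def _draw_amplitudes(
    k: int,
    L: float,
    seg: float,
    rng: np.random.Generator,
    min_last: float = 0.0,
    min_peak: float = MIN_SUBMOVEMENT_PEAK,
) -> np.ndarray:
    """Seeded submovement amplitudes summing exactly to L.

    Every amplitude guarantees a nominal speed peak >= min_peak; the last
    one additionally respects min_last (see MIN_LAST_REACH_AMPLITUDE)."""
    if k == 1:
        if L < min_last:
            raise ValueError(f"total displacement {L:.0f} mm below minimum {min_last:.0f}")
        return np.array([L])
    min_amp = min_peak * seg / MJ_PEAK_FACTOR
    floor_last = max(min_last, min_amp)
    if floor_last + (k - 1) * min_amp > L:
        raise ValueError(
            f"{k} submovements infeasible: need >= "
            f"{floor_last + (k - 1) * min_amp:.0f} mm, have {L:.0f} mm"
        )
    for _ in range(100):
        w = rng.uniform(0.75, 1.25, size=k)
        amps = L * w / w.sum()
        if amps[-1] >= floor_last and (amps >= min_amp).all():
            return amps
    # deterministic fallback: pin the last amplitude, split the rest evenly
    last = max(floor_last, L / k)
    rest = np.full(k - 1, (L - last) / (k - 1))
    return np.concatenate([rest, [last]])


def compose_submovements(
    k: int,
    D: float,
    T: float,
    fs: float,
    spacing: float = 0.25,
    seed: int | np.random.Generator | None = 0,
    min_last: float = 0.0,
) -> ScalarSeries:
    """Cumulative displacement of k chained minimum-jerk submovements.

    The submovements are non-overlapping (each occupies T/k), so the
    resulting speed has exactly k maxima above the 50 mm/s threshold,
    separated by >= T/k >= spacing."""
    if k < 1:
        raise ValueError("k must be >= 1")
    if k > 1 and T / k < spacing:
        raise ValueError(f"{k} submovements do not fit in {T} s at {spacing} s spacing")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    seg = T / k
    amps = _draw_amplitudes(k, D, seg, rng, min_last=min_last)
    t = np.arange(round(T * fs) + 1) / fs
    s = np.zeros_like(t)
    for i, a in enumerate(amps):
        s += a * np.asarray(_mj((t - i * seg) / seg))
    return ScalarSeries(values=s, fs=fs, unit="mm")


def _transport(
    n: int, fs: float, start_f: int, end_f: int, amps: np.ndarray
) -> np.ndarray:
    """Normalised transport progress (0 -> 1) over the whole trial record:
    0 before start_f, chained submovements over [start_f, end_f], 1 after."""
    t = np.arange(n, dtype=float)
    seg = (end_f - start_f) / len(amps)
    s = np.zeros(n)
    for i, a in enumerate(amps):
        s += a * np.asarray(_mj((t - start_f - i * seg) / seg))
    return s / amps.sum()


# ---------------------------------------------------------------------------
# full trial
# ---------------------------------------------------------------------------


def _elbow_from_angle(
    shoulder: np.ndarray, wrist: np.ndarray, theta_deg: np.ndarray
) -> np.ndarray:
    """Place the elbow marker so the included shoulder-elbow-wrist angle
    equals theta at every frame (isoceles construction below the
    shoulder-wrist chord)."""
    chord = wrist - shoulder
    c = np.linalg.norm(chord, axis=1)
    nhat = chord / c[:, None]
    down = np.array([0.0, 0.0, -1.0])
    perp = down - (nhat @ down)[:, None] * nhat
    pnorm = np.linalg.norm(perp, axis=1)
    # fall back to the forward axis if the chord is near-vertical
    fallback = np.array([1.0, 0.0, 0.0]) - nhat * nhat[:, [0]]
    bad = pnorm < 1e-9
    perp[bad] = fallback[bad]
    perp /= np.linalg.norm(perp, axis=1)[:, None]
    half = np.radians(theta_deg) / 2.0
    offset = (c / 2.0) / np.tan(np.clip(half, 1e-6, None))
    return (shoulder + wrist) / 2.0 + perp * offset[:, None]


def simulate_trial(
    cfg: StrategyConfig,
    subject_id: str = "sim",
    group: str = "control",
) -> tuple[Trial, GroundTruth]:
    """Generate one trial and its ground truth.  Deterministic per seed."""
    cfg.validate()
    fs = cfg.fs
    rng = np.random.default_rng(cfg.seed)
    sgn = 1.0 if cfg.side == "left" else -1.0  # lateral sign of the grasping side

    f = lambda s: round(s * fs)
    t1 = f(cfg.pre_s)
    t2 = t1 + f(cfg.rg_s)
    t3 = t2 + f(cfg.bgm_s)
    t4 = t3 + f(cfg.dg_s)
    t5 = t4 + f(cfg.tbgt_s)
    n = t5 + f(cfg.post_s) + 1

    # --- fixed skeleton & geometry (mm, lab frame) ---------------------
    gx = cfg.glass_distance_mm
    glass_bottom0 = np.array([gx, 0.0, 0.0])
    glass_top0 = glass_bottom0 + [0.0, 0.0, _GLASS_HEIGHT]
    grasp_off = np.array([0.0, sgn * 25.0, -25.0])  # hand relative to glass top
    lip_off = np.array([30.0, 0.0, -20.0])  # glass top relative to mouth at T3
    wrist_off = np.array([-60.0, 0.0, 15.0])  # wrist relative to hand
    c7_0 = np.array([-80.0, 0.0, 470.0])
    mouth0 = c7_0 + [100.0, 0.0, 130.0]
    shoulder0 = np.array([-40.0, sgn * 180.0, 430.0])

    hand_t2 = glass_top0 + grasp_off
    hand0 = np.array([gx - cfg.hand_reach_mm, sgn * 120.0, 25.0])
    hand_t2[0] = gx  # by construction: net forward reach = hand_reach_mm
    # (hand0 X is gx - hand_reach_mm, hand_t2 X is gx)

    dh = cfg.hand_reach_mm
    dc7 = np.array([cfg.tf / 100.0 * dh, 0.0, 0.0])
    dsh = np.array([(cfg.tf + cfg.ta) / 100.0 * dh, 0.0, 0.0])
    rho = cfg.mouth_return_fraction

    # --- trunk / head -------------------------------------------------
    tgrid = np.arange(n, dtype=float)
    prog_rg = np.asarray(_mj((tgrid - t1) / (t2 - t1)))
    prog_bgm = np.asarray(_mj((tgrid - t2) / (t3 - t2)))
    prog_tbgt = np.asarray(_mj((tgrid - t4) / (t5 - t4)))

    c7 = c7_0 + dc7 * (prog_rg - rho * prog_bgm)[:, None]
    shoulder = shoulder0 + dsh * (prog_rg - rho * prog_bgm)[:, None]

    # --- hand transports ----------------------------------------------
    path_rg = hand_t2 - hand0
    L_rg = float(np.linalg.norm(path_rg))
    amps_rg = _draw_amplitudes(
        cfg.k_rg, L_rg, (t2 - t1) / fs / cfg.k_rg, rng,
        min_last=MIN_LAST_REACH_AMPLITUDE,
    )
    mouth_t3 = mouth0 + (1.0 - rho) * dc7
    hand_t3 = mouth_t3 + lip_off + grasp_off
    path_bgm = hand_t3 - hand_t2
    amps_bgm = _draw_amplitudes(
        cfg.k_bgm, float(np.linalg.norm(path_bgm)), (t3 - t2) / fs / cfg.k_bgm, rng
    )
    hand_t5 = hand_t2  # glass returns to its initial spot
    path_tbgt = hand_t5 - hand_t3
    # trunk lean while putting back: shoulder and C7 advance together by the
    # share of the hand displacement not contributed by the arm
    lean_x = (1.0 - cfg.arm_contrib_tbgt / 100.0) * path_tbgt[0]
    lean_vec = np.array([lean_x, 0.0, 0.0])
    c7 = c7 + lean_vec * prog_tbgt[:, None]
    shoulder = shoulder + lean_vec * prog_tbgt[:, None]
    mouth = mouth0 + (c7 - c7_0)
    amps_tbgt = _draw_amplitudes(
        cfg.k_tbgt, float(np.linalg.norm(path_tbgt)), (t5 - t4) / fs / cfg.k_tbgt, rng
    )

    hand = (
        hand0
        + np.outer(_transport(n, fs, t1, t2, amps_rg), path_rg)
        + np.outer(_transport(n, fs, t2, t3, amps_bgm), path_bgm)
        + np.outer(_transport(n, fs, t4, t5, amps_tbgt), path_tbgt)
    )
    wrist = hand + wrist_off

    # --- elbow angle profile ------------------------------------------
    th_s, th_e = cfg.elbow_start_deg, cfg.elbow_end_deg
    th_bgm_end = min(th_s, th_e) - 20.0  # flexes while bringing to the mouth
    theta = (
        th_s
        + (th_e - th_s) * prog_rg
        + (th_bgm_end - th_e) * prog_bgm
        + (th_s - th_bgm_end) * prog_tbgt
    )
    elbow = _elbow_from_angle(shoulder, wrist, theta)

    # --- glass: carried by the hand, tilted for drinking ---------------
    glass_top = np.where((tgrid >= t2)[:, None], hand - grasp_off, glass_top0)
    up_start = t3 / fs - _TAU_UP * _TILT_RAMP_S - 0.25 / fs
    down_start = t4 / fs - _TAU_DOWN * _TILT_RAMP_S - 0.25 / fs
    tilt = _DRINK_TILT * (
        np.asarray(_mj((tgrid / fs - up_start) / _TILT_RAMP_S))
        - np.asarray(_mj((tgrid / fs - down_start) / _TILT_RAMP_S))
    )
    tilt_rad = np.radians(tilt)
    glass_bottom = glass_top + _GLASS_HEIGHT * np.stack(
        [np.sin(tilt_rad), np.zeros(n), -np.cos(tilt_rad)], axis=1
    )

    positions = {
        "HAND": hand,
        "WRIST": wrist,
        "ELBOW": elbow,
        "SHOULDER": shoulder,
        "C7": c7,
        "MOUTH": mouth,
        "GLASS_TOP": glass_top,
        "GLASS_BOTTOM": glass_bottom,
    }

    # --- ground truth from the noiseless record ------------------------
    events = TaskEvents(t1, t2, t3, t4, t5)
    dh_rg = hand[t2, 0] - hand[t1, 0]
    dsh_rg = shoulder[t2, 0] - shoulder[t1, 0]
    dc7_rg = c7[t2, 0] - c7[t1, 0]
    dh_bgm = hand[t3, 0] - hand[t2, 0]
    dsh_bgm = shoulder[t3, 0] - shoulder[t2, 0]
    dh_tbgt = hand[t5, 0] - hand[t4, 0]
    dsh_tbgt = shoulder[t5, 0] - shoulder[t4, 0]
    th_rg = theta[t1:t2]
    truth = GroundTruth(
        events=events,
        durations={
            "rg": (t2 - t1) / fs,
            "bgm": (t3 - t2) / fs,
            "dg": (t4 - t3) / fs,
            "tbgt": (t5 - t4) / fs,
        },
        ae=100.0 * (dh_rg - dsh_rg) / dh_rg,
        tf=100.0 * dc7_rg / dh_rg,
        ta=100.0 * (dsh_rg - dc7_rg) / dh_rg,
        hand_disp=float(dh_rg),
        elbow_rom=float(np.max(th_rg) - np.min(th_rg)),
        md12=float(mouth[t2, 0] - mouth[t1, 0]),
        md23=float(mouth[t3, 0] - mouth[t2, 0]),
        md13=float(mouth[t3, 0] - mouth[t1, 0]),
        arm_contrib_bgm=100.0 * (dh_bgm - dsh_bgm) / dh_bgm,
        arm_contrib_tbgt=100.0 * (dh_tbgt - dsh_tbgt) / dh_tbgt,
        nmu_rg=len(amps_rg),
        nmu_bgm=len(amps_bgm),
        nmu_total=len(amps_rg) + len(amps_bgm),
        config=cfg,
    )

    if cfg.noise_rms_mm > 0:
        sigma = cfg.noise_rms_mm / np.sqrt(3.0)  # per-axis; 3-D radial RMS = noise_rms
        positions = {
            m: xyz + rng.normal(0.0, sigma, size=xyz.shape)
            for m, xyz in positions.items()
        }

    trial = Trial(
        positions={m: np.ascontiguousarray(xyz) for m, xyz in positions.items()},
        fs=fs,
        side=cfg.side,
        meta=SubjectMeta(id=subject_id, group=group),
    ).validate()
    return trial, truth


# ---------------------------------------------------------------------------
# presets & cohorts
# ---------------------------------------------------------------------------


def _normalized(ae: float, tf: float, ta: float) -> tuple[float, float, float]:
    s = (ae + tf + ta) / 100.0
    return ae / s, tf / s, ta / s


def _healthy_preset() -> StrategyConfig:
    ae, tf, ta = _normalized(49.21, 37.84, 14.15)
    return StrategyConfig(
        ae=ae, tf=tf, ta=ta,
        rg_s=1.24, bgm_s=1.46, dg_s=1.0, tbgt_s=1.44,
        elbow_start_deg=90.0, elbow_end_deg=138.4,
        mouth_return_fraction=0.85,
        k_rg=1, k_bgm=1, k_tbgt=1,
        hand_reach_mm=260.0,
    )


def _stroke_preset(rho: float) -> StrategyConfig:
    ae, tf, ta = _normalized(5.63, 85.77, 10.20)
    return StrategyConfig(
        ae=ae, tf=tf, ta=ta,
        rg_s=3.09, bgm_s=2.59, dg_s=1.5, tbgt_s=2.22,
        elbow_start_deg=90.0, elbow_end_deg=100.1,
        mouth_return_fraction=rho,
        k_rg=5, k_bgm=4, k_tbgt=2,
        hand_reach_mm=222.0,
    )


#: Named strategy presets: a healthy reach, and the two post-stroke
#: compensation strategies (staying forward vs returning the trunk).
PRESETS = {
    "healthy": _healthy_preset,
    "stroke-forward-posture": lambda: _stroke_preset(0.2),
    "stroke-return": lambda: _stroke_preset(1.0),
}

#: Per-subject sampling bounds for cohort simulation (stroke group).
PATIENT_RANGES: dict[str, tuple[float, float]] = {
    "rg_s": (1.62, 3.54),
    "bgm_s": (1.68, 4.61),
    "dg_s": (1.0, 2.0),
    "tbgt_s": (1.85, 3.89),
    "ae": (-9.27, 35.83),
    "ta": (5.80, 12.53),
    "elbow_rom_deg": (3.37, 30.70),
    "k_rg": (1, 9),
    "k_bgm": (1, 17),
    "hand_reach_mm": (180.0, 260.0),
    "mouth_return_fraction": (0.1, 1.0),
    "arm_contrib_tbgt": (29.77, 76.77),
}

#: Per-subject sampling bounds for cohort simulation (control group).
CONTROL_RANGES: dict[str, tuple[float, float]] = {
    "rg_s": (1.09, 1.41),
    "bgm_s": (1.11, 1.64),
    "dg_s": (0.8, 1.5),
    "tbgt_s": (1.24, 1.52),
    "ae": (34.10, 69.50),
    "ta": (9.25, 17.37),
    "elbow_rom_deg": (34.20, 66.80),
    "k_rg": (1, 2),
    "k_bgm": (1, 2),
    "hand_reach_mm": (220.0, 300.0),
    "mouth_return_fraction": (0.7, 0.95),
    "arm_contrib_tbgt": (61.37, 80.57),
}


def _draw_subject_config(
    ranges: dict[str, tuple[float, float]], rng: np.random.Generator, side: str
) -> StrategyConfig:
    def u(key: str) -> float:
        lo, hi = ranges[key]
        if lo > hi:
            raise ValueError(f"inverted range for {key}: ({lo}, {hi})")
        return float(rng.uniform(lo, hi))

    ae = u("ae")
    ta = u("ta")
    tf = 100.0 - ae - ta
    rg_s, bgm_s, tbgt_s = u("rg_s"), u("bgm_s"), u("tbgt_s")
    dg_s = u("dg_s")
    reach = u("hand_reach_mm")
    spacing = 0.25
    L_rg = reach  # lower bound on the 3-D reach path length (safe side)
    k_rg = min(
        int(rng.integers(ranges["k_rg"][0], ranges["k_rg"][1] + 1)),
        _max_feasible_k(L_rg, rg_s, spacing, min_last=MIN_LAST_REACH_AMPLITUDE),
    )
    k_bgm = min(
        int(rng.integers(ranges["k_bgm"][0], ranges["k_bgm"][1] + 1)),
        _max_feasible_k(300.0, bgm_s, spacing),
    )
    rom = u("elbow_rom_deg")
    return StrategyConfig(
        ae=ae, tf=tf, ta=ta,
        rg_s=rg_s, bgm_s=bgm_s, dg_s=dg_s, tbgt_s=tbgt_s,
        elbow_start_deg=90.0, elbow_end_deg=90.0 + rom,
        mouth_return_fraction=u("mouth_return_fraction"),
        arm_contrib_tbgt=u("arm_contrib_tbgt"),
        k_rg=max(1, k_rg), k_bgm=max(1, k_bgm), k_tbgt=1,
        submovement_spacing_s=spacing,
        hand_reach_mm=reach,
        side=side,
    )


def simulate_cohort(
    n_patients: int,
    n_controls: int,
    patient_ranges: dict[str, tuple[float, float]] | None = None,
    control_ranges: dict[str, tuple[float, float]] | None = None,
    seed: int = 0,
    trials_per_subject: int = 3,
    noise_rms_mm: float = 0.5,
) -> tuple[list[tuple[Trial, GroundTruth]], pd.DataFrame]:
    """Simulate a two-group cohort: per subject, parameters drawn uniformly
    within the group's ranges and ``trials_per_subject`` repetitions
    (differing in noise and submovement amplitudes).  Returns the trials
    with their ground truths plus a subject metadata table."""
    if n_patients < 1 or n_controls < 1:
        raise ValueError("both groups need at least one subject")
    if trials_per_subject < 1:
        raise ValueError("trials_per_subject must be >= 1")
    rng = np.random.default_rng(seed)
    out: list[tuple[Trial, GroundTruth]] = []
    meta_rows = []
    groups = [("stroke", n_patients, patient_ranges or PATIENT_RANGES, "P"), (
        "control", n_controls, control_ranges or CONTROL_RANGES, "C")]
    for group, count, ranges, prefix in groups:
        for i in range(count):
            side = (
                str(rng.choice(["right", "right", "left"]))
                if group == "stroke"
                else "right"
            )
            cfg = _draw_subject_config(ranges, rng, side)
            sid = f"{prefix}{i + 1:02d}"
            for rep in range(trials_per_subject):
                trial_cfg = replace(
                    cfg,
                    noise_rms_mm=noise_rms_mm,
                    seed=int(rng.integers(0, 2**31 - 1)),
                )
                out.append(simulate_trial(trial_cfg, subject_id=sid, group=group))
            meta_rows.append(
                {
                    "id": sid,
                    "group": group,
                    "side": side,
                    "ae_true": cfg.ae,
                    "tf_true": cfg.tf,
                    "ta_true": cfg.ta,
                    "rg_s_true": cfg.rg_s,
                    "k_rg_true": cfg.k_rg,
                    "k_bgm_true": cfg.k_bgm,
                }
            )
    return out, pd.DataFrame(meta_rows)
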