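"""Per-trial quantitative indexes of the drinking task.

All "forward displacement" quantities are net changes of the X
(anteroposterior) coordinate between two event frames, not path lengths.
With Dh, Ds, Dc the forward displacements of the hand, shoulder
(acromion) and C7 over the reaching phase, the decomposition of the
reach into its contributing strategies is

    arm elongation          AE = 100 (Dh - Ds) / Dh
    trunk forward incl.     TF = 100  Dc       / Dh
    trunk axial rotation    TA = 100 (Ds - Dc) / Dh

which sums to 100% identically: the reach is fully accounted for by arm
lengthening, trunk inclination and trunk rotation.  The same
construction, signs preserved, measures the arm contribution in the
bringing-to-mouth and putting-back phases.  Smoothness is the number of
movement units (NMU): hand-speed local maxima above 50 mm/s, with a
prominence and a minimum-separation rule to keep noise ripples from
counting as submovements.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.signal import peak_prominences

from .marker_io import Trial
from .preprocess import tangential_speed, triangular_smooth
from .segmentation import PhaseWindows, TaskEvents, phase_windows

__all__ = [
    "IndexConfig",
    "ContributionBreakdown",
    "MouthDisplacement",
    "TrialIndexes",
    "DegenerateMovementError",
    "reaching_contributions",
    "elbow_angle",
    "elbow_rom",
    "mouth_displacements",
    "arm_contribution",
    "count_movement_units",
    "compute_trial_indexes",
]


class DegenerateMovementError(ValueError):
    """The displacement over a phase is too small for a ratio index."""


@dataclass
class IndexConfig:
    """Tunables of the index battery."""

    min_disp: float = 50.0  # minimum |hand X displacement| for ratio indexes, mm
    nmu_threshold: float = 50.0  # speed a movement-unit peak must exceed, mm/s
    nmu_prominence: float = 10.0  # minimum peak prominence, mm/s
    nmu_min_separation_s: float = 0.1  # minimum spacing between accepted peaks
    smoothing_passes: int = 1  # coordinate smoothing before everything
    speed_passes: int = 2  # extra smoothing of the NMU speed signal (clean data)
    speed_passes_noisy: int = 5  # deeper NMU-speed smoothing when the rest
    # period shows marker noise; suppresses ripple peaks on long plateaus
    rest_floor: float = 0.5  # raw rest speed above which a record counts as noisy


@dataclass(frozen=True)
class ContributionBreakdown:
    """Percent contributions to hand forward displacement in reaching."""

    ae: float
    tf: float
    ta: float
    hand_disp: float  # total hand forward displacement, mm

    @property
    def total(self) -> float:
        return self.ae + self.tf + self.ta


@dataclass(frozen=True)
class MouthDisplacement:
    """Forward mouth-marker displacement (mm) over reaching / bringing."""

    md12: float
    md23: float

    @property
    def md13(self) -> float:
        return self.md12 + self.md23


@dataclass
class TrialIndexes:
    """The full per-trial index battery."""

    durations: dict[str, float]  # phase -> seconds
    contributions: ContributionBreakdown
    elbow_rom: float  # degrees, reaching phase
    mouth: MouthDisplacement
    arm_contrib_bgm: float  # %
    arm_contrib_tbgt: float  # %
    nmu_rg: int
    nmu_bgm: int
    nmu_total: int  # over the concatenated [T1, T3) window
    extras: dict[str, float] = field(default_factory=dict)

    def as_dict(self) -> dict[str, float]:
        """Flat record with units embedded in key names (JSON/CSV friendly)."""
        d = {
            "rg_duration_s": self.durations["rg"],
            "bgm_duration_s": self.durations["bgm"],
            "dg_duration_s": self.durations["dg"],
            "tbgt_duration_s": self.durations["tbgt"],
            "arm_elongation_pct": self.contributions.ae,
            "trunk_forward_inclination_pct": self.contributions.tf,
            "trunk_axial_rotation_pct": self.contributions.ta,
            "hand_forward_displacement_mm": self.contributions.hand_disp,
            "elbow_rom_deg": self.elbow_rom,
            "mouth_forward_displacement_mm": self.mouth.md12,
            "mouth_backward_displacement_mm": self.mouth.md23,
            "mouth_overall_displacement_mm": self.mouth.md13,
            "arm_contribution_bgm_pct": self.arm_contrib_bgm,
            "arm_contribution_tbgt_pct": self.arm_contrib_tbgt,
            "nmu_reaching": float(self.nmu_rg),
            "nmu_bringing": float(self.nmu_bgm),
            "nmu_reaching_and_bringing": float(self.nmu_total),
        }
        d.update(self.extras)
        return d


def _x_delta(pos: np.ndarray, start: int, end: int) -> float:
    """Net forward (X) displacement between two event frames."""
    return float(pos[end, 0] - pos[start, 0])


def reaching_contributions(
    trial: Trial,
    events: TaskEvents,
    cfg: IndexConfig | None = None,
    _smoothed: dict[str, np.ndarray] | None = None,
) -> ContributionBreakdown:
    """Decompose the reach into AE / TF / TA percentages (sum = 100)."""
    cfg = cfg or IndexConfig()
    pos = _smoothed or {
        m: triangular_smooth(trial.positions[m], passes=cfg.smoothing_passes)
        for m in ("HAND", "SHOULDER", "C7")
    }
    dh = _x_delta(pos["HAND"], events.t1, events.t2)
    if dh <= cfg.min_disp:
        raise DegenerateMovementError(
            f"hand forward displacement {dh:.1f} mm over reaching <= "
            f"min_disp {cfg.min_disp:g} mm"
        )
    ds = _x_delta(pos["SHOULDER"], events.t1, events.t2)
    dc = _x_delta(pos["C7"], events.t1, events.t2)
    return ContributionBreakdown(
        ae=100.0 * (dh - ds) / dh,
        tf=100.0 * dc / dh,
        ta=100.0 * (ds - dc) / dh,
        hand_disp=dh,
    )


def elbow_angle(shoulder: np.ndarray, elbow: np.ndarray, wrist: np.ndarray) -> np.ndarray:
    """Included elbow angle (deg, 180 = full extension) between the
    elbow->shoulder and elbow->wrist vectors.  Accepts single points or
    (n, 3) stacks; coincident points (< 1 mm) raise ValueError."""
    s = np.atleast_2d(np.asarray(shoulder, dtype=float))
    e = np.atleast_2d(np.asarray(elbow, dtype=float))
    w = np.atleast_2d(np.asarray(wrist, dtype=float))
    u = s - e
    v = w - e
    nu = np.linalg.norm(u, axis=1)
    nv = np.linalg.norm(v, axis=1)
    if (nu < 1.0).any() or (nv < 1.0).any():
        raise ValueError("elbow angle degenerate: marker pair closer than 1 mm")
    cosang = np.clip(np.einsum("ij,ij->i", u, v) / (nu * nv), -1.0, 1.0)
    ang = np.degrees(np.arccos(cosang))
    return ang[0] if np.asarray(shoulder).ndim == 1 else ang


def elbow_rom(
    trial: Trial,
    events: TaskEvents,
    cfg: IndexConfig | None = None,
    _smoothed: dict[str, np.ndarray] | None = None,
) -> float:
    """Elbow range of motion (max - min included angle, deg) over reaching."""
    cfg = cfg or IndexConfig()
    pos = _smoothed or {
        m: triangular_smooth(trial.positions[m], passes=cfg.smoothing_passes)
        for m in ("SHOULDER", "ELBOW", "WRIST")
    }
    sl = slice(events.t1, events.t2)
    ang = elbow_angle(pos["SHOULDER"][sl], pos["ELBOW"][sl], pos["WRIST"][sl])
    return float(np.max(ang) - np.min(ang))


def mouth_displacements(
    trial: Trial,
    events: TaskEvents,
    cfg: IndexConfig | None = None,
    _smoothed: dict[str, np.ndarray] | None = None,
) -> MouthDisplacement:
    """Forward mouth displacements over reaching (MD12) and bringing (MD23);
    the overall MD13 is their sum by construction."""
    cfg = cfg or IndexConfig()
    pos = _smoothed or {
        "MOUTH": triangular_smooth(trial.positions["MOUTH"], passes=cfg.smoothing_passes)
    }
    mp = pos["MOUTH"][:, 0]
    return MouthDisplacement(
        md12=float(mp[events.t2] - mp[events.t1]),
        md23=float(mp[events.t3] - mp[events.t2]),
    )


def arm_contribution(
    trial: Trial,
    events: TaskEvents,
    phase: str,
    cfg: IndexConfig | None = None,
    _smoothed: dict[str, np.ndarray] | None = None,
) -> float:
    """Arm contribution (%) to hand forward displacement in BGM or TBGT:
    the reaching AE construction applied to the phase window, signs
    preserved (hand and shoulder displacements are typically negative in
    bringing)."""
    cfg = cfg or IndexConfig()
    windows = {"bgm": (events.t2, events.t3), "tbgt": (events.t4, events.t5)}
    key = phase.lower()
    if key not in windows:
        raise ValueError(f"phase must be 'BGM' or 'TBGT', got {phase!r}")
    start, end = windows[key]
    pos = _smoothed or {
        m: triangular_smooth(trial.positions[m], passes=cfg.smoothing_passes)
        for m in ("HAND", "SHOULDER")
    }
    dh = _x_delta(pos["HAND"], start, end)
    if abs(dh) <= cfg.min_disp:
        raise DegenerateMovementError(
            f"hand X displacement {dh:.1f} mm over {phase} within min_disp"
        )
    ds = _x_delta(pos["SHOULDER"], start, end)
    return 100.0 * (dh - ds) / dh


def count_movement_units(
    speed: np.ndarray,
    window: tuple[int, int],
    fs: float,
    threshold: float = 50.0,
    prominence: float = 10.0,
    min_separation_s: float = 0.1,
) -> int:
    """Number of movement units of a speed signal within [start, end).

    A movement unit is a strict local maximum of the hand speed whose
    value exceeds ``threshold`` (mm/s) and whose prominence within the
    window is at least ``prominence``; accepted peaks must be at least
    ``min_separation_s`` apart (earlier peaks win ties, scanning left to
    right)."""
    start, end = window
    speed = np.asarray(speed, dtype=float)
    if not (0 <= start < end <= speed.shape[0]):
        raise ValueError(f"invalid window {window} for signal of length {speed.shape[0]}")
    seg = speed[start:end]
    if seg.shape[0] < 3:
        raise ValueError(f"window {window} too short to contain a peak")
    interior = np.arange(1, seg.shape[0] - 1)
    # ">=" on the right shoulder counts a flat-topped (plateau) peak once,
    # at its first sample; spurious shoulder points this admits carry zero
    # prominence and are removed by the prominence rule
    is_peak = (seg[interior] > seg[interior - 1]) & (seg[interior] >= seg[interior + 1])
    peaks = interior[is_peak & (seg[interior] > threshold)]
    if peaks.size == 0:
        return 0
    prom = peak_prominences(seg, peaks)[0]
    peaks = peaks[prom >= prominence]
    min_sep = max(1, round(min_separation_s * fs))
    count = 0
    last = -min_sep - 1
    for p in peaks:
        if p - last >= min_sep:
            count += 1
            last = p
    return count


def compute_trial_indexes(
    trial: Trial,
    events: TaskEvents,
    cfg: IndexConfig | None = None,
) -> TrialIndexes:
    """Aggregate every index for one trial.  Deterministic; any failing
    sub-computation propagates (no partial result is returned)."""
    cfg = cfg or IndexConfig()
    smoothed = {
        m: triangular_smooth(trial.positions[m], passes=cfg.smoothing_passes)
        for m in ("HAND", "SHOULDER", "C7", "MOUTH", "ELBOW", "WRIST")
    }
    windows: PhaseWindows = phase_windows(events, trial.fs)
    # calibrate the NMU smoothing depth on the pre-onset rest period: noisy
    # records need deeper speed smoothing so differentiation-amplified
    # ripples do not masquerade as movement units
    raw = tangential_speed(trial.positions["HAND"], trial.fs, presmooth_passes=0)
    rest = raw[: max(5, events.t1)]
    noisy = float(np.median(rest)) > cfg.rest_floor
    hand_speed = tangential_speed(
        trial.positions["HAND"], trial.fs,
        presmooth_passes=cfg.smoothing_passes,
        speed_passes=cfg.speed_passes_noisy if noisy else cfg.speed_passes,
    )

    def nmu(win: tuple[int, int]) -> int:
        return count_movement_units(
            hand_speed, win, trial.fs,
            threshold=cfg.nmu_threshold,
            prominence=cfg.nmu_prominence,
            min_separation_s=cfg.nmu_min_separation_s,
        )

    return TrialIndexes(
        durations=windows.durations,
        contributions=reaching_contributions(trial, events, cfg, _smoothed=smoothed),
        elbow_rom=elbow_rom(trial, events, cfg, _smoothed=smoothed),
        mouth=mouth_displacements(trial, events, cfg, _smoothed=smoothed),
        arm_contrib_bgm=arm_contribution(trial, events, "BGM", cfg, _smoothed=smoothed),
        arm_contrib_tbgt=arm_contribution(trial, events, "TBGT", cfg, _smoothed=smoothed),
        nmu_rg=nmu(windows.rg),
        nmu_bgm=nmu(windows.bgm),
        nmu_total=nmu((events.t1, events.t3)),
    )
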