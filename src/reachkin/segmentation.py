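"""Event detection and phase segmentation of the drinking task.

The task is bounded by five events: onset of any body motion (T1), the
hand reaching the glass (T2), the tilted glass contacting the lips (T3),
the end of drinking (T4), and the glass repositioned on the table (T5).
They delimit four phases: reaching for the glass RG = [T1, T2), bringing
the glass to the mouth BGM = [T2, T3), drinking DG = [T3, T4), and
putting the glass back on the table TBGT = [T4, T5).

Detection is kinematic and deterministic: speed-threshold crossings with
a hold requirement, proximity criteria between the hand / glass / mouth
markers, and the glass-inclination angle.  Because speed crosses any
finite threshold strictly before motion ends (and after it starts), raw
crossings are refined: T1 is backtracked along the falling speed signal
to the rest floor, and T2/T5 follow the descending speed to its local
minimum (the settle point).  All thresholds live in
:class:`SegmentationConfig` and are configurable; events marked by an
operator can be supplied through a sidecar file and bypass detection.
"""

from __future__ import annotations

from dataclasses import dataclass, fields
from pathlib import Path

import numpy as np
import yaml

from .marker_io import Trial
from .preprocess import tangential_speed, triangular_smooth

__all__ = [
    "SegmentationConfig",
    "TaskEvents",
    "PhaseWindows",
    "SegmentationError",
    "glass_inclination",
    "detect_events",
    "phase_windows",
    "read_events_sidecar",
]


class SegmentationError(RuntimeError):
    """An event could not be located, or ordering is violated."""


@dataclass
class SegmentationConfig:
    """Thresholds of the event detector (all units mm, mm/s, deg, frames)."""

    onset_speed: float = 20.0  # body speed marking task onset
    onset_hold: int = 5  # consecutive frames a condition must hold
    grasp_dist: float = 50.0  # hand-to-glass proximity at T2
    grasp_speed: float = 50.0  # settle-speed ceiling at T2/T5
    lip_dist: float = 50.0  # glass-top-to-mouth proximity at T3
    drink_angle: float = 30.0  # inclination entry criterion (nominal tilt ~45 deg)
    table_tol: float = 10.0  # glass-bottom height tolerance at T5
    table_z: float = 0.0  # table surface height in the lab frame
    smoothing_passes: int = 1  # coordinate-level triangular smoothing
    detection_presmooth: int = 3  # deeper position smoothing for detection speeds
    rest_floor: float = 0.5  # rest-speed level treated as stationary, mm/s
    seek_patience_s: float = 0.1  # look-ahead when following a speed descent

    @classmethod
    def from_yaml(cls, path: str | Path) -> "SegmentationConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f.name for f in fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown segmentation config keys: {sorted(unknown)}")
        return cls(**raw)


@dataclass(frozen=True)
class TaskEvents:
    """The five event frame indices (0-based, strictly increasing)."""

    t1: int
    t2: int
    t3: int
    t4: int
    t5: int

    def __post_init__(self) -> None:
        seq = (self.t1, self.t2, self.t3, self.t4, self.t5)
        if any(int(e) != e or e < 0 for e in seq):
            raise SegmentationError(f"events must be non-negative integers: {seq}")
        if not all(a < b for a, b in zip(seq, seq[1:])):
            raise SegmentationError(f"events must be strictly increasing: {seq}")

    def as_tuple(self) -> tuple[int, int, int, int, int]:
        return (self.t1, self.t2, self.t3, self.t4, self.t5)


@dataclass(frozen=True)
class PhaseWindows:
    """Half-open frame windows of the four phases and their durations (s)."""

    rg: tuple[int, int]
    bgm: tuple[int, int]
    dg: tuple[int, int]
    tbgt: tuple[int, int]
    fs: float

    def duration(self, phase: str) -> float:
        start, end = getattr(self, phase)
        return (end - start) / self.fs

    @property
    def durations(self) -> dict[str, float]:
        return {p: self.duration(p) for p in ("rg", "bgm", "dg", "tbgt")}


def glass_inclination(trial: Trial, smoothing_passes: int = 0) -> np.ndarray:
    """Per-frame angle (deg) between the glass axis (bottom->top) and
    vertical: 0 = upright, 90 = horizontal."""
    top = trial.positions["GLASS_TOP"]
    bot = trial.positions["GLASS_BOTTOM"]
    if smoothing_passes:
        top = triangular_smooth(top, passes=smoothing_passes)
        bot = triangular_smooth(bot, passes=smoothing_passes)
    axis = top - bot
    norm = np.linalg.norm(axis, axis=1)
    if (norm < 1.0).any():
        raise SegmentationError(
            "glass markers closer than 1 mm: glass axis degenerate"
        )
    cosang = np.clip(axis[:, 2] / norm, -1.0, 1.0)
    return np.degrees(np.arccos(cosang))


def _first_sustained(mask: np.ndarray, hold: int, start: int = 0) -> int | None:
    """First index >= start where ``mask`` holds for ``hold`` consecutive frames."""
    n = mask.shape[0]
    run = 0
    for i in range(start, n):
        run = run + 1 if mask[i] else 0
        if run >= hold:
            return i - hold + 1
    return None


def _seek_speed_minimum(
    speed: np.ndarray, start: int, patience: int, floor: float = 0.0
) -> int:
    """Follow a descending speed signal from ``start`` to its settle point.

    Greedily jumps to the smallest sample within the next ``patience``
    frames while that improves on the current one; a sample at or below
    ``floor`` counts as settled immediately (stops the chase down the
    filter-smeared tail after a full stop).  Deterministic."""
    k = start
    n = speed.shape[0]
    while True:
        if speed[k] <= floor:
            return k
        lo, hi = k + 1, min(n, k + 1 + patience)
        if lo >= hi:
            return k
        window = speed[lo:hi]
        j = int(np.argmin(window))
        if window[j] < speed[k]:
            k = lo + j
        else:
            return k


def _settle_changepoint(
    speed: np.ndarray,
    cand: int,
    fs: float,
    rest: np.ndarray,
    lower_bound: int,
    ceiling: float,
) -> int:
    """Locate a full stop in a noisy speed signal by changepoint fitting.

    A smooth stop ends with a quadratic speed decay, v(t) ~ a (tau - t)^2.
    The terminal descent (samples between the noise floor and ``ceiling``)
    is fit with that model for every candidate stop frame tau, scoring
    also the residuals of the frames after the descent (which the model
    predicts at the noise floor); the tau minimising the squared error is
    the settle frame.  Extrapolating the descent is far less biased than
    thresholding it, whose crossing time degrades with slower approaches.
    """
    n = speed.shape[0]
    noise_mean = float(np.mean(rest))
    y = np.clip(speed - noise_mean, 0.0, None)
    lo = max(2.0 * float(np.median(rest)), 2.0)
    k = cand
    while k < n and y[k] >= lo:
        k += 1
    pre = []
    j = k - 1
    while j > lower_bound and lo <= y[j] < ceiling:
        pre.append(j)
        j -= 1
    pre_idx = np.array(pre[::-1], dtype=int)
    if pre_idx.size < 3:
        return min(k, n - 1)  # descent too brief to fit: plateau entry
    k2 = min(n, k + round(0.25 * fs))
    best_sse, best_tau = np.inf, k
    tail = np.arange(pre_idx[-1] + 1, k2)
    for tau in range(int(pre_idx[-1]) + 1, k2):
        u = (tau - pre_idx).astype(float)
        a = float((y[pre_idx] * u**2).sum() / (u**4).sum())
        resid = y[pre_idx] - a * u**2
        model_tail = np.where(tail < tau, a * (tau - tail).astype(float) ** 2, 0.0)
        sse = float((resid**2).sum() + ((y[tail] - model_tail) ** 2).sum())
        if sse < best_sse:
            best_sse, best_tau = sse, tau
    return min(best_tau, n - 1)


def detect_events(trial: Trial, cfg: SegmentationConfig | None = None) -> TaskEvents:
    """Detect T1..T5 on a trial.  Deterministic; raises
    :class:`SegmentationError` naming the first event that cannot be found."""
    cfg = cfg or SegmentationConfig()
    fs = trial.fs
    hold = int(cfg.onset_hold)
    patience = max(1, round(cfg.seek_patience_s * fs))

    pos = {
        m: triangular_smooth(trial.positions[m], passes=cfg.smoothing_passes)
        for m in ("HAND", "C7", "MOUTH", "GLASS_TOP", "GLASS_BOTTOM")
    }

    def speed(m: str, presmooth: int) -> np.ndarray:
        return tangential_speed(trial.positions[m], fs, presmooth_passes=presmooth)

    hand_speed = speed("HAND", cfg.detection_presmooth)
    body_speed = np.maximum(hand_speed, speed("C7", cfg.detection_presmooth))
    n = body_speed.shape[0]

    # ---- T1: onset of any body motion (hand or trunk) -----------------
    # The sustained threshold crossing is found on the robust (deeply
    # smoothed) signal; the onset frame is then backtracked along the
    # falling edge.  On clean data backtracking uses the raw-difference
    # signal, whose pre-onset values are exactly at rest (the smoothed
    # signal smears small values several frames before the true onset).
    cross = _first_sustained(body_speed > cfg.onset_speed, hold)
    if cross is None:
        raise SegmentationError("T1 not found: body speed never sustained above onset threshold")
    body_raw = np.maximum(speed("HAND", 0), speed("C7", 0))
    raw_baseline = float(np.median(body_raw[: max(hold, cross)]))
    if raw_baseline <= cfg.rest_floor:
        back_signal, floor = body_raw, 1.5 * raw_baseline
    else:
        back_signal = body_speed
        baseline = float(np.median(body_speed[: max(hold, cross)]))
        floor = max(cfg.rest_floor, 1.5 * baseline)
    t1 = cross
    while t1 > 0 and back_signal[t1 - 1] < back_signal[t1] and back_signal[t1] > floor:
        t1 -= 1

    # ---- T2: hand settles at the glass --------------------------------
    # Clean data: the raw-difference hand speed localises the grasp
    # settle to a frame; noisy data: the smoothed signal with a
    # rest-level floor (the rest period before T1 decides the regime).
    # a lightly smoothed signal keeps the between-submovement speed dips
    # (which deep smoothing would fill in) while taming raw noise
    hand_raw = speed("HAND", 0)
    hand_rest_raw = float(np.median(hand_raw[: max(hold, t1)]))
    if hand_rest_raw <= cfg.rest_floor:
        settle_speed, settle_floor = hand_raw, 1.5 * hand_rest_raw
    else:
        settle_speed = speed("HAND", cfg.smoothing_passes)
        settle_floor = 1.5 * float(np.median(settle_speed[: max(hold, t1)]))
    hand_glass = np.linalg.norm(pos["HAND"] - pos["GLASS_TOP"], axis=1)
    cond2 = (hand_glass < cfg.grasp_dist) & (settle_speed < cfg.grasp_speed)
    cond2[: t1 + 1] = False
    cand = np.flatnonzero(cond2)
    if cand.size == 0:
        raise SegmentationError("T2 not found: hand never settles within reach of the glass")
    t2 = _seek_speed_minimum(settle_speed, int(cand[0]), patience, floor=settle_floor)

    # ---- T3: tilted glass at the lips ---------------------------------
    incl = glass_inclination(trial, smoothing_passes=cfg.smoothing_passes)
    glass_mouth = np.linalg.norm(pos["GLASS_TOP"] - pos["MOUTH"], axis=1)
    cond3 = (glass_mouth < cfg.lip_dist) & (incl >= cfg.drink_angle)
    later = np.flatnonzero(cond3[t2 + 1 :])
    if later.size == 0:
        raise SegmentationError("T3 not found: glass never tilted at the lips")
    t3 = int(later[0]) + t2 + 1

    # ---- T4: drinking condition ceases --------------------------------
    t4 = _first_sustained(~cond3, hold, start=t3 + 1)
    if t4 is None:
        raise SegmentationError("T4 not found: drinking condition never ceases")

    # ---- T5: glass settles back on the table --------------------------
    # On clean data the raw-difference speed pinpoints the full stop
    # exactly (its post-stop tail is one frame); at realistic noise the
    # raw signal's floor is too high, so the smoothed signal with a
    # changepoint fit of the terminal decay is used instead.  The rest
    # period before T1 calibrates which regime applies.
    glass_raw = speed("GLASS_BOTTOM", 0)
    raw_rest = float(np.median(glass_raw[: max(hold, t1)]))
    clean = raw_rest <= cfg.rest_floor
    glass_speed = glass_raw if clean else speed("GLASS_BOTTOM", cfg.detection_presmooth)
    height = np.abs(pos["GLASS_BOTTOM"][:, 2] - cfg.table_z)
    cond5 = (height < cfg.table_tol) & (glass_speed < cfg.grasp_speed)
    cond5[: t4 + 1] = False
    cand5 = np.flatnonzero(cond5)
    if cand5.size == 0:
        raise SegmentationError("T5 not found: glass never settles back on the table")
    if clean:
        t5 = _seek_speed_minimum(glass_speed, int(cand5[0]), patience, floor=1.5 * raw_rest)
    else:
        t5 = _settle_changepoint(
            glass_speed, int(cand5[0]), fs,
            rest=glass_speed[: max(hold, t1)],
            lower_bound=t4,
            ceiling=2.0 * cfg.grasp_speed,
        )
    t5 = min(t5, n - 1)

    try:
        return TaskEvents(int(t1), int(t2), int(t3), int(t4), int(t5))
    except SegmentationError as exc:
        raise SegmentationError(f"detected events are non-monotonic: {exc}") from exc


def phase_windows(events: TaskEvents, fs: float) -> PhaseWindows:
    """Half-open phase windows; the four durations telescope to (T5-T1)/fs."""
    if fs <= 0:
        raise ValueError(f"fs must be > 0, got {fs}")
    return PhaseWindows(
        rg=(events.t1, events.t2),
        bgm=(events.t2, events.t3),
        dg=(events.t3, events.t4),
        tbgt=(events.t4, events.t5),
        fs=fs,
    )


def read_events_sidecar(path: str | Path) -> TaskEvents:
    """Read operator-marked events from a TSV sidecar with columns
    ``event<TAB>frame`` (event names t1..t5, case-insensitive)."""
    found: dict[str, int] = {}
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#") or line.lower().startswith("event"):
                continue
            name, frame = line.split("\t")
            found[name.strip().lower()] = int(frame)
    missing = [e for e in ("t1", "t2", "t3", "t4", "t5") if e not in found]
    if missing:
        raise SegmentationError(f"sidecar {path} missing events: {missing}")
    return TaskEvents(found["t1"], found["t2"], found["t3"], found["t4"], found["t5"])
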