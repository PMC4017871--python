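"""Marker-trajectory trial I/O and the functional marker set.

A :class:`Trial` holds labelled 3-D marker trajectories in the lab frame
(X forward toward the glass, Y subject's-left positive, Z vertical up,
origin at the table-edge midpoint, table surface at Z = 0, units mm).
Trials can be read from / written to the binary C3D motion-capture
standard or a plain-text TSV dialect used throughout the test suite.

Only eight markers are functionally required by the downstream analysis:
the grasping hand (3rd metacarpal head), wrist, elbow (lateral
epicondyle), shoulder (acromion, grasping side), C7, a head marker close
to the mouth, and two glass markers (top rim and bottom) from which the
glass inclination is computed.  Any further markers in a file are carried
through untouched.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np

from . import c3d_codec

__all__ = [
    "REQUIRED_MARKERS",
    "MARKER_ALIASES",
    "SubjectMeta",
    "Trial",
    "TrialValidationError",
    "MissingMarkerError",
    "read_trial",
    "write_trial",
    "mirror_trial",
    "interpolate_gaps",
]

#: Labels every analyzable trial must resolve (case-insensitively).
REQUIRED_MARKERS: tuple[str, ...] = (
    "HAND",
    "WRIST",
    "ELBOW",
    "SHOULDER",
    "C7",
    "MOUTH",
    "GLASS_TOP",
    "GLASS_BOTTOM",
)

#: Common alternative labels mapped onto the canonical functional set.
MARKER_ALIASES: dict[str, str] = {
    "3MH": "HAND",
    "MC3": "HAND",
    "METAC3": "HAND",
    "WRT": "WRIST",
    "WRIST_RADIAL": "WRIST",
    "ELB": "ELBOW",
    "LAT_EPICONDYLE": "ELBOW",
    "ACROMION": "SHOULDER",
    "ACR": "SHOULDER",
    "C7_SPINOUS": "C7",
    "HEAD_MOUTH": "MOUTH",
    "GLASS_RIM": "GLASS_TOP",
    "GLASS_BASE": "GLASS_BOTTOM",
}

#: Longest run of missing samples (frames) that may be linearly interpolated.
MAX_GAP_FRAMES = 6


class TrialValidationError(ValueError):
    """A trial violates a structural invariant (shape, finiteness, fs)."""


class MissingMarkerError(TrialValidationError):
    """A required marker label could not be resolved in a file."""

    def __init__(self, marker: str, path: str | Path | None = None):
        self.marker = marker
        where = f" in {path}" if path is not None else ""
        super().__init__(f"required marker {marker} missing{where}")


@dataclass
class SubjectMeta:
    """Subject-level metadata carried alongside a trial."""

    id: str = "anonymous"
    group: str = "control"  # 'stroke' | 'control'
    barthel: float | None = None  # disability score, 0-100
    fma: float | None = None  # upper-extremity motor score, 0-66

    def __post_init__(self) -> None:
        if self.group not in ("stroke", "control"):
            raise TrialValidationError(
                f"group must be 'stroke' or 'control', got {self.group!r}"
            )


@dataclass
class Trial:
    """Labelled 3-D marker trajectories plus acquisition metadata.

    positions maps marker label -> float array of shape (n_frames, 3), mm.
    """

    positions: dict[str, np.ndarray]
    fs: float
    side: str = "right"  # grasping side
    meta: SubjectMeta = field(default_factory=SubjectMeta)

    @property
    def n_frames(self) -> int:
        return next(iter(self.positions.values())).shape[0]

    @property
    def markers(self) -> list[str]:
        return list(self.positions)

    def duration_s(self) -> float:
        return self.n_frames / self.fs

    def validate(self) -> "Trial":
        """Raise :class:`TrialValidationError` on any broken invariant."""
        if self.fs <= 0:
            raise TrialValidationError(f"sampling frequency must be > 0, got {self.fs}")
        if self.side not in ("left", "right"):
            raise TrialValidationError(f"side must be 'left' or 'right', got {self.side!r}")
        if not self.positions:
            raise TrialValidationError("trial has no markers")
        n = None
        for label, xyz in self.positions.items():
            xyz = np.asarray(xyz, dtype=float)
            if xyz.ndim != 2 or xyz.shape[1] != 3:
                raise TrialValidationError(f"marker {label}: expected (n, 3) array")
            if n is None:
                n = xyz.shape[0]
            elif xyz.shape[0] != n:
                raise TrialValidationError(
                    f"marker {label}: frame count {xyz.shape[0]} != {n}"
                )
            if not np.isfinite(xyz).all():
                raise TrialValidationError(f"marker {label}: non-finite coordinates")
        if n is None or n < 30:
            raise TrialValidationError(f"trial too short: {n} frames (minimum 30)")
        for req in REQUIRED_MARKERS:
            if req not in self.positions:
                raise MissingMarkerError(req)
        return self

    def copy(self) -> "Trial":
        return Trial(
            positions={k: v.copy() for k, v in self.positions.items()},
            fs=self.fs,
            side=self.side,
            meta=replace(self.meta),
        )


def _canonical_label(raw: str) -> str:
    up = raw.strip().upper()
    return MARKER_ALIASES.get(up, up)


def resolve_markers(labels: list[str], path: str | Path | None = None) -> dict[str, str]:
    """Map raw file labels onto canonical names; error on a missing required one."""
    mapping: dict[str, str] = {}
    seen: set[str] = set()
    for raw in labels:
        canon = _canonical_label(raw)
        if canon in REQUIRED_MARKERS:
            if canon in seen:
                raise TrialValidationError(f"duplicate required marker {canon}")
            seen.add(canon)
            mapping[raw] = canon
        else:
            mapping[raw] = raw.strip()
    for req in REQUIRED_MARKERS:
        if req not in seen:
            raise MissingMarkerError(req, path)
    return mapping


def interpolate_gaps(xyz: np.ndarray, max_gap: int = MAX_GAP_FRAMES, label: str = "?") -> np.ndarray:
    """Fill NaN runs of <= ``max_gap`` frames by per-axis linear interpolation.

    Longer runs, or missing samples at either end of the record (which
    would require extrapolation), raise :class:`TrialValidationError`.
    """
    xyz = np.asarray(xyz, dtype=float).copy()
    bad = ~np.isfinite(xyz).all(axis=1)
    if not bad.any():
        return xyz
    n = xyz.shape[0]
    if bad[0] or bad[-1]:
        raise TrialValidationError(f"marker {label}: missing samples at record boundary")
    # locate runs of consecutive bad frames
    idx = np.flatnonzero(bad)
    run_start = idx[np.r_[True, np.diff(idx) > 1]]
    run_end = idx[np.r_[np.diff(idx) > 1, True]]
    for s, e in zip(run_start, run_end):
        if e - s + 1 > max_gap:
            raise TrialValidationError(
                f"marker {label}: gap of {e - s + 1} frames at frame {s} "
                f"exceeds {max_gap}-frame interpolation limit"
            )
    good = np.flatnonzero(~bad)
    for axis in range(3):
        xyz[bad, axis] = np.interp(idx.astype(float), good.astype(float), xyz[good, axis])
    return xyz


# ---------------------------------------------------------------------------
# TSV dialect
# ---------------------------------------------------------------------------
# One row per frame; tab-separated columns "<label>_x <label>_y <label>_z";
# leading comment lines "# key=value" carry fs, side and subject metadata.

_TSV_FLOAT_FMT = "%.9f"


def _write_tsv(trial: Trial, path: Path) -> None:
    labels = trial.markers
    header_meta = [
        f"# fs={trial.fs:g}",
        f"# side={trial.side}",
        f"# id={trial.meta.id}",
        f"# group={trial.meta.group}",
    ]
    if trial.meta.barthel is not None:
        header_meta.append(f"# barthel={trial.meta.barthel:g}")
    if trial.meta.fma is not None:
        header_meta.append(f"# fma={trial.meta.fma:g}")
    cols = [f"{lab}_{ax}" for lab in labels for ax in "xyz"]
    data = np.hstack([trial.positions[lab] for lab in labels])
    with open(path, "w") as fh:
        fh.write("\n".join(header_meta) + "\n")
        fh.write("\t".join(cols) + "\n")
        np.savetxt(fh, data, fmt=_TSV_FLOAT_FMT, delimiter="\t")


def _read_tsv(path: Path) -> Trial:
    meta_kv: dict[str, str] = {}
    header: list[str] | None = None
    rows: list[list[float]] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            if line.startswith("#"):
                body = line.lstrip("#").strip()
                if "=" in body:
                    k, v = body.split("=", 1)
                    meta_kv[k.strip().lower()] = v.strip()
                continue
            if header is None:
                header = line.split("\t")
                continue
            parts = line.split("\t")
            if len(parts) != len(header):
                raise TrialValidationError(
                    f"{path}: line {lineno}: {len(parts)} fields, expected {len(header)}"
                )
            try:
                rows.append([float(p) if p.strip() not in ("", "NA") else math.nan for p in parts])
            except ValueError as exc:
                raise TrialValidationError(f"{path}: line {lineno}: {exc}") from exc
    if header is None or not rows:
        raise TrialValidationError(f"{path}: no data rows")
    if "fs" not in meta_kv:
        raise TrialValidationError(f"{path}: TSV header lacks '# fs=' line")
    fs = float(meta_kv["fs"])
    if fs <= 0:
        raise TrialValidationError(f"{path}: fs must be > 0, got {fs}")

    # group columns into labels
    labels: list[str] = []
    for col in header:
        if not col.endswith(("_x", "_y", "_z")):
            raise TrialValidationError(f"{path}: column {col!r} lacks _x/_y/_z suffix")
        lab = col[:-2]
        if lab not in labels:
            labels.append(lab)
    for lab in labels:
        for ax in "xyz":
            if f"{lab}_{ax}" not in header:
                raise TrialValidationError(f"{path}: marker {lab} missing {ax} column")

    data = np.asarray(rows, dtype=float)
    col_index = {c: i for i, c in enumerate(header)}
    mapping = resolve_markers(labels, path)
    positions: dict[str, np.ndarray] = {}
    for lab in labels:
        xyz = np.stack(
            [data[:, col_index[f"{lab}_{ax}"]] for ax in "xyz"], axis=1
        )
        positions[mapping[lab]] = interpolate_gaps(xyz, label=mapping[lab])

    meta = SubjectMeta(
        id=meta_kv.get("id", "anonymous"),
        group=meta_kv.get("group", "control"),
        barthel=float(meta_kv["barthel"]) if "barthel" in meta_kv else None,
        fma=float(meta_kv["fma"]) if "fma" in meta_kv else None,
    )
    return Trial(positions=positions, fs=fs, side=meta_kv.get("side", "right"), meta=meta).validate()


# ---------------------------------------------------------------------------
# C3D
# ---------------------------------------------------------------------------


def _read_c3d(path: Path) -> Trial:
    labels, points, fs = c3d_codec.read(path)
    mapping = resolve_markers(labels, path)
    positions = {
        mapping[lab]: interpolate_gaps(points[:, i, :], label=mapping[lab])
        for i, lab in enumerate(labels)
    }
    if fs <= 0:
        raise TrialValidationError(f"{path}: fs must be > 0, got {fs}")
    return Trial(positions=positions, fs=fs).validate()


def _write_c3d(trial: Trial, path: Path) -> None:
    labels = trial.markers
    points = np.stack([trial.positions[lab] for lab in labels], axis=1)
    c3d_codec.write(path, labels, points, trial.fs)


# ---------------------------------------------------------------------------
# public API
# ---------------------------------------------------------------------------


def _infer_format(path: Path, fmt: str | None) -> str:
    if fmt is not None:
        fmt = fmt.lower()
        if fmt not in ("c3d", "tsv"):
            raise ValueError(f"unknown trial format {fmt!r}")
        return fmt
    suffix = path.suffix.lower()
    if suffix == ".c3d":
        return "c3d"
    if suffix in (".tsv", ".txt"):
        return "tsv"
    raise ValueError(f"cannot infer format from {path.name!r}; pass format=")


def read_trial(path: str | Path, format: str | None = None) -> Trial:
    """Read a trial from ``path`` (C3D or TSV, inferred from the suffix)."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    fmt = _infer_format(path, format)
    return _read_tsv(path) if fmt == "tsv" else _read_c3d(path)


def write_trial(trial: Trial, path: str | Path, format: str | None = None) -> None:
    """Write a validated trial to ``path`` (C3D or TSV)."""
    trial.validate()
    path = Path(path)
    fmt = _infer_format(path, format)
    if fmt == "tsv":
        _write_tsv(trial, path)
    else:
        _write_c3d(trial, path)


def mirror_trial(trial: Trial) -> Trial:
    """Reflect a trial across the sagittal plane (negate Y, flip side label).

    An involution: every downstream index is invariant under it, which is
    what allows pooling left- and right-affected subjects.
    """
    out = trial.copy()
    for xyz in out.positions.values():
        xyz[:, 1] *= -1.0
    out.side = "left" if trial.side == "right" else "right"
    return out
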