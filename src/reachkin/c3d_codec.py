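"""Minimal reader/writer for the C3D motion-capture file format.

Covers the subset of the standard needed to exchange labelled point
trajectories: Intel (little-endian) byte order, 3-D point data stored
either as float32 (negative POINT:SCALE) or as scaled int16, no analog
channels.  Files written here always use float32 storage, so round-trip
precision is limited by float32 (~6e-5 mm at 1 m range).

Layout per the C3D standard: 512-byte blocks; block 1 is the header,
the parameter section starts at the block named in header byte 0, and
point data start at the block named by POINT:DATA_START.  Invalid points
(negative residual) are returned as NaN.
"""

from __future__ import annotations

import struct
from pathlib import Path

import numpy as np

__all__ = ["read", "write", "C3DError"]

_BLOCK = 512
_PROC_INTEL = 84  # processor type tag: 84 Intel, 85 DEC, 86 MIPS


class C3DError(ValueError):
    pass


# ---------------------------------------------------------------------------
# writing
# ---------------------------------------------------------------------------


def _param_record(name: str, dtype: int, dims: list[int], payload: bytes, group_id: int) -> bytes:
    rec = struct.pack("bb", len(name), group_id)
    rec += name.encode("ascii")
    body = struct.pack("b", dtype) + struct.pack("B", len(dims))
    body += bytes(dims) + payload + b"\x00"  # zero-length description
    rec += struct.pack("<h", 2 + len(body)) + body
    return rec


def _group_record(name: str, group_id: int) -> bytes:
    rec = struct.pack("bb", len(name), -group_id)
    rec += name.encode("ascii")
    rec += struct.pack("<h", 2 + 1) + b"\x00"
    return rec


def write(path: str | Path, labels: list[str], points: np.ndarray, fs: float) -> None:
    """Write ``points`` of shape (n_frames, n_markers, 3) in mm at ``fs`` Hz."""
    points = np.asarray(points, dtype=np.float32)
    if points.ndim != 3 or points.shape[2] != 3:
        raise C3DError("points must have shape (n_frames, n_markers, 3)")
    n_frames, n_pts, _ = points.shape
    if n_pts != len(labels):
        raise C3DError(f"{len(labels)} labels for {n_pts} markers")
    if n_frames > 32767:
        raise C3DError("frame count exceeds int16 header field")

    label_len = max(4, max(len(l) for l in labels))
    label_blob = b"".join(l.ljust(label_len).encode("ascii") for l in labels)

    def build_params(data_start_block: int) -> bytes:
        params = b""
        params += _group_record("POINT", 1)
        params += _param_record("USED", 2, [], struct.pack("<h", n_pts), 1)
        params += _param_record("FRAMES", 2, [], struct.pack("<h", n_frames), 1)
        params += _param_record("RATE", 4, [], struct.pack("<f", float(fs)), 1)
        params += _param_record("SCALE", 4, [], struct.pack("<f", -1.0), 1)
        params += _param_record("DATA_START", 2, [], struct.pack("<h", data_start_block), 1)
        params += _param_record("LABELS", -1, [label_len, n_pts], label_blob, 1)
        params += struct.pack("bb", 0, 0)  # terminator
        return params

    # DATA_START depends on the parameter-section size; iterate to fixpoint
    data_start_block = 3
    for _ in range(3):
        params = build_params(data_start_block)
        n_param_blocks = -(-(4 + len(params)) // _BLOCK)
        if 2 + n_param_blocks == data_start_block:
            break
        data_start_block = 2 + n_param_blocks
    param_section = struct.pack("BBBB", 0x01, 0x50, n_param_blocks, _PROC_INTEL) + params
    param_section = param_section.ljust(n_param_blocks * _BLOCK, b"\x00")

    header = bytearray(_BLOCK)
    struct.pack_into("BB", header, 0, 2, 0x50)  # parameter block pointer, magic
    struct.pack_into("<h", header, 2, n_pts)
    struct.pack_into("<h", header, 4, 0)  # analog measurements per frame
    struct.pack_into("<h", header, 6, 1)  # first frame (1-based)
    struct.pack_into("<h", header, 8, n_frames)  # last frame
    struct.pack_into("<h", header, 10, 0)  # max interpolation gap
    struct.pack_into("<f", header, 12, -1.0)  # scale factor (negative = float)
    struct.pack_into("<h", header, 16, data_start_block)
    struct.pack_into("<h", header, 18, 0)  # analog samples per frame
    struct.pack_into("<f", header, 20, float(fs))

    frame_data = np.zeros((n_frames, n_pts, 4), dtype="<f4")
    frame_data[:, :, :3] = points
    payload = frame_data.tobytes()
    payload = payload.ljust(-(-len(payload) // _BLOCK) * _BLOCK, b"\x00")

    with open(path, "wb") as fh:
        fh.write(bytes(header))
        fh.write(param_section)
        fh.write(payload)


# ---------------------------------------------------------------------------
# reading
# ---------------------------------------------------------------------------


def _parse_params(raw: bytes, path: Path) -> dict[str, dict[str, object]]:
    """Parse the parameter section into {GROUP: {PARAM: value}}."""
    if len(raw) < 4:
        raise C3DError(f"{path}: truncated parameter section")
    proc = raw[3]
    if proc != _PROC_INTEL:
        raise C3DError(f"{path}: unsupported processor type {proc} (only Intel/84)")
    groups_by_id: dict[int, str] = {}
    params: list[tuple[int, str, object]] = []
    pos = 4
    while pos + 2 <= len(raw):
        nchar = struct.unpack_from("b", raw, pos)[0]
        gid = struct.unpack_from("b", raw, pos + 1)[0]
        if nchar == 0 or gid == 0:
            break
        name = raw[pos + 2 : pos + 2 + abs(nchar)].decode("ascii", "replace").upper()
        pos2 = pos + 2 + abs(nchar)
        offset = struct.unpack_from("<h", raw, pos2)[0]
        next_pos = pos2 + offset
        if gid < 0:  # group record
            groups_by_id[-gid] = name
        else:  # parameter record
            p = pos2 + 2
            dtype = struct.unpack_from("b", raw, p)[0]
            ndims = raw[p + 1]
            dims = list(raw[p + 2 : p + 2 + ndims])
            p += 2 + ndims
            count = int(np.prod(dims)) if dims else 1
            size = {-1: 1, 1: 1, 2: 2, 4: 4}.get(dtype)
            if size is None:
                raise C3DError(f"{path}: parameter {name}: bad type {dtype}")
            blob = raw[p : p + count * size]
            if len(blob) < count * size:
                raise C3DError(f"{path}: parameter {name}: truncated data")
            if dtype == -1:
                value: object = blob.decode("ascii", "replace")
                if len(dims) == 2:
                    w = dims[0]
                    value = [value[i * w : (i + 1) * w].strip() for i in range(dims[1])]
            elif dtype == 1:
                value = np.frombuffer(blob, dtype=np.int8).reshape(dims[::-1] or [1])
            elif dtype == 2:
                value = np.frombuffer(blob, dtype="<i2").reshape(dims[::-1] or [1])
            else:
                value = np.frombuffer(blob, dtype="<f4").reshape(dims[::-1] or [1])
            params.append((gid, name, value))
        if offset <= 0:
            break
        pos = next_pos
    out: dict[str, dict[str, object]] = {}
    for gid, name, value in params:
        gname = groups_by_id.get(gid, f"GROUP{gid}")
        out.setdefault(gname, {})[name] = value
    return out


def _scalar(v: object) -> float:
    arr = np.asarray(v).ravel()
    return float(arr[0])


def read(path: str | Path) -> tuple[list[str], np.ndarray, float]:
    """Read a C3D file -> (labels, points (n_frames, n_markers, 3) mm, fs)."""
    path = Path(path)
    raw = path.read_bytes()
    if len(raw) < 2 * _BLOCK:
        raise C3DError(f"{path}: file too small to be C3D")
    if raw[1] != 0x50:
        raise C3DError(f"{path}: missing C3D magic byte")
    param_block = raw[0]
    pstart = (param_block - 1) * _BLOCK
    n_param_blocks = raw[pstart + 2]
    pdict = _parse_params(raw[pstart : pstart + max(1, n_param_blocks) * _BLOCK], path)

    point = pdict.get("POINT", {})
    n_pts = int(_scalar(point.get("USED", struct.unpack_from("<h", raw, 2)[0])))
    n_frames = int(_scalar(point.get("FRAMES", 0)))
    if n_frames <= 0:
        first = struct.unpack_from("<h", raw, 6)[0]
        last = struct.unpack_from("<h", raw, 8)[0]
        n_frames = last - first + 1
    fs = _scalar(point.get("RATE", struct.unpack_from("<f", raw, 20)[0]))
    scale = _scalar(point.get("SCALE", struct.unpack_from("<f", raw, 12)[0]))
    data_start = int(_scalar(point.get("DATA_START", struct.unpack_from("<h", raw, 16)[0])))
    labels = point.get("LABELS")
    if labels is None:
        labels = [f"M{i:03d}" for i in range(n_pts)]
    labels = [str(l) for l in labels][:n_pts]
    if len(labels) < n_pts:
        labels += [f"M{i:03d}" for i in range(len(labels), n_pts)]

    dstart = (data_start - 1) * _BLOCK
    if scale < 0:  # float storage
        need = n_frames * n_pts * 4 * 4
        blob = raw[dstart : dstart + need]
        if len(blob) < need:
            got_frames = len(blob) // (n_pts * 16)
            raise C3DError(
                f"{path}: truncated point data at frame {got_frames} of {n_frames}"
            )
        frames = np.frombuffer(blob, dtype="<f4").reshape(n_frames, n_pts, 4)
        points = frames[:, :, :3].astype(float)
        residual = frames[:, :, 3]
    else:  # int16 storage scaled by POINT:SCALE
        need = n_frames * n_pts * 4 * 2
        blob = raw[dstart : dstart + need]
        if len(blob) < need:
            got_frames = len(blob) // (n_pts * 8)
            raise C3DError(
                f"{path}: truncated point data at frame {got_frames} of {n_frames}"
            )
        frames = np.frombuffer(blob, dtype="<i2").reshape(n_frames, n_pts, 4)
        points = frames[:, :, :3].astype(float) * scale
        residual = frames[:, :, 3].astype(float)
    points = points.copy()
    points[residual < 0] = np.nan  # invalid points -> gaps
    return labels, points, fs
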