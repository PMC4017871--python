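"""Trial I/O: TSV/C3D round-trips, marker resolution, gaps, mirroring."""

import struct

import numpy as np
import pytest

from reachkin import c3d_codec
from reachkin.marker_io import (
    REQUIRED_MARKERS,
    MissingMarkerError,
    Trial,
    TrialValidationError,
    interpolate_gaps,
    mirror_trial,
    read_trial,
    write_trial,
)


def test_tsv_round_trip_is_identity(healthy_trial, tmp_path):
    trial, _ = healthy_trial
    path = tmp_path / "trial.tsv"
    write_trial(trial, path)
    back = read_trial(path)
    assert back.fs == trial.fs
    assert back.side == trial.side
    assert back.meta.id == trial.meta.id
    assert back.meta.group == trial.meta.group
    assert set(back.positions) == set(trial.positions)
    for m in trial.positions:
        np.testing.assert_allclose(back.positions[m], trial.positions[m], atol=1e-6)


def test_c3d_round_trip_preserves_coordinates_and_rate(healthy_trial, tmp_path):
    # C3D stores float32, so the round-trip tolerance is the float32
    # quantisation at sub-metre range, not the TSV's 1e-6 mm.
    trial, _ = healthy_trial
    path = tmp_path / "trial.c3d"
    write_trial(trial, path)
    back = read_trial(path)
    assert back.fs == trial.fs
    assert set(back.positions) == set(trial.positions)
    for m in trial.positions:
        np.testing.assert_allclose(back.positions[m], trial.positions[m], atol=1e-3)


def test_c3d_reader_accepts_independently_packed_file(tmp_path):
    """Read a C3D byte stream assembled by hand (independent of the
    package's writer): int16-scaled storage, minimal parameter section."""
    n_frames, labels = 40, [f"M{i}" for i in range(3)]
    rng = np.random.default_rng(0)
    pts_int = rng.integers(-2000, 2000, size=(n_frames, 3, 3)).astype(np.int16)
    scale = 0.1

    def prm(name, dtype, dims, payload, gid=1):
        body = struct.pack("b", dtype) + struct.pack("B", len(dims)) + bytes(dims)
        body += payload + b"\x00"
        return (struct.pack("bb", len(name), gid) + name.encode()
                + struct.pack("<h", 2 + len(body)) + body)

    grp = struct.pack("bb", 5, -1) + b"POINT" + struct.pack("<h", 3) + b"\x00"
    label_blob = b"".join(l.ljust(4).encode() for l in labels)
    params = grp
    params += prm("USED", 2, [], struct.pack("<h", 3))
    params += prm("FRAMES", 2, [], struct.pack("<h", n_frames))
    params += prm("RATE", 4, [], struct.pack("<f", 60.0))
    params += prm("SCALE", 4, [], struct.pack("<f", scale))
    params += prm("DATA_START", 2, [], struct.pack("<h", 3))
    params += prm("LABELS", -1, [4, 3], label_blob)
    params += struct.pack("bb", 0, 0)
    param_section = (struct.pack("BBBB", 0x01, 0x50, 1, 84) + params).ljust(512, b"\x00")

    header = bytearray(512)
    struct.pack_into("BB", header, 0, 2, 0x50)
    struct.pack_into("<h", header, 2, 3)
    struct.pack_into("<h", header, 6, 1)
    struct.pack_into("<h", header, 8, n_frames)
    struct.pack_into("<f", header, 12, scale)
    struct.pack_into("<h", header, 16, 3)
    struct.pack_into("<f", header, 20, 60.0)

    data = np.zeros((n_frames, 3, 4), dtype="<i2")
    data[:, :, :3] = pts_int
    blob = data.tobytes().ljust(512 * ((n_frames * 3 * 8 + 511) // 512), b"\x00")

    path = tmp_path / "alien.c3d"
    path.write_bytes(bytes(header) + param_section + blob)

    got_labels, got_points, got_fs = c3d_codec.read(path)
    assert got_labels == labels
    assert got_fs == 60.0
    assert got_points.shape == (n_frames, 3, 3)
    np.testing.assert_allclose(got_points, pts_int.astype(float) * scale, atol=1e-6)


def test_missing_required_marker_is_named(healthy_trial, tmp_path):
    trial, _ = healthy_trial
    crippled = trial.copy()
    del crippled.positions["C7"]
    path = tmp_path / "bad.tsv"
    # bypass write-side validation to produce the defective file
    with pytest.raises(MissingMarkerError, match="C7"):
        Trial(crippled.positions, trial.fs).validate()
    write_trial(trial, path)
    text = path.read_text().replace("C7_", "CX_")
    path.write_text(text)
    with pytest.raises(MissingMarkerError, match="C7"):
        read_trial(path)


def test_write_refuses_non_finite_coordinates(healthy_trial, tmp_path):
    trial, _ = healthy_trial
    bad = trial.copy()
    bad.positions["HAND"][10, 0] = np.nan
    with pytest.raises(TrialValidationError, match="non-finite"):
        write_trial(bad, tmp_path / "nan.tsv")


@pytest.mark.parametrize("gap", [1, 3, 6])
def test_short_gaps_interpolated_linearly(gap):
    xyz = np.stack([np.arange(30.0)] * 3, axis=1)
    xyz[10 : 10 + gap] = np.nan
    filled = interpolate_gaps(xyz)
    np.testing.assert_allclose(filled, np.stack([np.arange(30.0)] * 3, axis=1))


def test_long_gap_rejected():
    xyz = np.zeros((30, 3))
    xyz[5:12] = np.nan  # 7 frames > 6-frame limit
    with pytest.raises(TrialValidationError, match="gap of 7 frames"):
        interpolate_gaps(xyz, label="HAND")


def test_mirror_is_an_involution_flipping_lateral_axis(stroke_trial):
    trial, _ = stroke_trial
    mirrored = mirror_trial(trial)
    assert mirrored.side != trial.side
    for m in trial.positions:
        np.testing.assert_array_equal(mirrored.positions[m][:, 0], trial.positions[m][:, 0])
        np.testing.assert_array_equal(mirrored.positions[m][:, 1], -trial.positions[m][:, 1])
        np.testing.assert_array_equal(mirrored.positions[m][:, 2], trial.positions[m][:, 2])
    twice = mirror_trial(mirrored)
    assert twice.side == trial.side
    for m in trial.positions:
        np.testing.assert_array_equal(twice.positions[m], trial.positions[m])


def test_marker_aliases_resolve_case_insensitively(healthy_trial, tmp_path):
    trial, _ = healthy_trial
    path = tmp_path / "alias.tsv"
    write_trial(trial, path)
    text = path.read_text().replace("SHOULDER_", "acromion_").replace("HAND_", "mc3_")
    path.write_text(text)
    back = read_trial(path)
    assert "SHOULDER" in back.positions and "HAND" in back.positions


def test_required_marker_set_is_complete_and_unique():
    assert len(set(REQUIRED_MARKERS)) == len(REQUIRED_MARKERS) == 8
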