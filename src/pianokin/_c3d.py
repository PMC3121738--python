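"""Minimal C3D motion-capture file support (Intel/float subset).

Reads and writes the subset of the C3D standard this pipeline uses: 3-D
point (marker) data stored as little-endian floats, marker labels and frame
rate from the parameter section, no analog channels.  Vertical marker height
is carried on the Z coordinate.  Multi-byte parameter records, parameter
arrays beyond 2-D, and DEC/MIPS number formats are out of scope.
"""

from __future__ import annotations

import struct

import numpy as np

__all__ = ["read_c3d", "write_c3d"]

_BLOCK = 512


def read_c3d(path) -> tuple[list[str], np.ndarray, float]:
    """Return (labels, points[frame, marker, xyz], frame_rate_hz)."""
    with open(path, "rb") as fh:
        data = fh.read()
    if len(data) < _BLOCK or data[1] != 0x50:
        raise ValueError(f"{path}: not a C3D file")
    param_block = data[0]
    n_points, _, first, last = struct.unpack_from("<HHHH", data, 2)
    scale = struct.unpack_from("<f", data, 12)[0]
    data_block = struct.unpack_from("<H", data, 16)[0]
    rate = struct.unpack_from("<f", data, 20)[0]
    if scale >= 0:
        raise ValueError(f"{path}: integer-scaled C3D not supported (scale={scale})")
    # parameter section: only LABELS from the POINT group are needed
    p = (param_block - 1) * _BLOCK
    proc = data[p + 3]
    if proc != 84:  # 83+1 = Intel
        raise ValueError(f"{path}: unsupported processor type {proc}")
    labels = _read_point_labels(data, p, n_points)
    n_frames = last - first + 1
    off = (data_block - 1) * _BLOCK
    words = np.frombuffer(data, dtype="<f4", offset=off, count=n_frames * n_points * 4)
    pts = words.reshape(n_frames, n_points, 4)[:, :, :3].astype(float)
    return labels, pts, float(rate)


def _read_point_labels(data: bytes, p: int, n_points: int) -> list[str]:
    pos = p + 4
    group_ids: dict[int, str] = {}
    labels: list[str] | None = None
    pending: list[tuple[int, list[str]]] = []
    while pos < len(data) - 1:
        nname = data[pos]
        if nname == 0:
            break
        nchar = nname if nname < 128 else 256 - nname
        gid = int.from_bytes(data[pos + 1 : pos + 2], "little", signed=True)
        name = data[pos + 2 : pos + 2 + nchar].decode("ascii", "replace")
        pos2 = pos + 2 + nchar
        next_off = struct.unpack_from("<h", data, pos2)[0]
        if gid < 0:  # group record
            group_ids[-gid] = name.upper()
        else:  # parameter record
            dtype = int.from_bytes(data[pos2 + 2 : pos2 + 3], "little", signed=True)
            ndims = data[pos2 + 3]
            dims = list(data[pos2 + 4 : pos2 + 4 + ndims])
            body = pos2 + 4 + ndims
            if name.upper() == "LABELS" and dtype == -1 and ndims == 2:
                width, count = dims
                raw = data[body : body + width * count]
                vals = [raw[i * width : (i + 1) * width].decode("ascii", "replace").strip()
                        for i in range(count)]
                pending.append((gid, vals))
        if next_off == 0:
            break
        pos = pos2 + next_off
    for gid, vals in pending:
        if group_ids.get(gid) == "POINT":
            labels = vals
    if labels is None:
        raise ValueError("C3D parameter section has no POINT:LABELS")
    return labels[:n_points]


def write_c3d(path, labels: list[str], points: np.ndarray, frame_rate: float) -> None:
    """Write markers as a float Intel C3D file.

    ``points`` has shape (n_frames, n_markers, 3), coordinates in mm.
    """
    pts = np.asarray(points, dtype=np.float32)
    n_frames, n_points, three = pts.shape
    if three != 3:
        raise ValueError("points must be (frames, markers, 3)")
    if len(labels) != n_points:
        raise ValueError("one label per marker required")
    width = max(4, max(len(s) for s in labels))
    if width > 127:
        raise ValueError("marker labels longer than 127 chars")

    # --- parameter section ---
    param = bytearray([1, 0x50, 0, 84])  # 1 param block (patched later), Intel
    def group(gid: int, name: bytes) -> bytes:
        rec = bytes([len(name)]) + gid.to_bytes(1, "little", signed=True) + name
        return rec + struct.pack("<h", 3) + b"\x00"  # next offset, 0-len description
    def param_rec(gid: int, name: bytes, dtype: int, dims: list[int], body: bytes) -> bytes:
        rec = bytes([len(name)]) + gid.to_bytes(1, "little") + name
        tail = dtype.to_bytes(1, "little", signed=True) + bytes([len(dims)] + dims) + body
        return rec + struct.pack("<h", len(tail) + 3) + tail + b"\x00"
    param += group(-1, b"POINT")
    param += param_rec(1, b"USED", 2, [], struct.pack("<h", n_points))
    param += param_rec(1, b"FRAMES", 2, [], struct.pack("<h", n_frames))
    param += param_rec(1, b"RATE", 4, [], struct.pack("<f", frame_rate))
    param += param_rec(1, b"SCALE", 4, [], struct.pack("<f", -1.0))
    param += param_rec(1, b"UNITS", -1, [2], b"mm")
    lab = b"".join(s.encode("ascii").ljust(width) for s in labels)
    param += param_rec(1, b"LABELS", -1, [width, n_points], lab)
    param += b"\x00"
    n_param_blocks = -(-len(param) // _BLOCK)
    param[0] = n_param_blocks
    param += b"\x00" * (n_param_blocks * _BLOCK - len(param))

    data_block = 2 + n_param_blocks
    header = bytearray(_BLOCK)
    header[0] = 2  # parameter section starts at block 2
    header[1] = 0x50
    struct.pack_into("<HHHH", header, 2, n_points, 0, 1, n_frames)
    struct.pack_into("<H", header, 10, 0)  # max interpolation gap
    struct.pack_into("<f", header, 12, -1.0)  # negative scale -> float data
    struct.pack_into("<H", header, 16, data_block)
    struct.pack_into("<H", header, 18, 1)  # analog samples per frame field
    struct.pack_into("<f", header, 20, frame_rate)

    frames = np.zeros((n_frames, n_points, 4), dtype="<f4")
    frames[:, :, :3] = pts
    with open(path, "wb") as fh:
        fh.write(bytes(header))
        fh.write(bytes(param))
        fh.write(frames.tobytes())
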