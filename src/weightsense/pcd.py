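"""Reader/writer for the PCD v0.7 point-cloud file format.

Supports the field subsets used by RGB-D(-T) recordings: ``x y z``, optional
``rgb`` (either one packed scalar in PCL's convention — ``r<<16|g<<8|b``
bit-cast into the field's storage type — or three separate unsigned byte
fields ``r g b``), and optional per-point temperature ``t`` in °C.  Both
``ascii`` and (little-endian) ``binary`` DATA dialects are handled.  The
writer emits 8-byte floats for coordinates and temperature so binary
round-trips are bit-exact.
"""

from __future__ import annotations

import os
from typing import List, Optional

import numpy as np

from .cloud import PointCloud, parse_dataset_filename

__all__ = ["PCDFormatError", "read_pcd", "write_pcd"]


class PCDFormatError(ValueError):
    """Raised when a PCD file violates the format."""


_TYPE_MAP = {
    ("F", 4): np.float32,
    ("F", 8): np.float64,
    ("U", 1): np.uint8,
    ("U", 2): np.uint16,
    ("U", 4): np.uint32,
    ("I", 1): np.int8,
    ("I", 2): np.int16,
    ("I", 4): np.int32,
}


def _parse_header(lines: List[bytes]):
    header = {}
    consumed = 0
    for raw in lines:
        consumed += 1
        line = raw.decode("ascii", errors="replace").strip()
        if not line or line.startswith("#"):
            continue
        parts = line.split()
        key = parts[0].upper()
        header[key] = parts[1:]
        if key == "DATA":
            break
    else:
        raise PCDFormatError("header ended without a DATA line")
    for required in ("FIELDS", "SIZE", "TYPE", "COUNT", "WIDTH", "HEIGHT", "POINTS", "DATA"):
        if required not in header:
            raise PCDFormatError(f"missing header line: {required}")
    fields = [f.lower() for f in header["FIELDS"]]
    n_fields = len(fields)
    for key in ("SIZE", "TYPE", "COUNT"):
        if len(header[key]) != n_fields:
            raise PCDFormatError(
                f"header line {key} {' '.join(header[key])!r} does not match "
                f"{n_fields} FIELDS"
            )
    try:
        sizes = [int(s) for s in header["SIZE"]]
        counts = [int(c) for c in header["COUNT"]]
        width = int(header["WIDTH"][0])
        height = int(header["HEIGHT"][0])
        points = int(header["POINTS"][0])
    except (ValueError, IndexError) as exc:
        raise PCDFormatError(f"non-numeric header value: {exc}") from None
    if any(c != 1 for c in counts):
        raise PCDFormatError("COUNT values other than 1 are not supported")
    if width * height != points:
        raise PCDFormatError(
            f"WIDTH {width} x HEIGHT {height} does not equal POINTS {points}"
        )
    types = [t.upper() for t in header["TYPE"]]
    dtypes = []
    for name, typ, size in zip(fields, types, sizes):
        key = (typ, size)
        if key not in _TYPE_MAP:
            raise PCDFormatError(f"unsupported TYPE/SIZE {typ}{size} for field {name!r}")
        dtypes.append((name, _TYPE_MAP[key]))
    data_kind = header["DATA"][0].lower()
    if data_kind not in ("ascii", "binary"):
        raise PCDFormatError(f"unsupported DATA dialect {data_kind!r}")
    return fields, dtypes, width, height, points, data_kind, consumed


def _unpack_rgb(packed: np.ndarray, storage: np.dtype) -> np.ndarray:
    """Decode PCL's packed color scalar into (n, 3) uint8."""
    if np.issubdtype(storage, np.floating):
        bits = packed.astype(np.float32).view(np.uint32)
    else:
        bits = packed.astype(np.uint32)
    r = (bits >> 16) & 0xFF
    g = (bits >> 8) & 0xFF
    b = bits & 0xFF
    return np.stack([r, g, b], axis=1).astype(np.uint8)


def _pack_rgb(rgb: np.ndarray) -> np.ndarray:
    bits = (
        (rgb[:, 0].astype(np.uint32) << 16)
        | (rgb[:, 1].astype(np.uint32) << 8)
        | rgb[:, 2].astype(np.uint32)
    )
    return bits.view(np.float32)


def read_pcd(path: str | os.PathLike, parse_meta: bool = False) -> PointCloud:
    """Read a PCD file into a :class:`PointCloud`.

    Parameters
    ----------
    path:
        File to read.  Must declare at least fields ``x y z``.
    parse_meta:
        If true, additionally parse the file name with the dataset's
        ``GENDER_WEIGHT_PERSON_FRAME.pcd`` convention into ``cloud.meta``.
    """
    with open(path, "rb") as fh:
        blob = fh.read()
    lines = blob.split(b"\n")
    fields, dtypes, width, height, points, data_kind, consumed = _parse_header(lines)
    for coord in ("x", "y", "z"):
        if coord not in fields:
            raise PCDFormatError(f"FIELDS must include {coord!r}")

    if data_kind == "ascii":
        rows = []
        body = lines[consumed:]
        for i, raw in enumerate(body):
            text = raw.decode("ascii", errors="replace").strip()
            if not text:
                continue
            tokens = text.split()
            if len(tokens) != len(fields):
                raise PCDFormatError(
                    f"data row {i} has {len(tokens)} values, expected {len(fields)}: {text!r}"
                )
            rows.append(tokens)
        if len(rows) != points:
            raise PCDFormatError(f"expected {points} data rows, found {len(rows)}")
        if points:
            table = np.array(rows)
        else:
            table = np.empty((0, len(fields)))
        columns = {}
        for j, (name, dt) in enumerate(dtypes):
            col = table[:, j] if points else np.empty(0)
            if np.issubdtype(dt, np.floating):
                columns[name] = col.astype(np.float64) if points else np.empty(0)
            else:
                # integer fields may still be printed as floats in the wild
                columns[name] = col.astype(np.float64).astype(dt) if points else np.empty(0, dt)
    else:
        record = np.dtype([(n, d) for n, d in dtypes])
        offset = len(b"\n".join(lines[:consumed])) + 1
        body = blob[offset : offset + record.itemsize * points]
        if len(body) < record.itemsize * points:
            raise PCDFormatError("binary body truncated")
        arr = np.frombuffer(body, dtype=record, count=points)
        columns = {name: arr[name] for name, _ in dtypes}

    xyz = np.stack(
        [np.asarray(columns[c], dtype=np.float64) for c in ("x", "y", "z")], axis=1
    )
    rgb: Optional[np.ndarray] = None
    if "rgb" in fields:
        storage = dict(dtypes)["rgb"]
        raw_col = columns["rgb"]
        if data_kind == "ascii" and np.issubdtype(storage, np.floating):
            raw_col = np.asarray(raw_col, dtype=np.float32)
        rgb = _unpack_rgb(np.asarray(raw_col), np.dtype(storage))
    elif all(c in fields for c in ("r", "g", "b")):
        rgb = np.stack(
            [np.asarray(columns[c]).astype(np.uint8) for c in ("r", "g", "b")], axis=1
        )
    temperature = None
    if "t" in fields:
        temperature = np.asarray(columns["t"], dtype=np.float64)

    organized = (height, width) if height > 1 else None
    meta = None
    if parse_meta:
        meta = parse_dataset_filename(os.path.basename(os.fspath(path)))
    return PointCloud(xyz=xyz, rgb=rgb, temperature=temperature, organized=organized, meta=meta)


def write_pcd(cloud: PointCloud, path: str | os.PathLike, dialect: str = "binary") -> None:
    """Write a :class:`PointCloud` as a PCD v0.7 file.

    Coordinates and temperature are stored as 8-byte floats, color as one
    packed 4-byte scalar, so a binary write/read round-trip is bit-exact.
    """
    if dialect not in ("ascii", "binary"):
        raise ValueError(f"dialect must be 'ascii' or 'binary', got {dialect!r}")
    fields = ["x", "y", "z"]
    sizes = [8, 8, 8]
    types = ["F", "F", "F"]
    columns = [cloud.xyz[:, 0], cloud.xyz[:, 1], cloud.xyz[:, 2]]
    if cloud.rgb is not None:
        fields.append("rgb")
        sizes.append(4)
        types.append("F")
        columns.append(_pack_rgb(cloud.rgb))
    if cloud.temperature is not None:
        fields.append("t")
        sizes.append(8)
        types.append("F")
        columns.append(cloud.temperature)

    if cloud.organized is not None:
        height, width = cloud.organized
    else:
        height, width = 1, len(cloud)
    n = len(cloud)
    header = (
        "# .PCD v0.7 - Point Cloud Data file format\n"
        "VERSION 0.7\n"
        f"FIELDS {' '.join(fields)}\n"
        f"SIZE {' '.join(map(str, sizes))}\n"
        f"TYPE {' '.join(types)}\n"
        f"COUNT {' '.join(['1'] * len(fields))}\n"
        f"WIDTH {width}\n"
        f"HEIGHT {height}\n"
        "VIEWPOINT 0 0 0 1 0 0 0\n"
        f"POINTS {n}\n"
        f"DATA {dialect}\n"
    )
    with open(path, "wb") as fh:
        fh.write(header.encode("ascii"))
        if dialect == "ascii":
            out = []
            for i in range(n):
                tokens = []
                for col, typ in zip(columns, types):
                    v = col[i]
                    if typ == "F":
                        tokens.append(f"{float(v):.10g}")
                    else:
                        tokens.append(str(int(v)))
                out.append(" ".join(tokens))
            if out:
                fh.write(("\n".join(out) + "\n").encode("ascii"))
        else:
            record = np.dtype(
                [(f, np.float64 if s == 8 else np.float32) for f, s in zip(fields, sizes)]
            )
            arr = np.empty(n, dtype=record)
            for f, col in zip(fields, columns):
                arr[f] = col
            fh.write(arr.tobytes())
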