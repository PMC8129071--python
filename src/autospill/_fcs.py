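"""Minimal FCS 3.0/3.1 list-mode reader and fixture writer.

Covers the subset of the standard produced by common acquisition software and
by :func:`autospill.synthetic.write_fixture_fcs`: list mode (``$MODE L``),
float (``$DATATYPE F``/``D``) or integer (``$DATATYPE I`` with uniform
``$PnB``) storage, little- or big-endian ``$BYTEORD``, one dataset per file.
Detector short names come from ``$PnN``, with ``$PnS`` as fallback when
``$PnN`` is empty.
"""

from __future__ import annotations

import struct
from pathlib import Path

import numpy as np

__all__ = ["read_fcs", "write_fcs", "FcsFormatError"]

_HEADER_LEN = 58


class FcsFormatError(ValueError):
    """Raised when a file does not parse as supported FCS 3.0/3.1."""


def _parse_text_segment(raw: bytes) -> dict[str, str]:
    if not raw:
        raise FcsFormatError("empty TEXT segment")
    delim = raw[0:1]
    body = raw[1:]
    if body.endswith(delim):
        body = body[:-1]
    # Escaped delimiters (doubled) are not produced by the writers we target;
    # split plainly and tolerate empty values.
    parts = body.split(delim)
    if len(parts) % 2 == 1:
        parts = parts[:-1]
    keywords: dict[str, str] = {}
    for key, value in zip(parts[0::2], parts[1::2]):
        keywords[key.decode("utf-8", "replace").strip().upper()] = value.decode(
            "utf-8", "replace"
        ).strip()
    return keywords


def read_fcs(path: str | Path) -> tuple[np.ndarray, list[str], dict[str, str]]:
    """Read one FCS dataset.

    Returns
    -------
    values : (n_events, n_detectors) float64 array
    names : detector short names ($PnN, falling back to $PnS)
    keywords : the full TEXT-segment keyword dictionary
    """
    path = Path(path)
    blob = path.read_bytes()
    if len(blob) < _HEADER_LEN:
        raise FcsFormatError(f"{path}: file shorter than an FCS header")
    version = blob[:6].decode("ascii", "replace")
    if version not in ("FCS3.0", "FCS3.1"):
        raise FcsFormatError(f"{path}: unsupported FCS version {version!r}")

    def _offset(field: bytes) -> int:
        text = field.decode("ascii", "replace").strip()
        return int(text) if text else 0

    text_start = _offset(blob[10:18])
    text_end = _offset(blob[18:26])
    data_start = _offset(blob[26:34])
    data_end = _offset(blob[34:42])

    keywords = _parse_text_segment(blob[text_start : text_end + 1])

    if data_start == 0 or data_end == 0:
        data_start = int(keywords.get("$BEGINDATA", 0))
        data_end = int(keywords.get("$ENDDATA", 0))
    if data_start <= 0 or data_end <= data_start:
        raise FcsFormatError(f"{path}: missing DATA segment offsets")

    mode = keywords.get("$MODE", "L").upper()
    if mode != "L":
        raise FcsFormatError(f"{path}: only list mode supported, got $MODE {mode}")

    n_par = int(keywords["$PAR"])
    n_tot = int(keywords["$TOT"])
    datatype = keywords.get("$DATATYPE", "F").upper()
    byteord = keywords.get("$BYTEORD", "1,2,3,4")
    little = byteord.startswith("1")
    order = "<" if little else ">"

    if datatype == "F":
        dtype = np.dtype(order + "f4")
    elif datatype == "D":
        dtype = np.dtype(order + "f8")
    elif datatype == "I":
        bits = {int(keywords.get(f"$P{i}B", 32)) for i in range(1, n_par + 1)}
        if len(bits) != 1 or bits.pop() not in (16, 32):
            raise FcsFormatError(f"{path}: integer data requires uniform $PnB of 16 or 32")
        width = int(keywords["$P1B"]) // 8
        dtype = np.dtype(f"{order}u{width}")
    else:
        raise FcsFormatError(f"{path}: unsupported $DATATYPE {datatype!r}")

    raw = blob[data_start : data_end + 1]
    needed = n_par * n_tot * dtype.itemsize
    if len(raw) < needed:
        raise FcsFormatError(f"{path}: DATA segment truncated")
    values = np.frombuffer(raw[:needed], dtype=dtype).reshape(n_tot, n_par)
    values = np.ascontiguousarray(values, dtype=np.float64)

    names = []
    for i in range(1, n_par + 1):
        name = keywords.get(f"$P{i}N", "") or keywords.get(f"$P{i}S", "")
        if not name:
            raise FcsFormatError(f"{path}: parameter {i} has neither $PnN nor $PnS")
        names.append(name)
    return values, names, keywords


def write_fcs(path: str | Path, values: np.ndarray, names: list[str]) -> None:
    """Write a minimal valid FCS 3.1 file (float32 list mode, little-endian)."""
    values = np.asarray(values, dtype=np.float32)
    if values.ndim != 2 or values.shape[0] < 1:
        raise ValueError("values must be a non-empty 2-d events x detectors array")
    n_tot, n_par = values.shape
    if len(names) != n_par:
        raise ValueError("one detector name required per column")

    keywords: list[tuple[str, str]] = [
        ("$BYTEORD", "1,2,3,4"),
        ("$DATATYPE", "F"),
        ("$MODE", "L"),
        ("$NEXTDATA", "0"),
        ("$PAR", str(n_par)),
        ("$TOT", str(n_tot)),
    ]
    for i, name in enumerate(names, start=1):
        top = float(np.max(np.abs(values[:, i - 1]))) if n_tot else 0.0
        keywords += [
            (f"$P{i}N", name),
            (f"$P{i}B", "32"),
            (f"$P{i}E", "0,0"),
            (f"$P{i}R", str(int(max(top, 1.0)) + 1)),
        ]

    data_bytes = values.astype("<f4").tobytes()

    # The TEXT segment must state the DATA offsets, which depend on its own
    # length; iterate until self-consistent.
    begin_data = 0
    end_data = 0
    for _ in range(4):
        text = "/" + "".join(f"{k}/{v}/" for k, v in keywords + [
            ("$BEGINDATA", str(begin_data)),
            ("$ENDDATA", str(end_data)),
        ])
        text_bytes = text.encode("ascii")
        text_start = _HEADER_LEN
        text_end = text_start + len(text_bytes) - 1
        new_begin = text_end + 1
        new_end = new_begin + len(data_bytes) - 1
        if (new_begin, new_end) == (begin_data, end_data):
            break
        begin_data, end_data = new_begin, new_end

    header = (
        b"FCS3.1    "
        + f"{text_start:>8d}".encode()
        + f"{text_end:>8d}".encode()
        + (f"{begin_data:>8d}".encode() if begin_data <= 99_999_999 else b"       0")
        + (f"{end_data:>8d}".encode() if end_data <= 99_999_999 else b"       0")
        + b"       0"
        + b"       0"
    )
    assert len(header) == _HEADER_LEN
    Path(path).write_bytes(header + text_bytes + data_bytes)
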