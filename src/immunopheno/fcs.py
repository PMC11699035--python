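"""Minimal FCS 3.0/3.1 reader and writer.

Covers the subset of the standard this package produces and consumes: list
mode ($MODE L), float ($DATATYPE F/D) and integer ($DATATYPE I, 8/16/32-bit)
data, little- or big-endian $BYTEORD, channel names from $PnN (with $PnS as
an optional override).  Analysis segments and multi-dataset files are out of
scope.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np

__all__ = ["read_fcs", "write_fcs"]

_DELIM = "/"


def _parse_text_segment(raw: bytes) -> dict[str, str]:
    text = raw.decode("utf-8", errors="replace")
    delim = text[0]
    parts = text[1:].split(delim)
    if parts and parts[-1] == "":
        parts = parts[:-1]
    kv = {}
    for i in range(0, len(parts) - 1, 2):
        kv[parts[i].strip().upper()] = parts[i + 1]
    return kv


def read_fcs(path):
    """Read one FCS dataset; returns ``(channel_names, values)``.

    Raises ``OSError`` with a byte offset on truncated files and
    ``ValueError`` on duplicate channel names or unsupported layouts.
    """
    path = Path(path)
    blob = path.read_bytes()
    if len(blob) == 0:
        raise OSError(f"{path}: empty file")
    if len(blob) < 58:
        raise OSError(f"{path}: truncated header at byte {len(blob)}")
    version = blob[:6].decode("ascii", errors="replace")
    if not version.startswith("FCS3"):
        raise ValueError(f"{path}: unsupported FCS version {version!r}")

    def _offset(lo, hi):
        s = blob[lo:hi].decode("ascii").strip()
        return int(s) if s else 0

    text_beg, text_end = _offset(10, 18), _offset(18, 26)
    data_beg, data_end = _offset(26, 34), _offset(34, 42)
    if text_end >= len(blob):
        raise OSError(f"{path}: truncated TEXT segment at byte {len(blob)}")
    kv = _parse_text_segment(blob[text_beg : text_end + 1])

    if data_beg == 0:
        data_beg = int(kv["$BEGINDATA"])
        data_end = int(kv["$ENDDATA"])
    if data_end >= len(blob):
        raise OSError(f"{path}: truncated DATA segment at byte {len(blob)}")

    mode = kv.get("$MODE", "L")
    if mode != "L":
        raise ValueError(f"{path}: only list mode is supported, got $MODE {mode}")
    n_par = int(kv["$PAR"])
    n_tot = int(kv["$TOT"])
    dtype_code = kv["$DATATYPE"]
    byteord = kv.get("$BYTEORD", "1,2,3,4")
    little = byteord.split(",")[0] == "1"
    endian = "<" if little else ">"

    names = []
    for i in range(1, n_par + 1):
        name = kv.get(f"$P{i}S") or kv.get(f"$P{i}N") or f"P{i}"
        names.append(name)
    if len(set(names)) != len(names):
        raise ValueError(f"{path}: duplicate channel names {names}")

    if dtype_code == "F":
        dt = np.dtype(f"{endian}f4")
        itemsizes = [4] * n_par
    elif dtype_code == "D":
        dt = np.dtype(f"{endian}f8")
        itemsizes = [8] * n_par
    elif dtype_code == "I":
        bits = [int(kv[f"$P{i}B"]) for i in range(1, n_par + 1)]
        if len(set(bits)) != 1 or bits[0] not in (8, 16, 32):
            raise ValueError(f"{path}: unsupported integer widths {bits}")
        dt = np.dtype(f"{endian}u{bits[0] // 8}")
        itemsizes = [bits[0] // 8] * n_par
    else:
        raise ValueError(f"{path}: unsupported $DATATYPE {dtype_code}")

    expected = n_tot * sum(itemsizes)
    raw = blob[data_beg : data_beg + expected]
    if len(raw) < expected:
        raise OSError(
            f"{path}: truncated DATA segment at byte {data_beg + len(raw)}"
        )
    values = np.frombuffer(raw, dtype=dt).reshape(n_tot, n_par).astype(float)
    return names, values


def write_fcs(path, channel_names, values) -> None:
    """Write an FCS 3.1 file (list mode, 32-bit float, little-endian)."""
    values = np.asarray(values, dtype=np.float32)
    if values.ndim != 2 or values.shape[1] != len(channel_names):
        raise ValueError("values must be events x channels matching channel_names")
    n_tot, n_par = values.shape
    if len(set(channel_names)) != n_par:
        raise ValueError("duplicate channel names")

    data_bytes = values.astype("<f4").tobytes()

    def build_text(data_beg, data_end):
        kv = [
            ("$BEGINANALYSIS", "0"),
            ("$ENDANALYSIS", "0"),
            ("$BEGINSTEXT", "0"),
            ("$ENDSTEXT", "0"),
            ("$BEGINDATA", str(data_beg)),
            ("$ENDDATA", str(data_end)),
            ("$BYTEORD", "1,2,3,4"),
            ("$DATATYPE", "F"),
            ("$MODE", "L"),
            ("$NEXTDATA", "0"),
            ("$PAR", str(n_par)),
            ("$TOT", str(n_tot)),
        ]
        for i, name in enumerate(channel_names, start=1):
            kv += [
                (f"$P{i}N", str(name)),
                (f"$P{i}B", "32"),
                (f"$P{i}E", "0,0"),
                (f"$P{i}R", str(int(max(1.0, np.ceil(values[:, i - 1].max(initial=1.0))))),),
            ]
        body = _DELIM + _DELIM.join(f"{k}{_DELIM}{v}" for k, v in kv) + _DELIM
        return body.encode("ascii")

    # iterate: TEXT length depends on the DATA offsets it embeds
    header_len = 58
    text = build_text(0, 0)
    for _ in range(4):
        text_beg = header_len
        text_end = text_beg + len(text) - 1
        data_beg = text_end + 1
        data_end = data_beg + len(data_bytes) - 1
        new_text = build_text(data_beg, data_end)
        if len(new_text) == len(text):
            text = new_text
            break
        text = new_text
    else:
        raise RuntimeError("FCS TEXT segment failed to converge")

    def fmt(x):
        s = str(x)
        if len(s) > 8:
            s = "0"  # too large for header; TEXT keywords carry the offsets
        return s.rjust(8).encode("ascii")

    header = b"FCS3.1    " + fmt(text_beg) + fmt(text_end) + fmt(data_beg) + fmt(data_end) + fmt(0) + fmt(0)
    assert len(header) == 58
    Path(path).write_bytes(header + text + data_bytes)
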