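"""Minimal FCS 3.0 read/write support.

One dataset per file, list mode, 32-bit little-endian floats, linear
amplification — the simplest dialect accepted by standard cytometry
parsers.  Channel short names ($PnN) carry the instrument-style labels
(FSC-A, FL1-A, ...); free metadata is stored as non-standard ``MR_<key>``
keywords.
"""

from __future__ import annotations

import struct
from pathlib import Path

import numpy as np

_DELIM = "/"

# instrument channel label <-> internal column name
CHANNEL_TO_COLUMN = {
    "FSC-A": "fsc_a",
    "FL1-A": "fl1_a",
    "mCherry-A": "mcherry_a",
    "Time": "t_acquire",
}
COLUMN_TO_CHANNEL = {v: k for k, v in CHANNEL_TO_COLUMN.items()}


def _meta_to_keywords(metadata: dict) -> dict[str, str]:
    out = {}
    for k, v in metadata.items():
        sv = "" if v is None else str(v)
        if _DELIM in sv or _DELIM in k:
            raise ValueError(f"metadata value for {k!r} may not contain '/'")
        out[f"MR_{k}"] = sv
    return out


def _keywords_to_meta(keywords: dict[str, str]) -> dict:
    meta: dict = {}
    for k, v in keywords.items():
        if not k.startswith("MR_"):
            continue
        key = k[3:]
        if v == "":
            meta[key] = None
            continue
        try:
            fv = float(v)
            meta[key] = int(fv) if fv.is_integer() and "." not in v else fv
        except ValueError:
            meta[key] = v
    return meta


def write_fcs(path, columns: dict[str, np.ndarray], metadata: dict) -> None:
    """Write named event columns as a single FCS 3.0 dataset."""
    names = list(columns)
    arrays = [np.asarray(columns[c], dtype="<f4") for c in names]
    n_events = len(arrays[0])
    if any(len(a) != n_events for a in arrays):
        raise ValueError("all columns must have the same length")
    data = np.column_stack(arrays).astype("<f4").tobytes()

    kw: dict[str, str] = {
        "$BEGINANALYSIS": "0",
        "$ENDANALYSIS": "0",
        "$BEGINSTEXT": "0",
        "$ENDSTEXT": "0",
        "$BYTEORD": "1,2,3,4",
        "$DATATYPE": "F",
        "$MODE": "L",
        "$NEXTDATA": "0",
        "$PAR": str(len(names)),
        "$TOT": str(n_events),
    }
    for i, (name, arr) in enumerate(zip(names, arrays), start=1):
        kw[f"$P{i}N"] = COLUMN_TO_CHANNEL.get(name, name)
        kw[f"$P{i}B"] = "32"
        kw[f"$P{i}E"] = "0,0"
        rmax = float(arr.max()) if n_events else 1.0
        kw[f"$P{i}R"] = str(int(max(rmax, 1.0)) + 1)
    kw.update(_meta_to_keywords(metadata))

    # fixed-width offsets so the text length is stable across the two passes
    kw["$BEGINDATA"] = "%012d" % 0
    kw["$ENDDATA"] = "%012d" % 0

    def render(kws: dict[str, str]) -> bytes:
        parts = [_DELIM]
        for k, v in kws.items():
            parts.append(f"{k}{_DELIM}{v if v != '' else ' '}{_DELIM}")
        return "".join(parts).encode("ascii")

    header_len = 58
    text = render(kw)
    text_begin = header_len
    text_end = text_begin + len(text) - 1
    data_begin = text_end + 1
    data_end = data_begin + len(data) - 1
    kw["$BEGINDATA"] = "%012d" % data_begin
    kw["$ENDDATA"] = "%012d" % data_end
    text = render(kw)

    header = (
        b"FCS3.0    "
        + b"%8d" % text_begin
        + b"%8d" % text_end
        + b"%8d" % data_begin
        + b"%8d" % data_end
        + b"%8d" % 0
        + b"%8d" % 0
    )
    assert len(header) == header_len
    Path(path).write_bytes(header + text + data)


def read_fcs(path) -> tuple[dict[str, np.ndarray], dict]:
    """Read a single-dataset FCS 3.0/3.1 file written in float list mode."""
    raw = Path(path).read_bytes()
    if not raw[:6] in (b"FCS3.0", b"FCS3.1"):
        raise ValueError(f"{path}: not an FCS 3.x file")
    text_begin = int(raw[10:18])
    text_end = int(raw[18:26])
    text = raw[text_begin : text_end + 1].decode("ascii", errors="replace")
    delim = text[0]
    tokens = text[1:].split(delim)
    if tokens and tokens[-1] == "":
        tokens = tokens[:-1]
    kw = {
        tokens[i].strip(): tokens[i + 1]
        for i in range(0, len(tokens) - 1, 2)
    }
    n_par = int(kw["$PAR"])
    n_tot = int(kw["$TOT"])
    dtype = kw.get("$DATATYPE", "F").strip().upper()
    if dtype != "F":
        raise ValueError(f"unsupported $DATATYPE {dtype!r} (only F)")
    byteord = kw.get("$BYTEORD", "1,2,3,4").strip()
    endian = "<" if byteord.startswith("1") else ">"
    data_begin = int(kw.get("$BEGINDATA") or raw[26:34])
    data_end = int(kw.get("$ENDDATA") or raw[34:42])
    buf = raw[data_begin : data_end + 1]
    arr = np.frombuffer(buf, dtype=f"{endian}f4", count=n_par * n_tot)
    arr = arr.reshape(n_tot, n_par)
    columns = {}
    for i in range(1, n_par + 1):
        chan = kw[f"$P{i}N"].strip()
        columns[CHANNEL_TO_COLUMN.get(chan, chan)] = arr[:, i - 1].astype(
            float
        )
    return columns, _keywords_to_meta(kw)
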