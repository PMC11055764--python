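"""Minimal FCS 3.0/3.1 list-mode adapter.

CSV is the pipeline's canonical event format; this adapter exists so
instrument exports can be ingested without conversion.  It supports the
common case only: list mode ($MODE L), float32/float64/uint data of a
single fixed width per parameter, and little- or big-endian byte order.
A channel map (e.g. ``{"fsc": "FSC-HLin", ...}``) ties the instrument's
$PnN names to the pipeline's fsc/ssc/rfp/gfp fields, since native
channel names vary by cytometer.
"""

from __future__ import annotations

from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

from .errors import FormatError
from .flow_io import EVENT_COLUMNS


def _parse_text_segment(raw: bytes) -> dict[str, str]:
    if not raw:
        raise FormatError("empty TEXT segment")
    delim = raw[0:1].decode("latin-1")
    parts = raw.decode("latin-1").split(delim)
    # parts[0] is empty (segment starts with the delimiter)
    fields = [p for p in parts[1:]]
    if fields and fields[-1] == "":
        fields = fields[:-1]
    if len(fields) % 2:
        fields = fields[:-1]
    return {
        fields[i].strip().upper(): fields[i + 1]
        for i in range(0, len(fields), 2)
    }


def read_fcs(path: str | Path, channel_map: Mapping[str, str]) -> pd.DataFrame:
    """Read events from an FCS file into the canonical event DataFrame.

    ``channel_map`` maps each of fsc/ssc/rfp/gfp to a $PnN channel name.
    """
    missing_keys = [c for c in EVENT_COLUMNS if c not in channel_map]
    if missing_keys:
        raise FormatError(f"channel map missing entries for {missing_keys}")

    data = Path(path).read_bytes()
    if len(data) < 58:
        raise FormatError(f"{path}: too short to be an FCS file")
    version = data[:6].decode("latin-1", "replace")
    if not version.startswith("FCS3"):
        raise FormatError(f"{path}: unsupported FCS version {version!r}")
    try:
        text_start = int(data[10:18])
        text_end = int(data[18:26])
        data_start = int(data[26:34])
        data_end = int(data[34:42])
    except ValueError as exc:
        raise FormatError(f"{path}: malformed FCS header") from exc

    text = _parse_text_segment(data[text_start : text_end + 1])
    if data_start == 0:
        data_start = int(text.get("$BEGINDATA", 0))
        data_end = int(text.get("$ENDDATA", 0))

    if text.get("$MODE", "L").upper() != "L":
        raise FormatError("only list-mode ($MODE L) FCS data is supported")
    n_par = int(text["$PAR"])
    n_tot = int(text["$TOT"])
    datatype = text.get("$DATATYPE", "F").upper()
    byteord = text.get("$BYTEORD", "1,2,3,4")
    endian = "<" if byteord.startswith("1") else ">"

    widths = {int(text.get(f"$P{i}B", 32)) for i in range(1, n_par + 1)}
    if len(widths) != 1:
        raise FormatError("mixed parameter bit widths are not supported")
    bits = widths.pop()
    dtype = {
        ("F", 32): "f4",
        ("D", 64): "f8",
        ("I", 16): "u2",
        ("I", 32): "u4",
    }.get((datatype, bits))
    if dtype is None:
        raise FormatError(f"unsupported $DATATYPE/$PnB combination {datatype}/{bits}")

    raw = data[data_start : data_end + 1]
    values = np.frombuffer(raw, dtype=endian + dtype, count=n_par * n_tot)
    matrix = values.reshape(n_tot, n_par).astype(float)

    names = [text.get(f"$P{i}N", f"P{i}") for i in range(1, n_par + 1)]
    frame = pd.DataFrame(matrix, columns=names)

    unmapped = [
        (col, channel_map[col])
        for col in EVENT_COLUMNS
        if channel_map[col] not in frame.columns
    ]
    if unmapped:
        raise FormatError(
            f"{path}: channels not present in file: {unmapped}; available {names}"
        )
    return pd.DataFrame(
        {col: frame[channel_map[col]].to_numpy() for col in EVENT_COLUMNS}
    )


def write_fcs(
    path: str | Path, events: pd.DataFrame, channel_map: Mapping[str, str]
) -> None:
    """Write canonical events as a little-endian float32 FCS 3.0 file.

    Intended for round-trip tests and for exporting simulated wells in
    an instrument-like container.
    """
    names = [channel_map[c] for c in EVENT_COLUMNS]
    matrix = events[EVENT_COLUMNS].to_numpy(dtype="<f4")
    n_tot, n_par = matrix.shape

    pairs = {
        "$MODE": "L",
        "$DATATYPE": "F",
        "$BYTEORD": "1,2,3,4",
        "$PAR": str(n_par),
        "$TOT": str(n_tot),
        "$NEXTDATA": "0",
    }
    for i, name in enumerate(names, start=1):
        pairs[f"$P{i}N"] = name
        pairs[f"$P{i}B"] = "32"
        pairs[f"$P{i}E"] = "0,0"
        pairs[f"$P{i}R"] = "262144"

    delim = "/"
    text = delim + delim.join(f"{k}{delim}{v}" for k, v in pairs.items()) + delim
    text_bytes = text.encode("latin-1")

    header_len = 58
    text_start = header_len
    text_end = text_start + len(text_bytes) - 1
    data_start = text_end + 1
    data_end = data_start + matrix.nbytes - 1
    if data_end > 99_999_999:
        raise FormatError("data segment too large for the fixed-width header")

    header = (
        b"FCS3.0    "
        + f"{text_start:8d}{text_end:8d}{data_start:8d}{data_end:8d}".encode()
        + f"{0:8d}{0:8d}".encode()
    )
    assert len(header) == header_len
    Path(path).write_bytes(header + text_bytes + matrix.tobytes())
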