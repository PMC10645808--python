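"""Minimal FCS 3.1 reader/writer for event tables.

Writes list-mode float32 data (``$DATATYPE/F``, ``$MODE/L``, little-endian
``$BYTEORD/1,2,3,4``) with the metal channel id in ``$PnN`` and the marker
name in ``$PnS``, which round-trips intensities to float precision.
Ground-truth labels are never emitted into FCS channels; callers write them
to a sidecar CSV (:meth:`ctcpheno.events.EventTable.to_csv`).
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .events import EventTable
from .panel import PanelDefinition

_DELIM = "/"


def _escape(v: str) -> str:
    return str(v).replace(_DELIM, _DELIM * 2)


def write_fcs(events: EventTable, path: str | Path, panel: PanelDefinition | None = None) -> None:
    """Write an event table as an FCS 3.1 file.

    Channel short names ($PnN) come from the panel's metal channel ids when
    a panel is supplied, otherwise the column names are used for both $PnN
    and $PnS.
    """
    if len(events) == 0:
        raise ValueError("refusing to write an empty event table")
    df = events.data
    markers = list(df.columns)

    def channel_id(marker: str) -> str:
        if panel is not None:
            try:
                return panel.channel_of(marker)
            except KeyError:
                pass
        return marker

    n_par = len(markers)
    n_tot = len(df)
    data = np.ascontiguousarray(df.to_numpy(dtype=np.float32))
    data_bytes = data.tobytes()

    keywords: dict[str, str] = {
        "$BEGINANALYSIS": "0",
        "$ENDANALYSIS": "0",
        "$BEGINSTEXT": "0",
        "$ENDSTEXT": "0",
        "$BEGINDATA": "0" * 10,  # fixed-width placeholders, patched below
        "$ENDDATA": "0" * 10,
        "$BYTEORD": "1,2,3,4",
        "$DATATYPE": "F",
        "$MODE": "L",
        "$NEXTDATA": "0",
        "$PAR": str(n_par),
        "$TOT": str(n_tot),
        "$FIL": Path(path).name,
        "$CYT": "synthetic",
        "$SRC": events.sample_id or "unknown",
    }
    for i, m in enumerate(markers, start=1):
        col_max = float(np.nanmax(df[m].to_numpy())) if n_tot else 0.0
        keywords[f"$P{i}B"] = "32"
        keywords[f"$P{i}E"] = "0,0"
        keywords[f"$P{i}N"] = channel_id(m)
        keywords[f"$P{i}S"] = m
        keywords[f"$P{i}R"] = str(int(np.ceil(col_max)) + 1)

    def render_text() -> bytes:
        parts = [_DELIM]
        for k, v in keywords.items():
            parts.append(f"{_escape(k)}{_DELIM}{_escape(v)}{_DELIM}")
        return "".join(parts).encode("ascii")

    header_len = 58  # "FCS3.1    " + 6 offset fields of 8 chars
    text = render_text()
    text_begin = header_len
    text_end = text_begin + len(text) - 1
    data_begin = text_end + 1
    data_end = data_begin + len(data_bytes) - 1
    keywords["$BEGINDATA"] = f"{data_begin:010d}"
    keywords["$ENDDATA"] = f"{data_end:010d}"
    text = render_text()
    assert text_begin + len(text) - 1 == text_end  # fixed-width patch kept length

    def off(v: int) -> bytes:
        s = str(v) if v <= 99999999 else "0"
        return s.rjust(8).encode("ascii")

    header = b"FCS3.1    " + b"".join(
        off(v) for v in (text_begin, text_end, data_begin, data_end, 0, 0)
    )
    assert len(header) == header_len
    with open(path, "wb") as fh:
        fh.write(header)
        fh.write(text)
        fh.write(data_bytes)


def _parse_text(raw: bytes) -> dict[str, str]:
    delim = chr(raw[0])
    body = raw.decode("ascii", errors="replace")[1:]
    if body.endswith(delim):
        body = body[:-1]
    # split on single delimiters; doubled delimiters are escaped literals
    tokens = body.replace(delim * 2, "\x00").split(delim)
    tokens = [t.replace("\x00", delim) for t in tokens]
    if len(tokens) % 2:
        raise ValueError("malformed TEXT segment: odd token count")
    return {tokens[i]: tokens[i + 1] for i in range(0, len(tokens), 2)}


def read_fcs(path: str | Path, panel: PanelDefinition | None = None) -> EventTable:
    """Read an FCS 3.x list-mode file into an :class:`EventTable`.

    Columns are named by $PnS (stain/marker name) when present, else $PnN.
    When a panel is supplied, $PnN metal channel ids are mapped back to
    marker names; unknown channels are retained under their own name.
    """
    raw = Path(path).read_bytes()
    if not raw[:6] in (b"FCS3.0", b"FCS3.1"):
        raise ValueError("not an FCS 3.x file (bad header magic)")
    offs = [int(raw[10 + i * 8 : 18 + i * 8].decode("ascii").strip() or 0) for i in range(4)]
    text_begin, text_end, data_begin, data_end = offs
    kw = _parse_text(raw[text_begin : text_end + 1])
    for required in ("$PAR", "$TOT", "$DATATYPE", "$BYTEORD", "$MODE"):
        if required not in kw:
            raise ValueError(f"missing mandatory keyword {required}")
    if kw["$DATATYPE"] != "F" or kw["$MODE"] != "L":
        raise ValueError("only list-mode float32 FCS is supported")
    if data_begin == 0:
        data_begin, data_end = int(kw["$BEGINDATA"]), int(kw["$ENDDATA"])
    n_par, n_tot = int(kw["$PAR"]), int(kw["$TOT"])
    order = "<" if kw["$BYTEORD"].startswith("1") else ">"
    payload = raw[data_begin : data_end + 1]
    expect = n_par * n_tot * 4
    if len(payload) < expect:
        raise ValueError("data segment shorter than $PAR * $TOT events")
    arr = np.frombuffer(payload[:expect], dtype=f"{order}f4").reshape(n_tot, n_par)

    names = []
    channel_to_marker = {}
    if panel is not None:
        channel_to_marker = {e.channel: e.marker for e in panel.entries}
    for i in range(1, n_par + 1):
        pnn = kw.get(f"$P{i}N", f"P{i}")
        pns = kw.get(f"$P{i}S", "")
        names.append(channel_to_marker.get(pnn, pns or pnn))
    df = pd.DataFrame(np.asarray(arr, dtype=float), columns=names)
    return EventTable(df, sample_id=kw.get("$SRC", ""), patient_id=kw.get("$SRC", ""))
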