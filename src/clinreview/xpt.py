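"""Minimal SAS transport (XPT v5) writer for fixture generation.

The public data layer reads XPT via pandas; this writer exists so the
synthetic-study generator can emit transport-format fixtures that
round-trip through the reader. Every variable is written as a character
field (the data model is text-valued), which keeps the encoding exact:
no IBM-float conversion, and blank fields read back as missing.

Layout follows the SAS Technical Note TS-140 record structure: 80-byte
card images, LIBRARY/MEMBER/NAMESTR/OBS header records, 140-byte
namestr entries, fixed-length observation records padded to an 80-byte
boundary.
"""

from __future__ import annotations

import struct
from pathlib import Path

from .datamodel import DomainTable

# Fixed creation stamp: transport metadata is not data, and a constant
# stamp keeps fixture bytes deterministic.
_STAMP = b"01JAN24:00:00:00"


def _card(text: bytes) -> bytes:
    assert len(text) <= 80
    return text.ljust(80)


def _header_record(kind: bytes, middle: bytes = b"0" * 30) -> bytes:
    return _card(
        b"HEADER RECORD*******" + kind.ljust(8) + b"HEADER RECORD!!!!!!!" + middle + b"  "
    )


def _namestr(varnum: int, name: str, label: str, length: int, pos: int) -> bytes:
    return struct.pack(
        ">hhhh8s40s8shhh2s8shh4s52s",
        2,                       # ntype: character
        0,                       # name hash, unused
        length,                  # field length in bytes
        varnum,                  # variable number (1-based)
        name.encode("ascii")[:8].ljust(8),
        label.encode("ascii", "replace")[:40].ljust(40),
        b" " * 8,                # output format
        0, 0, 0,                 # format length / decimals / justify
        b"  ",
        b" " * 8,                # input format
        0, 0,
        struct.pack(">i", pos),  # field position in the record
        b" " * 52,
    )


def write_xpt(table: DomainTable, path: str | Path) -> Path:
    """Write *table* as an XPT v5 member named after its domain code."""
    path = Path(path)
    records = table.data.fillna("").astype(str)
    columns = list(records.columns)
    widths = {
        c: max(1, int(records[c].str.encode("ascii", "replace").str.len().max() or 1))
        for c in columns
    }
    # Keep the observation record wider than one 80-byte card: readers
    # then count records by exact division instead of a blank-padding
    # heuristic that can swallow records whose fields are mostly blank.
    deficit = 81 - sum(widths.values())
    if deficit > 0:
        widths[columns[-1]] += deficit
    member = table.domain_code.upper()[:8]

    out = bytearray()
    out += _header_record(b"LIBRARY")
    out += _card(b"SAS     SAS     SASLIB  6.06    bsd4.2" + b" " * 26 + _STAMP)
    out += _card(_STAMP)
    out += _header_record(b"MEMBER", b"0" * 16 + b"01600000000140  "[:14])
    out += _header_record(b"DSCRPTR")
    out += _card(
        b"SAS     " + member.encode().ljust(8) + b"SASDATA 6.06    bsd4.2"
        + b" " * 26 + _STAMP
    )
    out += _card(_STAMP + b" " * 16 + table.label(member).encode("ascii", "replace")[:40].ljust(40) + b" " * 8)
    out += _header_record(b"NAMESTR", b"0" * 6 + str(len(columns)).zfill(4).encode() + b"0" * 20)
    pos = 0
    for i, col in enumerate(columns, start=1):
        out += _namestr(i, col, table.label(col), widths[col], pos)
        pos += widths[col]
    if len(out) % 80:
        out += b" " * (80 - len(out) % 80)
    out += _header_record(b"OBS")
    for _, row in records.iterrows():
        for col in columns:
            out += row[col].encode("ascii", "replace").ljust(widths[col])
    if len(out) % 80:
        out += b" " * (80 - len(out) % 80)
    path.write_bytes(bytes(out))
    return path
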