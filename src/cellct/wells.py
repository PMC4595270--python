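"""Plate well identifiers.

A well ID is the join key between the expression assay and the index-sort
table, so parsing must be forgiving on input (case, zero padding) but
strictly canonical on output: row letter + zero-padded two-digit column,
e.g. ``A01``.
"""

from __future__ import annotations

import re
from dataclasses import dataclass

from .errors import InputError

_WELL_RE = re.compile(r"^\s*([A-Za-z])\s*0*(\d{1,2})\s*$")

#: rows/columns available per supported plate format
PLATE_FORMATS = {96: ("ABCDEFGH", 12), 384: ("ABCDEFGHIJKLMNOP", 24)}


@dataclass(frozen=True, order=True)
class WellID:
    """Canonical plate coordinate (row letter + 1-based column)."""

    row: str
    column: int

    @property
    def canonical_text(self) -> str:
        return f"{self.row}{self.column:02d}"

    def __str__(self) -> str:  # pragma: no cover - convenience
        return self.canonical_text


def normalize_well_id(raw: str, plate_format: int = 96) -> WellID:
    """Parse ``raw`` into a canonical :class:`WellID`.

    Case-insensitive and tolerant of zero padding ("a1", "A01" -> A01).
    Raises :class:`InputError` for malformed text or coordinates outside
    the requested plate format.
    """
    if plate_format not in PLATE_FORMATS:
        raise InputError(f"unsupported plate format: {plate_format}")
    if not raw or not raw.strip():
        raise InputError("empty well ID")
    m = _WELL_RE.match(raw)
    if m is None:
        raise InputError(f"malformed well ID: {raw!r}")
    row = m.group(1).upper()
    column = int(m.group(2))
    rows, max_col = PLATE_FORMATS[plate_format]
    if row not in rows:
        raise InputError(
            f"well row {row!r} outside {plate_format}-well plate (rows {rows[0]}-{rows[-1]})"
        )
    if not 1 <= column <= max_col:
        raise InputError(
            f"well column {column} outside {plate_format}-well plate (columns 1-{max_col})"
        )
    return WellID(row, column)


def is_well_id(raw: str, plate_format: int = 96) -> bool:
    """True if ``raw`` parses as a well ID in the given plate format."""
    try:
        normalize_well_id(raw, plate_format)
        return True
    except InputError:
        return False


def canonical_label(raw: str, plate_format: int = 96) -> str:
    """Canonicalise ``raw`` if it is a well ID, else return it verbatim.

    Generic Ct matrices may label cells with arbitrary text; such labels
    are kept as opaque identifiers and simply cannot be joined against
    index-sort wells later.
    """
    try:
        return normalize_well_id(raw, plate_format).canonical_text
    except InputError:
        return raw.strip()
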