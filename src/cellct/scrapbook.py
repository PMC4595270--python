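"""Annotated figure collection ("scrapbook") carried inside a session."""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

from .errors import InputError


@dataclass
class ScrapbookEntry:
    seq: int
    figure: str  # file name of the captured figure (relative to the scrapbook)
    annotation: str
    timestamp: str

    def to_dict(self) -> dict:
        return {
            "seq": self.seq,
            "figure": self.figure,
            "annotation": self.annotation,
            "timestamp": self.timestamp,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "ScrapbookEntry":
        return cls(d["seq"], d["figure"], d["annotation"], d["timestamp"])


@dataclass
class Scrapbook:
    """Unlimited, append-only list of annotated figures.

    ``assets`` maps figure file names to the on-disk files holding their
    bytes; entries without a live asset (e.g. after loading an archive
    into memory only) keep their payload in ``asset_bytes``.
    """

    entries: list[ScrapbookEntry] = field(default_factory=list)
    asset_bytes: dict[str, bytes] = field(default_factory=dict)

    def add(
        self, figure_path: str | Path, annotation: str = "", timestamp: Optional[str] = None
    ) -> ScrapbookEntry:
        path = Path(figure_path)
        if not path.exists():
            raise InputError(f"figure file not found: {path}")
        name = f"{len(self.entries) + 1:04d}_{path.name}"
        self.asset_bytes[name] = path.read_bytes()
        entry = ScrapbookEntry(
            seq=self.entries[-1].seq + 1 if self.entries else 1,
            figure=name,
            annotation=annotation,
            timestamp=timestamp or "",
        )
        self.entries.append(entry)
        return entry

    def __len__(self) -> int:
        return len(self.entries)

    def __eq__(self, other) -> bool:
        if not isinstance(other, Scrapbook):
            return NotImplemented
        return (
            [e.to_dict() for e in self.entries] == [e.to_dict() for e in other.entries]
            and self.asset_bytes == other.asset_bytes
        )
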