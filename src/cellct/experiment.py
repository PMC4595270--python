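"""Core in-memory data model.

An :class:`Experiment` is a cells x genes expression table that moves
through a small stage machine::

    raw_ct -> inverted -> z_transformed
    raw_ct -> inverted -> hk_normalised -> z_transformed
    raw_ct -> hk_normalised -> z_transformed

Not-detected entries are tracked in an explicit boolean mask so detection
information survives the inversion step (where missing values become 0
and would otherwise be indistinguishable from on-the-floor measurements).
Cell IDs are plate-qualified (``<plate_id>:<well-or-label>``) because
bare well IDs collide across plates.
"""

from __future__ import annotations

import copy
from dataclasses import dataclass, field
from typing import Any, Iterator, Optional

import numpy as np
import pandas as pd

from .errors import InputError, StageError

STAGES = ("raw_ct", "inverted", "hk_normalised", "z_transformed")

CELL_ID_SEP = ":"


def make_cell_id(plate_id: str, label: str) -> str:
    if CELL_ID_SEP in plate_id:
        raise InputError(f"plate ID may not contain {CELL_ID_SEP!r}: {plate_id!r}")
    return f"{plate_id}{CELL_ID_SEP}{label}"


def split_cell_id(cell_id: str) -> tuple[str, str]:
    plate, _, label = cell_id.partition(CELL_ID_SEP)
    return plate, label


@dataclass
class LogEntry:
    seq: int
    operation: str
    params: dict
    counts: dict

    def to_dict(self) -> dict:
        return {
            "seq": self.seq,
            "operation": self.operation,
            "params": self.params,
            "counts": self.counts,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "LogEntry":
        return cls(d["seq"], d["operation"], dict(d["params"]), dict(d["counts"]))


class AnalysisLog:
    """Append-only record of executed, state-changing steps."""

    def __init__(self, entries: Optional[list[LogEntry]] = None):
        self.entries: list[LogEntry] = list(entries or [])

    def append(self, operation: str, params: dict, counts: Optional[dict] = None) -> LogEntry:
        entry = LogEntry(
            seq=self.entries[-1].seq + 1 if self.entries else 1,
            operation=operation,
            params=params,
            counts=counts or {},
        )
        self.entries.append(entry)
        return entry

    def copy(self) -> "AnalysisLog":
        return AnalysisLog([copy.deepcopy(e) for e in self.entries])

    def __len__(self) -> int:
        return len(self.entries)

    def __iter__(self) -> Iterator[LogEntry]:
        return iter(self.entries)

    def __eq__(self, other: Any) -> bool:
        if not isinstance(other, AnalysisLog):
            return NotImplemented
        return [e.to_dict() for e in self.entries] == [e.to_dict() for e in other.entries]


@dataclass
class PlateData:
    """One chip/run: wells x genes Ct matrix with a detection mask."""

    plate_id: str
    wells: list[str]  # canonical well IDs or opaque cell labels
    genes: list[str]
    ct: np.ndarray  # wells x genes, float; NaN where not detected
    detected: np.ndarray  # wells x genes, bool
    lod: float

    def __post_init__(self) -> None:
        self.ct = np.asarray(self.ct, dtype=float)
        self.detected = np.asarray(self.detected, dtype=bool)
        n, g = len(self.wells), len(self.genes)
        if self.ct.shape != (n, g) or self.detected.shape != (n, g):
            raise InputError(
                f"plate {self.plate_id!r}: matrix shape {self.ct.shape} does not "
                f"match {n} wells x {g} genes"
            )
        if len(set(self.wells)) != n:
            dupes = sorted({w for w in self.wells if self.wells.count(w) > 1})
            raise InputError(f"plate {self.plate_id!r}: duplicate wells {dupes}")
        if len(set(self.genes)) != g:
            dupes = sorted({x for x in self.genes if self.genes.count(x) > 1})
            raise InputError(f"plate {self.plate_id!r}: duplicate genes {dupes}")
        if not np.isfinite(self.ct[self.detected]).all():
            raise InputError(f"plate {self.plate_id!r}: non-finite Ct flagged as detected")
        # supra-LOD Ct counts as not detected; clamp the mask accordingly
        over = self.detected & (self.ct > self.lod)
        if over.any():
            self.detected = self.detected & ~over
        self.ct = np.where(self.detected, self.ct, np.nan)

    @property
    def n_wells(self) -> int:
        return len(self.wells)


@dataclass
class Experiment:
    """Concatenated plates plus optional index-sort markers and grouping.

    ``matrix``/``detected`` are cells x genes DataFrames sharing index and
    columns; ``index_markers`` (cells x markers) may contain NaN for cells
    without an index-sort record.
    """

    matrix: pd.DataFrame
    detected: pd.DataFrame
    stage: str
    lod: float
    plate_order: list[str]
    index_markers: Optional[pd.DataFrame] = None
    grouping: Optional["Grouping"] = None  # noqa: F821 - see grouping module
    log: AnalysisLog = field(default_factory=AnalysisLog)

    def __post_init__(self) -> None:
        if self.stage not in STAGES:
            raise InputError(f"unknown stage: {self.stage!r}")
        if self.matrix.index.has_duplicates:
            dupes = self.matrix.index[self.matrix.index.duplicated()].tolist()
            raise InputError(f"duplicate cell IDs: {dupes}")
        if not self.matrix.index.equals(self.detected.index) or not self.matrix.columns.equals(
            self.detected.columns
        ):
            raise InputError("matrix and detected mask are not aligned")
        if self.index_markers is not None and not self.index_markers.index.equals(
            self.matrix.index
        ):
            raise InputError("index_markers not aligned to cells")

    # -- basic accessors ------------------------------------------------
    @property
    def cells(self) -> list[str]:
        return list(self.matrix.index)

    @property
    def genes(self) -> list[str]:
        return list(self.matrix.columns)

    @property
    def n_cells(self) -> int:
        return len(self.matrix.index)

    def plate_of(self, cell_id: str) -> str:
        return split_cell_id(cell_id)[0]

    @property
    def plates(self) -> list[str]:
        present = {self.plate_of(c) for c in self.cells}
        return [p for p in self.plate_order if p in present]

    def require_stage(self, operation: str, *allowed: str) -> None:
        if self.stage not in allowed:
            raise StageError(operation, allowed, self.stage)

    # -- functional updates --------------------------------------------
    def evolve(self, **changes: Any) -> "Experiment":
        """Shallow-copy with replacements; the log is always deep-copied."""
        kwargs = dict(
            matrix=self.matrix,
            detected=self.detected,
            stage=self.stage,
            lod=self.lod,
            plate_order=list(self.plate_order),
            index_markers=self.index_markers,
            grouping=self.grouping,
            log=self.log.copy(),
        )
        kwargs.update(changes)
        return Experiment(**kwargs)

    def subset_cells(self, keep: list[str]) -> "Experiment":
        """Restrict to ``keep`` (in current order); prunes markers and grouping."""
        keep_set = set(keep)
        order = [c for c in self.cells if c in keep_set]
        markers = self.index_markers.loc[order] if self.index_markers is not None else None
        grouping = self.grouping.restrict(order) if self.grouping is not None else None
        return self.evolve(
            matrix=self.matrix.loc[order],
            detected=self.detected.loc[order],
            index_markers=markers,
            grouping=grouping,
        )

    def equals(self, other: "Experiment") -> bool:
        """Exact equality of data, stage, grouping, and log."""
        if self.stage != other.stage or self.lod != other.lod:
            return False
        if self.plate_order != other.plate_order:
            return False
        if not _frames_identical(self.matrix, other.matrix):
            return False
        if not _frames_identical(self.detected, other.detected):
            return False
        if (self.index_markers is None) != (other.index_markers is None):
            return False
        if self.index_markers is not None and not _frames_identical(
            self.index_markers, other.index_markers
        ):
            return False
        if (self.grouping is None) != (other.grouping is None):
            return False
        if self.grouping is not None and self.grouping != other.grouping:
            return False
        return self.log == other.log


def _frames_identical(a: pd.DataFrame, b: pd.DataFrame) -> bool:
    if not a.index.equals(b.index) or not a.columns.equals(b.columns):
        return False
    av, bv = a.to_numpy(), b.to_numpy()
    if av.dtype.kind == "f":
        return bool(((av == bv) | (np.isnan(av) & np.isnan(bv))).all())
    return bool((av == bv).all())
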