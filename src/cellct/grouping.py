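"""Ordered, coloured cell groupings.

A grouping is an ordered partition of the current cell set: groups are
pairwise disjoint, their union covers every cell, and colours are unique
within the grouping. Groups can come from plates, cluster assignments,
1-D expression cut-offs, rectangular 2-D gates, or from merging and
reordering existing groups.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import TYPE_CHECKING, Mapping, Optional, Sequence

import numpy as np

from .errors import InputError

if TYPE_CHECKING:  # pragma: no cover
    from .experiment import Experiment

# Colour-blind-safe 12-colour palette (Paul Tol's "muted" scheme extended);
# beyond 12 groups the palette cycles with progressively lighter shades.
PALETTE = (
    "#332288",
    "#88CCEE",
    "#44AA99",
    "#117733",
    "#999933",
    "#DDCC77",
    "#CC6677",
    "#882255",
    "#AA4499",
    "#DD7788",
    "#6699CC",
    "#661100",
)


def _lighten(hex_color: str, amount: float) -> str:
    r, g, b = (int(hex_color[i : i + 2], 16) for i in (1, 3, 5))
    mix = lambda c: int(round(c + (255 - c) * amount))  # noqa: E731
    return f"#{mix(r):02X}{mix(g):02X}{mix(b):02X}"


def palette_color(i: int) -> str:
    """i-th default group colour (cycled with shade variation past 12)."""
    base = PALETTE[i % len(PALETTE)]
    cycle = i // len(PALETTE)
    if cycle == 0:
        return base
    return _lighten(base, min(0.85, 0.3 * cycle))


@dataclass
class Group:
    label: str
    color: str
    members: frozenset[str]

    def __post_init__(self) -> None:
        self.members = frozenset(self.members)

    def __eq__(self, other) -> bool:
        if not isinstance(other, Group):
            return NotImplemented
        return (
            self.label == other.label
            and self.color == other.color
            and self.members == other.members
        )


@dataclass
class Grouping:
    groups: list[Group]
    source: str = "plates"

    def __post_init__(self) -> None:
        labels = [g.label for g in self.groups]
        if len(set(labels)) != len(labels):
            raise InputError(f"duplicate group labels: {labels}")
        colors = [g.color for g in self.groups]
        if len(set(colors)) != len(colors):
            raise InputError("group colours must be unique within a grouping")
        seen: set[str] = set()
        for g in self.groups:
            overlap = seen & g.members
            if overlap:
                raise InputError(f"groups overlap on cells: {sorted(overlap)[:5]}")
            seen |= g.members

    # -- queries --------------------------------------------------------
    @property
    def labels(self) -> list[str]:
        return [g.label for g in self.groups]

    def all_members(self) -> frozenset[str]:
        out: set[str] = set()
        for g in self.groups:
            out |= g.members
        return frozenset(out)

    def group_of(self) -> dict[str, str]:
        return {c: g.label for g in self.groups for c in g.members}

    def color_of(self) -> dict[str, str]:
        return {c: g.color for g in self.groups for c in g.members}

    def validate_against(self, cells: Sequence[str]) -> None:
        cells_set = set(cells)
        members = self.all_members()
        if members != cells_set:
            missing = sorted(cells_set - members)[:5]
            extra = sorted(members - cells_set)[:5]
            raise InputError(
                f"grouping does not partition the cell set (missing={missing}, extra={extra})"
            )

    def restrict(self, cells: Sequence[str]) -> "Grouping":
        """Drop cells not in ``cells``; empty groups vanish, colours kept."""
        cells_set = set(cells)
        groups = [
            Group(g.label, g.color, g.members & cells_set)
            for g in self.groups
            if g.members & cells_set
        ]
        return Grouping(groups, source=self.source)

    def __eq__(self, other) -> bool:
        if not isinstance(other, Grouping):
            return NotImplemented
        return self.source == other.source and self.groups == other.groups

    # -- (de)serialisation ---------------------------------------------
    def to_dict(self) -> dict:
        return {
            "source": self.source,
            "groups": [
                {"label": g.label, "color": g.color, "members": sorted(g.members)}
                for g in self.groups
            ],
        }

    @classmethod
    def from_dict(cls, d: dict) -> "Grouping":
        return cls(
            [Group(g["label"], g["color"], frozenset(g["members"])) for g in d["groups"]],
            source=d["source"],
        )


@dataclass
class Gate2D:
    """Inclusive rectangular gate in a two-gene expression plane."""

    gene_x: str
    gene_y: str
    x_min: float
    x_max: float
    y_min: float
    y_max: float
    label: Optional[str] = None

    def __post_init__(self) -> None:
        if self.x_min > self.x_max or self.y_min > self.y_max:
            raise InputError("gate bounds must satisfy min <= max")

    def contains(self, x: float, y: float) -> bool:
        if np.isnan(x) or np.isnan(y):
            return False
        return self.x_min <= x <= self.x_max and self.y_min <= y <= self.y_max


# ---------------------------------------------------------------------------
# constructors


def groups_from_plates(exp: "Experiment") -> Grouping:
    """One group per plate, in plate input order."""
    plates = exp.plates
    if not plates:
        raise InputError("experiment has no plates")
    by_plate: dict[str, set[str]] = {p: set() for p in plates}
    for c in exp.cells:
        by_plate[exp.plate_of(c)].add(c)
    groups = [
        Group(p, palette_color(i), frozenset(by_plate[p])) for i, p in enumerate(plates)
    ]
    return Grouping(groups, source="plates")


def groups_from_assignment(exp: "Experiment", assignment: Mapping[str, int]) -> Grouping:
    """Groups ordered by ascending cluster index, labelled ``cluster i``."""
    cells = set(exp.cells)
    assigned = set(assignment)
    if assigned != cells:
        missing = sorted(cells - assigned)[:5]
        extra = sorted(assigned - cells)[:5]
        raise InputError(
            f"assignment does not cover the cell set (missing={missing}, unknown={extra})"
        )
    indices = sorted(set(assignment.values()))
    groups = []
    for i, k in enumerate(indices):
        members = frozenset(c for c, v in assignment.items() if v == k)
        groups.append(Group(f"cluster {k}", palette_color(i), members))
    return Grouping(groups, source="cluster")


def groups_1d(exp: "Experiment", gene: str, cutoffs: Sequence[float]) -> Grouping:
    """Bin cells on one gene's current-stage value with half-open intervals.

    ``k`` cutoffs produce up to ``k + 1`` bins ``(-inf, c1), [c1, c2), ...,
    [ck, inf)``; a value exactly at a cutoff goes to the upper bin. Cells
    with a missing value fall in the lowest bin (no detection = lowest
    expression on the inverted scale). Empty bins are dropped.
    """
    if gene not in exp.matrix.columns:
        raise InputError(f"unknown gene: {gene!r}")
    if len(cutoffs) == 0:
        raise InputError("at least one cutoff required")
    cuts = [float(c) for c in cutoffs]
    if cuts != sorted(cuts):
        import warnings

        warnings.warn("cutoffs were not ascending; sorting them", stacklevel=2)
        cuts = sorted(cuts)
    values = exp.matrix[gene]
    edges = [-np.inf] + cuts + [np.inf]
    bins: list[list[str]] = [[] for _ in range(len(cuts) + 1)]
    for cell in exp.cells:
        v = values.loc[cell]
        if np.isnan(v):
            bins[0].append(cell)
            continue
        idx = int(np.searchsorted(cuts, v, side="right"))
        bins[idx].append(cell)
    groups = []
    color_i = 0
    for i, members in enumerate(bins):
        if not members:
            continue
        lo, hi = edges[i], edges[i + 1]
        if np.isinf(lo):
            label = f"{gene} < {hi:g}"
        elif np.isinf(hi):
            label = f"{gene} >= {lo:g}"
        else:
            label = f"{lo:g} <= {gene} < {hi:g}"
        groups.append(Group(label, palette_color(color_i), frozenset(members)))
        color_i += 1
    return Grouping(groups, source="1d")


def groups_2d(exp: "Experiment", gates: Sequence[Gate2D]) -> Grouping:
    """Assign cells to the first gate containing them; leftovers form "rest"."""
    if not gates:
        raise InputError("at least one gate required")
    for gate in gates:
        for gene in (gate.gene_x, gate.gene_y):
            if gene not in exp.matrix.columns:
                raise InputError(f"unknown gene: {gene!r}")
    taken: set[str] = set()
    groups: list[Group] = []
    for i, gate in enumerate(gates):
        xs = exp.matrix[gate.gene_x]
        ys = exp.matrix[gate.gene_y]
        members = frozenset(
            c
            for c in exp.cells
            if c not in taken and gate.contains(float(xs.loc[c]), float(ys.loc[c]))
        )
        taken |= members
        if members:
            label = gate.label or f"gate {i + 1} ({gate.gene_x}/{gate.gene_y})"
            groups.append(Group(label, palette_color(len(groups)), members))
    rest = frozenset(c for c in exp.cells if c not in taken)
    if rest:
        groups.append(Group("rest", palette_color(len(groups)), rest))
    return Grouping(groups, source="2d")


# ---------------------------------------------------------------------------
# rearrangement


def merge_groups(
    grouping: Grouping, labels_to_merge: Sequence[str], new_label: str
) -> Grouping:
    """Union the named groups; result sits at the earliest member's slot."""
    if len(labels_to_merge) < 2:
        raise InputError("need at least two groups to merge")
    known = set(grouping.labels)
    unknown = [x for x in labels_to_merge if x not in known]
    if unknown:
        raise InputError(f"unknown group labels: {unknown}")
    merge_set = set(labels_to_merge)
    groups: list[Group] = []
    merged_members: set[str] = set()
    merged_color: Optional[str] = None
    slot: Optional[int] = None
    for g in grouping.groups:
        if g.label in merge_set:
            merged_members |= g.members
            if merged_color is None:
                merged_color = g.color
                slot = len(groups)
                groups.append(g)  # placeholder; replaced below
        else:
            groups.append(g)
    assert slot is not None and merged_color is not None
    groups[slot] = Group(new_label, merged_color, frozenset(merged_members))
    return Grouping(groups, source="merged")


def reorder_groups(grouping: Grouping, new_order: Sequence[str]) -> Grouping:
    """Reorder groups; colours travel with their groups."""
    if sorted(new_order) != sorted(grouping.labels):
        raise InputError(
            f"new order {list(new_order)} is not a permutation of {grouping.labels}"
        )
    by_label = {g.label: g for g in grouping.groups}
    return Grouping([by_label[x] for x in new_order], source="reordered")
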