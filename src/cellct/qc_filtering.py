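"""Control-gene QC summaries and rule-based cell filtering.

Filtering operates on raw Ct, before inversion. Remember the scale:
lower Ct = higher expression, so "control gene too weakly expressed"
means Ct *above* the rule's ``max_ct``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy import stats

from .errors import InputError
from .experiment import Experiment


@dataclass(frozen=True)
class FilterRule:
    """Pass iff (detected, when required) and Ct <= max_ct."""

    gene: str
    max_ct: float
    require_detected: bool = True

    def __post_init__(self) -> None:
        if self.max_ct <= 0:
            raise InputError(f"max_ct must be positive, got {self.max_ct}")


@dataclass(frozen=True)
class FilterSpec:
    rules: tuple[FilterRule, ...]
    combinator: str = "all"  # every rule must pass (default) | any

    def __post_init__(self) -> None:
        object.__setattr__(self, "rules", tuple(self.rules))
        if not self.rules:
            raise InputError("FilterSpec needs at least one rule")
        if self.combinator not in ("all", "any"):
            raise InputError(f"combinator must be 'all' or 'any', got {self.combinator!r}")

    @classmethod
    def parse(cls, specs: Sequence[str], combinator: str = "all") -> "FilterSpec":
        """Build from CLI-style strings ``GENE:MAXCT[:detected]``."""
        rules = []
        for s in specs:
            parts = s.split(":")
            if len(parts) not in (2, 3):
                raise InputError(f"bad filter spec {s!r}; expected GENE:MAXCT[:detected]")
            gene = parts[0]
            try:
                max_ct = float(parts[1])
            except ValueError:
                raise InputError(f"bad filter threshold in {s!r}") from None
            require = True
            if len(parts) == 3:
                flag = parts[2].lower()
                if flag == "detected":
                    require = True
                elif flag in ("optional", "any"):
                    require = False
                else:
                    raise InputError(f"bad filter flag {parts[2]!r} in {s!r}")
            rules.append(FilterRule(gene, max_ct, require_detected=require))
        return cls(tuple(rules), combinator)


@dataclass
class GeneHistogram:
    gene: str
    bin_edges: np.ndarray
    counts: np.ndarray
    n_detected: int
    n_not_detected: int


@dataclass
class PlateDensity:
    plate_id: str
    gene: str
    grid: np.ndarray
    density: np.ndarray
    mean: float
    median: float
    n_detected: int


@dataclass
class QCSummary:
    """Pooled histograms per control gene + per-plate density estimates."""

    histograms: dict[str, GeneHistogram] = field(default_factory=dict)
    densities: dict[tuple[str, str], PlateDensity] = field(default_factory=dict)


def control_gene_summary(
    exp: Experiment, control_genes: Sequence[str], n_bins: int = 30
) -> QCSummary:
    """Histogram each control gene pooled over cells, with one Gaussian-KDE
    density per (plate, gene) so outlier chips stand out visually.

    Densities use Silverman's bandwidth rule for reproducibility.
    Not-detected values are excluded from the distributions and counted
    separately.
    """
    exp.require_stage("control_gene_summary", "raw_ct")
    summary = QCSummary()
    for gene in control_genes:
        if gene not in exp.matrix.columns:
            raise InputError(f"control gene not on panel: {gene!r}")
        col = exp.matrix[gene]
        det = exp.detected[gene]
        values = col[det].to_numpy()
        if values.size:
            counts, edges = np.histogram(values, bins=n_bins)
        else:
            counts, edges = np.zeros(n_bins, dtype=int), np.linspace(0, 1, n_bins + 1)
        summary.histograms[gene] = GeneHistogram(
            gene=gene,
            bin_edges=edges,
            counts=counts,
            n_detected=int(det.sum()),
            n_not_detected=int((~det).sum()),
        )
        for plate in exp.plates:
            mask = [exp.plate_of(c) == plate for c in exp.cells]
            pv = col[mask][det[mask]].to_numpy()
            if pv.size == 0:
                grid = np.linspace(0, 1, 2)
                dens = np.zeros(2)
                mean = median = float("nan")
            else:
                grid = np.linspace(pv.min() - 3, pv.max() + 3, 200)
                if pv.size > 1 and np.std(pv) > 0:
                    kde = stats.gaussian_kde(pv, bw_method="silverman")
                    dens = kde(grid)
                else:
                    dens = np.zeros_like(grid)
                    dens[np.argmin(np.abs(grid - pv[0]))] = 1.0
                mean, median = float(np.mean(pv)), float(np.median(pv))
            summary.densities[(plate, gene)] = PlateDensity(
                plate_id=plate,
                gene=gene,
                grid=grid,
                density=dens,
                mean=mean,
                median=median,
                n_detected=int(pv.size),
            )
    return summary


def _rule_passes(exp: Experiment, cell: str, rule: FilterRule) -> bool:
    if rule.gene not in exp.matrix.columns:
        raise InputError(f"filter rule gene not on panel: {rule.gene!r}")
    detected = bool(exp.detected.loc[cell, rule.gene])
    if not detected:
        return not rule.require_detected
    return float(exp.matrix.loc[cell, rule.gene]) <= rule.max_ct


def apply_cell_filter(
    exp: Experiment, spec: FilterSpec
) -> tuple[Experiment, list[tuple[str, str]]]:
    """Remove cells failing the filter; returns (filtered experiment,
    list of (cell, reason) with the first failing rule per removed cell).

    Grouping and index-marker rows are pruned consistently. An empty
    result is not an error but is flagged in the log.
    """
    exp.require_stage("apply_cell_filter", "raw_ct")
    for rule in spec.rules:
        if rule.gene not in exp.matrix.columns:
            raise InputError(f"filter rule gene not on panel: {rule.gene!r}")
    removed: list[tuple[str, str]] = []
    kept: list[str] = []
    for cell in exp.cells:
        results = [_rule_passes(exp, cell, r) for r in spec.rules]
        ok = all(results) if spec.combinator == "all" else any(results)
        if ok:
            kept.append(cell)
        else:
            first_fail = next(r for r, passed in zip(spec.rules, results) if not passed)
            removed.append(
                (
                    cell,
                    f"{first_fail.gene}: "
                    + (
                        "not detected"
                        if first_fail.require_detected
                        and not bool(exp.detected.loc[cell, first_fail.gene])
                        else f"Ct > {first_fail.max_ct}"
                    ),
                )
            )
    out = exp.subset_cells(kept)
    counts = {"n_removed": len(removed), "n_kept": len(kept)}
    if not kept:
        counts["empty_result"] = True
    out.log.append(
        "apply_cell_filter",
        {
            "rules": [
                {"gene": r.gene, "max_ct": r.max_ct, "require_detected": r.require_detected}
                for r in spec.rules
            ],
            "combinator": spec.combinator,
        },
        counts,
    )
    return out, removed


def drop_plate(exp: Experiment, plate_id: str) -> Experiment:
    """Remove every cell of one plate (for discarding outlier chips)."""
    if plate_id not in exp.plates:
        raise InputError(f"unknown plate: {plate_id!r} (have {exp.plates})")
    kept = [c for c in exp.cells if exp.plate_of(c) != plate_id]
    out = exp.subset_cells(kept)
    counts = {"n_removed": exp.n_cells - len(kept), "n_kept": len(kept)}
    if not kept:
        counts["empty_result"] = True
    out.log.append("drop_plate", {"plate_id": plate_id}, counts)
    return out
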