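"""Synthetic data generator with known group structure.

Produces instrument-dialect expression files (table + heatmap layout),
index-sort tables, and the generating truth, so the whole pipeline is
testable end to end without any external dataset. The statistical design:
per-group marker genes shifted down in Ct (up in expression) by a
configurable effect size, logistic dropout in true Ct, near-dropout-free
control genes, and log-normal index intensities with per-group shifts.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Optional, Union

import numpy as np

from .errors import InputError
from .experiment import Experiment, PlateData
from .io_formats import IndexTable, concatenate_plates, join_index
from .wells import PLATE_FORMATS

_SENTINEL = "999"


@dataclass
class SimConfig:
    n_groups: int = 5
    cells_per_group: int = 60
    n_genes: int = 96
    n_marker_genes_per_group: int = 15
    effect_size: float = 6.0  # delta-Ct between marker-gene groups
    baseline_mu: float = 26.0
    baseline_sigma: float = 1.5
    dropout_midpoint: float = 31.0
    dropout_slope: float = 0.7
    control_genes: int = 2
    failed_control_fraction: float = 0.0  # cells with failed controls, for QC tests
    n_index_markers: int = 5
    index_effect: float = 1.0  # per-group log-intensity shift
    index_sigma: float = 0.3
    compensation_shift: float = 0.0  # subtracted from intensities (can go negative)
    lod: float = 40.0
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.n_groups, self.cells_per_group, self.n_genes) < 1:
            raise InputError("counts must be >= 1")
        if self.effect_size < 0:
            raise InputError("effect_size must be >= 0")
        need = self.n_groups * self.n_marker_genes_per_group + self.control_genes
        if need > self.n_genes:
            raise InputError(
                f"{need} marker+control genes do not fit into {self.n_genes} genes"
            )
        if not 0 <= self.failed_control_fraction < 1:
            raise InputError("failed_control_fraction must be in [0, 1)")

    @property
    def n_cells(self) -> int:
        return self.n_groups * self.cells_per_group


@dataclass
class SimTruth:
    """Ground truth of a simulation: per-cell labels and per-group means."""

    labels: dict[str, int]  # cell ID -> true group (1..k)
    gene_group_mu: dict[str, list[float]]  # gene -> mean Ct per group
    marker_group_mu: dict[str, list[float]]  # marker -> mean log-intensity per group
    control_gene_names: list[str]
    failed_cells: list[str]

    def to_json(self, path: Union[str, Path]) -> Path:
        path = Path(path)
        path.write_text(json.dumps(asdict(self), indent=1))
        return path

    @classmethod
    def from_json(cls, path: Union[str, Path]) -> "SimTruth":
        d = json.loads(Path(path).read_text())
        return cls(
            labels={k: int(v) for k, v in d["labels"].items()},
            gene_group_mu=d["gene_group_mu"],
            marker_group_mu=d["marker_group_mu"],
            control_gene_names=d["control_gene_names"],
            failed_cells=d["failed_cells"],
        )


def _well_labels(n: int, plate_format: int = 96) -> list[list[str]]:
    """Lay ``n`` cells onto as many plates as needed, row-major."""
    rows, n_cols = PLATE_FORMATS[plate_format]
    per_plate = len(rows) * n_cols
    plates: list[list[str]] = []
    for start in range(0, n, per_plate):
        count = min(per_plate, n - start)
        wells = [
            f"{rows[i // n_cols]}{i % n_cols + 1:02d}" for i in range(count)
        ]
        plates.append(wells)
    return plates


def simulate_plates(
    config: SimConfig,
) -> tuple[list[PlateData], list[IndexTable], SimTruth]:
    """Generate in-memory plates + index tables + truth (deterministic
    for a fixed seed)."""
    rng = np.random.default_rng(config.seed)
    n = config.n_cells
    k = config.n_groups

    genes = [f"G{i + 1:03d}" for i in range(config.n_genes - config.control_genes)]
    controls = [f"CTRL{i + 1}" for i in range(config.control_genes)]
    all_genes = genes + controls

    # marker genes: first k * m genes, assigned to groups round-robin
    marker_group = {}
    for i in range(k * config.n_marker_genes_per_group):
        marker_group[genes[i]] = i % k + 1

    # interleave groups across wells/plates so plate != group
    labels_flat = rng.permutation(np.repeat(np.arange(1, k + 1), config.cells_per_group))

    gene_group_mu = {}
    for gene in all_genes:
        if gene in controls:
            mus = [config.baseline_mu - 10.0] * k
        else:
            mus = [
                config.baseline_mu
                - (config.effect_size if marker_group.get(gene) == g else 0.0)
                for g in range(1, k + 1)
            ]
        gene_group_mu[gene] = mus

    plate_wells = _well_labels(n)
    failed = rng.random(n) < config.failed_control_fraction

    plates: list[PlateData] = []
    index_tables: list[IndexTable] = []
    labels: dict[str, int] = {}
    failed_cells: list[str] = []

    markers = [f"M{i + 1}" for i in range(config.n_index_markers)]
    base_log = np.log(1000.0)
    marker_group_mu = {
        m: [
            base_log + (config.index_effect if (i % k) + 1 == g else 0.0)
            for g in range(1, k + 1)
        ]
        for i, m in enumerate(markers)
    }

    cell_i = 0
    for p, wells in enumerate(plate_wells, start=1):
        plate_id = f"P{p}"
        n_w = len(wells)
        grp = labels_flat[cell_i : cell_i + n_w]
        ct = np.empty((n_w, len(all_genes)))
        det = np.ones((n_w, len(all_genes)), dtype=bool)
        for j, gene in enumerate(all_genes):
            mus = np.array([gene_group_mu[gene][g - 1] for g in grp])
            true_ct = np.maximum(rng.normal(mus, config.baseline_sigma), 1.0)
            if gene in controls:
                p_drop = np.zeros(n_w)
            else:
                p_drop = 1.0 / (
                    1.0
                    + np.exp(-(true_ct - config.dropout_midpoint) * config.dropout_slope)
                )
            drop = rng.random(n_w) < p_drop
            drop |= true_ct >= config.lod
            ct[:, j] = np.where(drop, np.nan, true_ct)
            det[:, j] = ~drop
        # failed cells: all control genes fail to amplify
        for w in range(n_w):
            if failed[cell_i + w]:
                for j, gene in enumerate(all_genes):
                    if gene in controls:
                        ct[w, j] = np.nan
                        det[w, j] = False
                failed_cells.append(f"{plate_id}:{wells[w]}")
        plates.append(PlateData(plate_id, wells, all_genes, ct, det, config.lod))

        log_mu = np.array(
            [[marker_group_mu[m][g - 1] for m in markers] for g in grp]
        )
        intensity = (
            np.exp(rng.normal(log_mu, config.index_sigma)) - config.compensation_shift
        )
        index_tables.append(IndexTable(list(wells), markers, intensity, plate_id=plate_id))

        for w, g in zip(wells, grp):
            labels[f"{plate_id}:{w}"] = int(g)
        cell_i += n_w

    truth = SimTruth(
        labels=labels,
        gene_group_mu=gene_group_mu,
        marker_group_mu=marker_group_mu,
        control_gene_names=controls,
        failed_cells=failed_cells,
    )
    return plates, index_tables, truth


def _format_ct(v: float) -> str:
    return _SENTINEL if np.isnan(v) else repr(float(v))


def write_table_file(plate: PlateData, path: Union[str, Path]) -> Path:
    """Write a plate in long "table" dialect (comma-delimited, with a
    preamble, 999 sentinels and Pass/Fail calls)."""
    path = Path(path)
    lines = [
        "Chip Run Export",
        f"Plate,{plate.plate_id}",
        "Chamber ID,Gene,Ct,Call",
    ]
    for i, well in enumerate(plate.wells):
        for j, gene in enumerate(plate.genes):
            detected = plate.detected[i, j]
            lines.append(
                f"{well},{gene},{_format_ct(plate.ct[i, j])},"
                f"{'Pass' if detected else 'Fail'}"
            )
    path.write_text("\n".join(lines) + "\n")
    return path


def write_heatmap_file(plate: PlateData, path: Union[str, Path]) -> Path:
    """Write a plate in rectangular "heatmap" dialect (tab-delimited)."""
    path = Path(path)
    lines = ["well\t" + "\t".join(plate.genes)]
    for i, well in enumerate(plate.wells):
        lines.append(
            well + "\t" + "\t".join(_format_ct(v) for v in plate.ct[i])
        )
    path.write_text("\n".join(lines) + "\n")
    return path


def write_index_file(table: IndexTable, path: Union[str, Path]) -> Path:
    path = Path(path)
    lines = ["Well\t" + "\t".join(table.markers)]
    for i, well in enumerate(table.wells):
        lines.append(
            well + "\t" + "\t".join(repr(float(v)) for v in table.intensity[i])
        )
    path.write_text("\n".join(lines) + "\n")
    return path


def simulate_experiment(
    config: SimConfig, outdir: Union[str, Path]
) -> tuple[dict, SimTruth]:
    """Generate data files + truth under ``outdir``.

    The first plate is written in table dialect, remaining plates in
    heatmap dialect (both readers are exercised); one index TSV is
    written per plate, and the truth as ``truth.json``. Deterministic for
    a fixed seed — running twice yields byte-identical files.

    Returns a manifest dict: ``{"plates": [(path, dialect, plate_id)],
    "index": [(path, plate_id)], "truth": path, "lod": lod}``.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    plates, index_tables, truth = simulate_plates(config)
    manifest: dict = {"plates": [], "index": [], "lod": config.lod}
    for i, plate in enumerate(plates):
        if i == 0:
            path = write_table_file(plate, outdir / f"{plate.plate_id}_table.csv")
            manifest["plates"].append((str(path), "table", plate.plate_id))
        else:
            path = write_heatmap_file(plate, outdir / f"{plate.plate_id}_heatmap.tsv")
            manifest["plates"].append((str(path), "heatmap", plate.plate_id))
    for table in index_tables:
        path = write_index_file(table, outdir / f"{table.plate_id}_index.tsv")
        manifest["index"].append((str(path), table.plate_id))
    manifest["truth"] = str(truth.to_json(outdir / "truth.json"))
    (outdir / "sim_config.json").write_text(json.dumps(asdict(config), indent=1))
    return manifest, truth


def simulate_to_experiment(config: SimConfig) -> tuple[Experiment, SimTruth]:
    """Convenience: simulate and assemble an in-memory raw-Ct experiment
    with index markers joined (no files touched)."""
    plates, index_tables, truth = simulate_plates(config)
    exp = concatenate_plates(plates)
    exp = join_index(exp, index_tables)
    return exp, truth


# ---------------------------------------------------------------------------
# worked micro-fixture with hand-computed expectations


@dataclass
class MicroFixture:
    """4 cells x 3 genes (+2 markers) with literal expected matrices.

    Gene panel: Actb (control), G1, G2; LOD 40. Cell P1:A03 has control
    Ct 32 > 24 and is removed by the canonical filter rule
    (Actb, max_ct=24, require_detected).
    """

    plate: PlateData
    index: IndexTable
    filter_gene: str
    filter_max_ct: float
    removed_cell: str
    cells_after_filter: list[str]
    genes: list[str]
    expected_inverted: dict[str, list[float]]
    expected_z: dict[str, list[float]]


def worked_micro_fixture() -> MicroFixture:
    genes = ["Actb", "G1", "G2"]
    wells = ["A01", "A02", "A03", "A04"]
    nan = np.nan
    ct = np.array(
        [
            [18.0, 25.0, 30.0],
            [20.0, nan, 28.0],  # G1 not detected
            [32.0, 24.0, 26.0],  # control too weak -> filtered out
            [19.0, 22.0, nan],  # G2 not detected
        ]
    )
    detected = ~np.isnan(ct)
    plate = PlateData("P1", wells, genes, ct, detected, lod=40.0)
    index = IndexTable(
        wells=["A01", "A02", "A03", "A04"],
        markers=["CD55", "CD115"],
        intensity=np.array(
            [[850.0, 40.0], [900.0, 55.0], [120.0, 600.0], [-12.3, 700.0]]
        ),
        plate_id="P1",
    )
    return MicroFixture(
        plate=plate,
        index=index,
        filter_gene="Actb",
        filter_max_ct=24.0,
        removed_cell="P1:A03",
        cells_after_filter=["P1:A01", "P1:A02", "P1:A04"],
        genes=genes,
        # inversion by hand: detected -> 40 - ct, not-detected -> 0
        expected_inverted={
            "P1:A01": [22.0, 15.0, 10.0],
            "P1:A02": [20.0, 0.0, 12.0],
            "P1:A04": [21.0, 18.0, 0.0],
        },
        # per-gene z, sample sd; computed by hand from the inverted values:
        # Actb {22,20,21}: mean 21, sd 1; G1 {15,0,18}: mean 11, sd sqrt(93);
        # G2 {10,12,0}: mean 22/3, sd sqrt(744/18)
        expected_z={
            "P1:A01": [1.0, 0.4147806778921701, 0.4147806778921702],
            "P1:A02": [-1.0, -1.1406468642034677, 0.7258661863112978],
            "P1:A04": [0.0, 0.7258661863112977, -1.140646864203468],
        },
    )
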