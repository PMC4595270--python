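"""Session state machine tying the modules into the two-phase workflow:
(1) import / QC / normalise, (2) analyse / visualise.

Every state-changing step appends one entry to the experiment's analysis
log; the session (experiment + scrapbook + config snapshot + seed
registry) serialises completely into a ZIP archive and can be resumed.
``replay`` re-executes the logged steps from the raw input files and must
reproduce the final matrices bit-exactly.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence, Union

from .errors import InputError
from .experiment import Experiment
from .grouping import (
    Gate2D,
    Grouping,
    groups_1d,
    groups_2d,
    groups_from_assignment,
    groups_from_plates,
    merge_groups,
    reorder_groups,
)
from .io_formats import (
    IndexTable,
    concatenate_plates,
    join_index,
    load_session,
    read_biomark_heatmap,
    read_biomark_table,
    read_ct_matrix,
    read_index_table,
    save_session,
)
from .qc_filtering import FilterSpec, apply_cell_filter, control_gene_summary
from .scrapbook import Scrapbook
from .synthetic_fixtures import SimConfig, simulate_experiment
from .transform import invert_ct, normalize_housekeeping, z_transform
from . import embed_cluster as ec
from . import viz_report as viz

_READERS = {
    "table": read_biomark_table,
    "heatmap": read_biomark_heatmap,
    "matrix": read_ct_matrix,
}


@dataclass
class SessionState:
    experiment: Experiment
    scrapbook: Scrapbook = field(default_factory=Scrapbook)
    config: dict = field(default_factory=dict)
    seeds: dict = field(default_factory=dict)

    def save(self, path: Union[str, Path]) -> Path:
        return save_session(
            self.experiment,
            self.scrapbook,
            path,
            parameters={"config": self.config, "seeds": self.seeds},
        )


def import_data(config: dict) -> Experiment:
    """Read plates (+ optional index tables) named in ``config`` and
    assemble the raw-Ct experiment."""
    plate_specs = config.get("plates", [])
    if not plate_specs:
        raise InputError("config names no input plates")
    lod = float(config.get("lod", 40.0))
    plates = []
    for spec in plate_specs:
        dialect = spec.get("dialect", "table")
        if dialect not in _READERS:
            raise InputError(f"unknown dialect {dialect!r}; use table|heatmap|matrix")
        plates.append(
            _READERS[dialect](spec["path"], plate_id=spec.get("plate_id"), lod=lod)
        )
    exp = concatenate_plates(plates)
    index_specs = config.get("index", [])
    if index_specs:
        tables = [
            read_index_table(s["path"], plate_id=s.get("plate_id")) for s in index_specs
        ]
        exp = join_index(exp, tables)
    return exp


def _cluster_matrix(exp: Experiment, on: str):
    """Matrix to cluster on; for index data, complete rows only."""
    if on == "expression":
        return exp.matrix, []
    if on != "index":
        raise InputError(f"cluster target must be 'expression' or 'index', got {on!r}")
    if exp.index_markers is None:
        raise InputError("no index data joined; run join_index first")
    complete = exp.index_markers.dropna()
    excluded = [c for c in exp.cells if c not in complete.index]
    return complete, excluded


def cluster_step(exp: Experiment, params: dict) -> Experiment:
    """Run a clustering op and install the resulting grouping + log entry.

    params: method (hclust|kmeans), k, linkage, seed, restarts, on.
    Cells without index data (when clustering on markers) land in their
    own ``cluster 0`` group and are counted in the log.
    """
    method = params.get("method", "hclust")
    k = int(params["k"])
    on = params.get("on", "expression")
    matrix, excluded = _cluster_matrix(exp, on)
    if method == "hclust":
        linkage = params.get("linkage", "complete")
        dist = ec.correlation_distance(matrix)
        assignment = ec.cut_tree(ec.hcluster(dist, linkage), k)
    elif method == "kmeans":
        assignment = ec.kmeans_cluster(
            matrix,
            k,
            seed=int(params.get("seed", 0)),
            restarts=int(params.get("restarts", 10)),
        )
    else:
        raise InputError(f"unknown cluster method {method!r}")
    mapping = dict(assignment.assignment)
    for c in excluded:
        mapping[c] = 0
    grouping = groups_from_assignment(exp, mapping)
    out = exp.evolve(grouping=grouping)
    out.log.append(
        "cluster",
        dict(params, k=k, method=method, on=on),
        {"n_groups": grouping and len(grouping.groups), "n_excluded": len(excluded)},
    )
    return out


def embed_step(exp: Experiment, params: dict) -> tuple[Experiment, ec.Embedding]:
    method = params.get("method", "pca")
    k = int(params.get("k", 3))
    if method == "pca":
        emb = ec.pca_embed(exp.matrix, k)
    elif method == "isomap":
        emb = ec.isomap_embed(exp.matrix, k, int(params.get("n_neighbors", 15)))
    elif method == "lle":
        emb = ec.lle_embed(
            exp.matrix, k, int(params.get("n_neighbors", 15)), int(params.get("seed", 0))
        )
    else:
        raise InputError(f"unknown embedding method {method!r}")
    out = exp.evolve()
    out.log.append("embed", dict(params, method=method, k=k), {"n_cells": exp.n_cells})
    return out, emb


def group_step(exp: Experiment, kind: str, params: dict) -> Experiment:
    """Apply a grouping operation (plates|1d|2d|merge|reorder) and log it."""
    if kind == "plates":
        grouping = groups_from_plates(exp)
    elif kind == "1d":
        grouping = groups_1d(exp, params["gene"], params["cutoffs"])
    elif kind == "2d":
        gates = [Gate2D(**g) for g in params["gates"]]
        grouping = groups_2d(exp, gates)
    elif kind == "merge":
        if exp.grouping is None:
            raise InputError("no current grouping to merge")
        grouping = merge_groups(exp.grouping, params["labels"], params["new_label"])
    elif kind == "reorder":
        if exp.grouping is None:
            raise InputError("no current grouping to reorder")
        grouping = reorder_groups(exp.grouping, params["order"])
    else:
        raise InputError(f"unknown grouping kind {kind!r}")
    out = exp.evolve(grouping=grouping)
    out.log.append(
        f"group_{kind}", params, {"n_groups": len(grouping.groups)}
    )
    return out


def run_pipeline(config: dict, outdir: Union[str, Path]) -> SessionState:
    """Execute the full workflow described by ``config`` and archive it.

    Steps: import -> concatenate -> join -> QC filter -> invert ->
    (optional housekeeping normalisation) -> z-transform -> embed ->
    cluster -> figures -> report -> save. Stage-order violations raise
    with the expected stage named; all writes stay inside ``outdir``.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    exp = import_data(config)
    scrapbook = Scrapbook()

    control_genes = config.get("control_genes") or []
    if control_genes:
        control_gene_summary(exp, control_genes)

    filt = config.get("filter")
    if filt:
        spec = FilterSpec.parse(filt["rules"], filt.get("combinator", "all"))
        exp, _removed = apply_cell_filter(exp, spec)

    exp = invert_ct(exp, config.get("lod"))
    hk = config.get("hk_genes")
    if hk:
        exp = normalize_housekeeping(exp, hk)
    z = config.get("z", {})
    exp = z_transform(
        exp, z.get("axis", "per_gene"), z.get("denominator", "sample")
    )

    exp, embedding = embed_step(exp, config.get("embed", {"method": "pca", "k": 3}))
    cluster_params = config.get("cluster", {"method": "hclust", "k": 3})
    exp = cluster_step(exp, cluster_params)
    assert exp.grouping is not None

    figdir = outdir / "figures"
    violin_gene = config.get("violin_gene") or exp.genes[0]
    fig, _summary = viz.violin_figure(exp, violin_gene, exp.grouping)
    viz.scrapbook_add(scrapbook, fig, f"violin of {violin_gene}", figdir, "violin")
    exp.log.append("figure_violin", {"gene": violin_gene}, {})
    fig, layout = viz.expression_heatmap(exp, exp.grouping)
    viz.scrapbook_add(scrapbook, fig, "expression heatmap", figdir, "heatmap")
    exp.log.append("figure_expression_heatmap", {}, {"n_cells": len(layout.cell_order)})
    if exp.index_markers is not None:
        fig = viz.index_heatmap(exp, layout)
        viz.scrapbook_add(scrapbook, fig, "index-sort heatmap", figdir, "index")
        exp.log.append("figure_index_heatmap", {}, {})
    else:
        exp.log.append("index_heatmap_skipped", {}, {"reason": "no index data"})
    fig = viz.embedding_scatter(embedding, exp.grouping, dims=2)
    viz.scrapbook_add(scrapbook, fig, f"{embedding.method} scatter", figdir, "scatter")
    exp.log.append("figure_embedding_scatter", {"dims": 2}, {})
    exp.log.append("render_report", {"path": "report.html"}, {"n_entries": len(scrapbook)})
    import matplotlib.pyplot as plt

    plt.close("all")

    state = SessionState(
        experiment=exp,
        scrapbook=scrapbook,
        config=config,
        seeds={"cluster": cluster_params.get("seed", 0)},
    )
    viz.render_report(
        scrapbook, exp.log, outdir / "report.html", timestamp=config.get("timestamp", "")
    )
    state.save(outdir / "session.zip")
    return state


def resume(archive_path: Union[str, Path]) -> SessionState:
    """Load a saved session; appends a ``resume`` entry to the log."""
    exp, scrapbook = load_session(archive_path)
    # parameters live in the manifest; re-read them
    import zipfile

    with zipfile.ZipFile(archive_path) as zf:
        manifest = json.loads(zf.read("manifest.json"))
    params = manifest.get("parameters", {})
    exp.log.append("resume", {"archive": str(Path(archive_path).name)}, {})
    return SessionState(
        experiment=exp,
        scrapbook=scrapbook,
        config=params.get("config", {}),
        seeds=params.get("seeds", {}),
    )


def replay(archive_path: Union[str, Path]) -> Experiment:
    """Re-execute the archived analysis log from the raw input files.

    The import step is reconstructed from the archived config snapshot;
    every subsequent state-changing entry is dispatched to the matching
    operation with its logged parameters. The result must match the
    archived matrices bit-exactly (seeded determinism end to end).
    """
    saved, _ = load_session(archive_path)
    import zipfile

    with zipfile.ZipFile(archive_path) as zf:
        manifest = json.loads(zf.read("manifest.json"))
    config = manifest.get("parameters", {}).get("config")
    if not config:
        raise InputError("archive carries no config snapshot; cannot replay imports")
    exp = import_data(config)
    for entry in saved.log:
        op, params = entry.operation, entry.params
        if op in ("concatenate_plates", "join_index", "resume"):
            continue  # performed by import_data / not state-changing
        if op == "apply_cell_filter":
            rules = [
                f"{r['gene']}:{r['max_ct']}" + (":detected" if r["require_detected"] else ":optional")
                for r in params["rules"]
            ]
            exp, _ = apply_cell_filter(exp, FilterSpec.parse(rules, params["combinator"]))
        elif op == "drop_plate":
            from .qc_filtering import drop_plate

            exp = drop_plate(exp, params["plate_id"])
        elif op == "invert_ct":
            exp = invert_ct(exp, params["lod"])
        elif op == "normalize_housekeeping":
            exp = normalize_housekeeping(exp, params["hk_genes"])
        elif op == "z_transform":
            exp = z_transform(exp, params["axis"], params["denominator"])
        elif op == "embed":
            exp, _emb = embed_step(exp, params)
        elif op == "cluster":
            exp = cluster_step(exp, params)
        elif op.startswith("group_"):
            exp = group_step(exp, op[len("group_") :], params)
        # figure/report entries carry no state
    return exp


def simulate_cmd(config: SimConfig, outdir: Union[str, Path]) -> dict:
    manifest, _truth = simulate_experiment(config, outdir)
    return manifest
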