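"""Readers for the supported input dialects, plate concatenation,
index-table joins, and session archive persistence.

Supported inputs
----------------
* instrument "table" export: one row per (well, gene) reaction with Ct and
  a Pass/Fail call, possibly preceded by preamble lines;
* instrument "heatmap" export: rectangular wells x genes grid;
* generic Ct matrix: tab-delimited, cells x genes;
* index-sort table: tab-delimited, one well column + numeric marker columns.

Missing/non-detect convention: a 999 Ct sentinel, a blank cell, a declared
missing token (default ``NA``/empty), or a ``Fail`` call all map to
not-detected. The exact instrument dialects are not published; the
defaults here are documented assumptions and every column name, delimiter
and sentinel can be overridden through the dialect objects.
"""

from __future__ import annotations

import csv
import io
import json
import warnings
import zipfile
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence, Union

import numpy as np
import pandas as pd

from .errors import InputError
from .experiment import AnalysisLog, Experiment, LogEntry, PlateData, make_cell_id
from .grouping import Grouping, groups_from_plates
from .scrapbook import Scrapbook, ScrapbookEntry
from .wells import canonical_label, is_well_id, normalize_well_id

SESSION_FORMAT_VERSION = 1

_DEFAULT_MISSING = ("NA", "")
_SENTINEL = 999.0


def _auto_delimiter(line: str) -> str:
    return "\t" if line.count("\t") >= line.count(",") else ","


def _pick(candidates: Union[str, Sequence[str]], header: Sequence[str], what: str) -> str:
    if isinstance(candidates, str):
        candidates = (candidates,)
    for c in candidates:
        if c in header:
            return c
    raise InputError(f"no {what} column found; expected one of {list(candidates)}")


@dataclass
class TableDialect:
    """Column/delimiter conventions of a long-format export."""

    delimiter: Optional[str] = None  # None = auto-detect tab vs comma
    well_col: Union[str, Sequence[str]] = ("Well", "Chamber ID", "ID")
    gene_col: Union[str, Sequence[str]] = ("Gene", "Assay", "Name")
    ct_col: Union[str, Sequence[str]] = ("Ct", "Value", "Ct Value")
    call_col: Union[str, Sequence[str]] = ("Call", "Ct Call")
    fail_value: str = "Fail"
    sentinel: float = _SENTINEL
    missing_tokens: Sequence[str] = _DEFAULT_MISSING
    plate_format: int = 96


@dataclass
class HeatmapDialect:
    """Conventions of a rectangular wells x genes export."""

    delimiter: Optional[str] = None
    sentinel: float = _SENTINEL
    missing_tokens: Sequence[str] = _DEFAULT_MISSING
    plate_format: int = 96


def _read_lines(path: Union[str, Path]) -> list[str]:
    text = Path(path).read_text()
    return text.splitlines()


def read_biomark_table(
    path: Union[str, Path],
    dialect: Optional[TableDialect] = None,
    plate_id: Optional[str] = None,
    lod: float = 40.0,
) -> PlateData:
    """Parse a long-format (one row per reaction) Ct export.

    Preamble lines before the header are skipped; the header is the first
    line containing both a recognisable well column and a Ct column.
    """
    dialect = dialect or TableDialect()
    lines = _read_lines(path)
    plate_id = plate_id or Path(path).stem

    header_idx = None
    delim = dialect.delimiter
    fields: list[str] = []
    for i, line in enumerate(lines):
        d = delim or _auto_delimiter(line)
        parts = [p.strip() for p in next(csv.reader([line], delimiter=d))]
        ct_names = (dialect.ct_col,) if isinstance(dialect.ct_col, str) else dialect.ct_col
        well_names = (
            (dialect.well_col,) if isinstance(dialect.well_col, str) else dialect.well_col
        )
        if any(c in parts for c in ct_names) and any(w in parts for w in well_names):
            header_idx, fields, delim = i, parts, d
            break
    if header_idx is None:
        raise InputError(
            f"{path}: no header line containing a Ct column "
            f"({dialect.ct_col}) and a well column ({dialect.well_col})"
        )

    well_col = _pick(dialect.well_col, fields, "well")
    gene_col = _pick(dialect.gene_col, fields, "gene")
    ct_col = _pick(dialect.ct_col, fields, "Ct")
    try:
        call_col: Optional[str] = _pick(dialect.call_col, fields, "call")
    except InputError:
        call_col = None

    records: dict[tuple[str, str], tuple[float, bool]] = {}
    wells: list[str] = []
    genes: list[str] = []
    for lineno, line in enumerate(lines[header_idx + 1 :], start=header_idx + 2):
        if not line.strip():
            continue
        parts = [p.strip() for p in next(csv.reader([line], delimiter=delim))]
        row = dict(zip(fields, parts))
        well = normalize_well_id(row[well_col], dialect.plate_format).canonical_text
        gene = row[gene_col]
        if (well, gene) in records:
            raise InputError(f"{path}:{lineno}: duplicate entry for well {well}, gene {gene}")
        raw_ct = row.get(ct_col, "")
        detected = True
        if raw_ct in dialect.missing_tokens:
            ct, detected = np.nan, False
        else:
            try:
                ct = float(raw_ct)
            except ValueError:
                raise InputError(f"{path}:{lineno}: unparseable Ct value {raw_ct!r}") from None
            if ct == dialect.sentinel:
                ct, detected = np.nan, False
        if call_col is not None and row.get(call_col, "") == dialect.fail_value:
            ct, detected = np.nan, False
        records[(well, gene)] = (ct, detected)
        if well not in wells:
            wells.append(well)
        if gene not in genes:
            genes.append(gene)

    ct_m = np.full((len(wells), len(genes)), np.nan)
    det_m = np.zeros((len(wells), len(genes)), dtype=bool)
    for (well, gene), (ct, det) in records.items():
        i, j = wells.index(well), genes.index(gene)
        ct_m[i, j], det_m[i, j] = ct, det
    return PlateData(plate_id, wells, genes, ct_m, det_m, lod)


def read_biomark_heatmap(
    path: Union[str, Path],
    dialect: Optional[HeatmapDialect] = None,
    plate_id: Optional[str] = None,
    lod: float = 40.0,
) -> PlateData:
    """Parse a rectangular wells x genes grid export.

    First row: gene names (first field is a corner label); each following
    row: well ID then one Ct per gene.
    """
    dialect = dialect or HeatmapDialect()
    lines = [ln for ln in _read_lines(path) if ln.strip()]
    plate_id = plate_id or Path(path).stem
    if not lines:
        raise InputError(f"{path}: empty file")
    delim = dialect.delimiter or _auto_delimiter(lines[0])
    header = [p.strip() for p in next(csv.reader([lines[0]], delimiter=delim))]
    genes = header[1:]
    if not genes:
        raise InputError(f"{path}: header has no gene columns")

    wells: list[str] = []
    ct_rows: list[list[float]] = []
    det_rows: list[list[bool]] = []
    for lineno, line in enumerate(lines[1:], start=2):
        parts = [p.strip() for p in next(csv.reader([line], delimiter=delim))]
        if len(parts) != len(genes) + 1:
            raise InputError(
                f"{path}:{lineno}: ragged row ({len(parts) - 1} values for {len(genes)} genes)"
            )
        well = normalize_well_id(parts[0], dialect.plate_format).canonical_text
        if well in wells:
            raise InputError(f"{path}:{lineno}: duplicate well row {well}")
        cts, dets = [], []
        for gene, tok in zip(genes, parts[1:]):
            if tok in dialect.missing_tokens:
                cts.append(np.nan)
                dets.append(False)
                continue
            try:
                v = float(tok)
            except ValueError:
                raise InputError(
                    f"{path}:{lineno}: unparseable Ct {tok!r} for gene {gene}"
                ) from None
            if v == dialect.sentinel:
                cts.append(np.nan)
                dets.append(False)
            else:
                cts.append(v)
                dets.append(True)
        wells.append(well)
        ct_rows.append(cts)
        det_rows.append(dets)
    return PlateData(plate_id, wells, genes, np.array(ct_rows), np.array(det_rows), lod)


def read_ct_matrix(
    path: Union[str, Path],
    plate_id: Optional[str] = None,
    lod: float = 40.0,
    missing_tokens: Sequence[str] = _DEFAULT_MISSING,
    sentinel: float = _SENTINEL,
    plate_format: int = 96,
) -> PlateData:
    """Parse a generic tab-delimited cells x genes Ct matrix.

    Row labels that parse as well IDs are canonicalised; any other label
    is kept verbatim as an opaque cell label (such cells cannot be joined
    to index-sort data).
    """
    lines = [ln for ln in _read_lines(path) if ln.strip()]
    plate_id = plate_id or Path(path).stem
    if not lines:
        raise InputError(f"{path}: empty file")
    header = lines[0].split("\t")
    genes = [g.strip() for g in header[1:]]
    if not genes:
        raise InputError(f"{path}: header has no gene columns")
    labels: list[str] = []
    ct_rows: list[list[float]] = []
    det_rows: list[list[bool]] = []
    for lineno, line in enumerate(lines[1:], start=2):
        parts = [p.strip() for p in line.split("\t")]
        if len(parts) != len(genes) + 1:
            raise InputError(
                f"{path}:{lineno}: ragged row ({len(parts) - 1} values for {len(genes)} genes)"
            )
        label = canonical_label(parts[0], plate_format)
        cts, dets = [], []
        for tok in parts[1:]:
            if tok in missing_tokens:
                cts.append(np.nan)
                dets.append(False)
                continue
            try:
                v = float(tok)
            except ValueError:
                raise InputError(f"{path}:{lineno}: non-numeric entry {tok!r}") from None
            if v == sentinel:
                cts.append(np.nan)
                dets.append(False)
            else:
                cts.append(v)
                dets.append(True)
        labels.append(label)
        ct_rows.append(cts)
        det_rows.append(dets)
    return PlateData(plate_id, labels, genes, np.array(ct_rows), np.array(det_rows), lod)


@dataclass
class IndexTable:
    """Per-well surface-marker/scatter intensities from index sorting."""

    wells: list[str]
    markers: list[str]
    intensity: np.ndarray  # wells x markers; may contain negatives
    plate_id: Optional[str] = None

    def __post_init__(self) -> None:
        self.intensity = np.asarray(self.intensity, dtype=float)
        if len(set(self.wells)) != len(self.wells):
            dupes = sorted({w for w in self.wells if self.wells.count(w) > 1})
            raise InputError(f"index table: duplicate wells {dupes}")
        if len(set(self.markers)) != len(self.markers) or any(
            not m for m in self.markers
        ):
            raise InputError("index table: marker names must be non-empty and unique")
        if self.intensity.shape != (len(self.wells), len(self.markers)):
            raise InputError("index table: intensity shape mismatch")


_WELL_COL_NAMES = ("Well", "Well ID", "well", "Index")


def read_index_table(
    path: Union[str, Path],
    plate_id: Optional[str] = None,
    plate_format: int = 96,
) -> IndexTable:
    """Parse a tab-delimited index-sort table.

    The well column is found by name (``Well``/``Well ID``/...) or, failing
    that, as the unique column whose every value parses as a well ID.
    Remaining columns are numeric marker intensities (negative values are
    legitimate post-compensation fluorescence and are kept as-is).
    """
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    if df.empty:
        raise InputError(f"{path}: empty index table")
    well_col = None
    for c in df.columns:
        if c in _WELL_COL_NAMES:
            well_col = c
            break
    if well_col is None:
        candidates = [
            c for c in df.columns if df[c].map(lambda v: is_well_id(v, plate_format)).all()
        ]
        if not candidates:
            raise InputError(f"{path}: no column identifiable as well IDs")
        well_col = candidates[0]
    wells = [
        normalize_well_id(v, plate_format).canonical_text for v in df[well_col]
    ]
    if len(set(wells)) != len(wells):
        dupes = sorted({w for w in wells if wells.count(w) > 1})
        raise InputError(f"{path}: duplicate wells after canonicalisation: {dupes}")
    markers = [c for c in df.columns if c != well_col]
    if not markers:
        raise InputError(f"{path}: no marker columns")
    try:
        intensity = df[markers].astype(float).to_numpy()
    except ValueError as e:
        raise InputError(f"{path}: non-numeric marker intensity ({e})") from None
    return IndexTable(wells, markers, intensity, plate_id=plate_id)


# ---------------------------------------------------------------------------
# assembly


def concatenate_plates(plates: Sequence[PlateData]) -> Experiment:
    """Stack plates into a single raw-Ct experiment.

    Plates must share an identical gene panel (same names, any order) and
    LOD; gene columns are aligned by name to the first plate's order.
    Cell IDs are plate-qualified and the initial grouping is by plate.
    """
    if not plates:
        raise InputError("need at least one plate")
    ids = [p.plate_id for p in plates]
    if len(set(ids)) != len(ids):
        dupes = sorted({x for x in ids if ids.count(x) > 1})
        raise InputError(f"duplicate plate IDs: {dupes}")
    ref = plates[0]
    ref_genes = set(ref.genes)
    for p in plates[1:]:
        if set(p.genes) != ref_genes:
            only_ref = sorted(ref_genes - set(p.genes))
            only_p = sorted(set(p.genes) - ref_genes)
            raise InputError(
                f"gene panels differ between {ref.plate_id!r} and {p.plate_id!r}: "
                f"only in first: {only_ref}; only in {p.plate_id!r}: {only_p}"
            )
        if p.lod != ref.lod:
            raise InputError(
                f"LOD mismatch: {ref.plate_id!r} has {ref.lod}, {p.plate_id!r} has {p.lod}"
            )

    frames, det_frames = [], []
    for p in plates:
        idx = [make_cell_id(p.plate_id, w) for w in p.wells]
        frames.append(pd.DataFrame(p.ct, index=idx, columns=p.genes)[ref.genes])
        det_frames.append(pd.DataFrame(p.detected, index=idx, columns=p.genes)[ref.genes])
    matrix = pd.concat(frames)
    detected = pd.concat(det_frames)
    log = AnalysisLog()
    log.append(
        "concatenate_plates",
        {"plates": ids, "lod": ref.lod},
        {"n_cells": len(matrix), "n_genes": len(ref.genes)},
    )
    exp = Experiment(
        matrix=matrix,
        detected=detected,
        stage="raw_ct",
        lod=ref.lod,
        plate_order=list(ids),
        log=log,
    )
    return exp.evolve(grouping=groups_from_plates(exp))


def join_index(exp: Experiment, tables: Sequence[IndexTable]) -> Experiment:
    """Attach index-sort intensities to an experiment by well ID.

    Cells without an index row get missing marker values; index rows with
    no matching expression cell are dropped with a warning. Markers are
    the union over tables. The expression matrix itself is never touched.
    """
    plates = exp.plates
    markers: list[str] = []
    for t in tables:
        for m in t.markers:
            if m not in markers:
                markers.append(m)
    joined = pd.DataFrame(np.nan, index=exp.matrix.index, columns=markers)
    dropped: list[str] = []
    for t in tables:
        if t.plate_id is not None:
            if t.plate_id not in plates:
                raise InputError(
                    f"index table plate {t.plate_id!r} not among experiment plates {plates}"
                )
            plate = t.plate_id
        elif len(plates) == 1:
            plate = plates[0]
        else:
            raise InputError(
                f"index table without plate_id is ambiguous; experiment has plates {plates}"
            )
        for i, well in enumerate(t.wells):
            cell = make_cell_id(plate, well)
            if cell in joined.index:
                for j, m in enumerate(t.markers):
                    joined.loc[cell, m] = t.intensity[i, j]
            else:
                dropped.append(cell)
    if dropped:
        warnings.warn(
            f"{len(dropped)} index rows had no matching expression cell and were "
            f"dropped: {dropped[:5]}{'...' if len(dropped) > 5 else ''}",
            stacklevel=2,
        )
    out = exp.evolve(index_markers=joined)
    out.log.append(
        "join_index",
        {"n_tables": len(tables), "markers": markers},
        {"n_dropped_index_rows": len(dropped)},
    )
    return out


# ---------------------------------------------------------------------------
# session archive (ZIP)

_MANIFEST = "manifest.json"
_MATRIX = "matrix.tsv"
_DETECTED = "detected.tsv"
_INDEX = "index.tsv"
_GROUPING = "grouping.json"
_LOG = "log.jsonl"
_SCRAPBOOK = "scrapbook/annotations.json"


def _frame_to_tsv(df: pd.DataFrame, float_values: bool = True) -> str:
    # repr(float) is shortest-round-trip, so the TSV is bit-exact on reload
    buf = io.StringIO()
    buf.write("id\t" + "\t".join(map(str, df.columns)) + "\n")
    values = df.to_numpy()
    for i, idx in enumerate(df.index):
        if float_values:
            cells = ["NA" if np.isnan(v) else repr(float(v)) for v in values[i]]
        else:
            cells = ["1" if v else "0" for v in values[i]]
        buf.write(str(idx) + "\t" + "\t".join(cells) + "\n")
    return buf.getvalue()


def _frame_from_tsv(text: str, float_values: bool = True) -> pd.DataFrame:
    lines = text.splitlines()
    columns = lines[0].split("\t")[1:]
    index, rows = [], []
    for line in lines[1:]:
        parts = line.split("\t")
        index.append(parts[0])
        if float_values:
            rows.append([np.nan if t == "NA" else float(t) for t in parts[1:]])
        else:
            rows.append([t == "1" for t in parts[1:]])
    dtype = float if float_values else bool
    arr = np.array(rows, dtype=dtype) if rows else np.empty((0, len(columns)), dtype=dtype)
    return pd.DataFrame(arr, index=pd.Index(index), columns=columns)


def save_session(
    exp: Experiment,
    scrapbook: Optional[Scrapbook],
    path: Union[str, Path],
    parameters: Optional[dict] = None,
) -> Path:
    """Write the full session state to a ZIP archive.

    ``load_session(save_session(x))`` reproduces ``x`` exactly: matrices
    bit-identical, grouping order and colours preserved, log intact.
    """
    path = Path(path)
    scrapbook = scrapbook or Scrapbook()
    manifest = {
        "format_version": SESSION_FORMAT_VERSION,
        "stage": exp.stage,
        "lod": exp.lod,
        "plate_order": exp.plate_order,
        "parameters": parameters or {},
        "has_index": exp.index_markers is not None,
        "has_grouping": exp.grouping is not None,
    }
    with zipfile.ZipFile(path, "w", zipfile.ZIP_DEFLATED) as zf:
        zf.writestr(_MANIFEST, json.dumps(manifest, indent=1))
        zf.writestr(_MATRIX, _frame_to_tsv(exp.matrix))
        zf.writestr(_DETECTED, _frame_to_tsv(exp.detected, float_values=False))
        if exp.index_markers is not None:
            zf.writestr(_INDEX, _frame_to_tsv(exp.index_markers))
        if exp.grouping is not None:
            zf.writestr(_GROUPING, json.dumps(exp.grouping.to_dict(), indent=1))
        zf.writestr(_LOG, "\n".join(json.dumps(e.to_dict()) for e in exp.log))
        zf.writestr(
            _SCRAPBOOK, json.dumps([e.to_dict() for e in scrapbook.entries], indent=1)
        )
        for name, payload in scrapbook.asset_bytes.items():
            zf.writestr(f"scrapbook/{name}", payload)
    return path


def load_session(path: Union[str, Path]) -> tuple[Experiment, Scrapbook]:
    """Restore an experiment + scrapbook from a session archive."""
    path = Path(path)
    try:
        zf = zipfile.ZipFile(path)
    except (FileNotFoundError, zipfile.BadZipFile) as e:
        raise InputError(f"cannot open session archive {path}: {e}") from None
    with zf:
        names = set(zf.namelist())
        for required in (_MANIFEST, _MATRIX, _DETECTED, _LOG):
            if required not in names:
                raise InputError(f"archive {path} is missing member {required!r}")
        manifest = json.loads(zf.read(_MANIFEST))
        version = manifest.get("format_version")
        if version != SESSION_FORMAT_VERSION:
            raise InputError(
                f"unsupported session format version {version!r} "
                f"(this build reads version {SESSION_FORMAT_VERSION})"
            )
        matrix = _frame_from_tsv(zf.read(_MATRIX).decode())
        detected = _frame_from_tsv(zf.read(_DETECTED).decode(), float_values=False)
        index_markers = (
            _frame_from_tsv(zf.read(_INDEX).decode()) if _INDEX in names else None
        )
        grouping = (
            Grouping.from_dict(json.loads(zf.read(_GROUPING))) if _GROUPING in names else None
        )
        log_text = zf.read(_LOG).decode()
        log = AnalysisLog(
            [LogEntry.from_dict(json.loads(ln)) for ln in log_text.splitlines() if ln]
        )
        scrapbook = Scrapbook()
        if _SCRAPBOOK in names:
            scrapbook.entries = [
                ScrapbookEntry.from_dict(d) for d in json.loads(zf.read(_SCRAPBOOK))
            ]
            for name in names:
                if name.startswith("scrapbook/") and name != _SCRAPBOOK:
                    scrapbook.asset_bytes[name[len("scrapbook/") :]] = zf.read(name)
        exp = Experiment(
            matrix=matrix,
            detected=detected,
            stage=manifest["stage"],
            lod=manifest["lod"],
            plate_order=list(manifest["plate_order"]),
            index_markers=index_markers,
            grouping=grouping,
            log=log,
        )
    return exp, scrapbook
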