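# cellct

Analysis toolkit for single-cell qRT-PCR Ct data with integrated FACS
index-sorting intensities: import/QC/normalisation, dimensionality
reduction, clustering, flexible cell grouping, paired visualisation, and
reproducible session archives.

## What it does

* **Import** — instrument exports in long "table" layout (well/gene/Ct/call
  rows, 999 sentinels, Pass/Fail calls) or rectangular "heatmap" layout,
  plus generic tab-delimited Ct matrices and index-sort intensity tables.
  Well IDs are the join key between expression and sorter files; multiple
  plates concatenate into a single experiment with plate-qualified cell IDs.
* **QC & filtering** — control-gene histograms with per-chip density
  overlays; rule-based cell removal (`GENE:MAXCT[:detected]`), plate drop.
* **Normalisation** — limit-of-detection inversion (`LOD − Ct`,
  not-detected → 0), optional housekeeping-median scaling, z-transform
  (per gene or per cell).
* **Analysis** — PCA / Isomap / LLE embeddings; hierarchical clustering
  with correlation distance (selectable linkage) and k-means, on
  expression or index data.
* **Grouping** — groups from plates, cluster assignments, 1-D expression
  cut-offs, or rectangular 2-D gates; merge and reorder with colours that
  travel with their groups.
* **Visualisation** — grouped violin plots, expression and index-sort
  heatmaps sharing one cell order and group colour bar, 2-D/3-D embedding
  scatters, and an HTML report built from an annotated figure scrapbook
  plus the full analysis log.
* **Sessions** — the entire state (matrices, grouping, log, scrapbook)
  round-trips bit-exactly through a ZIP archive; `replay` re-executes the
  logged steps from the raw inputs and reproduces the final matrices
  exactly.
* **Synthetic data** — a seeded generator with known group structure
  (marker-gene Ct shifts, logistic dropout, log-normal index intensities)
  so every stage is testable without external data.

## CLI quick start

```bash
# generate a synthetic experiment (plates in both dialects + index TSVs)
cellct simulate -o data --groups 3 --cells-per-group 30 --genes 24 --seed 0

# import into a session archive
cellct import --plate data/P1_table.csv,table,P1 \
              --index data/P1_index.tsv,P1 -o session.zip

# QC, filter, normalise, cluster, plot, report
cellct qc -s session.zip --control CTRL1
cellct filter -s session.zip --filter CTRL1:24:detected
cellct normalize -s session.zip --z per_gene        # invert + z-transform
cellct cluster -s session.zip --method hclust -k 3
cellct plot violin -s session.zip --gene G001 -o figs
cellct report -s session.zip -o report.html

# or run everything from a JSON config and replay it later
cellct run -c config.json -o out
cellct replay -s out/session.zip
```

A `run` config names the inputs and stage parameters, e.g.

```json
{
  "lod": 40.0,
  "plates": [{"path": "data/P1_table.csv", "dialect": "table", "plate_id": "P1"}],
  "index":  [{"path": "data/P1_index.tsv", "plate_id": "P1"}],
  "filter": {"rules": ["CTRL1:24:detected"]},
  "z": {"axis": "per_gene"},
  "embed": {"method": "pca", "k": 3},
  "cluster": {"method": "kmeans", "k": 3, "seed": 0, "restarts": 10}
}
```

Exit codes: `0` ok, `2` input error, `3` stage-order violation.

## Notes & conventions

* Not-detected: Ct = 999, blank cells, `NA`/empty tokens, or a `Fail`
  call. Ct above the LOD is clamped to not-detected.
* Housekeeping scaling is an additive shift on the cycle scale
  (multiplicative in linear expression space) to the grand median of
  per-cell housekeeping medians.
* 1-D binning uses half-open intervals with boundary values going to the
  upper bin; 2-D gates are inclusive rectangles, first gate wins on
  overlap, ungated cells form a `rest` group.
* Index intensities may be negative (post-compensation fluorescence);
  they are never clamped.
* The instrument export dialects are documented assumptions; delimiters,
  column names, sentinels and missing tokens are all overridable via
  `TableDialect`/`HeatmapDialect`.
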