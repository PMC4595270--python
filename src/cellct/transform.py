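"""Scale conversion and normalisation.

Three steps, composing in documented order only:

* ``invert_ct``:    raw Ct -> expression (``LOD - Ct``; not-detected -> 0)
* ``normalize_housekeeping``: additive shift so every cell's housekeeping
  median hits a common reference (usable on raw or inverted scale)
* ``z_transform``:  centre/scale along genes or cells
"""

from __future__ import annotations

import warnings
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .errors import InputError
from .experiment import Experiment


def invert_ct(exp: Experiment, lod: Optional[float] = None) -> Experiment:
    """Map each detected Ct ``v`` to ``lod - v`` (clamped at 0 for supra-LOD
    cycles); not-detected entries become 0, i.e. expression at the floor.
    """
    exp.require_stage("invert_ct", "raw_ct")
    lod = exp.lod if lod is None else float(lod)
    if lod <= 0:
        raise InputError(f"LOD must be positive, got {lod}")
    values = exp.matrix.to_numpy()
    detected = exp.detected.to_numpy()
    inverted = np.where(detected, np.clip(lod - values, 0.0, None), 0.0)
    if detected.any() and (inverted[detected] == 0).all():
        warnings.warn(
            f"LOD {lod} is at or below every observed Ct; all expression is 0",
            stacklevel=2,
        )
    out = exp.evolve(
        matrix=pd.DataFrame(inverted, index=exp.matrix.index, columns=exp.matrix.columns),
        stage="inverted",
        lod=lod,
    )
    out.log.append("invert_ct", {"lod": lod}, {"n_cells": out.n_cells})
    return out


def normalize_housekeeping(exp: Experiment, hk_genes: Sequence[str]) -> Experiment:
    """Shift each cell so its housekeeping-gene median equals the common
    reference (the median over cells of per-cell housekeeping medians).

    The shift is additive on the cycle scale, i.e. multiplicative in
    linear expression space. Cells with no detected housekeeping gene are
    left unchanged and flagged in the log. Within-cell differences
    between genes are preserved exactly.
    """
    exp.require_stage("normalize_housekeeping", "raw_ct", "inverted")
    hk = list(hk_genes)
    if not hk:
        raise InputError("no housekeeping genes supplied")
    missing = [g for g in hk if g not in exp.matrix.columns]
    if missing:
        raise InputError(f"housekeeping genes not on panel: {missing}")

    det_hk = exp.detected[hk].to_numpy()
    val_hk = exp.matrix[hk].to_numpy()
    n = exp.n_cells
    medians = np.full(n, np.nan)
    for i in range(n):
        d = det_hk[i]
        if d.any():
            medians[i] = np.median(val_hk[i][d])
    usable = ~np.isnan(medians)
    if not usable.any():
        raise InputError("no cell has any detected housekeeping gene")
    reference = float(np.median(medians[usable]))
    # (v - m_c) + M rather than v + (M - m_c): the cell's median element then
    # lands on the reference exactly (no rounding) for odd detected counts
    values = exp.matrix.to_numpy()
    centred = values - np.where(usable, medians, 0.0)[:, None]
    shifted = centred + np.where(usable, reference, 0.0)[:, None]
    flagged = [c for c, u in zip(exp.cells, usable) if not u]
    out = exp.evolve(
        matrix=pd.DataFrame(shifted, index=exp.matrix.index, columns=exp.matrix.columns),
        stage="hk_normalised",
    )
    out.log.append(
        "normalize_housekeeping",
        {"hk_genes": hk, "reference": reference},
        {"n_flagged_no_hk": len(flagged), "flagged_cells": flagged},
    )
    return out


def z_transform(
    exp: Experiment, axis: str = "per_gene", denominator: str = "sample"
) -> Experiment:
    """Centre and scale expression along the chosen axis.

    axis ``per_gene`` standardises each gene over cells, ``per_cell``
    each cell over genes. ``denominator`` selects the sample (ddof=1,
    default) or population (ddof=0) standard deviation. Zero-variance
    vectors map to all-zeros with a warning instead of erroring, so
    all-dropout genes stay visible downstream.
    """
    exp.require_stage("z_transform", "inverted", "hk_normalised")
    if axis not in ("per_gene", "per_cell"):
        raise InputError(f"axis must be 'per_gene' or 'per_cell', got {axis!r}")
    if denominator not in ("sample", "population"):
        raise InputError(f"denominator must be 'sample' or 'population', got {denominator!r}")
    ddof = 1 if denominator == "sample" else 0
    values = exp.matrix.to_numpy(copy=True)
    ax = 0 if axis == "per_gene" else 1

    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)  # all-NaN slices handled below
        mean = np.nanmean(values, axis=ax, keepdims=True)
        sd = np.nanstd(values, axis=ax, ddof=ddof, keepdims=True)
    constant = ~(sd > 0)  # includes NaN sd (single value / all missing)
    n_constant = int(constant.sum())
    if n_constant:
        warnings.warn(
            f"{n_constant} zero-variance {'gene(s)' if ax == 0 else 'cell(s)'} "
            "mapped to all-zeros",
            stacklevel=2,
        )
    safe_sd = np.where(constant, 1.0, sd)
    mean = np.where(np.isnan(mean), 0.0, mean)
    z = (values - mean) / safe_sd
    z = np.where(np.broadcast_to(constant, z.shape), 0.0, z)
    z = np.where(np.isnan(values), np.nan, z)
    out = exp.evolve(
        matrix=pd.DataFrame(z, index=exp.matrix.index, columns=exp.matrix.columns),
        stage="z_transformed",
    )
    out.log.append(
        "z_transform",
        {"axis": axis, "denominator": denominator},
        {"n_zero_variance": n_constant},
    )
    return out
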