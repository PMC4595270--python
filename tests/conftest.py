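import numpy as np
import pandas as pd
import pytest

from cellct.experiment import AnalysisLog, Experiment
from cellct.grouping import Group, Grouping, palette_color
from cellct.synthetic_fixtures import SimConfig, simulate_to_experiment, worked_micro_fixture


@pytest.fixture
def micro():
    return worked_micro_fixture()


@pytest.fixture(scope="session")
def small_sim():
    """3-group simulated experiment, small enough for fast tests."""
    cfg = SimConfig(
        n_groups=3,
        cells_per_group=12,
        n_genes=12,
        n_marker_genes_per_group=3,
        control_genes=2,
        seed=7,
    )
    return simulate_to_experiment(cfg)


def random_experiment(seed: int, n_cells: int = 8, n_genes: int = 5,
                      with_index: bool = True, with_grouping: bool = True) -> Experiment:
    """Random raw-Ct experiment for round-trip/property tests."""
    rng = np.random.default_rng(seed)
    cells = [f"P1:A{i + 1:02d}" for i in range(n_cells)]
    genes = [f"g{j}" for j in range(n_genes)]
    values = rng.uniform(10, 39, size=(n_cells, n_genes))
    detected = rng.random((n_cells, n_genes)) > 0.2
    values = np.where(detected, values, np.nan)
    matrix = pd.DataFrame(values, index=cells, columns=genes)
    det = pd.DataFrame(detected, index=cells, columns=genes)
    index_markers = None
    if with_index:
        m = rng.normal(500, 100, size=(n_cells, 3))
        m[rng.random((n_cells, 3)) < 0.2] = np.nan
        index_markers = pd.DataFrame(m, index=cells, columns=["M1", "M2", "M3"])
    grouping = None
    if with_grouping:
        half = n_cells // 2
        grouping = Grouping(
            [
                Group("low", palette_color(0), frozenset(cells[:half])),
                Group("high", palette_color(1), frozenset(cells[half:])),
            ],
            source="1d",
        )
    log = AnalysisLog()
    log.append("concatenate_plates", {"plates": ["P1"], "lod": 40.0}, {"n_cells": n_cells})
    return Experiment(
        matrix=matrix,
        detected=det,
        stage="raw_ct",
        lod=40.0,
        plate_order=["P1"],
        index_markers=index_markers,
        grouping=grouping,
        log=log,
    )
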