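import json

import numpy as np
import pytest
from click.testing import CliRunner

from cellct.cli import main
from cellct.errors import InputError, StageError
from cellct.experiment import _frames_identical
from cellct.io_formats import load_session
from cellct.session import (
    cluster_step,
    import_data,
    replay,
    resume,
    run_pipeline,
)
from cellct.synthetic_fixtures import SimConfig, simulate_experiment


@pytest.fixture(scope="module")
def sim_files(tmp_path_factory):
    outdir = tmp_path_factory.mktemp("simdata")
    cfg = SimConfig(n_groups=3, cells_per_group=12, n_genes=16,
                    n_marker_genes_per_group=4, control_genes=2,
                    failed_control_fraction=0.1, seed=5)
    manifest, truth = simulate_experiment(cfg, outdir)
    return manifest, truth


def _config(manifest, **overrides):
    config = {
        "lod": 40.0,
        "plates": [
            {"path": p, "dialect": d, "plate_id": pid}
            for p, d, pid in manifest["plates"]
        ],
        "index": [{"path": p, "plate_id": pid} for p, pid in manifest["index"]],
        "control_genes": ["CTRL1"],
        "filter": {"rules": ["CTRL1:24:detected", "CTRL2:24:detected"]},
        "z": {"axis": "per_gene"},
        "embed": {"method": "pca", "k": 3},
        "cluster": {"method": "kmeans", "k": 3, "seed": 0, "restarts": 10},
    }
    config.update(overrides)
    return config


def test_full_pipeline_run(tmp_path, sim_files):
    manifest, truth = sim_files
    state = run_pipeline(_config(manifest), tmp_path / "out")
    exp = state.experiment
    assert exp.stage == "z_transformed"
    assert (tmp_path / "out" / "session.zip").exists()
    assert (tmp_path / "out" / "report.html").exists()
    assert len(exp.log) >= 9
    ops = [e.operation for e in exp.log]
    assert "apply_cell_filter" in ops and "cluster" in ops
    # failed-control cells were removed
    assert exp.n_cells == 36 - len(truth.failed_cells)


def test_pipeline_without_index_skips_index_heatmap(tmp_path, sim_files):
    manifest, _ = sim_files
    state = run_pipeline(_config(manifest, index=[]), tmp_path / "noix")
    ops = [e.operation for e in state.experiment.log]
    assert "index_heatmap_skipped" in ops
    assert state.experiment.index_markers is None


def test_pipeline_writes_only_inside_outdir(tmp_path, sim_files, monkeypatch):
    manifest, _ = sim_files
    out = tmp_path / "sandboxed"
    cwd_before = sorted(p.name for p in tmp_path.iterdir())
    run_pipeline(_config(manifest), out)
    after = sorted(p.name for p in tmp_path.iterdir())
    assert after == sorted(cwd_before + ["sandboxed"])


def test_stage_order_violation_names_stage(sim_files):
    manifest, _ = sim_files
    exp = import_data(_config(manifest))
    from cellct.transform import z_transform

    with pytest.raises(StageError) as exc:
        z_transform(exp)  # before inversion
    assert "raw_ct" in str(exc.value)
    assert "inverted" in str(exc.value)


def test_resume_identity_and_log_append(tmp_path, sim_files):
    manifest, _ = sim_files
    state = run_pipeline(_config(manifest), tmp_path / "o1")
    archive = tmp_path / "o1" / "session.zip"
    st2 = resume(archive)
    # identical apart from the appended resume entry
    assert _frames_identical(st2.experiment.matrix, state.experiment.matrix)
    assert st2.experiment.grouping == state.experiment.grouping
    assert len(st2.experiment.log) == len(state.experiment.log) + 1
    assert st2.experiment.log.entries[-1].operation == "resume"


def test_resume_then_recluster_same_seed_identical(tmp_path, sim_files):
    manifest, _ = sim_files
    state = run_pipeline(_config(manifest), tmp_path / "o2")
    st2 = resume(tmp_path / "o2" / "session.zip")
    re = cluster_step(st2.experiment, {"method": "kmeans", "k": 3, "seed": 0,
                                       "restarts": 10})
    assert re.grouping == state.experiment.grouping


def test_replay_reproduces_matrices_bit_exactly(tmp_path, sim_files):
    manifest, _ = sim_files
    state = run_pipeline(_config(manifest), tmp_path / "o3")
    replayed = replay(tmp_path / "o3" / "session.zip")
    assert _frames_identical(replayed.matrix, state.experiment.matrix)
    assert _frames_identical(replayed.detected, state.experiment.detected)
    assert replayed.grouping == state.experiment.grouping


def test_replay_after_save_resume_save(tmp_path, sim_files):
    manifest, _ = sim_files
    run_pipeline(_config(manifest), tmp_path / "o4")
    st = resume(tmp_path / "o4" / "session.zip")
    st.save(tmp_path / "o4" / "session2.zip")
    replayed = replay(tmp_path / "o4" / "session2.zip")
    saved, _ = load_session(tmp_path / "o4" / "session2.zip")
    assert _frames_identical(replayed.matrix, saved.matrix)


def test_import_errors():
    with pytest.raises(InputError, match="no input plates"):
        import_data({"plates": []})
    with pytest.raises(InputError, match="dialect"):
        import_data({"plates": [{"path": "x", "dialect": "bogus"}]})


def test_cluster_on_index(sim_files):
    manifest, _ = sim_files
    exp = import_data(_config(manifest))
    from cellct.transform import invert_ct, z_transform

    exp = z_transform(invert_ct(exp))
    out = cluster_step(exp, {"method": "kmeans", "k": 2, "on": "index", "seed": 0})
    out.grouping.validate_against(out.cells)


# ---------------------------------------------------------------------------
# CLI


def test_cli_simulate_import_normalize_cluster(tmp_path):
    runner = CliRunner()
    r = runner.invoke(main, ["simulate", "-o", str(tmp_path / "d"), "--groups", "2",
                             "--cells-per-group", "8", "--genes", "10", "--seed", "3"])
    assert r.exit_code == 0, r.output
    manifest = json.loads(r.output)
    plate_args = []
    for p, d, pid in manifest["plates"]:
        plate_args += ["--plate", f"{p},{d},{pid}"]
    index_args = []
    for p, pid in manifest["index"]:
        index_args += ["--index", f"{p},{pid}"]
    archive = str(tmp_path / "s.zip")
    r = runner.invoke(main, ["import", *plate_args, *index_args, "-o", archive])
    assert r.exit_code == 0, r.output
    assert "16 cells" in r.output

    r = runner.invoke(main, ["qc", "-s", archive, "--control", "CTRL1"])
    assert r.exit_code == 0, r.output

    r = runner.invoke(main, ["filter", "-s", archive, "--filter", "CTRL1:24:detected"])
    assert r.exit_code == 0, r.output

    r = runner.invoke(main, ["normalize", "-s", archive])
    assert r.exit_code == 0, r.output
    assert "z_transformed" in r.output

    r = runner.invoke(main, ["cluster", "-s", archive, "-k", "2"])
    assert r.exit_code == 0, r.output

    r = runner.invoke(main, ["plot", "violin", "-s", archive, "--gene", "G001",
                             "-o", str(tmp_path / "figs")])
    assert r.exit_code == 0, r.output

    r = runner.invoke(main, ["report", "-s", archive, "-o", str(tmp_path / "r.html")])
    assert r.exit_code == 0, r.output

    r = runner.invoke(main, ["resume", "-s", archive])
    assert r.exit_code == 0 and "stage=z_transformed" in r.output


def test_cli_exit_code_2_on_input_error(tmp_path):
    runner = CliRunner()
    bad = tmp_path / "bad.tsv"
    bad.write_text("id\tG1\nA1\toops\n")
    r = runner.invoke(main, ["import", "--plate", f"{bad},matrix", "-o",
                             str(tmp_path / "s.zip")])
    assert r.exit_code == 2


def test_cli_exit_code_3_on_stage_error(tmp_path):
    runner = CliRunner()
    r = runner.invoke(main, ["simulate", "-o", str(tmp_path / "d"), "--groups", "2",
                             "--cells-per-group", "4", "--genes", "8", "--seed", "1"])
    manifest = json.loads(r.output)
    plate_args = []
    for p, d, pid in manifest["plates"]:
        plate_args += ["--plate", f"{p},{d},{pid}"]
    archive = str(tmp_path / "s.zip")
    runner.invoke(main, ["import", *plate_args, "-o", archive])
    # normalize twice: second inversion violates the stage machine
    runner.invoke(main, ["normalize", "-s", archive])
    r = runner.invoke(main, ["normalize", "-s", archive])
    assert r.exit_code == 3


def test_cli_run_and_replay(tmp_path):
    runner = CliRunner()
    r = runner.invoke(main, ["simulate", "-o", str(tmp_path / "d"), "--groups", "2",
                             "--cells-per-group", "10", "--genes", "12", "--seed", "2"])
    manifest = json.loads(r.output)
    config = {
        "lod": 40.0,
        "plates": [{"path": p, "dialect": d, "plate_id": pid}
                   for p, d, pid in manifest["plates"]],
        "index": [{"path": p, "plate_id": pid} for p, pid in manifest["index"]],
        "filter": {"rules": ["CTRL1:24:detected"]},
        "cluster": {"method": "kmeans", "k": 2, "seed": 0},
    }
    cfg_path = tmp_path / "config.json"
    cfg_path.write_text(json.dumps(config))
    r = runner.invoke(main, ["run", "-c", str(cfg_path), "-o", str(tmp_path / "out")])
    assert r.exit_code == 0, r.output
    r = runner.invoke(main, ["replay", "-s", str(tmp_path / "out" / "session.zip")])
    assert r.exit_code == 0, r.output
    assert "matches archive" in r.output
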