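import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from cellct.errors import InputError
from cellct.grouping import (
    Gate2D,
    Group,
    Grouping,
    groups_1d,
    groups_2d,
    groups_from_assignment,
    groups_from_plates,
    merge_groups,
    palette_color,
    reorder_groups,
)

from conftest import random_experiment


def _check_partition(grouping, cells):
    grouping.validate_against(cells)
    colors = [g.color for g in grouping.groups]
    assert len(set(colors)) == len(colors)


# ---------------------------------------------------------------------------
# constructors


def test_groups_from_plates(small_sim):
    exp, _ = small_sim
    g = groups_from_plates(exp)
    assert g.labels == exp.plates
    _check_partition(g, exp.cells)


def test_groups_from_plates_single():
    exp = random_experiment(0, with_grouping=False)
    g = groups_from_plates(exp)
    assert len(g.groups) == 1
    assert g.groups[0].members == frozenset(exp.cells)


def test_groups_from_assignment():
    exp = random_experiment(1, n_cells=10, with_grouping=False)
    assignment = {c: i % 5 + 1 for i, c in enumerate(exp.cells)}
    g = groups_from_assignment(exp, assignment)
    assert g.labels == [f"cluster {k}" for k in range(1, 6)]
    _check_partition(g, exp.cells)


def test_groups_from_assignment_single_cluster():
    exp = random_experiment(2, n_cells=6, with_grouping=False)
    g = groups_from_assignment(exp, {c: 1 for c in exp.cells})
    assert len(g.groups) == 1


def test_groups_from_assignment_missing_cell():
    exp = random_experiment(3, n_cells=4, with_grouping=False)
    partial = {c: 1 for c in exp.cells[:-1]}
    with pytest.raises(InputError, match="cover"):
        groups_from_assignment(exp, partial)


# ---------------------------------------------------------------------------
# 1-D binning


def _exp_with_values(values, gene="G1"):
    import pandas as pd

    from cellct.experiment import AnalysisLog, Experiment

    cells = [f"P1:A{i + 1:02d}" for i in range(len(values))]
    matrix = pd.DataFrame({gene: values}, index=cells)
    det = ~matrix.isna()
    return Experiment(
        matrix=matrix, detected=det, stage="inverted", lod=40.0,
        plate_order=["P1"], log=AnalysisLog(),
    )


def test_1d_basic_binning():
    exp = _exp_with_values([0.0, 5.0, 12.0])
    g = groups_1d(exp, "G1", [10.0])
    assert len(g.groups) == 2
    assert len(g.groups[0].members) == 2  # low bin
    assert len(g.groups[1].members) == 1
    _check_partition(g, exp.cells)


def test_1d_three_singletons():
    exp = _exp_with_values([1.0, 5.0, 12.0])
    g = groups_1d(exp, "G1", [3.0, 9.0])
    assert [len(x.members) for x in g.groups] == [1, 1, 1]


def test_1d_boundary_goes_up():
    exp = _exp_with_values([10.0, 9.999])
    g = groups_1d(exp, "G1", [10.0])
    low, high = g.groups
    assert "P1:A01" in high.members and "P1:A02" in low.members


def test_1d_empty_bins_dropped():
    exp = _exp_with_values([1.0, 2.0])
    g = groups_1d(exp, "G1", [10.0, 20.0])
    assert len(g.groups) == 1


def test_1d_unsorted_cutoffs_sorted_with_warning():
    exp = _exp_with_values([1.0, 5.0, 12.0])
    with pytest.warns(UserWarning, match="sort"):
        g = groups_1d(exp, "G1", [9.0, 3.0])
    assert len(g.groups) == 3


def test_1d_unknown_gene():
    exp = _exp_with_values([1.0])
    with pytest.raises(InputError, match="unknown gene"):
        groups_1d(exp, "Nope", [1.0])


def test_1d_refinement_bruteforce():
    # adding cutoffs only splits bins, never moves cells across old edges
    rng = np.random.default_rng(0)
    vals = rng.uniform(0, 30, size=25)
    exp = _exp_with_values(list(vals))
    coarse = groups_1d(exp, "G1", [10.0])
    fine = groups_1d(exp, "G1", [5.0, 10.0, 20.0])
    coarse_of = coarse.group_of()
    fine_of = fine.group_of()
    for c1 in exp.cells:
        for c2 in exp.cells:
            if fine_of[c1] == fine_of[c2]:
                assert coarse_of[c1] == coarse_of[c2]


# ---------------------------------------------------------------------------
# 2-D gates


def _exp_2genes(xy):
    import pandas as pd

    from cellct.experiment import AnalysisLog, Experiment

    cells = [f"P1:A{i + 1:02d}" for i in range(len(xy))]
    matrix = pd.DataFrame(xy, index=cells, columns=["Gx", "Gy"])
    return Experiment(
        matrix=matrix, detected=~matrix.isna(), stage="inverted", lod=40.0,
        plate_order=["P1"], log=AnalysisLog(),
    )


def test_2d_full_range_gate_no_rest():
    exp = _exp_2genes([[1.0, 1.0], [5.0, 5.0]])
    g = groups_2d(exp, [Gate2D("Gx", "Gy", 0, 10, 0, 10)])
    assert len(g.groups) == 1
    assert g.groups[0].members == frozenset(exp.cells)


def test_2d_boundary_inclusive():
    exp = _exp_2genes([[0.0, 5.0]])
    g = groups_2d(exp, [Gate2D("Gx", "Gy", 0.0, 10.0, 0.0, 10.0)])
    assert g.groups[0].members == frozenset(exp.cells)


def test_2d_first_gate_wins_disjoint():
    exp = _exp_2genes([[5.0, 5.0], [15.0, 15.0]])
    g1 = Gate2D("Gx", "Gy", 0, 10, 0, 10, label="a")
    g2 = Gate2D("Gx", "Gy", 0, 20, 0, 20, label="b")  # overlaps g1
    g = groups_2d(exp, [g1, g2])
    assert g.groups[0].label == "a" and g.groups[0].members == {"P1:A01"}
    assert g.groups[1].members == {"P1:A02"}
    _check_partition(g, exp.cells)


def test_2d_rest_group():
    exp = _exp_2genes([[5.0, 5.0], [50.0, 50.0]])
    g = groups_2d(exp, [Gate2D("Gx", "Gy", 0, 10, 0, 10)])
    assert g.groups[-1].label == "rest"
    assert "P1:A02" in g.groups[-1].members


def test_2d_unknown_gene():
    exp = _exp_2genes([[1.0, 1.0]])
    with pytest.raises(InputError, match="unknown gene"):
        groups_2d(exp, [Gate2D("Gx", "Nope", 0, 1, 0, 1)])


def test_gate_bounds_validated():
    with pytest.raises(InputError):
        Gate2D("a", "b", 5, 1, 0, 1)


# ---------------------------------------------------------------------------
# merge / reorder


def _grouping(sizes, labels=None):
    labels = labels or [chr(ord("A") + i) for i in range(len(sizes))]
    groups, n = [], 0
    for i, (label, size) in enumerate(zip(labels, sizes)):
        members = frozenset(f"c{n + j}" for j in range(size))
        n += size
        groups.append(Group(label, palette_color(i), members))
    return Grouping(groups)


def test_merge_basic():
    g = _grouping([3, 2, 4])
    merged = merge_groups(g, ["A", "B"], "AB")
    assert merged.labels == ["AB", "C"]
    assert len(merged.groups[0].members) == 5
    assert merged.groups[0].color == g.groups[0].color  # earliest member's slot


def test_merge_all():
    g = _grouping([1, 2, 3])
    merged = merge_groups(g, ["A", "B", "C"], "all")
    assert merged.labels == ["all"]
    assert len(merged.groups[0].members) == 6


def test_merge_unknown_label():
    with pytest.raises(InputError, match="unknown"):
        merge_groups(_grouping([1, 1]), ["A", "Z"], "x")


def test_reorder():
    g = _grouping([1, 2, 3])
    r = reorder_groups(g, ["C", "B", "A"])
    assert r.labels == ["C", "B", "A"]
    assert r.groups[0].members == g.groups[2].members
    assert r.groups[0].color == g.groups[2].color  # colours travel


def test_reorder_identity():
    g = _grouping([1, 2])
    r = reorder_groups(g, ["A", "B"])
    assert r.labels == g.labels and r.groups[0].members == g.groups[0].members


def test_reorder_not_permutation():
    with pytest.raises(InputError, match="permutation"):
        reorder_groups(_grouping([1, 1]), ["A", "Z"])


@given(
    sizes=st.lists(st.integers(min_value=1, max_value=4), min_size=3, max_size=6),
    data=st.data(),
)
@settings(max_examples=40, deadline=None)
def test_merge_reorder_commute(sizes, data):
    g = _grouping(sizes)
    labels = g.labels
    pair = data.draw(
        st.lists(st.sampled_from(labels), min_size=2, max_size=2, unique=True)
    )
    # merge then reorder (merged label placed where merge put it)
    m1 = merge_groups(g, pair, "M")
    perm = data.draw(st.permutations(m1.labels))
    a = reorder_groups(m1, perm)
    # reorder first with a compatible permutation, then merge, then apply
    # the same final order
    other = [x for x in labels if x not in pair]
    pre = reorder_groups(g, data.draw(st.permutations(labels)))
    m2 = merge_groups(pre, pair, "M")
    b = reorder_groups(m2, perm)
    assert a.labels == b.labels
    assert [x.members for x in a.groups] == [x.members for x in b.groups]


@given(st.integers(min_value=0, max_value=40))
def test_palette_unique_first_24(i):
    colors = [palette_color(j) for j in range(24)]
    assert len(set(colors)) == 24


def test_grouping_rejects_overlap():
    with pytest.raises(InputError, match="overlap"):
        Grouping(
            [
                Group("a", palette_color(0), frozenset({"c1", "c2"})),
                Group("b", palette_color(1), frozenset({"c2"})),
            ]
        )
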