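"""Differential expression: fold change, Student t, BH FDR, joint gate."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

import _oracles as oracles
from cncnet.diffexpr import (ExpressionMatrix, bh_adjust, fold_change, run_de,
                             student_t_pvalue)
from cncnet.errors import DegenerateInputError, DomainError


def _matrix(rows, rna_types=None, n_per_group=3):
    ids = sorted(rows)
    cols = [f"C{i}" for i in range(n_per_group)] + \
           [f"B{i}" for i in range(n_per_group)]
    values = pd.DataFrame([rows[i] for i in ids], index=ids, columns=cols)
    groups = pd.Series(["control"] * n_per_group + ["case"] * n_per_group,
                       index=cols)
    types = pd.Series({i: (rna_types or {}).get(i, "mRNA") for i in ids})
    return ExpressionMatrix(values, types, groups)


@pytest.mark.parametrize("control,case,fc,direction", [
    ([2, 2, 2], [4, 4, 4], 2.0, "up"),
    ([4, 4, 4], [2, 2, 2], 2.0, "down"),
    ([1, 1, 1], [1, 1, 1], 1.0, "none"),
])
def test_fold_change_examples(control, case, fc, direction):
    got_fc, got_dir = fold_change(control, case)
    assert got_fc == pytest.approx(fc)
    assert got_dir == direction


@settings(deadline=None, max_examples=50, derandomize=True)
@given(st.lists(st.floats(0.01, 100), min_size=2, max_size=6),
       st.lists(st.floats(0.01, 100), min_size=2, max_size=6))
def test_fold_change_reciprocal_symmetry(a, b):
    fc_ab, dir_ab = fold_change(a, b)
    fc_ba, dir_ba = fold_change(b, a)
    assert fc_ab == pytest.approx(fc_ba, rel=1e-12)
    if dir_ab != "none":
        assert {dir_ab, dir_ba} == {"up", "down"}


def test_fold_change_rejects_nonpositive():
    with pytest.raises(DomainError):
        fold_change([1, 0, 2], [1, 1, 1])


def test_t_identical_groups_p_one():
    assert student_t_pvalue([1, 2, 3], [1, 2, 3]) == pytest.approx(1.0)


def test_t_against_integration_oracle():
    # [1,2,3] vs [4,5,6]: t = -3.674 at df = 4, two-tailed p ~ 0.021
    t = oracles.pooled_t_stat([1, 2, 3], [4, 5, 6])
    assert t == pytest.approx(3.0 / np.sqrt(2.0 / 3.0), rel=1e-12)
    expected = oracles.t_two_tailed_oracle(t, 4)
    assert expected == pytest.approx(0.0212, abs=2e-4)
    assert student_t_pvalue([1, 2, 3], [4, 5, 6]) == pytest.approx(
        expected, rel=1e-9)


def test_t_zero_variance_conventions():
    assert student_t_pvalue([5, 5], [5, 5]) == 1.0
    with pytest.raises(DegenerateInputError):
        student_t_pvalue([5, 5], [6, 6])


def test_bh_worked_example():
    np.testing.assert_allclose(bh_adjust([0.01, 0.02, 0.03, 0.04]),
                               [0.04, 0.04, 0.04, 0.04])
    np.testing.assert_allclose(bh_adjust([0.05]), [0.05])


def test_bh_constant_vector_unchanged():
    np.testing.assert_allclose(bh_adjust([0.2] * 7), [0.2] * 7)


def test_bh_rejects_out_of_range():
    with pytest.raises(DomainError):
        bh_adjust([0.5, 1.5])


@settings(deadline=None, max_examples=100, derandomize=True)
@given(st.lists(st.floats(0, 1), min_size=1, max_size=25))
def test_bh_matches_double_loop_oracle(pvals):
    got = bh_adjust(pvals)
    expected = oracles.bh_oracle(pvals)
    np.testing.assert_array_equal(got, expected)
    assert (got >= np.asarray(pvals) - 1e-15).all()


def test_bh_permutation_invariance():
    rng = np.random.default_rng(0)
    p = rng.uniform(size=40)
    perm = rng.permutation(40)
    np.testing.assert_allclose(bh_adjust(p)[perm], bh_adjust(p[perm]))


def test_run_de_fc_gate_blocks_small_changes():
    rng = np.random.default_rng(1)
    rows = {f"P{i}": 2 ** (8 + rng.normal(0, 0.01, 6)) for i in range(20)}
    # strong p but fc = 1.5 only
    rows["P_small"] = np.array([100.0, 100.1, 99.9, 150.0, 150.1, 149.9])
    de = run_de(_matrix(rows))
    assert not de.table.loc["P_small", "passes"]
    assert de.table.loc["P_small", "p"] < 1e-6


def test_run_de_largest_reported_change_passes():
    # a probe with fold change 7.86 and clean separation passes as "up"
    rng = np.random.default_rng(2)
    rows = {f"P{i}": 2 ** (8 + rng.normal(0, 0.05, 6)) for i in range(30)}
    base = np.array([1.0, 1.01, 0.99])
    rows["P_top"] = np.concatenate([base, 7.86 * base])
    de = run_de(_matrix(rows))
    row = de.table.loc["P_top"]
    assert row.passes and row.direction == "up"
    assert row.fc == pytest.approx(7.86, rel=1e-2)


def test_run_de_flat_probe_convention_and_errors():
    rows = {"FLAT": [4.0] * 6, "BROKEN": [1.0] * 3 + [2.0] * 3,
            "OK": [1, 1.1, 0.9, 4, 4.1, 3.9]}
    de = run_de(_matrix(rows))
    assert de.table.loc["FLAT", "p"] == 1.0
    assert not de.table.loc["FLAT", "passes"]
    assert ("BROKEN", "zero pooled variance with unequal means") in de.errors
    assert not de.table.loc["BROKEN", "passes"]
    assert de.table.loc["OK", "fc"] == pytest.approx(4.0, rel=0.05)


def test_run_de_stratified_vs_pooled_bh():
    rng = np.random.default_rng(3)
    rows, types = {}, {}
    for i in range(30):
        rows[f"M{i}"] = 2 ** (8 + rng.normal(0, 0.2, 6))
        types[f"M{i}"] = "mRNA"
    for i in range(30):
        rows[f"L{i}"] = 2 ** (8 + rng.normal(0, 0.2, 6))
        types[f"L{i}"] = "lncRNA"
    m = _matrix(rows, types)
    strat = run_de(m)
    # BH within each class equals BH run on that class's p-values alone
    for cls in ("mRNA", "lncRNA"):
        sub = strat.table[strat.table.rna_type == cls]
        np.testing.assert_allclose(sub["q"], bh_adjust(sub["p"].to_numpy()))
    pooled = run_de(m, pool_strata=True)
    np.testing.assert_allclose(pooled.table["q"],
                               bh_adjust(pooled.table["p"].to_numpy()))


def test_run_de_q_dominates_p(std_bundle):
    de = run_de(std_bundle.matrix)
    ok = ~de.table["q"].isna()
    assert (de.table.loc[ok, "q"] >= de.table.loc[ok, "p"] - 1e-15).all()


def test_run_de_partitions_match_table(small_bundle):
    de = run_de(small_bundle.matrix)
    for (cls, direction), ids in de.partitions.items():
        sub = de.table[de.table.passes & (de.table.rna_type == cls)
                       & (de.table.direction == direction)]
        assert sorted(sub.index) == ids
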