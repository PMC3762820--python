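"""Sørensen dissimilarity, Monte Carlo tests, abundance change, β-diversity."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from forestchange.change import (abundance_change_table, beta_diversity,
                                 change_per_town, group_permutation,
                                 paired_monte_carlo, sorensen, sorensen_matrix)
from forestchange.datamodel import (MODERN, PRECOLONIAL, CompositionTable,
                                    DataError)
from forestchange.taxa import TaxonSet


def comp_table(rows, era, taxa=None, towns=None):
    taxa = taxa or TaxonSet()
    rows = np.asarray(rows, dtype=float)
    padded = np.zeros((len(rows), len(taxa)))
    padded[:, :rows.shape[1]] = rows
    towns = towns or [f"T{i}" for i in range(len(rows))]
    return CompositionTable(towns, taxa, padded, era)


@pytest.mark.parametrize("x,y,expected", [
    ([0.5, 0.5, 0.0], [0.5, 0.5, 0.0], 0.0),
    ([1.0, 0.0], [0.0, 1.0], 1.0),                      # disjoint supports
    ([0.6, 0.4], [0.2, 0.8], 0.4),                      # (0.4+0.4)/2
    ([0.3, 0.3, 0.4], [0.4, 0.3, 0.3], 0.1),
])
def test_sorensen_values(x, y, expected):
    assert sorensen(np.array(x), np.array(y)) == pytest.approx(expected)


def test_sorensen_length_mismatch():
    with pytest.raises(DataError):
        sorensen(np.array([1.0]), np.array([0.5, 0.5]))


@settings(max_examples=100, deadline=None, derandomize=True)
@given(st.lists(st.floats(0.01, 10), min_size=3, max_size=8),
       st.lists(st.floats(0.01, 10), min_size=3, max_size=8))
def test_sorensen_semimetric_properties(a, b):
    """Symmetric, bounded in [0,1], zero iff equal (on the simplex)."""
    k = min(len(a), len(b))
    x = np.array(a[:k]) / np.sum(a[:k])
    y = np.array(b[:k]) / np.sum(b[:k])
    d = sorensen(x, y)
    assert 0.0 <= d <= 1.0 + 1e-12
    assert d == pytest.approx(sorensen(y, x))
    assert sorensen(x, x) == pytest.approx(0.0, abs=1e-12)


def test_sorensen_matrix_equals_double_loop(rng):
    v = rng.dirichlet(np.ones(6), size=12)
    m = sorensen_matrix(v)
    for i in range(12):
        for j in range(12):
            brute = (np.abs(v[i] - v[j]).sum()) / (v[i] + v[j]).sum()
            assert abs(m[i, j] - brute) <= 1e-12


def test_change_identical_tables_is_zero():
    t = comp_table([[0.5, 0.5], [0.2, 0.8]], PRECOLONIAL)
    m = comp_table([[0.5, 0.5], [0.2, 0.8]], MODERN)
    res = change_per_town(t, m)
    np.testing.assert_allclose(res.per_town["change"], 0.0, atol=1e-12)


def test_change_full_swap_is_one():
    t = comp_table([[1.0, 0.0]], PRECOLONIAL)
    m = comp_table([[0.0, 1.0]], MODERN)
    res = change_per_town(t, m)
    assert res.per_town["change"].iloc[0] == pytest.approx(1.0)


def test_change_mismatched_towns_error():
    t = comp_table([[1.0, 0.0]], PRECOLONIAL, towns=["A"])
    m = comp_table([[1.0, 0.0]], MODERN, towns=["B"])
    with pytest.raises(DataError, match="one era only"):
        change_per_town(t, m)


def test_paired_mc_identical_is_one():
    x = np.linspace(0.1, 0.9, 20)
    assert paired_monte_carlo(x, x, n_rand=500, seed=0) == 1.0


def test_paired_mc_constant_shift_hits_floor():
    pre = np.full(701, 0.5)
    mod = pre - 0.3
    p = paired_monte_carlo(pre, mod, n_rand=10_000, seed=0)
    assert p == pytest.approx(1 / 10_001)


def test_paired_mc_column_swap_invariance(rng):
    a, b = rng.random(30), rng.random(30)
    p1 = paired_monte_carlo(a, b, n_rand=999, seed=5)
    p2 = paired_monte_carlo(b, a, n_rand=999, seed=5)
    assert p1 == p2


def test_group_permutation_identical_groups():
    vals = np.array([0.1, 0.2, 0.3, 0.1, 0.2, 0.3])
    labels = np.array(["a", "a", "a", "b", "b", "b"])
    res = group_permutation(vals, labels, n_rand=500, seed=0)
    assert res["p"].iloc[0] == 1.0


def test_group_permutation_separated_means_hits_floor(rng):
    vals = np.concatenate([rng.normal(0, 1, 40), rng.normal(10, 1, 40)])
    labels = np.array(["a"] * 40 + ["b"] * 40)
    res = group_permutation(vals, labels, n_rand=999, seed=0)
    assert res["p"].iloc[0] == pytest.approx(1 / 1000)


def test_group_permutation_degenerate_group_flagged():
    vals = np.array([1.0, 2.0, 3.0, 9.0])
    labels = np.array(["a", "a", "a", "b"])
    res = group_permutation(vals, labels, n_rand=99, seed=0)
    assert bool(res["degenerate"].iloc[0])
    assert np.isnan(res["p"].iloc[0])


def test_beta_diversity_identical_towns_zero():
    rows = [[0.5, 0.5]] * 4
    pre = comp_table(rows, PRECOLONIAL)
    mod = comp_table(rows, MODERN)
    res = beta_diversity(pre, mod, n_rand=199, seed=0)
    np.testing.assert_allclose(res.per_town["mean_dissimilarity"], 0.0, atol=1e-12)


def test_beta_diversity_hand_arithmetic():
    """Pairwise distances {0.2, 0.6, 0.4} give per-town means {0.4, 0.3, 0.5}."""
    rows = [[1.0, 0.0], [0.8, 0.2], [0.4, 0.6]]
    pre = comp_table(rows, PRECOLONIAL)
    mod = comp_table(rows, MODERN)
    res = beta_diversity(pre, mod, n_rand=199, seed=0)
    m = res.per_town[res.per_town["era"] == PRECOLONIAL]
    np.testing.assert_allclose(m["mean_dissimilarity"], [0.4, 0.3, 0.5], atol=1e-12)


def test_beta_diversity_order_invariance(rng):
    v = rng.dirichlet(np.ones(5), size=6)
    pre = comp_table(v, PRECOLONIAL, towns=list("ABCDEF"))
    mod = comp_table(v[::-1], MODERN, towns=list("FEDCBA"))
    r1 = beta_diversity(pre, mod, n_rand=99, seed=0)
    means1 = r1.per_town.set_index(["town_id", "era"])["mean_dissimilarity"]
    perm = ["C", "A", "F", "B", "E", "D"]
    r2 = beta_diversity(pre, mod, towns=perm, n_rand=99, seed=0)
    means2 = r2.per_town.set_index(["town_id", "era"])["mean_dissimilarity"]
    for key in means1.index:
        assert means1[key] == pytest.approx(means2[key], abs=1e-12)


def test_beta_diversity_needs_three_towns():
    pre = comp_table([[1.0, 0.0], [0.5, 0.5]], PRECOLONIAL)
    mod = comp_table([[1.0, 0.0], [0.5, 0.5]], MODERN)
    with pytest.raises(DataError):
        beta_diversity(pre, mod)


def test_abundance_change_extirpated_taxon():
    taxa = TaxonSet()
    pre = comp_table([[0.9, 0.1], [0.7, 0.3]], PRECOLONIAL)
    mod = comp_table([[1.0, 0.0], [1.0, 0.0]], MODERN)
    table = abundance_change_table(pre, mod, n_rand=199, seed=0)
    second = table[table["taxon"] == taxa.codes[1]].iloc[0]
    assert second["mod_mean"] == 0.0
    assert second["delta"] == pytest.approx(-second["pre_mean"])
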