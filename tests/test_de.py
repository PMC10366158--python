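"""Rank-sum DE against enumeration oracles, marker gates, signatures and
hypergeometric enrichment."""

import itertools
import math

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from multilesion import de

from conftest import make_adata, make_lognorm_adata


# ---------------------------------------------------------------------------
# oracles
# ---------------------------------------------------------------------------

def ranksum_oracle(x, y):
    """Exhaustive two-sided rank-permutation p-value (independent of the
    package: direct enumeration of label assignments)."""
    pooled = np.concatenate([x, y])
    ranks = stats.rankdata(pooled)
    n, n_a = len(pooled), len(x)
    mu = n_a * (n + 1) / 2
    obs = abs(ranks[:n_a].sum() - mu)
    hits = total = 0
    for combo in itertools.combinations(range(n), n_a):
        total += 1
        if abs(ranks[list(combo)].sum() - mu) >= obs - 1e-9:
            hits += 1
    return hits / total


def hypergeom_oracle(universe_n, set_n, query_n, min_overlap):
    """P(overlap >= k) by exhaustive enumeration of all query draws."""
    hits = total = 0
    for draw in itertools.combinations(range(universe_n), query_n):
        total += 1
        if sum(1 for g in draw if g < set_n) >= min_overlap:
            hits += 1
    return hits / total


# ---------------------------------------------------------------------------
# rank-sum DE
# ---------------------------------------------------------------------------

def test_small_sample_p_matches_rank_permutation_oracle():
    rng = np.random.default_rng(3)
    values = rng.normal(size=(8, 6))
    values[:, 2] = [1, 1, 2, 2, 5, 6, 7, 8]  # strong separation with ties
    adata = make_lognorm_adata(values)
    mask_a = np.array([True] * 4 + [False] * 4)
    result = de.rank_sum_de(adata, mask_a, ~mask_a)
    for j, gene in enumerate(adata.var_names):
        expected = ranksum_oracle(values[:4, j], values[4:, j])
        assert result.loc[gene, "p_value"] == pytest.approx(expected, abs=1e-12)


def test_rank_sum_test_exact_matches_oracle_with_ties():
    x = [1.0, 1.0, 3.0, 4.0]
    y = [2.0, 2.0, 2.0, 5.0]
    assert de.rank_sum_test(x, y) == pytest.approx(ranksum_oracle(x, y))


def test_identical_groups_give_zero_fold_change_and_flat_p():
    rng = np.random.default_rng(0)
    block = rng.normal(1.0, 0.3, size=(30, 10)).clip(0)
    values = np.vstack([block, block[rng.permutation(30)]])
    adata = make_lognorm_adata(values)
    mask_a = np.arange(60) < 30
    result = de.rank_sum_de(adata, mask_a, ~mask_a)
    assert np.allclose(result["avg_log2FC"], 0.0, atol=1e-12)
    assert (result["p_value"] > 0.2).all()


def test_gene_expressed_only_in_group_a_has_zero_pct_out():
    counts = np.zeros((20, 3))
    counts[:10, 0] = 5
    counts[:, 1] = 1
    counts[:, 2] = 2
    adata = make_lognorm_adata(np.log1p(counts), counts=counts)
    result = de.rank_sum_de(adata, np.arange(20) < 10, np.arange(20) >= 10)
    assert result.loc["g0", "pct_out"] == 0.0
    assert result.loc["g0", "pct_in"] == 1.0


def test_p_values_approximately_uniform_under_null():
    rng = np.random.default_rng(5)
    values = np.abs(rng.normal(size=(100, 300)))
    adata = make_lognorm_adata(values)
    mask_a = np.arange(100) < 50
    p = de.rank_sum_de(adata, mask_a, ~mask_a)["p_value"]
    assert stats.kstest(p, "uniform").pvalue > 0.01


def test_group_validation():
    adata = make_lognorm_adata(np.random.default_rng(0).normal(size=(6, 3)))
    both = np.array([True] * 6)
    with pytest.raises(ValueError, match="disjoint"):
        de.rank_sum_de(adata, both, both)
    with pytest.raises(ValueError, match="at least 2"):
        de.rank_sum_de(adata, np.arange(6) < 1, np.arange(6) >= 1)


# ---------------------------------------------------------------------------
# markers
# ---------------------------------------------------------------------------

def _marker_fixture():
    rng = np.random.default_rng(7)
    counts = rng.poisson(3.0, (60, 5))
    counts[:20, 0] *= 8          # exclusive marker of cluster A
    counts[:, 3] = 0
    counts[:2, 3] = 3  # expressed in 10% of cluster A and nowhere else
    labels = ["A"] * 20 + ["B"] * 20 + ["C"] * 20
    from multilesion import qc
    return qc.normalize_log(make_adata(counts + (counts.sum(1) == 0)[:, None])), labels


def test_find_markers_gates_and_exclusive_marker():
    adata, labels = _marker_fixture()
    markers = de.find_markers(adata, labels)
    assert "g0" in markers["A"].index
    assert "g0" not in markers["B"].index and "g0" not in markers["C"].index
    # min.pct gate: a gene in <20% of its cluster and 0% elsewhere is excluded
    assert "g3" not in markers["A"].index
    # everything reported survives the fold-change gate
    for table in markers.values():
        assert (table["avg_log2FC"] >= 0.5).all()


def test_find_markers_skips_tiny_labels():
    adata, labels = _marker_fixture()
    labels = list(labels)
    labels[0] = "rare"
    with pytest.warns(UserWarning, match="rare"):
        markers = de.find_markers(adata, labels)
    assert "rare" not in markers


def test_shared_markers_exact_intersection():
    sets = [{"a", "b", "c"}, {"b", "c", "d"}, {"c", "b", "e"}]
    assert de.shared_markers(sets) == {"b", "c"}
    assert de.shared_markers([{"a"}, {"b"}]) == set()
    same = {"x", "y"}
    assert de.shared_markers([same, set(same)]) == same
    # a planted 28-gene overlap across three sample marker lists
    core = {f"m{i}" for i in range(28)}
    three = [core | {f"s{j}_{i}" for i in range(10)} for j in range(3)]
    assert len(de.shared_markers(three)) == 28


def test_signature_geneset_matches_sort_oracle():
    rng = np.random.default_rng(9)
    table = pd.DataFrame(
        {
            "p_value": rng.choice([1e-5, 1e-4, 1e-3], size=40),
            "avg_log2FC": rng.normal(1, 0.2, size=40).round(2),
        },
        index=[f"g{i:02d}" for i in range(40)],
    )
    got = de.signature_geneset(table, n=15)
    oracle = sorted(
        table.index, key=lambda g: (table.loc[g, "p_value"],
                                    -table.loc[g, "avg_log2FC"], g)
    )[:15]
    assert got == oracle
    assert de.signature_geneset(table.iloc[:15], n=15) == sorted(
        table.index[:15],
        key=lambda g: (table.loc[g, "p_value"], -table.loc[g, "avg_log2FC"], g),
    )


def test_signature_score_separates_planted_cells():
    rng = np.random.default_rng(2)
    values = rng.normal(1.0, 0.2, size=(40, 20)).clip(0)
    values[:15, :5] += 1.0  # planted over-expression of the set genes
    adata = make_lognorm_adata(values)
    gene_set = [f"g{i}" for i in range(5)]
    scores = de.signature_score(adata, gene_set)
    assert scores[:15].min() > scores[15:].max()
    # invariant to gene order; constant matrix scores 0
    assert np.allclose(scores, de.signature_score(adata, gene_set[::-1]))
    flat = de.signature_score(make_lognorm_adata(np.ones((10, 6))), ["g0", "g1"])
    assert np.allclose(flat, 0.0)
    with pytest.raises(ValueError, match="no signature gene"):
        de.signature_score(adata, ["absent"])


# ---------------------------------------------------------------------------
# hypergeometric enrichment
# ---------------------------------------------------------------------------

def test_hypergeom_matches_combinatorial_oracle():
    universe = {f"u{i}" for i in range(20)}
    geneset = {f"u{i}" for i in range(5)}
    query = {"u0", "u1", "u2", "u3", "u19"}  # overlap 4
    res = de.hypergeom_enrich(query, {"s": geneset}, universe)
    assert res.loc["s", "overlap"] == 4
    assert res.loc["s", "p_value"] == pytest.approx(
        hypergeom_oracle(20, 5, 5, 4), rel=1e-12
    )


def test_hypergeom_degenerate_cases():
    universe = {f"u{i}" for i in range(10)}
    sets = {"all": set(list(universe)[:4]), "off": {"x", "y"}}
    res = de.hypergeom_enrich(universe, sets, universe)
    assert res.loc["all", "overlap"] == 4
    assert res.loc["all", "p_value"] == pytest.approx(1.0)
    assert res.loc["off", "p_value"] == pytest.approx(1.0)  # disjoint
    with pytest.raises(ValueError, match="empty query"):
        de.hypergeom_enrich(set(), sets, universe)
    with pytest.raises(ValueError, match="subset"):
        de.hypergeom_enrich({"zzz"}, sets, universe)
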