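"""Hex-lattice geometry, consistency scores, co-localization and rings."""

import numpy as np
import pandas as pd
import pytest

from multilesion import spatial
from multilesion.spatial import NEIGHBOR_OFFSETS

from conftest import make_adata  # noqa: F401  (shared sys.path hook)


def full_lattice(n_rows, n_cols):
    coords = [(r, 2 * j + r % 2) for r in range(n_rows) for j in range(n_cols)]
    return pd.DataFrame(
        {"row": [r for r, _ in coords], "col": [c for _, c in coords]},
        index=[f"s{r}_{c}" for r, c in coords],
    )


def brute_force_edges(coords):
    """O(n^2) pairwise offset scan — independent of the graph builder."""
    pts = list(zip(coords["row"], coords["col"], coords.index))
    edges = set()
    for r1, c1, b1 in pts:
        for r2, c2, b2 in pts:
            if b1 < b2 and (r2 - r1, c2 - c1) in NEIGHBOR_OFFSETS:
                edges.add((b1, b2))
    return edges


def test_interior_degree_six_and_isolated_degree_zero():
    g = spatial.build_neighbor_graph(full_lattice(5, 5))
    assert g.degree["s2_4"] == 6
    lone = pd.DataFrame({"row": [0], "col": [0]}, index=["only"])
    assert spatial.build_neighbor_graph(lone).degree["only"] == 0


def test_graph_matches_brute_force_on_random_sublattices():
    rng = np.random.default_rng(0)
    base = full_lattice(8, 8)
    for _ in range(10):
        sub = base.iloc[rng.random(len(base)) < 0.6]
        g = spatial.build_neighbor_graph(sub)
        got = {tuple(sorted(e)) for e in g.edges}
        assert got == brute_force_edges(sub)
        degrees = [d for _, d in g.degree]
        assert max(degrees, default=0) <= 6


def test_coordinate_validation():
    bad = pd.DataFrame({"row": [0], "col": [1]}, index=["x"])
    with pytest.raises(ValueError, match="parity|even"):
        spatial.build_neighbor_graph(bad)
    dup = pd.DataFrame({"row": [0, 0], "col": [0, 0]}, index=["a", "b"])
    with pytest.raises(ValueError, match="duplicate"):
        spatial.build_neighbor_graph(dup)


def test_dominant_type_assignment():
    probs = pd.DataFrame(
        [[1.0, 0.0, 0.0], [0.4, 0.4, 0.2], [0.0, 0.0, 0.0]],
        columns=["T", "B", "Myeloid"], index=["s1", "s2", "s3"],
    )
    with pytest.raises(ValueError, match="zero"):
        spatial.assign_dominant_type(probs)
    labels = spatial.assign_dominant_type(probs.iloc[:2])
    assert labels["s1"] == "T"
    assert labels["s2"] == "B"  # tie breaks lexicographically
    # matches a brute-force max scan on random rows
    rng = np.random.default_rng(1)
    rand = pd.DataFrame(rng.random((50, 4)), columns=list("DCBA"))
    got = spatial.assign_dominant_type(rand)
    for i in rand.index:
        row = rand.loc[i]
        best = min([c for c in rand.columns if row[c] == row.max()])
        assert got[i] == best


def test_consistency_uniform_and_half_matching():
    coords = full_lattice(7, 7)
    g = spatial.build_neighbor_graph(coords)
    labels = pd.Series("A", index=coords.index)
    scores = spatial.consistency_scores(g, labels)
    assert scores["s3_7"] == 1.0
    # flip 3 of the 6 neighbors of an interior spot
    center = (3, 7)
    nbrs = [f"s{center[0] + dr}_{center[1] + dc}" for dr, dc in NEIGHBOR_OFFSETS]
    labels.loc[nbrs[:3]] = "B"
    assert spatial.consistency_scores(g, labels)[f"s{center[0]}_{center[1]}"] == 0.5


def test_consistency_mean_under_iid_labels_close_to_inverse_T():
    coords = full_lattice(15, 15)
    g = spatial.build_neighbor_graph(coords)
    rng = np.random.default_rng(2)
    T = 4
    means = []
    for _ in range(10):
        labels = pd.Series(rng.integers(T, size=len(coords)).astype(str),
                           index=coords.index)
        means.append(spatial.consistency_scores(g, labels).mean())
    se = np.std(means, ddof=1) / np.sqrt(len(means))
    assert abs(np.mean(means) - 1 / T) < 4 * se + 1e-3


def test_isolated_spot_has_missing_score():
    coords = pd.DataFrame({"row": [0, 10], "col": [0, 10]}, index=["a", "b"])
    g = spatial.build_neighbor_graph(coords)
    scores = spatial.consistency_scores(g, pd.Series("A", index=coords.index))
    assert scores.isna().all()


def test_colocalization_trivial_and_oracle():
    coords = full_lattice(6, 6)
    g = spatial.build_neighbor_graph(coords)
    uniform = pd.Series("A", index=coords.index)
    prof = spatial.colocalization_profile(g, uniform)
    assert prof.to_dict() == {("A", "A"): 1.0}

    pair = pd.DataFrame({"row": [0, 0], "col": [0, 2]}, index=["a", "b"])
    gp = spatial.build_neighbor_graph(pair)
    assert spatial.colocalization_profile(
        gp, pd.Series({"a": "A", "b": "B"})
    ).to_dict() == {("A", "B"): 1.0}

    # stripes vs brute-force edge enumeration
    labels = pd.Series(
        ["A" if r % 2 == 0 else "B" for r in coords["row"]], index=coords.index
    )
    prof = spatial.colocalization_profile(g, labels)
    brute = {}
    for a, b in g.edges:
        key = tuple(sorted((labels[a], labels[b])))
        brute[key] = brute.get(key, 0) + 1
    total = sum(brute.values())
    for key, count in brute.items():
        assert prof[key] == pytest.approx(count / total)
    assert prof.sum() == pytest.approx(1.0)


def test_colocalization_relabeling_invariance():
    coords = full_lattice(6, 6)
    g = spatial.build_neighbor_graph(coords)
    rng = np.random.default_rng(3)
    labels = pd.Series(rng.choice(["A", "B", "C"], len(coords)),
                       index=coords.index)
    prof = spatial.colocalization_profile(g, labels)
    swap = {"A": "X", "B": "Y", "C": "Z"}
    prof2 = spatial.colocalization_profile(g, labels.map(swap))
    for (a, b), v in prof.items():
        assert prof2[tuple(sorted((swap[a], swap[b])))] == pytest.approx(v)


def test_single_spot_rings_are_hexagonal():
    coords = full_lattice(15, 15)
    g = spatial.build_neighbor_graph(coords)
    rings = spatial.region_rings(g, {"s7_7"}, n_rings=3)
    assert [len(rings[r]) for r in (1, 2, 3)] == [6, 12, 18]
    seen = {"s7_7"}
    for r in (1, 2, 3):
        assert not rings[r] & seen  # disjoint from region and earlier rings
        seen |= rings[r]


def test_truncated_rings_match_bfs_oracle():
    import networkx as nx

    rng = np.random.default_rng(4)
    base = full_lattice(9, 9)
    for _ in range(5):
        sub = base.iloc[rng.random(len(base)) < 0.7]
        g = spatial.build_neighbor_graph(sub)
        region = set(rng.choice(sub.index, size=3, replace=False))
        rings = spatial.region_rings(g, region, n_rings=3)
        # oracle: shortest-path distance from an auxiliary source node
        aux = g.copy()
        aux.add_node("__src__")
        for s in region:
            aux.add_edge("__src__", s)
        dist = nx.single_source_shortest_path_length(aux, "__src__")
        for r in (1, 2, 3):
            expected = {n for n, d in dist.items()
                        if d == r + 1 and n not in region and n != "__src__"}
            assert rings[r] == expected
    with pytest.raises(ValueError, match="empty region"):
        spatial.region_rings(g, set())


def test_region_environment_composition():
    coords = full_lattice(13, 13)
    g = spatial.build_neighbor_graph(coords)
    labels = pd.Series("Immune", index=coords.index)
    center = {"s6_6"}
    patch = center | set().union(*spatial.region_rings(g, center, 1).values())
    labels.loc[list(patch)] = "Epithelial"

    res = spatial.compare_region_environment(g, labels, patch, n_rings=3)
    assert res.loc["Epithelial", "delta"] > 0
    assert res["delta"].sum() == pytest.approx(0.0, abs=1e-12)
    assert res["p_value"].isna().all()  # single region: descriptive only

    # identically labeled region and environment: zero deltas
    uniform = pd.Series("A", index=coords.index)
    res_u = spatial.compare_region_environment(g, uniform, patch)
    assert res_u["delta"].abs().max() == 0.0

    # two regions activate the rank-sum contrast
    res2 = spatial.compare_region_environment(
        g, labels, {"r1": patch, "r2": {"s10_10", "s10_12"}}, n_rings=2
    )
    assert res2["p_value"].notna().all()
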