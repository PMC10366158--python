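"""Hexagonal-lattice neighborhood statistics for spatial transcriptomics.

Spots sit on a staggered array addressed by integer (row, col) with
row + col even, so each spot has up to six direct neighbors at offsets
(0, ±2) and (±1, ±1). On that graph the toolkit computes the per-spot
consistency score (fraction of neighbors sharing the spot's dominant cell
type), the co-localization profile (distribution of unordered type pairs
over all adjacent spot pairs), breadth-first rings around annotated
histology regions, and region-versus-environment composition contrasts.
"""

from __future__ import annotations

import numpy as np
import networkx as nx
import pandas as pd

from .de import rank_sum_test

NEIGHBOR_OFFSETS = ((0, 2), (0, -2), (1, 1), (1, -1), (-1, 1), (-1, -1))


def assign_dominant_type(probabilities: pd.DataFrame) -> pd.Series:
    """Argmax cell type per spot; ties break to the lexicographically
    smallest type name. A row of zeros is an error."""
    probs = probabilities[sorted(probabilities.columns)]
    if (probs.to_numpy().sum(axis=1) <= 0).any():
        raise ValueError("probability row(s) sum to zero")
    return probs.idxmax(axis=1).rename("dominant_type")


def build_neighbor_graph(coords: pd.DataFrame) -> nx.Graph:
    """Undirected six-neighbor graph from (row, col) parity coordinates.

    ``coords`` is indexed by barcode with integer ``row``/``col`` columns;
    duplicated coordinates or parity violations are errors.
    """
    rows = coords["row"].to_numpy(dtype=int)
    cols = coords["col"].to_numpy(dtype=int)
    if ((rows + cols) % 2 != 0).any():
        raise ValueError("coordinates must satisfy row + col even")
    pos = {(r, c): b for r, c, b in zip(rows, cols, coords.index)}
    if len(pos) < len(coords):
        raise ValueError("duplicate spot coordinates")
    g = nx.Graph()
    g.add_nodes_from(coords.index)
    for (r, c), barcode in pos.items():
        for dr, dc in NEIGHBOR_OFFSETS:
            other = pos.get((r + dr, c + dc))
            if other is not None:
                g.add_edge(barcode, other)
    return g


def consistency_scores(graph: nx.Graph, labels: pd.Series) -> pd.Series:
    """Fraction of direct neighbors sharing each spot's label.

    Spots with no neighbors get NaN (excluded from summaries).
    """
    labels = labels.astype(str)
    out = {}
    for node in graph.nodes:
        nbrs = list(graph.neighbors(node))
        if not nbrs:
            out[node] = np.nan
        else:
            lab = labels[node]
            out[node] = sum(labels[n] == lab for n in nbrs) / len(nbrs)
    return pd.Series(out, name="consistency_score")


def colocalization_profile(graph: nx.Graph, labels: pd.Series) -> pd.Series:
    """Proportion of adjacent spot pairs per unordered type pair.

    Each edge is counted once; proportions sum to 1. No edges is an error.
    """
    if graph.number_of_edges() == 0:
        raise ValueError("graph has no edges")
    labels = labels.astype(str)
    pairs = [tuple(sorted((labels[a], labels[b]))) for a, b in graph.edges]
    counts = pd.Series(pairs).value_counts().sort_index()
    return (counts / counts.sum()).rename("proportion")


def region_rings(graph: nx.Graph, region, n_rings: int = 3) -> dict[int, set]:
    """Breadth-first rings around a spot region.

    Ring r (1-based) holds the spots at BFS distance exactly r from the
    region; rings are disjoint and exclude the region itself.
    """
    region = set(region)
    if not region:
        raise ValueError("empty region")
    missing = region - set(graph.nodes)
    if missing:
        raise ValueError(f"region spots not in graph: {sorted(missing)[:5]}")
    visited = set(region)
    frontier = set(region)
    rings: dict[int, set] = {}
    for r in range(1, n_rings + 1):
        nxt = set()
        for node in frontier:
            nxt.update(graph.neighbors(node))
        nxt -= visited
        rings[r] = nxt
        visited |= nxt
        frontier = nxt
    return rings


def _proportions(labels: pd.Series, spots, types) -> pd.Series:
    sub = labels.loc[list(spots)]
    return sub.value_counts(normalize=True).reindex(types).fillna(0.0)


def compare_region_environment(
    graph: nx.Graph,
    labels: pd.Series,
    regions,
    n_rings: int = 3,
) -> pd.DataFrame:
    """Cell-type composition of histology regions versus their surroundings.

    ``regions`` is either one spot set or a mapping region-id → spot set.
    The environment of a region is the union of its first ``n_rings`` BFS
    rings. With ≥2 regions a per-type two-sided rank-sum test contrasts the
    region proportions against the environment proportions across regions;
    a single region yields descriptive deltas only (p = NaN).
    """
    labels = labels.astype(str)
    if not isinstance(regions, dict):
        regions = {"region": set(regions)}
    types = sorted(labels.unique())
    reg_props, env_props = {}, {}
    for rid, spots in regions.items():
        spots = set(spots)
        if not spots:
            raise ValueError(f"region {rid!r} is empty")
        rings = region_rings(graph, spots, n_rings)
        env = set().union(*rings.values())
        if not env:
            raise ValueError(f"region {rid!r} has an empty environment")
        reg_props[rid] = _proportions(labels, spots, types)
        env_props[rid] = _proportions(labels, env, types)
    reg = pd.DataFrame(reg_props).T
    env = pd.DataFrame(env_props).T
    out = pd.DataFrame(
        {
            "region_proportion": reg.mean(axis=0),
            "environment_proportion": env.mean(axis=0),
        }
    )
    out["delta"] = out["region_proportion"] - out["environment_proportion"]
    if len(regions) >= 2:
        out["p_value"] = [
            rank_sum_test(reg[t].to_numpy(), env[t].to_numpy()) for t in types
        ]
    else:
        out["p_value"] = np.nan
    out.index.name = "cell_type"
    return out
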