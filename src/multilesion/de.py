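"""Rank-sum differential expression, marker detection, signature scoring and
hypergeometric gene-set enrichment.

The workhorse is the two-sided Wilcoxon rank-sum test. Small groups (both
sides at most 8 cells, or any comparison whose combination count stays under
``MAX_EXACT_COMBINATIONS`` in the 1-D helper) are tested by exhaustive
rank-permutation enumeration with midranks, which is exact under ties;
larger groups use the tie-corrected normal approximation. Fold changes are
average log2 ratios of back-transformed group means with a pseudocount of 1:

    avg_log2FC = log2((mean(expm1(x_A)) + 1) / (mean(expm1(x_B)) + 1))

computed over log-normalized expression, the formula used by the single-cell
framework generation this pipeline mirrors (re-expressed in base 2).
"""

from __future__ import annotations

import functools
import itertools
import logging
import math
import warnings

import anndata as ad
import numpy as np
import pandas as pd
import scipy.sparse as sp
from scipy import stats

from .qc import _to_dense

logger = logging.getLogger(__name__)

MAX_EXACT_COMBINATIONS = 200_000


@functools.lru_cache(maxsize=8)
def _combo_matrix(n: int, n_a: int) -> np.ndarray:
    return np.array(list(itertools.combinations(range(n), n_a)))


# ---------------------------------------------------------------------------
# rank-sum internals
# ---------------------------------------------------------------------------

def _exact_ranksum_pvalues(ranks: np.ndarray, n_a: int) -> np.ndarray:
    """Exhaustive two-sided rank-permutation p-values.

    ``ranks``: (n_cells, n_genes) midranks of the pooled sample; group A is
    the first ``n_a`` rows. The p-value is the fraction of the C(n, n_a)
    assignments whose rank sum deviates from its mean at least as much as
    the observed one.
    """
    n = ranks.shape[0]
    combos = _combo_matrix(n, n_a)
    mu = n_a * (n + 1) / 2.0
    obs = ranks[:n_a].sum(axis=0)
    # (n_combos, n_a, n_genes) -> (n_combos, n_genes)
    sums = ranks[combos].sum(axis=1)
    dev = np.abs(sums - mu)
    return (dev >= np.abs(obs - mu) - 1e-9).mean(axis=0)


def _normal_ranksum_pvalues(ranks: np.ndarray, n_a: int) -> np.ndarray:
    """Tie-corrected normal-approximation two-sided p-values (vectorized)."""
    n = ranks.shape[0]
    n_b = n - n_a
    w = ranks[:n_a].sum(axis=0)
    mu = n_a * (n + 1) / 2.0
    tie_term = np.empty(ranks.shape[1])
    for j in range(ranks.shape[1]):
        _, counts = np.unique(ranks[:, j], return_counts=True)
        tie_term[j] = (counts**3 - counts).sum()
    var = n_a * n_b / 12.0 * ((n + 1) - tie_term / (n * (n - 1)))
    p = np.ones(ranks.shape[1])
    pos = var > 0
    z = (w[pos] - mu) / np.sqrt(var[pos])
    p[pos] = np.minimum(1.0, 2.0 * stats.norm.sf(np.abs(z)))
    return p


def rank_sum_test(x, y, max_exact: int = MAX_EXACT_COMBINATIONS) -> float:
    """Two-sided rank-sum p-value for two 1-D samples.

    Exact by enumeration when C(n, n_a) is affordable, else tie-corrected
    normal approximation.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) < 2 or len(y) < 2:
        raise ValueError("each group needs at least 2 observations")
    pooled = np.concatenate([x, y])
    ranks = stats.rankdata(pooled)[:, None]
    if math.comb(len(pooled), len(x)) <= max_exact:
        return float(_exact_ranksum_pvalues(ranks, len(x))[0])
    return float(_normal_ranksum_pvalues(ranks, len(x))[0])


def bh_qvalues(p: np.ndarray) -> np.ndarray:
    """Benjamini–Hochberg adjusted p-values."""
    return stats.false_discovery_control(np.clip(np.asarray(p, float), 0, 1))


# ---------------------------------------------------------------------------
# DE on tables
# ---------------------------------------------------------------------------

def average_log2_fc(xa: np.ndarray, xb: np.ndarray) -> np.ndarray:
    """Pseudocount-stabilized log2 ratio of back-transformed group means."""
    mean_a = np.expm1(xa).mean(axis=0)
    mean_b = np.expm1(xb).mean(axis=0)
    return np.log2((mean_a + 1.0) / (mean_b + 1.0))


def rank_sum_de(adata: ad.AnnData, mask_a, mask_b) -> pd.DataFrame:
    """Per-gene two-sided rank-sum DE between two disjoint cell groups.

    Returns a DataFrame indexed by gene with ``p_value``, ``avg_log2FC``,
    ``pct_in``, ``pct_out`` (fraction of cells with a nonzero raw count) and
    BH ``q_value``. Exact enumeration is used when both groups have at most
    8 cells.
    """
    if "lognorm" not in adata.uns:
        raise ValueError("normalize_log must run before rank_sum_de")
    mask_a = np.asarray(mask_a, dtype=bool)
    mask_b = np.asarray(mask_b, dtype=bool)
    if (mask_a & mask_b).any():
        raise ValueError("groups must be disjoint")
    n_a, n_b = int(mask_a.sum()), int(mask_b.sum())
    if n_a < 2 or n_b < 2:
        raise ValueError("each group needs at least 2 cells")

    xa = _to_dense(adata.X[mask_a])
    xb = _to_dense(adata.X[mask_b])
    pooled = np.vstack([xa, xb])
    ranks = stats.rankdata(pooled, axis=0)
    if n_a <= 8 and n_b <= 8:
        p = _exact_ranksum_pvalues(ranks, n_a)
    else:
        p = _normal_ranksum_pvalues(ranks, n_a)

    counts = adata.layers["counts"] if "counts" in adata.layers else adata.X
    counts = sp.csr_matrix(counts)
    pct_in = np.asarray((counts[mask_a] > 0).sum(axis=0)).ravel() / n_a
    pct_out = np.asarray((counts[mask_b] > 0).sum(axis=0)).ravel() / n_b

    return pd.DataFrame(
        {
            "p_value": p,
            "avg_log2FC": average_log2_fc(xa, xb),
            "pct_in": pct_in,
            "pct_out": pct_out,
            "q_value": bh_qvalues(p),
        },
        index=adata.var_names.copy(),
    )


def find_markers(
    adata: ad.AnnData,
    labels,
    lfc_threshold: float = 0.5,
    min_pct: float = 0.2,
    only_pos: bool = True,
) -> dict[str, pd.DataFrame]:
    """One-vs-rest markers per label, Wilcoxon test with the printed gates.

    A gene survives for a label when avg_log2FC ≥ ``lfc_threshold`` (absolute
    value when ``only_pos`` is off), max(pct_in, pct_out) ≥ ``min_pct``, and
    the fold change is positive under ``only_pos``. Labels with fewer than 3
    cells are skipped with a warning. Results are sorted by p-value.
    """
    labels = pd.Series(np.asarray(labels), index=adata.obs_names)
    uniq = sorted(labels.unique())
    if len(uniq) < 2:
        raise ValueError("need at least 2 labels for marker detection")
    out: dict[str, pd.DataFrame] = {}
    for lab in uniq:
        mask = (labels == lab).to_numpy()
        if mask.sum() < 3:
            warnings.warn(f"label {lab!r} has < 3 cells; skipped")
            continue
        de = rank_sum_de(adata, mask, ~mask)
        lfc = de["avg_log2FC"]
        keep = np.maximum(de["pct_in"], de["pct_out"]) >= min_pct
        if only_pos:
            keep &= lfc >= lfc_threshold
        else:
            keep &= lfc.abs() >= lfc_threshold
        out[lab] = de[keep].sort_values(["p_value", "avg_log2FC"],
                                        ascending=[True, False])
    return out


def shared_markers(marker_sets: list[set[str]]) -> set[str]:
    """Exact intersection of marker gene sets across samples."""
    if len(marker_sets) < 2:
        raise ValueError("need at least 2 marker sets to intersect")
    return set.intersection(*(set(s) for s in marker_sets))


def signature_geneset(markers: pd.DataFrame, n: int = 15) -> list[str]:
    """Top-``n`` markers ranked by p-value; ties break toward the larger
    fold change, then by symbol."""
    if markers.empty:
        raise ValueError("marker table is empty")
    ranked = markers.sort_values(
        by=["p_value", "avg_log2FC"], ascending=[True, False],
        kind="mergesort",
    )
    # stable final tie-break on the symbol itself
    key = pd.DataFrame({
        "p": ranked["p_value"], "nlfc": -ranked["avg_log2FC"],
        "sym": ranked.index,
    })
    order = key.sort_values(["p", "nlfc", "sym"], kind="mergesort").index
    return list(order[:n])


def signature_score(adata: ad.AnnData, gene_set) -> pd.Series:
    """Mean of per-gene z-scores of log-normalized expression over the set.

    Zero-variance genes contribute 0. Errors when no set gene is present.
    """
    present = [g for g in adata.var_names if g in set(gene_set)]
    if not present:
        raise ValueError("no signature gene present in the table")
    X = _to_dense(adata[:, present].X)
    mu = X.mean(axis=0)
    sd = X.std(axis=0)
    z = np.zeros_like(X)
    nz = sd > 0
    z[:, nz] = (X[:, nz] - mu[nz]) / sd[nz]
    return pd.Series(z.mean(axis=1), index=adata.obs_names, name="signature_score")


def hypergeom_enrich(
    query: set[str],
    sets: dict[str, set[str]],
    universe: set[str],
) -> pd.DataFrame:
    """Upper-tail hypergeometric enrichment of ``query`` against named sets.

    Each set is intersected with the universe first; BH q-values are
    reported alongside. P(X ≥ k) for k = |query ∩ set| drawn from a universe
    of size M with |set| successes in |query| draws.
    """
    query = set(query)
    universe = set(universe)
    if not query:
        raise ValueError("empty query gene set")
    if not query <= universe:
        raise ValueError("query must be a subset of the universe")
    rows = []
    for name, genes in sets.items():
        s = set(genes) & universe
        k = len(query & s)
        p = stats.hypergeom.sf(k - 1, len(universe), len(s), len(query))
        rows.append((name, k, len(s), min(1.0, float(p))))
    df = pd.DataFrame(rows, columns=["set", "overlap", "set_size", "p_value"])
    df = df.set_index("set")
    df["q_value"] = bh_qvalues(df["p_value"].to_numpy()) if len(df) else []
    return df
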