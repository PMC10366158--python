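"""Bootstrap cell-type compositions and inter-sample similarity.

Proportions are reported as mean ± s.d. over bootstrap resamples of the
cells of one sample; sample-to-sample similarity is the Spearman correlation
of composition (or mean-expression) vectors, clustered with average linkage
on 1 − correlation.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster import hierarchy
from scipy.spatial.distance import squareform

from .qc import _to_dense


def bootstrap_proportions(labels, B: int = 1000, seed: int = 0) -> pd.DataFrame:
    """Bootstrap mean ± s.d. of per-type proportions for one sample.

    Cells are resampled with replacement ``B`` times (realized as multinomial
    draws from the empirical composition, which is distributionally
    identical and O(B·T)).
    """
    if B < 2:
        raise ValueError("need at least 2 bootstrap replicates")
    labels = pd.Series(np.asarray(labels))
    if labels.empty:
        raise ValueError("need at least one cell")
    n = len(labels)
    types = sorted(labels.unique())
    emp = labels.value_counts(normalize=True).reindex(types).to_numpy()
    rng = np.random.default_rng(seed)
    reps = rng.multinomial(n, emp, size=B) / n
    return pd.DataFrame(
        {"mean": reps.mean(axis=0), "sd": reps.std(axis=0, ddof=1), "B": B},
        index=pd.Index(types, name="cell_type"),
    )


def composition_delta(prop_a: pd.Series, prop_b: pd.Series) -> pd.Series:
    """|Δproportion| per type; missing types count as 0."""
    types = sorted(set(prop_a.index) | set(prop_b.index))
    a = prop_a.reindex(types).fillna(0.0)
    b = prop_b.reindex(types).fillna(0.0)
    return (a - b).abs()


@dataclass
class SimilarityMatrix:
    """Sample × sample Spearman correlations with a clustering order."""

    corr: pd.DataFrame
    linkage: np.ndarray | None = None
    order: list[str] = field(default_factory=list)


def _spearman_matrix(mat: pd.DataFrame) -> pd.DataFrame:
    """Pairwise Spearman (midranks for ties) over the rows of ``mat``."""
    names = list(mat.index)
    k = len(names)
    corr = np.ones((k, k))
    constant = mat.std(axis=1).to_numpy() == 0
    for i in range(k):
        for j in range(i + 1, k):
            if constant[i] or constant[j]:
                corr[i, j] = corr[j, i] = np.nan
            else:
                corr[i, j] = corr[j, i] = stats.spearmanr(
                    mat.iloc[i], mat.iloc[j]
                ).statistic
    return pd.DataFrame(corr, index=names, columns=names)


def _cluster(corr: pd.DataFrame) -> SimilarityMatrix:
    valid = corr.index[~corr.isna().any(axis=1)]
    if len(valid) < len(corr):
        warnings.warn(
            "constant composition vector(s) excluded from linkage: "
            f"{sorted(set(corr.index) - set(valid))}"
        )
    if len(valid) >= 2:
        dist = 1.0 - corr.loc[valid, valid].to_numpy()
        np.fill_diagonal(dist, 0.0)
        link = hierarchy.average(squareform(dist, checks=False))
        order = [valid[i] for i in hierarchy.leaves_list(link)]
    else:
        link, order = None, list(valid)
    return SimilarityMatrix(corr=corr, linkage=link, order=order)


def composition_similarity(samples: pd.DataFrame) -> SimilarityMatrix:
    """Spearman similarity of composition vectors (samples × types).

    Constant vectors yield undefined correlations: recorded as missing and
    excluded from the average-linkage clustering with a warning.
    """
    if len(samples) < 2:
        raise ValueError("need at least 2 samples")
    return _cluster(_spearman_matrix(samples))


def expression_similarity(tables: dict, variable_genes) -> SimilarityMatrix:
    """Spearman similarity of per-sample mean log-normalized expression over
    a shared variable-gene set; genes absent from a sample count as 0."""
    genes = list(variable_genes)
    if not genes:
        raise ValueError("variable gene set is empty")
    rows = {}
    for name, adata in tables.items():
        present = [g for g in genes if g in adata.var_names]
        if len(present) < len(genes):
            warnings.warn(f"sample {name}: {len(genes) - len(present)} "
                          "variable genes absent, treated as 0")
        vec = pd.Series(0.0, index=genes)
        if present:
            vec[present] = _to_dense(adata[:, present].X).mean(axis=0)
        rows[name] = vec
    return _cluster(_spearman_matrix(pd.DataFrame(rows).T))
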