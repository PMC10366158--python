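"""Expression-derived relative copy-number profiles and malignancy calling.

The copy signal is estimated per gene as log2 expression minus the mean of
a reference cell population (immune cells in practice), clipped to ±3
reference standard deviations and smoothed by a centered moving average
along genomic order within each chromosome, followed by per-cell median
re-centering. Malignancy is called by k-means (k = 7 by default) over
reference and epithelial observation cells jointly: epithelial cells
landing in reference-dominated clusters are non-malignant, all others
malignant. Lesion-specific clones are found by re-clustering the malignant
cells (k = 4) and flagging clusters dominated by one lesion.
"""

from __future__ import annotations

import re
import warnings
from dataclasses import dataclass

import anndata as ad
import numpy as np
import pandas as pd
from sklearn.cluster import KMeans

from .qc import _to_dense

LN2 = np.log(2.0)


@dataclass
class CNVMatrix:
    """Cells × genomic-bin relative copy signal with per-cell metadata.

    ``cell_meta`` carries boolean ``reference`` and ``epithelial`` flags and
    a ``lesion`` column; ``bin_meta`` carries chromosome and ordered
    position.
    """

    values: np.ndarray
    bin_meta: pd.DataFrame
    cell_meta: pd.DataFrame

    def __post_init__(self) -> None:
        if self.values.shape != (len(self.cell_meta), len(self.bin_meta)):
            raise ValueError("values shape does not match metadata")
        if "reference" not in self.cell_meta:
            raise ValueError("cell_meta must carry a 'reference' flag column")

    def subset_cells(self, mask) -> "CNVMatrix":
        mask = np.asarray(mask, dtype=bool)
        return CNVMatrix(self.values[mask].copy(),
                         self.bin_meta.copy(),
                         self.cell_meta[mask].copy())


@dataclass
class MalignancyCall:
    """Joint k-means clusters, per-cluster reference fractions and per-cell
    malignant flags (defined for epithelial observation cells)."""

    assignments: pd.DataFrame  # cell_meta + cluster + malignant
    cluster_ref_fraction: pd.Series

    @property
    def malignant_mask(self) -> np.ndarray:
        return self.assignments["malignant"].fillna(False).to_numpy(dtype=bool)


def _chrom_sort_key(c: str):
    m = re.match(r"(?:chr)?(\d+|[XYM]T?)$", str(c), re.IGNORECASE)
    if m:
        tok = m.group(1).upper()
        if tok.isdigit():
            return (0, int(tok), "")
        return (1, 0, tok)
    return (2, 0, str(c))


def estimate_cnv(
    adata: ad.AnnData,
    gene_order: pd.DataFrame,
    ref_mask,
    window: int = 101,
    clip_sd: float = 3.0,
) -> CNVMatrix:
    """Smoothed relative copy profiles versus a reference population.

    ``gene_order`` maps gene → (chromosome, position); genes missing from it
    are dropped. Chromosomes shorter than ``window`` genes shrink the
    smoothing window to their size (with a warning).
    """
    ref_mask = np.asarray(ref_mask, dtype=bool)
    if not ref_mask.any():
        raise ValueError("reference mask selects no cells")
    order = gene_order.copy()
    order["_ckey"] = order["chromosome"].map(_chrom_sort_key)
    order = order.sort_values(["_ckey", "position"], kind="mergesort")
    genes = [g for g in order["gene"] if g in set(adata.var_names)]
    if not genes:
        raise ValueError("no gene of the table is present in the order file")
    sub = adata[:, genes]
    # log2-scale expression from the natural-log normalized layer
    expr = _to_dense(sub.X) / LN2

    ref_mean = expr[ref_mask].mean(axis=0)
    ref_sd = expr[ref_mask].std(axis=0)
    resid = np.clip(expr - ref_mean, -clip_sd * ref_sd, clip_sd * ref_sd)

    chrom = order.set_index("gene").loc[genes, "chromosome"].to_numpy()
    smoothed = np.empty_like(resid)
    for c in pd.unique(chrom):
        idx = np.where(chrom == c)[0]
        if len(idx) < window:
            warnings.warn(f"chromosome {c}: only {len(idx)} genes; "
                          "smoothing window shrinks to chromosome size")
        block = pd.DataFrame(resid[:, idx].T)
        smoothed[:, idx] = (
            block.rolling(window, center=True, min_periods=1).mean().to_numpy().T
        )
    smoothed -= np.median(smoothed, axis=1, keepdims=True)

    cell_meta = pd.DataFrame(index=adata.obs_names.copy())
    cell_meta["reference"] = ref_mask
    cell_meta["lesion"] = (
        adata.obs["lesion"].to_numpy() if "lesion" in adata.obs else ""
    )
    if "cell_type" in adata.obs:
        cell_meta["epithelial"] = (
            adata.obs["cell_type"].astype(str).str.lower().eq("epithelial").to_numpy()
        )
    else:
        cell_meta["epithelial"] = ~ref_mask
    bin_meta = order.set_index("gene").loc[genes, ["chromosome", "position"]]
    return CNVMatrix(smoothed, bin_meta, cell_meta)


def call_malignancy(cnv: CNVMatrix, k: int = 7, seed: int = 0) -> MalignancyCall:
    """Joint k-means over reference + epithelial observation cells.

    Clusters whose reference fraction reaches 0.5 are reference-dominated
    (the tie resolves conservatively to non-malignant); epithelial
    observation cells elsewhere are called malignant. Reference cells are
    never flagged.
    """
    meta = cnv.cell_meta
    use = meta["reference"].to_numpy() | meta["epithelial"].to_numpy()
    values = cnv.values[use]
    if not meta["reference"].any():
        raise ValueError("at least one reference cell is required")
    if k > values.shape[0]:
        raise ValueError(f"k={k} exceeds the {values.shape[0]} clustered cells")
    if not (meta["reference"][use].any() and (~meta["reference"][use]).any()):
        raise ValueError("need both reference and observation cells")
    km = KMeans(n_clusters=k, n_init=10, random_state=seed)
    labels = km.fit_predict(values) + 1  # clusters 1..k

    assignments = meta.copy()
    assignments["cluster"] = pd.array([np.nan] * len(meta), dtype="Int64")
    assignments.loc[use, "cluster"] = labels
    is_ref = meta["reference"][use].to_numpy()
    ref_frac = pd.Series(
        {c: is_ref[labels == c].mean() for c in range(1, k + 1)},
        name="reference_fraction",
    )
    nonmal_clusters = set(ref_frac[ref_frac >= 0.5].index)
    malignant = pd.Series(pd.NA, index=meta.index, dtype="boolean")
    epi_obs = use & ~meta["reference"].to_numpy()
    malignant[epi_obs] = [
        c not in nonmal_clusters for c in assignments.loc[epi_obs, "cluster"]
    ]
    malignant[meta["reference"].to_numpy()] = False
    assignments["malignant"] = malignant
    return MalignancyCall(assignments, ref_frac)


def lesion_specific_clusters(
    cnv: CNVMatrix,
    k: int = 4,
    seed: int = 0,
    specificity: float = 0.75,
) -> pd.DataFrame:
    """Re-cluster malignant epithelial CNV profiles and report lesion shares.

    ``cnv`` should already be restricted to malignant epithelial cells. A
    cluster is lesion-specific when one lesion contributes at least
    ``specificity`` of its cells. Returns one row per cluster with size,
    per-lesion shares and the specific lesion (or None).
    """
    lesions = cnv.cell_meta["lesion"].astype(str)
    uniq = sorted(lesions.unique())
    if len(uniq) < 2:
        raise ValueError("need at least 2 lesions")
    for les in uniq:
        if (lesions == les).sum() < k:
            warnings.warn(f"lesion {les!r} has fewer than k={k} cells")
    km = KMeans(n_clusters=k, n_init=10, random_state=seed)
    labels = km.fit_predict(cnv.values) + 1

    rows = []
    for c in range(1, k + 1):
        in_c = labels == c
        shares = {les: float((lesions[in_c] == les).mean()) for les in uniq}
        specific = [les for les, s in shares.items() if s >= specificity]
        rows.append({"cluster": c, "size": int(in_c.sum()),
                     **{f"share_{les}": shares[les] for les in uniq},
                     "specific_lesion": specific[0] if specific else None})
    return pd.DataFrame(rows).set_index("cluster")
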