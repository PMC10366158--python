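"""Five-way inter-lesion gene-concordance classification.

Each patient contributes two tumor-versus-matched-normal DE tables: one for
the inferior-lobe lesion (TI vs NI) and one pooling the remaining lesions
(TOthers vs NOthers). A gene is significant on a side when its p-value is
strictly below ``p_thresh`` (default 0.01) and |avg_log2FC| strictly above
``lfc_thresh`` (default 0.25). The five mutually exclusive, exhaustive
classes are:

* ``Same``    — significant on both sides with the same fold-change sign
                (first/third quadrant of the TI × TOthers log-FC plane);
* ``OP``      — significant on both sides with opposite signs;
* ``TI``      — significant only on the TI side;
* ``TOthers`` — significant only on the other-lesion side;
* ``NotSig``  — everything else.

A p-value exactly at the threshold, or a fold change exactly at the
threshold magnitude, is not significant; a fold change of exactly 0 has no
quadrant and can never be Same or OP.
"""

from __future__ import annotations

import warnings
from collections import namedtuple
from dataclasses import dataclass, field

import anndata as ad
import numpy as np
import pandas as pd

from .de import rank_sum_de

CLASSES = ("Same", "NotSig", "OP", "TI", "TOthers")

SharedMutationCounts = namedtuple(
    "SharedMutationCounts", ["shared", "unique_a", "unique_b"]
)


@dataclass
class MutationSet:
    """Tumor-specific mutations of one lesion as (gene, variant) identifiers."""

    lesion: str
    mutations: set[tuple[str, str]] = field(default_factory=set)


def classify_concordance(
    de_ti: pd.DataFrame,
    de_tothers: pd.DataFrame,
    p_thresh: float = 0.01,
    lfc_thresh: float = 0.25,
) -> pd.DataFrame:
    """Classify every gene of the union universe into the five classes.

    Genes missing from one table are NotSig (with a warning). Returns a
    DataFrame indexed by gene with ``category`` plus the underlying p-values
    and fold changes of both sides.
    """
    if p_thresh <= 0 or lfc_thresh <= 0:
        raise ValueError("thresholds must be positive")
    genes = de_ti.index.union(de_tothers.index)
    missing = len(genes) - len(de_ti.index.intersection(de_tothers.index))
    if missing:
        warnings.warn(f"{missing} genes absent from one DE table -> NotSig")

    def side(de: pd.DataFrame, pcol: str, lcol: str) -> pd.DataFrame:
        out = pd.DataFrame(index=genes)
        out[pcol] = de["p_value"].reindex(genes)
        out[lcol] = de["avg_log2FC"].reindex(genes)
        return out

    df = pd.concat(
        [side(de_ti, "p_TI", "lfc_TI"), side(de_tothers, "p_TOthers", "lfc_TOthers")],
        axis=1,
    )
    sig_ti = (df["p_TI"] < p_thresh) & (df["lfc_TI"].abs() > lfc_thresh)
    sig_to = (df["p_TOthers"] < p_thresh) & (df["lfc_TOthers"].abs() > lfc_thresh)
    sig_ti = sig_ti.fillna(False)
    sig_to = sig_to.fillna(False)
    prod = (df["lfc_TI"] * df["lfc_TOthers"]).fillna(0.0)

    category = pd.Series("NotSig", index=genes, name="category")
    category[sig_ti & ~sig_to] = "TI"
    category[sig_to & ~sig_ti] = "TOthers"
    category[sig_ti & sig_to & (prod > 0)] = "Same"
    category[sig_ti & sig_to & (prod < 0)] = "OP"
    df.insert(0, "category", category)
    df.index.name = "gene"
    return df


def cross_patient_same(records: dict[str, pd.DataFrame]) -> pd.DataFrame:
    """Genes classified Same in every patient, with per-patient signs.

    Returns a DataFrame indexed by gene with one sign column per patient
    (sign of the TI-side fold change, which Same forces to agree with the
    other side) and a ``sign_consistent`` flag across patients.
    """
    if len(records) < 2:
        raise ValueError("need records for at least 2 patients")
    same_sets = [
        set(df.index[df["category"] == "Same"]) for df in records.values()
    ]
    universal = sorted(set.intersection(*same_sets))
    out = pd.DataFrame(index=pd.Index(universal, name="gene"))
    for patient, df in records.items():
        out[f"sign_{patient}"] = np.sign(df["lfc_TI"].reindex(universal))
    signs = out.to_numpy()
    out["sign_consistent"] = (
        (signs == signs[:, :1]).all(axis=1) if len(out) else []
    )
    return out


def lesion_de_pair(
    adata: ad.AnnData,
    patient: str,
    ti_lesion: str = "TI",
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """TI-vs-NI and pooled TOthers-vs-NOthers DE tables for one patient."""
    obs = adata.obs
    mine = (obs["patient"].astype(str) == str(patient)).to_numpy()
    is_ti = (obs["lesion"].astype(str) == ti_lesion).to_numpy()
    tumor = (obs["tissue"].astype(str) == "tumor").to_numpy()
    de_ti = rank_sum_de(adata, mine & is_ti & tumor, mine & is_ti & ~tumor)
    de_to = rank_sum_de(adata, mine & ~is_ti & tumor, mine & ~is_ti & ~tumor)
    return de_ti, de_to


def stratified_concordance(
    adata: ad.AnnData,
    cell_type: str,
    patient: str,
    ti_lesion: str = "TI",
    p_thresh: float = 0.01,
    lfc_thresh: float = 0.25,
    min_cells: int = 3,
) -> pd.DataFrame | None:
    """Concordance classification restricted to one cell type.

    Requires at least ``min_cells`` cells of the type in each of the four
    sample classes (TI tumor/normal, TOthers tumor/normal); otherwise the
    stratum is skipped with a warning and None is returned.
    """
    obs = adata.obs
    in_type = (obs["cell_type"].astype(str) == cell_type).to_numpy()
    mine = (obs["patient"].astype(str) == str(patient)).to_numpy()
    is_ti = (obs["lesion"].astype(str) == ti_lesion).to_numpy()
    tumor = (obs["tissue"].astype(str) == "tumor").to_numpy()
    groups = {
        "TI tumor": mine & in_type & is_ti & tumor,
        "TI normal": mine & in_type & is_ti & ~tumor,
        "TOthers tumor": mine & in_type & ~is_ti & tumor,
        "TOthers normal": mine & in_type & ~is_ti & ~tumor,
    }
    for name, mask in groups.items():
        if mask.sum() < min_cells:
            warnings.warn(
                f"cell type {cell_type!r}, patient {patient!r}: "
                f"{name} has < {min_cells} cells; stratum skipped"
            )
            return None
    sub = adata[in_type].copy()
    de_ti, de_to = lesion_de_pair(sub, patient, ti_lesion)
    return classify_concordance(de_ti, de_to, p_thresh, lfc_thresh)


def shared_mutations(a: MutationSet, b: MutationSet) -> SharedMutationCounts:
    """Shared / lesion-unique counts of (gene, variant) identifiers."""
    inter = a.mutations & b.mutations
    return SharedMutationCounts(
        shared=len(inter),
        unique_a=len(a.mutations - inter),
        unique_b=len(b.mutations - inter),
    )
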