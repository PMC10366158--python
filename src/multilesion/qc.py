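"""Quality-control filters, normalization and variable-gene selection.

Cells are dropped when they have fewer than 250 detected genes, more than
25% mitochondrial transcripts, or a gene/count complexity ratio
log10(n_genes)/log10(n_counts) at or below 0.75; spots use 250 genes, 20%
mitochondrial and 1% hemoglobin. Fractions are always computed on the raw
matrix before any gene-family exclusion, so dropping MT- genes afterwards
does not change who was filtered.
"""

from __future__ import annotations

import logging
import re
import warnings
from dataclasses import dataclass

import anndata as ad
import numpy as np
import scipy.sparse as sp

logger = logging.getLogger(__name__)

SCALE_FACTOR = 10_000.0

MITO_PREFIX = "MT-"
RIBO_PREFIXES = ("RPS", "RPL")
# hemoglobin symbols start with HB but HBP1 (HMG-box protein) must survive
HEMOGLOBIN_RE = re.compile(r"^HB(?!P)")


@dataclass(frozen=True)
class QCThresholds:
    """Printed filter thresholds; spots use the spot-specific members."""

    min_genes: int = 250
    max_mito_frac: float = 0.25
    max_mito_frac_spots: float = 0.20
    ratio_floor: float = 0.75
    max_hb_frac: float = 0.01

    def __post_init__(self) -> None:
        for f in (self.max_mito_frac, self.max_mito_frac_spots, self.max_hb_frac):
            if not 0.0 <= f <= 1.0:
                raise ValueError("fraction thresholds must lie in [0, 1]")


def _to_dense(x) -> np.ndarray:
    return np.asarray(x.todense()) if sp.issparse(x) else np.asarray(x)


def _counts(adata: ad.AnnData) -> sp.csr_matrix:
    mat = adata.layers["counts"] if "counts" in adata.layers else adata.X
    return sp.csr_matrix(mat)


def _is_mito(symbols) -> np.ndarray:
    return np.array([s.upper().startswith(MITO_PREFIX) for s in symbols])


def _is_hemoglobin(symbols) -> np.ndarray:
    return np.array([bool(HEMOGLOBIN_RE.match(s.upper())) for s in symbols])


def cell_qc_metrics(adata: ad.AnnData) -> dict[str, np.ndarray]:
    """n_genes, n_counts, mito and hemoglobin fractions on the raw matrix."""
    counts = _counts(adata)
    n_genes = np.asarray((counts > 0).sum(axis=1)).ravel()
    n_counts = np.asarray(counts.sum(axis=1)).ravel()
    symbols = adata.var_names
    with np.errstate(divide="ignore", invalid="ignore"):
        mito = np.asarray(counts[:, _is_mito(symbols)].sum(axis=1)).ravel() / n_counts
        hb = np.asarray(counts[:, _is_hemoglobin(symbols)].sum(axis=1)).ravel() / n_counts
        ratio = np.log10(n_genes) / np.log10(n_counts)
    mito = np.nan_to_num(mito)
    hb = np.nan_to_num(hb)
    ratio = np.nan_to_num(ratio)  # degenerate cells fail the gene floor anyway
    return {"n_genes": n_genes, "n_counts": n_counts, "mito_frac": mito,
            "hb_frac": hb, "ratio": ratio}


def filter_cells(adata: ad.AnnData, th: QCThresholds | None = None) -> ad.AnnData:
    """Drop cells violating the gene-floor, mito-fraction or ratio rule.

    Removal counts per rule are logged and stored in
    ``adata.uns['qc_cell_filter']``. Raises if nothing survives, naming the
    rule that removed the most cells.
    """
    th = th or QCThresholds()
    m = cell_qc_metrics(adata)
    rules = {
        "min_genes": m["n_genes"] >= th.min_genes,
        "max_mito_frac": m["mito_frac"] <= th.max_mito_frac,
        "ratio_floor": m["ratio"] > th.ratio_floor,
    }
    return _apply_rules(adata, rules, "qc_cell_filter")


def filter_spots(adata: ad.AnnData, th: QCThresholds | None = None) -> ad.AnnData:
    """Spot analogue of :func:`filter_cells` with the hemoglobin rule."""
    th = th or QCThresholds()
    m = cell_qc_metrics(adata)
    rules = {
        "min_genes": m["n_genes"] >= th.min_genes,
        "max_mito_frac": m["mito_frac"] <= th.max_mito_frac_spots,
        "max_hb_frac": m["hb_frac"] <= th.max_hb_frac,
    }
    return _apply_rules(adata, rules, "qc_spot_filter")


def _apply_rules(adata: ad.AnnData, rules: dict[str, np.ndarray], key: str) -> ad.AnnData:
    keep = np.ones(adata.n_obs, dtype=bool)
    removed = {}
    for name, ok in rules.items():
        removed[name] = int((~ok).sum())
        keep &= ok
    for name, n in removed.items():
        logger.info("%s: rule %s removed %d records", key, name, n)
    if not keep.any():
        binding = max(removed, key=removed.get)
        raise ValueError(f"all records removed by QC; binding rule: {binding}")
    out = adata[keep].copy()
    out.uns[key] = {"removed_per_rule": removed,
                    "n_before": int(adata.n_obs), "n_after": int(keep.sum())}
    return out


def filter_genes(adata: ad.AnnData) -> ad.AnnData:
    """Exclude MALAT1, mitochondrial (MT-), ribosomal (RPS/RPL) and
    hemoglobin (HB*, not HBP*) genes."""
    symbols = np.array([s.upper() for s in adata.var_names])
    drop = (
        (symbols == "MALAT1")
        | _is_mito(symbols)
        | np.array([s.startswith(RIBO_PREFIXES) for s in symbols])
        | _is_hemoglobin(symbols)
    )
    out = adata[:, ~drop].copy()
    out.uns["gene_filter"] = {"removed": int(drop.sum())}
    logger.info("gene filter removed %d genes", int(drop.sum()))
    return out


def normalize_log(adata: ad.AnnData, scale_factor: float = SCALE_FACTOR) -> ad.AnnData:
    """Library-size normalize to ``scale_factor`` counts per cell, then log1p.

    Raw counts are preserved in ``layers['counts']``; ``X`` becomes the
    log-normalized layer. Zero-count cells are an error.
    """
    out = adata.copy()
    counts = _counts(out)
    totals = np.asarray(counts.sum(axis=1)).ravel()
    if (totals == 0).any():
        raise ValueError("zero-count cell(s) present; filter before normalizing")
    out.layers["counts"] = counts.copy()
    norm = counts.multiply(scale_factor / totals[:, None]).tocsr()
    norm.data = np.log1p(norm.data)
    out.X = norm
    out.uns["lognorm"] = {"scale_factor": scale_factor}
    return out


def select_variable_genes(adata: ad.AnnData, n: int = 2000) -> list[str]:
    """Top-``n`` genes by variance of log-normalized expression.

    Ties (and the all-constant corner) break deterministically by symbol.
    """
    if "lognorm" not in adata.uns:
        raise ValueError("normalize_log must run before variable-gene selection")
    if n > adata.n_vars:
        warnings.warn(f"requested {n} variable genes but only {adata.n_vars} present")
        n = adata.n_vars
    X = _to_dense(adata.X)
    var = X.var(axis=0)
    order = sorted(range(adata.n_vars), key=lambda i: (-var[i], adata.var_names[i]))
    return [adata.var_names[i] for i in order[:n]]
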