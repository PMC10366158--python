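"""Readers and writers for the plain-text formats the toolkit exchanges.

Count matrices travel as MatrixMarket (MTX) with row/column TSVs, everything
else as TSV; gene sets as GMT. All functions round-trip through
:class:`anndata.AnnData`, the in-memory container used throughout.
"""

from __future__ import annotations

import os
from typing import Mapping

import anndata as ad
import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse as sp


def write_cell_table(adata: ad.AnnData, outdir: str, prefix: str = "cells") -> None:
    """Write counts as MTX plus obs/var TSVs under ``outdir``."""
    os.makedirs(outdir, exist_ok=True)
    counts = adata.layers.get("counts", adata.X)
    scipy.io.mmwrite(os.path.join(outdir, f"{prefix}.mtx"), sp.csr_matrix(counts))
    adata.obs.to_csv(os.path.join(outdir, f"{prefix}_obs.tsv"), sep="\t")
    adata.var.to_csv(os.path.join(outdir, f"{prefix}_var.tsv"), sep="\t")


def read_cell_table(outdir: str, prefix: str = "cells") -> ad.AnnData:
    """Read an MTX + TSV trio written by :func:`write_cell_table`."""
    counts = sp.csr_matrix(scipy.io.mmread(os.path.join(outdir, f"{prefix}.mtx")))
    obs = pd.read_csv(os.path.join(outdir, f"{prefix}_obs.tsv"), sep="\t", index_col=0)
    var = pd.read_csv(os.path.join(outdir, f"{prefix}_var.tsv"), sep="\t", index_col=0)
    obs.index = obs.index.astype(str)
    var.index = var.index.astype(str)
    adata = ad.AnnData(X=counts, obs=obs, var=var)
    adata.layers["counts"] = adata.X.copy()
    return adata


def read_gene_order(path: str) -> pd.DataFrame:
    """Gene genomic-order table: columns gene, chromosome, position (1-based)."""
    df = pd.read_csv(path, sep="\t")
    required = {"gene", "chromosome", "position"}
    if not required.issubset(df.columns):
        raise ValueError(f"gene order table needs columns {sorted(required)}")
    return df


def read_gmt(path: str) -> dict[str, set[str]]:
    """Parse a GMT gene-set file: name <tab> description <tab> genes..."""
    sets: dict[str, set[str]] = {}
    with open(path) as fh:
        for line in fh:
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 3:
                continue
            sets[parts[0]] = set(g for g in parts[2:] if g)
    return sets


def write_gmt(sets: Mapping[str, set[str]], path: str) -> None:
    with open(path, "w") as fh:
        for name, genes in sets.items():
            fh.write("\t".join([name, name] + sorted(genes)) + "\n")


def read_mutations(path: str) -> pd.DataFrame:
    """Per-lesion mutation list: columns lesion, gene, variant."""
    df = pd.read_csv(path, sep="\t")
    required = {"lesion", "gene", "variant"}
    if not required.issubset(df.columns):
        raise ValueError(f"mutation table needs columns {sorted(required)}")
    return df


def read_spot_coords(path: str) -> pd.DataFrame:
    """Spot coordinate TSV: barcode, row, col (doubled-column parity lattice)."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    if not {"row", "col"}.issubset(df.columns):
        raise ValueError("spot coordinate table needs columns row, col")
    return df


def write_tsv(df: pd.DataFrame, path: str, index: bool = True) -> None:
    os.makedirs(os.path.dirname(os.path.abspath(path)), exist_ok=True)
    df.to_csv(path, sep="\t", index=index)
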