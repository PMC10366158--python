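"""Shared fixtures: small hand-built tables and a reusable synthetic cohort."""

import anndata as ad
import numpy as np
import pandas as pd
import pytest
import scipy.sparse as sp

from multilesion import qc
from multilesion.synth import CohortConfig, gen_cell_cohort


def make_adata(counts, gene_names=None, obs=None) -> ad.AnnData:
    counts = np.asarray(counts)
    n_obs, n_var = counts.shape
    gene_names = gene_names or [f"g{i}" for i in range(n_var)]
    adata = ad.AnnData(
        X=sp.csr_matrix(counts.astype(float)),
        obs=obs if obs is not None else pd.DataFrame(
            index=[f"c{i}" for i in range(n_obs)]
        ),
        var=pd.DataFrame(index=pd.Index(gene_names, name="gene")),
    )
    adata.layers["counts"] = adata.X.copy()
    return adata


def make_lognorm_adata(values, counts=None) -> ad.AnnData:
    """AnnData whose normalized layer is set directly (for statistical tests
    of the DE machinery on continuous data)."""
    values = np.asarray(values, dtype=float)
    adata = make_adata(counts if counts is not None else np.ceil(values))
    adata.X = sp.csr_matrix(values)
    adata.uns["lognorm"] = {"scale_factor": qc.SCALE_FACTOR}
    return adata


@pytest.fixture(scope="session")
def small_cohort():
    """One patient, two lesions, planted markers and concordance genes."""
    cfg = CohortConfig(n_patients=1, cells_per_sample=300, seed=11)
    adata, truth = gen_cell_cohort(cfg)
    norm = qc.normalize_log(qc.filter_genes(qc.filter_cells(adata)))
    return norm, truth
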