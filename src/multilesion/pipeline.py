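"""End-to-end orchestration: synthesize → QC → markers → compositions →
CNV malignancy → spatial statistics → concordance → IHC, with a flat YAML
config and a machine-readable JSON report.

Every printed analysis constant is surfaced as a named, defaulted RunConfig
field; rerunning with the same seed produces a byte-identical report.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import os
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import yaml

from . import composition, concordance, de, ihc, qc, spatial, synth
from .cnv import call_malignancy, estimate_cnv, lesion_specific_clusters
from .io import write_cell_table, write_tsv
from .synth import CloneSpec, CohortConfig, LatticeConfig

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """Flat pipeline configuration; defaults are the printed analysis values."""

    # stage toggles
    run_synth: bool = True
    run_qc: bool = True
    run_markers: bool = True
    run_composition: bool = True
    run_cnv: bool = True
    run_spatial: bool = True
    run_concordance: bool = True
    run_ihc: bool = True
    # QC
    min_genes: int = 250
    max_mito_frac: float = 0.25
    max_mito_frac_spots: float = 0.20
    ratio_floor: float = 0.75
    max_hb_frac: float = 0.01
    # markers / variable genes / signatures
    marker_lfc_threshold: float = 0.5
    marker_min_pct: float = 0.2
    marker_only_pos: bool = True
    n_variable_genes: int = 2000
    signature_size: int = 15
    # composition
    bootstrap_B: int = 1000
    # CNV
    cnv_window: int = 101
    k_joint: int = 7
    k_lesion: int = 4
    # spatial
    n_rings: int = 3
    # concordance
    p_thresh: float = 0.01
    lfc_thresh: float = 0.25
    # synthetic study design
    n_patients: int = 4
    cells_per_sample: int = 300
    n_genes: int = 1200
    effect_size: float = 2.0
    # global
    seed: int = 0
    outdir: str = "pipeline_out"

    def to_yaml(self, path: str) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(dataclasses.asdict(self), fh, sort_keys=True)

    @classmethod
    def from_yaml(cls, path: str) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)


def validate_inputs(
    counts_shape=None,
    obs: pd.DataFrame | None = None,
    coords: pd.DataFrame | None = None,
    probabilities: pd.DataFrame | None = None,
) -> list[str]:
    """Shape/parity/normalization diagnostics; returns messages, never raises."""
    diagnostics: list[str] = []
    if counts_shape is not None and obs is not None:
        if counts_shape[0] != len(obs):
            diagnostics.append(
                f"metadata rows ({len(obs)}) do not match matrix rows "
                f"({counts_shape[0]})"
            )
    if coords is not None:
        parity = (coords["row"].astype(int) + coords["col"].astype(int)) % 2
        bad = coords.index[parity != 0]
        if len(bad):
            diagnostics.append(
                f"{len(bad)} spot(s) violate row+col parity, e.g. {bad[0]!r}"
            )
        if coords.duplicated(["row", "col"]).any():
            diagnostics.append("duplicate spot coordinates present")
    if probabilities is not None:
        sums = probabilities.to_numpy(dtype=float).sum(axis=1)
        off = np.abs(sums - 1.0) > 1e-6
        if off.any():
            diagnostics.append(
                f"{int(off.sum())} probability row(s) do not sum to 1"
            )
    return diagnostics


def run_pipeline(config: RunConfig) -> dict:
    """Execute the enabled stages in dependency order and write a report."""
    os.makedirs(config.outdir, exist_ok=True)
    report: dict = {"seed": config.seed, "stages": []}

    if not config.run_synth:
        raise ValueError("missing dependency stage: synth (external inputs "
                         "are supplied through the per-stage CLI commands)")

    # --- synthesize -------------------------------------------------------
    cohort_cfg = CohortConfig(
        n_patients=config.n_patients,
        cells_per_sample=config.cells_per_sample,
        n_genes=config.n_genes,
        concordance_effect=config.effect_size,
        seed=config.seed,
    )
    cells, cell_truth = synth.gen_cell_cohort(cohort_cfg)
    spots, _spot_truth = synth.gen_spot_grid(LatticeConfig(seed=config.seed + 1))
    cnv_mat, _cnv_truth = synth.gen_cnv_cohort(
        n_ref=300, n_obs=150, n_bins=200,
        clones=[
            CloneSpec("cloneA", ((20, 60, 0.5),), lesion="TI"),
            CloneSpec("cloneB", ((120, 160, -0.5),), lesion="TOther1"),
        ],
        seed=config.seed + 2,
    )
    ihc_records = synth.gen_ihc_table(
        n_per_group=12,
        group_shifts={"MPLC": 1.5, "IPM": 1.5, "solitary": 0.5},
        seed=config.seed + 3,
    )
    write_cell_table(cells, config.outdir, "cells")
    write_tsv(spots.obs, os.path.join(config.outdir, "spots.tsv"))
    write_tsv(ihc.records_frame(ihc_records),
              os.path.join(config.outdir, "ihc.tsv"), index=False)
    report["stages"].append("synth")
    report["synth"] = {"n_cells": int(cells.n_obs), "n_spots": int(spots.n_obs)}

    # --- QC + normalization ----------------------------------------------
    th = qc.QCThresholds(
        min_genes=config.min_genes,
        max_mito_frac=config.max_mito_frac,
        max_mito_frac_spots=config.max_mito_frac_spots,
        ratio_floor=config.ratio_floor,
        max_hb_frac=config.max_hb_frac,
    )
    if config.run_qc:
        cells = qc.filter_cells(cells, th)
        cell_removed = cells.uns["qc_cell_filter"]
        cells = qc.filter_genes(cells)
        cells = qc.normalize_log(cells)
        report["stages"].append("qc")
        report["qc"] = {
            "cells": cell_removed,
            "genes_removed": cells.uns["gene_filter"]["removed"],
        }
    else:
        cells = qc.normalize_log(cells)

    # --- markers ----------------------------------------------------------
    if config.run_markers:
        markers = de.find_markers(
            cells, cells.obs["cell_type"],
            lfc_threshold=config.marker_lfc_threshold,
            min_pct=config.marker_min_pct,
            only_pos=config.marker_only_pos,
        )
        signatures = {
            t: de.signature_geneset(m, config.signature_size)
            for t, m in markers.items() if len(m)
        }
        report["stages"].append("markers")
        report["markers"] = {t: int(len(m)) for t, m in markers.items()}
        report["signature_sizes"] = {t: len(s) for t, s in signatures.items()}

    # --- composition ------------------------------------------------------
    if config.run_composition:
        props = {}
        for i, sample in enumerate(sorted(cells.obs["sample"].unique())):
            labels = cells.obs.loc[cells.obs["sample"] == sample, "cell_type"]
            props[sample] = composition.bootstrap_proportions(
                labels, B=config.bootstrap_B, seed=config.seed + 100 + i
            )["mean"]
        sim = composition.composition_similarity(pd.DataFrame(props).T.fillna(0.0))
        report["stages"].append("composition")
        report["composition"] = {
            "n_samples": len(props),
            "mean_offdiag_spearman": float(
                np.nanmean(sim.corr.to_numpy()[~np.eye(len(props), dtype=bool)])
            ),
        }

    # --- CNV malignancy ---------------------------------------------------
    if config.run_cnv:
        call = call_malignancy(cnv_mat, k=config.k_joint, seed=config.seed)
        mal = cnv_mat.subset_cells(call.malignant_mask)
        lesion_tab = lesion_specific_clusters(
            mal, k=config.k_lesion, seed=config.seed
        )
        write_tsv(call.assignments, os.path.join(config.outdir, "cnv_calls.tsv"))
        report["stages"].append("cnv")
        report["cnv"] = {
            "n_malignant": int(call.malignant_mask.sum()),
            "lesion_specific_clusters": int(
                lesion_tab["specific_lesion"].notna().sum()
            ),
        }

    # --- spatial ----------------------------------------------------------
    if config.run_spatial:
        graph = spatial.build_neighbor_graph(spots.obs[["row", "col"]])
        labels = spatial.assign_dominant_type(spots.obsm["type_probabilities"])
        scores = spatial.consistency_scores(graph, labels)
        coloc = spatial.colocalization_profile(graph, labels)
        write_tsv(scores.to_frame(), os.path.join(config.outdir, "consistency.tsv"))
        report["stages"].append("spatial")
        report["spatial"] = {
            "mean_consistency": float(scores.mean()),
            "n_pair_types": int(len(coloc)),
        }

    # --- concordance ------------------------------------------------------
    if config.run_concordance:
        records = {}
        tallies = {}
        for patient in sorted(cells.obs["patient"].unique()):
            de_ti, de_to = concordance.lesion_de_pair(cells, patient)
            rec = concordance.classify_concordance(
                de_ti, de_to, config.p_thresh, config.lfc_thresh
            )
            records[patient] = rec
            tallies[patient] = rec["category"].value_counts().to_dict()
        universal = concordance.cross_patient_same(records)
        planted_same = set(
            cell_truth.gene_class.index[cell_truth.gene_class == "Same"]
        )
        report["stages"].append("concordance")
        report["concordance"] = {
            "per_patient_classes": tallies,
            "n_universal_same": int(len(universal)),
            "universal_same_planted_recall": (
                float(len(set(universal.index) & planted_same) / len(planted_same))
                if planted_same else None
            ),
        }

    # --- IHC --------------------------------------------------------------
    if config.run_ihc:
        contrasts = ihc.group_compare(ihc_records)
        report["stages"].append("ihc")
        report["ihc"] = {
            name: round(float(p), 6)
            for name, p in contrasts["p_value"].items()
        }

    report_path = os.path.join(config.outdir, "report.json")
    with open(report_path, "w") as fh:
        json.dump(report, fh, indent=2, sort_keys=True)
    logger.info("pipeline report written to %s", report_path)
    return report
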