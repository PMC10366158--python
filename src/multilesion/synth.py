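"""Synthetic cohorts with planted ground truth.

Emulates the statistical structure of a multi-lesion lung-tumor study: each
patient carries one inferior-lobe tumor (TI) plus one or more other-lobe
tumors, each paired with an adjacent normal sample; cell types carry
disjoint marker genes; a configurable set of genes is planted with
tumor-vs-normal shifts realizing the five inter-lesion concordance classes;
clone-specific copy-number blocks and Visium-style label lattices and
group-shifted IHC tables cover the remaining pipeline stages.

Counts are negative-binomial via a gamma–Poisson mixture (the standard
stand-in for UMI counts); identical seeds give bit-identical outputs.
Gene–gene correlation, doublets, ambient RNA and batch effects are out of
scope.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import anndata as ad
import numpy as np
import pandas as pd
import scipy.sparse as sp

CONCORDANCE_CLASSES = ("Same", "OP", "TI", "TOthers")

# a handful of housekeeping-like special symbols so QC rules have targets;
# mitochondrial mass is ~5% of the library, far below the 25% cutoff
MITO_GENES = tuple(f"MT-SYN{i}" for i in range(1, 6))
SPECIAL_GENES = MITO_GENES + ("MALAT1",)


@dataclass(frozen=True)
class CellTypeSpec:
    name: str
    n_markers: int = 20
    effect: float = 2.0  # log2 units


@dataclass
class CohortConfig:
    """Study-design knobs for the cell cohort generator.

    Defaults mirror the emulated design: 4 patients, 2 lesions each, tumor +
    matched normal per lesion, 300 cells per sample, log2 effect 2.0 for
    both markers and planted concordance genes.
    """

    n_patients: int = 4
    lesions_per_patient: int = 2
    cells_per_sample: int = 300
    n_genes: int = 1200
    cell_types: tuple[CellTypeSpec, ...] = (
        CellTypeSpec("Epithelial"),
        CellTypeSpec("Immune"),
        CellTypeSpec("Stromal"),
    )
    concordance_plant: dict = field(
        default_factory=lambda: {"Same": 20, "OP": 20, "TI": 20, "TOthers": 20}
    )
    concordance_effect: float = 2.0  # log2 units
    concordance_cell_type: str | None = None  # None -> shift all cell types
    library_size: float = 2000.0
    dispersion: float = 0.3
    n_chromosomes: int = 10
    seed: int = 0

    def __post_init__(self) -> None:
        for name, val in [
            ("n_patients", self.n_patients),
            ("lesions_per_patient", self.lesions_per_patient),
            ("cells_per_sample", self.cells_per_sample),
            ("n_genes", self.n_genes),
        ]:
            if val <= 0:
                raise ValueError(f"{name} must be positive")
        if not np.isfinite(self.concordance_effect):
            raise ValueError("effect sizes must be finite")
        bad = set(self.concordance_plant) - set(CONCORDANCE_CLASSES)
        if bad:
            raise ValueError(f"unknown concordance classes: {sorted(bad)}")
        n_marker = sum(t.n_markers for t in self.cell_types)
        n_plant = sum(self.concordance_plant.values())
        if n_marker + n_plant > self.n_genes:
            raise ValueError(
                f"planted gene counts ({n_marker + n_plant}) exceed n_genes "
                f"({self.n_genes})"
            )


@dataclass
class LatticeConfig:
    """Visium-style parity-lattice label generator configuration."""

    n_rows: int = 30
    n_cols: int = 30
    n_types: int = 4
    patch_count: int = 4
    patch_radius: int = 3  # lattice rings
    background_mixing: float = 0.3  # probability a background spot is random
    n_genes: int = 100
    library_size: float = 1000.0
    dispersion: float = 0.3
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.n_rows, self.n_cols, self.n_types) <= 0:
            raise ValueError("lattice dimensions and n_types must be positive")
        if self.patch_radius < 0:
            raise ValueError("patch_radius must be >= 0")
        if not 0.0 <= self.background_mixing <= 1.0:
            raise ValueError("background_mixing must lie in [0, 1]")


@dataclass
class CloneSpec:
    """Contiguous gain/loss blocks of one tumor clone.

    ``blocks`` are (start, end, amplitude) with end exclusive in bin units;
    blocks within one clone must not overlap.
    """

    name: str
    blocks: tuple = ()
    lesion: str | None = None

    def validate(self, n_bins: int) -> None:
        blocks = sorted(self.blocks)
        for start, end, _amp in blocks:
            if not (0 <= start < end <= n_bins):
                raise ValueError(f"clone {self.name}: block ({start},{end}) "
                                 f"outside [0,{n_bins})")
        for (s1, e1, _), (s2, _e2, _) in zip(blocks, blocks[1:]):
            if s2 < e1:
                raise ValueError(f"clone {self.name}: overlapping blocks")


@dataclass
class SyntheticTruth:
    """Planted ground truth; fields are filled by the relevant generator."""

    gene_class: pd.Series | None = None  # planted concordance class per gene
    gene_sign: pd.Series | None = None   # planted TI-side shift sign
    marker_genes: dict | None = None     # cell type -> list of marker genes
    cell_type: pd.Series | None = None
    cell_clone: pd.Series | None = None
    spot_type: pd.Series | None = None
    spot_patch: pd.Series | None = None  # True where a planted patch sits
    clone_bins: pd.DataFrame | None = None  # clone, start, end, amplitude


# ---------------------------------------------------------------------------
# cell cohort
# ---------------------------------------------------------------------------

def gen_cell_cohort(config: CohortConfig) -> tuple[ad.AnnData, SyntheticTruth]:
    """Multi-patient cohort of tumor + matched-normal samples.

    Planted concordance genes are differentially expressed tumor-vs-normal
    exactly per their class: Same shifts both lesions with one sign, OP with
    opposite signs, TI/TOthers shift one lesion side only.
    """
    rng = np.random.default_rng(config.seed)
    n_reg = config.n_genes
    genes = [f"G{i:05d}" for i in range(n_reg)] + list(SPECIAL_GENES)

    # baseline relative abundance; planted genes floored to stay detectable
    theta = rng.lognormal(0.0, 1.0, n_reg)
    perm = rng.permutation(n_reg)
    cursor = 0
    marker_idx: dict[str, np.ndarray] = {}
    for spec in config.cell_types:
        marker_idx[spec.name] = perm[cursor:cursor + spec.n_markers]
        cursor += spec.n_markers
    class_idx: dict[str, np.ndarray] = {}
    for cls in CONCORDANCE_CLASSES:
        n = config.concordance_plant.get(cls, 0)
        class_idx[cls] = perm[cursor:cursor + n]
        cursor += n
    # balanced up/down shifts per class; up-shifted genes sit at baseline
    # abundance t and down-shifted at t * 2^e / (1 - 2^-e) * (2^e - 1)^-1
    # (= 4t at e = 2), so the planted mass change cancels within each tumor
    # stratum and does not bleed into null-gene fold changes through
    # library-size normalization. OP genes flip direction between lesions,
    # where exact cancellation is impossible; they stay at low abundance so
    # the residual imbalance is negligible.
    signs = pd.Series(0, index=genes, dtype=int)
    for cls in CONCORDANCE_CLASSES:
        n = len(class_idx[cls])
        s = rng.permutation(np.where(np.arange(n) % 2 == 0, 1, -1))
        signs.iloc[class_idx[cls]] = s
    eff = config.concordance_effect
    base_t = 1.5
    down_t = base_t * (2.0**eff - 1.0) / (1.0 - 2.0**-eff) if eff > 0 else base_t
    for cls in ("Same", "TI", "TOthers"):
        s = signs.iloc[class_idx[cls]].to_numpy()
        theta[class_idx[cls]] = np.where(s > 0, base_t, down_t)
    theta[class_idx["OP"]] = base_t
    marker_all = np.concatenate(list(marker_idx.values())) if marker_idx else []
    if len(marker_all):
        theta[marker_all] = np.maximum(theta[marker_all], 1.0)
    total = theta.sum()
    theta_full = np.concatenate(
        [theta, np.full(len(MITO_GENES), 0.01 * total), [0.005 * total]]
    )
    rel = theta_full / theta_full.sum()

    type_names = [t.name for t in config.cell_types]
    lesions = ["TI"] + [f"TOther{j}" for j in range(1, config.lesions_per_patient)]

    def shift_vector(lesion: str, tissue: str, cell_type: str) -> np.ndarray:
        """log2 mean shift per gene for one (lesion, tissue, type) stratum."""
        shift = np.zeros(len(genes))
        spec = config.cell_types[type_names.index(cell_type)]
        shift[marker_idx[cell_type]] += spec.effect
        if tissue == "tumor" and (
            config.concordance_cell_type is None
            or config.concordance_cell_type == cell_type
        ):
            eff = config.concordance_effect
            s = signs.to_numpy()
            if len(class_idx["Same"]):
                shift[class_idx["Same"]] += s[class_idx["Same"]] * eff
            if len(class_idx["OP"]):
                op_sign = 1.0 if lesion == "TI" else -1.0
                shift[class_idx["OP"]] += op_sign * s[class_idx["OP"]] * eff
            if lesion == "TI" and len(class_idx["TI"]):
                shift[class_idx["TI"]] += s[class_idx["TI"]] * eff
            if lesion != "TI" and len(class_idx["TOthers"]):
                shift[class_idx["TOthers"]] += s[class_idx["TOthers"]] * eff
        return shift

    blocks, obs_rows = [], []
    for p in range(1, config.n_patients + 1):
        patient = f"P{p}"
        for lesion in lesions:
            for tissue in ("tumor", "normal"):
                sample = f"{patient}_{lesion}_{tissue}"
                types = rng.choice(type_names, size=config.cells_per_sample)
                for cell_type in type_names:
                    n_cells = int((types == cell_type).sum())
                    if n_cells == 0:
                        continue
                    mean = (
                        config.library_size
                        * rel
                        * 2.0 ** shift_vector(lesion, tissue, cell_type)
                    )
                    counts = _nb_counts(rng, mean, config.dispersion, n_cells)
                    blocks.append(sp.csr_matrix(counts))
                    clone = f"{patient}:{lesion}" if tissue == "tumor" else "none"
                    obs_rows += [
                        {"patient": patient, "sample": sample, "lesion": lesion,
                         "tissue": tissue, "cell_type": cell_type, "clone": clone}
                    ] * n_cells

    obs = pd.DataFrame(obs_rows)
    obs.index = [f"cell_{i:06d}" for i in range(len(obs))]
    var = pd.DataFrame(index=pd.Index(genes, name="gene"))
    chrom_of = np.minimum(
        np.arange(n_reg) * config.n_chromosomes // n_reg,
        config.n_chromosomes - 1,
    )
    var["chromosome"] = [f"chr{c + 1}" for c in chrom_of] + ["chrM"] * len(
        MITO_GENES
    ) + ["chrOther"]
    pos = np.zeros(len(genes), dtype=int)
    for c in range(config.n_chromosomes):
        idx = np.where(chrom_of == c)[0]
        pos[idx] = (np.arange(len(idx)) + 1) * 100
    pos[n_reg:] = np.arange(len(SPECIAL_GENES)) + 1
    var["position"] = pos

    adata = ad.AnnData(X=sp.vstack(blocks).tocsr(), obs=obs, var=var)
    adata.layers["counts"] = adata.X.copy()

    gene_class = pd.Series("none", index=genes)
    for cls in CONCORDANCE_CLASSES:
        gene_class.iloc[class_idx[cls]] = cls
    truth = SyntheticTruth(
        gene_class=gene_class,
        gene_sign=signs,
        marker_genes={t: [genes[i] for i in marker_idx[t]] for t in type_names},
        cell_type=obs["cell_type"].copy(),
        cell_clone=obs["clone"].copy(),
    )
    return adata, truth


def _nb_counts(rng, mean: np.ndarray, dispersion: float, n_cells: int) -> np.ndarray:
    """Gamma–Poisson (negative binomial) draws, Poisson when dispersion=0."""
    m = np.broadcast_to(mean, (n_cells, len(mean)))
    if dispersion <= 0:
        return rng.poisson(m)
    lam = rng.gamma(1.0 / dispersion, m * dispersion)
    return rng.poisson(lam)


def gene_order_frame(adata: ad.AnnData) -> pd.DataFrame:
    """Genomic-order table (gene, chromosome, position) for autosomal genes."""
    var = adata.var
    keep = var["chromosome"].astype(str).str.match(r"chr\d+$")
    return pd.DataFrame(
        {
            "gene": var.index[keep],
            "chromosome": var["chromosome"][keep].to_numpy(),
            "position": var["position"][keep].to_numpy(),
        }
    ).reset_index(drop=True)


# ---------------------------------------------------------------------------
# spot lattice
# ---------------------------------------------------------------------------

def _hex_distance(r1: int, c1: int, r2: int, c2: int) -> int:
    """Ring distance on the doubled-column parity lattice."""
    dy = abs(r1 - r2)
    dx = abs(c1 - c2)
    return dy + max(0, (dx - dy) // 2)


def gen_spot_grid(config: LatticeConfig) -> tuple[ad.AnnData, SyntheticTruth]:
    """Labeled spots on the parity lattice: single-type patches on a mixed
    background (pure background type at ``background_mixing = 0``)."""
    rng = np.random.default_rng(config.seed)
    coords = [
        (r, 2 * j + r % 2)
        for r in range(config.n_rows)
        for j in range(config.n_cols)
    ]
    barcodes = [f"spot_{r}_{c}" for r, c in coords]
    types = [f"T{i}" for i in range(1, config.n_types + 1)]

    labels = np.array(
        [
            types[rng.integers(config.n_types)]
            if rng.random() < config.background_mixing
            else types[0]
            for _ in coords
        ],
        dtype=object,
    )
    if config.patch_count == 0 and config.n_types > 1:
        warnings.warn("patch_count = 0 with multiple types: pure background")
    patch_types = types[1:] if config.n_types > 1 else types
    centers = rng.choice(len(coords), size=min(config.patch_count, len(coords)),
                         replace=False)
    in_patch = np.zeros(len(coords), dtype=bool)
    for i, ci in enumerate(centers):
        ptype = patch_types[i % len(patch_types)]
        r0, c0 = coords[ci]
        for j, (r, c) in enumerate(coords):
            if _hex_distance(r0, c0, r, c) <= config.patch_radius:
                labels[j] = ptype
                in_patch[j] = True

    genes = [f"SG{i:04d}" for i in range(config.n_genes)] + list(MITO_GENES) + [
        "HB-SYN1", "HB-SYN2"
    ]
    theta = rng.lognormal(0.0, 1.0, config.n_genes)
    total = theta.sum()
    theta_full = np.concatenate(
        [theta, np.full(len(MITO_GENES), 0.01 * total), [0.002 * total] * 2]
    )
    rel = theta_full / theta_full.sum()
    block = max(1, config.n_genes // (2 * config.n_types))
    counts = np.empty((len(coords), len(genes)), dtype=np.int64)
    for t_i, t in enumerate(types):
        mask = labels == t
        if not mask.any():
            continue
        shift = np.zeros(len(genes))
        shift[t_i * block:(t_i + 1) * block] = 1.0  # type-marker boost
        mean = config.library_size * rel * 2.0**shift
        counts[mask] = _nb_counts(rng, mean, config.dispersion, int(mask.sum()))

    obs = pd.DataFrame(
        {"row": [r for r, _ in coords], "col": [c for _, c in coords],
         "label": labels},
        index=pd.Index(barcodes, name="barcode"),
    )
    adata = ad.AnnData(X=sp.csr_matrix(counts), obs=obs,
                       var=pd.DataFrame(index=pd.Index(genes, name="gene")))
    adata.layers["counts"] = adata.X.copy()
    probs = pd.DataFrame(0.1 / config.n_types, index=obs.index, columns=types)
    for t in types:
        probs.loc[obs["label"] == t, t] += 0.9
    adata.obsm["type_probabilities"] = probs
    truth = SyntheticTruth(
        spot_type=obs["label"].copy(),
        spot_patch=pd.Series(in_patch, index=obs.index, name="in_patch"),
    )
    return adata, truth


# ---------------------------------------------------------------------------
# CNV cohort
# ---------------------------------------------------------------------------

def gen_cnv_cohort(
    n_ref: int,
    n_obs: int,
    n_bins: int,
    clones: list[CloneSpec],
    seed: int = 0,
    noise_sd: float = 0.1,
):
    """Reference cells around 0 plus clone-shifted observation cells.

    Observation cells are split evenly across the clones; each carries its
    clone's contiguous block shifts plus Gaussian noise. Returns a
    :class:`~multilesion.cnv.CNVMatrix` and the planted truth.
    """
    from .cnv import CNVMatrix  # local import to avoid cycle

    if min(n_ref, n_obs, n_bins) <= 0:
        raise ValueError("n_ref, n_obs and n_bins must be positive")
    if not clones:
        raise ValueError("need at least one clone spec")
    for clone in clones:
        clone.validate(n_bins)
    rng = np.random.default_rng(seed)
    values = rng.normal(0.0, noise_sd, (n_ref + n_obs, n_bins))

    per = np.full(len(clones), n_obs // len(clones))
    per[: n_obs % len(clones)] += 1
    clone_of, lesion_of = [], []
    row = n_ref
    for clone, n in zip(clones, per):
        for start, end, amp in clone.blocks:
            values[row:row + n, start:end] += amp
        clone_of += [clone.name] * n
        lesion_of += [clone.lesion or clone.name] * n
        row += n

    cell_meta = pd.DataFrame(
        {
            "reference": [True] * n_ref + [False] * n_obs,
            "epithelial": [False] * n_ref + [True] * n_obs,
            "lesion": ["reference"] * n_ref + lesion_of,
            "clone": ["reference"] * n_ref + clone_of,
        },
        index=[f"cnv_cell_{i:05d}" for i in range(n_ref + n_obs)],
    )
    bin_meta = pd.DataFrame(
        {"chromosome": "chr1", "position": np.arange(1, n_bins + 1)},
        index=[f"bin_{i:05d}" for i in range(n_bins)],
    )
    truth = SyntheticTruth(
        cell_clone=cell_meta["clone"].copy(),
        clone_bins=pd.DataFrame(
            [
                {"clone": cl.name, "start": s, "end": e, "amplitude": a}
                for cl in clones
                for s, e, a in cl.blocks
            ],
            columns=["clone", "start", "end", "amplitude"],
        ),
    )
    return CNVMatrix(values, bin_meta, cell_meta), truth


# ---------------------------------------------------------------------------
# IHC tables
# ---------------------------------------------------------------------------

def gen_ihc_table(
    n_per_group: int,
    group_shifts: dict[str, float],
    seed: int = 0,
) -> list:
    """Group-shifted IHC records (tumor + matched normal per group).

    ``group_shifts`` maps group name → latent location shift applied to
    tumor sections; a shift of 0 everywhere makes all group contrasts null.
    """
    from .ihc import IHCRecord  # local import to avoid cycle

    if n_per_group < 2:
        raise ValueError("need at least 2 sections per group for group tests")
    for g, s in group_shifts.items():
        if not np.isfinite(s):
            raise ValueError(f"shift for group {g!r} is not finite")
    rng = np.random.default_rng(seed)
    records = []
    for group in sorted(group_shifts):
        for tissue in ("tumor", "normal"):
            for i in range(n_per_group):
                latent = rng.normal(-0.5, 1.0)
                if tissue == "tumor":
                    latent += group_shifts[group]
                positivity = float(1.0 / (1.0 + np.exp(-latent)))
                grade_latent = latent + rng.normal(0.0, 0.7)
                if grade_latent < -1.0:
                    grade = "none"
                elif grade_latent < 0.0:
                    grade = "weak"
                elif grade_latent < 1.0:
                    grade = "moderate"
                else:
                    grade = "strong"
                records.append(
                    IHCRecord(
                        sample=f"{group}_{tissue}_{i:03d}",
                        group=group,
                        tissue=tissue,
                        positivity=positivity,
                        intensity=grade,
                    )
                )
    return records
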