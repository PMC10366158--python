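# multilesion

Statistical toolkit for studies of patients carrying **several synchronous
lung tumors**, where the central question is whether the lesions are
independent primaries (multiple primary lung cancer, MPLC) or seeding of one
tumor into another lobe (intrapulmonary metastasis, IPM). It implements, as
a tested and reusable library with a CLI, the bespoke computational layer
such studies need on top of standard single-cell tooling:

* **QC and expression statistics** — cell filters (≥250 detected genes,
  ≤25% mitochondrial transcripts, complexity ratio
  log₁₀(n_genes)/log₁₀(n_counts) > 0.75; spot variants with a 20%
  mitochondrial and 1% hemoglobin rule), library-size log-normalization,
  top-2000 variable genes, two-sided Wilcoxon rank-sum differential
  expression with exact small-sample enumeration, one-vs-rest marker
  detection (log₂FC ≥ 0.5, min.pct 0.2, positive-only), top-15 signature
  gene sets with mean-z scoring, and hypergeometric gene-set enrichment.
* **Compositions** — bootstrap cell-type proportions (mean ± s.d. over
  B = 1000 resamples), |Δproportion| between samples, and Spearman
  composition/expression similarity matrices with average-linkage
  clustering.
* **CNV-based malignancy calling** — smoothed relative copy-number
  profiles from expression against a reference cell population, joint
  k-means (k = 7) malignancy calls (epithelial cells in reference-dominated
  clusters are non-malignant), and lesion-specific clone detection by
  re-clustering malignant cells (k = 4, 75% dominance rule).
* **Spatial statistics** — six-neighbor graphs on the staggered Visium
  lattice (row + col even; offsets (0, ±2), (±1, ±1)), the per-spot
  **consistency score** (fraction of direct neighbors sharing the spot's
  dominant cell type), the **co-localization profile** (distribution of
  unordered type pairs over adjacent spots), breadth-first **rings** around
  annotated histology regions, and region-vs-environment composition
  contrasts.
* **Inter-lesion concordance** — each gene's tumor-vs-normal change in the
  inferior-lobe lesion (TI vs NI) and in the pooled remaining lesions
  (TOthers vs NOthers) is classified into five classes:

  | class | rule (p < 0.01, &#124;log₂FC&#124; > 0.25 per side) |
  |---|---|
  | Same | significant on both sides, same sign |
  | OP | significant on both sides, opposite signs |
  | TI | significant on the TI side only |
  | TOthers | significant on the other-lesion side only |
  | NotSig | everything else |

  plus the cross-patient intersection of Same genes, cell-type-stratified
  classification, and shared/unique mutation counts between lesions.
* **IHC scoring** — semi-quantitative score = positivity bin (0–4 for 0%,
  1–10%, 11–50%, 51–80%, >80%) × intensity bin (0–3 for none/weak/
  moderate/strong), with unpaired rank-sum group contrasts.
* **Synthetic cohorts** — a first-class generator of multi-patient,
  two-lesion cohorts with negative-binomial counts, planted marker and
  concordance genes, clone-specific CNV blocks, patchy spot lattices and
  group-shifted IHC tables, so every stage is testable against known truth
  without any data download.

## Worked example

```python
from multilesion import concordance, ihc, qc
from multilesion.synth import CohortConfig, gen_cell_cohort

ihc.ihc_score(0.85, "strong")
# 12        (positivity bin 4 x intensity bin 3)

cfg = CohortConfig(n_patients=1, cells_per_sample=300, seed=11)
adata, truth = gen_cell_cohort(cfg)
norm = qc.normalize_log(qc.filter_genes(qc.filter_cells(adata)))
de_ti, de_others = concordance.lesion_de_pair(norm, "P1")
record = concordance.classify_concordance(de_ti, de_others)
record["category"].value_counts().to_dict()
# {'NotSig': 1093, 'TOthers': 33, 'TI': 33, 'Same': 21, 'OP': 20}
```

The cohort plants 20 genes per concordance class at log₂ effect 2.0; the
tallies above show the classifier recovering them (21 Same = 20 planted
plus one borderline null gene; the extra TI/TOthers calls are genes whose
fold change crossed 0.25 by chance on one side). Checking directly:

```python
same = truth.gene_class.index[truth.gene_class == "Same"]
(record.loc[same, "category"] == "Same").sum()
# 20  (all planted Same genes recovered)
```

The same flow is available from the shell:

```bash
multilesion synth --outdir out --seed 3 --n-patients 1
multilesion qc --indir out --outdir out_qc
multilesion run-all --seed 5 --outdir full_run   # end-to-end + report.json
```

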