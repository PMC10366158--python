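# Methods

This note documents the statistical procedures the package implements, the
defaults it ships, what the synthetic-data generator does and does not
emulate, and the numerical choices made where the design was open.

## Quality control

Cells are removed when any of three rules fires: fewer than 250 detected
genes; more than 25% mitochondrial transcripts; complexity ratio
log₁₀(n_genes)/log₁₀(n_counts) ≤ 0.75. Spots use 250 genes, a 20%
mitochondrial rule and an additional 1% hemoglobin rule. All fractions are
computed on the **raw** matrix, before gene-family exclusion, so removing
MT- genes afterwards cannot change which cells were filtered; the filters
are therefore idempotent. Gene-family exclusion drops MALAT1 and the
mitochondrial (`MT-` prefix), ribosomal (`RPS`/`RPL` prefixes) and
hemoglobin (`^HB` not followed by `P`, so HBP1 survives) families —
standard human-symbol conventions. Per-rule removal counts are logged and
stored on the returned object; an empty result raises an error naming the
rule that removed the most records.

## Normalization and differential expression

Counts are scaled to 10,000 per cell and log1p-transformed (the common
default of the single-cell frameworks this mirrors); raw counts are kept in
a `counts` layer. Variable genes are the top-2000 by variance of the
log-normalized layer, with a deterministic tie-break by symbol. This is a
simpler criterion than variance-stabilized selection, adequate here because
downstream consumers only need a reproducible, expression-variability-
ranked gene list.

The DE test is the two-sided Wilcoxon rank-sum test. When both groups have
at most 8 cells the p-value comes from exhaustive enumeration of all
C(n, n_A) label assignments using midranks — exact under ties; larger
groups use the tie-corrected normal approximation without continuity
correction. One-dimensional contrasts elsewhere in the package (IHC groups,
region-vs-environment) use the same machinery but switch to enumeration
whenever C(n, n_A) ≤ 200,000, so e.g. a fully separated 10-vs-10 contrast
reports the exact tail 2/C(20,10).

Fold changes are `avg_log2FC = log2((mean(expm1(x_A)) + 1) /
(mean(expm1(x_B)) + 1))` over log-normalized values — the classic
framework's formula, expressed in base 2 to match how such values are
plotted. `pct_in`/`pct_out` are fractions of cells with a nonzero raw
count. Raw p-values are reported (downstream rules threshold raw p);
Benjamini–Hochberg q-values are carried alongside as an extra column.

Marker detection is one-vs-rest DE per label gated by avg_log2FC ≥ 0.5,
max(pct_in, pct_out) ≥ 0.2 and positivity — the `max` form of the min.pct
gate matches the cited implementations. Labels with fewer than 3 cells are
skipped with a warning. Signature gene sets take the 15 smallest p-values
(ties: larger fold change, then symbol); signature scoring is the mean of
per-gene z-scores of log-normalized expression over the set, with
zero-variance genes contributing 0 — a transparent substitute for
sample-wise gene-set variation analysis that preserves the rank separation
downstream comparisons rely on. Enrichment is the upper-tail hypergeometric
probability of the query/set overlap within a user-supplied universe.

## Compositions

Bootstrap proportions resample the cells of one sample with replacement
B = 1000 times (realized as multinomial draws from the empirical
composition — distributionally identical and O(B·T)) and report the mean
and s.d. of the replicate proportions. Composition deltas are element-wise
absolute differences with missing types as 0. Similarity matrices are
pairwise Spearman correlations (midranks for ties); constant vectors have
undefined correlations and are recorded as missing and excluded from the
average-linkage clustering on 1 − ρ. Between-sample expression similarity
correlates per-sample mean log-normalized expression over a shared
variable-gene list (absent genes count 0 with a warning).

## CNV profiles and malignancy

The relative copy signal is estimated per gene as log₂ expression minus the
reference-population mean, clipped to ±3 reference standard deviations,
smoothed by a centered moving average of 101 genes within each chromosome
(the window shrinks, with a warning, on shorter chromosomes), and re-centered
by the per-cell median. This is the standard expression-derived CNV
smoothing scheme; HMM/Bayesian refinements and allele-specific inference
are out of scope. Immune (T&NK-like) cells serve as the reference;
epithelial tumor cells are the observations.

Malignancy is called by k-means (k-means++ initialization, 10 restarts,
seeded) with k = 7 over reference and epithelial observation cells jointly.
A cluster whose reference fraction reaches 0.5 is reference-dominated; the
tie at exactly 0.5 resolves to non-malignant (conservative). Epithelial
cells outside those clusters are malignant; reference cells are never
flagged. Lesion-specific clones re-cluster the malignant cells with k = 4
and flag clusters where one lesion contributes ≥ 75% of the members. The
0.5 dominance and 0.75 specificity cut-offs are package choices — the
procedure's verbal description fixes neither — and both are parameters.

Note that with a balanced reference/observation mix the 0.5 dominance rule
sits at the knife edge under the null (every joint cluster hovers at 50%
reference), so the default study conditions use a reference-rich design
(2:1), which matches how abundant immune reference populations are in
practice and gives a null malignant-call rate well under 10%.

## Spatial statistics

Spots live on a staggered ("checkerboard") integer lattice with row + col
even; direct neighbors sit at offsets (0, ±2) and (±1, ±1), giving maximum
degree six. The consistency score of a spot is the fraction of its existing
neighbors sharing its dominant type — the denominator is the actual
neighbor count so boundary spots keep valid scores, and isolated spots get
a missing value excluded from summaries. Under i.i.d. labels over T types
its expectation is 1/T, which the tests verify by Monte Carlo. Dominant
types are per-spot probability argmaxes with a lexicographic tie-break.
The co-localization profile counts each lattice edge once as an unordered
label pair and normalizes to sum 1. Region rings are breadth-first-distance
shells on the neighbor graph (not Euclidean annuli): ring r holds spots at
graph distance exactly r from the region, so rings are disjoint, exclude
the region, and truncate naturally at tissue boundaries. The
region-vs-environment contrast compares type proportions inside a region
with the union of its first three rings; with several regions a per-type
two-sided rank-sum test across regions is added.

## Inter-lesion concordance

For one patient, tumor-vs-matched-normal DE is computed for the
inferior-lobe lesion (TI vs NI) and for the pooled remaining lesions
(TOthers vs NOthers). A side is significant when p < 0.01 and
|avg_log2FC| > 0.25 — strict inequalities, so values exactly at a threshold
are not significant, and a fold change of exactly 0 has no quadrant and can
never be Same or OP. The five classes (Same, OP, TI, TOthers, NotSig) are
mutually exclusive and exhaustive by construction; swapping the two inputs
maps TI ↔ TOthers and fixes the rest. The cross-patient intersection
reports genes classified Same in every patient together with per-patient
fold-change signs. Mutation comparison is exact set arithmetic on
(gene, variant-string) identifiers; variant calling and position-level
normalization are out of scope.

## IHC scoring

Score = positivity bin × intensity bin. Positivity fractions are rounded
half-up to an integer percent and binned 0 (0%), 1 (1–10%), 2 (11–50%),
3 (51–80%), 4 (>80%); intensity maps none/weak/moderate/strong → 0–3. The
score is monotone in both components and ranges over the bin products
(never 5, 7, 10, 11). Group contrasts are unpaired two-sided rank-sum
tests (group-vs-group on tumor sections, tumor-vs-normal within group).
One consolidated value per section is consumed; reconciling two blinded
raters is outside computational scope.

## Synthetic cohorts

The generator emulates the study design every stage assumes: each patient
carries a TI lesion plus other-lobe lesions, each with one tumor and one
matched adjacent-normal sample; cell types with disjoint marker genes;
planted concordance genes shifted tumor-vs-normal per their class
definition; clone-specific contiguous CNV blocks over genomic bins; patchy
single-type regions on a mixed background lattice; and IHC tables with
group-shifted tumor scores. Counts are negative-binomial via a
gamma–Poisson mixture (dispersion 0.3 by default, configurable), the
standard stand-in for UMI data. Defaults are the emulated study
conditions: 4 patients, 2 lesions, 300 cells per sample, 1200 genes,
library size 2000, log₂ effect 2.0 for markers and planted classes, 20
planted genes per class.

Planted genes sit at fixed moderate abundances chosen so up- and
down-shifted mass cancels within each tumor stratum: an up-shifted gene at
baseline t and its down-shifted partner at t(2ᵉ−1)/(1−2⁻ᵉ) (4t at e = 2)
leave the expected library size unchanged, so the planted signal does not
bleed into null-gene fold changes through library normalization. OP genes
flip direction between lesions, where this cancellation is impossible;
they stay at the low baseline so the residual imbalance is negligible. A
small mitochondrial gene set (~5% of the library) and a MALAT1 stand-in
give the QC and gene filters realistic targets.

Not emulated: gene–gene correlation, doublets, ambient RNA, batch effects,
spot deconvolution mixtures, or asymmetric per-patient sampling. Passing
tests therefore demonstrate correctness of the statistics on data matching
the generative assumptions, not robustness to those artifacts.

## Problem sizes and determinism

The test suite runs the full recovery simulations at the study-condition
scale: concordance recovery on 300-cell samples with ~1200 genes, CNV
recovery over 20 seeds at 450 cells × 200 bins, consistency-score
calibration on ~2000-spot lattices over 20 seeds, bootstrap calibration at
n = 1000, B = 1000. All randomness flows through explicit integer seeds
(`numpy.random.default_rng`); identical seeds give bit-identical outputs,
including the end-to-end pipeline report.
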