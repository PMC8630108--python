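# Methods

## Quality control and normalization

Cells are removed when they have fewer than 400 detected genes, more than
10% mitochondrial counts, or a doublet score above 0.4. The thresholds are
strict removal conditions, so boundary cells (exactly 400 genes, exactly
10% mito, score exactly 0.4) are retained. Doublet scores are consumed as
per-cell annotations, never computed. QC metrics are computed once on the
raw matrix and cached in `.obs`, which makes the filter idempotent even
after gene-axis edits. The mitochondrial fraction is computed on the raw
matrix, before any gene removal.

Immunoglobulin genes (IGH/IGK/IGL prefixes) are removed from the gene axis
because of their extreme abundance in plasma/myeloma cells and the ambient
background they create; their raw counts are retained as cell metadata. A
12-gene blacklist of genes upregulated across all cell types in myeloma
samples is removed the same way. Both lists are configurable.

Expression is total-count normalized to 10,000 and natural-log
transformed: `v = ln(count / total x 1e4 + 1)`. All downstream statistics
(rank tests, bin-matched scores, CNA residuals) operate on ranks,
reference-centered residuals, or control-matched differences, none of
which depends on the choice of variance stabilizer, so plain
log-normalization is used throughout.

## CNA inference from expression

Per-cell copy-number signal is derived from the normalized matrix in five
steps: (1) genes with mean normalized expression < 0.1 across all cells
are dropped — lowly expressed genes carry no dosage information and only
add noise; (2) the per-gene mean of a copy-number-neutral reference
population (normal plasma cells; at least 30 cells required) is
subtracted; (3) residuals are clipped at ±3 reference SDs per gene so a
single outlier gene cannot mimic a CNA; (4) residuals are smoothed per
cell with a centered moving average of 101 genes inside each chromosome
(the window shrinks symmetrically at chromosome ends and never crosses a
boundary); (5) each cell is recentered at its median signal, absorbing
per-cell global shifts. The window of 101 genes is the scale at which
arm-level events dominate technical noise; it is configurable.

Key assumption: expression of genes in a region scales with DNA copy
number (mean multiplier `copy_number / 2`), so sustained positive/negative
smoothed signal over a region indicates gain/loss. Focal events shorter
than the smoothing window are invisible by construction.

## Subclone calling

Non-reference cells are clustered hierarchically (Ward linkage, Euclidean
distance on smoothed profiles). The dendrogram is cut at the largest
number of clusters for which every cluster keeps at least 40 cells — the
floor below which a cluster's mean profile and arm states are too noisy to
certify a clone, and which deterministically absorbs smaller planted
clones into their nearest relative. Because Ward happily splits one
genomic clone into expression-noise subclusters that all clear the 40-cell
floor, clusters whose per-arm gain/neutral/loss genotypes are identical
are then merged: a subclone is defined by its CNA genotype, not by
expression substructure. On planted three-clone cohorts the literal
largest-k cut alone yields adjusted Rand indices near 0.5; with genotype
merging, recovery is ≥ 0.9 and the number of clones is exact. The merge
step can be disabled (`merge_identical_states=False`). Two subclones that
differ only by events below the arm-state resolution (sub-arm or focal)
will be merged — a known limitation.

Arm states are called per subclone from the mean signal over the arm's
retained genes (at least 10 required): gain above, loss below ±3 SDs of
the reference cells' arm means. Final labels are ordered by decreasing
clone size with deterministic tie-breaks.

The 1q-gain cell fraction of a sample is the fraction of its tumor cells
sitting in gain-state subclones, classified into the three abundance
bands: not-detected/rare `[0, 0.1)`, subclonal `[0.1, 0.8]`, dominant
`(0.8, 1]` (closed subclonal interval; the band edges themselves count as
subclonal).

## Matched-clone differential expression and the 1q signature

For each patient in which a 1q-gained subclone coexists with a 1q-neutral
one, the gained clone is compared against its genetically closest neutral
relative — minimal Euclidean distance between mean CNA profiles computed
outside the 1q arm, ties to the lower label. Matching against the nearest
relative controls for the shared genetic background, so the comparison
isolates 1q-dosage effects within a sample.

Differential expression uses the two-sided Wilcoxon rank-sum test on
normalized values (exact enumeration when both groups together hold ≤ 20
cells, tie-corrected normal approximation otherwise), Bonferroni
correction over the tested genes, and requires adjusted p < 0.05 and
|logFC| > 0.1. Only genes expressed in ≥ 10% of either group are tested,
which keeps the Bonferroni denominator honest. The log fold change follows
the common single-cell convention: natural log of the pseudocounted
de-logged group means.

The signature keeps genes significantly upregulated in at least
`min_recurrence` patients (default: half the contributing patients,
rounded up), located on 1q, and not mitochondrially encoded. Recurrence is
counted before the location filter; the order does not change the final
set, since both filters are intersective.

## Module scores

A gene set is scored per cell as its mean expression minus the mean of
pooled control genes: all genes are ranked into 24 bins by average
expression, and each signature gene draws 100 controls (with replacement)
from its bin, excluding signature genes. Expression-matched controls make
the expectation for a random gene set ≈ 0; measured bias over random
25-gene signatures is ~0.01, an order of magnitude below the per-cell
score spread. If a bin consists entirely of signature genes, controls fall
back to the bin itself and the score collapses toward 0. A fixed seed
makes the control draw, and hence the score vector, reproducible.

Scores are evaluated two ways: the positive predictive value of
`score ≥ threshold` against the CNA-derived per-cell truth (threshold 0.2
by default; zero positives give PPV = NaN with counts reported), and the
Pearson correlation between per-sample mean score and per-sample 1q
fraction.

## Clone stability

For pre/post-treatment fraction maps, every clone in the union with a
nonzero fraction at either timepoint contributes the ratio
`min(f_pre, f_post) / max(f_pre, f_post)` (a clone absent at one timepoint
contributes 0 — births and deaths count as instability); the score is the
mean ratio. It is symmetric in the two timepoints and equals 1 exactly
when the compositions are identical over the union.

## Ligand-receptor interactions

Complex expression per cell is the minimum over subunit genes (a complex
is only as available as its scarcest subunit). Within one patient sample,
only cell types with more than 20 cells participate. A pair is tested for
sender A and receiver B when the ligand complex is expressed in more than
10% of A and the receptor complex in more than 10% of B; the statistic is
the mean of the two complex means. The null permutes cell-type labels over
the eligible cells (1,000 permutations by default) and the p-value uses
the add-one estimator `(1 + #{perm ≥ obs}) / (n_perm + 1)`, so it is never
exactly zero and its floor is `1/(n_perm+1)`. Measured type-I error at
alpha = 0.05 under random labels sits inside the 95% binomial band.

Cohort summaries: significant-interaction counts per ordered type pair are
averaged over the patients in which *both* types were eligible (patients
in which a type failed the cell floor do not dilute the mean); strengths
sum the observed statistics of significant pairs across patients. The
network connects every cell type to its top-4 partners by symmetrized
strength (`s(A,B) + s(B,A)`; the drawn graph is undirected), ties broken
lexicographically; node degree is computed on the union of all selections.
Each patient sample (patient x timepoint) is tested independently;
timepoints are not pooled.

## Composition

Per-sample cell-type fractions drop types with fewer than 5 cells and
renormalize over the retained types (renormalization is switchable).
Group comparisons use the two-sided Wilcoxon rank-sum test per cell type
with Bonferroni correction over the tested types; types present in only
one group are flagged and reported with NaN p-values.

## The synthetic cohort generator

The generator emulates exactly the statistical structure the analysis
assumes: negative-binomial counts with per-gene base means, per-cell
library factors, patient-specific tumor expression programs, multiplicative
arm-level dosage (`copy_number / 2`, optionally attenuated per gene by a
Beta-distributed response), marker-gene fold changes for eight
bone-marrow cell types, planted ligand-receptor co-expression, junk cells
and doublet scores for QC, and pre/post clone-fraction tables.

Scale: the toy genome compresses a ~20,000-gene transcriptome into a
~2,000-gene panel on 22 autosomes whose arm proportions mirror real
centromere positions (13/14/15/21/22 are acrocentric, q-only; chromosome
1, the most gene-dense, gets double weight and a 50/50 p/q split).
Each panel gene therefore behaves like an aggregate of roughly ten real
genes: lognormal base means around ~12 counts and NB inverse-dispersion 10
are the moments of such meta-gene sums at typical droplet sequencing
depth. This keeps the information content per 101-gene smoothing window
comparable to real data on the shortened genome; with per-gene counts at
raw droplet depth, 45-gene toy arms would carry ~10x less information than
the ~450-gene real arms they stand in for.

The stock cohort has 10 patients with paired pre/post samples (500 tumor,
120 normal-plasma, 400 microenvironment cells per sample — scaled to run
the full chain in minutes on one core), planted 1q fractions spanning
0 → 1 across all three abundance bands, gained clones that expand after
treatment, and a shifted microenvironment composition (more tumor-
associated macrophages, fewer NK cells) in patients with detectable 1q
gain. The signature cohort plants a subclonal 1q clone (fraction 0.45)
in each of 10 patients with 100 dosage-responsive genes on 1q.

What the generator does **not** emulate: transcriptome-wide co-expression
and pathway structure, ambient RNA, true doublet expression profiles,
batch or chemistry effects, and focal/sub-arm or allele-specific CNAs.
Passing tests therefore certify the statistical machinery under the
model's own assumptions — dosage acting multiplicatively on NB means with
an expression-neutral background — not robustness to every artifact of
real tissue data.

## Numerical and reproducibility choices

- All stochastic stages draw from `numpy` Generators; a single pipeline
  seed fans out per stage via `seed * 1_000_003 + crc32(stage)` mod 2^31,
  so stages are individually reproducible and two runs with one seed are
  byte-identical (verified down to the written TSVs).
- Hierarchical-clustering cut search scans k from `n_cells // 40` down to
  2 and takes the first k whose clusters all clear the floor; dendrogram
  and permutation procedures are deterministic given their inputs.
- Degenerate inputs fail loudly: zero-total cells at normalization, < 30
  reference cells, too few retained genes for the window, all-zero
  fraction maps, out-of-range fractions, zero-variance correlations.
- Constant genes (all ties) receive p = 1 in rank tests rather than NaN.
- Reference per-gene SDs are floored at 1e-8 before clipping.
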