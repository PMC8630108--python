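# mmscope

Subclone-resolved single-cell RNA-seq analysis for multiple myeloma.

Relapsed/refractory multiple myeloma (RRMM) tumors are mosaics of genetic
subclones, and gain of chromosome arm 1q (+1q) is a high-risk aberration
that can emerge from clones comprising only 1–2% of tumor cells. `mmscope`
re-implements, as a tested and reusable Python library plus CLI, an
analysis chain that resolves this structure directly from droplet scRNA-seq
count matrices:

1. **Expression-inferred CNA profiles.** For each cell, log-normalized
   expression is centered on a normal-plasma-cell reference, clipped at
   ±3 reference SDs per gene, smoothed along the genome with a 101-gene
   moving average that never crosses a chromosome boundary, and recentered
   at the cell's median — gains/losses appear as sustained positive/negative
   signal over genomic regions.
2. **Subclone calling.** Cells are clustered hierarchically (Ward,
   Euclidean) on their CNA profiles; the dendrogram is cut at the largest
   number of clusters with ≥ 40 cells each, and clusters with identical
   per-arm gain/neutral/loss genotypes are merged — a subclone is a group
   of cells sharing a CNA genotype.
3. **+1q signature.** Within each patient, differential expression
   (two-sided Wilcoxon rank-sum, Bonferroni p<sub>adj</sub> < 0.05,
   logFC > 0.1) between a +1q clone and its genetically closest 1q-neutral
   relative; genes upregulated in ≥ 5 of 10 patients, located on 1q, and
   not mitochondrially encoded form the signature.
4. **Per-cell module scores.** Signature expression minus the expression
   of expression-bin-matched control genes (24 bins, 100 controls per
   gene), so a random gene set scores ≈ 0; evaluated by PPV against the
   CNA-derived truth and by the per-sample score-vs-+1q-fraction Pearson
   correlation.
5. **Clone dynamics.** Subclone fractions per pre/post-treatment sample and
   the clone-stability score `mean over clones of min(f_pre, f_post) /
   max(f_pre, f_post)` (1 = stable composition, 0 = complete turnover).
6. **Ligand–receptor interaction networks.** Per patient, a pair's
   statistic between sender type A and receiver type B is
   `(mean ligand-complex in A + mean receptor-complex in B) / 2`
   (complex expression = minimum over subunits), tested against a
   cell-type-label permutation null; cohort summaries average significant
   counts and sum strengths, and every cell type connects to its top-4
   partners by summed strength.
7. **Composition analysis.** Per-sample cell-type fractions (≥ 5-cell
   floor) compared between groups with Wilcoxon/Bonferroni.

The patient data behind the original study are restricted-access, so the
package ships a first-class synthetic cohort generator
(`mmscope.synthetic`) that plants known subclones with copy-number dosage
effects (NB counts with mean scaled by `copy_number / 2`), +1q clones at
controlled fractions, bone-marrow cell types with markers, and
ligand–receptor co-expression — every stage is validated against this
planted truth.

## Worked example

```python
from mmscope import synthetic, io_core, cna
from sklearn.metrics import adjusted_rand_score

cfg = synthetic.three_clone_config(seed=1)       # 3 clones: 0.5 / 0.3 / 0.2
ds = synthetic.simulate_cohort(cfg)              # 2,000 tumor + 300 reference cells
norm = io_core.normalize_log(io_core.qc_filter(ds.adata))
reference = list(norm.obs_names[norm.obs["cell_type"] == "nPC"])
profiles = cna.infer_cna_profiles(norm, ds.gene_order, reference)
subclones = cna.call_subclones(profiles)
print(subclones.sizes.to_dict())
print(subclones.arm_states[["3q", "11q", "13q"]])
truth = ds.adata.obs.loc[profiles.tumor_ids, "subclone"]
print("ARI vs planted clones:",
      round(adjusted_rand_score(truth, subclones.labels[truth.index]), 3))
```

prints

```
{'SC1': 1006, 'SC2': 600, 'SC3': 394}
          3q      11q      13q
SC1  neutral  neutral  neutral
SC2     gain  neutral     loss
SC3  neutral     gain  neutral
ARI vs planted clones: 0.956
```

The three planted clones (1,000 / 600 / 400 cells) are recovered almost
perfectly, the clone carrying the 3q gain + 13q loss and the clone carrying
the 11q gain are each assigned the correct arm states, and the remaining
clone is copy-number neutral.

The same chain runs from the shell:

```bash
mmscope simulate --seed 1 --out cohort/
mmscope run-all --data cohort/ --seed 1 --out results/
```

`run-all` writes subclone assignments, arm states, clone fractions and
stability scores, the derived 1q signature with per-cell scores and PPV,
per-sample ligand–receptor tests with the top-4 network, and cell-type
composition tables — all as TSV/JSON, byte-identical for a fixed seed.

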