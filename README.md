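# spheroid-ith

Analysis toolkit for quantifying **intratumoural heterogeneity (ITH)** in
single-cell-derived tumour spheroids from label-free DIA proteomics and
functional assays.

Clonal spheroids grown from FACS-sorted single cells (e.g. of the
patient-matched colorectal cancer lines SW480 and SW620) differ in
morphology, size, viability, proteome and chemotherapy response. This
package implements the full desk-side analysis of such a cohort:

* **Preprocessing** of DIA-NN `pg_matrix` protein-group tables: log2
  transform, per-sample proteome-depth filter (default 2500 quantified
  proteins), complete-case protein filter, row-wise Z-scoring for
  heatmaps.
* **Pairwise fold-change Borda ranking** — the core statistic. Within a
  cell line with *n* spheroid proteomes, log2 fold changes
  FC<sub>p</sub>(i, j) = x<sub>p,i</sub> − x<sub>p,j</sub> are computed
  for every protein *p* and every unordered pair of spheroids. For each
  of the C(n, 2) pairs the *k* = 50 proteins with the largest |FC| form a
  top-k list and receive Borda points (50 for the largest |FC| down
  to 1). Points are summed across all lists; sorting by total points
  gives the ranked list of **candidate ITH-driver proteins** (the union
  of all top-k lists), which can be partitioned into shared and
  line-specific drivers between two cell lines.
* **Phenotype statistics**: the diameter-related metabolic activity
  DMA = viability / diameter (RLU/µm), per-attribute 2×2 morphology
  tables with Fisher's exact test, Shapiro + two-sample
  Kolmogorov–Smirnov distribution comparisons, coefficients of
  variation, and size–viability least-squares regression.
* **Therapy response**: four-parameter logistic (4PL) dose–response
  fitting for IC50 determination
  (v(d) = bottom + (top − bottom) / (1 + (d/IC50)<sup>h</sup>)),
  percent viability reduction, an exact Wilcoxon matched-pairs
  signed-rank test, and size–resistance regression.
* **Multivariate / enrichment**: PCA of spheroid proteomes and
  single-sample GSEA (per-sample difference of the weighted in-set ECDF
  and the out-set ECDF over the gene ranking), with top-30 pathway
  selection and redundancy collapsing.
* **Synthetic cohorts** with planted ground truth: log-normal diameter
  distributions, linear diameter–viability coupling, morphology
  frequencies, size-ordered proteome clusters, bimodal driver proteins,
  size-coupled missingness and 4PL dose–response — so every stage is
  testable without any external download.

## Worked example

```python
import spheroid_ith as si

cfg = si.SimulationConfig(seed=1)            # two lines, 16 spheroids each
cohort = si.simulate_cohort(cfg)
matrix, truth = si.simulate_protein_matrix(cfg, cohort)
filtered, report = si.preprocess_matrix(matrix, min_proteins=cfg.depth_threshold)
print(f"spheroids: {len(cohort)}  proteins: {matrix.shape[0]} "
      f"-> complete-case: {filtered.shape[0]}")

ids = [r.spheroid_id for r in cohort.subset("SW480")]
ranking = si.rank_proteins(filtered, ids, k=50)
print(f"candidate ITH-driver proteins (SW480): {len(si.candidate_set(ranking))}")
for e in ranking.top(3):
    print(f"  rank {e.rank}: {e.protein_id}  total_points={e.total_points}  "
          f"n_lists={e.n_lists}")
top50 = {e.protein_id for e in ranking.top(50)}
print(f"planted drivers recovered in top 50: "
      f"{len(set(truth.protein_ids) & top50)}/{len(truth)}")
```

prints

```
spheroids: 32  proteins: 1200 -> complete-case: 660
candidate ITH-driver proteins (SW480): 545
  rank 1: P0643  total_points=2798  n_lists=64
  rank 2: P0599  total_points=2655  n_lists=61
  rank 3: P0640  total_points=2581  n_lists=60
planted drivers recovered in top 50: 15/15
```

The 660 complete-case proteins are those quantified in every spheroid;
the ranking's top protein accumulated 2798 Borda points over 64 of the
120 pairwise comparisons, and all 15 planted bimodal drivers surface in
the aggregated top 50 — the pairwise |FC| statistic is built to catch
exactly this kind of two-subpopulation expression split.

The same pipeline runs from the shell:

```sh
spheroid-ith run --mode simulate --seed 1 --out-dir run_out
spheroid-ith run --mode real --matrix pg_matrix.tsv --cohort cohort.csv \
    --dose-response doses.csv --out-dir results
```

producing cohort/matrix/ranking/overlap/phenotype/therapy tables plus a
`manifest.json` recording parameters, seed and input checksums; two runs
with identical config and seed are byte-identical.

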