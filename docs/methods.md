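# Methods

## The Borda fold-change ranking

The central statistic targets proteins whose abundance differs strongly
*between* clonal spheroids of the same cell line, i.e. candidate drivers
of intratumoural heterogeneity, without assuming any group structure.

For one cell line with $n$ complete spheroid proteomes ($x_{p,s}$ =
log2 intensity of protein $p$ in spheroid $s$):

1. for every unordered pair $(i, j)$, $\mathrm{FC}_p(i,j) = x_{p,i} - x_{p,j}$;
2. per pair, proteins are sorted by $|\mathrm{FC}|$ and the top $k = 50$
   receive Borda points $k, k-1, \dots, 1$;
3. points are summed over all $\binom{n}{2}$ lists; the final list is
   sorted by total points. Every protein with at least one point (the
   union of the per-pair lists) is a *candidate ITH-driver protein*; no
   further point cutoff is applied, because the candidate-set size then
   arises naturally from the overlap of the per-pair lists. An optional
   `min_points` argument tightens the set.

Only $|\mathrm{FC}|$ enters the statistic, so the orientation of each
pair is irrelevant; only one orientation (matrix order) is stored.
Because a two-subpopulation ("bimodal") expression split produces large
|FC| for every *across*-subpopulation pair — roughly half of all pairs —
such proteins dominate many lists and accumulate points roughly in
proportion to $n_a n_b$ (the subpopulation sizes), which is what makes
the statistic sensitive to clonal heterogeneity rather than to single
outlier samples.

**Tie-breaking.** Equal $|\mathrm{FC}|$ at a list boundary and equal
total points in the final ranking are broken by ascending protein
accession (and, for totals, by descending number of contributing lists
first). This makes results deterministic and invariant to the sample
order of the input matrix; no tie-break ever references sample order.

**Points for short lists.** When fewer than $k$ proteins exist, points
still start at $k$ (running $k, k-1, \dots$), so a pair's best protein
is always worth $k$ points regardless of matrix size, keeping scores
comparable across pairs.

## Preprocessing

Raw DIA protein-group intensities are log2-transformed (zero or negative
intensities are a hard error — the matrix is expected to carry either a
positive intensity or a missing value). Two filters follow:

1. **depth filter** — samples quantifying fewer than `min_proteins`
   proteins (default 2500) are removed;
2. **complete-case filter** — proteins with any remaining missing value
   are removed.

Samples are filtered *before* proteins so that a protein missing only in
a discarded low-depth sample is rescued; the order is configurable. The
composite is idempotent provided the depth threshold does not exceed the
complete-case protein count. Nothing is ever imputed: the missing mask
only shrinks through row/column removal. Row-wise Z-scores (used for
heatmap matrices) use the sample standard deviation (ddof = 1); constant
rows map to zeros rather than erroring, the usual heatmap convention.

## Phenotype statistics

* **DMA** (diameter-related metabolic activity) = viability (RLU) /
  diameter (µm). It normalises the ATP readout by spheroid size so that
  metabolically distinct subpopulations are visible beyond sheer cell
  number. It is invariant under joint rescaling of both inputs.
* **Morphology tables**: each attribute (round/diffuse shape,
  compact/loose clustering, budding yes/no, sharp/blurred margin) forms
  a 2×2 table (levels × cell lines) tested with the conventional
  two-sided Fisher's exact test (point-probability method: the p-value
  sums hypergeometric probabilities no larger than the observed
  table's). Degenerate tables (a zero margin) return p = 1 with a
  warning. Percentages are reported to one decimal.
* **Distribution comparisons** run Shapiro normality per sample (both
  p-values reported) followed by a two-sample Kolmogorov–Smirnov test;
  the Shapiro outcome does not gate the KS test — the KS comparison is
  reported regardless — since the KS test is valid either way.
* **Regressions** are ordinary least squares with R² = squared Pearson
  correlation; the coefficient of variation is sample SD (ddof = 1) /
  mean.

## Therapy response

The 4PL model $v(d) = b + (t - b) / (1 + (d/\mathrm{IC50})^h)$ is fitted
on the natural dose scale; a zero dose contributes exactly the top
asymptote (no log transform of doses is needed), and IC50 and Hill slope
are bounded positive. Initialisation: top/bottom from the mean viability
at the lowest/highest dose, IC50 from the geometric mid-range of the
positive doses, $h = 1$. Residuals are weighted by 1/viability by
default ("relative" weighting): luminescence viability assays carry
multiplicative noise, under which an unweighted fit systematically
underestimates the IC50 (in our simulations, ~10% median error at 10%
noise versus ~4% with weighting); `weighting="none"` restores the
ordinary fit. Noise-free curves are recovered exactly either way.

The Wilcoxon matched-pairs signed-rank test is exact up to n = 25: the
null distribution of the positive-rank sum is enumerated over all
$2^n$ sign assignments by dynamic programming (ranks doubled so
tie-averaged half-ranks become integers); the two-sided p is twice the
smaller tail probability, capped at 1. Above n = 25 a normal
approximation with continuity and tie corrections is used. Zero
differences are dropped and their count reported. At n = 8 with all
differences of one sign this yields p = 2/256 ≈ 0.0078, the smallest
two-sided p attainable at that sample size.

## PCA and ssGSEA

PCA operates on samples in protein space after per-protein centering
(full SVD solver). Each component's sign is fixed so its
largest-magnitude protein loading is positive — a deterministic
convention, since the sign of a principal axis is otherwise arbitrary.

The ssGSEA score of a gene set in one sample ranks all genes by
descending value (ties broken by gene name), then sums, across the
ranking, the difference between the in-set ECDF — each in-set gene
weighted by $|v|^{w}$, normalised to total 1 — and the uniform out-set
ECDF. Expression profiles are rank-normalised per sample (average ranks
scaled to (0, 1]) before scoring. The weight exponent defaults to
$w = 0.25$, the common ssGSEA convention, and is configurable; at
$w = 0$ the score is purely rank-based and invariant under monotone
transforms of the profile. "Most differentially represented" pathways
are those with the largest absolute score spread across samples (or the
largest absolute group-mean difference when two sample groups are
given); redundant sets — gene-content overlap coefficient ≥ 0.9 with a
higher-ranked set — are collapsed, keeping the higher-scoring one.

## The synthetic cohort generator

The generator reproduces the statistical structure of a two-line
single-cell-derived spheroid study so that every pipeline stage can be
validated against planted ground truth. All outputs are pure functions
of (config, seed); cohort, matrix and dose-response stages draw from
independent deterministic substreams.

| parameter | default | rationale |
|---|---|---|
| diameter law | log-normal | strictly positive, supports the target CVs; medians 100 µm / 251 µm (the absolute scale is arbitrary — only the 2.51 ratio and CVs 0.53 / 0.66 are studied conditions) |
| viability | slope · d · (1 + ε), ε ~ N(0, 0.18²), truncated at 0 | linear coupling (the readout is analysed with linear regressions; a cubic volume law is arguable but is not what the assay's regression models); noise CV calibrated so the **median** R² over 100 seeds at n = 45 sits in 0.86–0.91 — individual n = 45 draws scatter roughly 0.65–0.97 by sampling alone, so a per-seed band would be unattainable |
| morphology | Bernoulli per attribute | first-level probabilities 15/28, 23/28, 18/28, 19/28 (line A) and 4/45, 20/45, 23/45, 17/45 (line B) |
| proteome | 1200 proteins, baseline centres N(14, 2²) log2, noise sd 0.3 | desk-scale stand-in for a few-thousand-protein DIA run |
| clusters | 3 size-ordered groups per line, ± up to 0.8 log2 on 15% of proteins | produces the size-associated PCA structure |
| drivers | 15 proteins, bimodal: a random 50% subpopulation shifted ± 2.0 log2 | bimodality is the minimal generative form the pairwise-FC statistic targets; the shift is comfortably above the noise floor but far below a trivial separation |
| missingness | per-sample mean rate 0.05 + 0.30 · (1 − normalised diameter); concentrated in the 45% least abundant proteins | smaller spheroids quantify fewer proteins; see below |
| dose-response | 4PL, IC50 350 µM, Hill 1, 8 log-spaced doses plus dose 0, 10% multiplicative noise, optional resistant subset (IC50 × factor) | resistant at low dose, collapsing at high dose |

**Missingness model.** An i.i.d. per-cell missingness rate would make
the complete-case proteome vanish (with 32 samples at a mean rate of
0.2, essentially no protein survives), which contradicts how DIA data
behave: missingness concentrates in low-abundance proteins near the
detection limit. The generator therefore keeps a `quantified_fraction`
(default 0.55) of the most abundant proteins complete in every run and
places the entire size-coupled rate on the low-abundance remainder,
preserving the configured per-sample mean rate exactly. Drivers and
cluster proteins are planted among the always-quantified proteins —
matching the real-data situation, where candidate drivers are by
construction members of the complete-case set.

**What the generator does not emulate**: peptide/precursor-level
effects and FDR behaviour, between-run normalisation artefacts,
correlated protein modules beyond the planted clusters, spatial/3D
spheroid geometry, necrotic cores, and immune or stromal compartments.
Passing recovery tests therefore demonstrates that the statistics detect
the targeted structure at realistic noise levels — not that real
cohorts contain such structure, nor that the pipeline is robust to
artefacts the generator omits.

## Problem sizes used in tests and the acceptance script

Desk-scale conditions: 16 spheroids per line, 1200 proteins, 15 planted
drivers (candidate/top-50 recovery over 5 seeds); 5000 spheroids per
line for distributional calibration; 100 seeds × n = 45 for the R²
median; 50 seeds × 4 spheroids for noisy IC50 recovery; 200 random
matrices up to 6 × 30 for brute-force oracle equivalence. These sizes
keep every check well-powered while running in seconds.

## Known limitations

* The Borda ranking attaches no significance measure — it is a
  prioritisation, not a test; permutation p-values would be a natural
  extension.
* Candidate-set size depends on k, the pair count and the noise
  spectrum; it is not comparable across matrices of different size
  without calibration.
* The exact signed-rank enumeration treats ties by average ranks; its
  null distribution then differs slightly from the classic untied
  tables (this is the conditional, tie-aware distribution).
* ssGSEA normalisation variants differ between tools; only the
  weighted-ECDF difference core is implemented, with the exponent
  exposed.
* The 4PL fit assumes monotone inhibition; hormetic (low-dose
  stimulatory) responses are flagged only as a "no inhibition" warning.
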