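# Methods

## Model and assumptions

The classifier rests on two empirical assumptions about tumor scRNA-seq
data: (1) a compact set of genes is consistently up-regulated in malignant
cells (and another set in the immune/stromal compartment) across cancer
types, so that the intersection of per-dataset differential-expression
calls is a transferable feature space; and (2) in that feature space,
after per-gene min–max scaling within each dataset, malignant and
non-malignant cells occupy separable neighborhoods, so a lazy k-NN
classifier per labeled reference plus a majority vote across references is
sufficient. No parametric model of expression is fitted at prediction
time; k-NN makes no distributional assumption, which suits the non-normal,
zero-inflated character of single-cell counts.

The ensemble is deliberately simple: each reference dataset contributes one
independent vote, and disagreement between references is surfaced as the
vote frequency rather than hidden in a pooled training set. This keeps
references with different protocols or compositions from contaminating one
another and lets users append references without retraining anything.

## Normalization

Two dialects, chosen by protocol:

| dialect | transform | used for |
|---|---|---|
| `tpm_log2` | `log2(TPM/10 + 1)` | full-length protocols (e.g. Smart-seq2) |
| `umi_lognorm` | per-cell depth scaling to 10,000 counts, then `ln(x+1)` | UMI protocols |

The UMI log is the natural log, matching the convention of the standard
single-cell normalization in Seurat. Cells with zero total count normalize
to all-zero columns and are retained: quality control is treated as an
upstream responsibility, and this tool never silently drops cells.

Min–max scaling is per gene, *within* each dataset — the reference is
scaled by its own per-gene min/max and the query by its own. Genes constant
within a dataset map to all-zero rows, which makes them inert in Euclidean
distance; this is also why adding a constant gene provably changes no
prediction. Scaling statistics are computed on the aligned marker-feature
rows after feature alignment. Because scaling is per gene, scaling all
genes versus only the marker features is equivalent on the feature
subspace, so the implementation scales exactly the features it uses.

## Marker discovery

Per gene and dataset: two-sided Wilcoxon rank-sum p-value (exact
enumeration when both classes have ≤ 8 cells and the pooled values are
tie-free, otherwise the normal approximation with tie and continuity
corrections — the exact branch exists so the test is verifiable against an
enumeration oracle at small n); Bonferroni multiplier equal to the *total*
number of genes in the dataset (conservative, independent of any
pre-filtering); detection fractions `pct` computed as the share of cells
with normalized value > 0.

`log_fc` defaults to the difference of class means of log-normalized
expression (malignant − non-malignant). A `fold_change="log2_ratio"`
switch provides the alternative convention (log2 ratio of de-logged class
means with pseudocount 1) for parity experiments with pipelines that use
it; the two conventions can call slightly different gene sets near the
0.25 threshold. The detection filter applies to the favored class only: an
up-in-malignant call requires detection in ≥ 10 % of *malignant* cells.

All genes are tested; the vectorized rank-sum implementation is fast
enough that no speed pre-filter is needed, and the reported p-values are
therefore complete.

Consensus: a gene enters the TMG (NMG) list iff it is called up-malignant
(up-non-malignant) in every table passed to `intersect_markers`; output
order follows the first table. Adding tables can only shrink the
consensus.

## Classification

- Distance: Euclidean on the scaled features (default; `cosine`
  available). The metric is configurable because plain k-NN convention
  does not fix it; Euclidean is the default of standard k-NN
  implementations.
- k = 5 by default, odd by contract so a single base vote cannot tie.
- Distance ties at the k-th neighbor break by ascending reference cell
  index via a stable sort — deterministic across runs and platforms.
- Ensemble tie (possible only with a user-supplied even reference count):
  the label follows the continuous score (> 0.5 → malignant); a score of
  exactly 0.5 falls to non-malignant with a logged warning. The CLI warns
  whenever an even number of references is supplied.
- References that share no marker genes with the query are dropped with a
  warning; if none survive, prediction fails. Coverage below 50 % of the
  marker set logs a warning but proceeds.
- Query cells are classified independently; `workers > 1` parallelizes
  over query-cell chunks with bit-identical results to sequential
  execution.

## Evaluation

Malignant is the positive class. Balanced accuracy is exactly
(sensitivity + specificity)/2. AUROC is rank-based (Mann–Whitney), ties
counted 0.5, computed on the ensemble's continuous score (mean
malignant-neighbor fraction) rather than the 6-level vote frequency — the
finer granularity gives a better-resolved ROC for a discrete ensemble;
any strictly monotone transform of scores leaves it unchanged. If the
truth contains a single class, the undefined rate is NaN with a warning
and AUROC is unavailable.

Cross-validation is stratified by class and seeded. Each held-out fold is
predicted by a *single* base classifier referenced on the remaining folds
(no ensemble — CV characterizes one dataset's self-consistency); train and
test partitions are each min–max scaled with their own statistics,
mirroring how reference and query are scaled at prediction time.
Predictions are pooled over folds before computing metrics, so the pooled
confusion counts sum to the dataset size.

## Synthetic data

`simulate_dataset` draws counts gene-by-cell from a gamma-mixed Poisson
(negative binomial; `dispersion` is the inverse-size parameter, variance
mu + dispersion·mu²), with lognormal per-cell library sizes (sigma 0.3
around `library_size_mean`) and independent dropout zeroing at
`dropout_rate`. Planted up-in-malignant genes get a `effect_size`
natural-log mean shift in malignant cells (planted non-malignant markers
symmetrically). Planted genes' baseline relative abundances are drawn from
a moderately-expressed regime (lognormal, median 2× the null median), as
real marker genes are detectably expressed; this exercises the detection
filter rather than trivially failing it. Counts are passed through the UMI
normalization, so downstream modules see the same representation as real
data.

Defaults (300 cells per class, 2,000 genes, 25 + 50 planted markers,
effect size 2.0, dropout 0.2, dispersion 0.5, mean library 5,000) describe
a mid-sized, well-powered dataset; they are the conditions under which the
power and end-to-end recovery properties in the test suite are stated.
Panel members derive their seeds as `seed + 1 + index`, and a
`shared_marker_fraction` controls how many planted markers are common to
all members versus private (private markers occupy disjoint gene blocks,
so a private marker of one member is null in all others — giving the
consensus intersection true negatives).

What the simulation does **not** emulate: batch effects, cell-cycle
structure, doublets, multiple non-malignant subtypes, gene–gene
correlation, or any real dataset's empirical distribution. Passing tests
demonstrate correctness of the algorithms under the stated generative
model, not field performance on real tissue.

## Numerical choices and degenerate inputs

- Constant genes: p-value fixed at 1 (the rank-sum z-statistic is 0/0),
  log-fold-change 0, direction none; min–max maps them to zero rows.
- All-zero cells survive UMI normalization as all-zero columns.
- Bonferroni-adjusted p-values are clipped at 1.
- `wilcoxon_rank_sum` switches exact → asymptotic at group size 8 or on
  any tie.
- Problem sizes in the test suite are scaled-down versions of the default
  simulation (80–300 cells per class, 300–2,000 genes), chosen to keep the
  full suite fast while leaving every filter (detection, fold change,
  Bonferroni) active rather than saturated.

## Known limitations

Binary output only — no subtype annotation of non-malignant cells, no
rejection/unknown class, no probability calibration. The AUROC score
definition for an ensemble of hard voters is a design choice (documented
above) and may differ from other implementations. Whether min–max scaling
should ever pool reference and query is decided here as "never" (each
dataset on its own statistics); pipelines that pool will produce slightly
different neighborhoods.
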