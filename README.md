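# precancell

Classify single cells from tumor single-cell transcriptomes as **malignant**
or **non-malignant**, using consensus marker genes and an ensemble of
per-reference k-nearest-neighbor classifiers.

Distinguishing cancer cells from the surrounding immune and stromal cells is
a routine first step in analyzing tumor scRNA-seq data. Copy-number-based
inference needs extra reference material, and generic cell-type annotators
are not tuned for the malignant/non-malignant split. This package takes the
supervised route: learn what malignant cells look like from well-annotated
labeled datasets, and vote.

## Method

**Consensus marker discovery.** For each labeled reference dataset, every
gene is tested malignant vs non-malignant with a two-sided Wilcoxon rank-sum
test, Bonferroni-corrected over all genes. A gene is *up in malignant cells*
when

- adjusted p < 0.05,
- it is detected (expression > 0) in ≥ 10 % of malignant cells, and
- its mean log-expression difference (malignant − non-malignant) exceeds 0.25;

*up in non-malignant* is the mirror image. Genes up in the same direction in
**every** dataset form the tumor marker genes (TMGs) and non-tumor marker
genes (NMGs). A bundled set of 73 TMGs and 186 NMGs — derived from five
labeled datasets covering renal cell carcinoma, head-and-neck squamous
carcinoma, melanoma, lung adenocarcinoma and breast cancer — ships with the
package and is the default feature space.

**Ensemble k-NN prediction.** Expression is log-normalized
(`E = log2(TPM/10 + 1)` for full-length data; size-factor 10,000 + `ln(x+1)`
for UMI data), then each gene is min–max scaled to [0, 1] *within each
dataset*:

```
x_scaled = (x − min(x)) / (max(x) − min(x))
```

Each reference dataset drives one base classifier: a query cell takes the
majority label of its k = 5 nearest reference cells (Euclidean distance on
the marker features). With R references, the cell's final label is the
majority of the R base votes; the *vote frequency* (fraction of malignant
votes) and the *score* (mean malignant-neighbor fraction) quantify ensemble
agreement. Evaluation reports accuracy, sensitivity, specificity, balanced
accuracy ((sensitivity + specificity)/2) and rank-based AUROC, plus a
stratified 10-fold cross-validation protocol for single datasets.

A negative-binomial simulator with planted class-specific genes, library-size
variation and dropout generates labeled datasets for testing and power
analysis (`precancell.simulate`).

## Worked example

`examples/` contains one short script per capability. Running
`python examples/03_ensemble_prediction.py` simulates a 5-dataset reference
panel, derives consensus markers and classifies an independent query:

```
consensus feature space: 25 TMGs + 50 NMGs
query cells: 600  confusion: tp=300 fp=0 tn=300 fn=0
accuracy=1.000 sensitivity=1.000 specificity=1.000 balanced=1.000 AUROC=1.000
fraction of cells with a unanimous 5-0 vote: 1.000
```

All 75 planted marker genes survive the five-way intersection, and every one
of the 600 held-out cells is voted 5–0 to its true class — the planted
log-mean shift of 2.0 separates the classes far beyond what k = 5 neighbors
need. Real tissue is harder (see `docs/methods.md` for what the simulation
does and does not emulate).

The same pipeline is scriptable from the shell:

```bash
precancell simulate --config sim.json --out-dir panel/
precancell find-markers --expr panel/ref_0.csv --labels panel/ref_0.labels.csv --out t0.tsv
precancell intersect --table ref_0=t0.tsv --table ref_1=t1.tsv --out consensus.tsv
precancell predict --query query.csv --references panel/ --markers bundled --out predictions.csv
precancell evaluate --predictions predictions.csv --truth labels.csv --out report.json
```

## Limitations

The method assigns malignant vs non-malignant only — it does not annotate
subtypes of non-cancer cells (immune, stromal, epithelial), produce an
"unknown" class, or calibrate probabilities. Upstream quality control is
assumed to have been applied to the inputs.
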