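"""Normalize a tiny raw count matrix two ways and min–max scale it.

Builds a 4-gene × 3-cell UMI count matrix in memory, applies per-cell
depth normalization (size factor 10,000, then ln(x+1)), shows the
full-length TPM dialect on the same numbers, and finishes with per-gene
min–max scaling — the feature scaling the k-NN classifiers operate on.
"""

import numpy as np

from precancell import (
    ExpressionMatrix,
    minmax_scale,
    normalize_full_length,
    normalize_umi,
)

counts = ExpressionMatrix(
    values=np.array(
        [
            [5.0, 0.0, 10.0],
            [0.0, 2.0, 10.0],
            [3.0, 1.0, 0.0],
            [0.0, 0.0, 20.0],
        ]
    ),
    gene_ids=["GENE_A", "GENE_B", "GENE_C", "GENE_D"],
    cell_ids=["cell_1", "cell_2", "cell_3"],
)

umi = normalize_umi(counts)
print("UMI log-normalized (ln of depth-scaled counts + 1):")
print(umi.to_frame().round(3))
print("-> each column is depth-normalized, so doubling a cell's reads changes nothing\n")

tpm = normalize_full_length(counts)  # pretend the same numbers were TPM
print("full-length dialect, log2(TPM/10 + 1):")
print(tpm.to_frame().round(3))

scaled = minmax_scale(umi)
print("\nper-gene min–max scaled to [0, 1]:")
print(scaled.to_frame().round(3))
print("-> 0 is each gene's lowest cell, 1 its highest; these are k-NN coordinates")
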