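"""Marker-gene discovery: per-dataset differential expression and
cross-dataset consensus.

Within each labeled reference dataset, every gene is tested malignant vs
non-malignant with a two-sided Wilcoxon rank-sum test, Bonferroni-corrected
over all genes in the dataset. A gene is called up-in-malignant when the
adjusted p-value is below threshold, it is detected (value > 0) in at least
``min_pct`` of malignant cells, and its mean log-expression exceeds the
non-malignant mean by more than ``min_log_fc``; up-in-non-malignant is the
mirror image. Genes up in the same direction in *every* dataset of a
collection form the consensus tumor marker genes (TMGs) and non-tumor
marker genes (NMGs) — the feature space of the downstream classifiers.
"""

from __future__ import annotations

import enum
import json
import warnings
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from .matrix import LOG_NORMALIZED, ExpressionMatrix

MALIGNANT = "malignant"
NON_MALIGNANT = "non_malignant"
LABELS = (MALIGNANT, NON_MALIGNANT)


class Direction(str, enum.Enum):
    UP_MALIGNANT = "up_malignant"
    UP_NON_MALIGNANT = "up_non_malignant"
    NONE = "none"


@dataclass
class ReferenceDataset:
    """A log-normalized expression matrix with a binary label per cell."""

    expr: ExpressionMatrix
    labels: np.ndarray
    name: str

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels, dtype=object).astype(str)
        if self.labels.shape != (self.expr.n_cells,):
            raise ValueError("need exactly one label per cell")
        bad = sorted(set(self.labels) - set(LABELS))
        if bad:
            raise ValueError(f"unknown labels: {bad}")
        if not self.name:
            raise ValueError("dataset name must be non-empty")

    @property
    def malignant_mask(self) -> np.ndarray:
        return self.labels == MALIGNANT

    def class_counts(self) -> tuple[int, int]:
        m = int(self.malignant_mask.sum())
        return m, self.expr.n_cells - m


@dataclass
class MarkerStats:
    """Differential-expression summary for one gene in one dataset."""

    gene_id: str
    p_value: float
    p_adjusted: float
    log_fc: float
    pct_malignant: float
    pct_non_malignant: float
    direction: Direction


@dataclass
class MarkerGeneSet:
    """Disjoint TMG / NMG lists — the classifier's feature space."""

    tmg: list[str]
    nmg: list[str]
    provenance: str = ""

    def __post_init__(self) -> None:
        if len(set(self.tmg)) != len(self.tmg) or len(set(self.nmg)) != len(self.nmg):
            raise ValueError("duplicate gene ids within a marker list")
        overlap = set(self.tmg) & set(self.nmg)
        if overlap:
            raise ValueError(f"TMG/NMG overlap: {sorted(overlap)[:10]}")

    @property
    def all_genes(self) -> list[str]:
        return list(self.tmg) + list(self.nmg)

    def to_tsv(self, path: str | Path) -> None:
        rows = [(g, "TMG") for g in self.tmg] + [(g, "NMG") for g in self.nmg]
        pd.DataFrame(rows, columns=["gene_id", "class"]).to_csv(path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path: str | Path, provenance: str | None = None) -> "MarkerGeneSet":
        df = pd.read_csv(path, sep="\t", dtype=str)
        if not {"gene_id", "class"} <= set(df.columns):
            raise ValueError(f"marker TSV {path} needs columns gene_id, class")
        return cls(
            tmg=list(df.loc[df["class"] == "TMG", "gene_id"]),
            nmg=list(df.loc[df["class"] == "NMG", "gene_id"]),
            provenance=provenance if provenance is not None else str(path),
        )

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(
            json.dumps(
                {"tmg": self.tmg, "nmg": self.nmg, "provenance": self.provenance}, indent=1
            )
        )

    @classmethod
    def from_json(cls, path: str | Path) -> "MarkerGeneSet":
        d = json.loads(Path(path).read_text())
        return cls(tmg=d["tmg"], nmg=d["nmg"], provenance=d.get("provenance", str(path)))


def load_bundled_markers() -> MarkerGeneSet:
    """The packaged consensus marker set (73 TMGs, 186 NMGs) derived from
    five labeled tumor single-cell datasets (RCC, HNSCC, melanoma, LUAD,
    breast cancer)."""
    with resources.as_file(
        resources.files("precancell.data") / "table1_markers.tsv"
    ) as p:
        return MarkerGeneSet.from_tsv(p, provenance="bundled_table1")


# ---------------------------------------------------------------------------
# testing


def wilcoxon_rank_sum(group_a, group_b) -> float:
    """Two-sided Wilcoxon rank-sum (Mann–Whitney) p-value.

    Exact enumeration when both groups have at most 8 observations and the
    pooled sample has no ties; otherwise the normal approximation with tie
    and continuity corrections.
    """
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both groups must be non-empty")
    pooled = np.concatenate([a, b])
    if pooled.min() == pooled.max():
        return 1.0
    no_ties = np.unique(pooled).size == pooled.size
    method = "exact" if (a.size <= 8 and b.size <= 8 and no_ties) else "asymptotic"
    res = stats.mannwhitneyu(a, b, alternative="two-sided", method=method)
    return float(min(res.pvalue, 1.0))


def _vectorized_rank_sum(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Row-wise two-sided rank-sum p-values for genes × cells blocks."""
    with np.errstate(invalid="ignore", divide="ignore"):
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            res = stats.mannwhitneyu(a, b, alternative="two-sided", method="asymptotic", axis=1)
    p = np.asarray(res.pvalue, dtype=float)
    # genes constant across both groups carry no information
    const = np.max(np.hstack([a, b]), axis=1) == np.min(np.hstack([a, b]), axis=1)
    p[const] = 1.0
    p[np.isnan(p)] = 1.0
    return np.minimum(p, 1.0)


def find_markers(
    ds: ReferenceDataset,
    p_adj_threshold: float = 0.05,
    min_pct: float = 0.10,
    min_log_fc: float = 0.25,
    fold_change: str = "mean_diff",
) -> list[MarkerStats]:
    """Per-gene differential expression between malignant and non-malignant
    cells of one dataset.

    ``fold_change='mean_diff'`` (default) defines log_fc as the difference
    of group means of log-normalized expression (malignant −
    non-malignant); ``'log2_ratio'`` instead uses log2 of the ratio of
    mean de-logged expressions plus pseudocount 1 (the Seurat v4
    convention), for parity experiments. The Bonferroni multiplier is the
    total number of genes in the dataset.
    """
    if ds.expr.normalization not in LOG_NORMALIZED:
        raise ValueError("find_markers requires a log-normalized dataset")
    n_mal, n_non = ds.class_counts()
    if n_mal < 2 or n_non < 2:
        raise ValueError("each class needs at least 2 cells")
    if fold_change not in ("mean_diff", "log2_ratio"):
        raise ValueError("fold_change must be 'mean_diff' or 'log2_ratio'")

    mal = ds.malignant_mask
    a = ds.expr.values[:, mal]
    b = ds.expr.values[:, ~mal]
    pct_m = (a > 0).mean(axis=1)
    pct_n = (b > 0).mean(axis=1)
    if fold_change == "mean_diff":
        lfc = a.mean(axis=1) - b.mean(axis=1)
    else:
        lfc = np.log2((np.expm1(a).mean(axis=1) + 1.0) / (np.expm1(b).mean(axis=1) + 1.0))

    if n_mal <= 8 and n_non <= 8:
        p = np.array([wilcoxon_rank_sum(a[g], b[g]) for g in range(ds.expr.n_genes)])
    else:
        p = _vectorized_rank_sum(a, b)
    p_adj = np.minimum(1.0, p * ds.expr.n_genes)

    sig = p_adj < p_adj_threshold
    up_m = sig & (pct_m >= min_pct) & (lfc > min_log_fc)
    up_n = sig & (pct_n >= min_pct) & (-lfc > min_log_fc)

    out = []
    for g, gene in enumerate(ds.expr.gene_ids):
        direction = (
            Direction.UP_MALIGNANT
            if up_m[g]
            else Direction.UP_NON_MALIGNANT
            if up_n[g]
            else Direction.NONE
        )
        out.append(
            MarkerStats(
                gene_id=gene,
                p_value=float(p[g]),
                p_adjusted=float(p_adj[g]),
                log_fc=float(lfc[g]),
                pct_malignant=float(pct_m[g]),
                pct_non_malignant=float(pct_n[g]),
                direction=direction,
            )
        )
    return out


def markers_to_frame(table: list[MarkerStats]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "gene_id": [m.gene_id for m in table],
            "p_value": [m.p_value for m in table],
            "p_adjusted": [m.p_adjusted for m in table],
            "log_fc": [m.log_fc for m in table],
            "pct_malignant": [m.pct_malignant for m in table],
            "pct_non_malignant": [m.pct_non_malignant for m in table],
            "direction": [m.direction.value for m in table],
        }
    )


def frame_to_markers(df: pd.DataFrame) -> list[MarkerStats]:
    return [
        MarkerStats(
            gene_id=str(r.gene_id),
            p_value=float(r.p_value),
            p_adjusted=float(r.p_adjusted),
            log_fc=float(r.log_fc),
            pct_malignant=float(r.pct_malignant),
            pct_non_malignant=float(r.pct_non_malignant),
            direction=Direction(r.direction),
        )
        for r in df.itertuples()
    ]


def intersect_markers(tables: list[tuple[str, list[MarkerStats]]]) -> MarkerGeneSet:
    """Consensus marker set: genes up in the same direction in every table.

    Output order follows the order of appearance in the first table.
    """
    if not tables:
        raise ValueError("need at least one marker table")

    def up_sets(table: list[MarkerStats]) -> tuple[set[str], set[str]]:
        return (
            {m.gene_id for m in table if m.direction is Direction.UP_MALIGNANT},
            {m.gene_id for m in table if m.direction is Direction.UP_NON_MALIGNANT},
        )

    first_name, first = tables[0]
    tmg, nmg = up_sets(first)
    for _, table in tables[1:]:
        t, n = up_sets(table)
        tmg &= t
        nmg &= n
    order = [m.gene_id for m in first]
    return MarkerGeneSet(
        tmg=[g for g in order if g in tmg],
        nmg=[g for g in order if g in nmg],
        provenance=",".join(name for name, _ in tables),
    )
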