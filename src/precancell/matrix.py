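"""Expression-matrix containers, readers/writers, and normalization.

Two normalization dialects are supported, matching the conventions of
full-length (TPM-quantified) and UMI-based single-cell protocols:

* full-length: ``E = log2(TPM / 10 + 1)``
* UMI: per-cell depth normalization to a 10,000 size factor followed by
  ``ln(x + 1)``

plus per-gene min–max scaling to ``[0, 1]``, the feature scaling used by
the k-NN classifiers.
"""

from __future__ import annotations

import dataclasses
import enum
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse


class Normalization(str, enum.Enum):
    """Processing state of an expression matrix."""

    RAW = "raw"
    TPM_LOG2 = "tpm_log2"
    UMI_LOGNORM = "umi_lognorm"
    MINMAX_SCALED = "minmax_scaled"


LOG_NORMALIZED = (Normalization.TPM_LOG2, Normalization.UMI_LOGNORM)


def _check_unique(ids: list[str], what: str) -> None:
    seen: dict[str, int] = {}
    for i in ids:
        seen[i] = seen.get(i, 0) + 1
    dups = sorted(i for i, c in seen.items() if c > 1)
    if dups:
        raise ValueError(f"duplicate {what}: {', '.join(dups[:10])}")


@dataclass
class ExpressionMatrix:
    """A genes × cells expression matrix with identifiers.

    Parameters
    ----------
    values
        Dense float array of shape ``(n_genes, n_cells)``; all entries
        finite.
    gene_ids, cell_ids
        Unique, ordered identifiers for the rows and columns.
    normalization
        The processing state of ``values`` (see :class:`Normalization`).
    """

    values: np.ndarray
    gene_ids: list[str]
    cell_ids: list[str]
    normalization: Normalization = Normalization.RAW

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.gene_ids = [str(g) for g in self.gene_ids]
        self.cell_ids = [str(c) for c in self.cell_ids]
        self.normalization = Normalization(self.normalization)
        if self.values.ndim != 2:
            raise ValueError("values must be a 2-D genes × cells array")
        if self.values.shape != (len(self.gene_ids), len(self.cell_ids)):
            raise ValueError(
                f"shape {self.values.shape} does not match "
                f"{len(self.gene_ids)} genes × {len(self.cell_ids)} cells"
            )
        _check_unique(self.gene_ids, "gene ids")
        _check_unique(self.cell_ids, "cell ids")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("values must be finite")

    @property
    def n_genes(self) -> int:
        return len(self.gene_ids)

    @property
    def n_cells(self) -> int:
        return len(self.cell_ids)

    def gene_index(self) -> dict[str, int]:
        return {g: i for i, g in enumerate(self.gene_ids)}

    def subset_genes(self, genes: list[str]) -> "ExpressionMatrix":
        """Row-subset to ``genes`` (all must be present), preserving order."""
        idx = self.gene_index()
        missing = [g for g in genes if g not in idx]
        if missing:
            raise KeyError(f"genes not in matrix: {', '.join(missing[:10])}")
        rows = [idx[g] for g in genes]
        return dataclasses.replace(
            self, values=self.values[rows, :], gene_ids=list(genes)
        )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.gene_ids, columns=self.cell_ids)


@dataclass
class ScaledMatrix(ExpressionMatrix):
    """An :class:`ExpressionMatrix` after per-gene min–max scaling.

    ``scaling_stats`` records the per-gene ``(min, max)`` used, shape
    ``(n_genes, 2)``.
    """

    scaling_stats: np.ndarray = field(default_factory=lambda: np.zeros((0, 2)))

    def __post_init__(self) -> None:
        super().__post_init__()
        self.scaling_stats = np.asarray(self.scaling_stats, dtype=float)
        if self.scaling_stats.shape != (self.n_genes, 2):
            raise ValueError("scaling_stats must have shape (n_genes, 2)")
        if self.normalization is not Normalization.MINMAX_SCALED:
            raise ValueError("ScaledMatrix must carry minmax_scaled state")
        if self.values.size and (self.values.min() < 0 or self.values.max() > 1):
            raise ValueError("scaled values must lie in [0, 1]")

    def subset_genes(self, genes: list[str]) -> "ScaledMatrix":
        idx = self.gene_index()
        missing = [g for g in genes if g not in idx]
        if missing:
            raise KeyError(f"genes not in matrix: {', '.join(missing[:10])}")
        rows = [idx[g] for g in genes]
        return dataclasses.replace(
            self,
            values=self.values[rows, :],
            gene_ids=list(genes),
            scaling_stats=self.scaling_stats[rows, :],
        )


# ---------------------------------------------------------------------------
# readers / writers


def _read_dense(path: Path, sep: str) -> pd.DataFrame:
    try:
        df = pd.read_csv(path, sep=sep, index_col=0)
    except (pd.errors.ParserError, ValueError) as exc:
        raise ValueError(f"malformed delimited file {path}: {exc}") from exc
    if df.columns.duplicated().any() or df.index.duplicated().any():
        dups = sorted(
            set(df.index[df.index.duplicated()]) | set(df.columns[df.columns.duplicated()])
        )
        raise ValueError(f"duplicate ids in {path}: {', '.join(map(str, dups[:10]))}")
    return df


def _read_mtx(path: Path) -> ExpressionMatrix:
    path = Path(path)
    genes_path = None
    for cand in ("genes.tsv", "features.tsv"):
        if (path.parent / cand).exists():
            genes_path = path.parent / cand
            break
    barcodes_path = path.parent / "barcodes.tsv"
    if genes_path is None or not barcodes_path.exists():
        raise FileNotFoundError(
            f"mtx sidecars genes.tsv/features.tsv and barcodes.tsv required next to {path}"
        )
    try:
        mat = scipy.io.mmread(path)
    except ValueError as exc:
        raise ValueError(f"malformed Matrix Market file {path}: {exc}") from exc
    genes_df = pd.read_csv(genes_path, sep="\t", header=None, dtype=str)
    # 10x convention: column 1 = accession, column 2 = symbol; prefer the symbol
    gene_ids = list(genes_df.iloc[:, 1] if genes_df.shape[1] >= 2 else genes_df.iloc[:, 0])
    cell_ids = list(pd.read_csv(barcodes_path, sep="\t", header=None, dtype=str).iloc[:, 0])
    dense = np.asarray(mat.todense() if scipy.sparse.issparse(mat) else mat, dtype=float)
    if dense.shape != (len(gene_ids), len(cell_ids)):
        raise ValueError(
            f"matrix shape {dense.shape} does not match sidecars "
            f"({len(gene_ids)} genes, {len(cell_ids)} barcodes)"
        )
    return ExpressionMatrix(dense, gene_ids, cell_ids, Normalization.RAW)


def read_expression_matrix(
    path: str | Path,
    format: str = "csv",
    genes_as: str = "rows",
) -> ExpressionMatrix:
    """Read an expression matrix from ``csv``, ``tsv`` or ``mtx``.

    Dense formats carry gene ids in the first column and cell ids in the
    header (or vice versa with ``genes_as='columns'``). Matrix Market input
    expects ``genes.tsv``/``features.tsv`` and ``barcodes.tsv`` sidecars in
    the same directory and is always genes × cells on disk. The result is
    oriented genes × cells and tagged :attr:`Normalization.RAW`.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if genes_as not in ("rows", "columns"):
        raise ValueError("genes_as must be 'rows' or 'columns'")
    if format == "mtx":
        return _read_mtx(path)
    if format not in ("csv", "tsv"):
        raise ValueError(f"unknown format {format!r}")
    df = _read_dense(path, "," if format == "csv" else "\t")
    if genes_as == "columns":
        df = df.T
        _check_unique([str(g) for g in df.index], "gene ids")
    return ExpressionMatrix(
        df.to_numpy(dtype=float),
        [str(g) for g in df.index],
        [str(c) for c in df.columns],
        Normalization.RAW,
    )


def write_expression_matrix(m: ExpressionMatrix, path: str | Path, format: str = "csv") -> None:
    """Write ``m`` as dense csv/tsv or as mtx-plus-sidecars.

    For ``mtx`` the path is treated as a directory receiving ``matrix.mtx``,
    ``genes.tsv`` and ``barcodes.tsv``.
    """
    path = Path(path)
    if format in ("csv", "tsv"):
        m.to_frame().to_csv(path, sep="," if format == "csv" else "\t")
    elif format == "mtx":
        path.mkdir(parents=True, exist_ok=True)
        scipy.io.mmwrite(path / "matrix.mtx", scipy.sparse.coo_matrix(m.values))
        pd.DataFrame({"id": m.gene_ids, "symbol": m.gene_ids}).to_csv(
            path / "genes.tsv", sep="\t", header=False, index=False
        )
        pd.Series(m.cell_ids).to_csv(path / "barcodes.tsv", sep="\t", header=False, index=False)
    else:
        raise ValueError(f"unknown format {format!r}")


def read_labels(path: str | Path) -> pd.Series:
    """Read a two-column ``cell_id,label`` CSV/TSV into a Series."""
    sep = "\t" if str(path).endswith((".tsv", ".txt")) else ","
    df = pd.read_csv(path, sep=sep, dtype=str)
    if df.shape[1] < 2:
        raise ValueError(f"labels file {path} needs columns cell_id,label")
    return pd.Series(df.iloc[:, 1].values, index=df.iloc[:, 0].values, name="label")


# ---------------------------------------------------------------------------
# normalization


def normalize_full_length(tpm: ExpressionMatrix) -> ExpressionMatrix:
    """log2(TPM/10 + 1) transform for full-length (TPM) protocols."""
    if tpm.normalization is not Normalization.RAW:
        raise ValueError("input must be raw TPM values")
    if tpm.values.size and tpm.values.min() < 0:
        raise ValueError("TPM values must be non-negative")
    return dataclasses.replace(
        tpm,
        values=np.log2(tpm.values / 10.0 + 1.0),
        normalization=Normalization.TPM_LOG2,
    )


def normalize_umi(counts: ExpressionMatrix, size_factor: float = 10_000.0) -> ExpressionMatrix:
    """Depth-normalize UMI counts to ``size_factor`` per cell, then ln(x+1).

    Cells with zero total count stay all-zero rather than being dropped:
    quality-control filtering is assumed to have happened upstream.
    """
    if counts.normalization is not Normalization.RAW:
        raise ValueError("input must be raw counts")
    if size_factor <= 0:
        raise ValueError("size_factor must be positive")
    if counts.values.size and counts.values.min() < 0:
        raise ValueError("counts must be non-negative")
    totals = counts.values.sum(axis=0)
    safe = np.where(totals > 0, totals, 1.0)
    scaled = counts.values * (size_factor / safe)
    return dataclasses.replace(
        counts,
        values=np.log1p(scaled),
        normalization=Normalization.UMI_LOGNORM,
    )


def minmax_scale(m: ExpressionMatrix) -> ScaledMatrix:
    """Per-gene min–max scaling to [0, 1] within this matrix.

    Each gene is mapped by ``(x - min) / (max - min)`` using its own min and
    max across all cells of this matrix; genes constant across all cells map
    to all-zero rows. Statistics are never borrowed from another dataset —
    reference and query are each scaled on their own cells.
    """
    if m.normalization not in LOG_NORMALIZED:
        raise ValueError("minmax_scale expects a log-normalized matrix")
    lo = m.values.min(axis=1, keepdims=True) if m.n_cells else np.zeros((m.n_genes, 1))
    hi = m.values.max(axis=1, keepdims=True) if m.n_cells else np.zeros((m.n_genes, 1))
    span = hi - lo
    with np.errstate(invalid="ignore", divide="ignore"):
        scaled = np.where(span > 0, (m.values - lo) / np.where(span > 0, span, 1.0), 0.0)
    return ScaledMatrix(
        values=scaled,
        gene_ids=list(m.gene_ids),
        cell_ids=list(m.cell_ids),
        normalization=Normalization.MINMAX_SCALED,
        scaling_stats=np.hstack([lo, hi]),
    )


def as_lognormalized(m: ExpressionMatrix, dialect: str = "umi_lognorm") -> ExpressionMatrix:
    """Re-tag a matrix known to hold already log-normalized values.

    Used when loading matrices that were normalized outside this package
    (files store no processing state).
    """
    norm = Normalization(dialect)
    if norm not in LOG_NORMALIZED:
        raise ValueError("dialect must be tpm_log2 or umi_lognorm")
    if m.values.size and m.values.min() < 0:
        raise ValueError("log-normalized values must be non-negative")
    return dataclasses.replace(m, normalization=norm)
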