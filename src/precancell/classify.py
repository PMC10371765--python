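"""Ensemble k-NN malignancy prediction.

Each labeled reference dataset drives one base classifier: query cells are
assigned the majority label of their k = 5 nearest reference cells
(Euclidean distance on min–max-scaled marker-gene features). One base vote
is cast per reference, and the final call is the majority of base votes.
The continuous ``score`` (mean malignant-neighbor fraction across
references) supports ROC analysis.

Reference and query are min–max scaled independently, each with per-gene
statistics from its own cells, computed on the aligned feature rows.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from joblib import Parallel, delayed
from scipy.spatial.distance import cdist

from .markers import MALIGNANT, NON_MALIGNANT, MarkerGeneSet, ReferenceDataset
from .matrix import ExpressionMatrix, minmax_scale

logger = logging.getLogger(__name__)

METRICS = ("euclidean", "cosine")


@dataclass
class FeatureAlignment:
    """Marker genes usable by one base classifier (present in both the
    reference and the query), with the covered fraction of the marker set."""

    features: list[str]
    coverage: float


@dataclass
class BaseVote:
    reference_name: str
    label: str
    malignant_neighbor_fraction: float


@dataclass
class Prediction:
    """Final ensemble call for one query cell.

    ``vote_frequency`` is the fraction of base classifiers voting
    malignant; ``score`` is the mean malignant-neighbor fraction over base
    classifiers, a finer-grained continuous malignancy score.
    """

    cell_id: str
    label: str
    votes: list[BaseVote]
    vote_frequency: float
    score: float


def align_features(
    markers: MarkerGeneSet, reference: ReferenceDataset, query: ExpressionMatrix
) -> FeatureAlignment:
    """Intersect the marker set with reference and query genes, in marker order."""
    universe = markers.all_genes
    ref_genes = set(reference.expr.gene_ids)
    query_genes = set(query.gene_ids)
    features = [g for g in universe if g in ref_genes and g in query_genes]
    coverage = len(features) / len(universe) if universe else 0.0
    if not features:
        raise ValueError(
            f"no marker genes shared between reference {reference.name!r} and query"
        )
    if coverage < 0.5:
        logger.warning(
            "reference %s: only %.0f%% of marker genes usable",
            reference.name,
            100 * coverage,
        )
    return FeatureAlignment(features=features, coverage=coverage)


def _neighbor_fractions(
    ref_values: np.ndarray,
    ref_malignant: np.ndarray,
    query_values: np.ndarray,
    k: int,
    metric: str,
) -> np.ndarray:
    """Fraction of malignant cells among the k nearest reference cells.

    Values are features × cells. Distance ties at the k-th neighbor break
    by ascending reference cell index (stable sort) for determinism.
    """
    d = cdist(query_values.T, ref_values.T, metric=metric)
    nearest = np.argsort(d, axis=1, kind="stable")[:, :k]
    return ref_malignant[nearest].mean(axis=1)


def knn_base_classify(
    reference: ReferenceDataset,
    query: ExpressionMatrix,
    features: list[str],
    k: int = 5,
    metric: str = "euclidean",
) -> list[BaseVote]:
    """One base classifier: k-NN vote of one reference over the query cells.

    Both matrices are used as given (the caller scales them); each query
    cell receives the label held by the majority of its k nearest reference
    cells.
    """
    if k <= 0 or k % 2 == 0:
        raise ValueError("k must be a positive odd integer")
    if k > reference.expr.n_cells:
        raise ValueError(f"k={k} exceeds reference size {reference.expr.n_cells}")
    if metric not in METRICS:
        raise ValueError(f"metric must be one of {METRICS}")
    ref = reference.expr.subset_genes(features)
    qry = query.subset_genes(features)
    frac = _neighbor_fractions(
        ref.values, reference.malignant_mask.astype(float), qry.values, k, metric
    )
    return [
        BaseVote(
            reference_name=reference.name,
            label=MALIGNANT if f > 0.5 else NON_MALIGNANT,
            malignant_neighbor_fraction=float(f),
        )
        for f in frac
    ]


def _prepare_base(
    reference: ReferenceDataset,
    query: ExpressionMatrix,
    markers: MarkerGeneSet,
) -> tuple[str, np.ndarray, np.ndarray, np.ndarray]:
    """Align features and min–max scale reference and query independently."""
    alignment = align_features(markers, reference, query)
    ref_scaled = minmax_scale(reference.expr.subset_genes(alignment.features))
    qry_scaled = minmax_scale(query.subset_genes(alignment.features))
    return (
        reference.name,
        ref_scaled.values,
        reference.malignant_mask.astype(float),
        qry_scaled.values,
    )


def ensemble_predict(
    references: list[ReferenceDataset],
    query: ExpressionMatrix,
    markers: MarkerGeneSet,
    k: int = 5,
    metric: str = "euclidean",
    workers: int = 1,
) -> list[Prediction]:
    """Majority vote of one k-NN base classifier per reference dataset.

    References failing feature alignment are dropped with a warning; if all
    fail, an error is raised. With an even number of surviving references a
    split vote is broken toward the label implied by the continuous score
    (exact 0.5 falls to non-malignant with a warning). Query cells are
    classified independently; ``workers > 1`` parallelizes over query-cell
    chunks with results identical to sequential execution.
    """
    if not references:
        raise ValueError("need at least one reference dataset")
    prepared = []
    for ref in references:
        try:
            prepared.append(_prepare_base(ref, query, markers))
        except ValueError as exc:
            logger.warning("dropping reference %s: %s", ref.name, exc)
    if not prepared:
        raise ValueError("no reference shares marker genes with the query")
    for name, ref_values, _, _ in prepared:
        if k > ref_values.shape[1]:
            raise ValueError(f"k={k} exceeds reference {name!r} size {ref_values.shape[1]}")
    if len(prepared) % 2 == 0:
        logger.warning(
            "even number of usable references (%d): split votes break by score",
            len(prepared),
        )

    n_query = query.n_cells

    def fractions_for_chunk(lo: int, hi: int) -> np.ndarray:
        return np.stack(
            [
                _neighbor_fractions(rv, rm, qv[:, lo:hi], k, metric)
                for _, rv, rm, qv in prepared
            ]
        )

    if workers > 1:
        bounds = np.linspace(0, n_query, num=min(workers, max(n_query, 1)) + 1, dtype=int)
        chunks = Parallel(n_jobs=workers)(
            delayed(fractions_for_chunk)(lo, hi) for lo, hi in zip(bounds[:-1], bounds[1:])
        )
        fractions = np.concatenate(chunks, axis=1)  # refs × query cells
    else:
        fractions = fractions_for_chunk(0, n_query)

    predictions = []
    ref_names = [name for name, *_ in prepared]
    for j, cell_id in enumerate(query.cell_ids):
        per_ref = fractions[:, j]
        votes = [
            BaseVote(
                reference_name=ref_names[i],
                label=MALIGNANT if per_ref[i] > 0.5 else NON_MALIGNANT,
                malignant_neighbor_fraction=float(per_ref[i]),
            )
            for i in range(len(ref_names))
        ]
        n_malignant_votes = sum(v.label == MALIGNANT for v in votes)
        vote_frequency = n_malignant_votes / len(votes)
        score = float(per_ref.mean())
        if vote_frequency > 0.5:
            label = MALIGNANT
        elif vote_frequency < 0.5:
            label = NON_MALIGNANT
        elif score != 0.5:
            label = MALIGNANT if score > 0.5 else NON_MALIGNANT
        else:
            logger.warning("cell %s: split vote with score 0.5; assigning non_malignant", cell_id)
            label = NON_MALIGNANT
        predictions.append(
            Prediction(
                cell_id=cell_id,
                label=label,
                votes=votes,
                vote_frequency=float(vote_frequency),
                score=score,
            )
        )
    return predictions


def predictions_to_frame(predictions: list[Prediction]):
    """Tabulate predictions: cell_id, label, vote_frequency, score, then one
    vote column per reference."""
    import pandas as pd

    ref_names = [v.reference_name for v in predictions[0].votes] if predictions else []
    data = {
        "cell_id": [p.cell_id for p in predictions],
        "label": [p.label for p in predictions],
        "vote_frequency": [p.vote_frequency for p in predictions],
        "score": [p.score for p in predictions],
    }
    for i, name in enumerate(ref_names):
        data[f"vote_{name}"] = [p.votes[i].label for p in predictions]
    return pd.DataFrame(data)
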