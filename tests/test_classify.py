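import dataclasses

import numpy as np
import pytest

from precancell import (
    MALIGNANT,
    NON_MALIGNANT,
    MarkerGeneSet,
    Normalization,
    ReferenceDataset,
    align_features,
    ensemble_predict,
    knn_base_classify,
    load_bundled_markers,
)
from conftest import make_matrix, make_separated_reference


def _constant_pattern_reference(n_per_class=10, n_genes=4, name="ref"):
    """Malignant cells at the all-ones vector, non-malignant at all-zeros."""
    values = np.hstack(
        [np.ones((n_genes, n_per_class)), np.zeros((n_genes, n_per_class))]
    )
    return ReferenceDataset(
        expr=make_matrix(values, Normalization.UMI_LOGNORM, gene_prefix="f"),
        labels=[MALIGNANT] * n_per_class + [NON_MALIGNANT] * n_per_class,
        name=name,
    )


class TestAlignFeatures:
    def test_full_coverage(self):
        markers = load_bundled_markers()
        genes = markers.all_genes
        ref = ReferenceDataset(
            expr=make_matrix(
                np.ones((len(genes), 4)), Normalization.UMI_LOGNORM
            ),
            labels=[MALIGNANT, MALIGNANT, NON_MALIGNANT, NON_MALIGNANT],
            name="r",
        )
        ref = dataclasses.replace(
            ref, expr=dataclasses.replace(ref.expr, gene_ids=genes)
        )
        query = dataclasses.replace(ref.expr, cell_ids=[f"q{i}" for i in range(4)])
        out = align_features(markers, ref, query)
        assert out.coverage == 1.0
        assert out.features == genes

    def test_half_coverage_and_order(self):
        markers = MarkerGeneSet(tmg=["A", "B"], nmg=["C", "D"])
        ref = ReferenceDataset(
            expr=make_matrix(np.ones((4, 4)), Normalization.UMI_LOGNORM),
            labels=[MALIGNANT, MALIGNANT, NON_MALIGNANT, NON_MALIGNANT],
            name="r",
        )
        ref = dataclasses.replace(
            ref, expr=dataclasses.replace(ref.expr, gene_ids=["A", "C", "X", "Y"])
        )
        query = make_matrix(np.ones((3, 2)), Normalization.UMI_LOGNORM)
        query = dataclasses.replace(query, gene_ids=["C", "A", "Z"])
        out = align_features(markers, ref, query)
        assert out.features == ["A", "C"]  # marker-set order, not matrix order
        assert out.coverage == 0.5

    def test_no_shared_markers_is_an_error(self):
        markers = MarkerGeneSet(tmg=["A"], nmg=["B"])
        ref = _constant_pattern_reference()
        query = make_matrix(np.ones((2, 2)), Normalization.UMI_LOGNORM)
        with pytest.raises(ValueError, match="no marker genes"):
            align_features(markers, ref, query)


class TestKnnBase:
    def test_zero_distance_cluster(self):
        ref = _constant_pattern_reference()
        query = make_matrix(np.ones((4, 3)), Normalization.UMI_LOGNORM, gene_prefix="f")
        votes = knn_base_classify(ref, query, ref.expr.gene_ids, k=5)
        assert all(v.label == MALIGNANT for v in votes)
        assert all(v.malignant_neighbor_fraction == 1.0 for v in votes)

    def test_k1_returns_nearest_cell_label(self, rng):
        ref = make_separated_reference(seed=5, n_per_class=6, n_markers=3, n_noise=0)
        target = 4  # a malignant cell
        query = dataclasses.replace(
            ref.expr,
            values=ref.expr.values[:, [target]],
            cell_ids=["probe"],
        )
        votes = knn_base_classify(ref, query, ref.expr.gene_ids, k=1)
        assert votes[0].label == ref.labels[target]
        assert votes[0].malignant_neighbor_fraction in (0.0, 1.0)

    @pytest.mark.parametrize("seed", [0, 1, 2, 3, 4])
    def test_matches_brute_force_oracle(self, seed):
        rng = np.random.default_rng(seed)
        n_ref, n_query, k = 10, 15, 5
        ref = ReferenceDataset(
            expr=make_matrix(rng.random((3, n_ref)), Normalization.UMI_LOGNORM),
            labels=rng.choice([MALIGNANT, NON_MALIGNANT], n_ref),
            name="r",
        )
        query = make_matrix(rng.random((3, n_query)), Normalization.UMI_LOGNORM,
                            cell_prefix="q")
        votes = knn_base_classify(ref, query, ref.expr.gene_ids, k=k)
        for j in range(n_query):
            dists = sorted(
                (np.linalg.norm(query.values[:, j] - ref.expr.values[:, i]), i)
                for i in range(n_ref)
            )
            frac = np.mean([ref.labels[i] == MALIGNANT for _, i in dists[:k]])
            assert votes[j].malignant_neighbor_fraction == pytest.approx(frac)
            assert votes[j].label == (MALIGNANT if frac > 0.5 else NON_MALIGNANT)

    def test_even_k_rejected(self):
        ref = _constant_pattern_reference()
        query = make_matrix(np.ones((4, 1)), Normalization.UMI_LOGNORM, gene_prefix="f")
        with pytest.raises(ValueError, match="odd"):
            knn_base_classify(ref, query, ref.expr.gene_ids, k=4)

    def test_k_larger_than_reference_rejected(self):
        ref = _constant_pattern_reference(n_per_class=2)
        query = make_matrix(np.ones((4, 1)), Normalization.UMI_LOGNORM, gene_prefix="f")
        with pytest.raises(ValueError, match="exceeds"):
            knn_base_classify(ref, query, ref.expr.gene_ids, k=5)


def _marker_set_for(ds):
    n = len(ds.expr.gene_ids)
    return MarkerGeneSet(tmg=ds.expr.gene_ids[: n // 2], nmg=ds.expr.gene_ids[n // 2:])


class TestEnsemble:
    def test_majority_vote_and_frequency(self):
        refs = [
            make_separated_reference(seed=s, name=f"ref{s}") for s in range(5)
        ]
        markers = _marker_set_for(refs[0])
        query = dataclasses.replace(
            refs[0].expr, cell_ids=[f"q{i}" for i in range(refs[0].expr.n_cells)]
        )
        preds = ensemble_predict(refs, query, markers)
        for p in preds:
            n_mal = sum(v.label == MALIGNANT for v in p.votes)
            assert p.vote_frequency == pytest.approx(n_mal / 5)
            assert (p.label == MALIGNANT) == (p.vote_frequency > 0.5)
            assert min(abs(p.vote_frequency - v) for v in (0, 0.2, 0.4, 0.6, 0.8, 1.0)) < 1e-12

    def test_five_identical_references_equal_single(self):
        ref = make_separated_reference(seed=9)
        markers = _marker_set_for(ref)
        query = make_separated_reference(seed=10, name="q").expr
        single = ensemble_predict([ref], query, markers)
        five = ensemble_predict(
            [dataclasses.replace(ref, name=f"r{i}") for i in range(5)], query, markers
        )
        assert [p.label for p in five] == [p.label for p in single]
        assert [p.score for p in five] == pytest.approx([p.score for p in single])

    def test_even_split_with_score_above_half_breaks_malignant(self):
        # hand-built vote table: two references vote malignant with
        # neighbor fraction 1.0, two vote non-malignant with fraction 1/3,
        # so the 2-2 split breaks toward malignant (score 2/3 > 0.5)
        def mixed_reference(name):
            # cell 0: zeros, malignant; cells 1-10: zeros, non-malignant;
            # cells 11-20: ones, malignant
            values = np.hstack([np.zeros((4, 11)), np.ones((4, 10))])
            labels = [MALIGNANT] + [NON_MALIGNANT] * 10 + [MALIGNANT] * 10
            return ReferenceDataset(
                expr=make_matrix(values, Normalization.UMI_LOGNORM, gene_prefix="f"),
                labels=labels,
                name=name,
            )

        def flipped_reference(name):
            ref = _constant_pattern_reference(name=name)
            return dataclasses.replace(
                ref,
                labels=np.where(ref.labels == MALIGNANT, NON_MALIGNANT, MALIGNANT),
            )

        refs = [
            flipped_reference("r0"),
            flipped_reference("r1"),
            mixed_reference("r2"),
            mixed_reference("r3"),
        ]
        markers = MarkerGeneSet(
            tmg=refs[0].expr.gene_ids[:2], nmg=refs[0].expr.gene_ids[2:]
        )
        # a 1-cell query min–max scales to all zeros, landing on the zero cluster
        query = make_matrix(
            np.ones((4, 1)), Normalization.UMI_LOGNORM, gene_prefix="f", cell_prefix="q"
        )
        p = ensemble_predict(refs, query, markers, k=3)[0]
        assert p.vote_frequency == 0.5
        assert p.score == pytest.approx(2 / 3)
        assert p.label == MALIGNANT

    def test_even_reference_split_with_score_exactly_half(self):
        # symmetric 2-2 split: fractions (1, 1, 0, 0) give score exactly
        # 0.5, the documented fall-back to non-malignant
        refs = []
        for i, flip in enumerate([False, False, True, True]):
            ref = _constant_pattern_reference(name=f"r{i}")
            if flip:
                ref = dataclasses.replace(
                    ref,
                    labels=np.where(
                        ref.labels == MALIGNANT, NON_MALIGNANT, MALIGNANT
                    ),
                )
            refs.append(ref)
        markers = MarkerGeneSet(tmg=refs[0].expr.gene_ids[:2], nmg=refs[0].expr.gene_ids[2:])
        query = make_matrix(
            np.ones((4, 1)), Normalization.UMI_LOGNORM, gene_prefix="f", cell_prefix="q"
        )
        preds = ensemble_predict(refs, query, markers, k=3)
        p = preds[0]
        assert p.vote_frequency == 0.5
        votes = {v.reference_name: v.label for v in p.votes}
        assert sorted(votes.values()).count(MALIGNANT) == 2
        assert p.score == 0.5
        assert p.label == NON_MALIGNANT

    def test_reference_order_invariance(self, rng):
        refs = [make_separated_reference(seed=s, name=f"ref{s}") for s in range(5)]
        markers = _marker_set_for(refs[0])
        query = make_separated_reference(seed=77, name="q").expr
        fwd = ensemble_predict(refs, query, markers)
        perm = [refs[i] for i in rng.permutation(5)]
        rev = ensemble_predict(perm, query, markers)
        assert [p.label for p in fwd] == [p.label for p in rev]
        assert [p.vote_frequency for p in fwd] == [p.vote_frequency for p in rev]
        assert [p.score for p in fwd] == pytest.approx([p.score for p in rev], abs=1e-12)

    def test_query_permutation_permutes_predictions(self, rng):
        refs = [make_separated_reference(seed=s, name=f"ref{s}") for s in range(3)]
        markers = _marker_set_for(refs[0])
        query = make_separated_reference(seed=55, name="q").expr
        perm = rng.permutation(query.n_cells)
        shuffled = dataclasses.replace(
            query,
            values=query.values[:, perm],
            cell_ids=[query.cell_ids[i] for i in perm],
        )
        base = {p.cell_id: (p.label, p.score) for p in ensemble_predict(refs, query, markers)}
        for p in ensemble_predict(refs, shuffled, markers):
            assert (p.label, p.score) == base[p.cell_id]

    def test_constant_gene_changes_nothing(self):
        refs = [make_separated_reference(seed=s, name=f"ref{s}") for s in range(3)]
        markers = _marker_set_for(refs[0])
        query = make_separated_reference(seed=66, name="q").expr

        def add_constant_gene(expr, value):
            return dataclasses.replace(
                expr,
                values=np.vstack([expr.values, np.full((1, expr.n_cells), value)]),
                gene_ids=list(expr.gene_ids) + ["CONST"],
            )

        refs2 = [dataclasses.replace(r, expr=add_constant_gene(r.expr, 3.0)) for r in refs]
        query2 = add_constant_gene(query, 7.0)
        markers2 = MarkerGeneSet(tmg=markers.tmg + ["CONST"], nmg=markers.nmg)
        base = ensemble_predict(refs, query, markers)
        extended = ensemble_predict(refs2, query2, markers2)
        assert [p.label for p in base] == [p.label for p in extended]
        assert [p.score for p in base] == pytest.approx(
            [p.score for p in extended], abs=1e-12
        )

    def test_parallel_workers_bit_identical(self):
        refs = [make_separated_reference(seed=s, name=f"ref{s}") for s in range(3)]
        markers = _marker_set_for(refs[0])
        query = make_separated_reference(seed=88, name="q").expr
        seq = ensemble_predict(refs, query, markers, workers=1)
        par = ensemble_predict(refs, query, markers, workers=3)
        assert [(p.label, p.vote_frequency, p.score) for p in seq] == [
            (p.label, p.vote_frequency, p.score) for p in par
        ]

    @pytest.mark.parametrize("seed", [101, 202, 303])
    def test_well_separated_classes_classified_accurately(self, seed):
        refs = [
            make_separated_reference(
                seed=seed + i, n_per_class=200, n_markers=20, n_noise=5,
                separation=2.0, noise_sd=1.0, name=f"ref{i}"
            )
            for i in range(5)
        ]
        markers = _marker_set_for(refs[0])
        truth_ds = make_separated_reference(
            seed=seed + 99, n_per_class=200, n_markers=20, n_noise=5,
            separation=2.0, noise_sd=1.0, name="q"
        )
        preds = ensemble_predict(refs, truth_ds.expr, markers)
        acc = np.mean([p.label for p in preds] == truth_ds.labels)
        assert acc >= 0.95

    def test_ensemble_beats_median_single_with_corrupted_references(self):
        rng = np.random.default_rng(4242)
        refs = []
        for i in range(5):
            ref = make_separated_reference(
                seed=500 + i, n_per_class=100, n_markers=20, n_noise=5, name=f"ref{i}"
            )
            if i < 2:  # corrupt 30% of labels in two references
                flip = rng.random(ref.expr.n_cells) < 0.3
                labels = np.where(
                    flip,
                    np.where(ref.labels == MALIGNANT, NON_MALIGNANT, MALIGNANT),
                    ref.labels,
                )
                ref = dataclasses.replace(ref, labels=labels)
            refs.append(ref)
        markers = _marker_set_for(refs[0])
        truth_ds = make_separated_reference(
            seed=999, n_per_class=100, n_markers=20, n_noise=5, name="q"
        )
        single_accs = []
        for ref in refs:
            preds = ensemble_predict([ref], truth_ds.expr, markers)
            single_accs.append(np.mean([p.label for p in preds] == truth_ds.labels))
        ens = ensemble_predict(refs, truth_ds.expr, markers)
        ens_acc = np.mean([p.label for p in ens] == truth_ds.labels)
        assert ens_acc >= np.median(single_accs)

    def test_all_references_unalignable_is_error(self):
        ref = _constant_pattern_reference()
        markers = MarkerGeneSet(tmg=["NOPE"], nmg=["NADA"])
        query = make_matrix(np.ones((4, 2)), Normalization.UMI_LOGNORM, gene_prefix="f")
        with pytest.raises(ValueError, match="no reference shares"):
            ensemble_predict([ref], query, markers)
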