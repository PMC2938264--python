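"""Cross-validation engine: folds, fold-internal filtering, grid
evaluation, permutation nulls and the leakage self-test."""

import numpy as np
import pytest

from mirscreen import classify, diffexp
from mirscreen.errors import ConfigurationError, FoldDegeneracyError

SMALL_CV = classify.CVConfig(
    n_folds=4,
    n_repeats=3,
    subset_sizes=(10, 30),
    kernels=("radial",),
    cost_grid=(1.0,),
    seed=2,
)


def study_labels():
    return np.array(["case"] * 24 + ["control"] * 15)


class TestAssignFolds:
    def test_study_design_folds(self):
        folds = classify.assign_folds(study_labels(), 10, True, 0)
        sizes = np.bincount(folds)
        assert set(sizes) <= {3, 4}
        labels = study_labels()
        for f in range(10):
            fold_labels = set(labels[folds == f])
            assert fold_labels == {"case", "control"}

    def test_leave_one_out_degeneracy(self):
        labels = study_labels()[:8]
        folds = classify.assign_folds(labels, 8, False, 1)
        assert sorted(folds) == list(range(8))

    def test_deterministic_in_seed(self):
        a = classify.assign_folds(study_labels(), 10, True, 5)
        b = classify.assign_folds(study_labels(), 10, True, 5)
        assert np.array_equal(a, b)

    def test_small_class_rejected_when_stratified(self):
        labels = np.array(["case"] * 20 + ["control"] * 5)
        with pytest.raises(ConfigurationError):
            classify.assign_folds(labels, 10, True, 0)


class TestFeatureRanking:
    def test_full_data_ranking_matches_global_de_table(self, planted_cohort):
        _, _, matrix = planted_cohort
        ranked = classify.rank_features_on_training(matrix)
        table = diffexp.build_de_table(matrix, top_k=matrix.n_probes).table
        assert ranked == list(table["probe_id"])

    def test_training_only_contract(self, separable_matrix_small):
        matrix = separable_matrix_small
        # corrupting the held-out columns must not change the ranking
        train_idx = np.concatenate([np.arange(8), np.arange(12, 18)])
        held_out = np.setdiff1d(np.arange(matrix.n_samples), train_idx)
        ranked = classify.rank_features_on_training(matrix, train_idx=train_idx)
        corrupted = matrix.values.copy()
        corrupted[:, held_out] = 1e6
        ranked2 = classify.rank_features_on_training(
            corrupted.T, matrix.labels, train_idx=train_idx
        )
        order = [matrix.probe_ids.index(p) for p in ranked]
        assert order == list(ranked2)

    def test_single_class_training_fold_rejected(self):
        rng = np.random.default_rng(0)
        X = rng.normal(size=(6, 10))
        with pytest.raises(FoldDegeneracyError):
            classify.rank_features_on_training(X, np.array(["case"] * 6))

    def test_permuted_labels_bury_planted_probes(self, separable_matrix_small):
        matrix = separable_matrix_small
        rng = np.random.default_rng(3)
        ranks = []
        # planted probes are the 20 most significant under true labels
        true_top = set(classify.rank_features_on_training(matrix)[:20])
        for _ in range(30):
            permuted = rng.permutation(matrix.labels)
            ranked = classify.rank_features_on_training(matrix, permuted)
            ranks.extend(ranked.index(p) for p in true_top)
        median_rank = np.median(ranks)
        assert 0.25 * matrix.n_probes < median_rank < 0.75 * matrix.n_probes


class TestEvaluateSubset:
    def test_separable_cohort_is_classified(self, separable_matrix_small):
        folds = classify.assign_folds(separable_matrix_small.labels, 4, True, 0)
        acc, sens, spec = classify.evaluate_subset(
            separable_matrix_small, None, folds, 10, "radial", 1.0
        )
        assert acc >= 0.95

    def test_confusion_matrix_identity(self, null_matrix_small):
        labels = null_matrix_small.labels
        n_case = (labels == "case").sum()
        n_control = (labels == "control").sum()
        folds = classify.assign_folds(labels, 4, True, 1)
        for kernel in ("linear", "radial"):
            acc, sens, spec = classify.evaluate_subset(
                null_matrix_small, None, folds, 20, kernel, 1.0
            )
            pooled = (sens * n_case + spec * n_control) / (n_case + n_control)
            assert acc == pytest.approx(pooled, abs=1e-12)

    def test_sample_permutation_equivariance(self, null_matrix_small):
        matrix = null_matrix_small
        folds = classify.assign_folds(matrix.labels, 4, True, 3)
        base = classify.evaluate_subset(matrix, None, folds, 15, "radial", 1.0)
        rng = np.random.default_rng(4)
        perm = rng.permutation(matrix.n_samples)
        permuted = classify.evaluate_subset(
            matrix.values.T[perm], matrix.labels[perm], folds[perm],
            15, "radial", 1.0,
        )
        assert base == pytest.approx(permuted, abs=1e-12)

    def test_invalid_cell_rejected(self, null_matrix_small):
        folds = classify.assign_folds(null_matrix_small.labels, 4, True, 0)
        with pytest.raises(ConfigurationError):
            classify.evaluate_subset(null_matrix_small, None, folds, 10,
                                     "quadratic", 1.0)
        with pytest.raises(ConfigurationError):
            classify.evaluate_subset(null_matrix_small, None, folds, 10_000,
                                     "radial", 1.0)


class TestRepeatedCV:
    def test_bit_identical_reports_from_same_seed(self, separable_matrix_small):
        a = classify.run_repeated_cv(separable_matrix_small, config=SMALL_CV)
        b = classify.run_repeated_cv(separable_matrix_small, config=SMALL_CV)
        for ra, rb in zip(a.results, b.results):
            assert np.array_equal(ra.accuracies, rb.accuracies)
        assert a.best.subset_size == b.best.subset_size
        assert a.best.kernel == b.best.kernel and a.best.cost == b.best.cost

    def test_best_cell_maximizes_mean_accuracy(self, separable_matrix_small):
        report = classify.run_repeated_cv(separable_matrix_small, config=SMALL_CV)
        assert report.best.mean_accuracy == max(
            r.mean_accuracy for r in report.results
        )

    def test_single_repeat_reduces_to_one_pass(self, separable_matrix_small):
        cfg = classify.CVConfig(
            n_folds=4, n_repeats=1, subset_sizes=(10,), kernels=("radial",),
            cost_grid=(1.0,), seed=9,
        )
        report = classify.run_repeated_cv(separable_matrix_small, config=cfg)
        fold_seed = classify._repeat_seeds(cfg.seed, 1)[0]
        folds = classify._folds_with_redraw(
            separable_matrix_small.labels, cfg, fold_seed
        )
        single = classify.evaluate_subset(
            separable_matrix_small, None, folds, 10, "radial", 1.0
        )
        assert report.results[0].accuracies[0] == pytest.approx(single[0])

    def test_mean_equals_average_of_repeats(self, separable_matrix_small):
        report = classify.run_repeated_cv(separable_matrix_small, config=SMALL_CV)
        for r in report.results:
            assert r.mean_accuracy == pytest.approx(r.accuracies.mean())

    def test_oversized_subset_rejected(self, null_matrix_small):
        cfg = classify.CVConfig(subset_sizes=(10_000,), n_repeats=1)
        with pytest.raises(ConfigurationError):
            classify.run_repeated_cv(null_matrix_small, config=cfg)


class TestPermutation:
    def test_planted_signal_beats_permuted_labels(self, separable_matrix_small):
        report = classify.run_permutation(
            separable_matrix_small, config=SMALL_CV, n_permutation_runs=9
        )
        assert report.observed["accuracy"] >= 0.9
        assert report.observed["accuracy"] > report.permuted_accuracy.mean() + 0.2
        assert report.exceedance["accuracy"] == pytest.approx(1 / 10)

    def test_exceedance_is_add_one_fraction(self, null_matrix_small):
        cfg = classify.CVConfig(
            n_folds=4, n_repeats=1, subset_sizes=(10,), kernels=("radial",),
            cost_grid=(1.0,), seed=5,
        )
        report = classify.run_permutation(
            null_matrix_small, config=cfg, n_permutation_runs=5
        )
        for m, frac in report.exceedance.items():
            count = (getattr(report, f"permuted_{m}") >=
                     report.observed[m]).sum()
            assert frac == pytest.approx((count + 1) / 6)
            assert 0.0 < frac <= 1.0


class TestLeakageProbe:
    def test_leaky_filter_inflates_null_accuracy(self, null_matrix_small):
        cfg = classify.CVConfig(
            n_folds=4, n_repeats=3, subset_sizes=(30,), kernels=("radial",),
            cost_grid=(1.0,), seed=7,
        )
        probe = classify.leakage_probe(null_matrix_small, config=cfg)
        assert probe.leaky_accuracy > probe.correct_accuracy
        assert probe.selection_bias > 0.1

    def test_variants_coincide_without_selection(self, null_matrix_small):
        # subset = all probes: the filter selects everything, leaky and
        # correct variants run the same classifier
        cfg = classify.CVConfig(
            n_folds=4, n_repeats=2,
            subset_sizes=(null_matrix_small.n_probes,),
            kernels=("radial",), cost_grid=(1.0,), seed=8,
        )
        probe = classify.leakage_probe(null_matrix_small, config=cfg)
        assert probe.leaky_accuracy == pytest.approx(probe.correct_accuracy)
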