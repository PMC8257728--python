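"""AUC/ROC, prevalence cutoffs, cross-validated AUC and permutation tests."""

import numpy as np
import pytest
from sklearn.metrics import roc_auc_score

from breathvoc.evaluation import (
    CvResult,
    FitConfig,
    auc,
    cross_validated_auc,
    external_validation,
    permutation_model_test,
    prevalence_cutoff,
    roc_points,
)
from breathvoc.lasso_lr import DesignMatrix, LassoModel


def brute_force_auc(scores, labels):
    """Oracle: average pairwise concordance over all case/control pairs."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels)
    cases = scores[labels == 1]
    controls = scores[labels == 0]
    total = 0.0
    for c in cases:
        for d in controls:
            total += 1.0 if c > d else (0.5 if c == d else 0.0)
    return total / (len(cases) * len(controls))


class TestAuc:
    def test_perfect_separation(self):
        assert auc([0.9, 0.8, 0.7, 0.1], [1, 1, 0, 0]) == 1.0

    def test_four_pair_hand_case(self):
        assert auc([0.9, 0.4, 0.6, 0.2], [1, 1, 0, 0]) == pytest.approx(0.75)

    def test_all_ties_give_half(self):
        assert auc([0.3] * 6, [1, 1, 1, 0, 0, 0]) == 0.5

    def test_matches_brute_force_oracle(self, rng):
        for _ in range(200):
            n = int(rng.integers(4, 30))
            labels = np.zeros(n)
            labels[: int(rng.integers(1, n))] = 1
            rng.shuffle(labels)
            scores = np.round(rng.normal(size=n), 1)  # ties likely
            assert auc(scores, labels) == pytest.approx(
                brute_force_auc(scores, labels), abs=1e-12
            )

    def test_invariant_under_monotone_transform(self, rng):
        scores = rng.normal(size=40)
        labels = rng.integers(0, 2, size=40)
        labels[0], labels[1] = 0, 1
        a = auc(scores, labels)
        assert auc(np.exp(scores), labels) == pytest.approx(a)
        assert auc(3 * scores - 7, labels) == pytest.approx(a)

    def test_complement_under_score_negation(self, rng):
        scores = rng.normal(size=30)  # continuous: ties improbable
        labels = np.r_[np.ones(10), np.zeros(20)]
        assert auc(scores, labels) + auc(-scores, labels) == pytest.approx(1.0)

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            auc([0.1, 0.2], [1, 1])


class TestRocPoints:
    def test_auc_equals_trapezoid_and_sklearn(self, rng):
        scores = rng.normal(size=50)
        labels = np.r_[np.ones(15), np.zeros(35)]
        curve = roc_points(scores, labels)
        assert curve.auc == pytest.approx(np.trapezoid(curve.tpr, curve.fpr))
        assert curve.auc == pytest.approx(roc_auc_score(labels, scores))

    def test_rates_monotone_as_threshold_decreases(self, rng):
        scores = rng.normal(size=40)
        labels = rng.permutation(np.r_[np.ones(10), np.zeros(30)])
        curve = roc_points(scores, labels)
        assert np.all(np.diff(curve.tpr) >= 0)
        assert np.all(np.diff(curve.fpr) >= 0)


class TestPrevalenceCutoff:
    def test_group_imbalance_value(self):
        labels = np.r_[np.ones(25), np.zeros(186)]
        assert prevalence_cutoff(labels) == pytest.approx(25 / 211)

    def test_balanced_and_sparse(self):
        assert prevalence_cutoff([1, 0, 1, 0]) == 0.5
        assert prevalence_cutoff([1] + [0] * 9) == pytest.approx(0.1)

    def test_degenerate_labels_rejected(self):
        with pytest.raises(ValueError):
            prevalence_cutoff([])
        with pytest.raises(ValueError):
            prevalence_cutoff([1, 1, 1])


def _noise_design(rng, n=60, p=10, n_case=15):
    X = rng.normal(size=(n, p))
    y = np.zeros(n)
    y[:n_case] = 1
    return DesignMatrix(X, [f"f{i}" for i in range(p)]), rng.permutation(y)


class TestCrossValidatedAuc:
    def test_mean_of_fold_aucs(self):
        r = CvResult(
            fold_aucs=np.array([0.6, 0.7, 0.8, 0.65, 0.75]),
            auc_cv=float(np.mean([0.6, 0.7, 0.8, 0.65, 0.75])),
            fold_indices=[], seed=0,
        )
        assert r.auc_cv == pytest.approx(0.70)

    def test_deterministic_given_seed(self, rng):
        dm, y = _noise_design(rng)
        cfg = FitConfig(n_lambda=15, inner_folds=3)
        r1 = cross_validated_auc(dm, y, seed=3, fit_config=cfg)
        r2 = cross_validated_auc(dm, y, seed=3, fit_config=cfg)
        np.testing.assert_array_equal(r1.fold_aucs, r2.fold_aucs)

    def test_folds_are_disjoint_stratified_partition(self, rng):
        dm, y = _noise_design(rng)
        r = cross_validated_auc(
            dm, y, k=5, seed=1, fit_config=FitConfig(n_lambda=10, inner_folds=3)
        )
        flat = np.sort(np.concatenate(r.fold_indices))
        np.testing.assert_array_equal(flat, np.arange(len(y)))
        for fold in r.fold_indices:
            assert len(np.unique(y[fold])) == 2

    def test_null_data_near_chance(self):
        cfg = FitConfig(n_lambda=15, inner_folds=3)
        aucs = []
        for seed in range(8):
            rng = np.random.default_rng(200 + seed)
            dm, y = _noise_design(rng, n=80, p=20, n_case=20)
            aucs.append(cross_validated_auc(dm, y, seed=seed, fit_config=cfg).auc_cv)
        assert 0.35 < np.mean(aucs) < 0.65

    def test_separable_signal_high_auc(self):
        cfg = FitConfig(n_lambda=15, inner_folds=3)
        hits = 0
        for seed in range(5):
            rng = np.random.default_rng(300 + seed)
            X = rng.normal(size=(100, 10))
            y = rng.permutation(np.r_[np.ones(30), np.zeros(70)])
            X[y == 1, :3] += 2.0
            dm = DesignMatrix(X, [f"f{i}" for i in range(10)])
            if cross_validated_auc(dm, y, seed=seed, fit_config=cfg).auc_cv >= 0.85:
                hits += 1
        assert hits >= 4


class TestPermutationModelTest:
    def test_determinism(self, rng):
        dm, y = _noise_design(rng, n=40, p=6)
        cfg = FitConfig(n_lambda=10, inner_folds=3)
        r1 = permutation_model_test(dm, y, B=10, seed=9, fit_config=cfg,
                                    refit_lambda=False)
        r2 = permutation_model_test(dm, y, B=10, seed=9, fit_config=cfg,
                                    refit_lambda=False)
        np.testing.assert_array_equal(r1.null_auc_cv, r2.null_auc_cv)
        assert r1.p_value == r2.p_value

    def test_add_one_rule_bounds(self, rng):
        dm, y = _noise_design(rng, n=40, p=6)
        cfg = FitConfig(n_lambda=10, inner_folds=3)
        r = permutation_model_test(dm, y, B=19, seed=2, fit_config=cfg,
                                   refit_lambda=False)
        assert 1 / 20 <= r.p_value <= 1.0
        assert r.p_value == (1 + int((r.null_auc_cv >= r.observed_auc_cv).sum())) / 20

    def test_planted_signal_beats_all_nulls(self):
        rng = np.random.default_rng(7)
        X = rng.normal(size=(100, 8))
        y = rng.permutation(np.r_[np.ones(30), np.zeros(70)])
        X[y == 1, :3] += 2.0
        dm = DesignMatrix(X, [f"f{i}" for i in range(8)])
        cfg = FitConfig(n_lambda=15, inner_folds=3)
        r = permutation_model_test(dm, y, B=99, seed=1, fit_config=cfg,
                                   refit_lambda=True)
        assert r.p_value == pytest.approx(0.01)


def _oracle_model(p):
    return LassoModel(
        lambda_=0.0, intercept=0.0, beta=np.zeros(p),
        beta_standardized=np.zeros(p), intercept_standardized=0.0,
        variable_names=[f"f{i}" for i in range(p)],
        standardization={f"f{i}": (0, 1) for i in range(p)},
    )


class TestExternalValidation:
    def test_perfect_probability_model(self):
        # single variable that *is* the true class probability's logit
        model = _oracle_model(1)
        model.beta = np.array([1.0])
        model.beta_standardized = np.array([1.0])
        y = np.r_[np.ones(5), np.zeros(5)]
        X = np.where(y, 5.0, -5.0)[:, None]
        m = external_validation(model, 0.5, X, y)
        assert m.auc_vs == 1.0
        assert m.sensitivity_pct == 100 and m.specificity_pct == 100
        assert m.confusion.sum() == 10

    def test_constant_model_all_ties(self):
        model = _oracle_model(2)
        X = np.zeros((8, 2))
        y = np.r_[np.ones(3), np.zeros(5)]
        m = external_validation(model, 0.5, X, y)
        assert m.auc_vs == 0.5
        # probability exactly at the cutoff classifies as case
        assert m.sensitivity_pct == 100 and m.specificity_pct == 0

    def test_single_class_validation_rejected(self):
        model = _oracle_model(1)
        with pytest.raises(ValueError):
            external_validation(model, 0.5, np.zeros((3, 1)), np.ones(3))
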