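import numpy as np
import pytest
from sklearn.linear_model import LogisticRegression

from dvmrank.feature_space import RankedPair
from dvmrank.ranking_classifier import (classify_pair, cross_val_accuracy,
                                        evaluate, extract_coefficients,
                                        nearest_neighbor_baseline,
                                        train_separator)


def toy_separable():
    return [RankedPair(np.array([1.0, 0.0]), 1),
            RankedPair(np.array([-1.0, 0.0]), -1),
            RankedPair(np.array([0.9, 0.1]), 1),
            RankedPair(np.array([-0.8, 0.2]), -1)]


def oracle_pairs(n_pairs, lam, seed, scale=1.0):
    """Pairs of random macro-parameter vectors labelled by a known fitness."""
    rng = np.random.default_rng(seed)
    pairs = []
    while len(pairs) < n_pairs:
        Mv, Mw = rng.normal(size=(2, lam.size)) * scale
        diff = Mv - Mw
        margin = lam @ diff
        if margin == 0:
            continue
        pairs.append(RankedPair(diff, 1 if margin > 0 else -1))
    return pairs


def cosine(a, b):
    return a @ b / (np.linalg.norm(a) * np.linalg.norm(b))


class TestTrainSeparator:
    def test_separable_toy(self):
        model = train_separator(toy_separable())
        assert model.weights[0] > 0
        acc = np.mean([classify_pair(model, p.diff)[0] == p.label
                       for p in toy_separable()])
        assert acc == 1.0

    def test_known_coefficient_recovery(self, study_lin):
        lam = study_lin.as_vector()
        model = train_separator(oracle_pairs(500, lam, seed=0))
        assert cosine(model.weights, lam) >= 0.99

    def test_duplicated_pairs_leave_direction_unchanged(self):
        pairs = toy_separable()
        w1 = train_separator(pairs).weights
        w2 = train_separator(pairs + pairs).weights
        assert cosine(w1, w2) == pytest.approx(1.0, abs=1e-6)

    def test_loss_curve_is_non_increasing(self, small_ds):
        model = train_separator(small_ds)
        assert np.all(np.diff(model.loss_curve) <= 1e-15)

    def test_deterministic_refit(self, small_ds):
        w1 = train_separator(small_ds).weights
        w2 = train_separator(small_ds).weights
        np.testing.assert_array_equal(w1, w2)

    def test_degenerate_inputs_rejected(self):
        with pytest.raises(ValueError, match="zero"):
            train_separator([RankedPair(np.zeros(3), 1),
                             RankedPair(np.zeros(3), -1)])
        with pytest.raises(ValueError, match="at least 2"):
            train_separator([RankedPair(np.ones(3), 1)])

    def test_agrees_with_reference_logistic_fit(self, small_ds):
        """Independent oracle: sklearn's no-intercept logistic regression
        recovers an equivalent hyperplane direction on the same pairs."""
        model = train_separator(small_ds)
        X = np.array([p.diff for p in small_ds.train_pairs])
        y = np.array([p.label for p in small_ds.train_pairs])
        Xa, ya = np.vstack([X, -X]), np.concatenate([y, -y])
        sc = Xa.std(axis=0)
        ref = LogisticRegression(fit_intercept=False, C=1e4, max_iter=10000)
        ref.fit(Xa / sc, ya)
        w_ref = ref.coef_[0] / sc
        assert cosine(model.weights, w_ref) >= 0.99


class TestClassifyPair:
    def test_on_hyperplane_probability(self):
        model = train_separator(toy_separable())
        label, prob = classify_pair(model, np.zeros(2))
        assert label == 1 and prob == pytest.approx(0.5)

    def test_swap_antisymmetry(self, small_ds):
        model = train_separator(small_ds)
        rng = np.random.default_rng(2)
        for _ in range(20):
            diff = rng.normal(size=model.weights.size)
            l1, p1 = classify_pair(model, diff)
            l2, p2 = classify_pair(model, -diff)
            assert p1 == pytest.approx(1 - p2, abs=1e-12)
            if model.decision(diff)[0] != 0:
                assert l1 == -l2


class TestEvaluate:
    def test_perfect_model_on_separable_data(self):
        lam = np.array([3.0, 1.0, 0.5])
        pairs = oracle_pairs(300, lam, seed=4)
        model = train_separator(pairs)
        rep = evaluate(model, pairs)
        assert rep.accuracy == 1.0
        assert rep.logloss < 0.05
        assert rep.confusion["fp"] == rep.confusion["fn"] == 0

    def test_random_labels_score_at_chance(self):
        rng = np.random.default_rng(9)
        pairs = []
        for _ in range(400):
            d = rng.normal(size=4)
            s = 1 if rng.random() < 0.5 else -1
            pairs.append(RankedPair(s * d, s * (1 if rng.random() < 0.5 else -1)))
        model = train_separator(pairs)
        rep = evaluate(model, pairs)
        assert abs(rep.accuracy - 0.5) < 0.1  # ~2 sigma of binomial noise

    def test_empty_test_set_rejected(self, small_ds):
        model = train_separator(small_ds)
        with pytest.raises(ValueError, match="empty"):
            evaluate(model, [])

    def test_cv_requires_enough_pairs(self):
        with pytest.raises(ValueError):
            cross_val_accuracy(toy_separable(), n_folds=5)


class TestNearestNeighborBaseline:
    def test_separable_dataset(self, small_ds):
        rep = nearest_neighbor_baseline(small_ds, k_nn=1)
        assert rep.accuracy > 0.9

    def test_separator_at_least_as_good_as_knn(self, small_ds):
        model = train_separator(small_ds)
        rep_lin = evaluate(model, small_ds.test_pairs, cv_pairs=small_ds.pairs)
        rep_knn = nearest_neighbor_baseline(small_ds, k_nn=1)
        assert rep_lin.accuracy >= rep_knn.accuracy

    def test_oversized_neighborhood_rejected(self, small_ds):
        with pytest.raises(ValueError, match="k_nn"):
            nearest_neighbor_baseline(small_ds, k_nn=10 ** 6)


class TestExtractCoefficients:
    def test_unit_convention(self):
        model = train_separator(toy_separable())
        model.weights = np.array([2.0, 0.0])
        out = extract_coefficients(model, "unit")
        np.testing.assert_allclose(out.lambdas, [1.0, 0.0])

    def test_match_convention(self):
        model = train_separator(toy_separable())
        model.weights = np.array([0.5, 1.0])
        out = extract_coefficients(model, "match", match_index=0,
                                   match_value=1.96)
        assert out.lambdas[0] == pytest.approx(1.96)
        assert out.lambdas[1] == pytest.approx(1.96 * 2)

    def test_positive_rescaling_invariance(self):
        model = train_separator(toy_separable())
        base = extract_coefficients(model, "unit").lambdas
        model.weights = model.weights * 37.5
        np.testing.assert_allclose(
            extract_coefficients(model, "unit").lambdas, base, rtol=1e-12)

    def test_zero_weights_rejected(self):
        model = train_separator(toy_separable())
        model.weights = np.zeros(2)
        with pytest.raises(ZeroDivisionError):
            extract_coefficients(model, "unit")
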