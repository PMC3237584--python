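import itertools

import numpy as np
import pytest

from metspace.models import (
    ModelSpec,
    NaiveBayes,
    classify,
    cross_validate,
    default_grid,
    metabolite_likeness,
    train,
)


def nb_posterior_oracle(X_train, y_train, x, smoothing=1.0, prior=0.5):
    """Hand-applied Bayes rule with additive smoothing, bit by bit."""
    X_train = np.asarray(X_train)
    y_train = np.asarray(y_train)
    likelihood = {}
    for c in (0, 1):
        rows = X_train[y_train == c]
        l = prior if c == 1 else (1 - prior)
        for j, bit in enumerate(x):
            theta = (rows[:, j].sum() + smoothing) / (len(rows) + 2 * smoothing)
            l *= theta if bit == 1 else (1 - theta)
        likelihood[c] = l
    return likelihood[1] / (likelihood[0] + likelihood[1])


class TestNaiveBayes:
    def test_two_bit_toy_matches_hand_bayes(self):
        X = np.array([[1, 1], [1, 1], [0, 0], [0, 0]])
        y = np.array([1, 1, 0, 0])
        nb = NaiveBayes(smoothing=1.0).fit(X, y)
        # theta_1 = 3/4, theta_0 = 1/4 per bit -> posterior(11) = 0.5625/0.625
        assert nb.predict_proba([[1, 1]])[0, 1] == pytest.approx(0.9)
        assert nb.predict_proba([[1, 1]])[0, 1] == pytest.approx(nb_posterior_oracle(X, y, (1, 1)))

    @pytest.mark.parametrize("n_bits", [2, 3, 4])
    def test_matches_enumeration_oracle_on_all_inputs(self, rng, n_bits):
        X = rng.integers(0, 2, size=(12, n_bits))
        y = np.r_[np.zeros(6, int), np.ones(6, int)]
        nb = NaiveBayes(smoothing=1.0).fit(X, y)
        for x in itertools.product((0, 1), repeat=n_bits):
            expected = nb_posterior_oracle(X, y, x)
            assert nb.predict_proba([list(x)])[0, 1] == pytest.approx(expected, abs=1e-12)

    def test_identical_classes_give_prior(self):
        X = np.array([[1, 0], [0, 1], [1, 0], [0, 1]])
        y = np.array([0, 0, 1, 1])
        nb = NaiveBayes().fit(X, y)
        for x in ([1, 0], [0, 1]):
            assert nb.predict_proba([x])[0, 1] == pytest.approx(0.5)

    def test_ordering_follows_class_conditional_bits(self):
        X = np.array([[1, 1], [1, 1], [0, 0], [0, 0]])
        y = np.array([1, 1, 0, 0])
        nb = NaiveBayes().fit(X, y)
        assert nb.predict_proba([[1, 1]])[0, 1] > 0.5 > nb.predict_proba([[0, 0]])[0, 1]

    def test_gaussian_mode_for_continuous_features(self, rng):
        X = np.vstack([rng.normal(0, 1, (50, 3)), rng.normal(3, 1, (50, 3))])
        y = np.r_[np.zeros(50, int), np.ones(50, int)]
        nb = NaiveBayes().fit(X, y)
        assert nb.mode == "gaussian"
        assert nb.predict_proba([[3.0, 3.0, 3.0]])[0, 1] > 0.95

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            NaiveBayes().fit(np.array([[1], [0]]), np.array([1, 1]))


class TestTrainAndScore:
    def test_rf_degenerate_single_tree_fits_training_set(self, rng):
        X = rng.integers(0, 2, size=(30, 6)).astype(float)
        y = (X[:, 0] > 0).astype(int)
        spec = ModelSpec("rf", "ecfp4", {"ntree": 1, "mtry": None, "bootstrap": False})
        model = train(X, y, spec, seed=0)
        scores = metabolite_likeness(model, X)
        assert np.array_equal((scores >= 0.5).astype(int), y)

    def test_vote_fraction_in_unit_interval(self, rng):
        X = rng.random((40, 5))
        y = np.r_[np.zeros(20, int), np.ones(20, int)]
        for clf in ("rf", "svm", "nb"):
            model = train(X, y, ModelSpec(clf, "pp_desc"), seed=1)
            s = metabolite_likeness(model, X)
            assert ((s >= 0) & (s <= 1)).all(), clf

    def test_descriptor_mismatch_rejected(self, rng):
        X = rng.random((20, 5))
        y = np.r_[np.zeros(10, int), np.ones(10, int)]
        model = train(X, y, ModelSpec("nb", "pp_desc"), seed=0)
        with pytest.raises(ValueError):
            metabolite_likeness(model, np.zeros(7))

    def test_scores_deterministic_given_seed(self, rng):
        X = rng.random((30, 4))
        y = np.r_[np.zeros(15, int), np.ones(15, int)]
        s1 = metabolite_likeness(train(X, y, ModelSpec("rf", "pp_desc"), seed=7), X)
        s2 = metabolite_likeness(train(X, y, ModelSpec("rf", "pp_desc"), seed=7), X)
        assert np.array_equal(s1, s2)


class TestCrossValidate:
    def test_stratified_fold_sizes(self):
        # 1064 balanced samples, 5 folds: held-out sizes in {212, 213}
        from sklearn.model_selection import StratifiedKFold

        y = np.r_[np.zeros(532, int), np.ones(532, int)]
        X = np.zeros((1064, 1))
        sizes = [len(te) for _, te in StratifiedKFold(5, shuffle=True, random_state=0).split(X, y)]
        assert set(sizes) <= {212, 213} and sum(sizes) == 1064

    def test_single_point_grid_returned(self, rng):
        X = rng.integers(0, 2, (40, 8)).astype(float)
        y = np.r_[np.zeros(20, int), np.ones(20, int)]
        cv = cross_validate(X, y, ModelSpec("nb", "ecfp4"), [{"smoothing": 1.0}], k=5, seed=0)
        assert cv.best_params == {"smoothing": 1.0}

    def test_best_point_is_argmax_of_mean_auc(self, rng):
        X = rng.random((60, 4))
        y = (X[:, 0] + 0.1 * rng.random(60) > 0.5).astype(int)
        grid = default_grid("rf", 4)
        cv = cross_validate(X, y, ModelSpec("rf", "pp_desc"), grid, k=3, seed=0)
        assert cv.mean_auc[cv.best_index] == max(cv.mean_auc)

    def test_k_larger_than_class_rejected(self, rng):
        X = rng.random((6, 2))
        y = np.array([0, 0, 0, 1, 1, 1])
        with pytest.raises(ValueError):
            cross_validate(X, y, ModelSpec("nb", "pp_desc"), [{}], k=4, seed=0)


class TestClassify:
    @pytest.mark.parametrize(
        "score, expected",
        [(0.354, "non_metabolite"), (0.488, "non_metabolite"), (0.5, "metabolite"), (0.9, "metabolite")],
    )
    def test_cutoff_convention(self, score, expected):
        assert classify(score) == expected

    def test_vectorized(self):
        out = classify(np.array([0.2, 0.8]))
        assert list(out) == ["non_metabolite", "metabolite"]

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            classify(1.2)
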