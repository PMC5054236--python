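"""Regularized logistic fit, AUC, and nested cross-validation."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy.optimize import minimize
from sklearn.metrics import roc_auc_score

from newsworthy import auc, cross_validate, fit_logreg, predict_scores
from newsworthy.logreg import LogRegModel


def reference_fit(X, y, lam):
    """Independent high-precision optimizer of the penalized objective."""
    X = np.asarray(X, dtype=float)
    ytilde = 2.0 * np.asarray(y) - 1.0
    p = X.shape[1]

    def obj(params):
        w, w0 = params[:p], params[p]
        z = ytilde * (X @ w + w0)
        return 0.5 * w @ w + lam * np.sum(np.logaddexp(0.0, -z))

    res = minimize(obj, np.zeros(p + 1), method="BFGS",
                   options={"gtol": 1e-12, "maxiter": 20_000})
    return res.x[:p], res.x[p], res.fun


class TestFitLogreg:
    def test_matches_reference_optimizer(self, rng):
        """Fitted weights agree with an independent optimizer on random data."""
        for trial in range(5):
            X = rng.normal(size=(20, 5))
            y = rng.integers(0, 2, size=20)
            y[:2] = [0, 1]  # both classes guaranteed
            lam = float(rng.choice([0.1, 1.0, 10.0]))
            m = fit_logreg(X, y, lam, tol=1e-12)
            w_ref, w0_ref, _ = reference_fit(X, y, lam)
            np.testing.assert_allclose(m.w, w_ref, atol=1e-4)
            assert abs(m.w0 - w0_ref) < 1e-4

    def test_strong_regularization_shrinks_weights(self, rng):
        X = rng.normal(size=(30, 4))
        y = np.r_[np.ones(15, dtype=int), np.zeros(15, dtype=int)]
        m = fit_logreg(X, y, lam=1e-8, tol=1e-12)
        assert np.linalg.norm(m.w) < 1e-3

    def test_label_flip_negates_weights(self, rng):
        X = rng.normal(size=(25, 3))
        y = rng.integers(0, 2, size=25)
        y[:2] = [0, 1]
        m1 = fit_logreg(X, y, lam=1.0, tol=1e-12)
        m2 = fit_logreg(X, 1 - y, lam=1.0, tol=1e-12)
        np.testing.assert_allclose(m1.w, -m2.w, atol=1e-5)
        assert m1.w0 == pytest.approx(-m2.w0, abs=1e-5)

    def test_single_class_and_nonfinite_rejected(self, rng):
        X = rng.normal(size=(10, 2))
        with pytest.raises(ValueError):
            fit_logreg(X, np.ones(10), lam=1.0)
        X[0, 0] = np.nan
        with pytest.raises(ValueError):
            fit_logreg(X, np.r_[np.ones(5), np.zeros(5)], lam=1.0)


class TestPredictScores:
    def test_zero_model_scores_zero(self):
        m = LogRegModel(w=np.zeros(3), w0=0.0, lam=1.0)
        assert np.all(predict_scores(m, np.eye(3)) == 0.0)

    def test_one_hot_recovers_weight_plus_intercept(self):
        m = LogRegModel(w=np.array([1.5, -2.0, 0.25]), w0=0.5, lam=1.0)
        np.testing.assert_allclose(predict_scores(m, np.eye(3)), m.w + 0.5)

    def test_matches_hand_matrix_product(self, rng):
        X = rng.normal(size=(5, 3))
        m = LogRegModel(w=rng.normal(size=3), w0=float(rng.normal()), lam=1.0)
        expected = np.array([X[i] @ m.w + m.w0 for i in range(5)])
        np.testing.assert_allclose(predict_scores(m, X), expected)

    def test_dimension_mismatch(self, rng):
        m = LogRegModel(w=np.zeros(3), w0=0.0, lam=1.0)
        with pytest.raises(ValueError):
            predict_scores(m, rng.normal(size=(4, 2)))


def brute_force_auc(scores, labels):
    pos = [s for s, l in zip(scores, labels) if l == 1]
    neg = [s for s, l in zip(scores, labels) if l == 0]
    total = sum((p > n) + 0.5 * (p == n) for p in pos for n in neg)
    return total / (len(pos) * len(neg))


class TestAUC:
    def test_perfect_separation_is_one(self):
        assert auc([3, 4, 1, 2], [1, 1, 0, 0]) == 1.0

    def test_constant_scores_are_chance(self):
        assert auc([2.0] * 6, [1, 0, 1, 0, 0, 0]) == 0.5

    def test_matches_brute_force_with_ties(self, rng):
        for _ in range(200):
            n = int(rng.integers(4, 50))
            labels = rng.integers(0, 2, size=n)
            labels[:2] = [0, 1]
            scores = rng.integers(0, 6, size=n).astype(float)  # many ties
            assert auc(scores, labels) == pytest.approx(brute_force_auc(scores, labels))

    def test_agrees_with_sklearn(self, rng):
        scores = rng.normal(size=40)
        labels = rng.integers(0, 2, size=40)
        labels[:2] = [0, 1]
        assert auc(scores, labels) == pytest.approx(roc_auc_score(labels, scores))

    def test_single_class_is_error(self):
        with pytest.raises(ValueError):
            auc([1.0, 2.0], [1, 1])

    @settings(deadline=None, max_examples=30, derandomize=True)
    @given(st.lists(st.floats(-5, 5).map(lambda v: round(v, 3)), min_size=4, max_size=20),
           st.floats(0.1, 3.0), st.floats(-2, 2))
    def test_invariant_under_increasing_transforms(self, scores, a, b):
        # scores rounded to 1e-3 so distinct values stay distinct under exp()
        labels = [i % 2 for i in range(len(scores))]
        s = np.asarray(scores)
        assert auc(a * s + b, labels) == pytest.approx(auc(s, labels))
        assert auc(np.exp(s / 5.0), labels) == pytest.approx(auc(s, labels))


class TestCrossValidate:
    def make_data(self, rng, n=60, p=4, signal=2.0):
        X = rng.normal(size=(n, p))
        logits = signal * X[:, 0]
        y = (rng.random(n) < 1 / (1 + np.exp(-logits))).astype(int)
        y[:2] = [0, 1]
        return X, y

    def test_folds_disjoint_exhaustive_reproducible(self, rng):
        X, y = self.make_data(rng)
        r1 = cross_validate(X, y, k=3, lambda_grid=[0.1, 1.0], seed=5)
        r2 = cross_validate(X, y, k=3, lambda_grid=[0.1, 1.0], seed=5)
        assert np.array_equal(r1.fold_assignments, r2.fold_assignments)
        assert r1.fold_aucs == r2.fold_aucs
        assert set(r1.fold_assignments) == {0, 1, 2}  # exhaustive partition

    def test_folds_are_stratified(self, rng):
        X, y = self.make_data(rng, n=100)
        r = cross_validate(X, y, k=5, lambda_grid=[1.0], seed=3)
        frac = y.mean()
        for fold in range(5):
            mask = r.fold_assignments == fold
            # within one citation of the corpus fraction
            assert abs(y[mask].sum() - frac * mask.sum()) <= 1.0

    def test_mean_sd_recomputable_from_folds(self, rng):
        X, y = self.make_data(rng)
        r = cross_validate(X, y, k=3, lambda_grid=[1.0], seed=0)
        assert r.mean_auc == pytest.approx(np.mean(r.fold_aucs))
        assert r.sd_auc == pytest.approx(np.std(r.fold_aucs, ddof=1))

    def test_informative_signal_beats_chance(self, rng):
        X, y = self.make_data(rng, n=200, signal=3.0)
        r = cross_validate(X, y, k=5, lambda_grid=[0.1, 1.0, 10.0], seed=1)
        assert r.mean_auc > 0.75

    def test_empty_grid_is_error(self, rng):
        X, y = self.make_data(rng)
        with pytest.raises(ValueError):
            cross_validate(X, y, k=3, lambda_grid=[], seed=0)

    def test_selection_ignores_outer_fold(self, rng, monkeypatch):
        """Lambda selection only ever sees training-fold rows."""
        import newsworthy.logreg as lr
        X, y = self.make_data(rng, n=50)
        seen_sizes = []
        orig = lr._select_lambda

        def spy(Xtr, ytr, *args, **kwargs):
            seen_sizes.append(len(ytr))
            return orig(Xtr, ytr, *args, **kwargs)

        monkeypatch.setattr(lr, "_select_lambda", spy)
        r = cross_validate(X, y, k=5, lambda_grid=[0.1, 1.0], seed=2)
        for fold, n_train in enumerate(seen_sizes):
            n_test = int((r.fold_assignments == fold).sum())
            assert n_train == 50 - n_test
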