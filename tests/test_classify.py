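"""Sparse linear SVM vs a generic convex-solver oracle; CV and metrics."""

import numpy as np
import pandas as pd
import pytest
from scipy import optimize

from crosspath.classify import (
    LinearL1SVM,
    default_c_grid,
    evaluate,
    fit_l1_svm,
    nonzero_features,
    predict,
    select_C,
)


def svm_objective(w, b, X, y, C):
    """||w||_1 + |b| + C sum cw(y) max(0, 1 - y~(w.x + b))^2 (test-local)."""
    ysgn = 2 * np.asarray(y) - 1
    n = len(y)
    cw = np.array([n / (2.0 * np.sum(y == yi)) for yi in y])
    margins = ysgn * (X @ w + b)
    return np.abs(w).sum() + abs(b) + C * np.sum(cw * np.maximum(0.0, 1.0 - margins) ** 2)


def oracle_solve(X, y, C):
    """Generic convex solver: split-variable L-BFGS-B on the same objective.

    Each signed coefficient is written as a difference of two non-negative
    parts, which makes the L1 term linear and the whole problem smooth and
    bound-constrained.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=int)
    n, p = X.shape
    ysgn = 2 * y - 1
    cw = np.array([n / (2.0 * np.sum(y == yi)) for yi in y])
    d = p + 1  # weights plus intercept

    def fun(z):
        v = z[:d] - z[d:]
        w, b = v[:p], v[p]
        margins = ysgn * (X @ w + b)
        viol = np.maximum(0.0, 1.0 - margins)
        loss = C * np.sum(cw * viol**2)
        grad_v = np.empty(d)
        gw = -2.0 * C * X.T @ (cw * viol * ysgn)
        gb = -2.0 * C * np.sum(cw * viol * ysgn)
        grad_v[:p], grad_v[p] = gw, gb
        val = z.sum() + loss
        grad = np.concatenate([1.0 + grad_v, 1.0 - grad_v])
        return val, grad

    z0 = np.zeros(2 * d)
    res = optimize.minimize(
        fun, z0, jac=True, method="L-BFGS-B",
        bounds=[(0, None)] * (2 * d),
        options={"maxiter": 20000, "ftol": 1e-15, "gtol": 1e-12},
    )
    v = res.x[:d] - res.x[d:]
    return v[:p], v[p]


class TestFitAgainstOracle:
    @pytest.mark.parametrize("seed", range(6))
    def test_weights_and_objective_match(self, seed):
        rng = np.random.default_rng(seed)
        n, p = 20, 5
        X = rng.normal(size=(n, p))
        y = np.array([0, 1] * (n // 2))
        X[y == 1, 0] += 1.0
        C = float(10 ** rng.uniform(-1.5, 1.0))
        model = fit_l1_svm(X, y, C)
        w_star, b_star = oracle_solve(X, y, C)
        obj_impl = svm_objective(model.weights, model.intercept, X, y, C)
        obj_star = svm_objective(w_star, b_star, X, y, C)
        assert obj_impl <= obj_star + 1e-6
        assert np.abs(model.weights - w_star).max() < 1e-3
        assert abs(model.intercept - b_star) < 1e-3

    def test_separable_one_dimensional(self):
        X = np.array([[-1.0], [-1.0], [1.0], [1.0]])
        y = np.array([0, 0, 1, 1])
        model = fit_l1_svm(X, y, C=100.0)
        assert model.weights[0] > 0
        labels, _ = predict(model, X)
        assert list(labels) == [0, 0, 1, 1]

    def test_tiny_C_gives_zero_weights(self):
        rng = np.random.default_rng(0)
        X = rng.normal(size=(10, 4))
        y = np.array([0, 1] * 5)
        model = fit_l1_svm(X, y, C=1e-9)
        np.testing.assert_allclose(model.weights, 0.0, atol=1e-12)

    def test_single_class_rejected(self):
        with pytest.raises(ValueError, match="both classes"):
            fit_l1_svm(np.ones((3, 2)), [1, 1, 1], 1.0)

    def test_sparsity_grows_with_penalty(self):
        # number of nonzero weights at C=1e-3 <= at C=1e2 (spot check)
        violations = 0
        for seed in range(10):
            rng = np.random.default_rng(seed)
            X = rng.normal(size=(16, 8))
            y = np.array([0, 1] * 8)
            X[y == 1] += 0.5
            lo = len(nonzero_features(fit_l1_svm(X, y, 1e-3)))
            hi = len(nonzero_features(fit_l1_svm(X, y, 1e2)))
            violations += lo > hi
        assert violations <= 2


class TestSelectC:
    def test_single_value_grid(self):
        rng = np.random.default_rng(1)
        X = rng.normal(size=(8, 3))
        y = np.array([0, 1] * 4)
        report = select_C(X, y, [0.7])
        assert report.chosen_C == 0.7

    def test_separable_tie_break_smallest(self):
        rng = np.random.default_rng(2)
        X = rng.normal(size=(20, 2))
        y = np.array([0, 1] * 10)
        X[y == 0, 0] -= 3.0
        X[y == 1, 0] += 3.0
        grid = [0.01, 0.1, 1.0, 10.0]
        report = select_C(X, y, grid)
        perfect = report.grid[report.pooled_f1 == 1.0]
        assert len(perfect) > 1
        assert report.chosen_C == perfect.min()
        assert "tie" in report.tie_note

    @pytest.mark.parametrize("seed", range(3))
    def test_matches_exhaustive_oracle(self, seed):
        from sklearn.metrics import f1_score

        rng = np.random.default_rng(seed)
        X = rng.normal(size=(12, 4))
        y = np.array([0, 1] * 6)
        X[y == 1, 1] += 1.2
        grid = [0.005, 0.05, 0.5, 5.0, 50.0]
        report = select_C(X, y, grid)
        # independent re-evaluation: pooled LOOCV F1 per grid C
        best_f1, best_c = -1.0, None
        for C in sorted(grid):
            truths, preds = [], []
            for i in range(len(y)):
                mask = np.ones(len(y), dtype=bool)
                mask[i] = False
                m = fit_l1_svm(X[mask], y[mask], C)
                truths.append(y[i])
                preds.append(int(predict(m, X[i][None, :])[0][0]))
            f1 = f1_score(truths, preds, zero_division=0)
            if f1 > best_f1:
                best_f1, best_c = f1, C
        assert report.chosen_C == best_c

    def test_default_grid_span(self):
        grid = default_c_grid()
        assert len(grid) == 50
        assert grid[0] == pytest.approx(1e-3)
        assert grid[-1] == pytest.approx(1e2)


class TestPredictEvaluate:
    def test_constant_classifier(self):
        model = LinearL1SVM(["f0"], np.array([0.0]), -0.5, 1.0)
        labels, decisions = predict(model, np.array([[3.0], [-2.0]]))
        assert list(labels) == [0, 0]
        np.testing.assert_allclose(decisions, -0.5)

    def test_forced_arithmetic(self):
        model = LinearL1SVM(["f0"], np.array([1.0]), 0.0, 1.0)
        labels, decisions = predict(model, np.array([[0.3]]))
        assert labels[0] == 1 and decisions[0] == pytest.approx(0.3)

    def test_boundary_goes_healthy(self):
        model = LinearL1SVM(["f0"], np.array([1.0]), 0.0, 1.0)
        labels, _ = predict(model, np.array([[0.0]]))
        assert labels[0] == 0

    def test_positive_rescaling_invariance(self):
        rng = np.random.default_rng(3)
        X = rng.normal(size=(10, 3))
        w = rng.normal(size=3)
        m1 = LinearL1SVM(["a", "b", "c"], w, 0.2, 1.0)
        m2 = LinearL1SVM(["a", "b", "c"], 7.0 * w, 1.4, 1.0)
        assert list(predict(m1, X)[0]) == list(predict(m2, X)[0])

    def test_metrics_forced_counts(self):
        y_true = [1, 1, 1, 1, 1, 0, 0, 0, 0]
        y_pred = [1, 1, 1, 1, 0, 0, 0, 0, 1]
        m = evaluate(y_true, y_pred)
        assert (m.tp, m.fn, m.tn, m.fp) == (4, 1, 3, 1)
        assert m.accuracy == pytest.approx(7 / 9)
        assert m.f1 == pytest.approx(0.8)

    def test_perfect_predictions(self):
        m = evaluate([0, 1, 0, 1], [0, 1, 0, 1], [-1.0, 2.0, -0.5, 1.0])
        assert m.accuracy == 1.0 and m.f1 == 1.0 and m.auc == 1.0

    def test_tied_decisions_auc_half(self):
        m = evaluate([0, 1, 0, 1], [0, 0, 0, 0], [0.3, 0.3, 0.3, 0.3])
        assert m.auc == pytest.approx(0.5)

    def test_feature_mismatch_rejected(self):
        model = LinearL1SVM(["a", "b"], np.array([1.0, 2.0]), 0.0, 1.0)
        with pytest.raises(ValueError, match="feature"):
            predict(model, pd.DataFrame([[1.0, 2.0]], columns=["b", "a"]))


class TestNonzeroFeatures:
    def test_threshold(self):
        model = LinearL1SVM(["a", "b", "c"], np.array([0.3, 0.0, -0.1]), 0.0, 1.0)
        assert nonzero_features(model) == {"a", "c"}

    def test_all_zero(self):
        model = LinearL1SVM(["a", "b"], np.zeros(2), 0.0, 1.0)
        assert nonzero_features(model) == set()

    def test_single_informative_feature_selected(self):
        rng = np.random.default_rng(4)
        n = 20
        y = np.array([0, 1] * (n // 2))
        X = rng.normal(size=(n, 5)) * 0.3
        X[:, 2] += 2.5 * y  # the one informative feature
        model = fit_l1_svm(X, y, C=0.5)
        assert nonzero_features(model) == {"2"}
        w_star, _ = oracle_solve(X, y, 0.5)
        assert set(np.flatnonzero(np.abs(w_star) > 1e-6)) == {2}
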