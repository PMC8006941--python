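"""Fused-lasso objective, proximal operator, solver and tile classification."""

import numpy as np
import pytest
import statsmodels.api as sm
from scipy.optimize import lsq_linear

from tipmap.fusedlasso import (
    FusedLassoModel,
    classify_tile,
    cv_select,
    fit_fused_lasso,
    fl_objective,
    fused_prox,
    tv1d_prox,
)
from tipmap.spatial import LCurveFeatures


def tv_prox_oracle(y, lam):
    """Exact TV proximity via its dual box-constrained least-squares problem."""
    n = len(y)
    if n == 1 or lam <= 0:
        return np.asarray(y, dtype=float).copy()
    D = np.diff(np.eye(n), axis=0)
    res = lsq_linear(D.T, y, bounds=(-lam, lam), method="bvls", tol=1e-14)
    return y - D.T @ res.x


class TestTvProx:
    def test_matches_dual_oracle_on_random_inputs(self):
        rng = np.random.default_rng(0)
        for _ in range(100):
            n = int(rng.integers(1, 60))
            y = rng.normal(0, rng.uniform(0.1, 10), n)
            lam = float(rng.uniform(0, 5))
            np.testing.assert_allclose(tv1d_prox(y, lam), tv_prox_oracle(y, lam), atol=1e-10)

    def test_large_penalty_averages(self):
        y = np.array([3.0, -1.0, 5.0, 2.0])
        np.testing.assert_allclose(tv1d_prox(y, 1e6), np.full(4, y.mean()), atol=1e-9)

    def test_combined_prox_is_optimal(self):
        # fused_prox must minimize 0.5||x-v||^2 + t1*TV(x) + t2*||x||_1
        rng = np.random.default_rng(1)
        v = rng.normal(0, 3, 30)
        t1, t2 = 0.7, 0.4
        x = fused_prox(v, t1, t2)

        def obj(z):
            return 0.5 * np.sum((z - v) ** 2) + t1 * np.sum(np.abs(np.diff(z))) + t2 * np.sum(np.abs(z))

        base = obj(x)
        for _ in range(500):
            pert = x + rng.normal(0, rng.uniform(1e-4, 0.1), 30)
            assert obj(pert) >= base - 1e-12


class TestObjective:
    def test_zero_model_balanced_labels_gives_log2(self):
        rng = np.random.default_rng(2)
        X = rng.normal(size=(10, 4))
        y = np.r_[np.ones(5), np.zeros(5)]
        assert fl_objective(0.0, np.zeros(4), X, y, 0.3, 0.7) == pytest.approx(np.log(2))

    def test_constant_beta_has_zero_fusion_term(self):
        rng = np.random.default_rng(3)
        X = rng.normal(size=(6, 5))
        y = np.r_[np.ones(3), np.zeros(3)]
        for c in (0.5, -2.0):
            with_fusion = fl_objective(0.1, np.full(5, c), X, y, 100.0, 0.0)
            without = fl_objective(0.1, np.full(5, c), X, y, 0.0, 0.0)
            assert with_fusion == pytest.approx(without)

    def test_matches_independent_term_by_term_evaluation(self):
        rng = np.random.default_rng(4)
        for _ in range(10):
            S, n = 4, 5
            X = rng.normal(size=(S, n))
            y = rng.integers(0, 2, S).astype(float)
            if len(np.unique(y)) < 2:
                y[0] = 1 - y[0]
            b0, b = rng.normal(), rng.normal(size=n)
            l1, l2 = rng.uniform(0, 2, 2)
            # independent evaluation, written directly from the model definition
            acc = 0.0
            for s in range(S):
                z = b0 + sum(b[r] * X[s, r] for r in range(n))
                acc += y[s] * z - np.log(1 + np.exp(z))
            expected = -acc / S
            expected += l1 * sum(abs(b[r + 1] - b[r]) for r in range(n - 1))
            expected += l2 * sum(abs(b[r]) for r in range(n))
            assert fl_objective(b0, b, X, y, l1, l2) == pytest.approx(expected, abs=1e-12)

    def test_non_binary_labels_rejected(self):
        with pytest.raises(ValueError):
            fl_objective(0.0, np.zeros(2), np.zeros((3, 2)), np.array([0.0, 0.5, 1.0]), 0, 0)


@pytest.fixture(scope="module")
def logistic_data():
    rng = np.random.default_rng(5)
    S, n = 200, 10
    X = rng.normal(size=(S, n))
    beta = rng.normal(size=n) * 0.5
    p = 1 / (1 + np.exp(-(0.3 + X @ beta)))
    y = (rng.uniform(size=S) < p).astype(float)
    return X, y


class TestFit:
    def test_unpenalized_fit_matches_irls_oracle(self, logistic_data):
        X, y = logistic_data
        m = fit_fused_lasso(X, y, 0.0, 0.0, tol=1e-12, max_iter=20000)
        irls = sm.GLM(y, sm.add_constant(X), family=sm.families.Binomial()).fit()
        np.testing.assert_allclose(np.r_[m.beta0, m.beta], irls.params, atol=1e-4)

    def test_fusion_limit_gives_constant_coefficients(self, logistic_data):
        X, y = logistic_data
        m = fit_fused_lasso(X, y, 1e6, 0.0)
        assert np.ptp(m.beta) < 1e-6

    def test_sparsity_limit_gives_intercept_only_model(self, logistic_data):
        X, y = logistic_data
        m = fit_fused_lasso(X, y, 0.0, 1e6)
        assert np.abs(m.beta).max() < 1e-6
        ybar = y.mean()
        assert m.beta0 == pytest.approx(np.log(ybar / (1 - ybar)), abs=1e-6)

    def test_objective_non_increasing_across_iterations(self, logistic_data):
        X, y = logistic_data
        m = fit_fused_lasso(X, y, 0.05, 0.01)
        hist = np.asarray(m.objective_history)
        assert (np.diff(hist) <= 1e-12).all()

    def test_fit_is_local_minimum_under_random_perturbations(self, logistic_data):
        X, y = logistic_data
        l1, l2 = 0.02, 0.01
        m = fit_fused_lasso(X, y, l1, l2, tol=1e-12, max_iter=20000)
        base = fl_objective(m.beta0, m.beta, X, y, l1, l2)
        rng = np.random.default_rng(6)
        for _ in range(1000):
            db0 = rng.normal(0, 0.01)
            db = rng.normal(0, 0.01, len(m.beta))
            assert fl_objective(m.beta0 + db0, m.beta + db, X, y, l1, l2) >= base - 1e-9

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            fit_fused_lasso(np.zeros((4, 2)), np.ones(4), 0.1, 0.1)

    def test_json_round_trip(self, logistic_data, tmp_path):
        X, y = logistic_data
        m = fit_fused_lasso(X, y, 0.01, 0.01, r_grid=np.linspace(1, 338, 10))
        m.to_json(tmp_path / "m.json")
        back = FusedLassoModel.from_json(tmp_path / "m.json")
        np.testing.assert_allclose(back.beta, m.beta, atol=1e-15)
        assert back.beta0 == pytest.approx(m.beta0)


class TestCvSelect:
    def test_single_pair_grid_returned(self):
        rng = np.random.default_rng(7)
        X = rng.normal(size=(40, 6))
        y = np.r_[np.ones(20), np.zeros(20)]
        l1, l2, table = cv_select(X, y, [0.3], [0.02], seed=0)
        assert (l1, l2) == (0.3, 0.02)
        assert len(table) == 1

    def test_default_is_five_folds(self):
        import inspect

        assert inspect.signature(cv_select).parameters["folds"].default == 5

    def test_ties_break_toward_stronger_regularization(self):
        # perfectly separable in one coordinate: many penalty pairs reach
        # identical accuracy; the strongest regularization must win
        rng = np.random.default_rng(8)
        S = 40
        y = np.r_[np.ones(20), np.zeros(20)]
        X = np.column_stack([y * 10 - 5 + rng.normal(0, 0.1, S), rng.normal(size=S)])
        l1, l2, table = cv_select(X, y, [0.0, 0.001], [0.0001, 0.001], seed=1)
        best_acc = max(r[2] for r in table)
        tied = [(a, b) for a, b, acc in table if acc == best_acc]
        assert (l1, l2) == max(tied, key=lambda t: (t[0] + t[1], t[0]))


class TestClassifyTile:
    def _features(self, n_i, n_j, x=None, n=8):
        return LCurveFeatures(tile_id=0, x=np.zeros(n) if x is None else x,
                              n_i=n_i, n_j=n_j, r_grid=np.linspace(1, 338, n))

    def _model(self, n=8, beta0=0.0, seed=0):
        rng = np.random.default_rng(seed)
        return FusedLassoModel(beta0=beta0, beta=rng.normal(size=n), lambda1=0, lambda2=0)

    def test_five_immune_cells_is_deserted(self):
        assert classify_tile(self._model(), self._features(50, 5)).label == "deserted"

    def test_empty_tile_is_deserted(self):
        assert classify_tile(self._model(), self._features(0, 0)).label == "deserted"

    def test_deserted_rule_invariant_to_model_coefficients(self):
        f = self._features(30, 4)
        labels = {classify_tile(self._model(seed=s, beta0=s - 5.0), f).label for s in range(20)}
        assert labels == {"deserted"}

    def test_too_few_tumor_cells_is_unclassifiable(self):
        assert classify_tile(self._model(), self._features(1, 20)).label == "unclassifiable"

    def test_probability_threshold_at_half(self):
        f = self._features(30, 20, x=np.ones(8))
        m = FusedLassoModel(beta0=0.0, beta=np.full(8, 0.5), lambda1=0, lambda2=0)
        res = classify_tile(m, f)
        assert res.label == "inflamed" and res.probability > 0.5
        m_neg = FusedLassoModel(beta0=0.0, beta=np.full(8, -0.5), lambda1=0, lambda2=0)
        assert classify_tile(m_neg, f).label == "excluded"

    def test_dimension_mismatch_rejected(self):
        with pytest.raises(ValueError):
            classify_tile(self._model(n=8), self._features(30, 20, x=np.zeros(5)))

    def test_inflamed_synthetic_tile_classified_inflamed(self, trained_model, config):
        from conftest import tile_features

        f = tile_features("inflamed", 777, config)
        assert f.n_j > 5
        assert classify_tile(trained_model, f, t=config.deserted_threshold).label == "inflamed"
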