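"""Normalization, constrained deconvolution, signatures, TIP predictor."""

import numpy as np
import pandas as pd
import pytest

from tipmap import ExpressionMatrix
from tipmap.deconv import (
    deconvolve,
    fit_tip_predictor,
    immune_fraction,
    normalize_expression,
    predict_tip,
    project_simplex,
    signature_genes,
)
from tipmap.simulate import planted_residuals, simulate_expression


def _em(values, genes=None, samples=None):
    values = np.asarray(values, dtype=float)
    genes = genes or [f"g{k}" for k in range(values.shape[0])]
    samples = samples or [f"s{k}" for k in range(values.shape[1])]
    return ExpressionMatrix(genes, samples, values)


class TestNormalize:
    def test_constant_matrix_becomes_sqrt_of_constant(self):
        c = 4.0
        out = normalize_expression(_em(np.full((3, 4), c)))
        np.testing.assert_allclose(out.values, np.sqrt(c))

    def test_column_totals_equal_after_sample_step(self):
        rng = np.random.default_rng(0)
        X = _em(rng.uniform(1, 10, (20, 6)))
        totals = X.values.sum(axis=0)
        scaled = X.values * (totals.mean() / totals)
        np.testing.assert_allclose(scaled.sum(axis=0), totals.mean(), rtol=1e-12)

    def test_gene_division_by_sqrt_mean(self):
        # equal column totals make the sample step a no-op; gene0 values
        # (1,4,4,7) have mean 4 and are divided by 2
        X = np.array([[1.0, 4.0, 4.0, 7.0], [7.0, 4.0, 4.0, 1.0]])
        out = normalize_expression(_em(X))
        np.testing.assert_allclose(out.values[0], [0.5, 2.0, 2.0, 3.5])

    def test_zero_mean_gene_dropped_with_warning(self):
        X = np.array([[1.0, 2.0], [0.0, 0.0], [3.0, 1.0]])
        with pytest.warns(UserWarning, match="zero mean"):
            out = normalize_expression(_em(X))
        assert out.genes == ["g0", "g2"]


class TestImmuneFraction:
    @pytest.mark.parametrize(
        "tumor,cd8,cd4,expected", [(70, 20, 10, 0.3), (50, 0, 0, 0.0), (0, 3, 7, 1.0)]
    )
    def test_fraction_formula(self, tumor, cd8, cd4, expected):
        df = pd.DataFrame({"tumor": [tumor], "CD8": [cd8], "CD4": [cd4]})
        assert immune_fraction(df)[0] == pytest.approx(expected)

    def test_zero_total_rejected(self):
        with pytest.raises(ValueError):
            immune_fraction(pd.DataFrame({"tumor": [0], "CD8": [0], "CD4": [0]}))


class TestProjectSimplex:
    def test_output_on_simplex_and_idempotent(self):
        rng = np.random.default_rng(1)
        for _ in range(50):
            v = rng.normal(0, 3, int(rng.integers(1, 40)))
            p = project_simplex(v)
            assert p.min() >= 0
            assert p.sum() == pytest.approx(1.0)
            np.testing.assert_allclose(project_simplex(p), p, atol=1e-12)


class TestDeconvolve:
    def test_noiseless_mixture_recovery(self):
        expr, _, truth = simulate_expression(G=200, S=30, seed=7)
        res = deconvolve(expr, truth.lam)
        assert res.objective < 1e-8
        assert np.abs(res.immune_profile - truth.immune_profile).max() < 1e-3
        assert np.abs(res.cancer_profile - truth.cancer_profile).max() < 1e-3

    def test_constraints_and_kkt_satisfied(self):
        expr, _, truth = simulate_expression(G=100, S=12, noise_sd=0.2, seed=8)
        res = deconvolve(expr, truth.lam)
        assert res.immune_profile.sum() == pytest.approx(1.0, abs=1e-9)
        assert res.cancer_profile.sum() == pytest.approx(1.0, abs=1e-9)
        assert res.immune_profile.min() >= -1e-9
        assert res.cancer_profile.min() >= -1e-9
        assert res.kkt_residual < 1e-6

    def test_constant_lambda_flagged_unidentifiable(self):
        expr, _, truth = simulate_expression(G=60, S=10, lambda_range=(0.3, 0.3), seed=9)
        with pytest.warns(UserWarning, match="not identifiable"):
            res = deconvolve(expr, np.full(10, 0.3))
        assert not res.identifiable

    def test_recovery_error_grows_with_noise(self):
        errs = []
        for sd in (0.0, 0.05, 0.1):
            per_seed = []
            for seed in (20, 21, 22):
                expr, _, truth = simulate_expression(G=120, S=25, noise_sd=sd, seed=seed)
                res = deconvolve(expr, truth.lam)
                per_seed.append(np.abs(res.immune_profile - truth.immune_profile).max())
            errs.append(np.mean(per_seed))
        assert errs[0] <= errs[1] <= errs[2]

    def test_residuals_complement_fit(self):
        expr, _, truth = simulate_expression(G=80, S=15, noise_sd=0.1, seed=10)
        res = deconvolve(expr, truth.lam)
        np.testing.assert_allclose(res.fitted + res.residuals, expr.values, atol=1e-12)


class TestSignatureGenes:
    def test_planted_genes_recovered_without_false_positives(self):
        R, a, truth = planted_residuals(G=2000, S=40, n_signature=30, seed=3)
        sig = signature_genes(R, a)
        found = set(sig.genes)
        planted = set(truth.signature_genes)
        assert len(found & planted) >= 0.8 * len(planted)
        assert len(found - planted) <= 1

    def test_orthogonal_residuals_excluded(self):
        # residual row orthogonal to the TIP: beta = 0, p = 1
        a = np.array([1.0, -1.0, 1.0, -1.0])
        R = np.vstack([np.array([1.0, 1.0, -1.0, -1.0]), np.array([1.0, 2.0, 1.0, 2.0])])
        sig = signature_genes(R, a)
        row = sig.table.set_index("gene").loc["g0"]
        assert row["beta"] == pytest.approx(0.0)
        assert row["p_raw"] == pytest.approx(1.0)
        assert not row["significant"]

    def test_bonferroni_rule_consistent(self):
        R, a, _ = planted_residuals(G=500, S=30, n_signature=10, seed=4)
        sig = signature_genes(R, a, alpha=0.05)
        t = sig.table
        assert (t.loc[t["significant"], "p_raw"] * sig.n_tested < 0.05).all()
        assert (t.loc[~t["significant"], "p_raw"] * sig.n_tested >= 0.05).all()

    def test_zero_variance_rows_skipped(self):
        rng = np.random.default_rng(5)
        R = rng.normal(size=(5, 8))
        R[2] = 0.0
        sig = signature_genes(R, rng.uniform(0, 1, 8))
        assert "g2" not in set(sig.table["gene"])
        assert sig.n_tested == 4


@pytest.fixture(scope="module")
def planted_expression():
    G, S = 2000, 150
    R, a, truth = planted_residuals(G=G, S=S, seed=11)
    em = ExpressionMatrix([f"g{k}" for k in range(G)], [f"s{k}" for k in range(S)], R)
    return em, a, truth


class TestTipPredictor:
    def test_defaults_match_tuned_parameters(self, planted_expression):
        em, a, truth = planted_expression
        model = fit_tip_predictor(_restrict(em, range(100)), a[:100], truth.signature_genes)
        assert model.cost == 4.0
        assert model.gamma == 0.0009765625

    def test_held_out_correlation(self, planted_expression):
        em, a, truth = planted_expression
        model = fit_tip_predictor(_restrict(em, range(100)), a[:100], truth.signature_genes)
        pred = predict_tip(model, _restrict(em, range(100, 150)))
        r = np.corrcoef(pred, a[100:150])[0, 1]
        assert r >= 0.8

    def test_prediction_deterministic_and_permutation_equivariant(self, planted_expression):
        em, a, truth = planted_expression
        train = _restrict(em, range(100))
        model = fit_tip_predictor(train, a[:100], truth.signature_genes)
        p1 = predict_tip(model, train)
        p2 = predict_tip(model, train)
        np.testing.assert_array_equal(p1, p2)
        perm = list(range(99, -1, -1))
        p3 = predict_tip(model, _restrict(em, perm))
        np.testing.assert_allclose(p3, p1[perm], atol=1e-12)

    def test_constant_tip_gives_constant_predictions(self, planted_expression):
        em, _, truth = planted_expression
        train = _restrict(em, range(100))
        model = fit_tip_predictor(train, np.full(100, 0.4), truth.signature_genes)
        pred = predict_tip(model, train)
        assert np.ptp(pred) < 0.2  # within the epsilon tube

    def test_missing_signature_gene_rejected(self, planted_expression):
        em, a, truth = planted_expression
        model = fit_tip_predictor(_restrict(em, range(100)), a[:100], truth.signature_genes)
        small = ExpressionMatrix(em.genes[50:], em.samples, em.values[50:])
        with pytest.raises(KeyError, match="g0"):
            predict_tip(model, small)

    def test_two_group_difference_detected(self, planted_expression):
        from scipy import stats

        em, a, truth = planted_expression
        model = fit_tip_predictor(_restrict(em, range(100)), a[:100], truth.signature_genes)
        test_idx = np.arange(100, 150)
        hi = test_idx[a[test_idx] > np.median(a[test_idx])]
        lo = test_idx[a[test_idx] <= np.median(a[test_idx])]
        p_hi = predict_tip(model, _restrict(em, hi))
        p_lo = predict_tip(model, _restrict(em, lo))
        assert stats.mannwhitneyu(p_hi, p_lo, alternative="two-sided").pvalue < 0.01

    def test_empty_signature_rejected(self, planted_expression):
        em, a, _ = planted_expression
        with pytest.raises(ValueError):
            fit_tip_predictor(em, a, [])


def _restrict(em: ExpressionMatrix, idx) -> ExpressionMatrix:
    idx = list(idx)
    return ExpressionMatrix(em.genes, [em.samples[i] for i in idx], em.values[:, idx])
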