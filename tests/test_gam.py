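"""Penalized-spline GAM engine: bases, families, GCV selection, prediction."""

import numpy as np
import pandas as pd
import pytest
import statsmodels.api as sm

from winterhab import gam
from winterhab.gam import TermSpec


def logistic(x):
    return 1.0 / (1.0 + np.exp(-x))


@pytest.fixture()
def binom_df(rng):
    x = rng.uniform(-2, 2, 600)
    y = rng.binomial(1, logistic(-0.4 + 1.1 * x)).astype(float)
    return pd.DataFrame({"x": x, "y": y})


class TestBasis:
    def test_k3_gives_two_centred_columns(self, rng):
        X, S = gam.build_basis(rng.uniform(0, 1, 100), k=3)
        assert X.shape == (100, 2)
        assert np.allclose(X.sum(axis=0), 0.0, atol=1e-8)
        assert S.shape == (2, 2)
        w = np.linalg.eigvalsh(S)
        assert np.all(w > 0)  # shrinkage penalty is positive definite

    def test_degenerate_covariate_rejected(self):
        with pytest.raises(ValueError, match="degenerate"):
            gam.build_basis(np.ones(50), k=3)

    def test_straight_line_unpenalized_without_shrinkage(self, rng):
        """The cubic-spline penalty's null space is the straight lines: the
        quadratic form of coefficients reproducing a line is zero."""
        x = np.sort(rng.uniform(0, 10, 200))
        basis = gam.CubicSplineBasis(np.array([0.0, 5.0, 10.0]))
        beta_line = 2.0 + 0.7 * basis.knots  # spline through a line
        assert beta_line @ basis.S @ beta_line == pytest.approx(0.0, abs=1e-10)
        # and the spline evaluates to that line everywhere
        f = basis.design(x) @ beta_line
        assert np.allclose(f, 2.0 + 0.7 * x, atol=1e-9)

    def test_interaction_zero_coefficients_zero_effect(self, rng):
        X, pens = gam.build_interaction(rng.uniform(1, 8, 50),
                                        rng.uniform(0, 300, 50))
        assert X.shape[1] == 8  # 3x3 tensor minus the sum-to-zero constraint
        assert len(pens) == 2
        assert np.allclose(X @ np.zeros(8), 0.0)

    def test_evaluation_at_training_points_is_design_product(self, rng):
        df = pd.DataFrame({"a": rng.uniform(1, 8, 80),
                           "b": rng.uniform(0, 10, 80)})
        term = gam._BuiltTerm(TermSpec.tensor("a", "b"), df)
        X1, _, _ = term.design(df)
        X2, _, _ = term.design(df.copy())
        assert np.array_equal(X1, X2)


class TestFitGLMOracle:
    def test_unpenalized_binomial_matches_statsmodels_irls(self, binom_df):
        """At lambda = 0 the penalized fitter reproduces the GLM."""
        fit = gam.fit(binom_df, "y", [TermSpec.smooth("x")],
                      family="quasibinomial", select=False)
        X, _ = gam.build_basis(binom_df["x"].to_numpy(), k=3)
        Xd = np.column_stack([np.ones(len(binom_df)), X])
        glm = sm.GLM(binom_df["y"], Xd, family=sm.families.Binomial()).fit()
        assert np.max(np.abs(fit.beta - glm.params)) < 1e-6
        assert fit.deviance == pytest.approx(glm.deviance, rel=1e-8)

    def test_unpenalized_gamma_matches_statsmodels_irls(self, rng):
        x = rng.uniform(-1, 1, 800)
        y = rng.gamma(4.0, np.exp(0.8 + 0.5 * x) / 4.0)
        df = pd.DataFrame({"x": x, "y": y})
        fit = gam.fit(df, "y", [TermSpec.smooth("x")], family="gamma",
                      select=False)
        X, _ = gam.build_basis(x, k=3)
        Xd = np.column_stack([np.ones(len(x)), X])
        glm = sm.GLM(y, Xd, family=sm.families.Gamma(
            link=sm.families.links.Log())).fit(tol=1e-12, maxiter=300)
        assert np.max(np.abs(fit.beta - glm.params)) < 1e-6

    def test_intercept_score_equation_holds(self, binom_df):
        fit = gam.fit(binom_df, "y", [TermSpec.smooth("x")],
                      family="quasibinomial", select=False)
        pred = gam.predict(fit, binom_df)
        assert np.sum(binom_df["y"].to_numpy() - pred.response) == \
            pytest.approx(0.0, abs=1e-6)


class TestGCV:
    def test_profile_matches_hat_matrix_oracle(self, rng):
        """Gaussian single-smooth GCV(lambda) equals the brute-force
        influence-matrix computation."""
        x = rng.uniform(0, 1, 300)
        y = np.sin(2 * np.pi * x) + rng.normal(0, 0.4, 300)
        df = pd.DataFrame({"x": x, "y": y})
        X, S = gam.build_basis(x, k=3)
        Xd = np.column_stack([np.ones(300), X])
        Sfull = np.zeros((3, 3))
        Sfull[1:, 1:] = S
        for lam in (0.0, 0.1, 1.0, 10.0, 1000.0):
            fit = gam.fit(df, "y", [TermSpec.smooth("x")], family="gaussian",
                          lam=[lam])
            A = Xd @ np.linalg.solve(Xd.T @ Xd + lam * Sfull, Xd.T)
            edf = np.trace(A)
            rss = float(np.sum((y - A @ y) ** 2))
            gcv_oracle = 300 * rss / (300 - edf) ** 2
            assert fit.gcv == pytest.approx(gcv_oracle, rel=1e-6)
            assert fit.edf_total == pytest.approx(edf, rel=1e-6)

    def test_selected_lambda_beats_random_vectors(self, rng):
        x = rng.uniform(0, 1, 400)
        y = np.sin(2 * np.pi * x) + rng.normal(0, 0.3, 400)
        df = pd.DataFrame({"x": x, "y": y})
        fit = gam.fit(df, "y", [TermSpec.smooth("x")], family="gaussian")
        for _ in range(20):
            lam = np.exp(rng.uniform(-8, 12))
            alt = gam.fit(df, "y", [TermSpec.smooth("x")], family="gaussian",
                          lam=[lam])
            assert fit.gcv <= alt.gcv + 1e-9

    def test_deviance_formulas_match_direct_sums(self, rng):
        y = rng.integers(0, 2, 40).astype(float)
        mu = rng.uniform(0.05, 0.95, 40)
        fam = gam.QuasiBinomial()
        direct = 2 * sum(
            (np.log(1 / m) if yi > 0 else np.log(1 / (1 - m)))
            for yi, m in zip(y, mu)
        )
        assert fam.deviance(y, mu) == pytest.approx(direct, rel=1e-12)
        yg = rng.gamma(2, 2, 40) + 0.1
        mug = rng.uniform(0.5, 5.0, 40)
        gfam = gam.GammaLog()
        directg = 2 * sum(
            -np.log(yi / m) + (yi - m) / m for yi, m in zip(yg, mug)
        )
        assert gfam.deviance(yg, mug) == pytest.approx(directg, rel=1e-12)

    def test_saturated_and_null_edges(self, rng):
        y = rng.gamma(3, 1, 30) + 0.1
        fam = gam.GammaLog()
        assert fam.deviance(y, y.copy()) == pytest.approx(0.0, abs=1e-12)
        df = pd.DataFrame({"y": rng.binomial(1, 0.3, 200).astype(float)})
        fit = gam.fit(df, "y", [], family="quasibinomial")
        assert fit.percent_deviance == pytest.approx(0.0, abs=1e-9)
        assert fit.gcv == pytest.approx(
            200 * fit.deviance / (200 - 1) ** 2, rel=1e-9
        )


class TestShrinkage:
    def test_infinite_lambda_removes_term(self, rng):
        x = rng.uniform(0, 1, 300)
        y = np.sin(2 * np.pi * x) + rng.normal(0, 0.3, 300)
        df = pd.DataFrame({"x": x, "y": y})
        fit = gam.fit(df, "y", [TermSpec.smooth("x")], family="gaussian",
                      lam=[1e14])
        assert fit.edf_by_term["s(x)"] < 0.05
        eff, _ = gam.partial_effect(fit, "s(x)", df)
        assert np.max(np.abs(eff)) < 1e-6

    def test_edf_non_increasing_in_lambda(self, binom_df):
        edfs = []
        for lam in 10.0 ** np.arange(-2, 7):
            fit = gam.fit(binom_df, "y", [TermSpec.smooth("x")],
                          family="quasibinomial", lam=[lam])
            edfs.append(fit.edf_by_term["s(x)"])
        assert all(a >= b - 1e-8 for a, b in zip(edfs[:-1], edfs[1:]))
        assert max(e for e in edfs) <= 2.0 + 1e-6  # k = 3 caps df at 2


class TestRecovery:
    def test_gamma_log_curve_recovery(self):
        """Pointwise 95% bands of the fitted curve cover the truth at >= 90%
        of grid points across 20 replicates."""
        covered = []
        for rep in range(20):
            r = np.random.default_rng(100 + rep)
            x = r.uniform(-1, 1, 2000)
            mu = np.exp(1.0 + 0.5 * x)
            y = r.gamma(5.0, mu / 5.0)
            df = pd.DataFrame({"x": x, "y": y})
            fit = gam.fit(df, "y", [TermSpec.smooth("x")], family="gamma")
            grid = pd.DataFrame({"x": np.linspace(-0.9, 0.9, 25)})
            pred = gam.predict(fit, grid)
            truth = 1.0 + 0.5 * grid["x"].to_numpy()
            ok = np.abs(pred.eta - truth) <= 1.96 * pred.se_eta + 1e-9
            covered.append(ok.mean())
        assert np.mean(covered) >= 0.9

    def test_separable_interaction_recovery(self, rng):
        n = 3000
        a = rng.uniform(1, 8, n)
        b = rng.uniform(0, 300, n)
        f = np.sin(a / 3.0) * (b / 300.0)
        y = f + rng.normal(0, 0.2, n)
        df = pd.DataFrame({"a": a, "b": b, "y": y})
        fit = gam.fit(df, "y", [TermSpec.tensor("a", "b")], family="gaussian")
        eff, _ = gam.partial_effect(fit, "te(a,b)", df)
        corr = np.corrcoef(eff, f - f.mean())[0, 1]
        assert corr > 0.95


class TestPredict:
    def test_training_rows_reproduce_fitted_values(self, binom_df):
        fit = gam.fit(binom_df, "y", [TermSpec.smooth("x")],
                      family="quasibinomial", select=False)
        pred = gam.predict(fit, binom_df.iloc[:10])
        pred_all = gam.predict(fit, binom_df)
        assert np.allclose(pred.eta, pred_all.eta[:10])
        assert np.all((pred.response > 0) & (pred.response < 1))

    def test_out_of_range_rows_masked_with_reason(self, binom_df):
        fit = gam.fit(binom_df, "y", [TermSpec.smooth("x")],
                      family="quasibinomial", select=False)
        hi = binom_df["x"].max()
        new = pd.DataFrame({"x": [0.0, hi + 1.0]})
        pred = gam.predict(fit, new, exclude_out_of_range=True)
        assert pred.mask[0] and not pred.mask[1]
        assert pred.mask_reason[1] == "out_of_range:x"

    def test_unseen_factor_level_masked(self, rng):
        df = pd.DataFrame({
            "g": rng.choice(["a", "b"], 200),
            "y": rng.normal(0, 1, 200),
        })
        fit = gam.fit(df, "y", [TermSpec.factor("g")], family="gaussian")
        pred = gam.predict(fit, pd.DataFrame({"g": ["a", "c"]}))
        assert pred.mask[0] and not pred.mask[1]
        assert pred.mask_reason[1].startswith("unseen_level")

    def test_se_positive_and_larger_at_range_edges(self, rng):
        x = rng.uniform(0, 1, 500)
        y = np.sin(2 * np.pi * x) + rng.normal(0, 0.3, 500)
        fit = gam.fit(pd.DataFrame({"x": x, "y": y}), "y",
                      [TermSpec.smooth("x")], family="gaussian")
        grid = pd.DataFrame({"x": np.linspace(0.001, 0.999, 50)})
        pred = gam.predict(fit, grid)
        assert np.all(pred.se_eta > 0)
        assert pred.se_eta[0] > pred.se_eta[25]
        assert pred.se_eta[-1] > pred.se_eta[25]

    def test_missing_covariate_column_errors(self, binom_df):
        fit = gam.fit(binom_df, "y", [TermSpec.smooth("x")],
                      family="quasibinomial", select=False)
        with pytest.raises(KeyError, match="x"):
            gam.predict(fit, pd.DataFrame({"z": [1.0]}))
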