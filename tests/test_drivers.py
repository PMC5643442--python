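"""Collinearity screen, all-subsets selection, averaging, VIF and Moran's I."""

import itertools
import math

import numpy as np
import pandas as pd
import pytest

import elevgrad as eg
from elevgrad.drivers import build_driver_design, fit_candidate_set
from elevgrad.trends import LinearModelFit


def _covariate_table(rng, n=12):
    elev = np.tile(np.linspace(0, 1, n // 2), 2)
    mat = 15 - 6 * elev + rng.normal(0, 0.2, n)
    mah = 75 + 6 * elev + rng.normal(0, 0.4, n)
    ndvi = 0.3 - 0.02 * mat + 0.005 * mah + rng.normal(0, 0.005, n)
    psr = rng.uniform(10, 40, n)  # deliberately unrelated
    return pd.DataFrame({"MAT": mat, "MAH": mah, "NDVI": ndvi, "PSR": psr})


class TestCorrelationScreen:
    def test_ndvi_retained_over_climate(self, rng):
        table = _covariate_table(rng)
        retained, corr = eg.correlation_screen(table, keep_priority=("NDVI",))
        assert abs(corr.loc["MAT", "NDVI"]) > 0.7
        assert abs(corr.loc["MAH", "NDVI"]) > 0.7
        assert "NDVI" in retained
        assert "MAT" not in retained and "MAH" not in retained
        assert "PSR" in retained

    def test_uncorrelated_all_retained(self, rng):
        table = pd.DataFrame(rng.normal(size=(20, 4)), columns=list("abcd"))
        retained, corr = eg.correlation_screen(table)
        assert retained == list("abcd")
        assert np.allclose(corr, corr.T)
        assert np.allclose(np.diag(corr), 1.0)

    def test_constant_column_rejected(self, rng):
        table = pd.DataFrame({"a": rng.normal(size=5), "b": np.ones(5)})
        with pytest.raises(ValueError, match="b"):
            eg.correlation_screen(table)


def brute_force_models(mains, inters):
    """Oracle: filter all subsets of all terms by the marginality rule."""
    terms = list(mains) + list(inters)
    out = set()
    for k in range(len(terms) + 1):
        for sub in itertools.combinations(terms, k):
            ok = all(
                t.split(":")[0] in sub and t.split(":")[1] in sub
                for t in sub if ":" in t
            )
            if ok:
                out.add(tuple(t for t in terms if t in sub))
    return out


class TestEnumerateModels:
    def test_two_mains_no_interactions(self):
        assert len(eg.enumerate_models(["A", "B"])) == 4

    def test_single_interaction_with_marginality(self):
        models = eg.enumerate_models(["slope", "X"], ["slope:X"])
        assert len(models) == 5
        assert ("slope", "X", "slope:X") in [tuple(m) for m in models]

    def test_global_model_count_matches_brute_force(self):
        mains = ["slope", "MDE", "area", "NDVI", "PSR"]
        inters = [f"slope:{t}" for t in mains[1:]]
        models = {tuple(m) for m in eg.enumerate_models(mains, inters)}
        assert models == brute_force_models(mains, inters)
        assert len(models) == 97

    def test_orphan_interaction_rejected(self):
        with pytest.raises(ValueError):
            eg.enumerate_models(["A"], ["A:B"])


class TestFitModel:
    def test_exact_log_area_effect(self, rng):
        cov = pd.DataFrame({
            "slope": ["west"] * 6 + ["east"] * 6,
            "elevation": list(range(1800, 3000, 200)) * 2,
            "area": rng.uniform(5, 50, 12),
        })
        design = build_driver_design(cov)
        y = 2.0 * np.log(cov["area"])
        fit = eg.fit_model(y, design, ["area"])
        assert fit.coef["area"] == pytest.approx(2.0)
        assert fit.r_squared == pytest.approx(1.0)

    def test_r2_never_decreases_with_terms(self, rng):
        design = pd.DataFrame(rng.normal(size=(12, 3)), columns=["a", "b", "c"])
        design["slope"] = np.repeat([0.0, 1.0], 6)
        y = rng.normal(size=12)
        r2_small = eg.fit_model(y, design, ["a"]).r_squared
        r2_big = eg.fit_model(y, design, ["a", "b", "c"]).r_squared
        assert r2_big >= r2_small - 1e-12

    def test_matches_normal_equations(self, rng):
        design = pd.DataFrame(rng.normal(size=(15, 2)), columns=["a", "b"])
        y = rng.normal(size=15)
        fit = eg.fit_model(y, design, ["a", "b"])
        X = np.column_stack([np.ones(15), design["a"], design["b"]])
        beta = np.linalg.solve(X.T @ X, X.T @ y)
        assert np.allclose(fit.coefficients, beta)
        # |t| importance equals coefficient / SE from the same solve
        s2 = ((y - X @ beta) ** 2).sum() / (15 - 3)
        se = np.sqrt(np.diag(s2 * np.linalg.inv(X.T @ X)))
        imp = eg.variable_importance_best(fit)
        assert imp["a"] == pytest.approx(abs(beta[1] / se[1]))
        assert imp["b"] == pytest.approx(abs(beta[2] / se[2]))

    def test_rank_deficient_rejected(self):
        design = pd.DataFrame({"a": [1.0, 2, 3, 4], "b": [2.0, 4, 6, 8]})
        with pytest.raises(ValueError):
            eg.fit_model([1.0, 2, 3, 4], design, ["a", "b"])

    def test_interaction_column_is_product(self, rng):
        design = pd.DataFrame(rng.normal(size=(20, 1)), columns=["x"])
        design["slope"] = np.repeat([0.0, 1.0], 10)
        y = 1.0 + design["slope"] * design["x"] * 3.0
        fit = eg.fit_model(y, design, ["slope", "x", "slope:x"])
        assert fit.coef["slope:x"] == pytest.approx(3.0)


class TestSelectionAndAveraging:
    def _cms(self, rng, n=40):
        design = pd.DataFrame(rng.normal(size=(n, 2)), columns=["a", "b"])
        y = 2.0 * design["a"] + rng.normal(0, 0.5, n)
        models = eg.enumerate_models(["a", "b"])
        return fit_candidate_set(y, design, models)

    def test_best_has_maximum_weight(self, rng):
        cms = self._cms(rng)
        best = eg.select_best(cms)
        i = cms.order[0]
        assert cms.fits[i] is best
        assert cms.weights[i] == cms.weights.max()
        assert cms.delta_aicc[i] == 0.0

    def test_single_candidate(self, rng):
        design = pd.DataFrame(rng.normal(size=(10, 1)), columns=["a"])
        cms = fit_candidate_set(rng.normal(size=10), design, [("a",)])
        assert eg.select_best(cms).terms == ("intercept", "a")

    def test_averaging_arithmetic(self):
        def make(terms, coefs):
            return LinearModelFit(terms=terms, coefficients=coefs, n=10, K=3,
                                  log_likelihood=0.0, r_squared=0.5, aicc=0.0)

        cms = eg.CandidateModelSet(
            fits=(make(("intercept", "A"), (0.0, 1.0)),
                  make(("intercept", "A", "B"), (0.0, 1.0, 2.0))),
            delta_aicc=np.array([0.0, 1.0]),
            weights=np.array([0.7, 0.3]),
            order=np.array([0, 1]),
            confidence_set_95=np.array([True, True]),
        )
        avg = eg.model_average(cms)
        assert avg.importance["A"] == pytest.approx(1.0)
        assert avg.importance["B"] == pytest.approx(0.3)
        # full averaging substitutes zero where B is absent
        assert avg.averaged_coefficients["B"] == pytest.approx(0.3 * 2.0)
        cond = eg.model_average(cms, method="conditional")
        assert cond.averaged_coefficients["B"] == pytest.approx(2.0)
        assert abs(avg.averaged_coefficients["B"]) <= abs(
            cond.averaged_coefficients["B"])

    def test_confidence_set_weights_renormalized(self, rng):
        cms = self._cms(rng)
        avg = eg.model_average(cms)
        assert all(0.0 <= v <= 1.0 + 1e-12 for v in avg.importance.values())

    def test_undefined_aicc_models_excluded(self, rng):
        design = pd.DataFrame(rng.normal(size=(6, 4)), columns=list("abcd"))
        y = rng.normal(size=6)
        models = eg.enumerate_models(list("abcd"))
        with pytest.warns(UserWarning, match="AICc undefined"):
            cms = fit_candidate_set(y, design, models)
        # n=6: K = #coefficients + 1 must satisfy n - K - 1 > 0
        assert all(6 - (len(f.terms) + 1) - 1 > 0 for f in cms.fits)
        assert len(cms.excluded) > 0


class TestVif:
    def test_closed_form_at_r_08(self, rng):
        # exactly orthonormal u, v -> empirical corr(x1, x2) = 0.8 exactly
        z = rng.normal(size=(30, 2))
        z -= z.mean(axis=0)
        q, _ = np.linalg.qr(z)
        u, v = q[:, 0], q[:, 1]
        design = pd.DataFrame({"x1": u, "x2": 0.8 * u + 0.6 * v})
        out = eg.vif(design)
        assert out["x1"] == pytest.approx(1 / (1 - 0.64), abs=1e-9)
        assert out["x2"] == pytest.approx(2.7778, abs=1e-3)

    def test_orthogonal_predictors(self, rng):
        z = rng.normal(size=(40, 3))
        z -= z.mean(axis=0)
        q, _ = np.linalg.qr(z)
        out = eg.vif(pd.DataFrame(q, columns=["a", "b", "c"]))
        assert all(v == pytest.approx(1.0, abs=1e-9) for v in out.values())

    def test_scale_invariance(self, rng):
        design = pd.DataFrame(rng.normal(size=(25, 3)), columns=["a", "b", "c"])
        before = eg.vif(design)
        design["a"] = design["a"] * 1000.0
        after = eg.vif(design)
        assert before["b"] == pytest.approx(after["b"])

    def test_perfect_collinearity_flagged_infinite(self):
        design = pd.DataFrame({"a": [1.0, 2, 3, 4, 5], "b": [2.0, 4, 6, 8, 10]})
        out = eg.vif(design)
        assert math.isinf(out["a"]) and math.isinf(out["b"])


class TestSpatialWeights:
    def _table(self, slopes=("west",)):
        rows = [{"slope": s, "elevation": e}
                for s in slopes for e in range(1800, 3000, 200)]
        return pd.DataFrame(rows)

    def test_single_slope_chain_is_tridiagonal(self):
        w = eg.build_spatial_weights(self._table(), row_standardize=False)
        m = w.matrix
        assert np.array_equal(m, m.T)
        assert np.all(np.triu(m, 2) == 0)
        assert np.all(np.diag(m, 1) == 1)

    def test_row_standardized_rows_sum_to_one(self):
        w = eg.build_spatial_weights(self._table())
        assert np.allclose(w.matrix.sum(axis=1), 1.0)

    def test_two_slopes_block_diagonal(self):
        w = eg.build_spatial_weights(self._table(("east", "west")),
                                     row_standardize=False)
        m = w.matrix
        assert np.all(m[:6, 6:] == 0) and np.all(m[6:, :6] == 0)
        assert np.any(m[:6, :6] > 0) and np.any(m[6:, 6:] > 0)


class TestMoransI:
    def _weights(self, n=12):
        table = pd.DataFrame({"slope": ["a"] * n,
                              "elevation": np.arange(n) * 200})
        return eg.build_spatial_weights(table)

    def test_expected_value_n12(self, rng):
        res = eg.morans_i(rng.normal(size=12), self._weights())
        assert res.expected == pytest.approx(-1 / 11)
        assert res.expected == pytest.approx(-0.0909, abs=5e-5)

    def test_alternating_residuals_negative_autocorrelation(self):
        resid = np.tile([1.0, -1.0], 6)
        res = eg.morans_i(resid, self._weights())
        assert res.I < res.expected

    def test_smooth_residuals_positive_autocorrelation(self):
        resid = np.linspace(-1, 1, 12)
        res = eg.morans_i(resid, self._weights())
        assert res.I > res.expected
        assert res.p_value < 0.05

    def test_normal_p_close_to_permutation_p(self, rng):
        w = self._weights()
        for _ in range(5):
            resid = rng.normal(size=12)
            res = eg.morans_i(resid, w)
            perm = np.array([
                eg.morans_i(rng.permutation(resid), w).I for _ in range(999)
            ])
            p_perm = (1 + np.sum(np.abs(perm - res.expected)
                                 >= abs(res.I - res.expected))) / 1000
            assert abs(res.p_value - p_perm) < 0.05

    def test_null_rejection_rate_near_nominal(self, rng):
        # iid residuals: the 5% test should reject at roughly 5%
        w = self._weights()
        rej = np.mean([
            eg.morans_i(rng.normal(size=12), w).p_value < 0.05
            for _ in range(800)
        ])
        assert 0.02 <= rej <= 0.08

    def test_zero_variance_rejected(self):
        with pytest.raises(ValueError):
            eg.morans_i(np.ones(12), self._weights())
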