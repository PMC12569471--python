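"""Multivariate PGLS: preparation, VIF, sequential SS, RRPP inference."""

import numpy as np
import pandas as pd
import pytest

from nestarch.errors import ValidationError
from nestarch.mvpgls import fit, gls_univariate, prepare_predictors, vif
from nestarch.phylo import inv_sqrt, vcv

from conftest import bm_simulate, star_covariance


def frame(values, labels=None, columns=None):
    values = np.asarray(values, dtype=float)
    labels = labels or [f"s{i:03d}" for i in range(values.shape[0])]
    return pd.DataFrame(values, index=labels, columns=columns)


class TestPreparePredictors:
    def test_scaling_uses_sample_sd(self):
        out = prepare_predictors(frame([[1.0], [2.0], [3.0]], columns=["x"]))
        # sd of {1,2,3} with n-1 denominator is exactly 1
        np.testing.assert_allclose(out["x"], [-1.0, 0.0, 1.0], atol=1e-12)

    def test_idempotent_on_standardized_column(self, rng):
        x = rng.standard_normal(50)
        x = (x - x.mean()) / x.std(ddof=1)
        out = prepare_predictors(frame(x[:, None], columns=["x"]))
        np.testing.assert_allclose(out["x"], x, atol=1e-12)

    def test_constant_column_named_in_error(self):
        with pytest.raises(ValidationError, match="flat"):
            prepare_predictors(
                frame(np.column_stack([np.ones(5), np.arange(5)]),
                      columns=["flat", "x"])
            )


class TestVif:
    def test_orthogonal_columns_have_unit_vif(self):
        # orthogonal to each other *and* to the intercept
        raw = np.random.default_rng(1).standard_normal((30, 4))
        raw[:, 0] = 1.0
        q, _ = np.linalg.qr(raw)
        out = vif(frame(q[:, 1:], columns=list("abc")))
        np.testing.assert_allclose(out, 1.0, atol=1e-10)

    def test_duplicated_column_is_infinite(self, rng):
        x = rng.standard_normal(20)
        out = vif(frame(np.column_stack([x, x, rng.standard_normal(20)]),
                        columns=list("abc")))
        assert np.isinf(out["a"]) and np.isinf(out["b"])

    def test_known_correlation_matches_least_squares_oracle(self, rng):
        n = 2000
        z = rng.standard_normal(n)
        x1 = z + 0.75 * rng.standard_normal(n)
        x2 = z + 0.75 * rng.standard_normal(n)
        x3 = rng.standard_normal(n)
        X = frame(np.column_stack([x1, x2, x3]), columns=list("abc"))
        out = vif(X)
        # oracle: direct OLS R^2 of each column on the others
        for j, col in enumerate("abc"):
            y = X[col].to_numpy()
            others = np.column_stack(
                [np.ones(n), np.delete(X.to_numpy(), j, axis=1)]
            )
            beta, *_ = np.linalg.lstsq(others, y, rcond=None)
            r2 = 1 - ((y - others @ beta) ** 2).sum() / ((y - y.mean()) ** 2).sum()
            assert out[col] == pytest.approx(1 / (1 - r2), rel=1e-10)


class TestMvPglsFit:
    def test_star_phylogeny_equals_ols(self, rng):
        n, k, p = 30, 4, 3
        C = star_covariance(n, depth=2.0)
        Y = frame(rng.standard_normal((n, k)), labels=C.labels)
        X = frame(rng.standard_normal((n, p)), labels=C.labels, columns=list("abc"))
        f = fit(Y, X, C, n_perm=9, seed=0)
        design = np.column_stack([np.ones(n), X.to_numpy()])
        ols, *_ = np.linalg.lstsq(design, Y.to_numpy(), rcond=None)
        np.testing.assert_allclose(f.coefficients.to_numpy(), ols, atol=1e-8)

    def test_constant_response_has_zero_ss(self):
        n = 20
        C = star_covariance(n)
        Y = frame(np.full((n, 3), 2.5), labels=C.labels)
        X = frame(np.random.default_rng(0).standard_normal((n, 2)),
                  labels=C.labels, columns=list("ab"))
        f = fit(Y, X, C, n_perm=9, seed=0)
        assert f.total_ss == pytest.approx(0.0, abs=1e-18)
        np.testing.assert_allclose(f.anova.loc[list("ab"), "SS"], 0.0, atol=1e-18)
        assert (f.anova.loc[list("ab"), "R2"] == 0).all()

    def test_sequential_ss_sums_to_total(self, bd_tree_64, rng):
        C = vcv(bd_tree_64)
        Y = bm_simulate(C, 5, rng)
        X = bm_simulate(C, 4, rng)
        X.columns = list("abcd")
        f = fit(Y, prepare_predictors(X), C, n_perm=19, seed=3)
        ss = f.anova.loc[list("abcd"), "SS"].sum() + f.residual_ss
        assert ss == pytest.approx(f.total_ss, abs=1e-8 * max(1, f.total_ss))

    def test_univariate_response_matches_scalar_permutation_oracle(
        self, bd_tree_64, rng
    ):
        """k=1 fit agrees with an independently coded scalar PGLS-RRPP."""
        C = vcv(bd_tree_64)
        n = 64
        y = bm_simulate(C, 1, rng)
        X = bm_simulate(C, 2, rng)
        X.columns = ["a", "b"]
        Xs = prepare_predictors(X)
        seed, n_perm = 11, 99
        f = fit(y, Xs, C, n_perm=n_perm, seed=seed)

        # oracle: plain loops, pinv-based projections, same seed discipline
        P = inv_sqrt(C)
        yw = P @ y.to_numpy()[:, 0]
        dm = P @ np.column_stack([np.ones(n), Xs.to_numpy()])
        rng2 = np.random.default_rng(seed)
        perms = [np.arange(n)] + [rng2.permutation(n) for _ in range(n_perm)]

        def rss(a, b):
            beta = np.linalg.pinv(a) @ b
            r = b - a @ beta
            return float(r @ r)

        df_res = n - 3
        for j, term in enumerate(["a", "b"]):
            red, full = dm[:, : j + 1], dm[:, : j + 2]
            beta_red = np.linalg.pinv(red) @ yw
            fitted, resid = red @ beta_red, yw - red @ beta_red
            f_stats = []
            for pi in perms:
                ystar = fitted + resid[pi]
                ss_term = rss(red, ystar) - rss(full, ystar)
                ss_res = rss(dm, ystar)
                f_stats.append((ss_term / 1) / (ss_res / df_res))
            f_stats = np.array(f_stats)
            p_oracle = (np.sum(f_stats[1:] >= f_stats[0] - 1e-12) + 1) / (n_perm + 1)
            assert f.anova.loc[term, "F"] == pytest.approx(f_stats[0], rel=1e-8)
            assert f.anova.loc[term, "p_perm"] == pytest.approx(p_oracle, abs=1e-12)

    def test_permutation_p_reproducible_and_seed_stable(self, bd_tree_64, rng):
        C = vcv(bd_tree_64)
        Y = bm_simulate(C, 3, rng)
        X = bm_simulate(C, 2, rng)
        X.columns = ["a", "b"]
        Xs = prepare_predictors(X)
        p1 = fit(Y, Xs, C, n_perm=199, seed=5).anova["p_perm"]
        p2 = fit(Y, Xs, C, n_perm=199, seed=5).anova["p_perm"]
        pd.testing.assert_series_equal(p1, p2)
        p3 = fit(Y, Xs, C, n_perm=199, seed=6).anova["p_perm"]
        # different seed: p moves by at most Monte-Carlo error
        for term in ["a", "b"]:
            se = np.sqrt(p1[term] * (1 - p1[term]) / 199)
            assert abs(p1[term] - p3[term]) < 5 * se + 2 / 199

    def test_power_exceeds_null_rate_with_planted_effect(self, bd_tree_128, rng):
        C = vcv(bd_tree_128)
        X = bm_simulate(C, 2, rng)
        X.columns = ["a", "b"]
        Xs = prepare_predictors(X)
        hits = 0
        reps = 15
        for rep in range(reps):
            Y = bm_simulate(C, 4, rng)
            Y.iloc[:, 0] += 1.0 * Xs["a"]  # slope 1 sd on the first axis
            f = fit(Y, Xs, C, n_perm=99, seed=rep)
            hits += f.anova.loc["a", "p_perm"] <= 0.05
        assert hits >= 8  # well above the 5% null rate


class TestGlsUnivariate:
    def test_identity_covariance_matches_ols(self, rng):
        n = 40
        C = star_covariance(n)
        X = frame(rng.standard_normal((n, 2)), labels=C.labels, columns=["a", "b"])
        y = pd.Series(rng.standard_normal(n), index=C.labels)
        ours = gls_univariate(y, X, C)
        import statsmodels.api as sm

        ref = sm.OLS(y.to_numpy(),
                     np.column_stack([np.ones(n), X.to_numpy()])).fit()
        np.testing.assert_allclose(ours.params, ref.params, atol=1e-10)
        np.testing.assert_allclose(ours.bse, ref.bse, atol=1e-10)
        np.testing.assert_allclose(ours.pvalues, ref.pvalues, atol=1e-10)

    def test_matches_statsmodels_gls_on_tree(self, bd_tree_64, rng):
        C = vcv(bd_tree_64)
        X = bm_simulate(C, 2, rng)
        X.columns = ["a", "b"]
        y = bm_simulate(C, 1, rng)[0]
        ours = gls_univariate(y, X, C)
        import statsmodels.api as sm

        ref = sm.GLS(
            y.to_numpy(),
            np.column_stack([np.ones(64), X.to_numpy()]),
            sigma=C.values,
        ).fit()
        np.testing.assert_allclose(ours.params, ref.params, atol=1e-8)
        np.testing.assert_allclose(ours.bse, ref.bse, atol=1e-8)

    def test_slope_recovery_under_bm_noise(self, rng):
        from nestarch.synthetic_data import SimConfig, sim_tree

        tree = sim_tree(SimConfig(seed=2024, n_tips=200))
        C = vcv(tree)
        x = bm_simulate(C, 1, rng)[0]
        noise = bm_simulate(C, 1, rng)[0]
        y = 2.0 * x + noise
        f = gls_univariate(y, x.to_frame("x"), C)
        assert abs(f.params["x"] - 2.0) < 3 * f.bse["x"]

    def test_intercept_only_is_phylogenetic_grand_mean(self, bd_tree_64, rng):
        C = vcv(bd_tree_64)
        y = bm_simulate(C, 1, rng)[0]
        # closed form (1' C^-1 1)^-1 1' C^-1 y via an empty predictor set
        X = pd.DataFrame(index=y.index)
        cinv = np.linalg.inv(C.values)
        expected = float(cinv.sum(axis=0) @ y.loc[C.labels] / cinv.sum())
        f = gls_univariate(y, X, C)
        assert f.params["intercept"] == pytest.approx(expected, abs=1e-10)
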