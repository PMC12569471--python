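"""Phylogenetic logistic regression and the 17-state univariate suite."""

import numpy as np
import pandas as pd
import pytest

from nestarch.errors import ValidationError
from nestarch.phylo import vcv
from nestarch.plogit import (
    binarize_traits,
    congruence_report,
    phyloglm_fit,
    run_univariate_suite,
)
from nestarch.synthetic_data import SimConfig, simulate_dataset
from nestarch.traits import recode_table

from conftest import (
    bm_simulate,
    firth_logistic_oracle,
    make_recoded,
    random_recoded,
    star_covariance,
)


class TestBinarize:
    def test_indicator_values(self):
        records = [make_recoded("a", nest_type="cavity"),
                   make_recoded("b", nest_type="non_cavity")]
        ind = binarize_traits(records)
        assert ind.loc["a", "nest_type_cavity"] == 1
        assert ind.loc["a", "nest_type_non_cavity"] == 0
        assert ind.loc["b", "nest_type_non_cavity"] == 1

    def test_17_columns_partitioned_by_trait(self, rng):
        ind = binarize_traits(random_recoded(rng, 40))
        assert ind.shape[1] == 17
        for trait, width in [("nest_type", 2), ("structure", 4), ("site", 4),
                             ("attachment", 3), ("height_class", 4)]:
            cols = [c for c in ind.columns if c.startswith(trait)]
            assert len(cols) == width
            assert (ind[cols].sum(axis=1) == 1).all()


def star_logit_data(rng, n=40, beta=(0.3, 1.0, -0.7)):
    C = star_covariance(n)
    X = rng.standard_normal((n, len(beta) - 1))
    eta = np.column_stack([np.ones(n), X]) @ np.array(beta)
    y = (rng.random(n) < 1 / (1 + np.exp(-eta))).astype(float)
    cols = [f"x{j}" for j in range(X.shape[1])]
    return (pd.Series(y, index=C.labels),
            pd.DataFrame(X, index=C.labels, columns=cols), C)


class TestPhyloglmFit:
    def test_star_tree_reduces_to_firth_oracle(self, rng):
        for _ in range(3):
            y, X, C = star_logit_data(rng)
            if y.min() == y.max():
                continue
            fit = phyloglm_fit(y, X, C)
            oracle = firth_logistic_oracle(y.to_numpy(), X.to_numpy())
            np.testing.assert_allclose(fit.params.to_numpy(), oracle, atol=1e-4)
            assert fit.phylo_signal == 0.0

    def test_no_signal_limit_on_real_tree_equals_firth(self, bd_tree_64, rng):
        C = vcv(bd_tree_64)
        x = bm_simulate(C, 1, rng)[0]
        y = (x + 0.5 * rng.standard_normal(64) > 0).astype(float)
        fit = phyloglm_fit(pd.Series(y, index=C.labels), x.to_frame("x"), C,
                           s_grid=(0.0,))
        oracle = firth_logistic_oracle(y, x.to_numpy()[:, None])
        np.testing.assert_allclose(fit.params.to_numpy(), oracle, atol=1e-4)

    def test_separated_data_stay_finite(self):
        n = 20
        C = star_covariance(n)
        x = np.linspace(-1, 1, n)
        y = (x > 0).astype(float)
        fit = phyloglm_fit(pd.Series(y, index=C.labels),
                           pd.DataFrame({"x": x}, index=C.labels), C)
        assert np.isfinite(fit.params.to_numpy()).all()
        assert fit.converged

    def test_constant_response_rejected(self):
        n = 10
        C = star_covariance(n)
        with pytest.raises(ValidationError):
            phyloglm_fit(pd.Series(np.ones(n), index=C.labels),
                         pd.DataFrame({"x": np.arange(n)}, index=C.labels), C)

    def test_slope_recovery_under_liability_generator(self, rng):
        """Latent-liability simulation with true slope 1: estimates on the
        logistic scale should average near 1 (pilot-calibrated window)."""
        from nestarch.synthetic_data import SimConfig, sim_tree

        tree = sim_tree(SimConfig(seed=11, n_tips=200))
        C = vcv(tree)
        chol = np.linalg.cholesky(C.values + 1e-12 * np.eye(200))
        estimates = []
        for _ in range(30):
            x = chol @ rng.standard_normal(200)
            x = (x - x.mean()) / x.std(ddof=1)
            liability = x + 1.5 * (chol @ rng.standard_normal(200))
            y = (liability > np.median(liability)).astype(float)
            fit = phyloglm_fit(pd.Series(y, index=C.labels),
                               pd.DataFrame({"x": x}, index=C.labels), C)
            estimates.append(fit.params["x"])
        assert 0.9 <= np.mean(estimates) <= 1.5

    def test_wald_type_one_error_on_star_null(self, rng):
        n, reps = 200, 400
        C = star_covariance(n)
        hits = 0
        for _ in range(reps):
            x = rng.standard_normal(n)
            y = (rng.random(n) < 0.5).astype(float)
            fit = phyloglm_fit(pd.Series(y, index=C.labels),
                               pd.DataFrame({"x": x}, index=C.labels), C)
            hits += fit.pvalues["x"] < 0.05
        assert 0.03 <= hits / reps <= 0.08


@pytest.fixture(scope="module")
def suite_inputs():
    ds = simulate_dataset(SimConfig(seed=77, n_tips=96))
    recoded, _ = recode_table(ds.records)
    ids = [r.species_id for r in recoded]
    X = pd.DataFrame(
        {
            "ndvi": ds.covariates.loc[ids, "ndvi"],
            "predators": ds.covariates.loc[ids, "predator_diversity"],
        }
    )
    X = (X - X.mean()) / X.std(ddof=1)
    return recoded, X, vcv(ds.tree, order=ids)


class TestSuite:
    def test_suite_has_17_rows_and_flags(self, suite_inputs):
        recoded, X, C = suite_inputs
        suite = run_univariate_suite(recoded, X, C)
        assert len(suite) == 17
        assert "p_holm_ndvi" in suite.columns
        # constant indicators (absent states) are flagged, not raised
        constant = binarize_traits(recoded).nunique() == 1
        for state in constant[constant].index:
            assert not suite.loc[state, "converged"]

    def test_species_exclusion_shrinks_sample(self, suite_inputs):
        recoded, X, C = suite_inputs
        drop = recoded[0].species_id
        suite = run_univariate_suite(recoded, X, C, exclude=(drop,))
        assert len(suite) == 17  # still every state reported

    def test_deterministic_output_bytes(self, suite_inputs):
        recoded, X, C = suite_inputs
        a = run_univariate_suite(recoded, X, C).to_csv()
        b = run_univariate_suite(recoded, X, C).to_csv()
        assert a == b

    def test_congruence_report_alignment(self, suite_inputs):
        recoded, X, C = suite_inputs
        suite = run_univariate_suite(recoded, X, C)
        assoc = pd.DataFrame(
            [
                {"trait_state": "nest_type_cavity", "predictor": "ndvi",
                 "association": "tendency_positive"},
                {"trait_state": "site_ground", "predictor": "predators",
                 "association": "none"},
            ]
        )
        rep = congruence_report(suite, assoc)
        assert set(rep.columns) >= {"trait_state", "predictor", "agree"}
        none_row = rep[rep["trait_state"] == "site_ground"].iloc[0]
        assert none_row["multivariate_sign"] == 0 and not none_row["agree"]
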