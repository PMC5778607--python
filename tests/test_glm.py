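"""Core numerics: size factors, penalized GLM, dispersion, shrinkage prior."""

import numpy as np
import pandas as pd
import pytest
from scipy.optimize import minimize

from tdexon.glm import (
    DesignTable,
    SizeFactors,
    estimate_dispersion,
    estimate_shrinkage_prior,
    estimate_size_factors,
    fit_gp_glm,
    nb_loglik,
    usage_design_matrix,
)
from tdexon.simulate import gamma_poisson

from conftest import make_design, unit_size_factors


class TestSizeFactors:
    def test_identical_columns_give_unit_factors(self):
        m = pd.DataFrame({"a": [5, 10, 3], "b": [5, 10, 3], "c": [5, 10, 3]})
        s = estimate_size_factors(m).s
        assert np.allclose(s, 1.0)

    def test_scaling_a_column_scales_its_relative_factor(self):
        # doubling one column doubles its factor relative to the others
        # (the geometric-mean reference rescales all factors by a constant)
        rng = np.random.default_rng(0)
        base = rng.poisson(50, size=(100, 3)) + 1
        m = pd.DataFrame(base, columns=list("abc"))
        m2 = m.copy()
        m2["b"] = m2["b"] * 2
        s1 = estimate_size_factors(m).s
        s2 = estimate_size_factors(m2).s
        assert np.isclose(s2["b"] / s2["a"], 2 * s1["b"] / s1["a"])
        assert np.isclose(s2["c"] / s2["a"], s1["c"] / s1["a"])

    def test_median_of_ratios_hand_oracle(self):
        m = pd.DataFrame([[2, 4], [4, 8], [8, 16]], columns=["a", "b"])
        s = estimate_size_factors(m).s
        # every row has ratio (1/sqrt(2), sqrt(2)) to its geometric mean
        assert np.allclose(s.to_numpy(), [1 / np.sqrt(2), np.sqrt(2)], atol=1e-12)

    def test_no_all_positive_row_is_informative_error(self):
        m = pd.DataFrame([[0, 4], [4, 0]], columns=["a", "b"])
        with pytest.raises(ValueError, match="size factors"):
            estimate_size_factors(m)


def brute_force_penalized_fit(y, X, offset, alpha, penalty):
    """Independent penalized-likelihood optimizer (generic quasi-Newton)."""

    def negpll(b):
        mu = np.exp(offset + X @ b)
        return -(nb_loglik(y, mu, alpha) - 0.5 * float(penalty @ b**2))

    def grad(b):
        mu = np.exp(offset + X @ b)
        return -(X.T @ ((y - mu) / (1 + alpha * mu)) - penalty * b)

    res = minimize(
        negpll, np.zeros(X.shape[1]), jac=grad, method="L-BFGS-B",
        options={"maxiter": 10000, "ftol": 1e-15, "gtol": 1e-10},
    )
    return res.x


class TestFitGpGlm:
    def test_constant_counts_saturated_poisson(self, design_2x2):
        sf = unit_size_factors(design_2x2)
        cs = fit_gp_glm(
            np.full(4, 2), np.full(4, 8), design_2x2, sf, 0.0,
            prior_variance=np.inf, prior_variance_sex=np.inf,
        )
        assert np.isclose(np.exp(cs.beta_E), 0.25, atol=1e-6)
        assert cs.beta_UT.abs().max().max() < 1e-6

    def test_sex_covariate_coding_and_sign(self):
        design = make_design(4, 2)  # alternating M/F
        sf = unit_size_factors(design)
        x = design.x_sex
        assert set(np.unique(x)) == {-0.5, 0.5}
        # females (x=+1/2) use the exon 4x more
        k1 = np.where(x > 0, 80, 20)
        k0 = np.full(design.n_samples, 100)
        cs = fit_gp_glm(k1, k0, design, sf, 0.0, prior_variance=0.5,
                        prior_variance_sex=10.0)
        assert cs.beta_sex > 0.5  # log(4) minus shrinkage

    def test_matches_brute_force_optimizer(self, design_3x2):
        rng = np.random.default_rng(5)
        sf = unit_size_factors(design_3x2)
        n = design_3x2.n_samples
        k1 = rng.poisson(40, n)
        k0 = rng.poisson(120, n)
        alpha, pv = 0.05, 1.0
        cs = fit_gp_glm(k1, k0, design_3x2, sf, alpha, prior_variance=pv,
                        prior_variance_sex=pv)
        X, _mask, meta = usage_design_matrix(design_3x2)
        y = np.concatenate([k0, k1]).astype(float)
        pen = np.zeros(X.shape[1])
        pen[meta["col_UT"]] = 1 / pv
        pen[meta["col_sex"]] = 1 / pv
        b_star = brute_force_penalized_fit(y, X, np.zeros(2 * n), alpha, pen)
        b_fit = np.concatenate(
            [cs.beta_S.to_numpy(), [cs.beta_E, cs.beta_sex], cs.ut_vector(design_3x2)]
        )
        assert np.max(np.abs(b_fit - b_star)) < 1e-4

    def test_shrinkage_monotone_in_prior_variance(self, design_3x2):
        rng = np.random.default_rng(9)
        sf = unit_size_factors(design_3x2)
        n = design_3x2.n_samples
        k1 = rng.poisson(np.where(design_3x2.table["tissue"] == "T1", 120, 30))
        k0 = rng.poisson(200, n)
        prev = None
        for pv in [10.0, 1.0, 0.1, 0.01]:
            cs = fit_gp_glm(k1, k0, design_3x2, sf, 0.05, prior_variance=pv)
            cur = np.abs(cs.ut_vector(design_3x2))
            if prev is not None:
                assert (cur <= prev + 1e-8).all()
            prev = cur

    def test_size_factor_invariance(self, design_2x2):
        # multiplying one sample's counts by c and its size factor by c
        # leaves the unpenalized score equations (hence the fit) unchanged;
        # with a finite prior the likelihood/penalty balance shifts, so the
        # exact invariance is checked on the unpenalized fit
        rng = np.random.default_rng(3)
        n = design_2x2.n_samples
        k1 = rng.poisson(50, n)
        k0 = rng.poisson(150, n)
        sf1 = unit_size_factors(design_2x2)
        cs1 = fit_gp_glm(k1, k0, design_2x2, sf1, 0.0, prior_variance=np.inf)
        c = 3
        k1b, k0b = k1.copy(), k0.copy()
        k1b[0] *= c
        k0b[0] *= c
        s2 = pd.Series(1.0, index=design_2x2.samples)
        s2.iloc[0] = c
        cs2 = fit_gp_glm(
            k1b, k0b, design_2x2, SizeFactors(s2), 0.0, prior_variance=np.inf
        )
        assert np.allclose(cs1.ut_vector(design_2x2), cs2.ut_vector(design_2x2), atol=1e-6)
        assert np.isclose(cs1.beta_E, cs2.beta_E, atol=1e-6)

    def test_negative_dispersion_rejected(self, design_2x2):
        sf = unit_size_factors(design_2x2)
        with pytest.raises(ValueError):
            fit_gp_glm(np.ones(4), np.ones(4), design_2x2, sf, -0.1)


@pytest.fixture(scope="module")
def big_design():
    return make_design(250, 2, sexes=False)


class TestDispersion:
    def test_poisson_data_hits_floor(self, big_design):
        rng = np.random.default_rng(11)
        sf = unit_size_factors(big_design)
        k1 = rng.poisson(100, 500)
        k0 = rng.poisson(300, 500)
        assert estimate_dispersion(k1, k0, big_design, sf) <= 1e-4

    def test_recovers_moderate_dispersion(self, big_design):
        rng = np.random.default_rng(12)
        sf = unit_size_factors(big_design)
        hits = 0
        n_rep = 100
        for _ in range(n_rep):
            k1 = gamma_poisson(rng, np.full(500, 100.0), 0.1)
            k0 = gamma_poisson(rng, np.full(500, 300.0), 0.1)
            a = estimate_dispersion(k1, k0, big_design, sf)
            hits += abs(a - 0.1) <= 0.03
        assert hits >= 0.9 * n_rep

    def test_underdispersed_counts_clipped_at_floor(self, design_3x2):
        sf = unit_size_factors(design_3x2)
        n = design_3x2.n_samples
        a = estimate_dispersion(np.full(n, 50), np.full(n, 150), design_3x2, sf)
        assert a <= 1e-4

    def test_all_zero_counts_rejected(self, design_3x2):
        sf = unit_size_factors(design_3x2)
        n = design_3x2.n_samples
        with pytest.raises(ValueError, match="zero"):
            estimate_dispersion(np.zeros(n), np.zeros(n), design_3x2, sf)


class TestShrinkagePrior:
    def test_all_zero_mles_give_minimum_prior(self):
        assert estimate_shrinkage_prior(np.zeros(200), min_prior=0.01) == 0.01

    def test_too_few_inputs_fall_back_to_default(self):
        assert estimate_shrinkage_prior(np.ones(10), default=1.0) == 1.0

    def test_recovers_generating_variance(self):
        rng = np.random.default_rng(21)
        errs = []
        for _ in range(50):
            betas = rng.normal(0, 0.5, size=2000)
            errs.append(estimate_shrinkage_prior(betas))
        assert abs(np.mean(errs) - 0.25) < 0.05  # within 20% of 0.25

    def test_sampling_variance_is_subtracted(self):
        rng = np.random.default_rng(22)
        betas = rng.normal(0, np.sqrt(0.25 + 0.1), size=5000)
        v = estimate_shrinkage_prior(betas, sampling_variances=np.full(5000, 0.1))
        assert abs(v - 0.25) < 0.08

    def test_infinite_prior_reproduces_unpenalized_fit(self, design_2x2):
        rng = np.random.default_rng(23)
        sf = unit_size_factors(design_2x2)
        n = design_2x2.n_samples
        k1 = rng.poisson(60, n)
        k0 = rng.poisson(180, n)
        cs_inf = fit_gp_glm(k1, k0, design_2x2, sf, 0.05, prior_variance=np.inf)
        cs_big = fit_gp_glm(k1, k0, design_2x2, sf, 0.05, prior_variance=1e8)
        assert np.allclose(
            cs_inf.ut_vector(design_2x2), cs_big.ut_vector(design_2x2), atol=1e-4
        )


def test_design_table_validation():
    with pytest.raises(ValueError, match="missing columns"):
        DesignTable(pd.DataFrame({"sample": ["a"], "individual": ["i"]}))
    d = make_design(2, 3)
    assert d.is_fully_crossed()
    broken = d.table.iloc[:-1]
    assert not DesignTable(broken).is_fully_crossed()
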