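import warnings

import numpy as np
import pytest

from pairedlcs import (
    DegenerateDataError,
    MomentSummary,
    PairedSample,
    beta_hat,
    compute_moments,
    extract_lcs_estimates,
    fit_ar_lagged,
    fit_lcs_correlated,
    fit_lcs_no_sfm,
    fit_lcs_sfm,
    gamma_hat,
    moments_from_summary,
    paired_t_test,
    psi_hat,
    r_level_change,
    standardized_stability,
)

from conftest import random_paired_summary


class TestPairedTTest:
    def test_toy_oracle(self, toy_summary):
        res = paired_t_test(toy_summary)
        assert res.d == pytest.approx(2.0)
        assert res.se_d == pytest.approx(np.sqrt((2.0 / 3.0) / 4.0), abs=1e-12)
        assert res.t_stat == pytest.approx(4.898979485566, abs=1e-9)
        assert res.df_t == 3
        # frozen from scipy's t CDF: 2 * sf(4.898979, 3)
        assert res.p_two_sided == pytest.approx(0.0162766, abs=1e-6)

    def test_null_case(self):
        m = moments_from_summary(50, 1.0, 1.0, 1.0, 1.2, 0.4)
        res = paired_t_test(m)
        assert res.t_stat == 0.0
        assert res.p_two_sided == 1.0

    def test_uniform_change_is_degenerate(self):
        # y2 = y1 + 1 exactly: the change score has zero variance
        s = PairedSample([1.0, 2.0, 3.0, 4.0], [2.0, 3.0, 4.0, 5.0])
        with pytest.raises(DegenerateDataError, match="zero variance"):
            paired_t_test(compute_moments(s))


class TestCorrelatedLcs:
    def test_toy_matches_t_test_with_normal_reference(self, toy_summary_centered):
        res = fit_lcs_correlated(toy_summary_centered)
        assert res.df == 0
        assert res.estimates["mu_delta"] == pytest.approx(2.0, abs=1e-10)
        assert res.standard_errors["mu_delta"] == pytest.approx(0.4082483, abs=1e-7)
        assert res.crit_ratios["mu_delta"] == pytest.approx(4.898979, abs=1e-5)
        # frozen from the normal CDF: 2 * Phi(-4.899)
        assert res.p_values["mu_delta"] == pytest.approx(9.63e-7, rel=1e-2)

    def test_cov_fixed_zero_leaves_mean_change_unchanged(self, toy_summary_centered):
        free = fit_lcs_correlated(toy_summary_centered)
        fixed = fit_lcs_correlated(toy_summary_centered, cov_fixed_zero=True)
        assert fixed.df == 1
        assert fixed.estimates["mu_delta"] == pytest.approx(
            free.estimates["mu_delta"], abs=1e-10
        )
        assert fixed.standard_errors["mu_delta"] == pytest.approx(
            free.standard_errors["mu_delta"], abs=1e-8
        )
        assert fixed.chi_square > 0.0


class TestSfmLcs:
    def test_toy_regression_oracle(self, toy_summary_centered):
        res = fit_lcs_sfm(toy_summary_centered)
        assert res.df == 0
        assert res.estimates["gamma"] == pytest.approx(0.6, abs=1e-10)
        assert res.estimates["alpha"] == pytest.approx(2.0, abs=1e-10)
        assert res.estimates["psi"] == pytest.approx(1.0 / 15.0, abs=1e-10)
        assert res.standard_errors["alpha"] == pytest.approx(0.1290994, abs=1e-7)
        assert res.crit_ratios["alpha"] == pytest.approx(15.4919, abs=1e-3)

    def test_uncentered_data_warns(self, toy_summary):
        with pytest.warns(UserWarning, match="uncentered"):
            fit_lcs_sfm(toy_summary)

    def test_zero_level_change_correlation_gives_t_test_se(self):
        # cov(Y1, D) = 0  <=>  cov12 = var1: conditioning on baseline buys nothing
        m = MomentSummary(n=30, mean1=0.0, mean2=-0.4, var1=1.0, var2=2.0, cov12=1.0)
        assert r_level_change(m) == pytest.approx(0.0)
        sfm = fit_lcs_sfm(m)
        corr = fit_lcs_correlated(m)
        assert sfm.estimates["gamma"] == pytest.approx(0.0, abs=1e-10)
        assert sfm.standard_errors["alpha"] == pytest.approx(
            corr.standard_errors["mu_delta"], abs=1e-8
        )

    def test_sfm_se_never_exceeds_correlated_se(self):
        rng = np.random.default_rng(5)
        for _ in range(25):
            m = random_paired_summary(rng)
            m = MomentSummary(m.n, 0.0, m.d, m.var1, m.var2, m.cov12)
            sfm = fit_lcs_sfm(m)
            corr = fit_lcs_correlated(m)
            assert sfm.standard_errors["alpha"] <= corr.standard_errors["mu_delta"] + 1e-10
            assert sfm.estimates["alpha"] == pytest.approx(
                corr.estimates["mu_delta"], abs=1e-10
            )


class TestNoSfmLcs:
    def test_constraint_already_satisfied(self):
        m = MomentSummary(n=30, mean1=0.0, mean2=-0.4, var1=1.0, var2=2.0, cov12=1.0)
        res = fit_lcs_no_sfm(m)
        assert res.chi_square == pytest.approx(0.0, abs=1e-6)

    def test_toy_chi_square(self, toy_summary_centered):
        res = fit_lcs_no_sfm(toy_summary_centered)
        assert res.chi_square == pytest.approx(6.907755, abs=1e-5)


class TestArLagged:
    def test_toy_slope_and_identity_with_gamma(self, toy_summary_centered):
        res = fit_ar_lagged(toy_summary_centered)
        assert res.estimates["beta"] == pytest.approx(1.6, abs=1e-10)
        assert res.estimates["beta"] == pytest.approx(
            1.0 + gamma_hat(toy_summary_centered), abs=1e-12
        )

    def test_perfect_stability(self):
        # Y2 = Y1 + c: beta = 1, gamma = 0, change identical in all persons
        m = MomentSummary(n=20, mean1=0.0, mean2=3.0, var1=2.0, var2=2.0, cov12=2.0 - 1e-9)
        assert beta_hat(m) == pytest.approx(1.0, abs=1e-8)
        assert gamma_hat(m) == pytest.approx(0.0, abs=1e-8)

    def test_equal_variance_gamma_is_one_minus_standardized_stability(self):
        """With sd1 = sd2 the standardized stability equals rho and
        |gamma| = 1 - rho."""
        rng = np.random.default_rng(17)
        for _ in range(20):
            m = random_paired_summary(rng)
            eq = MomentSummary(m.n, m.mean1, m.mean2, m.var1, m.var1, m.rho * m.var1)
            assert abs(gamma_hat(eq)) == pytest.approx(
                1.0 - standardized_stability(eq), abs=1e-10
            )


def test_extract_lcs_estimates_maps_parameters(toy_summary_centered):
    sfm = extract_lcs_estimates(fit_lcs_sfm(toy_summary_centered))
    assert sfm.mean_change == pytest.approx(2.0, abs=1e-10)
    assert sfm.gamma == pytest.approx(0.6, abs=1e-10)
    assert sfm.abs_gamma == pytest.approx(0.6, abs=1e-10)
    corr = extract_lcs_estimates(fit_lcs_correlated(toy_summary_centered))
    assert corr.mean_change == pytest.approx(2.0, abs=1e-10)
    assert corr.gamma is None


def test_psi_hat_equals_regression_residual_variance():
    rng = np.random.default_rng(23)
    for _ in range(20):
        m = random_paired_summary(rng)
        assert psi_hat(m) == pytest.approx(m.var2 - m.cov12**2 / m.var1, rel=1e-10)
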