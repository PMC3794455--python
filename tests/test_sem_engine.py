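import numpy as np
import pytest

from pairedlcs import (
    MomentSummary,
    SingularModelError,
    chi_square_no_sfm_closed_form,
    fit,
    implied_moments,
    ml_discrepancy,
)
from pairedlcs.lcs_models import (
    spec_ar_lagged,
    spec_lcs_correlated,
    spec_lcs_no_sfm,
    spec_lcs_sfm,
)
from pairedlcs.sem_engine import ModelSpec, Parameter

from conftest import random_paired_summary


class TestImpliedMoments:
    def test_correlated_spec_substitution(self, toy_summary_centered):
        spec = spec_lcs_correlated(toy_summary_centered)
        mu, sigma = implied_moments(spec, [0.0, -0.395, 1.0, 1.0, 0.0])
        np.testing.assert_allclose(mu, [0.0, -0.395])
        np.testing.assert_allclose(sigma, [[1.0, 1.0], [1.0, 2.0]])

    def test_sfm_spec_covariance_algebra(self, toy_summary_centered):
        # Y2 = (1+gamma) Y1 + alpha + zeta  =>  Cov(Y1,Y2) = (1+gamma) var1
        spec = spec_lcs_sfm(toy_summary_centered)
        mu, sigma = implied_moments(spec, [0.0, 2.0, 0.6, 5.0 / 3.0, 0.05])
        assert sigma[0, 1] == pytest.approx(1.6 * 5.0 / 3.0)
        assert sigma[0, 1] == pytest.approx(8.0 / 3.0)
        assert sigma[1, 1] == pytest.approx(1.6**2 * 5.0 / 3.0 + 0.05)

    def test_saturated_identity_at_sample_moments(self, toy_summary):
        m = toy_summary
        spec = spec_lcs_correlated(m)
        theta = [p.value for p in spec.free_parameters]
        mu, sigma = implied_moments(spec, theta)
        np.testing.assert_allclose(mu, m.mean_vector, atol=1e-12)
        np.testing.assert_allclose(sigma, m.cov_matrix, atol=1e-12)


class TestMlDiscrepancy:
    def test_zero_at_sample_moments(self, toy_summary):
        m = toy_summary
        assert ml_discrepancy(m, m.mean_vector, m.cov_matrix) == pytest.approx(0.0, abs=1e-12)

    def test_closed_form_value(self):
        # S = I, Sigma = diag(1, 2), equal means: F = ln 2 + 1.5 - 2
        m = MomentSummary(n=10, mean1=0.0, mean2=0.0, var1=1.0, var2=1.0, cov12=0.0)
        f = ml_discrepancy(m, [0.0, 0.0], [[1.0, 0.0], [0.0, 2.0]])
        assert f == pytest.approx(np.log(2.0) - 0.5, abs=1e-12)

    def test_singular_implied_covariance_raises(self, toy_summary):
        with pytest.raises(SingularModelError):
            ml_discrepancy(toy_summary, [0.0, 0.0], [[1.0, 1.0], [1.0, 1.0]])

    def test_mean_misfit_contributes_quadratic_form(self, toy_summary):
        m = toy_summary
        f = ml_discrepancy(m, m.mean_vector + [0.1, 0.0], m.cov_matrix)
        siginv = np.linalg.inv(m.cov_matrix)
        assert f == pytest.approx(0.01 * siginv[0, 0], abs=1e-12)


class TestFit:
    def test_saturated_fit_reproduces_moments(self, toy_summary):
        res = fit(spec_lcs_correlated(toy_summary), toy_summary)
        assert res.df == 0
        assert res.converged
        assert res.f_min < 1e-10
        assert res.chi_square <= 1e-6
        assert res.estimates["mu_delta"] == pytest.approx(toy_summary.d, abs=1e-8)

    def test_crit_ratio_is_estimate_over_se(self, toy_summary):
        res = fit(spec_lcs_sfm(toy_summary), toy_summary)
        for name, cr in res.crit_ratios.items():
            se = res.standard_errors[name]
            if se > 0:
                assert cr == pytest.approx(res.estimates[name] / se, abs=1e-10)

    def test_constrained_toy_chi_square(self, toy_summary_centered):
        # gamma = 0 on the toy: chi2(1) = -3 ln(1 - 0.9) = 6.9078
        res = fit(spec_lcs_no_sfm(toy_summary_centered), toy_summary_centered)
        assert res.df == 1
        assert res.chi_square == pytest.approx(-3.0 * np.log(0.1), abs=1e-8)
        assert res.chi_square == pytest.approx(6.9078, abs=5e-5)

    def test_chi_square_scale_flag(self, toy_summary_centered):
        m = toy_summary_centered
        res = fit(spec_lcs_no_sfm(m), m, chisq_scale="n")
        assert res.chi_square == pytest.approx(-4.0 * np.log(0.1), abs=1e-8)

    def test_recovers_optimum_from_perturbed_start(self, toy_summary):
        """The optimizer must find the optimum even when the start values
        are nowhere near the closed-form solution."""
        m = toy_summary
        base = spec_lcs_no_sfm(m)
        perturbed = ModelSpec(
            base.name,
            tuple(
                Parameter(p.name, p.role, p.free, p.value * 1.8 + 0.7 if p.free else p.value)
                for p in base.parameters
            ),
            base.structure,
        )
        res = fit(perturbed, m)
        assert res.converged
        assert res.f_min == pytest.approx(-np.log(0.1), rel=1e-7)

    def test_oracle_equivalence_gamma_zero(self):
        """Engine chi-square for the gamma = 0 model equals the closed form
        -(n-1) ln(1 - r^2) on many random datasets."""
        rng = np.random.default_rng(42)
        for _ in range(100):
            m = random_paired_summary(rng)
            res = fit(spec_lcs_no_sfm(m), m)
            assert abs(res.chi_square - chi_square_no_sfm_closed_form(m)) < 1e-6

    def test_reparameterization_invariance(self):
        """SF/M and lagged-AR are the same model in different coordinates:
        identical F_min and chi-square."""
        rng = np.random.default_rng(11)
        for _ in range(25):
            m = random_paired_summary(rng)
            a = fit(spec_lcs_sfm(m), m)
            b = fit(spec_ar_lagged(m), m)
            assert abs(a.f_min - b.f_min) < 1e-12
            assert abs(a.chi_square - b.chi_square) < 1e-10

    def test_se_positivity(self):
        rng = np.random.default_rng(3)
        for _ in range(20):
            m = random_paired_summary(rng)
            for builder in (spec_lcs_correlated, spec_lcs_sfm, spec_ar_lagged):
                res = fit(builder(m), m)
                for se in res.standard_errors.values():
                    assert np.isfinite(se) and se > 0.0
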