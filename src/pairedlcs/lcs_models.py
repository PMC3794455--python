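"""Model builders, closed-form estimators, and the concrete fits.

Four structural specifications of two-wave change, all built on the
identity ``Y2 = Y1 + LCS21`` with unit loadings, no residual on ``Y2``,
and the ``Y2`` intercept fixed at zero, so the latent change score LCS21
*is* the within-person change:

* **correlated** — the change score covaries freely with the baseline
  level; its mean ``mu_delta`` is the quantity the paired *t*-test
  examines, and the fit reproduces the classical ``d`` and ``s_D/sqrt(n)``
  exactly (only the reference distribution of the critical ratio differs).
* **self-feedback (SF/M)** — a directed path ``gamma`` from baseline to
  change; the intercept ``alpha`` is the mean change controlled for
  baseline, with the smaller residual-based standard error
  ``sqrt(psi/n)``, ``psi = var_D (1 - r^2)`` where ``r`` is the sample
  correlation between baseline and change.
* **no-SF/M** — the same model with ``gamma`` fixed at 0 (df = 1); its
  chi-square is the likelihood ratio ``-(n-1) ln(1 - r^2)``.
* **lagged autoregressive** — ``Y2 = c + beta Y1 + e``; the same model as
  SF/M in different coordinates, with ``beta = 1 + gamma``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .data_model import MomentSummary
from .exceptions import DegenerateDataError
from .inference import p_normal_two_sided, p_t_two_sided
from .sem_engine import FitResult, ModelSpec, Parameter, fit


# ---------------------------------------------------------------------------
# closed-form building blocks (also the oracles for the numeric engine)
# ---------------------------------------------------------------------------

def gamma_hat(summary: MomentSummary) -> float:
    """OLS slope of the change score on baseline: cov(Y1, D) / var(Y1)."""
    return (summary.cov12 - summary.var1) / summary.var1


def beta_hat(summary: MomentSummary) -> float:
    """Unstandardized autoregressive (stability) slope cov12 / var1."""
    return summary.cov12 / summary.var1


def r_level_change(summary: MomentSummary) -> float:
    """Sample correlation between baseline level and change score."""
    var_d = summary.var_d
    if var_d <= 0.0:
        raise DegenerateDataError("change score has zero variance")
    return float(
        (summary.cov12 - summary.var1) / np.sqrt(summary.var1 * var_d)
    )


def psi_hat(summary: MomentSummary) -> float:
    """Residual variance of the change regression: var_D * (1 - r^2)."""
    r = r_level_change(summary)
    return float(summary.var_d * (1.0 - r * r))


def chi_square_no_sfm_closed_form(summary: MomentSummary, chisq_scale: str = "n-1") -> float:
    """Likelihood-ratio chi-square of the gamma = 0 constraint.

    Equals ``-scale * ln(1 - r^2)`` with ``r`` the baseline/change
    correlation — the independent closed form the numeric engine is
    checked against.
    """
    scale = summary.n - 1 if chisq_scale == "n-1" else summary.n
    r = r_level_change(summary)
    return float(-scale * np.log1p(-r * r))


def corr_spec_wald_p(summary: MomentSummary) -> float:
    """Normal-reference p of the mean change in the correlated spec
    (closed form of the saturated fit; CR = d / sqrt(var_D/n))."""
    se = np.sqrt(summary.var_d / summary.n)
    if se <= 0.0:
        raise DegenerateDataError("change score has zero variance")
    return p_normal_two_sided(summary.d / se)


def sfm_wald_p(summary: MomentSummary) -> float:
    """Normal-reference p of the SF/M intercept (closed form of the
    saturated fit at a centered baseline; CR = d / sqrt(psi/n))."""
    se = np.sqrt(psi_hat(summary) / summary.n)
    if se <= 0.0:
        raise DegenerateDataError("change regression has zero residual variance")
    return p_normal_two_sided(summary.d / se)


# ---------------------------------------------------------------------------
# classical paired t-test
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class TTestResult:
    """Classical paired t-test computed from sample moments."""

    d: float
    se_d: float
    t_stat: float
    df_t: int
    p_two_sided: float
    rho: float
    n: int

    def to_dict(self) -> dict:
        return {
            "d": self.d,
            "se_d": self.se_d,
            "t_stat": self.t_stat,
            "df_t": self.df_t,
            "p_two_sided": self.p_two_sided,
            "rho": self.rho,
            "n": self.n,
        }


def paired_t_test(summary: MomentSummary) -> TTestResult:
    """Test whether the mean within-person change equals zero.

    Uses ``SE = s_D / sqrt(n)`` (``n-1`` denominator for ``s_D``) and the
    *t* distribution with ``n - 1`` degrees of freedom.
    """
    var_d = summary.var_d
    if var_d <= 0.0:
        raise DegenerateDataError(
            "change score has zero variance (perfectly uniform change); "
            "the paired t-test is undefined"
        )
    se = float(np.sqrt(var_d / summary.n))
    t = summary.d / se
    return TTestResult(
        d=float(summary.d),
        se_d=se,
        t_stat=float(t),
        df_t=summary.n - 1,
        p_two_sided=p_t_two_sided(t, summary.n - 1),
        rho=summary.rho,
        n=summary.n,
    )


# ---------------------------------------------------------------------------
# model specs (start values are the closed-form moment solutions)
# ---------------------------------------------------------------------------

def spec_lcs_correlated(summary: MomentSummary, cov_fixed_zero: bool = False) -> ModelSpec:
    """Correlated-change LCS spec.

    Free parameters: baseline mean ``mu1``, change mean ``mu_delta``,
    baseline variance ``var1``, change variance ``var_delta``, and the
    level-change covariance ``cov_level_change`` (fixed at 0 when
    ``cov_fixed_zero``).  Implied structure::

        mu    = (mu1, mu1 + mu_delta)
        Sigma = [[v1,        v1 + c       ],
                 [v1 + c,    v1 + vd + 2c ]]
    """
    c0 = 0.0 if cov_fixed_zero else summary.cov12 - summary.var1
    params = (
        Parameter("mu1", "mean", True, summary.mean1),
        Parameter("mu_delta", "mean", True, summary.d),
        Parameter("var1", "variance", True, summary.var1),
        Parameter("var_delta", "variance", True, summary.var_d),
        Parameter("cov_level_change", "covariance", not cov_fixed_zero, c0),
    )

    def structure(v):
        mu = np.array([v["mu1"], v["mu1"] + v["mu_delta"]])
        v1, vd, c = v["var1"], v["var_delta"], v["cov_level_change"]
        sigma = np.array([[v1, v1 + c], [v1 + c, v1 + vd + 2.0 * c]])
        return mu, sigma

    name = "lcs_correlated_cov0" if cov_fixed_zero else "lcs_correlated"
    return ModelSpec(name, params, structure)


def _sfm_like_spec(summary, name, gamma_free, gamma_value=None):
    if summary.var1 <= 0.0:  # pragma: no cover - MomentSummary already guards
        raise DegenerateDataError("baseline variance is zero")
    g0 = gamma_hat(summary) if gamma_value is None else gamma_value
    b0 = 1.0 + g0
    alpha0 = summary.d - g0 * summary.mean1
    psi0 = psi_hat(summary) if gamma_free else summary.var_d
    params = (
        Parameter("mu1", "mean", True, summary.mean1),
        Parameter("alpha", "mean", True, alpha0),
        Parameter("gamma", "path", gamma_free, g0 if gamma_free else gamma_value),
        Parameter("var1", "variance", True, summary.var1),
        Parameter("psi", "variance", True, psi0),
    )

    def structure(v):
        b = 1.0 + v["gamma"]
        mu = np.array([v["mu1"], v["alpha"] + b * v["mu1"]])
        v1, psi = v["var1"], v["psi"]
        sigma = np.array([[v1, b * v1], [b * v1, b * b * v1 + psi]])
        return mu, sigma

    return ModelSpec(name, params, structure)


def spec_lcs_sfm(summary: MomentSummary) -> ModelSpec:
    """Self-feedback LCS spec: change regressed on baseline (gamma free)."""
    return _sfm_like_spec(summary, "lcs_sfm", gamma_free=True)


def spec_lcs_no_sfm(summary: MomentSummary) -> ModelSpec:
    """SF/M spec with the self-feedback path fixed at zero (df = 1)."""
    return _sfm_like_spec(summary, "lcs_no_sfm", gamma_free=False, gamma_value=0.0)


def spec_ar_lagged(summary: MomentSummary) -> ModelSpec:
    """Lagged autoregressive spec ``Y2 = c + beta * Y1 + e``."""
    b0 = beta_hat(summary)
    params = (
        Parameter("mu1", "mean", True, summary.mean1),
        Parameter("intercept", "mean", True, summary.mean2 - b0 * summary.mean1),
        Parameter("beta", "path", True, b0),
        Parameter("var1", "variance", True, summary.var1),
        Parameter("psi", "variance", True, psi_hat(summary)),
    )

    def structure(v):
        b = v["beta"]
        mu = np.array([v["mu1"], v["intercept"] + b * v["mu1"]])
        v1, psi = v["var1"], v["psi"]
        sigma = np.array([[v1, b * v1], [b * v1, b * b * v1 + psi]])
        return mu, sigma

    return ModelSpec("ar_lagged", params, structure)


# ---------------------------------------------------------------------------
# fits
# ---------------------------------------------------------------------------

def fit_lcs_correlated(
    summary: MomentSummary, cov_fixed_zero: bool = False, chisq_scale: str = "n-1"
) -> FitResult:
    """Fit the correlated-change LCS model.

    Saturated (df = 0) with the covariance free: the mean-change estimate
    equals ``d`` and its SE equals the classical ``s_D/sqrt(n)``; only the
    normal (rather than *t*) reference for the critical ratio differs from
    the paired t-test.  With the covariance fixed at zero the mean change
    and its SE are unchanged but the model gains one df.
    """
    return fit(spec_lcs_correlated(summary, cov_fixed_zero), summary, chisq_scale)


def fit_lcs_sfm(summary: MomentSummary, chisq_scale: str = "n-1") -> FitResult:
    """Fit the self-feedback LCS model (saturated).

    The intercept ``alpha`` is the mean change at the average baseline;
    fitting on baseline-centered data is expected (a warning is issued
    otherwise, since the intercept then refers to baseline = 0 rather than
    to the baseline mean).
    """
    if abs(summary.mean1) > 1e-8 * max(summary.sd1, 1.0):
        warnings.warn(
            "SF/M model fitted on uncentered data: the intercept is the mean "
            "change at baseline = 0, not at the average baseline; consider "
            "center_on_wave1 first",
            stacklevel=2,
        )
    return fit(spec_lcs_sfm(summary), summary, chisq_scale)


def fit_lcs_no_sfm(summary: MomentSummary, chisq_scale: str = "n-1") -> FitResult:
    """Fit the LCS model with the self-feedback path forced to zero."""
    return fit(spec_lcs_no_sfm(summary), summary, chisq_scale)


def fit_ar_lagged(summary: MomentSummary, chisq_scale: str = "n-1") -> FitResult:
    """Fit the lagged autoregressive model ``Y2 = c + beta Y1 + e``.

    The unstandardized slope satisfies ``beta = 1 + gamma`` exactly; the
    standardized stability ``beta * sd1/sd2`` (the correlation ``rho``) is
    exposed via :func:`standardized_stability`.
    """
    return fit(spec_ar_lagged(summary), summary, chisq_scale)


def standardized_stability(summary: MomentSummary, fit_result: FitResult | None = None) -> float:
    """Standardized autoregressive slope ``beta * sd1 / sd2`` (= rho)."""
    b = fit_result.estimates["beta"] if fit_result is not None else beta_hat(summary)
    return float(b * summary.sd1 / summary.sd2)


# ---------------------------------------------------------------------------
# convenience extraction
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class LcsEstimates:
    """Substantive parameters of one LCS fit, by interpretation rather than
    by internal parameter name."""

    model: str
    mu1: float
    mean_change: float
    gamma: float | None
    abs_gamma: float | None
    sigma1_sq: float
    change_var: float
    cov_level_change: float | None


def extract_lcs_estimates(result: FitResult) -> LcsEstimates:
    """Map a fitted model's parameter names onto substantive quantities."""
    est = result.estimates
    if result.model.startswith("lcs_correlated"):
        return LcsEstimates(
            model=result.model,
            mu1=est["mu1"],
            mean_change=est["mu_delta"],
            gamma=None,
            abs_gamma=None,
            sigma1_sq=est["var1"],
            change_var=est["var_delta"],
            cov_level_change=est.get("cov_level_change", 0.0),
        )
    if result.model in ("lcs_sfm", "lcs_no_sfm"):
        g = est.get("gamma")
        return LcsEstimates(
            model=result.model,
            mu1=est["mu1"],
            mean_change=est["alpha"],
            gamma=g,
            abs_gamma=abs(g) if g is not None else None,
            sigma1_sq=est["var1"],
            change_var=est["psi"],
            cov_level_change=None,
        )
    raise ValueError(f"not an LCS fit: {result.model!r}")
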