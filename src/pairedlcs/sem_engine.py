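"""Maximum-likelihood fitting of two-variable path models with mean structure.

A model is a map from a small set of named parameters to an implied mean
vector ``mu(theta)`` and implied covariance ``Sigma(theta)`` of the pair
``(Y1, Y2)``.  Fitting minimizes the normal-theory discrepancy

    F(theta) = ln|Sigma| - ln|S| + tr(S Sigma^-1) - 2
               + (m - mu)' Sigma^-1 (m - mu)

over the free parameters, where ``m`` and ``S`` are the sample mean vector
and covariance matrix.  ``F >= 0`` with equality iff the implied moments
reproduce the sample moments, so a saturated model (df = 0) fits perfectly.

Conventions
-----------
* ``chi_square = (n - 1) * F_min`` by default (the convention of the
  classical SEM packages this mirrors); ``n * F_min`` behind a flag.
* Standard errors come from the observed information of the Gaussian
  log-likelihood ``-(n/2) * F`` at the optimum.  Combined with the
  unbiased (``n-1``) sample-moment convention this makes the saturated
  mean-change SE equal the classical paired-test SE ``s_D / sqrt(n)``.
* Gradients are exact (complex-step differentiation through the 2x2
  closed forms); the Hessian uses central differences of that gradient.
"""

from __future__ import annotations

import logging
import zlib
from dataclasses import dataclass, field
from typing import Callable, Mapping

import numpy as np
from scipy import optimize

from .data_model import MomentSummary
from .exceptions import ConfigError, ConvergenceError, SingularModelError
from .inference import p_normal_two_sided

logger = logging.getLogger(__name__)

_N_OBSERVED_MOMENTS = 5  # two means + two variances + one covariance
_ROLES = ("mean", "path", "variance", "covariance")
_CS_STEP = 1e-20        # complex-step size (exact to machine precision)
_HESS_REL_STEP = 1e-6   # relative step for the central-difference Hessian
_PENALTY = 1e10         # objective value returned outside the feasible region


@dataclass(frozen=True)
class Parameter:
    """One named model parameter.

    ``value`` is the starting value when free, or the fixed value otherwise.
    Variance-role parameters are kept positive during optimization via a
    log transform.
    """

    name: str
    role: str
    free: bool = True
    value: float = 0.0

    def __post_init__(self):
        if self.role not in _ROLES:
            raise ConfigError(f"unknown parameter role {self.role!r}")


@dataclass(frozen=True)
class ModelSpec:
    """A two-variable path model: parameters plus the structure map.

    ``structure`` receives a mapping of parameter name -> value (possibly
    complex, for derivative evaluation) and must return ``(mu, Sigma)``
    built by plain arithmetic, with ``Sigma`` symmetric.
    """

    name: str
    parameters: tuple[Parameter, ...]
    structure: Callable[[Mapping[str, complex]], tuple[np.ndarray, np.ndarray]]

    def __post_init__(self):
        names = [p.name for p in self.parameters]
        if len(set(names)) != len(names):
            raise ConfigError(f"duplicate parameter names in model {self.name!r}")
        if len(self.free_names) > _N_OBSERVED_MOMENTS:
            raise ConfigError(
                f"model {self.name!r} has {len(self.free_names)} free parameters; "
                f"at most {_N_OBSERVED_MOMENTS} are identified by two variables"
            )

    @property
    def free_parameters(self) -> tuple[Parameter, ...]:
        return tuple(p for p in self.parameters if p.free)

    @property
    def free_names(self) -> tuple[str, ...]:
        return tuple(p.name for p in self.parameters if p.free)

    @property
    def df(self) -> int:
        """Model degrees of freedom: observed moments minus free parameters."""
        return _N_OBSERVED_MOMENTS - len(self.free_parameters)

    def param_values(self, theta) -> dict:
        """Full name -> value mapping with free values taken from ``theta``."""
        theta = np.asarray(theta)
        if theta.size != len(self.free_parameters):
            raise ConfigError(
                f"theta has {theta.size} entries, model {self.name!r} has "
                f"{len(self.free_parameters)} free parameters"
            )
        values = {p.name: p.value for p in self.parameters}
        for p, v in zip(self.free_parameters, theta):
            values[p.name] = v
        return values


@dataclass(frozen=True)
class FitResult:
    """Estimates, SEs, critical ratios and fit statistics for one model."""

    model: str
    estimates: dict = field(default_factory=dict)
    standard_errors: dict = field(default_factory=dict)
    crit_ratios: dict = field(default_factory=dict)
    p_values: dict = field(default_factory=dict)
    f_min: float = 0.0
    chi_square: float = 0.0
    df: int = 0
    converged: bool = False
    n_used: int = 0
    chisq_scale: str = "n-1"
    convention: str = "n-1"

    def to_dict(self) -> dict:
        return {
            "model": self.model,
            "estimates": dict(self.estimates),
            "standard_errors": dict(self.standard_errors),
            "crit_ratios": dict(self.crit_ratios),
            "p_values": dict(self.p_values),
            "f_min": self.f_min,
            "chi_square": self.chi_square,
            "df": self.df,
            "converged": self.converged,
            "n_used": self.n_used,
            "chisq_scale": self.chisq_scale,
            "convention": self.convention,
        }


# ---------------------------------------------------------------------------
# discrepancy
# ---------------------------------------------------------------------------

def _core(mu, sigma, m, S):
    """Discrepancy F via 2x2 closed forms; complex-safe for derivatives."""
    s11, s12, s22 = sigma[0, 0], 0.5 * (sigma[0, 1] + sigma[1, 0]), sigma[1, 1]
    det = s11 * s22 - s12 * s12
    det_s = S[0, 0] * S[1, 1] - S[0, 1] * S[0, 1]
    # inverse of the implied covariance
    i11, i12, i22 = s22 / det, -s12 / det, s11 / det
    tr = S[0, 0] * i11 + 2.0 * S[0, 1] * i12 + S[1, 1] * i22
    d0, d1 = m[0] - mu[0], m[1] - mu[1]
    quad = d0 * d0 * i11 + 2.0 * d0 * d1 * i12 + d1 * d1 * i22
    return np.log(det) - np.log(det_s) + tr - 2.0 + quad


def implied_moments(spec: ModelSpec, theta) -> tuple[np.ndarray, np.ndarray]:
    """Implied mean vector and (symmetrized) covariance at ``theta``."""
    mu, sigma = spec.structure(spec.param_values(theta))
    mu = np.asarray(mu, dtype=float).reshape(2)
    sigma = np.asarray(sigma, dtype=float).reshape(2, 2)
    return mu, 0.5 * (sigma + sigma.T)


def ml_discrepancy(summary: MomentSummary, mu, sigma) -> float:
    """Normal-theory ML discrepancy between sample and implied moments.

    Raises
    ------
    SingularModelError
        If either covariance matrix is not positive definite.
    """
    mu = np.asarray(mu, dtype=float).reshape(2)
    sigma = np.asarray(sigma, dtype=float).reshape(2, 2)
    S = summary.cov_matrix
    for mat, label in ((sigma, "implied"), (S, "sample")):
        det = mat[0, 0] * mat[1, 1] - mat[0, 1] * mat[1, 0]
        if not (det > 0.0 and mat[0, 0] > 0.0):
            raise SingularModelError(
                f"{label} covariance is not positive definite (det={det})"
            )
    return float(_core(mu, sigma, summary.mean_vector, S).real)


# ---------------------------------------------------------------------------
# fitting
# ---------------------------------------------------------------------------

def _chisq_scale_factor(n: int, chisq_scale: str) -> float:
    if chisq_scale == "n-1":
        return float(n - 1)
    if chisq_scale == "n":
        return float(n)
    raise ConfigError(f"unknown chi-square scale {chisq_scale!r}")


class _Objective:
    """F as a function of the optimizer vector (variances log-transformed)."""

    def __init__(self, spec: ModelSpec, summary: MomentSummary):
        self.spec = spec
        self.m = summary.mean_vector
        self.S = summary.cov_matrix
        self.is_var = np.array(
            [p.role == "variance" for p in spec.free_parameters], dtype=bool
        )

    def theta_of(self, x: np.ndarray) -> np.ndarray:
        theta = np.array(x, copy=True)
        theta[self.is_var] = np.exp(theta[self.is_var])
        return theta

    def x_of(self, theta: np.ndarray) -> np.ndarray:
        x = np.array(theta, dtype=float, copy=True)
        x[self.is_var] = np.log(x[self.is_var])
        return x

    def f_theta(self, theta) -> complex:
        """Discrepancy at untransformed theta; complex-safe, penalized
        outside the positive-definite region."""
        mu, sigma = self.spec.structure(self.spec.param_values(theta))
        mu = np.asarray(mu)
        sigma = np.asarray(sigma)
        det = sigma[0, 0] * sigma[1, 1] - sigma[0, 1] * sigma[1, 0]
        if det.real <= 0.0 or sigma[0, 0].real <= 0.0:
            return _PENALTY + abs(det.real)
        return _core(mu, sigma, self.m, self.S)

    def value(self, x: np.ndarray) -> float:
        return float(np.real(self.f_theta(self.theta_of(x))))

    def value_and_grad(self, x: np.ndarray) -> tuple[float, np.ndarray]:
        f0 = self.value(x)
        if f0 >= _PENALTY:
            return f0, np.zeros_like(x)
        g = np.empty_like(x)
        for i in range(x.size):
            xc = x.astype(complex)
            xc[i] += 1j * _CS_STEP
            g[i] = np.imag(self.f_theta(self.theta_of_complex(xc))) / _CS_STEP
        return f0, g

    def theta_of_complex(self, x: np.ndarray) -> np.ndarray:
        theta = np.array(x, copy=True)
        theta[self.is_var] = np.exp(theta[self.is_var])
        return theta

    def grad_theta(self, theta: np.ndarray) -> np.ndarray:
        """Complex-step gradient of F in the *original* parameterization."""
        g = np.empty(theta.size)
        for i in range(theta.size):
            tc = theta.astype(complex)
            tc[i] += 1j * _CS_STEP
            g[i] = np.imag(self.f_theta(tc)) / _CS_STEP
        return g

    def hessian_theta(self, theta: np.ndarray) -> np.ndarray:
        """Central-difference Hessian of F (built on exact gradients)."""
        k = theta.size
        H = np.empty((k, k))
        for i in range(k):
            h = _HESS_REL_STEP * max(abs(theta[i]), 1.0)
            tp = theta.copy()
            tp[i] += h
            tm = theta.copy()
            tm[i] -= h
            H[:, i] = (self.grad_theta(tp) - self.grad_theta(tm)) / (2.0 * h)
        return 0.5 * (H + H.T)


def fit(
    spec: ModelSpec,
    summary: MomentSummary,
    chisq_scale: str = "n-1",
    max_restarts: int = 5,
    f_tol: float = 1e-10,
) -> FitResult:
    """Fit a model to sample moments by ML.

    Starts from the spec's start values (the model builders set these to
    closed-form moment-based solutions, typically at or next to the
    optimum), runs a quasi-Newton search with exact gradients, and retries
    from jittered starts (fixed sub-seeds) on failure.

    Raises
    ------
    ConvergenceError
        If no restart converges; carries the best point found.
    """
    obj = _Objective(spec, summary)
    theta0 = np.array([p.value for p in spec.free_parameters], dtype=float)
    if np.any(theta0[obj.is_var] <= 0.0):
        raise ConfigError(f"variance start values must be positive in {spec.name!r}")
    x0 = obj.x_of(theta0)

    best = None
    rng_key = zlib.adler32(spec.name.encode())
    for attempt in range(max_restarts + 1):
        if attempt == 0:
            x_start = x0
        else:
            rng = np.random.default_rng((rng_key + attempt) % 2**31)
            x_start = x0 + 0.1 * rng.standard_normal(x0.size)
        res = optimize.minimize(
            obj.value_and_grad,
            x_start,
            jac=True,
            method="L-BFGS-B",
            options={"ftol": 1e-15, "gtol": 1e-12, "maxiter": 500},
        )
        if best is None or res.fun < best.fun:
            best = res
        grad_norm = float(np.max(np.abs(res.jac)))
        if res.fun < _PENALTY and (res.success or grad_norm < 1e-6):
            best = res if res.fun <= best.fun else best
            break
        logger.debug(
            "restart %d for %s: fun=%g success=%s", attempt, spec.name, res.fun, res.success
        )
    else:
        partial = _build_result(spec, summary, obj, best.x, chisq_scale, converged=False)
        raise ConvergenceError(
            f"model {spec.name!r} failed to converge after {max_restarts} restarts",
            best_result=partial,
        )

    # never accept a point worse than the analytic start
    f_start = obj.value(x0)
    x_hat = best.x if best.fun <= f_start + f_tol else x0
    return _build_result(spec, summary, obj, x_hat, chisq_scale, converged=True)


def _build_result(
    spec: ModelSpec,
    summary: MomentSummary,
    obj: _Objective,
    x_hat: np.ndarray,
    chisq_scale: str,
    converged: bool,
) -> FitResult:
    theta_hat = obj.theta_of(x_hat)
    f_min = obj.value(x_hat)
    f_min = 0.0 if -1e-8 < f_min < 0.0 else f_min

    names = spec.free_names
    estimates = {name: float(v) for name, v in zip(names, theta_hat)}

    # observed information of the log-likelihood -(n/2) F, original coordinates
    ses = {}
    if names:
        info = 0.5 * summary.n * obj.hessian_theta(theta_hat)
        try:
            cov = np.linalg.inv(info)
            diag = np.diag(cov)
            ses = {
                name: float(np.sqrt(d)) if d > 0 else float("nan")
                for name, d in zip(names, diag)
            }
        except np.linalg.LinAlgError:  # pragma: no cover - defensive
            logger.warning("singular information matrix in %s", spec.name)
            ses = {name: float("nan") for name in names}

    crs, ps = {}, {}
    for name in names:
        se = ses.get(name, float("nan"))
        if np.isfinite(se) and se > 0:
            cr = estimates[name] / se
            crs[name] = float(cr)
            ps[name] = p_normal_two_sided(cr)
        else:
            crs[name] = float("nan")
            ps[name] = float("nan")

    scale = _chisq_scale_factor(summary.n, chisq_scale)
    return FitResult(
        model=spec.name,
        estimates=estimates,
        standard_errors=ses,
        crit_ratios=crs,
        p_values=ps,
        f_min=float(f_min),
        chi_square=float(scale * max(f_min, 0.0)),
        df=spec.df,
        converged=converged,
        n_used=summary.n,
        chisq_scale=chisq_scale,
        convention=summary.convention,
    )
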