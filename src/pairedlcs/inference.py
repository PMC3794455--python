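"""Significance machinery: reference distributions and the nested chi-square test.

The classical paired *t*-test refers ``d / SE`` to a Student *t* with
``n - 1`` degrees of freedom; structural-model output refers the same
critical ratio (CR) to the standard normal.  The normal has lighter tails,
so the SEM p-value is always the smaller of the two at the same nonzero
CR — that difference, not the point estimate, is what separates the two
framings of the test.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .exceptions import ConfigError, NestingError


def p_normal_two_sided(cr: float) -> float:
    """Two-sided p-value of a critical ratio under the standard normal."""
    if not np.isfinite(cr):
        raise ConfigError(f"critical ratio must be finite, got {cr}")
    return float(2.0 * stats.norm.sf(abs(cr)))


def p_t_two_sided(t: float, df: float) -> float:
    """Two-sided p-value of a *t* statistic with ``df`` degrees of freedom."""
    if df < 1:
        raise ConfigError(f"t reference needs df >= 1, got {df}")
    return float(2.0 * stats.t.sf(abs(t), df))


def p_chi_square_upper(x: float, df: int) -> float:
    """Upper-tail chi-square probability."""
    if df < 1:
        raise ConfigError(f"chi-square reference needs df >= 1, got {df}")
    return float(stats.chi2.sf(max(x, 0.0), df))


@dataclass(frozen=True)
class ChiSqDiffTest:
    """Likelihood-ratio comparison of a constrained model against the model
    that nests it (here: the self-feedback path fixed to zero vs. free)."""

    delta_chi_square: float
    delta_df: int
    p_value: float
    alpha: float
    constraint_tenable: bool


def chisq_diff_test(constrained, free, alpha: float = 0.05) -> ChiSqDiffTest:
    """Nested chi-square difference test.

    Parameters
    ----------
    constrained, free
        :class:`~pairedlcs.sem_engine.FitResult` objects for the constrained
        model and the nesting (more general) model, fitted to the same data.
    alpha
        Level for the advisory ``constraint_tenable`` verdict; never gates
        any computation.

    Raises
    ------
    NestingError
        If ``constrained.df <= free.df`` (not a genuine constraint test).
    """
    if constrained.df <= free.df:
        raise NestingError(
            f"constrained model must have more df than the free model "
            f"(got {constrained.df} vs {free.df})"
        )
    if constrained.n_used != free.n_used:
        raise NestingError("both fits must use the same data (n differs)")
    delta_df = int(constrained.df - free.df)
    delta = constrained.chi_square - free.chi_square
    if delta < -1e-8:
        raise NestingError(
            f"constrained chi-square {constrained.chi_square} below the free "
            f"model's {free.chi_square}; models are not nested on these data"
        )
    delta = max(delta, 0.0)
    p = p_chi_square_upper(delta, delta_df)
    return ChiSqDiffTest(
        delta_chi_square=float(delta),
        delta_df=delta_df,
        p_value=p,
        alpha=alpha,
        constraint_tenable=bool(p >= alpha),
    )
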