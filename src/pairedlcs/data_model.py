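"""Core data containers and exact sample-moment computation.

Everything downstream — the classical paired *t*-test, the latent change
score (LCS) model fits, and the summary-statistics sensitivity sweep —
consumes a :class:`MomentSummary` (sample size, mean vector, covariance
matrix of the two waves).  This module computes those moments from raw
paired data, re-centers data on the baseline mean, and reconstructs
moments from published summary statistics so that summary-only input is
indistinguishable to the fitting code from raw data with the same moments.

Denominator convention
----------------------
Variances and covariances default to the unbiased ``n-1`` denominator.
Under that convention the saturated LCS mean-change standard error equals
the classical paired-test standard error ``s_D / sqrt(n)``.  The biased
``n`` denominator is available for pure-ML comparisons.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .exceptions import ConfigError, DataSizeError, DegenerateDataError

logger = logging.getLogger(__name__)

#: Supported variance/covariance denominator conventions.
CONVENTIONS = ("n-1", "n")

_MIN_N = 3  # smallest n leaving a nonzero-df residual in the change regression


def _check_convention(convention: str) -> int:
    if convention not in CONVENTIONS:
        raise ConfigError(
            f"unknown denominator convention {convention!r}; expected one of {CONVENTIONS}"
        )
    return 1 if convention == "n-1" else 0


@dataclass(frozen=True)
class PairedSample:
    """Raw two-wave paired measurements, one row per subject.

    Parameters
    ----------
    y1, y2
        Baseline and follow-up values, same units, identical length ``n >= 3``.
    ids
        Optional subject labels (same length).
    """

    y1: np.ndarray
    y2: np.ndarray
    ids: np.ndarray | None = None

    def __post_init__(self):
        y1 = np.asarray(self.y1, dtype=float).ravel()
        y2 = np.asarray(self.y2, dtype=float).ravel()
        if y1.shape != y2.shape:
            raise DataSizeError(
                f"y1 and y2 must have identical length, got {y1.size} and {y2.size}"
            )
        if y1.size < _MIN_N:
            raise DataSizeError(
                f"need at least {_MIN_N} complete pairs, got {y1.size}"
            )
        if not (np.all(np.isfinite(y1)) and np.all(np.isfinite(y2))):
            raise DegenerateDataError(
                "missing or non-finite values present; drop incomplete pairs first"
            )
        object.__setattr__(self, "y1", y1)
        object.__setattr__(self, "y2", y2)
        if self.ids is not None:
            ids = np.asarray(self.ids).ravel()
            if ids.size != y1.size:
                raise DataSizeError("ids must match the number of pairs")
            object.__setattr__(self, "ids", ids)

    @property
    def n(self) -> int:
        return self.y1.size

    @property
    def diffs(self) -> np.ndarray:
        """Element-wise change scores ``y2 - y1``."""
        return self.y2 - self.y1


@dataclass(frozen=True)
class CenteringRecord:
    """Record of the common offset subtracted from both waves."""

    offset: float
    applied: bool


@dataclass(frozen=True)
class MomentSummary:
    """Sample size, wave means and the 2x2 wave covariance matrix.

    The sufficient statistics for every model in this package.  Derived
    quantities — the mean change ``d``, the change-score variance
    ``var_d``, and the paired correlation ``rho`` — are pure functions of
    these fields.
    """

    n: int
    mean1: float
    mean2: float
    var1: float
    var2: float
    cov12: float
    convention: str = "n-1"

    def __post_init__(self):
        _check_convention(self.convention)
        if self.n < _MIN_N:
            raise DataSizeError(f"need n >= {_MIN_N}, got {self.n}")
        if not (self.var1 > 0.0 and self.var2 > 0.0):
            raise DegenerateDataError(
                f"wave variances must be positive, got var1={self.var1}, var2={self.var2}"
            )
        bound = np.sqrt(self.var1 * self.var2)
        if abs(self.cov12) > bound * (1.0 + 1e-12):
            raise DegenerateDataError(
                f"covariance {self.cov12} violates the Cauchy-Schwarz bound {bound}"
            )

    # -- derived quantities -------------------------------------------------
    @property
    def d(self) -> float:
        """Mean paired difference (follow-up minus baseline)."""
        return self.mean2 - self.mean1

    @property
    def var_d(self) -> float:
        """Variance of the change score ``Y2 - Y1``."""
        return self.var1 + self.var2 - 2.0 * self.cov12

    @property
    def sd_d(self) -> float:
        return float(np.sqrt(self.var_d))

    @property
    def sd1(self) -> float:
        return float(np.sqrt(self.var1))

    @property
    def sd2(self) -> float:
        return float(np.sqrt(self.var2))

    @property
    def rho(self) -> float:
        """Paired (test-retest) correlation between the two waves."""
        r = self.cov12 / np.sqrt(self.var1 * self.var2)
        return float(np.clip(r, -1.0, 1.0))

    @property
    def mean_vector(self) -> np.ndarray:
        return np.array([self.mean1, self.mean2])

    @property
    def cov_matrix(self) -> np.ndarray:
        return np.array([[self.var1, self.cov12], [self.cov12, self.var2]])


def compute_moments(sample: PairedSample, convention: str = "n-1") -> MomentSummary:
    """Exact sample moments of a paired sample under the requested denominator.

    Raises
    ------
    DegenerateDataError
        If either wave has zero variance.
    """
    ddof = _check_convention(convention)
    n = sample.n
    mean1 = float(np.mean(sample.y1))
    mean2 = float(np.mean(sample.y2))
    cov = np.cov(sample.y1, sample.y2, ddof=ddof)
    summary = MomentSummary(
        n=n,
        mean1=mean1,
        mean2=mean2,
        var1=float(cov[0, 0]),
        var2=float(cov[1, 1]),
        cov12=float(cov[0, 1]),
        convention=convention,
    )
    return summary


def center_on_wave1(sample: PairedSample) -> tuple[PairedSample, CenteringRecord]:
    """Shift both waves by the baseline mean.

    Centering on the wave-1 mean leaves all change scores, variances and
    covariances untouched; after centering the follow-up mean equals the
    mean paired difference, which makes the self-feedback model's
    intercept directly interpretable as the mean change at the average
    baseline.
    """
    offset = float(np.mean(sample.y1))
    centered = PairedSample(sample.y1 - offset, sample.y2 - offset, sample.ids)
    return centered, CenteringRecord(offset=offset, applied=True)


def moments_from_summary(
    n: int,
    mean1: float,
    sd1: float,
    mean2: float,
    sd2: float,
    rho: float,
    convention: str = "n-1",
) -> MomentSummary:
    """Build a :class:`MomentSummary` from published summary statistics.

    ``cov12 = rho * sd1 * sd2``; the result is indistinguishable to all
    downstream fits from moments computed from raw data with the same
    means, SDs and paired correlation.

    Raises
    ------
    DegenerateDataError
        If ``|rho| >= 1`` or either SD is non-positive.
    """
    if not (-1.0 < rho < 1.0):
        raise DegenerateDataError(f"rho must lie strictly in (-1, 1), got {rho}")
    if not (sd1 > 0.0 and sd2 > 0.0):
        raise DegenerateDataError(f"SDs must be positive, got sd1={sd1}, sd2={sd2}")
    return MomentSummary(
        n=int(n),
        mean1=float(mean1),
        mean2=float(mean2),
        var1=float(sd1) ** 2,
        var2=float(sd2) ** 2,
        cov12=float(rho) * float(sd1) * float(sd2),
        convention=convention,
    )


def read_paired_csv(
    path: str | Path,
    y1_col: str = "y1",
    y2_col: str = "y2",
    id_col: str | None = None,
) -> tuple[PairedSample, int]:
    """Read a two-column paired-data CSV (header required, UTF-8).

    Rows with any missing value in the two wave columns are dropped
    (listwise deletion) and the dropped count is logged at warning level
    and returned alongside the sample.
    """
    frame = pd.read_csv(path, encoding="utf-8")
    for col in (y1_col, y2_col):
        if col not in frame.columns:
            raise ConfigError(
                f"column {col!r} not found in {path}; available: {list(frame.columns)}"
            )
    complete = frame[[y1_col, y2_col]].notna().all(axis=1)
    n_dropped = int((~complete).sum())
    if n_dropped:
        logger.warning("dropped %d incomplete pair(s) from %s", n_dropped, path)
    kept = frame.loc[complete]
    ids = kept[id_col].to_numpy() if id_col is not None and id_col in kept else None
    sample = PairedSample(
        kept[y1_col].to_numpy(dtype=float), kept[y2_col].to_numpy(dtype=float), ids
    )
    return sample, n_dropped


_SUMMARY_KEYS = ("n", "mean1", "sd1", "mean2", "sd2")


def load_summary_config(path: str | Path) -> dict:
    """Load a YAML/JSON summary-statistics config.

    Required keys: ``n, mean1, sd1, mean2, sd2``; plus either ``rho``
    (scalar) or ``rho_grid`` (mapping with ``min, max, step``).
    """
    text = Path(path).read_text(encoding="utf-8")
    try:
        cfg = yaml.safe_load(text)
    except yaml.YAMLError as exc:  # pragma: no cover - malformed input path
        raise ConfigError(f"could not parse {path}: {exc}") from exc
    if not isinstance(cfg, dict):
        raise ConfigError(f"summary config {path} must be a mapping")
    missing = [k for k in _SUMMARY_KEYS if k not in cfg]
    if missing:
        raise ConfigError(f"summary config missing keys: {missing}")
    if "rho" not in cfg and "rho_grid" not in cfg:
        raise ConfigError("summary config needs either 'rho' or 'rho_grid'")
    if "rho_grid" in cfg:
        grid = cfg["rho_grid"]
        if not isinstance(grid, dict) or not {"min", "max", "step"} <= set(grid):
            raise ConfigError("'rho_grid' must be a mapping with min, max, step")
    return cfg


def dump_json(obj, path: str | Path) -> None:
    """Deterministic JSON writer used by reports and study outputs."""
    Path(path).write_text(
        json.dumps(obj, sort_keys=True, indent=2) + "\n", encoding="utf-8"
    )
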