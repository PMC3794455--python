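import numpy as np
import pytest

from pairedlcs import PairedSample, center_on_wave1, compute_moments


@pytest.fixture
def toy_sample():
    """Four-subject toy with hand-computable moments:
    means (2.5, 4.5), var1 = 5/3, var2 = 13/3, cov = 8/3,
    d = 2, var_D = 2/3, r(Y1, D)^2 = 0.9."""
    return PairedSample(np.array([1.0, 2.0, 3.0, 4.0]), np.array([2.0, 4.0, 5.0, 7.0]))


@pytest.fixture
def toy_summary(toy_sample):
    return compute_moments(toy_sample)


@pytest.fixture
def toy_summary_centered(toy_sample):
    centered, _ = center_on_wave1(toy_sample)
    return compute_moments(centered)


def random_paired_summary(rng, n=None, rho=None):
    """One random bivariate-normal sample's moments, for property suites."""
    n = int(rng.integers(5, 501)) if n is None else n
    rho = float(rng.uniform(-0.9, 0.9)) if rho is None else rho
    s1, s2 = rng.uniform(0.5, 2.0, size=2)
    cov = np.array([[s1**2, rho * s1 * s2], [rho * s1 * s2, s2**2]])
    y = rng.multivariate_normal([rng.normal(0, 1), rng.normal(0, 1)], cov, size=n)
    return compute_moments(PairedSample(y[:, 0], y[:, 1]))
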