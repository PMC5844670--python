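import numpy as np
import pytest
from hypothesis import HealthCheck, settings
from scipy.stats import t as student_t

from cmrct import DesignParams, PoolSpec, SimConfig

settings.register_profile(
    "ci", derandomize=True, max_examples=50,
    suppress_health_check=[HealthCheck.too_slow])
settings.load_profile("ci")


@pytest.fixture
def default_params() -> DesignParams:
    return DesignParams()


@pytest.fixture
def motivating_pool() -> PoolSpec:
    return PoolSpec(cohort_size=4377, eligible_count=1306)


@pytest.fixture
def small_sim() -> SimConfig:
    """A shrunken scenario for fast unit-level Monte-Carlo checks."""
    return SimConfig(cohort_size=800, eligibility_rate=0.5, n_offered=150,
                     replicates=200, seed=11)


def mc_power_oracle(d: float, n1: int, n2: int, a: float = 0.25,
                    rho: float = 0.5, alpha: float = 0.05,
                    R: int = 20_000, seed: int = 12345) -> float:
    """Independent Monte-Carlo oracle for two-arm ANCOVA rejection rates.

    Simulates the generating model directly (fixed analysis arm sizes
    n_i*(1-a), baseline-adjusted least squares, two-sided t test) without
    touching the package's power formula, vectorized across replicates.
    """
    m1, m2 = int(round(n1 * (1 - a))), int(round(n2 * (1 - a)))
    rng = np.random.default_rng(seed)
    s = np.sqrt(1 - rho ** 2)
    y0t = rng.standard_normal((R, m1))
    y0c = rng.standard_normal((R, m2))
    y1t = rho * y0t + s * rng.standard_normal((R, m1)) + d
    y1c = rho * y0c + s * rng.standard_normal((R, m2))
    x = np.concatenate([y0t, y0c], axis=1)
    y = np.concatenate([y1t, y1c], axis=1)
    g = np.concatenate([np.ones(m1), np.zeros(m2)])
    n = m1 + m2
    xc = x - x.mean(1, keepdims=True)
    gc = g - g.mean()
    sxx = (xc * xc).sum(1)
    sxg = (xc * gc).sum(1)
    sgg = float(gc @ gc)
    sxy = (xc * y).sum(1)
    sgy = (y * gc).sum(1)
    det = sxx * sgg - sxg ** 2
    bg = (sxx * sgy - sxg * sxy) / det
    bx = (sgg * sxy - sxg * sgy) / det
    resid = y - y.mean(1, keepdims=True) - bx[:, None] * xc - bg[:, None] * gc
    s2 = (resid ** 2).sum(1) / (n - 3)
    se = np.sqrt(s2 * sxx / det)
    crit = student_t.ppf(1 - alpha / 2, n - 3)
    return float((np.abs(bg / se) > crit).mean())
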