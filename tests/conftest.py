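"""Shared fixtures: synthetic curves and the (expensive) Monte Carlo run."""

import numpy as np
import pandas as pd
import pytest

import renalpk as rk


@pytest.fixture(scope="session")
def blood_aif() -> rk.Curve:
    """Default synthetic whole-blood AIF on the 100-frame / 3 s grid."""
    return rk.make_aif()


@pytest.fixture(scope="session")
def plasma_aif(blood_aif) -> rk.Curve:
    return rk.to_plasma(blood_aif)


@pytest.fixture(scope="session")
def preset_2cirf() -> rk.TwoCIRFParams:
    return rk.DEFAULT_2CIRF_TRUTH


@pytest.fixture(scope="session")
def tissue_2cirf(plasma_aif, preset_2cirf) -> rk.Curve:
    return rk.predict_cortex(preset_2cirf, plasma_aif)


@pytest.fixture(scope="session")
def monte_carlo_tables(plasma_aif) -> pd.DataFrame:
    """One shared Monte Carlo run: 2C-IRF at 500 trials per noise level for
    the reliability bounds, the four comparators at 300 trials for the
    ranking comparison.  Session-scoped because it dominates suite runtime.
    """
    reliability = rk.run_monte_carlo(
        ["2cirf"], plasma_aif, rk.NoiseSpec(seed=1), n_trials=500
    )
    ranking = rk.run_monte_carlo(
        ["pr", "2c", "2cd", "sp"], plasma_aif, rk.NoiseSpec(seed=1), n_trials=300
    )
    return pd.concat([reliability, ranking], ignore_index=True)


def convolve_oracle(f: np.ndarray, g: np.ndarray, dt: float) -> np.ndarray:
    """Brute-force double-loop trapezoid convolution, the independent oracle
    for the vectorised engine."""
    n = len(f)
    out = np.zeros(n)
    for k in range(n):
        acc = 0.0
        for j in range(k + 1):
            w = 1.0
            if j == 0:
                w -= 0.5
            if j == k:
                w -= 0.5  # k == 0: zero-length integration interval
            acc += w * f[j] * g[k - j]
        out[k] = dt * acc
    return out
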