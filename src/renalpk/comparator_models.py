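"""Comparator renal pharmacokinetic models: PR, 2C, 2CD and SP.

Four published cortical/whole-kidney models are provided as forward
predictors sharing the ``Curve`` interface, for head-to-head Monte Carlo
comparison with the 2C-IRF model:

* PR  — Patlak-Rutland: vascular term plus irreversible uptake integral,
        neglecting tubular outflow.
* 2C  — two-compartment filtration model with first-order tubular outflow
        ``k_out``.
* 2CD — the same with the arterial input first dispersed by a normalised
        single-exponential vascular kernel of time constant ``d``.
* SP  — separable plasma/tubule cascade: an exponential plasma compartment
        (volume fraction V_p, transit time T_p) feeding a tubular compartment
        of transit time T_t; equivalent to 2CD under T_t = 1/k_out,
        V_p = f_a, T_p = d.

Flow parameters are given in ml/min and converted internally to a per-second
scale against a nominal unit ROI volume, matching the 2C-IRF convention.
Rate/time presets (k_out, d, T_t, T_p) are interpreted on the second scale of
the sampling grid.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.integrate import cumulative_trapezoid

from .kinetics_core import SECONDS_PER_MINUTE, Curve, causal_convolve

#: preset of the external three-compartment model, recorded for documentation
#: only; its functional form is not implemented here.
THREE_COMPARTMENT_PRESETS = {
    "gfr": 3.0, "rpf": 3.0, "f_p": 0.18, "w_a_c": 0.2, "w_a_m": 0.08, "w_p": 0.18,
}


@dataclass(frozen=True)
class PatlakParams:
    """Patlak-Rutland parameters: gfr (ml/min) and vascular scale v_a."""

    gfr: float
    v_a: float

    def __post_init__(self) -> None:
        if self.gfr < 0 or self.v_a < 0:
            raise ValueError("gfr and v_a must be >= 0")


@dataclass(frozen=True)
class TwoCParams:
    """Two-compartment filtration model parameters.

    gfr   : ml/min.
    k_out : tubular outflow rate (1/s).
    f_a   : vascular fraction (dimensionless).
    d     : dispersion time constant (s); ignored by the undispersed 2C
            variant, required by 2CD.
    """

    gfr: float
    k_out: float
    f_a: float
    d: float | None = None

    def __post_init__(self) -> None:
        if self.gfr < 0 or self.k_out < 0 or self.f_a < 0:
            raise ValueError("gfr, k_out and f_a must be >= 0")
        if self.d is not None and self.d < 0:
            raise ValueError("dispersion constant d must be >= 0")


@dataclass(frozen=True)
class SeparableParams:
    """Separable plasma/tubule cascade parameters.

    gfr : ml/min; t_t : tubular transit time (s); v_p : plasma volume
    fraction; t_p : plasma transit time (s).
    """

    gfr: float
    t_t: float
    v_p: float
    t_p: float

    def __post_init__(self) -> None:
        if self.gfr < 0:
            raise ValueError("gfr must be >= 0")
        if self.t_t <= 0 or self.v_p <= 0 or self.t_p <= 0:
            raise ValueError("t_t, v_p and t_p must be > 0")


def exp_dispersion_kernel(dt: float, n: int, tau_c: float) -> np.ndarray:
    """Discretised normalised exponential kernel (1/tau_c) exp(-t/tau_c).

    The kernel is integrated analytically over each sample cell
    [t_k - dt/2, t_k + dt/2] (first cell [0, dt/2]) and then rescaled so its
    trapezoid mass on the grid is exactly 1.  Cell averaging keeps narrow
    kernels (tau_c << dt, e.g. d = 0.42 s on 3 s frames) mass-preserving, and
    the renormalisation makes the tau_c -> 0 limit reproduce the identity
    under the trapezoid convolution engine.
    """
    if tau_c <= 0:
        raise ValueError("kernel time constant must be > 0")
    edges = (np.arange(n + 1) - 0.5) * dt
    edges[0] = 0.0
    mass = np.exp(-edges[:-1] / tau_c) - np.exp(-edges[1:] / tau_c)
    g = mass / dt
    # first cell spans [0, dt/2] but carries trapezoid weight dt/2
    g[0] = mass[0] / (0.5 * dt)
    trap = dt * (np.sum(g) - 0.5 * g[0] - 0.5 * g[-1])
    if trap <= 0:
        raise ValueError("degenerate dispersion kernel")
    return g / trap


def predict_patlak(p: PatlakParams, aif_plasma: Curve) -> Curve:
    """Patlak-Rutland prediction C = v_a*A_p + GFR' * cumulative integral."""
    gfr_s = p.gfr / SECONDS_PER_MINUTE
    integral = cumulative_trapezoid(aif_plasma.v, dx=aif_plasma.dt, initial=0.0)
    return aif_plasma.with_values(p.v_a * aif_plasma.v + gfr_s * integral)


def predict_2c(p: TwoCParams, aif_plasma: Curve, dispersed: bool = False) -> Curve:
    """Two-compartment prediction, optionally with vascular dispersion (2CD).

    With A* the (possibly dispersed) plasma input:
        C(t) = f_a * A*(t) + GFR' * int_0^t A*(u) exp(-k_out (t-u)) du.
    """
    gfr_s = p.gfr / SECONDS_PER_MINUTE
    dt = aif_plasma.dt
    a = aif_plasma.v
    if dispersed:
        if p.d is None or p.d <= 0:
            raise ValueError("2CD requires a positive dispersion constant d")
        kernel = exp_dispersion_kernel(dt, len(a), p.d)
        a = causal_convolve(a, kernel, dt)
    decay = np.exp(-p.k_out * (aif_plasma.t - aif_plasma.t[0]))
    tubular = causal_convolve(a, decay, dt)
    return aif_plasma.with_values(p.f_a * a + gfr_s * tubular)


def predict_sp(p: SeparableParams, aif_plasma: Curve) -> Curve:
    """Separable-model prediction: plasma compartment feeding a tubule.

    The plasma compartment has impulse response (1/T_p) exp(-t/T_p); its
    output drives the tubule, whose residue function is exp(-t/T_t):
        C(t) = V_p * (A_p (*) g_p)(t) + GFR' * (A_p (*) g_p (*) exp(-t/T_t))(t).
    """
    gfr_s = p.gfr / SECONDS_PER_MINUTE
    dt = aif_plasma.dt
    g_p = exp_dispersion_kernel(dt, len(aif_plasma), p.t_p)
    plasma = causal_convolve(aif_plasma.v, g_p, dt)
    decay = np.exp(-(aif_plasma.t - aif_plasma.t[0]) / p.t_t)
    tubular = causal_convolve(plasma, decay, dt)
    return aif_plasma.with_values(p.v_p * plasma + gfr_s * tubular)
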