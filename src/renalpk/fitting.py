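"""Nonlinear least-squares estimation of renal model parameters.

All five implemented models (2C-IRF, PR, 2C, 2CD, SP) minimise the
unweighted sum of squared residuals between predicted and observed cortical
concentration curves.  Each model is *separable*: for fixed shape
parameters (washout rates, transit times, delays) the prediction is linear
in two amplitude parameters (GFR and a vascular scale), so the fit uses
variable projection -- the amplitudes are solved exactly by non-negative
linear least squares at every step, and only the low-dimensional shape
subproblem is searched nonlinearly.  A deterministic coarse grid over the
shape parameters seeds several damped least-squares refinements
(Levenberg-Marquardt family, bound-constrained), and the lowest-cost
solution is polished over the full parameter vector.  This sidesteps the
local minima that plague convolved-exponential objectives started from a
single generic point.

Goodness of fit is reported as the coefficient of determination
R^2 = 1 - SS_res/SS_tot.
"""

from __future__ import annotations

import itertools
import json
import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Callable

import numpy as np
from scipy.integrate import cumulative_trapezoid
from scipy.optimize import least_squares, nnls

from . import comparator_models as cm
from .kinetics_core import (
    SECONDS_PER_MINUTE,
    Curve,
    IRFParams,
    TwoCIRFParams,
    causal_convolve,
    mtt_summary,
    predict_cortex,
    retention_curves,
)

logger = logging.getLogger("renalpk")

MODEL_NAMES = ("2cirf", "pr", "2c", "2cd", "sp")

#: solver tolerances (step, cost and gradient) and the per-start iteration cap
_TOL = 1e-10
DEFAULT_MAX_ITER = 500


# ---------------------------------------------------------------------------
# Model registry
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ModelSpec:
    """A fittable separable model.

    ``param_names`` orders the full parameter vector; ``linear_idx`` marks
    the two amplitude parameters (GFR first), ``nonlinear_idx`` the shape
    parameters.  ``basis(theta, aif)`` returns the (n, 2) design matrix of
    the amplitudes for shape vector ``theta``; ``predictor(x, aif)`` the
    full forward prediction.  ``shape_grid`` yields the deterministic
    coarse-search nodes over the shape parameters.
    """

    name: str
    param_names: tuple[str, ...]
    default_bounds: tuple[tuple[float, float], ...]
    predictor: Callable[[np.ndarray, Curve], Curve]
    linear_idx: tuple[int, int]
    nonlinear_idx: tuple[int, ...]
    basis: Callable[[np.ndarray, Curve], np.ndarray]
    shape_grid: Callable[[], list[np.ndarray]]

    @property
    def n_params(self) -> int:
        return len(self.param_names)

    def assemble(self, theta: np.ndarray, coefs: np.ndarray) -> np.ndarray:
        """Merge shape vector and (gfr, vascular) amplitudes into a full
        parameter vector."""
        x = np.empty(self.n_params)
        for j, idx in enumerate(self.nonlinear_idx):
            x[idx] = theta[j]
        x[self.linear_idx[0]] = coefs[0]
        x[self.linear_idx[1]] = coefs[1]
        return x


def _grid(*axes: np.ndarray) -> list[np.ndarray]:
    return [np.array(node) for node in itertools.product(*axes)]


# -- 2C-IRF -----------------------------------------------------------------

def _make_2cirf_predictor(fit_tau_t: bool) -> Callable[[np.ndarray, Curve], Curve]:
    def predict(x: np.ndarray, aif: Curve) -> Curve:
        p = TwoCIRFParams(
            gfr=x[0], rpf=x[1],
            irf_a=IRFParams(tau=x[3], m=x[2]),
            irf_t=IRFParams(tau=x[5] if fit_tau_t else 0.0, m=x[4]),
        )
        return predict_cortex(p, aif)
    return predict


def _make_2cirf_basis(fit_tau_t: bool) -> Callable[[np.ndarray, Curve], np.ndarray]:
    def basis(theta: np.ndarray, aif: Curve) -> np.ndarray:
        # theta = (m_a, tau_a, m_t[, tau_t]); unit-flow retention curves
        p = TwoCIRFParams(
            gfr=SECONDS_PER_MINUTE, rpf=SECONDS_PER_MINUTE,
            irf_a=IRFParams(tau=theta[1], m=theta[0]),
            irf_t=IRFParams(tau=theta[3] if fit_tau_t else 0.0, m=theta[2]),
        )
        ret = retention_curves(p, aif.t, upsample=1)
        b_gfr = causal_convolve(aif.v, ret.r_t, aif.dt) / SECONDS_PER_MINUTE
        b_rpf = causal_convolve(aif.v, ret.r_a, aif.dt) / SECONDS_PER_MINUTE
        return np.column_stack([b_gfr, b_rpf])
    return basis


def _2cirf_grid(fit_tau_t: bool) -> Callable[[], list[np.ndarray]]:
    def grid() -> list[np.ndarray]:
        m_a = np.geomspace(0.02, 1.5, 8)
        tau_a = np.array([0.0, 1.5, 3.0, 4.5, 6.0, 9.0, 12.0])
        m_t = np.geomspace(0.005, 0.8, 8)
        if fit_tau_t:
            return _grid(m_a, tau_a, m_t, np.array([0.0, 5.0, 10.0]))
        return _grid(m_a, tau_a, m_t)
    return grid


# -- Patlak-Rutland ---------------------------------------------------------

def _predict_pr(x: np.ndarray, aif: Curve) -> Curve:
    return cm.predict_patlak(cm.PatlakParams(gfr=x[0], v_a=x[1]), aif)


def _basis_pr(theta: np.ndarray, aif: Curve) -> np.ndarray:
    b_gfr = cumulative_trapezoid(aif.v, dx=aif.dt, initial=0.0) / SECONDS_PER_MINUTE
    return np.column_stack([b_gfr, aif.v])


# -- 2C / 2CD ---------------------------------------------------------------

def _predict_2c(x: np.ndarray, aif: Curve) -> Curve:
    return cm.predict_2c(cm.TwoCParams(gfr=x[0], k_out=x[1], f_a=x[2]), aif)


def _basis_2c(theta: np.ndarray, aif: Curve) -> np.ndarray:
    decay = np.exp(-theta[0] * (aif.t - aif.t[0]))
    b_gfr = causal_convolve(aif.v, decay, aif.dt) / SECONDS_PER_MINUTE
    return np.column_stack([b_gfr, aif.v])


def _predict_2cd(x: np.ndarray, aif: Curve) -> Curve:
    p = cm.TwoCParams(gfr=x[0], k_out=x[1], f_a=x[2], d=x[3])
    return cm.predict_2c(p, aif, dispersed=True)


def _basis_2cd(theta: np.ndarray, aif: Curve) -> np.ndarray:
    kernel = cm.exp_dispersion_kernel(aif.dt, len(aif), theta[1])
    a_star = causal_convolve(aif.v, kernel, aif.dt)
    decay = np.exp(-theta[0] * (aif.t - aif.t[0]))
    b_gfr = causal_convolve(a_star, decay, aif.dt) / SECONDS_PER_MINUTE
    return np.column_stack([b_gfr, a_star])


# -- SP ---------------------------------------------------------------------

def _predict_sp(x: np.ndarray, aif: Curve) -> Curve:
    p = cm.SeparableParams(gfr=x[0], t_t=x[1], v_p=x[2], t_p=x[3])
    return cm.predict_sp(p, aif)


def _basis_sp(theta: np.ndarray, aif: Curve) -> np.ndarray:
    g_p = cm.exp_dispersion_kernel(aif.dt, len(aif), theta[1])
    plasma = causal_convolve(aif.v, g_p, aif.dt)
    decay = np.exp(-(aif.t - aif.t[0]) / theta[0])
    b_gfr = causal_convolve(plasma, decay, aif.dt) / SECONDS_PER_MINUTE
    return np.column_stack([b_gfr, plasma])


def model_spec(name: str, fit_tau_t: bool = False) -> ModelSpec:
    """Look up a model by its name token: 2cirf | pr | 2c | 2cd | sp."""
    name = name.lower()
    if name == "2cirf":
        names = ("gfr", "rpf", "m_a", "tau_a", "m_t")
        bounds = ((0.0, 20.0), (0.0, 20.0), (1e-4, 2.0), (0.0, 30.0), (1e-4, 2.0))
        nl = (2, 3, 4)
        if fit_tau_t:
            names += ("tau_t",)
            bounds += ((0.0, 30.0),)
            nl = (2, 3, 4, 5)
        return ModelSpec(
            name, names, bounds, _make_2cirf_predictor(fit_tau_t),
            linear_idx=(0, 1), nonlinear_idx=nl,
            basis=_make_2cirf_basis(fit_tau_t), shape_grid=_2cirf_grid(fit_tau_t),
        )
    if name == "pr":
        return ModelSpec(
            "pr", ("gfr", "v_a"), ((0.0, 20.0), (0.0, 10.0)), _predict_pr,
            linear_idx=(0, 1), nonlinear_idx=(),
            basis=_basis_pr, shape_grid=lambda: [np.empty(0)],
        )
    if name == "2c":
        return ModelSpec(
            "2c", ("gfr", "k_out", "f_a"),
            ((0.0, 20.0), (1e-4, 2.0), (0.0, 5.0)), _predict_2c,
            linear_idx=(0, 2), nonlinear_idx=(1,),
            basis=_basis_2c,
            shape_grid=lambda: _grid(np.geomspace(1e-3, 1.5, 20)),
        )
    if name == "2cd":
        return ModelSpec(
            "2cd", ("gfr", "k_out", "f_a", "d"),
            ((0.0, 20.0), (1e-4, 2.0), (0.0, 5.0), (1e-3, 30.0)), _predict_2cd,
            linear_idx=(0, 2), nonlinear_idx=(1, 3),
            basis=_basis_2cd,
            shape_grid=lambda: _grid(
                np.geomspace(1e-3, 1.5, 12), np.geomspace(0.05, 15.0, 8)
            ),
        )
    if name == "sp":
        return ModelSpec(
            "sp", ("gfr", "t_t", "v_p", "t_p"),
            ((0.0, 20.0), (0.1, 500.0), (1e-3, 5.0), (1e-3, 30.0)), _predict_sp,
            linear_idx=(0, 2), nonlinear_idx=(1, 3),
            basis=_basis_sp,
            shape_grid=lambda: _grid(
                np.geomspace(0.8, 300.0, 12), np.geomspace(0.05, 15.0, 8)
            ),
        )
    raise ValueError(f"unknown model {name!r}; expected one of {MODEL_NAMES}")


# ---------------------------------------------------------------------------
# Configuration and result types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class FitConfig:
    """Configuration of a nonlinear fit.

    model      : model name token.
    init       : optional full starting parameter vector.  When given, the
                 fit polishes from it (plus jittered restarts) and skips the
                 variable-projection grid search.
    bounds     : optional per-parameter [lo, hi] overriding the defaults.
    max_iter   : iteration cap per solver run.
    multistart : number of refinement starts (grid-selected nodes, or
                 jittered copies of ``init``).
    seed       : RNG seed for restart jitter; fits are deterministic given
                 (data, config, seed).
    fit_tau_t  : release the tubular delay tau_T (2C-IRF only); fixed at 0
                 by default.
    """

    model: str = "2cirf"
    init: tuple[float, ...] | None = None
    bounds: tuple[tuple[float, float], ...] | None = None
    max_iter: int = DEFAULT_MAX_ITER
    multistart: int = 5
    seed: int = 0
    fit_tau_t: bool = False

    def __post_init__(self) -> None:
        if self.max_iter < 1:
            raise ValueError("max_iter must be >= 1")
        if self.multistart < 1:
            raise ValueError("multistart must be >= 1")

    def resolved(self) -> tuple[ModelSpec, np.ndarray, np.ndarray]:
        spec = model_spec(self.model, self.fit_tau_t)
        bounds = np.asarray(
            self.bounds if self.bounds is not None else spec.default_bounds, float
        )
        if bounds.shape != (spec.n_params, 2):
            raise ValueError(f"bounds must be {spec.n_params} [lo, hi] pairs")
        lo, hi = bounds[:, 0], bounds[:, 1]
        if self.init is not None:
            init = np.asarray(self.init, float)
            if init.shape != (spec.n_params,):
                raise ValueError(f"init must have {spec.n_params} entries")
            if np.any(init < lo) or np.any(init > hi):
                raise ValueError("init must lie within bounds")
        return spec, lo, hi


@dataclass(frozen=True)
class FitResult:
    """Outcome of a model fit.

    params holds the estimates in acquisition units (gfr ml/min, rpf
    ml/g/min, rates 1/s, delays/transit times s); mtts is (MTT_A, MTT_T,
    MTT_K) in seconds for the 2C-IRF model and None otherwise.
    """

    model: str
    params: dict[str, float]
    r2: float
    residual_norm: float
    converged: bool
    n_starts: int
    n_converged: int
    mtts: tuple[float, float, float] | None = None
    message: str = ""

    def to_json(self, path: str | Path) -> None:
        payload = {
            "model": self.model,
            "params": self.params,
            "units": {k: _UNITS_BY_NAME[k] for k in self.params},
            "r2": self.r2,
            "residual_norm": self.residual_norm,
            "converged": self.converged,
            "n_starts": self.n_starts,
            "n_converged": self.n_converged,
            "mtts_s": self.mtts,
            "message": self.message,
        }
        Path(path).write_text(json.dumps(payload, indent=2))


_UNITS_BY_NAME = {
    "gfr": "ml/min", "rpf": "ml/g/min", "m_a": "1/s", "tau_a": "s",
    "m_t": "1/s", "tau_t": "s", "v_a": "dimensionless", "k_out": "1/s",
    "f_a": "dimensionless", "d": "s", "t_t": "s", "v_p": "dimensionless",
    "t_p": "s",
}


def r_squared(obs: np.ndarray, pred: np.ndarray) -> float:
    """Coefficient of determination 1 - SS_res/SS_tot.

    Undefined (NaN, with a warning) when the observations are constant.
    """
    obs = np.asarray(obs, dtype=float)
    pred = np.asarray(pred, dtype=float)
    if obs.shape != pred.shape:
        raise ValueError("obs and pred must have equal length")
    ss_tot = float(np.sum((obs - np.mean(obs)) ** 2))
    if ss_tot == 0.0:
        logger.warning("R^2 undefined for constant observations; returning NaN")
        return float("nan")
    ss_res = float(np.sum((obs - pred) ** 2))
    return 1.0 - ss_res / ss_tot


# ---------------------------------------------------------------------------
# Fitting
# ---------------------------------------------------------------------------

def _projected_solution(
    spec: ModelSpec, theta: np.ndarray, aif: Curve, obs: np.ndarray
) -> tuple[np.ndarray, np.ndarray, float]:
    """Exact non-negative amplitudes and residual for a shape vector."""
    design = spec.basis(theta, aif)
    coefs, _ = nnls(design, obs)
    resid = design @ coefs - obs
    return coefs, resid, 0.5 * float(resid @ resid)


def _varpro_starts(
    spec: ModelSpec, aif: Curve, obs: np.ndarray,
    lo: np.ndarray, hi: np.ndarray, n_starts: int, max_iter: int,
) -> list[np.ndarray]:
    """Grid-scored variable-projection search returning full-vector starts."""
    nl = list(spec.nonlinear_idx)
    nodes = spec.shape_grid()
    scored = sorted(
        (( _projected_solution(spec, th, aif, obs)[2], i) for i, th in enumerate(nodes)),
        key=lambda z: z[0],
    )
    # keep the best nodes subject to a log-space separation so the restarts
    # probe distinct basins instead of clustering around one minimum
    top: list[np.ndarray] = []
    for _, i in scored:
        th = nodes[i]
        if any(
            np.all(np.abs(np.log((th + 1e-3) / (other + 1e-3))) < 0.7)
            for other in top
        ):
            continue
        top.append(th)
        if len(top) >= n_starts:
            break
    starts = []
    if nl:
        nl_lo, nl_hi = lo[nl], hi[nl]
        for theta0 in top:
            res = least_squares(
                lambda th: _projected_solution(spec, th, aif, obs)[1],
                np.clip(theta0, nl_lo, nl_hi), bounds=(nl_lo, nl_hi),
                method="trf", x_scale="jac",
                xtol=_TOL, ftol=_TOL, gtol=_TOL,
                max_nfev=max_iter * (len(nl) + 1),
            )
            coefs, _, _ = _projected_solution(spec, res.x, aif, obs)
            starts.append(spec.assemble(res.x, coefs))
    else:
        coefs, _, _ = _projected_solution(spec, np.empty(0), aif, obs)
        starts.append(spec.assemble(np.empty(0), coefs))
    return starts


def fit_model(tissue: Curve, aif_plasma: Curve, cfg: FitConfig) -> FitResult:
    """Fit a renal model to a cortical concentration curve.

    Without an explicit ``cfg.init``, a deterministic coarse grid over the
    model's shape parameters is scored with the amplitudes projected out,
    the best ``cfg.multistart`` nodes are refined by bounded damped least
    squares on the shape subproblem, and each refined candidate is polished
    over the full parameter vector; the lowest-cost polish wins.  With
    ``cfg.init`` the grid stage is skipped and the solver starts from the
    given vector plus seeded jittered restarts.

    If no start converges, the best attempt is returned flagged
    ``converged=False`` -- never an unflagged estimate.
    """
    if len(tissue) != len(aif_plasma) or not np.allclose(tissue.t, aif_plasma.t):
        raise ValueError("tissue and AIF must share one time grid")
    spec, lo, hi = cfg.resolved()
    obs = tissue.v

    def residuals(x: np.ndarray) -> np.ndarray:
        return spec.predictor(x, aif_plasma).v - obs

    if cfg.init is not None:
        starts = [np.asarray(cfg.init, float)]
        rng = np.random.default_rng(cfg.seed)
        for _ in range(cfg.multistart - 1):
            jitter = starts[0] * rng.uniform(0.5, 1.5, spec.n_params)
            starts.append(np.clip(jitter, lo, hi))
    else:
        starts = _varpro_starts(
            spec, aif_plasma, obs, lo, hi, cfg.multistart, cfg.max_iter
        )

    best = None
    n_converged = 0
    for x0 in starts:
        try:
            res = least_squares(
                residuals, np.clip(x0, lo, hi), bounds=(lo, hi), method="trf",
                x_scale="jac", xtol=_TOL, ftol=_TOL, gtol=_TOL,
                max_nfev=cfg.max_iter * (spec.n_params + 1),
            )
        except Exception as exc:  # pragma: no cover - solver failure path
            logger.warning("fit start failed: %s", exc)
            continue
        if res.success and np.all(np.isfinite(res.x)):
            n_converged += 1
        if best is None or res.cost < best.cost:
            best = res

    if best is None:
        return FitResult(
            model=spec.name, params={}, r2=float("nan"),
            residual_norm=float("nan"), converged=False,
            n_starts=len(starts), n_converged=0, message="all starts raised",
        )

    params = dict(zip(spec.param_names, map(float, best.x)))
    pred = spec.predictor(best.x, aif_plasma)
    mtts = None
    if spec.name == "2cirf":
        p = TwoCIRFParams(
            gfr=params["gfr"], rpf=params["rpf"],
            irf_a=IRFParams(tau=params["tau_a"], m=params["m_a"]),
            irf_t=IRFParams(tau=params.get("tau_t", 0.0), m=params["m_t"]),
        )
        mtts = mtt_summary(p)
    return FitResult(
        model=spec.name,
        params=params,
        r2=r_squared(obs, pred.v),
        residual_norm=float(np.sqrt(2.0 * best.cost)),
        converged=n_converged > 0,
        n_starts=len(starts),
        n_converged=n_converged,
        mtts=mtts,
        message=str(best.message),
    )
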