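"""Fitting each measure's free parameters against relevance judgments.

Every measure is fitted independently, by minimizing the mean squared
error between the measure's per-trial value and the reported relevance
over all main trials.  First-order scaled measures have one parameter
(the scale base ``r_scale`` of g); second-order measures are fitted
jointly over ``(a_link, b_link, r_scale)``, since the commitment linking
function kappa = a * b**c is part of the measure.  Bayes factor utility
and probability change are parameter-free and report their MSE only;
commitment change (raw, on 0..6) gets a proportionality coefficient so
its MSE is commensurable with the unit-interval relevance slider.

The optimizer is a logarithmic grid scan followed by Nelder-Mead
refinement on log-parameters: derivative-free, deterministic, and robust
over the many-orders-of-magnitude range the scale base can take.  The
parameters of second-order measures can trade off against each other, so
recovery guarantees are stated in prediction space (per-trial values),
not parameter space.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import minimize, minimize_scalar

from .beliefs import MeasureParams
from .measures import (
    DEFAULT_PARAMS,
    G_SCALED,
    MEASURE_NAMES,
    PARAMETER_FREE,
    SECOND_ORDER,
    evaluate_measure,
)

__all__ = ["SearchConfig", "FitResult", "measure_predictions", "fit_measure", "fit_all",
           "compare_joint_linking"]

# log-parameter bounds: r_scale in [1.001, 1e7], a in [0.1, 20], b in (1.01, 20]
_LOG_LNR_LO, _LOG_LNR_HI = math.log(math.log(1.001)), math.log(math.log(1e7))
_LOG_A_LO, _LOG_A_HI = math.log(0.1), math.log(20.0)
_LOG_LNB_LO, _LOG_LNB_HI = math.log(math.log(1.01)), math.log(math.log(20.0))


@dataclass(frozen=True)
class SearchConfig:
    """Grid density and refinement settings for the MSE search."""

    n_grid_r: int = 33
    n_grid_ab: int = 11
    n_starts: int = 4
    refine: bool = True
    maxiter: int = 4000
    fatol: float = 1e-16
    xatol: float = 1e-10


@dataclass
class FitResult:
    """Fitted parameters and objective for one measure."""

    measure: str
    params: MeasureParams
    mse: float
    n_trials: int
    scale_coef: float | None = None
    converged: bool = True
    trace: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "measure": self.measure,
            "r_scale": self.params.r_scale,
            "a_link": self.params.a_link,
            "b_link": self.params.b_link,
            "scale_coef": self.scale_coef,
            "mse": self.mse,
            "n_trials": self.n_trials,
            "converged": self.converged,
        }


def _arrays(data) -> tuple[np.ndarray, ...]:
    """Extract (p, c, q, d, r) over main trials with complete quintuples."""
    df = data.main_trials if hasattr(data, "main_trials") else data
    df = df[df["trial_type"] == "main"] if "trial_type" in df.columns else df
    cols = ["prior_prob", "prior_commit", "post_prob", "post_commit", "relevance"]
    df = df.dropna(subset=cols)
    if df.empty:
        raise ValueError("no complete main trials to fit on")
    return tuple(df[c].to_numpy(dtype=float) for c in cols)


def measure_predictions(name, p, c, q, d, params=None, scale_coef=None):
    """Per-trial predicted relevance under a measure (vectorized).

    Identical to the raw measure except for commitment change, whose raw
    0..6 value is multiplied by ``scale_coef`` (default 1) to live on the
    relevance slider's scale.
    """
    vals = np.asarray(evaluate_measure(name, p, c, q, d, params), dtype=float)
    if name == "commitment_change":
        vals = (1.0 if scale_coef is None else scale_coef) * vals
    return vals


def _mse(pred: np.ndarray, r: np.ndarray) -> float:
    return float(np.mean((pred - r) ** 2))


def fit_measure(data, measure_name: str, search: SearchConfig | None = None) -> FitResult:
    """Fit one registry measure by MSE over main trials.

    Deterministic given the data and search config.  Parameter-free
    measures return a degenerate result carrying their MSE only.
    """
    if measure_name not in MEASURE_NAMES:
        raise KeyError(f"unknown measure {measure_name!r}")
    search = search or SearchConfig()
    p, c, q, d, r = _arrays(data)
    n = r.size

    if measure_name in ("probability_change", "bayes_factor_utility"):
        pred = measure_predictions(measure_name, p, c, q, d)
        return FitResult(measure_name, MeasureParams(), _mse(pred, r), n)

    if measure_name == "commitment_change":
        m = measure_predictions(measure_name, p, c, q, d)
        denom = float(np.sum(m * m))
        coef = float(np.sum(m * r) / denom) if denom > 0 else 0.0
        return FitResult(
            measure_name, MeasureParams(), _mse(coef * m, r), n, scale_coef=coef
        )

    second = measure_name in SECOND_ORDER

    def params_from_theta(theta) -> MeasureParams:
        # box-constrain the log-parameters so refinement stays in the
        # searched region (r in [1.001, 1e7], a in [0.1, 20], b in (1.01, 20])
        if second:
            la, llnb, llnr = theta
            la = min(max(la, _LOG_A_LO), _LOG_A_HI)
            llnb = min(max(llnb, _LOG_LNB_LO), _LOG_LNB_HI)
            llnr = min(max(llnr, _LOG_LNR_LO), _LOG_LNR_HI)
            return MeasureParams(
                r_scale=math.exp(math.exp(llnr)),
                a_link=math.exp(la),
                b_link=math.exp(math.exp(llnb)),
            )
        llnr = min(max(theta[0], _LOG_LNR_LO), _LOG_LNR_HI)
        return MeasureParams(r_scale=math.exp(math.exp(llnr)))

    def objective(theta) -> float:
        try:
            params = params_from_theta(np.atleast_1d(theta))
        except (OverflowError, ValueError):
            return np.inf
        pred = measure_predictions(measure_name, p, c, q, d, params)
        if not np.all(np.isfinite(pred)):
            raise FloatingPointError(
                f"non-finite {measure_name} values at params {params}"
            )
        return _mse(pred, r)

    r_grid = np.linspace(_LOG_LNR_LO, _LOG_LNR_HI, search.n_grid_r)
    if second:
        a_grid = np.linspace(_LOG_A_LO, _LOG_A_HI, search.n_grid_ab)
        b_grid = np.linspace(_LOG_LNB_LO, _LOG_LNB_HI, search.n_grid_ab)
        grid = [(la, lb, lr) for la in a_grid for lb in b_grid for lr in r_grid]
    else:
        grid = [(lr,) for lr in r_grid]
    scores = [objective(np.array(g)) for g in grid]
    best_i = int(np.argmin(scores))
    theta0 = np.array(grid[best_i])
    best = scores[best_i]
    converged = True

    if search.refine:
        # multi-start Nelder-Mead from the best grid points (the 3-parameter
        # second-order objectives have shallow local basins)
        order = np.argsort(scores)
        starts = [np.array(grid[i]) for i in order[: search.n_starts]]
        converged = False
        for start in starts:
            res = minimize(
                objective,
                start,
                method="Nelder-Mead",
                options={
                    "maxiter": search.maxiter,
                    "fatol": search.fatol,
                    "xatol": search.xatol,
                },
            )
            if res.fun <= best:
                theta0, best = res.x, float(res.fun)
                converged = converged or bool(res.success)
        converged = converged or best <= scores[best_i]

    params = params_from_theta(theta0)
    return FitResult(
        measure_name,
        params,
        best,
        n,
        converged=converged,
        trace={"grid_points": len(grid), "grid_best_mse": float(scores[best_i])},
    )


def fit_all(data, search: SearchConfig | None = None) -> dict[str, FitResult]:
    """One independent FitResult per registry measure.

    A failure in one measure is recorded (``converged=False``,
    ``mse=nan``) without aborting the rest.
    """
    results: dict[str, FitResult] = {}
    for name in MEASURE_NAMES:
        try:
            results[name] = fit_measure(data, name, search)
        except (ValueError, FloatingPointError, KeyError) as exc:
            results[name] = FitResult(
                name, MeasureParams(), float("nan"), 0, converged=False,
                trace={"error": str(exc)},
            )
    return results


def fits_table(fits: dict[str, FitResult]) -> pd.DataFrame:
    """Best-fit parameter table (measure, a, b, r, mse) in registry order."""
    rows = []
    for name in MEASURE_NAMES:
        f = fits[name]
        rows.append(
            {
                "measure": name,
                "a": f.params.a_link,
                "b": f.params.b_link,
                "r": f.params.r_scale,
                "scale_coef": f.scale_coef,
                "mse": f.mse,
            }
        )
    return pd.DataFrame(rows)


def compare_joint_linking(
    data, fits: dict[str, FitResult] | None = None, search: SearchConfig | None = None
) -> pd.DataFrame:
    """MSE penalty of sharing one linking function across second-order measures.

    Fits a single (a_link, b_link) for all g-scaled second-order measures,
    with per-measure scale bases, and reports each measure's MSE increase
    relative to its individually fitted optimum.
    """
    search = search or SearchConfig(n_grid_ab=7, n_grid_r=17)
    targets = [m for m in SECOND_ORDER if m in G_SCALED]
    if fits is None:
        fits = {m: fit_measure(data, m, search) for m in targets}
    p, c, q, d, r = _arrays(data)

    def per_measure_best(name, a, b) -> float:
        def obj(llnr):
            params = MeasureParams(
                r_scale=math.exp(math.exp(llnr)), a_link=a, b_link=b
            )
            return _mse(measure_predictions(name, p, c, q, d, params), r)

        res = minimize_scalar(obj, bounds=(_LOG_LNR_LO, _LOG_LNR_HI), method="bounded")
        return float(res.fun)

    def joint_obj(theta) -> float:
        la, llnb = theta
        a, b = math.exp(la), math.exp(math.exp(llnb))
        return sum(per_measure_best(m, a, b) for m in targets)

    a_grid = np.linspace(_LOG_A_LO, _LOG_A_HI, search.n_grid_ab)
    b_grid = np.linspace(_LOG_LNB_LO, _LOG_LNB_HI, search.n_grid_ab)
    grid = [(la, lb) for la in a_grid for lb in b_grid]
    scores = [joint_obj(np.array(g)) for g in grid]
    theta0 = np.array(grid[int(np.argmin(scores))])
    res = minimize(joint_obj, theta0, method="Nelder-Mead",
                   options={"maxiter": 400, "fatol": 1e-10})
    la, llnb = res.x if res.fun <= min(scores) else theta0
    a, b = math.exp(la), math.exp(math.exp(llnb))

    rows = []
    for m in targets:
        joint_mse = per_measure_best(m, a, b)
        rows.append(
            {
                "measure": m,
                "individual_mse": fits[m].mse,
                "joint_mse": joint_mse,
                "penalty": joint_mse - fits[m].mse,
                "shared_a": a,
                "shared_b": b,
            }
        )
    return pd.DataFrame(rows)
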