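"""Sigmoidal valve-resistance model: evaluation, fitting, validation, threshold.

The valve's resistance to forward flow is modeled as a logistic function of
the pressure gradient across the valve,

    R_valve(dp) = R_vl + R_vh / (1 + exp(s * dp)),

dropping from a high plateau ``R_vl + R_vh`` (valve closed, adverse
gradient) to a low plateau ``R_vl`` (valve fully open).  An auxiliary
exponential map ``dp_valve = P0 * exp(A * dp_total)`` regularizes the
measured valve pressure gradients before the sigmoid fit and supplies the
gradients used for forward flow prediction.  The opening threshold is the
gradient at which the modeled resistance falls within 5% of ``R_vl``.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
from scipy.optimize import minimize
from scipy.special import expit

from .errors import (
    DroppedPointsWarning,
    FitConvergenceError,
    InsufficientDataError,
    InvalidModelError,
)

__all__ = [
    "ValveResistanceModel",
    "ExponentialPressureModel",
    "ValveFit",
    "ThresholdSummary",
    "eval_valve_resistance",
    "fit_pressure_map",
    "fit_valve_model",
    "predict_flow",
    "valve_opening_threshold",
    "threshold_summary",
    "coefficient_of_determination",
]


@dataclass(frozen=True)
class ValveResistanceModel:
    """Parameters of the logistic valve-resistance law.

    ``r_vl`` [cmH2O.min/mL] is the open-valve plateau, ``r_vh`` the span
    above it (closed-valve resistance is ``r_vl + r_vh``), ``s`` [1/cmH2O]
    the transition steepness.  All strictly positive.
    """

    r_vl: float
    r_vh: float
    s: float

    def __post_init__(self) -> None:
        if not (self.r_vl > 0 and self.r_vh > 0 and self.s > 0):
            raise InvalidModelError(
                f"valve parameters must be > 0, got r_vl={self.r_vl}, r_vh={self.r_vh}, s={self.s}"
            )


@dataclass(frozen=True)
class ExponentialPressureModel:
    """Exponential map from total to valve pressure gradient: dp_valve = p0 * exp(a * dp_total)."""

    p0: float
    a: float

    def __post_init__(self) -> None:
        if not self.p0 > 0:
            raise InvalidModelError(f"p0 must be > 0, got {self.p0}")

    def __call__(self, dp_total):
        return self.p0 * np.exp(self.a * np.asarray(dp_total, dtype=float))


@dataclass(frozen=True)
class ValveFit:
    """Fitted models and diagnostics for one segment."""

    segment_id: str
    model: ValveResistanceModel
    pressure_map: ExponentialPressureModel
    r_squared_resistance: float
    r_squared_flow: float
    threshold: float


@dataclass(frozen=True)
class ThresholdSummary:
    """Opening thresholds across segments: per-segment values, mean, population sd."""

    per_segment: np.ndarray
    mean: float
    sd: float


def eval_valve_resistance(model: ValveResistanceModel, dp_valve):
    """Evaluate the logistic valve resistance at ``dp_valve`` [cmH2O].

    Numerically safe for arbitrarily large ``|s * dp_valve|`` (the logistic
    term is computed via :func:`scipy.special.expit`).  Accepts scalars or
    arrays.
    """
    dp = np.asarray(dp_valve, dtype=float)
    # r_vh / (1 + exp(s dp)) == r_vh * expit(-s dp), overflow-free
    out = model.r_vl + model.r_vh * expit(-model.s * dp)
    return float(out) if out.ndim == 0 else out


def coefficient_of_determination(model_values, data_values) -> float:
    """R^2 = 1 - SS_res / SS_tot with SS_tot about the data mean.

    May be negative for a poor model; reported as computed.
    """
    m = np.asarray(model_values, dtype=float)
    d = np.asarray(data_values, dtype=float)
    if m.shape != d.shape or d.size < 2:
        raise InsufficientDataError("need >= 2 aligned points for R^2")
    ss_tot = float(np.sum((d - d.mean()) ** 2))
    if ss_tot == 0:
        raise InvalidModelError("R^2 undefined: data values all identical")
    ss_res = float(np.sum((m - d) ** 2))
    return 1.0 - ss_res / ss_tot


def _nelder_mead(objective, x0, maxiter=20000):
    return minimize(
        objective,
        x0,
        method="Nelder-Mead",
        options={"maxiter": maxiter, "maxfev": maxiter, "xatol": 1e-12, "fatol": 1e-14},
    )


def fit_pressure_map(dp_total, dp_valve) -> ExponentialPressureModel:
    """Least-squares fit of ``p0 * exp(a * dp_total)`` to measured valve gradients.

    Non-positive ``dp_valve`` points are dropped with a warning (the
    exponential form exists to keep modeled gradients positive).  ``p0`` is
    constrained positive by optimizing its logarithm; ``a`` is unbounded.
    Nelder-Mead on summed squared residuals, seeded from a log-linear
    regression.
    """
    dp_total = np.asarray(dp_total, dtype=float)
    dp_valve = np.asarray(dp_valve, dtype=float)
    keep = dp_valve > 0
    if not np.all(keep):
        warnings.warn(
            f"dropping {int(np.sum(~keep))} non-positive dp_valve point(s) from pressure-map fit",
            DroppedPointsWarning,
            stacklevel=2,
        )
        dp_total, dp_valve = dp_total[keep], dp_valve[keep]
    if dp_valve.size < 2:
        raise InsufficientDataError("pressure-map fit needs >= 2 points with dp_valve > 0")

    # log-linear seed: ln dp_valve = ln p0 + a dp_total
    if np.ptp(dp_total) > 0:
        a0, logp0 = np.polyfit(dp_total, np.log(dp_valve), 1)
    else:
        a0, logp0 = 0.0, float(np.mean(np.log(dp_valve)))

    def objective(theta):
        logp0_, a_ = theta
        resid = np.exp(logp0_ + a_ * dp_total) - dp_valve
        return float(np.dot(resid, resid))

    res = _nelder_mead(objective, np.array([logp0, a0]))
    if not res.success:
        raise FitConvergenceError(
            f"pressure-map fit did not converge: {res.message}",
            best_model=ExponentialPressureModel(math.exp(res.x[0]), res.x[1]),
            best_objective=float(res.fun),
        )
    return ExponentialPressureModel(p0=math.exp(res.x[0]), a=float(res.x[1]))


def _initial_valve_guess(dp_valve: np.ndarray, r_valve: np.ndarray) -> np.ndarray:
    """Scale-aware deterministic start in log space: (ln r_vl, ln r_vh, ln s)."""
    positive = r_valve[r_valve > 0]
    if positive.size == 0:
        positive = np.array([1e-3])
    r_vl0 = float(positive.min())
    r_vh0 = max(float(positive.max() - positive.min()), r_vl0)
    span = np.ptp(dp_valve)
    s0 = 10.0 / span if span > 0 else 10.0
    return np.log([r_vl0, r_vh0, s0])


def _profiled_starts(dp_valve: np.ndarray, r_valve: np.ndarray, n_best: int = 3) -> list[np.ndarray]:
    """Starts from profiling s: given s the model is linear in (r_vl, r_vh).

    For each candidate steepness the plateau and span solve a 2-parameter
    linear least squares; the best few (lowest SSE) seed the simplex.  This
    rescues series where only one step samples the closed-valve branch,
    where the naive start collapses onto the data mean.
    """
    candidates = []
    for s in np.geomspace(0.1, 2000.0, 40):
        basis = expit(-s * dp_valve)
        design = np.column_stack([np.ones_like(dp_valve), basis])
        coef, *_ = np.linalg.lstsq(design, r_valve, rcond=None)
        r_vl, r_vh = (max(c, 1e-12) for c in coef)
        resid = r_vl + r_vh * basis - r_valve
        candidates.append((float(np.dot(resid, resid)), np.log([r_vl, r_vh, s])))
    candidates.sort(key=lambda c: c[0])
    return [theta for _, theta in candidates[:n_best]]


def fit_valve_model(
    dp_valve,
    r_valve,
    *,
    objective: str = "linear",
    multistart: int = 5,
    seed: int = 0,
) -> tuple[ValveResistanceModel, float]:
    """Fit the logistic valve-resistance law to decomposed per-step data.

    Parameters
    ----------
    dp_valve, r_valve : array-like
        Aligned valve pressure gradients [cmH2O] and valve resistances
        [cmH2O.min/mL]; at least 3 points (3 free parameters).
    objective : {"linear", "log"}
        "linear": unweighted summed squared residuals on resistance values.
        "log": residuals on log-resistance (guards against the open-valve
        plateau being swamped when the closed-valve branch is huge);
        requires positive data, non-positive points dropped with a warning.
    multistart : int
        Number of deterministic Nelder-Mead starts (first from the
        scale-aware initial guess, remainder jittered in log space from
        ``seed``); the best objective wins.

    Returns
    -------
    (ValveResistanceModel, r_squared)
        Fitted model and its R^2 against ``r_valve`` (always evaluated on
        the linear scale, whatever the fitting objective).
    """
    dp_valve = np.asarray(dp_valve, dtype=float)
    r_valve = np.asarray(r_valve, dtype=float)
    if dp_valve.shape != r_valve.shape:
        raise InsufficientDataError("dp_valve and r_valve must be aligned")
    if objective not in ("linear", "log"):
        raise ValueError(f"unknown objective {objective!r}")
    if objective == "log":
        keep = r_valve > 0
        if not np.all(keep):
            warnings.warn(
                f"dropping {int(np.sum(~keep))} non-positive r_valve point(s) for log objective",
                DroppedPointsWarning,
                stacklevel=2,
            )
            dp_valve, r_valve = dp_valve[keep], r_valve[keep]
    if dp_valve.size < 3:
        raise InsufficientDataError("valve-model fit needs >= 3 points")

    if objective == "linear":

        def loss(theta):
            r_vl, r_vh, s = np.exp(theta)
            resid = r_vl + r_vh * expit(-s * dp_valve) - r_valve
            return float(np.dot(resid, resid))

    else:
        log_data = np.log(r_valve)

        def loss(theta):
            r_vl, r_vh, s = np.exp(theta)
            resid = np.log(r_vl + r_vh * expit(-s * dp_valve)) - log_data
            return float(np.dot(resid, resid))

    x0 = _initial_valve_guess(dp_valve, r_valve)
    rng = np.random.default_rng(seed)
    starts = [x0] + _profiled_starts(dp_valve, r_valve)
    starts += [x0 + rng.normal(scale=1.0, size=3) for _ in range(max(0, multistart - 1))]

    best = None
    for start in starts:
        res = _nelder_mead(loss, start)
        if best is None or res.fun < best.fun:
            best = res
    assert best is not None
    model = ValveResistanceModel(*np.exp(best.x))
    if not best.success and best.fun > 0:
        # Nelder-Mead can hit maxiter on flat plateaus; only a genuinely
        # unconverged *and* poor fit is an error.
        r2_check = coefficient_of_determination(eval_valve_resistance(model, dp_valve), r_valve)
        if not np.isfinite(r2_check) or r2_check < 0:
            raise FitConvergenceError(
                f"valve-model fit did not converge: {best.message}",
                best_model=model,
                best_objective=float(best.fun),
            )
    r2 = coefficient_of_determination(eval_valve_resistance(model, dp_valve), r_valve)
    return model, r2


def predict_flow(dp_total, fit: ValveFit, r_conn: float, r_vessel, dp_valve=None):
    """Model-based forward flow: Q = dp_total / (r_conn + r_vessel + R_valve).

    The valve pressure gradient at each step is taken from the fitted
    exponential pressure map (or from ``dp_valve`` if supplied), the valve
    resistance from the logistic law, and ``r_vessel`` is the per-step
    Poiseuille resistance at the measured diameter.
    """
    dp_total = np.asarray(dp_total, dtype=float)
    r_vessel = np.broadcast_to(np.asarray(r_vessel, dtype=float), dp_total.shape)
    dpv = fit.pressure_map(dp_total) if dp_valve is None else np.asarray(dp_valve, dtype=float)
    r_valve_m = eval_valve_resistance(fit.model, dpv)
    denom = r_conn + r_vessel + r_valve_m
    if np.any(denom <= 0):
        raise InvalidModelError("non-positive total model resistance")
    return dp_total / denom


def valve_opening_threshold(model: ValveResistanceModel) -> float:
    """Pressure gradient at which the modeled resistance is within 5% of r_vl.

    Closed form (1/s) ln(r_vh / (0.05 r_vl)); the exact inversion's "-1"
    term is dropped, negligible whenever r_vh >> 0.05 r_vl.
    """
    return math.log(model.r_vh / (0.05 * model.r_vl)) / model.s


def threshold_summary(fits) -> ThresholdSummary:
    """Mean and population standard deviation of per-segment opening thresholds.

    Accepts :class:`ValveFit` objects, :class:`ValveResistanceModel`
    objects, or raw threshold values.
    """
    values = []
    for f in fits:
        if isinstance(f, ValveFit):
            values.append(f.threshold)
        elif isinstance(f, ValveResistanceModel):
            values.append(valve_opening_threshold(f))
        else:
            values.append(float(f))
    if not values:
        raise InsufficientDataError("threshold summary needs >= 1 fit")
    arr = np.asarray(values, dtype=float)
    return ThresholdSummary(per_segment=arr, mean=float(arr.mean()), sd=float(arr.std(ddof=0)))
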