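"""Connector-resistance calibration from a rigid phantom tube.

The connectors (cannulae, fittings, rigid tubing) contribute a constant
series resistance.  Perfusing a rigid phantom of known geometry gives a
linear pressure-flow relation whose slope is the total setup resistance;
subtracting the phantom's exactly computable Poiseuille resistance isolates
the connector resistance, which is then shared by all segment analyses.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .core import FluidProperties, TubeGeometry, poiseuille_resistance
from .errors import CalibrationInconsistentError, InsufficientDataError, SingularFitError

__all__ = [
    "PhantomExperiment",
    "ConnectorCalibration",
    "fit_phantom_line",
    "connector_resistance",
    "calibrate_connector",
]

DEFAULT_PHANTOM_TUBE = TubeGeometry(length_mm=31.0, inner_diameter_mm=3.0)


@dataclass(frozen=True)
class PhantomExperiment:
    """Pressure-flow series measured across the setup with a rigid phantom mounted."""

    tube: TubeGeometry
    dp_total: np.ndarray
    flow: np.ndarray

    def __post_init__(self) -> None:
        object.__setattr__(self, "dp_total", np.asarray(self.dp_total, dtype=float))
        object.__setattr__(self, "flow", np.asarray(self.flow, dtype=float))
        if self.dp_total.size < 2 or self.flow.size != self.dp_total.size:
            raise InsufficientDataError("phantom series needs >= 2 aligned points")
        if np.any(np.diff(self.dp_total) <= 0):
            raise ValueError("dp_total must be strictly increasing")


@dataclass(frozen=True)
class ConnectorCalibration:
    """Result of the phantom calibration.

    ``slope`` is the fitted total resistance of the phantom setup
    [cmH2O.min/mL]; ``r_conn = slope - r_phantom``.  The intercept is a
    diagnostic only (the physical line passes through the origin).
    """

    slope: float
    intercept: float
    r_squared_linear: float
    r_phantom: float
    r_conn: float


def fit_phantom_line(exp: PhantomExperiment) -> tuple[float, float, float]:
    """Ordinary least-squares line of dp_total against flow.

    Returns ``(slope, intercept, r_squared)`` with the slope in
    cmH2O.min/mL.  The zero-pressure/zero-flow point is a valid anchor and
    should be included.
    """
    if np.ptp(exp.flow) == 0:
        raise SingularFitError("all flows identical; pressure-flow slope is undefined")
    res = stats.linregress(exp.flow, exp.dp_total)
    return float(res.slope), float(res.intercept), float(res.rvalue**2)


def connector_resistance(
    slope: float,
    fluid: FluidProperties,
    tube: TubeGeometry,
    intercept: float = 0.0,
    r_squared_linear: float = float("nan"),
) -> ConnectorCalibration:
    """Connector resistance by Poiseuille subtraction: r_conn = slope - r_phantom."""
    if not slope > 0:
        raise CalibrationInconsistentError(f"slope must be > 0, got {slope}")
    r_phantom = poiseuille_resistance(fluid, tube)
    r_conn = slope - r_phantom
    if r_conn < 0:
        raise CalibrationInconsistentError(
            f"slope {slope:.6g} below phantom Poiseuille resistance {r_phantom:.6g}; "
            "calibration physically inconsistent"
        )
    return ConnectorCalibration(
        slope=float(slope),
        intercept=float(intercept),
        r_squared_linear=float(r_squared_linear),
        r_phantom=float(r_phantom),
        r_conn=float(r_conn),
    )


def calibrate_connector(exp: PhantomExperiment, fluid: FluidProperties) -> ConnectorCalibration:
    """Full calibration: fit the phantom line, then subtract the Poiseuille resistance."""
    slope, intercept, r2 = fit_phantom_line(exp)
    return connector_resistance(slope, fluid, exp.tube, intercept=intercept, r_squared_linear=r2)
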