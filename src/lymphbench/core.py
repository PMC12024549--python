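"""Core hydraulic types and the per-step resistance decomposition.

A mounted duct segment in series with rigid connectors behaves as three
resistances in series: connector, vessel (Poiseuille), and valve.  Given a
measured pressure/flow/diameter series and a calibrated connector
resistance, each retained pressure step is decomposed into those three
contributions; the valve resistance is what remains after subtracting the
computable parts.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np

from .errors import (
    EmptySeriesError,
    InvalidGeometryError,
    InvalidMeasurementError,
    NegativeValveResistanceWarning,
    UndefinedResistanceError,
)
from .units import M_PER_MM, PAS_PER_CP, resistance_from_si

__all__ = [
    "FluidProperties",
    "TubeGeometry",
    "SegmentSpec",
    "BenchSeries",
    "ResistanceSeries",
    "poiseuille_resistance",
    "total_resistance",
    "inner_diameter",
    "decompose_resistance",
]


@dataclass(frozen=True)
class FluidProperties:
    """Newtonian working fluid.

    Parameters
    ----------
    viscosity_cP : float
        Dynamic viscosity in centipoise.  The bench default (0.9% saline)
        is 0.7 cP.
    """

    viscosity_cP: float = 0.7

    def __post_init__(self) -> None:
        if not self.viscosity_cP > 0:
            raise InvalidGeometryError(f"viscosity must be > 0, got {self.viscosity_cP}")


@dataclass(frozen=True)
class TubeGeometry:
    """A straight circular tube: mounted length and inner diameter, both in mm."""

    length_mm: float
    inner_diameter_mm: float

    def __post_init__(self) -> None:
        if not (self.length_mm > 0 and self.inner_diameter_mm > 0):
            raise InvalidGeometryError(
                f"length and diameter must be > 0, got L={self.length_mm}, D={self.inner_diameter_mm}"
            )

    @property
    def fully_developed(self) -> bool:
        """Whether the tube is long enough (L > 5 D) for fully developed laminar flow."""
        return self.length_mm > 5.0 * self.inner_diameter_mm


@dataclass(frozen=True)
class SegmentSpec:
    """Identity and fixed geometry of one mounted duct segment.

    ``mounted_length_mm`` defaults to ``ex_vivo_length_mm * stretch_ratio``
    (the bench protocol stretches the excised segment before mounting); if
    given explicitly it must agree with that product within rounding.
    """

    segment_id: str
    ex_vivo_length_mm: float
    wall_thickness_mm: float
    stretch_ratio: float = 1.30
    mounted_length_mm: float | None = None

    def __post_init__(self) -> None:
        if not self.ex_vivo_length_mm > 0:
            raise InvalidGeometryError("ex_vivo_length_mm must be > 0")
        if not self.wall_thickness_mm > 0:
            raise InvalidGeometryError("wall_thickness_mm must be > 0")
        if not self.stretch_ratio > 0:
            raise InvalidGeometryError("stretch_ratio must be > 0")
        expected = self.ex_vivo_length_mm * self.stretch_ratio
        if self.mounted_length_mm is None:
            object.__setattr__(self, "mounted_length_mm", expected)
        elif not math.isclose(self.mounted_length_mm, expected, rel_tol=5e-3, abs_tol=0.05):
            raise InvalidGeometryError(
                f"mounted_length_mm={self.mounted_length_mm} inconsistent with "
                f"ex_vivo_length x stretch = {expected:.3f}"
            )


@dataclass(frozen=True)
class BenchSeries:
    """One segment's aligned bench measurements.

    Vectors (one entry per applied pressure step, low to high):
    total pressure gradient [cmH2O], volumetric flow [mL/min], outer
    diameter [mm].
    """

    segment: SegmentSpec
    dp_total: np.ndarray
    flow: np.ndarray
    d_out: np.ndarray

    def __post_init__(self) -> None:
        for name in ("dp_total", "flow", "d_out"):
            object.__setattr__(self, name, np.asarray(getattr(self, name), dtype=float))
        n = self.dp_total.size
        if n < 2 or self.flow.size != n or self.d_out.size != n:
            raise InvalidMeasurementError(
                f"dp_total, flow, d_out must be aligned with >= 2 entries "
                f"(got {n}, {self.flow.size}, {self.d_out.size})"
            )
        if np.any(self.dp_total < 0) or np.any(np.diff(self.dp_total) <= 0):
            raise InvalidMeasurementError("dp_total must be non-negative and strictly increasing")
        if np.any(self.flow < 0):
            raise InvalidMeasurementError("flow must be non-negative")
        if np.any(self.d_out <= self.segment.wall_thickness_mm):
            raise InvalidMeasurementError("outer diameter must exceed wall thickness")

    def __len__(self) -> int:
        return int(self.dp_total.size)


@dataclass(frozen=True)
class ResistanceSeries:
    """Per-step resistance decomposition of a bench series (zero-flow steps dropped).

    All resistances in cmH2O.min/mL, pressures in cmH2O, diameters in mm.
    By construction ``r_total == r_conn + r_vessel + r_valve`` and
    ``dp_conn + dp_vessel + dp_valve == dp_total`` at every step.
    """

    segment: SegmentSpec
    r_conn: float
    dp_total: np.ndarray
    flow: np.ndarray
    inner_diameter: np.ndarray
    r_total: np.ndarray
    r_vessel: np.ndarray
    r_valve: np.ndarray
    dp_conn: np.ndarray
    dp_vessel: np.ndarray
    dp_valve: np.ndarray

    def __len__(self) -> int:
        return int(self.dp_total.size)


def poiseuille_resistance(fluid: FluidProperties, tube: TubeGeometry) -> float:
    """Poiseuille hydraulic resistance 128 mu L / (pi D^4) of a circular tube.

    Inputs are in bench units (cP, mm); the law is evaluated in SI and the
    result converted back to cmH2O.min/mL.
    """
    mu = fluid.viscosity_cP * PAS_PER_CP
    length = tube.length_mm * M_PER_MM
    diameter = tube.inner_diameter_mm * M_PER_MM
    r_si = 128.0 * mu * length / (math.pi * diameter**4)
    return resistance_from_si(r_si)


def total_resistance(dp_total: float, flow: float) -> float:
    """Total setup resistance dp_total / Q for one pressure step.

    Raises
    ------
    UndefinedResistanceError
        If ``flow`` is zero (the 0-cmH2O step); callers must exclude
        zero-flow steps before computing resistances.
    """
    if flow == 0:
        raise UndefinedResistanceError("total resistance undefined at zero flow")
    return dp_total / flow


def inner_diameter(d_out, wall_thickness: float, convention: str = "printed"):
    """Inner diameter from outer diameter and wall thickness.

    ``convention="printed"`` uses D = Dout - t (single thickness, the
    convention used in the source analysis); ``"geometric"`` uses the
    geometric D = Dout - 2t.  Accepts scalars or arrays.
    """
    if convention == "printed":
        factor = 1.0
    elif convention == "geometric":
        factor = 2.0
    else:
        raise ValueError(f"unknown diameter convention {convention!r}")
    d_out = np.asarray(d_out, dtype=float)
    d_in = d_out - factor * wall_thickness
    if np.any(d_in <= 0):
        raise InvalidMeasurementError(
            f"outer diameter {d_out} not greater than {factor:g} x wall thickness {wall_thickness}"
        )
    return float(d_in) if d_in.ndim == 0 else d_in


def decompose_resistance(
    series: BenchSeries,
    r_conn: float,
    fluid: FluidProperties,
    convention: str = "printed",
) -> ResistanceSeries:
    """Decompose measured total resistance into connector, vessel and valve parts.

    Steps with zero flow (the zero-pressure anchor) are dropped.  Per
    retained step: vessel resistance is Poiseuille at that step's inner
    diameter and the segment's mounted length; valve resistance is
    ``r_total - (r_conn + r_vessel)``; the valve pressure gradient is
    ``dp_total - dp_conn - dp_vessel``.

    Negative valve resistances are kept (the fit sees raw data) but raise a
    :class:`NegativeValveResistanceWarning`.
    """
    if r_conn < 0:
        raise InvalidMeasurementError(f"r_conn must be >= 0, got {r_conn}")
    keep = series.flow > 0
    if not np.any(keep):
        raise EmptySeriesError(f"segment {series.segment.segment_id}: all steps have zero flow")

    dp = series.dp_total[keep]
    q = series.flow[keep]
    d_in = inner_diameter(series.d_out[keep], series.segment.wall_thickness_mm, convention)
    length = series.segment.mounted_length_mm

    r_vessel = np.array(
        [poiseuille_resistance(fluid, TubeGeometry(length, d)) for d in d_in]
    )
    r_total = dp / q
    r_cv = r_conn + r_vessel
    r_valve = r_total - r_cv
    dp_conn = r_conn * q
    dp_vessel = r_vessel * q
    dp_valve = dp - dp_conn - dp_vessel

    if np.any(r_valve < 0):
        bad = dp[r_valve < 0]
        warnings.warn(
            f"segment {series.segment.segment_id}: negative valve resistance at "
            f"dp_total={np.array2string(bad, precision=3)} cmH2O (kept, not floored)",
            NegativeValveResistanceWarning,
            stacklevel=2,
        )

    return ResistanceSeries(
        segment=series.segment,
        r_conn=float(r_conn),
        dp_total=dp,
        flow=q,
        inner_diameter=d_in,
        r_total=r_total,
        r_vessel=r_vessel,
        r_valve=r_valve,
        dp_conn=dp_conn,
        dp_vessel=dp_vessel,
        dp_valve=dp_valve,
    )
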