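"""Synthetic bench generator with known ground truth.

Builds phantom and segment pressure-flow series from a self-consistent
lumped series circuit (connector + Poiseuille vessel + logistic valve), so
every pipeline stage can be exercised and its recovery error measured
without any external data.  The outer diameter follows a saturating
rectangular-hyperbola pressure law (rapid rise then plateau); flow at each
pressure step solves the implicit circuit equation by bisection.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .calibration import PhantomExperiment
from .core import (
    BenchSeries,
    FluidProperties,
    SegmentSpec,
    TubeGeometry,
    inner_diameter,
    poiseuille_resistance,
)
from .errors import InvalidGeometryError
from .valve import ValveResistanceModel, eval_valve_resistance

__all__ = [
    "PressureGrid",
    "SyntheticGroundTruth",
    "diameter_at_pressure",
    "solve_steady_flow",
    "generate_segment_series",
    "generate_phantom_series",
    "solve_series",
]

_RESIDUAL_TOL = 1e-10  # cmH2O, circuit-equation closure
_MAX_REDRAWS = 100


@dataclass(frozen=True)
class PressureGrid:
    """Applied total pressure gradients [cmH2O]; bench default 0..10 in 1-cmH2O steps."""

    values: np.ndarray = field(default_factory=lambda: np.arange(0.0, 11.0))

    def __post_init__(self) -> None:
        object.__setattr__(self, "values", np.asarray(self.values, dtype=float))
        if np.any(self.values < 0) or np.any(np.diff(self.values) <= 0):
            raise InvalidGeometryError("pressure grid must be non-negative and strictly increasing")


@dataclass(frozen=True)
class SyntheticGroundTruth:
    """True parameters behind one synthetic segment series.

    The diameter law is ``d_out(dp) = d_min + (d_max - d_min) dp/(dp + p_half)``.
    Noise levels are relative standard deviations of multiplicative
    Gaussian noise on flow and outer diameter.
    """

    valve: ValveResistanceModel
    r_conn: float
    segment: SegmentSpec
    d_min: float = 1.5
    d_max: float = 3.5
    p_half: float = 2.0
    noise_flow: float = 0.0
    noise_diameter: float = 0.0
    seed: int = 0
    fluid: FluidProperties = field(default_factory=FluidProperties)
    diameter_convention: str = "printed"

    def __post_init__(self) -> None:
        if not (self.d_max > self.d_min > self.segment.wall_thickness_mm):
            raise InvalidGeometryError(
                f"need d_max > d_min > wall thickness, got {self.d_max}, {self.d_min}, "
                f"{self.segment.wall_thickness_mm}"
            )
        if not self.p_half > 0:
            raise InvalidGeometryError("p_half must be > 0")
        if self.noise_flow < 0 or self.noise_diameter < 0:
            raise InvalidGeometryError("noise levels must be >= 0")
        if self.r_conn < 0:
            raise InvalidGeometryError("r_conn must be >= 0")


def diameter_at_pressure(truth: SyntheticGroundTruth, dp_total):
    """Saturating outer diameter [mm] at applied pressure gradient [cmH2O]."""
    dp = np.asarray(dp_total, dtype=float)
    out = truth.d_min + (truth.d_max - truth.d_min) * dp / (dp + truth.p_half)
    return float(out) if out.ndim == 0 else out


def _vessel_resistance(truth: SyntheticGroundTruth, d_out: float) -> float:
    d_in = inner_diameter(d_out, truth.segment.wall_thickness_mm, truth.diameter_convention)
    tube = TubeGeometry(truth.segment.mounted_length_mm, d_in)
    return poiseuille_resistance(truth.fluid, tube)


def solve_steady_flow(truth: SyntheticGroundTruth, dp_total: float) -> tuple[float, float]:
    """Self-consistent (flow, valve pressure gradient) at one pressure step.

    Solves ``Q (r_conn + r_vessel + R_valve(dp_valve(Q))) = dp_total`` with
    ``dp_valve(Q) = dp_total - (r_conn + r_vessel) Q`` by bisection on
    ``Q in [0, dp_total / (r_conn + r_vessel + r_vl)]``; the residual is
    strictly increasing in Q, so the bracket is guaranteed.  Converges to an
    absolute circuit residual <= 1e-10 cmH2O.
    """
    if dp_total == 0:
        return 0.0, 0.0
    r_cv = truth.r_conn + _vessel_resistance(truth, diameter_at_pressure(truth, dp_total))

    def residual(q: float) -> float:
        dpv = dp_total - r_cv * q
        return q * (r_cv + eval_valve_resistance(truth.valve, dpv)) - dp_total

    lo, hi = 0.0, dp_total / (r_cv + truth.valve.r_vl)
    f_lo, f_hi = residual(lo), residual(hi)
    # f_hi >= 0 analytically; rounding can leave it a few ulp below zero
    assert f_lo <= 0 and f_hi >= -_RESIDUAL_TOL, "bisection bracket failed for valid ground truth"
    if abs(f_hi) <= _RESIDUAL_TOL:
        return hi, dp_total - r_cv * hi
    q = lo
    for _ in range(300):
        mid = 0.5 * (lo + hi)
        f_mid = residual(mid)
        if abs(f_mid) <= _RESIDUAL_TOL:
            q = mid
            break
        if f_mid < 0:
            lo = mid
        else:
            hi = mid
        # stop once the bracket is at the floating-point spacing of the root
        if hi - lo <= np.finfo(float).eps * abs(mid):
            q = mid
            break
    else:  # pragma: no cover - 300 halvings exhaust double precision
        q = 0.5 * (lo + hi)
    return q, dp_total - r_cv * q


def solve_series(truth: SyntheticGroundTruth, grid: PressureGrid) -> dict[str, np.ndarray]:
    """Noiseless forward solution on a grid: the generator's ground-truth tables.

    Returns aligned arrays ``dp_total, flow, d_out, dp_valve, r_vessel,
    r_valve`` (resistance entries are NaN at zero-flow steps).
    """
    dp = grid.values
    d_out = diameter_at_pressure(truth, dp)
    flow = np.empty_like(dp)
    dp_valve = np.empty_like(dp)
    r_vessel = np.array([_vessel_resistance(truth, d) for d in d_out])
    for i, p in enumerate(dp):
        flow[i], dp_valve[i] = solve_steady_flow(truth, p)
    r_valve = eval_valve_resistance(truth.valve, dp_valve)
    r_valve = np.where(flow > 0, r_valve, np.nan)
    return {
        "dp_total": dp,
        "flow": flow,
        "d_out": d_out,
        "dp_valve": dp_valve,
        "r_vessel": r_vessel,
        "r_valve": r_valve,
    }


def _noisy(rng: np.random.Generator, value: float, rel_sd: float, lower: float) -> float:
    """Multiplicative Gaussian perturbation, redrawn while non-physical (<= lower)."""
    if rel_sd == 0:
        return value
    for _ in range(_MAX_REDRAWS):
        drawn = value * (1.0 + rel_sd * rng.standard_normal())
        if drawn > lower:
            return drawn
    raise RuntimeError(f"could not draw a physical value near {value} after {_MAX_REDRAWS} tries")


def generate_segment_series(truth: SyntheticGroundTruth, grid: PressureGrid | None = None) -> BenchSeries:
    """Bench-like noisy series for one synthetic segment.

    Per pressure step the deterministic diameter and self-consistent flow
    get independent multiplicative Gaussian noise from a generator seeded
    with ``truth.seed`` (same truth, same series).  Flow at dp = 0 stays
    exactly zero.
    """
    grid = grid or PressureGrid()
    rng = np.random.default_rng(truth.seed)
    t = truth.segment.wall_thickness_mm
    d_out = np.empty_like(grid.values)
    flow = np.empty_like(grid.values)
    for i, dp in enumerate(grid.values):
        d_true = diameter_at_pressure(truth, dp)
        q_true, _ = solve_steady_flow(truth, dp)
        d_out[i] = _noisy(rng, d_true, truth.noise_diameter, lower=t)
        flow[i] = 0.0 if dp == 0 else _noisy(rng, q_true, truth.noise_flow, lower=0.0)
    return BenchSeries(segment=truth.segment, dp_total=grid.values.copy(), flow=flow, d_out=d_out)


def generate_phantom_series(
    r_conn: float,
    tube: TubeGeometry,
    fluid: FluidProperties,
    grid: PressureGrid | None = None,
    noise: float = 0.0,
    seed: int = 0,
) -> PhantomExperiment:
    """Rigid-phantom calibration series: Q = dp / (r_conn + r_phantom), plus noise."""
    grid = grid or PressureGrid()
    rng = np.random.default_rng(seed)
    r_total = r_conn + poiseuille_resistance(fluid, tube)
    flow = np.empty_like(grid.values)
    for i, dp in enumerate(grid.values):
        q = dp / r_total
        flow[i] = 0.0 if dp == 0 else _noisy(rng, q, noise, lower=0.0)
    return PhantomExperiment(tube=tube, dp_total=grid.values.copy(), flow=flow)
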