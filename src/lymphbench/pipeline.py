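"""End-to-end analysis: decomposition -> pressure map -> valve fit -> validation.

One fit per segment.  The connector resistance comes from a single phantom
calibration shared across segments.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace

import numpy as np

from .calibration import ConnectorCalibration
from .core import BenchSeries, FluidProperties, ResistanceSeries, decompose_resistance
from .errors import EmptySeriesError, InsufficientDataError, LymphBenchError
from .valve import (
    ThresholdSummary,
    ValveFit,
    coefficient_of_determination,
    fit_pressure_map,
    fit_valve_model,
    predict_flow,
    threshold_summary,
    valve_opening_threshold,
)

__all__ = ["FitOptions", "SegmentResult", "BenchAnalysis", "analyze_segment", "analyze_bench"]


@dataclass(frozen=True)
class FitOptions:
    """Knobs for the per-segment fit.

    ``use_pressure_map``: fit and validate the sigmoid against
    exponential-map-smoothed valve gradients instead of the raw decomposed
    ones.  The smoothing keeps noisy gradients positive but its model error
    biases the fitted parameters, so the default works on raw gradients;
    the map itself is always fitted (it is the forward-prediction input for
    unseen pressures).
    """

    objective: str = "linear"
    multistart: int = 5
    seed: int = 0
    use_pressure_map: bool = False
    diameter_convention: str = "printed"


@dataclass(frozen=True)
class SegmentResult:
    fit: ValveFit
    resistance: ResistanceSeries


@dataclass(frozen=True)
class BenchAnalysis:
    results: list[SegmentResult]
    skipped: list[tuple[str, str]]
    thresholds: ThresholdSummary


def analyze_segment(
    series: BenchSeries,
    r_conn: float | ConnectorCalibration,
    fluid: FluidProperties,
    options: FitOptions | None = None,
) -> SegmentResult:
    """Fit the valve model for one segment and validate by flow prediction."""
    options = options or FitOptions()
    if isinstance(r_conn, ConnectorCalibration):
        r_conn = r_conn.r_conn
    rs = decompose_resistance(series, r_conn, fluid, options.diameter_convention)
    if len(rs) < 3:
        raise InsufficientDataError(
            f"segment {series.segment.segment_id}: only {len(rs)} nonzero-flow steps, need >= 3"
        )
    pmap = fit_pressure_map(rs.dp_total, rs.dp_valve)
    dpv_for_fit = pmap(rs.dp_total) if options.use_pressure_map else rs.dp_valve
    model, r2_resistance = fit_valve_model(
        dpv_for_fit,
        rs.r_valve,
        objective=options.objective,
        multistart=options.multistart,
        seed=options.seed,
    )
    fit = ValveFit(
        segment_id=series.segment.segment_id,
        model=model,
        pressure_map=pmap,
        r_squared_resistance=r2_resistance,
        r_squared_flow=float("nan"),
        threshold=valve_opening_threshold(model),
    )
    q_pred = predict_flow(
        rs.dp_total,
        fit,
        r_conn,
        rs.r_vessel,
        dp_valve=None if options.use_pressure_map else rs.dp_valve,
    )
    fit = replace(fit, r_squared_flow=coefficient_of_determination(q_pred, rs.flow))
    return SegmentResult(fit=fit, resistance=rs)


def analyze_bench(
    series_list: list[BenchSeries],
    r_conn: float | ConnectorCalibration,
    fluid: FluidProperties,
    options: FitOptions | None = None,
) -> BenchAnalysis:
    """Analyze every segment; under-determined segments are skipped with a warning."""
    results: list[SegmentResult] = []
    skipped: list[tuple[str, str]] = []
    for series in series_list:
        try:
            results.append(analyze_segment(series, r_conn, fluid, options))
        except (EmptySeriesError, InsufficientDataError) as exc:
            warnings.warn(f"skipping segment {series.segment.segment_id}: {exc}", stacklevel=2)
            skipped.append((series.segment.segment_id, str(exc)))
    if not results:
        raise LymphBenchError("no segment could be analyzed")
    return BenchAnalysis(
        results=results,
        skipped=skipped,
        thresholds=threshold_summary([r.fit for r in results]),
    )
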