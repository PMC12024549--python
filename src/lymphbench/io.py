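"""Readers and writers for the canonical bench tables.

Canonical formats (UTF-8, header row, decimal point):

* bench CSV: ``segment_id, dp_total_cmH2O, Q_mL_min, Dout_mm``
* segment CSV: ``segment_id, ex_vivo_length_mm, stretch_ratio, wall_thickness_mm``
  (optional ``mounted_length_mm``)
* phantom CSV: ``dp_total_cmH2O, Q_mL_min``

A single-workbook spreadsheet reader accepts the same two segment tables as
sheets named ``bench`` and ``segments``.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .calibration import ConnectorCalibration, PhantomExperiment
from .core import BenchSeries, SegmentSpec, TubeGeometry
from .pipeline import BenchAnalysis

BENCH_COLUMNS = ["segment_id", "dp_total_cmH2O", "Q_mL_min", "Dout_mm"]
SEGMENT_COLUMNS = ["segment_id", "ex_vivo_length_mm", "stretch_ratio", "wall_thickness_mm"]
PHANTOM_COLUMNS = ["dp_total_cmH2O", "Q_mL_min"]


def _require_columns(df: pd.DataFrame, required: list[str], where: str) -> None:
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValueError(f"{where}: missing required column(s) {', '.join(missing)}")


def _segments_from_frame(df: pd.DataFrame, where: str) -> dict[str, SegmentSpec]:
    _require_columns(df, SEGMENT_COLUMNS, where)
    specs: dict[str, SegmentSpec] = {}
    for _, row in df.iterrows():
        sid = str(row["segment_id"])
        specs[sid] = SegmentSpec(
            segment_id=sid,
            ex_vivo_length_mm=float(row["ex_vivo_length_mm"]),
            stretch_ratio=float(row["stretch_ratio"]),
            wall_thickness_mm=float(row["wall_thickness_mm"]),
            mounted_length_mm=(
                float(row["mounted_length_mm"]) if "mounted_length_mm" in df.columns else None
            ),
        )
    return specs


def _series_from_frames(
    bench: pd.DataFrame, segments: dict[str, SegmentSpec], where: str
) -> list[BenchSeries]:
    _require_columns(bench, BENCH_COLUMNS, where)
    if bench.empty:
        raise ValueError(f"{where}: no data rows")
    out: list[BenchSeries] = []
    for sid, group in bench.groupby("segment_id", sort=False):
        sid = str(sid)
        if sid not in segments:
            raise ValueError(f"{where}: segment {sid!r} absent from the segment table")
        group = group.sort_values("dp_total_cmH2O")
        out.append(
            BenchSeries(
                segment=segments[sid],
                dp_total=group["dp_total_cmH2O"].to_numpy(float),
                flow=group["Q_mL_min"].to_numpy(float),
                d_out=group["Dout_mm"].to_numpy(float),
            )
        )
    return out


def read_segment_table(path: str | Path) -> dict[str, SegmentSpec]:
    return _segments_from_frame(pd.read_csv(path), str(path))


def read_bench_csv(bench_path: str | Path, segment_path: str | Path) -> list[BenchSeries]:
    """Load all segment series from the canonical bench + segment CSV pair."""
    segments = read_segment_table(segment_path)
    return _series_from_frames(pd.read_csv(bench_path), segments, str(bench_path))


def read_bench_workbook(
    path: str | Path, bench_sheet: str = "bench", segment_sheet: str = "segments"
) -> list[BenchSeries]:
    """Load segment series from a single spreadsheet with ``bench`` and ``segments`` sheets."""
    bench = pd.read_excel(path, sheet_name=bench_sheet)
    segments = _segments_from_frame(pd.read_excel(path, sheet_name=segment_sheet), str(path))
    return _series_from_frames(bench, segments, str(path))


def read_phantom_csv(path: str | Path, tube: TubeGeometry) -> PhantomExperiment:
    df = pd.read_csv(path)
    _require_columns(df, PHANTOM_COLUMNS, str(path))
    if df.empty:
        raise ValueError(f"{path}: no data rows")
    df = df.sort_values("dp_total_cmH2O")
    return PhantomExperiment(
        tube=tube,
        dp_total=df["dp_total_cmH2O"].to_numpy(float),
        flow=df["Q_mL_min"].to_numpy(float),
    )


def write_bench_csv(series_list: list[BenchSeries], bench_path: str | Path, segment_path: str | Path) -> None:
    rows = []
    for s in series_list:
        for dp, q, d in zip(s.dp_total, s.flow, s.d_out):
            rows.append({"segment_id": s.segment.segment_id, "dp_total_cmH2O": dp, "Q_mL_min": q, "Dout_mm": d})
    pd.DataFrame(rows, columns=BENCH_COLUMNS).to_csv(bench_path, index=False, float_format="%.8g")
    seg_rows = [
        {
            "segment_id": s.segment.segment_id,
            "ex_vivo_length_mm": s.segment.ex_vivo_length_mm,
            "stretch_ratio": s.segment.stretch_ratio,
            "wall_thickness_mm": s.segment.wall_thickness_mm,
            "mounted_length_mm": s.segment.mounted_length_mm,
        }
        for s in series_list
    ]
    pd.DataFrame(seg_rows).to_csv(segment_path, index=False, float_format="%.8g")


def write_phantom_csv(exp: PhantomExperiment, path: str | Path) -> None:
    pd.DataFrame({"dp_total_cmH2O": exp.dp_total, "Q_mL_min": exp.flow}).to_csv(
        path, index=False, float_format="%.8g"
    )


def calibration_to_json(calib: ConnectorCalibration, path: str | Path) -> None:
    Path(path).write_text(
        json.dumps(
            {
                "slope_cmH2O_min_per_mL": calib.slope,
                "intercept_cmH2O": calib.intercept,
                "r_squared_linear": calib.r_squared_linear,
                "r_phantom_cmH2O_min_per_mL": calib.r_phantom,
                "r_conn_cmH2O_min_per_mL": calib.r_conn,
            },
            indent=2,
        )
        + "\n"
    )


def calibration_from_json(path: str | Path) -> ConnectorCalibration:
    d = json.loads(Path(path).read_text())
    return ConnectorCalibration(
        slope=d["slope_cmH2O_min_per_mL"],
        intercept=d["intercept_cmH2O"],
        r_squared_linear=d["r_squared_linear"],
        r_phantom=d["r_phantom_cmH2O_min_per_mL"],
        r_conn=d["r_conn_cmH2O_min_per_mL"],
    )


def write_fit_table(analysis: BenchAnalysis, path: str | Path) -> None:
    """Fit-results CSV: one row per segment, >= 6 significant digits, Rvh in scientific notation."""
    rows = []
    for res in analysis.results:
        f = res.fit
        rows.append(
            {
                "segment_id": f.segment_id,
                "Rvl": f"{f.model.r_vl:.6g}",
                "Rvh": f"{f.model.r_vh:.6e}",
                "s": f"{f.model.s:.6g}",
                "P0": f"{f.pressure_map.p0:.6g}",
                "A": f"{f.pressure_map.a:.6g}",
                "threshold_cmH2O": f"{f.threshold:.6g}",
                "R2_resistance": f"{f.r_squared_resistance:.6g}",
                "R2_flow": f"{f.r_squared_flow:.6g}",
            }
        )
    pd.DataFrame(rows).to_csv(path, index=False)


def write_resistance_table(analysis: BenchAnalysis, path: str | Path) -> None:
    """Per-step resistance decomposition CSV across all analyzed segments."""
    rows = []
    for res in analysis.results:
        rs = res.resistance
        for i in range(len(rs)):
            rows.append(
                {
                    "segment_id": rs.segment.segment_id,
                    "dp_total_cmH2O": rs.dp_total[i],
                    "Q_mL_min": rs.flow[i],
                    "D_inner_mm": rs.inner_diameter[i],
                    "R_total": rs.r_total[i],
                    "R_conn": rs.r_conn,
                    "R_vessel": rs.r_vessel[i],
                    "R_valve": rs.r_valve[i],
                    "dp_conn_cmH2O": rs.dp_conn[i],
                    "dp_vessel_cmH2O": rs.dp_vessel[i],
                    "dp_valve_cmH2O": rs.dp_valve[i],
                }
            )
    pd.DataFrame(rows).to_csv(path, index=False, float_format="%.8g")


def analysis_summary(analysis: BenchAnalysis) -> dict:
    r2_res = np.array([r.fit.r_squared_resistance for r in analysis.results])
    r2_flow = np.array([r.fit.r_squared_flow for r in analysis.results])
    return {
        "n_segments": len(analysis.results),
        "skipped": [{"segment_id": sid, "reason": why} for sid, why in analysis.skipped],
        "threshold_cmH2O": {
            "per_segment": analysis.thresholds.per_segment.tolist(),
            "mean": analysis.thresholds.mean,
            "sd_population": analysis.thresholds.sd,
        },
        "r_squared_resistance": {"mean": float(r2_res.mean()), "sd": float(r2_res.std(ddof=0))},
        "r_squared_flow": {"mean": float(r2_flow.mean()), "sd": float(r2_flow.std(ddof=0))},
    }
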