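# lymphbench

Pressure–flow bench analysis of single-valve lymphatic duct segments.

A mounted duct segment perfused on a bench behaves as three hydraulic
resistances in series: the rigid connectors, the vessel lumen (Poiseuille),
and the valve. `lymphbench`:

* calibrates the constant **connector resistance** from a rigid-phantom
  experiment (linear pressure–flow fit, Poiseuille subtraction);
* **decomposes** each measured pressure step into connector, vessel, and
  valve contributions (`R_valve = R_total − R_conn − R_vessel`);
* fits a **logistic valve-resistance model**
  `R_valve(Δp) = R_vl + R_vh / (1 + exp(s·Δp))` per segment
  (Nelder–Mead on summed squared residuals, log-parameterized, multistart),
  plus an exponential map `Δp_valve = P0·exp(A·Δp_total)`;
* **validates** by forward flow prediction
  `Q = Δp_total / (R_conn + R_vessel + R_valve)` and the coefficient of
  determination;
* computes the **valve-opening threshold**
  `Δp_t = (1/s)·ln(R_vh / (0.05·R_vl))` and its across-segment mean ±
  population SD;
* **generates synthetic bench data** with known ground truth (saturating
  diameter–pressure law, self-consistent implicit flow solver, seeded
  multiplicative noise) so every stage is testable end to end.

Working units are the bench units throughout: cmH₂O, mL/min, mm, cP
(1 cmH₂O = 98.0665 Pa).

## CLI

```sh
# 1. synthesize a dataset (or bring your own CSVs, see below)
lymphbench simulate --out-dir data/ --seed 7 --segments reference

# 2. connector calibration from the phantom series
lymphbench calibrate --phantom data/phantom.csv --out calib.json

# 3. per-segment decomposition + valve-model fit + validation
lymphbench analyze --bench data/bench.csv --segments data/segments.csv \
    --calibration calib.json --out-dir results/

# 4. flow-prediction R^2 only, from an existing fit table
lymphbench validate --bench data/bench.csv --segments data/segments.csv \
    --calibration calib.json --fits results/fits.csv --out validate.json
```

`analyze` writes `fits.csv` (per-segment `Rvl, Rvh, s, P0, A,
threshold_cmH2O, R2_resistance, R2_flow`), `resistance_steps.csv` (per-step
decomposition), `summary.json` (threshold mean ± SD, R² summaries, skipped
segments), and a provenance record (config hash + version). Physical
defaults are surfaced as options (`--viscosity 0.7`, phantom 3 mm × 31 mm,
0–10 cmH₂O grid in 1-cmH₂O steps).

By default the sigmoid is fitted against the raw decomposed valve
gradients; `--pressure-map` fits it against the exponential-map-smoothed
gradients instead (useful when decomposed gradients are noisy or
non-positive).

### Input formats

CSV with header, UTF-8, decimal point:

* bench table: `segment_id, dp_total_cmH2O, Q_mL_min, Dout_mm`
* segment table: `segment_id, ex_vivo_length_mm, stretch_ratio,
  wall_thickness_mm` (optional `mounted_length_mm`)
* phantom table: `dp_total_cmH2O, Q_mL_min`

A single `.xlsx` workbook with sheets `bench` and `segments` is also
accepted (`lymphbench.io.read_bench_workbook`).

## Library sketch

```python
from lymphbench import (
    FluidProperties, PressureGrid, SyntheticGroundTruth, ValveResistanceModel,
    analyze_segment, calibrate_connector, generate_phantom_series,
    generate_segment_series,
)
from lymphbench.reference import reference_segment_spec

fluid = FluidProperties(0.7)
truth = SyntheticGroundTruth(
    valve=ValveResistanceModel(r_vl=0.088, r_vh=1.54e4, s=25.4),
    r_conn=0.393, segment=reference_segment_spec("TD1"), fluid=fluid,
)
series = generate_segment_series(truth, PressureGrid())
result = analyze_segment(series, truth.r_conn, fluid)
print(result.fit.model, result.fit.threshold, result.fit.r_squared_flow)
```
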