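"""Published reference values used as defaults and worked-example inputs.

Five fitted valve parameter sets for porcine thoracic-duct segments, the
phantom-setup slope, and the bench geometry defaults.  These are inputs to
worked examples and to the synthetic generator's "reference" mode, not
outputs of this package.
"""

from .core import FluidProperties, SegmentSpec, TubeGeometry
from .valve import ValveResistanceModel

#: Saline working fluid used on the bench.
REFERENCE_FLUID = FluidProperties(viscosity_cP=0.7)

#: Rigid phantom tube used for connector calibration.
REFERENCE_PHANTOM_TUBE = TubeGeometry(length_mm=31.0, inner_diameter_mm=3.0)

#: Fitted pressure-flow slope of the phantom setup [cmH2O.min/mL].
REFERENCE_PHANTOM_SLOPE = 0.395

#: Reported connector resistance [cmH2O.min/mL].
REFERENCE_R_CONN = 0.393

#: Fitted logistic valve parameters (r_vl, r_vh [cmH2O.min/mL], s [1/cmH2O])
#: for the five tested single-valve duct segments.
REFERENCE_VALVE_MODELS: dict[str, ValveResistanceModel] = {
    "TD1": ValveResistanceModel(r_vl=0.088, r_vh=1.54e4, s=25.4),
    "TD2": ValveResistanceModel(r_vl=0.085, r_vh=6.42e10, s=85.8),
    "TD3": ValveResistanceModel(r_vl=0.154, r_vh=6.33e7, s=28.5),
    "TD4": ValveResistanceModel(r_vl=0.011, r_vh=7.38e9, s=19.0),
    "TD5": ValveResistanceModel(r_vl=0.071, r_vh=9.09e2, s=14.5),
}

#: Reported mean wall thickness [mm] across tested segments.
REFERENCE_WALL_THICKNESS = 0.11

#: Bench mounting: segments stretched 30%; worked-example mounted length 40.3 mm.
REFERENCE_STRETCH_RATIO = 1.30
REFERENCE_MOUNTED_LENGTH = 40.3


def reference_segment_spec(segment_id: str) -> SegmentSpec:
    """A segment spec with the reference geometry (40.3 mm mounted, 0.11 mm wall)."""
    return SegmentSpec(
        segment_id=segment_id,
        ex_vivo_length_mm=REFERENCE_MOUNTED_LENGTH / REFERENCE_STRETCH_RATIO,
        wall_thickness_mm=REFERENCE_WALL_THICKNESS,
        stretch_ratio=REFERENCE_STRETCH_RATIO,
        mounted_length_mm=REFERENCE_MOUNTED_LENGTH,
    )
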