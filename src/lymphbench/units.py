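"""Unit conventions and conversions.

Canonical working units are the bench units: pressure in cmH2O, flow in
mL/min, lengths in mm, viscosity in cP, and hydraulic resistance in
cmH2O.min/mL.  Conversion to SI happens only where a physical law is
evaluated (Poiseuille resistance).
"""

PA_PER_CMH2O: float = 98.0665
"""Conventional water-column pressure: 1 cmH2O = 98.0665 Pa."""

PAS_PER_CP: float = 1e-3
"""1 cP = 1e-3 Pa.s."""

M3S_PER_ML_MIN: float = 1e-6 / 60.0
"""1 mL/min = (1e-6 / 60) m^3/s."""

M_PER_MM: float = 1e-3

#: Pa.s/m^3 per cmH2O.min/mL
RESISTANCE_SI_PER_BENCH: float = PA_PER_CMH2O / M3S_PER_ML_MIN


def resistance_to_si(r_bench: float) -> float:
    """Convert a hydraulic resistance from cmH2O.min/mL to Pa.s/m^3."""
    return r_bench * RESISTANCE_SI_PER_BENCH


def resistance_from_si(r_si: float) -> float:
    """Convert a hydraulic resistance from Pa.s/m^3 to cmH2O.min/mL."""
    return r_si / RESISTANCE_SI_PER_BENCH
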