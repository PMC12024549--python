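import numpy as np
import pytest

from lymphbench import (
    FluidProperties,
    PressureGrid,
    SegmentSpec,
    SyntheticGroundTruth,
    TubeGeometry,
    ValveResistanceModel,
)
from lymphbench.reference import (
    REFERENCE_VALVE_MODELS,
    reference_segment_spec,
)

R_CONN = 0.393


@pytest.fixture(scope="session")
def fluid() -> FluidProperties:
    return FluidProperties(viscosity_cP=0.7)


@pytest.fixture(scope="session")
def phantom_tube() -> TubeGeometry:
    return TubeGeometry(length_mm=31.0, inner_diameter_mm=3.0)


@pytest.fixture(scope="session")
def reference_models() -> dict[str, ValveResistanceModel]:
    return REFERENCE_VALVE_MODELS


@pytest.fixture
def segment_spec() -> SegmentSpec:
    return reference_segment_spec("TD1")


@pytest.fixture
def default_grid() -> PressureGrid:
    return PressureGrid()


@pytest.fixture
def make_truth(fluid):
    """Factory for synthetic ground truths with sensible bench defaults."""

    def _make(
        valve: ValveResistanceModel | None = None,
        segment_id: str = "SYN",
        r_conn: float = R_CONN,
        **kwargs,
    ) -> SyntheticGroundTruth:
        return SyntheticGroundTruth(
            valve=valve or ValveResistanceModel(r_vl=0.088, r_vh=1.54e4, s=25.4),
            r_conn=r_conn,
            segment=reference_segment_spec(segment_id),
            fluid=fluid,
            **kwargs,
        )

    return _make
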