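import pytest

from celltransit import AxisymChannel, CellModel, Plasma, RectChannel


@pytest.fixture
def control_channel() -> RectChannel:
    """Control rectangular channel: H = 8.2, R_con = 27.525, W_con = 4.368 um."""
    return RectChannel(H=8.2)


@pytest.fixture
def axisym_channel() -> AxisymChannel:
    return AxisymChannel()


@pytest.fixture
def cell() -> CellModel:
    return CellModel()


@pytest.fixture
def plasma() -> Plasma:
    return Plasma()
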