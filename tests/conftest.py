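import numpy as np
import pytest

from macscount import CameraModel, CellGeometry, DetectionConfig, OpticsModel


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def cell():
    """A typical unpressed rod: 3 x 0.9 um spherocylinder."""
    return CellGeometry(length=3.0, width=0.9, center=(2.0, 1.0))


@pytest.fixture
def pressed_cell(cell):
    return cell.pressed_twin()


@pytest.fixture
def optics():
    return OpticsModel()


@pytest.fixture
def bright_optics():
    """High-SNR optics for detection-quality checks."""
    return OpticsModel(photons_per_molecule=400.0)


@pytest.fixture
def camera():
    return CameraModel()


@pytest.fixture
def detection():
    return DetectionConfig()
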