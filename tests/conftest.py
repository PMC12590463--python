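import numpy as np
import pytest

from pifir.axes import WavenumberAxis
from pifir.components import default_components
from pifir.scene import (
    make_cell_scene,
    make_hyperspectral_scene,
    render_hyperspectrum,
    sample_point_spectra,
)


@pytest.fixture(scope="session")
def axis():
    return WavenumberAxis(900.0, 1800.0, 1.0)


@pytest.fixture(scope="session")
def components(axis):
    return default_components(axis)


@pytest.fixture(scope="session")
def treated_scene():
    return make_cell_scene("treated", seed=11)


@pytest.fixture(scope="session")
def control_scene():
    return make_cell_scene("control", seed=12)


@pytest.fixture(scope="session")
def labeled_set(treated_scene, control_scene):
    """Default 51 treated / 13 control labelled point-spectra set."""
    spectra, truth = sample_point_spectra(treated_scene, control_scene, seed=13)
    return spectra, truth


@pytest.fixture(scope="session")
def hyper_scene():
    return make_hyperspectral_scene(seed=21)


@pytest.fixture(scope="session")
def hyper_cube(hyper_scene):
    return render_hyperspectrum(hyper_scene, seed=22)


@pytest.fixture(scope="session")
def quiet_scene():
    """Treated scene with noise, anisotropy and envelope all disabled."""
    from pifir.scene import IlluminationSpec

    return make_cell_scene(
        "treated",
        seed=31,
        illumination=IlluminationSpec(strength=0.0),
        noise=dict(mult_sigma=0.0, add_sigma=0.0),
        power_envelope=False,
    )
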