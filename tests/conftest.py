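import numpy as np
import pytest

from fireflysim.instrument import InstrumentModel
from fireflysim.scene import default_scene_config, make_scene_cube
from fireflysim.sif import default_sif_params


@pytest.fixture(scope="session")
def instrument():
    return InstrumentModel()


@pytest.fixture(scope="session")
def sif_params():
    return default_sif_params()


@pytest.fixture(scope="session")
def noisefree_scene():
    """Default calibrated vegetation scene (24 pixels), noise off."""
    return make_scene_cube(default_scene_config(noise_on=False))


@pytest.fixture(scope="session")
def veg36_scene():
    """36 vegetation pixels, noise off (aggregation experiments)."""
    cfg = default_scene_config(n_vegetation=36, panels=False, noise_on=False)
    return make_scene_cube(cfg)


@pytest.fixture(scope="session")
def scan_records(instrument):
    from fireflysim.calibration import simulate_scan
    return simulate_scan(instrument, seed=3)


@pytest.fixture(scope="session")
def asr_curves(scan_records):
    from fireflysim.calibration import estimate_asr
    return estimate_asr(scan_records)
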