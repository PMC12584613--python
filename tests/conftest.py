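import numpy as np
import pytest

import ramanquant as rq
from ramanquant.synthetic import SceneTruth


@pytest.fixture
def interface_spectrum_noiseless():
    """Default gas-solid interface spectrum at 50 mmol/L, no noise/baseline."""
    bands = rq.default_interface_bands(50.0, carotenoid_level=1.0, s8_level=1.0)
    return rq.simulate_spectrum(SceneTruth(bands=bands))


@pytest.fixture
def paper_model():
    """Calibration model with the published coefficients."""
    return rq.CalibrationModel(
        slope=0.01802, intercept=-0.04239, r_squared=0.99938, conc_range=(25.0, 75.0)
    )


@pytest.fixture
def tiny_spectrum():
    return rq.Spectrum([100.0, 200.0, 300.0], [1.5, 2.5, 3.5], {"label": "tiny"})
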