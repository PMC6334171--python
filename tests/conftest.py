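import numpy as np
import pytest

from kdnaquant.dye_response import fit_response
from kdnaquant.synthetic import (
    DAPI_TRUTH,
    REDDOT1_TRUTH,
    OpticsSpec,
    make_species_cell,
    render_field,
    simulate_calibration,
)

TRUTHS = [DAPI_TRUTH, REDDOT1_TRUTH]
AT_SERIES = list(np.linspace(0.0, 1.0, 21))


@pytest.fixture(scope="session")
def calibration_records():
    """Noise-free 21-oligo calibration series for both dyes."""
    return simulate_calibration(TRUTHS, AT_SERIES, noise_sd=0.0, seed=0)


@pytest.fixture(scope="session")
def reddot_model(calibration_records):
    return fit_response(calibration_records, "RedDot1")


@pytest.fixture(scope="session")
def dapi_model(calibration_records):
    return fit_response(calibration_records, "DAPI")


@pytest.fixture(scope="session")
def clean_optics():
    """Noise-free analog optics: exact forward model, 1 px blur."""
    return OpticsSpec(shot_noise=False, read_noise_sd=0.0, digitize=False)


@pytest.fixture(scope="session")
def tbrucei_field(clean_optics):
    """Noise-free trypanosome-like field (nominal amounts) with ground truth."""
    cell = make_species_cell("T_brucei")
    return render_field([cell], TRUTHS, clean_optics, seed=0)
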