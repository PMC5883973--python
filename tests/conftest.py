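import numpy as np
import pytest

from calfnmr.library import load_library
from calfnmr.processing import process_fid
from calfnmr.simulate import AcquisitionParams, synthesize_fid


@pytest.fixture(scope="session")
def library():
    return load_library()


@pytest.fixture(scope="session")
def quiet_params():
    """Noise- and jitter-free CPMG acquisition for deterministic checks."""
    return AcquisitionParams(
        experiment="cpmg", noise_sd=0.0, shift_jitter_sd_ppm=0.0, peak_jitter_sd_ppm=0.0
    )


def make_spectrum(library, concentrations, params=None, seed=0, phase=True, lb_hz=0.3):
    """Synthesize and fully process one sample."""
    params = params or AcquisitionParams(experiment="cpmg")
    fid = synthesize_fid(concentrations, library, params, seed=seed)
    return process_fid(fid, lb_hz=lb_hz, phase=phase)


@pytest.fixture(scope="session")
def ha_mean_concentrations(library):
    return {m.name: m.group_distributions["Ha"][0] for m in library.metabolites}
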