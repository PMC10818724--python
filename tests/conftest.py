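import numpy as np
import pytest

import ramanratio as rr


@pytest.fixture(scope="session")
def clean_params() -> rr.PhantomParams:
    """Noise-free, gain-free phantom parameters."""
    return rr.PhantomParams(noise_sd=0.0, intensity_scale_sd=0.0)


@pytest.fixture(scope="session")
def default_params() -> rr.PhantomParams:
    return rr.PhantomParams()


@pytest.fixture(scope="session")
def clean_spectrum_317(clean_params) -> rr.Spectrum:
    """One noise-free acquisition planted at the treated-group mean ratio."""
    return rr.generate_spectrum(clean_params, 3.17, seed=7)


@pytest.fixture(scope="session")
def planted_centers() -> np.ndarray:
    return np.array(sorted(rr.REFERENCE_CLASS_TABLE))
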