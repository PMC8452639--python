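import numpy as np
import pytest

from spectraldcm import CMCParameters, FitSettings


@pytest.fixture(scope="session")
def default_params() -> CMCParameters:
    return CMCParameters()


@pytest.fixture(scope="session")
def coarse_settings() -> FitSettings:
    """Reduced fit grid for fast inversions in tests (1-100 Hz, 2 Hz step)."""
    return FitSettings(freq_range=(1.0, 100.0), freq_step=2.0, max_iter=64)


@pytest.fixture(scope="session")
def fit_freqs(coarse_settings) -> np.ndarray:
    return coarse_settings.freqs
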