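import numpy as np
import pytest

from libsquant import SimConfig, area_normalize, generate_dataset


@pytest.fixture(scope="session")
def small_config():
    """Desk-scale config: 48 samples, 401 channels over the full span at a
    2 nm step (wider 1 nm lines so every line still lands on the grid)."""
    return SimConfig(
        n_per_group=6,
        wl_step=2.0,
        sigma=1.0,
        n_shots=8,
        matrix_lines=((285.21, 400.0), (393.37, 800.0)),
    )


@pytest.fixture(scope="session")
def small_dataset(small_config):
    spectra, conc = generate_dataset(small_config, seed=7)
    return area_normalize(spectra), conc


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
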