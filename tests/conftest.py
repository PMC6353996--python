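import numpy as np
import pytest

from fpolimg import CellFieldSpec, generate_polarized_pair


@pytest.fixture(scope="session")
def noiseless_field():
    """Small noiseless two-compartment field with exact ground truth."""
    spec = CellFieldSpec(
        image_shape=(256, 256), n_cells=12, noise_model="none",
        fpol_nucleus=0.24, fpol_cytoplasm=0.20, g_factor=0.75, seed=7,
    )
    pair, labels, truth = generate_polarized_pair(spec)
    return spec, pair, labels, truth


@pytest.fixture(scope="session")
def poisson_field():
    """Photon-noise field used by the recovery checks."""
    spec = CellFieldSpec(
        image_shape=(512, 512), n_cells=100, noise_model="poisson",
        fpol_nucleus=0.24, fpol_cytoplasm=0.20, g_factor=0.75,
        total_intensity=150.0, seed=4,
    )
    pair, labels, truth = generate_polarized_pair(spec)
    return spec, pair, labels, truth


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
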