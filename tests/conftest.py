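import numpy as np
import pytest

from ohcquant.synthetic import SyntheticCellSpec, generate_cell_image


@pytest.fixture(scope="session")
def noiseless_cell():
    """Bent cell, NE enrichment k=3, no noise: masks and intensities exact."""
    spec = SyntheticCellSpec(
        axis_curvature=0.3, true_relative_position=0.75,
        ne_enrichment_factor=3.0, photon_scaling=0.0, gaussian_sd=0.0,
    )
    return spec, *generate_cell_image(spec, seed=1)


@pytest.fixture(scope="session")
def noisy_cell():
    """Bent cell with default Poisson+Gaussian noise and k=3 enrichment."""
    spec = SyntheticCellSpec(
        axis_curvature=0.3, true_relative_position=0.75, ne_enrichment_factor=3.0,
    )
    return spec, *generate_cell_image(spec, seed=7)


@pytest.fixture()
def rng():
    return np.random.default_rng(20260920)
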