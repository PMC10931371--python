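import numpy as np
import pytest

from nanouptake import (
    make_confocal_fixture,
    make_raman_fixture,
)


@pytest.fixture(scope="session")
def noiseless_raman():
    """Small noiseless 3-component cube with pure pixels."""
    return make_raman_fixture(
        grid=(30, 30),
        n_z=1,
        snr=np.inf,
        baseline_degree=0,
        spike_fraction=0.0,
        seed=11,
    )


@pytest.fixture(scope="session")
def noisy_raman():
    """Default single-cell-scan cube: baseline, shot noise, spikes."""
    return make_raman_fixture(seed=1)


@pytest.fixture(scope="session")
def confocal_fixture():
    """Mid-concentration confocal scene, full default geometry."""
    return make_confocal_fixture(n_cells=20, concentration=15.63, seed=3)


@pytest.fixture(scope="session")
def small_confocal():
    """Fast small field for segmentation tests."""
    return make_confocal_fixture(
        image_shape=(256, 256), n_cells=8, concentration=7.81, seed=5
    )
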