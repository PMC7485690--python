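import numpy as np
import pytest

from nucleotrack.presets import get_preset
from nucleotrack.synthetic import (
    AcquisitionConfig,
    CellGeometry,
    MotionModel,
    Photophysics,
    simulate_trajectories,
)


@pytest.fixture(scope="session")
def smc_trajectories():
    """Two-state Smc-like trajectories under recovery conditions, ~10^4 steps."""
    p = get_preset("Smc-YFP")
    model, geom, phot = p.recovery_conditions()
    trajset, truth = simulate_trajectories(model, geom, phot, p.acquisition(), 1400, seed=7)
    return trajset, truth, p


@pytest.fixture(scope="session")
def single_state_steps():
    """Pure single-population diffusion (D = 0.21, 10 ms), unconfined, ~2e4 steps."""
    model = MotionModel.single(0.21)
    geom = CellGeometry.unconfined_proxy()
    phot = Photophysics(localization_sigma=0.0)
    acq = AcquisitionConfig(frame_interval=0.010)
    trajset, _ = simulate_trajectories(model, geom, phot, acq, 900, seed=11)
    return trajset


def render_gaussian_spot(shape, row, col, sigma=1.0, amplitude=1000.0, background=0.0):
    """Noise-free 2D Gaussian test image (pixel centres at integers)."""
    rr, cc = np.mgrid[0:shape[0], 0:shape[1]]
    img = amplitude * np.exp(-((rr - row) ** 2 + (cc - col) ** 2) / (2 * sigma**2))
    return img + background
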