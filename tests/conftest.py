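import numpy as np
import pytest

from spineqct.synthetic import (GridSpec, LinearHUMap, PhantomSpec, VertebraSpec,
                                default_muscles, render_session)

IDENTITY_CAL = LinearHUMap(1.0, 0.0)


@pytest.fixture(scope="session")
def grid():
    return GridSpec()


@pytest.fixture(scope="session")
def noiseless_scene(grid):
    """One noiseless session rendered with the identity calibration."""
    rng = np.random.default_rng(0)
    vol, labels, legend = render_session(
        VertebraSpec(), default_muscles(), PhantomSpec(), IDENTITY_CAL,
        noise_sd=0.0, rng=rng, grid=grid,
    )
    return vol, labels, legend


@pytest.fixture(scope="session")
def noisy_scene(grid):
    """Same anatomy with the default 10 HU noise."""
    rng = np.random.default_rng(1)
    vol, labels, legend = render_session(
        VertebraSpec(), default_muscles(), PhantomSpec(), IDENTITY_CAL,
        noise_sd=10.0, rng=rng, grid=grid,
    )
    return vol, labels, legend
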