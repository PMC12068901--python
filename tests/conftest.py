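import numpy as np
import pytest

import habsens as h


@pytest.fixture(scope="session")
def landscape_low():
    """Uncorrelated-landscape replicate (both covariates fract_dim=0.01)."""
    return h.make_landscape_set(128, 0.01, 0.01, seed=11)


@pytest.fixture(scope="session")
def landscape_smooth():
    """Highly autocorrelated landscape (both covariates fract_dim=1)."""
    return h.make_landscape_set(128, 1.0, 1.0, seed=11)


@pytest.fixture(scope="session")
def homog64():
    """Spatially homogeneous landscape: selection weights cancel."""
    return h.uniform_landscape_set(64)


@pytest.fixture(scope="session")
def track_mid(landscape_low):
    """2000-fix selection-driven track on the uncorrelated landscape."""
    params = h.SelectionParams(omega_elev=2.0, omega_hab=-2.0)
    return h.simulate_track(landscape_low, params, 200_000, keep_every=100,
                            seed=7, animal_id="mid")


def make_rigid_track(xs, ys, animal_id="toy"):
    xs = np.asarray(xs)
    return h.Track(animal_id=animal_id, times=np.arange(1, len(xs) + 1),
                   xs=xs, ys=np.asarray(ys))
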