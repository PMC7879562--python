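import numpy as np
import pytest

import pixtraj as px


@pytest.fixture
def rng():
    return np.random.default_rng(20260925)


@pytest.fixture
def stationary_bundle():
    """Stationary emitter, Gaussian optics, 60x60 6.5 um detector, 100x."""
    return px.example_bundle(D=0.0, f=0.0, n_photons=3)


@pytest.fixture
def moving_bundle():
    """Drifting, diffusing molecule (OU) on the same detector."""
    return px.example_bundle()


@pytest.fixture
def half_plane_bundle():
    """Two giant pixels splitting the plane at the image of x0; unit M.

    The emitter sits exactly on the boundary, so each photon hits either
    pixel with probability 1/2 -- the textbook multinomial fixture.
    """
    x0 = (0.4, 0.2)
    big = 1e4
    motion = px.MotionModel.stationary(x0)
    optics = px.OpticalMap(px.Gaussian2D(0.1), M=1.0)
    arrivals = px.ArrivalProcess(0.0, 0.02, rate=150.0)
    grid = px.PixelGrid(n_rows=1, n_cols=2, pixel_width=big,
                        pixel_height=2 * big,
                        origin=(x0[0] - big, x0[1] - big))
    return px.ModelBundle(motion=motion, optics=optics, arrivals=arrivals,
                          grid=grid)
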