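import numpy as np
import pytest

from octasv.phantom import PhantomSpec, Tube, default_phantom_spec, simulate


@pytest.fixture(scope="session")
def small_phantom():
    """Motion-free phantom with one vessel per plexus, shared across tests."""
    spec = PhantomSpec(S=16, R=4, Z=64, X=64, seed=7)
    spec.vessels = [
        Tube(points=[(0, 15.0, 20.0), (15, 15.0, 26.0)], radius_px=2.0, plexus="SVP"),
        Tube(points=[(0, 34.0, 44.0), (15, 34.0, 40.0)], radius_px=1.5, plexus="DVP",
             reflectance=0.9),
    ]
    vol, truth = simulate(spec)
    return spec, vol, truth


@pytest.fixture(scope="session")
def default_phantom():
    """The study-condition phantom (motion on, randomized vessels), seed 0."""
    spec = default_phantom_spec(0)
    vol, truth = simulate(spec)
    return spec, vol, truth


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
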