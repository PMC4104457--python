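import numpy as np
import pytest

from vfinger import Camera, PhantomSpec, make_phantom


@pytest.fixture
def cam_z():
    """Identity camera: view along +z, screen = (x, y)."""
    return Camera.identity()


@pytest.fixture
def cam_x():
    """Side view along +x, screen = (y, z)."""
    return Camera(np.array([[0.0, 1, 0], [0, 0, 1], [1, 0, 0]]))


@pytest.fixture(scope="session")
def blob_phantom():
    spec = PhantomSpec("blob", sigma=2.0, params={"center": (16, 16, 16)})
    return make_phantom(spec, (32, 32, 32))


@pytest.fixture(scope="session")
def tube_phantom():
    """Noiseless straight tube along x at y=z=16."""
    return make_phantom(PhantomSpec("straight-tube"), (48, 32, 32))


@pytest.fixture(scope="session")
def helix_phantom():
    """Noiseless helical arc (radius 8, pitch 10)."""
    return make_phantom(PhantomSpec("helix-tube"), (64, 64, 48))


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
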