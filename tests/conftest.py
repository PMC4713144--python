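"""Shared fixtures: small phantoms generated once per session."""

import numpy as np
import pytest

from thrombodens.image_core import RigidTransform
from thrombodens.phantom import PhantomSpec, generate_phantom


SMALL = dict(shape=(64, 64, 64), spacing=(1.25, 1.25, 1.25))


def small_spec(**kw):
    base = dict(SMALL)
    base.update(kw)
    return PhantomSpec(**base)


@pytest.fixture(scope="session")
def default_phantom():
    """Default-parameter phantom at reduced grid size, with misalignment."""
    spec = small_spec(
        seed=11,
        misalignment=RigidTransform((2.0, -1.5, 1.0), (2.0, -1.5, 1.0), (39.375,) * 3),
    )
    return generate_phantom(spec)


@pytest.fixture(scope="session")
def noiseless_phantom():
    """Noise-free, blur-free phantom with a uniform 45 HU thrombus."""
    spec = small_spec(
        seed=5,
        noise_sd=0.0,
        blur_fwhm_mm=0.0,
        density_components=((1.0, 45.0, 0.0),),
    )
    return generate_phantom(spec)


@pytest.fixture(scope="session")
def heterogeneous_phantom():
    """Two-component mixture phantom (no misalignment) for observer tests."""
    spec = small_spec(
        seed=23,
        density_components=((0.6, 30.0, 5.0), (0.4, 60.0, 5.0)),
    )
    return generate_phantom(spec)


def dice(a, b) -> float:
    a = np.asarray(a, bool)
    b = np.asarray(b, bool)
    return 2.0 * np.logical_and(a, b).sum() / (a.sum() + b.sum())
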