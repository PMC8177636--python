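import numpy as np
import pytest

from nuctract.contour import Contour
from nuctract.elasticity import ElasticParams
from nuctract.synth import make_shape


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def circle():
    return make_shape("circle", radius=5.0, n_points=200)


@pytest.fixture
def small_circle():
    return make_shape("circle", radius=5.0, n_points=48)


@pytest.fixture
def ellipse():
    return make_shape("ellipse", a=5.0, b=3.0, n_points=200)


@pytest.fixture
def params():
    return ElasticParams()


@pytest.fixture
def gl_params():
    return ElasticParams(strain_convention="green-lagrange")


def star_polygon(rng, n=10, r_lo=1.0, r_hi=3.0):
    """Random star-shaped polygon about the origin (always simple)."""
    radii = rng.uniform(r_lo, r_hi, size=n)
    th = -np.pi + 2.0 * np.pi * np.arange(n) / n
    return Contour(np.column_stack([radii * np.cos(th), radii * np.sin(th)]))
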