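import numpy as np
import pytest

from sarscan.geometry import BoundingBox, ContactSurface, CoordinateFrame, Point3
from sarscan.simulator import (
    ApplicatorModel,
    DiodeSensor,
    SessionNoise,
    applicator_preset,
)


@pytest.fixture
def frame():
    return CoordinateFrame(origin_in_robot=Point3(25.0, 25.0, 20.0), z_sign_flip=True)


@pytest.fixture
def flat_surface():
    return ContactSurface(kind="flat")


@pytest.fixture
def cylinder_surface():
    return ContactSurface(kind="cylinder", radius=17.5)


@pytest.fixture
def xy_bbox():
    return BoundingBox(x=(-16.0, 16.0), y=(-12.0, 12.0))


@pytest.fixture
def sensor():
    return DiodeSensor(a=0.02, b=0.5, c=0.0)


@pytest.fixture
def no_noise():
    return SessionNoise.none()


@pytest.fixture
def model_5h():
    return applicator_preset("5H")


@pytest.fixture
def model_3h():
    return applicator_preset("3H")


@pytest.fixture
def centred_separable():
    """Separable (kappa=0) field centred at the origin: every closed form holds."""
    return applicator_preset("5H", centre_offset=(0.0, 0.0), kappa=0.0)


def gaussian_plane_grid(sigma_x, sigma_y, centre=(0.0, 0.0), half=(16.0, 16.0)):
    """Directly constructed 0.1 cm grid of a centred 2-D Gaussian, percent units."""
    from sarscan.metrics import GRID_SPACING, RelativeSARGrid

    u = np.round(np.arange(-half[0], half[0] + 1e-9, GRID_SPACING), 10)
    v = np.round(np.arange(-half[1], half[1] + 1e-9, GRID_SPACING), 10)
    uu, vv = np.meshgrid(u, v, indexing="ij")
    vals = 100.0 * np.exp(
        -((uu - centre[0]) ** 2) / (2 * sigma_x**2)
        - ((vv - centre[1]) ** 2) / (2 * sigma_y**2)
    )
    return RelativeSARGrid(
        u=u, v=v, values=vals, mask=np.zeros_like(vals, dtype=bool)
    )
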