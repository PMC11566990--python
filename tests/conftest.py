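import numpy as np
import pytest

from synquant.scenegen import Scene, generate_scene, make_preset
from synquant.segment import CellGeometry


def _disk_geometry(shape, center, radius) -> CellGeometry:
    """Analytic circular-cell geometry (no segmentation), for closed-form
    checks of the radial and quadrant operators."""
    yy, xx = np.mgrid[0 : shape[0], 0 : shape[1]].astype(float)
    r = np.hypot(yy - center[0], xx - center[1])
    mask = r <= radius
    ang = np.linspace(0, 2 * np.pi, 720, endpoint=False)
    poly = np.stack(
        [center[0] + radius * np.sin(ang), center[1] + radius * np.cos(ang)], axis=1
    )
    return CellGeometry(
        cell_mask=mask,
        contour=poly,
        centroid=tuple(center),
        equivalent_radius_px=float(np.sqrt(mask.sum() / np.pi)),
        boundary_angles=ang,
        boundary_radii=np.full(720, float(radius)),
    )


def _single_channel_scene(img, role, pixel_size_um=0.1) -> Scene:
    return Scene(
        planes=np.asarray(img, dtype=float)[None, None],
        channel_roles={0: role},
        pixel_size_um=pixel_size_um,
    )


@pytest.fixture
def disk_geometry():
    return _disk_geometry


@pytest.fixture
def channel_scene():
    return _single_channel_scene


@pytest.fixture(scope="session")
def soluble_scene():
    return generate_scene(make_preset("control_soluble_10min", seed=42))


@pytest.fixture(scope="session")
def ko_soluble_scene():
    return generate_scene(make_preset("ko_soluble_10min", seed=42))


@pytest.fixture(scope="session")
def bead_scene():
    return generate_scene(make_preset("ko_bead", seed=42))
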