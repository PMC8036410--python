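import math

import numpy as np
import pytest

from spheromorph import Mask2D, Mask3D, PhantomSpec, make_phantom_3d


@pytest.fixture(scope="session")
def disk_mask():
    """Rasterized disk of radius 100 px, 1 µm pixels."""
    n = 221
    yy, xx = np.mgrid[:n, :n]
    c = (n - 1) / 2
    return Mask2D((yy - c) ** 2 + (xx - c) ** 2 <= 100**2, pixel_size=(1.0, 1.0))


@pytest.fixture(scope="session")
def sphere_mask():
    """Voxelized sphere of radius 50 voxels, 1 µm spacing."""
    n = 110
    zz, yy, xx = np.mgrid[:n, :n, :n]
    c = (n - 1) / 2
    data = (zz - c) ** 2 + (yy - c) ** 2 + (xx - c) ** 2 <= 50**2
    return Mask3D(data, spacing=(1.0, 1.0, 1.0))


@pytest.fixture(scope="session")
def noisy_sphere_phantom():
    """Bivariate sphere phantom (r = 80 µm, anisotropic spacing, SNR 6)."""
    spec = PhantomSpec(shape="sphere", axes=(80.0, 80.0, 80.0),
                       spacing=(2.0, 1.3, 1.3), seed=11)
    return make_phantom_3d(spec)


def rasterize_ellipsoid_mask(axes_um, spacing, margin_um=15.0):
    """Axis-aligned solid ellipsoid mask (helper for descriptor tests)."""
    ax, ay, az = axes_um
    sz, sy, sx = spacing
    nz = int(math.ceil(2 * (az + margin_um) / sz))
    ny = int(math.ceil(2 * (ay + margin_um) / sy))
    nx = int(math.ceil(2 * (ax + margin_um) / sx))
    z = (np.arange(nz) + 0.5) * sz - (az + margin_um)
    y = (np.arange(ny) + 0.5) * sy - (ay + margin_um)
    x = (np.arange(nx) + 0.5) * sx - (ax + margin_um)
    zz, yy, xx = np.meshgrid(z, y, x, indexing="ij")
    inside = (xx / ax) ** 2 + (yy / ay) ** 2 + (zz / az) ** 2 <= 1.0
    return Mask3D(inside, spacing=spacing)
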