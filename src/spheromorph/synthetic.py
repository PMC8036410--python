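"""Seeded phantoms with analytic ground truth.

Every pipeline stage can be exercised without microscope data by
rasterizing simple solids whose volume, surface, moment-equivalent axes and
extents are known in closed form:

* ``sphere`` / ``ellipsoid`` — axis-aligned or rotated solid ellipsoids;
* ``half_sphere`` — a hemisphere resting flat-side-down, the shape young
  self-aggregated spheroids adopt on the plate bottom;
* ``flat_bottom_cap`` — the upper half of an oblate spheroid, emulating the
  late-stage regime where the top flattens and the aggregate grows in
  diameter but not in height.

Intensity models follow the two gray-level structures seen in light-sheet
stacks: ``bivariate`` (dark background + homogeneous object) and
``trivariate`` (dark background + bright peripheral rim + dimmer core,
reflecting the higher cell density of the peripheral layers).  Additive
Gaussian noise is drawn from a seeded generator; identical specs with
identical seeds produce bit-identical stacks.

Ground truth is always computed from the closed forms, never from the
rasterized mask, so recovery tests are genuine.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional

import numpy as np
from scipy.spatial.transform import Rotation

from .io import Image2D, Mask2D, Mask3D, VoxelGrid
from .morpho3d import EllipsoidAxes, eccentricities, roundness_3d, sphericity_3d

UM3_PER_MM3 = 1.0e9
UM2_PER_MM2 = 1.0e6

#: sqrt(5 * var_z) / C for a uniform half-ellipsoid of height C resting on
#: its flat face: var_z = 19 C^2 / 320.
_HALF_MOMENT_FACTOR = math.sqrt(95.0 / 320.0)


@dataclass
class PhantomSpec:
    """Recipe for one synthetic stack.

    axes
        Semi-axes (a, b, c) in µm along (x, y, z) before rotation.  For
        ``sphere`` all three must be equal; for the flat-bottomed shapes
        ``c`` is the height and rotation is not supported (the flat face
        defines z).
    levels
        (background, core, rim) gray levels in a.u.; the bivariate model
        uses ``core`` for the whole object.
    rim_fraction
        Thickness of the bright rim as a fraction of the normalized
        ellipsoidal radius (trivariate model only).
    margin_um
        Background padding around the shape on every side.
    rotation_deg
        Optional extrinsic XYZ Euler angles for sphere/ellipsoid phantoms.
    """

    shape: str = "sphere"
    axes: tuple[float, float, float] = (250.0, 250.0, 250.0)
    spacing: tuple[float, float, float] = (2.0, 1.3, 1.3)
    intensity_model: str = "bivariate"
    levels: tuple[float, float, float] = (30.0, 600.0, 600.0)
    rim_fraction: float = 0.25
    noise_sigma: float = 95.0
    seed: int = 0
    margin_um: float = 25.0
    rotation_deg: Optional[tuple[float, float, float]] = None

    def __post_init__(self) -> None:
        if self.shape not in ("sphere", "ellipsoid", "half_sphere", "flat_bottom_cap"):
            raise ValueError(f"unknown shape {self.shape!r}")
        if any(a <= 0 for a in self.axes):
            raise ValueError("axes must be positive")
        if self.shape == "sphere" and len(set(self.axes)) != 1:
            raise ValueError("sphere requires equal axes")
        if not 0 <= self.rim_fraction < 1:
            raise ValueError("rim_fraction must be in [0, 1)")
        if self.noise_sigma < 0:
            raise ValueError("noise_sigma must be >= 0")
        bg, core, _rim = self.levels
        if self.noise_sigma > 0 and core - bg < 3.0 * self.noise_sigma:
            raise ValueError(
                "object level must exceed background by >= 3 x noise_sigma"
            )
        if self.rotation_deg is not None and self.shape in ("half_sphere", "flat_bottom_cap"):
            raise ValueError("flat-bottomed shapes cannot be rotated")

    @property
    def is_half(self) -> bool:
        return self.shape in ("half_sphere", "flat_bottom_cap")


@dataclass
class GroundTruth:
    """Analytic truth for one phantom (mask is the ideal rasterization)."""

    mask: Mask3D
    true_volume_mm3: float
    true_surface_mm2: float
    true_axes: EllipsoidAxes
    true_e1: float
    true_e2: float
    true_sphericity: float
    true_roundness: float
    true_thickness_um: float
    true_diameter_um: float


def _ellipsoid_surface_um2(a: float, b: float, c: float) -> float:
    """Thomsen approximation (p = 1.6075), exact-enough (<1.1% worst case)."""
    p = 1.6075
    return 4.0 * math.pi * (((a * b) ** p + (a * c) ** p + (b * c) ** p) / 3.0) ** (1.0 / p)


def _oblate_surface_um2(a: float, c: float) -> float:
    """Closed-form surface of an oblate spheroid (a = b >= c)."""
    if abs(a - c) < 1e-12 * a:
        return 4.0 * math.pi * a * a
    e = math.sqrt(1.0 - c * c / (a * a))
    return 2.0 * math.pi * a * a + math.pi * (c * c / e) * math.log((1 + e) / (1 - e))


def _analytic_truth(spec: PhantomSpec, mask: Mask3D) -> GroundTruth:
    ax, ay, az = spec.axes  # semi-axes along x, y, z
    if spec.is_half:
        if not (ax == ay and ax >= az):
            raise ValueError("flat-bottomed shapes need ax == ay >= az")
        vol_um3 = (2.0 / 3.0) * math.pi * ax * ay * az
        surf_um3 = 0.5 * _oblate_surface_um2(ax, az) + math.pi * ax * ay
        # moment-equivalent semi-axes of a uniform half-ellipsoid
        semis = sorted([ax, ay, _HALF_MOMENT_FACTOR * az], reverse=True)
        thickness = az
        diameter = 2.0 * ax
    else:
        vol_um3 = (4.0 / 3.0) * math.pi * ax * ay * az
        if ax == ay:
            surf_um3 = _oblate_surface_um2(ax, az) if ax >= az else _ellipsoid_surface_um2(ax, ay, az)
        else:
            surf_um3 = _ellipsoid_surface_um2(ax, ay, az)
        semis = sorted([ax, ay, az], reverse=True)
        d = np.diag(np.array([ax, ay, az], dtype=float))
        rot = (Rotation.from_euler("xyz", spec.rotation_deg, degrees=True).as_matrix()
               if spec.rotation_deg is not None else np.eye(3))
        m = rot @ d @ d @ rot.T  # support: extent along u = 2 sqrt(u' M u)
        thickness = 2.0 * math.sqrt(m[2, 2])
        diameter = 2.0 * math.sqrt(np.linalg.eigvalsh(m[:2, :2])[-1])
    axes = EllipsoidAxes(*[float(s) for s in semis])
    e1, e2 = eccentricities(axes)
    vol_mm3 = vol_um3 / UM3_PER_MM3
    surf_mm2 = surf_um3 / UM2_PER_MM2
    return GroundTruth(
        mask=mask,
        true_volume_mm3=vol_mm3,
        true_surface_mm2=surf_mm2,
        true_axes=axes,
        true_e1=e1,
        true_e2=e2,
        true_sphericity=sphericity_3d(vol_mm3, surf_mm2),
        true_roundness=roundness_3d(vol_mm3, 2.0 * axes.a / 1.0e3),
        true_thickness_um=float(thickness),
        true_diameter_um=float(diameter),
    )


def make_phantom_3d(spec: PhantomSpec) -> tuple[VoxelGrid, GroundTruth]:
    """Rasterize a phantom stack and its analytic ground truth.

    The shape is centered in a grid padded by ``margin_um`` of background;
    for flat-bottomed shapes the flat face sits at low z (on the "plate").
    """
    ax, ay, az = spec.axes
    sz, sy, sx = spec.spacing
    margin = spec.margin_um

    if spec.rotation_deg is not None:
        rot = Rotation.from_euler("xyz", spec.rotation_deg, degrees=True).as_matrix()
    else:
        rot = np.eye(3)
    # bounding half-extents of the (rotated) shape along x, y, z
    d2 = rot @ np.diag([ax**2, ay**2, az**2]) @ rot.T
    hx, hy, hz = (math.sqrt(d2[i, i]) for i in (0, 1, 2))

    nx = int(math.ceil(2 * (hx + margin) / sx))
    ny = int(math.ceil(2 * (hy + margin) / sy))
    nz = int(math.ceil(((hz if spec.is_half else 2 * hz) + 2 * margin) / sz))
    if max(nx, ny, nz) > 1200:
        raise ValueError(f"requested grid {(nz, ny, nx)} too large for this phantom")

    z = (np.arange(nz) + 0.5) * sz - (margin + (0.0 if spec.is_half else hz))
    y = (np.arange(ny) + 0.5) * sy - (hy + margin)
    x = (np.arange(nx) + 0.5) * sx - (hx + margin)
    zz, yy, xx = np.meshgrid(z, y, x, indexing="ij")
    pts = np.stack([xx, yy, zz])  # shape frame is (x, y, z)
    if spec.rotation_deg is not None:
        pts = np.einsum("ij,jzyx->izyx", rot.T, pts)
    rho2 = (pts[0] / ax) ** 2 + (pts[1] / ay) ** 2 + (pts[2] / az) ** 2
    inside = rho2 <= 1.0
    if spec.is_half:
        inside &= pts[2] >= 0.0

    bg, core, rim = spec.levels
    img = np.full(inside.shape, bg, dtype=np.float64)
    if spec.intensity_model == "bivariate":
        img[inside] = core
    elif spec.intensity_model == "trivariate":
        shell = inside & (rho2 >= (1.0 - spec.rim_fraction) ** 2)
        img[inside] = core
        img[shell] = rim
    else:
        raise ValueError(f"unknown intensity model {spec.intensity_model!r}")
    if spec.noise_sigma > 0:
        rng = np.random.default_rng(spec.seed)
        img = img + rng.normal(0.0, spec.noise_sigma, img.shape)

    grid = VoxelGrid(img, spacing=spec.spacing, channel_label="synthetic")
    mask = Mask3D(inside, spacing=spec.spacing)
    return grid, _analytic_truth(spec, mask)


def make_growth_series(day_params: list[PhantomSpec]) -> list[tuple[VoxelGrid, GroundTruth]]:
    """Phantoms for a culture time course (one spec per timepoint).

    The caller controls the geometry sequence, so a series with
    monotonically increasing diameter and non-monotone thickness (the
    observed growth pattern: height saturates while diameter keeps growing)
    is directly expressible.
    """
    if len(day_params) < 1:
        raise ValueError("need at least one timepoint")
    return [make_phantom_3d(spec) for spec in day_params]


def day_series_specs(
    diameters_um: list[float],
    thicknesses_um: list[float],
    spacing: tuple[float, float, float] = (2.0, 1.3, 1.3),
    seed: int = 0,
    noise_sigma: float = 95.0,
) -> list[PhantomSpec]:
    """Convenience recipe for a growth series of flat-bottomed shapes.

    Each timepoint is a half-ellipsoid (hemisphere when thickness equals
    the radius, flattening oblate cap when thinner), mirroring the
    near-half-sphere early regime and the late top-flattened one.
    """
    if len(diameters_um) != len(thicknesses_um):
        raise ValueError("diameter and thickness lists must have equal length")
    specs = []
    for i, (d, t) in enumerate(zip(diameters_um, thicknesses_um)):
        r = d / 2.0
        if t > r:
            raise ValueError("flat-bottomed shapes need thickness <= radius")
        shape = "half_sphere" if t == r else "flat_bottom_cap"
        model = "bivariate" if t == r else "trivariate"
        specs.append(
            PhantomSpec(
                shape=shape,
                axes=(r, r, t),
                spacing=spacing,
                intensity_model=model,
                noise_sigma=noise_sigma,
                seed=seed + i,
            )
        )
    return specs


def make_pi_phantom(
    bf_radius_um: float,
    dead_fraction: float,
    pattern: str = "rim",
    seed: int = 0,
    pixel_size: tuple[float, float] = (1.3, 1.3),
    margin_um: float = 50.0,
    noise_sigma: float = 3.0,
) -> tuple[Image2D, Image2D, dict]:
    """Paired BF / PI projection images with a known dead-area fraction.

    The BF image is a dark disk on a bright background (transmitted light);
    the PI image carries a bright dye-positive region covering
    ``dead_fraction`` of the disk, either as a peripheral annulus (``rim``,
    the basal pattern) or as scattered pixels (``diffuse``).
    """
    if not 0 <= dead_fraction <= 1:
        raise ValueError("dead_fraction must be in [0, 1]")
    if pattern not in ("rim", "diffuse"):
        raise ValueError(f"unknown pattern {pattern!r}")
    py, px = pixel_size
    ny = int(math.ceil(2 * (bf_radius_um + margin_um) / py))
    nx = int(math.ceil(2 * (bf_radius_um + margin_um) / px))
    yy, xx = np.meshgrid(
        (np.arange(ny) + 0.5) * py - (bf_radius_um + margin_um),
        (np.arange(nx) + 0.5) * px - (bf_radius_um + margin_um),
        indexing="ij",
    )
    r2 = yy**2 + xx**2
    disk = r2 <= bf_radius_um**2

    rng = np.random.default_rng(seed)
    bf = np.where(disk, 50.0, 200.0)
    pi = np.full(disk.shape, 10.0)
    if dead_fraction > 0:
        if pattern == "rim":
            inner = bf_radius_um * math.sqrt(1.0 - dead_fraction)
            positive = disk & (r2 >= inner**2)
        else:
            idx = np.flatnonzero(disk)
            take = rng.choice(idx, size=int(round(dead_fraction * idx.size)), replace=False)
            positive = np.zeros_like(disk)
            positive.ravel()[take] = True
        pi[positive] = 200.0
    else:
        positive = np.zeros_like(disk)
    if noise_sigma > 0:
        bf = bf + rng.normal(0, noise_sigma, bf.shape)
        pi = pi + rng.normal(0, noise_sigma, pi.shape)

    truth = {
        "dead_fraction": dead_fraction,
        "bf_mask": Mask2D(disk, pixel_size=pixel_size),
        "pi_mask": Mask2D(positive, pixel_size=pixel_size),
        "bf_area_mm2": disk.sum() * py * px / UM2_PER_MM2,
    }
    return (
        Image2D(bf, pixel_size=pixel_size),
        Image2D(pi, pixel_size=pixel_size),
        truth,
    )
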