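"""2D spheroid morphometrics from projection images.

A spheroid imaged in transmitted light is routinely reduced to its 2D
projection and characterised by a handful of shape indices:

* projected radius ``R = sqrt(S / pi)`` of the circle with the measured
  area ``S``;
* sphere-equivalent ("projected") volume ``V = (4/3) pi R^3`` — unbiased
  only if the object really is a sphere;
* circularity ``Cir = 4 pi S / P^2`` and the sphericity index
  ``SI = sqrt(Cir)``, both 1 for a perfect circle;
* roundness ``RI = 4 S / (pi L^2)`` with ``L`` the major axis of the
  best-fit (second-moment) ellipse;
* solidity ``S / area(convex hull)``, a surface-roughness indicator.

The sphericity index is sometimes printed without the radical (SI = Cir);
since both conventions equal 1 for a circle, this module reports both
``circularity`` and ``sphericity_index = sqrt(circularity)`` so either is
recoverable.

Areas are reported in mm², perimeters in mm, volumes in mm³.  The perimeter
is the length of the 0.5 iso-contour of the lightly smoothed mask (marching
squares), accurate to <1% for disks, ellipses and squares alike; naive
boundary-pixel counting (or even multi-direction Crofton estimates, which
are biased several percent for grid-aligned straight edges) would distort
circularity well beyond that.
"""

from __future__ import annotations

import math
from dataclasses import asdict, dataclass

import numpy as np
from scipy import ndimage as ndi
from skimage.measure import find_contours, label, regionprops

from .io import Image2D, Mask2D

UM2_PER_MM2 = 1.0e6


@dataclass
class Morphometrics2D:
    """Shape descriptors of one segmented 2D projection.

    Dimensionless indices are stored raw (they can exceed 1 by rasterization
    error); :meth:`as_record` clips them to 1 for reporting.
    """

    area_mm2: float
    perimeter_mm: float
    circularity: float
    sphericity_index: float
    roundness: float
    solidity: float
    projected_radius_mm: float
    projected_volume_mm3: float

    def as_record(self, clip: bool = True) -> dict:
        rec = asdict(self)
        if clip:
            for key in ("circularity", "sphericity_index", "roundness", "solidity"):
                rec[key] = min(rec[key], 1.0)
        return rec


def circularity(area: float, perimeter: float) -> float:
    """``Cir = 4 pi A / P^2``; 1 for a perfect circle."""
    if area < 0 or perimeter <= 0:
        raise ValueError("area must be >= 0 and perimeter > 0")
    return 4.0 * math.pi * area / perimeter**2


def sphericity_index(cir: float) -> float:
    """``SI = sqrt(Cir)``; 1 for a perfect circle."""
    if cir < 0:
        raise ValueError("circularity must be >= 0")
    return math.sqrt(cir)


def projected_radius(area_mm2: float) -> float:
    """Radius (mm) of the circle with the given projected area (mm²)."""
    if area_mm2 < 0:
        raise ValueError(f"area must be >= 0, got {area_mm2}")
    return math.sqrt(area_mm2 / math.pi)


def projected_volume(area_mm2: float) -> float:
    """Sphere-equivalent volume (mm³) inferred from a projected area (mm²).

    ``V = (4/3) pi R^3`` with ``R = sqrt(S/pi)``.  For any object flatter
    than a sphere this overestimates the true volume — by exactly 2x for a
    half-sphere.
    """
    r = projected_radius(area_mm2)
    return (4.0 / 3.0) * math.pi * r**3


def contour_perimeter(mask: np.ndarray, smooth_sigma: float = 1.0) -> float:
    """Perimeter (pixels) of a binary mask via the 0.5 iso-contour of the
    Gaussian-smoothed mask.  Smoothing suppresses the pixel staircase that
    biases simpler boundary estimators."""
    pad = int(math.ceil(3 * smooth_sigma)) + 1
    img = np.pad(np.asarray(mask, bool), pad).astype(np.float64)
    if smooth_sigma > 0:
        img = ndi.gaussian_filter(img, smooth_sigma)
    total = 0.0
    for contour in find_contours(img, 0.5):
        total += float(np.sqrt((np.diff(contour, axis=0) ** 2).sum(axis=1)).sum())
    return total


def segment_projection_2d(image: Image2D, polarity: str = "dark_object") -> Mask2D:
    """Segment the single spheroid in a projection image.

    Global Otsu threshold (object side chosen by ``polarity``), then the
    largest 8-connected foreground component with holes filled.  Bright-field
    spheroids are dark on a bright background (``dark_object``); fluorescence
    projections are the opposite.
    """
    from .morpho3d import otsu_threshold  # shared thresholding primitive

    data = image.data
    if np.ptp(data) == 0:
        raise ValueError("cannot threshold a constant image")
    if polarity not in ("dark_object", "bright_object"):
        raise ValueError(f"unknown polarity {polarity!r}")
    t = otsu_threshold(data)
    fg = data < t if polarity == "dark_object" else data > t
    if not fg.any():
        raise ValueError("empty foreground after thresholding")
    labels = label(fg, connectivity=2)  # 8-connectivity
    largest = np.argmax(np.bincount(labels.ravel())[1:]) + 1
    mask = ndi.binary_fill_holes(labels == largest)
    return Mask2D(mask, pixel_size=image.pixel_size)


def measure_shape_2d(mask: Mask2D) -> Morphometrics2D:
    """Compute all 2D shape descriptors for a single-component mask.

    Requires exactly one connected component of at least 25 pixels and
    (near-)square pixels — the index definitions assume an isotropic
    projection raster.
    """
    py, px = mask.pixel_size
    if abs(py - px) > 1e-9 * max(py, px):
        raise NotImplementedError("2D morphometrics require square pixels")
    labels = label(mask.data, connectivity=2)
    n = labels.max()
    if n == 0:
        raise ValueError("empty mask")
    if n > 1:
        raise ValueError(f"mask has {n} components; expected exactly one")
    props = regionprops(labels)[0]
    if props.area < 25:
        raise ValueError(f"component too small ({int(props.area)} px < 25)")

    area_mm2 = float(props.area) * py * px / UM2_PER_MM2
    perimeter_mm = contour_perimeter(labels > 0) * px / 1.0e3
    cir = circularity(area_mm2, perimeter_mm)
    major_mm = float(props.axis_major_length) * px / 1.0e3
    roundness = 4.0 * area_mm2 / (math.pi * major_mm**2)
    r_mm = projected_radius(area_mm2)
    return Morphometrics2D(
        area_mm2=area_mm2,
        perimeter_mm=perimeter_mm,
        circularity=cir,
        sphericity_index=sphericity_index(cir),
        roundness=roundness,
        solidity=float(props.solidity),
        projected_radius_mm=r_mm,
        projected_volume_mm3=projected_volume(area_mm2),
    )
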