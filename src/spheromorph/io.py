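"""Image-stack I/O, shared container types and tabular output.

Axis convention: volumes are indexed ``(z, y, x)`` with z the optical /
gravitational axis — the plate bottom sits at low z.  Spacings are physical
voxel pitches in micrometres per voxel, ordered like the axes.  Spacing is
supplied by the caller (TIFF tags are unreliable across instruments); when
omitted it defaults to the light-sheet acquisition settings of 2 µm z-step
and 1.3 µm pixels.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile

#: (sz, sy, sx) in µm/voxel — light-sheet defaults.
DEFAULT_SPACING = (2.0, 1.3, 1.3)


class StackFormatError(ValueError):
    """Raised for TIFFs this package cannot interpret as grayscale stacks."""


@dataclass
class VoxelGrid:
    """A 3D scalar intensity image with physical voxel spacing.

    Parameters
    ----------
    data : ndarray, shape (nz, ny, nx)
        Non-negative intensities in arbitrary units; stored as float64.
    spacing : tuple of float
        (sz, sy, sx) in µm/voxel, all > 0.
    channel_label : str
        Free-text channel tag (e.g. ``"BF"``, ``"PI"``, ``"Ki67"``).
    """

    data: np.ndarray
    spacing: tuple[float, float, float] = DEFAULT_SPACING
    channel_label: str = ""

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=np.float64)
        if self.data.ndim != 3:
            raise ValueError(f"VoxelGrid needs 3 axes, got {self.data.ndim}")
        if not np.all(np.isfinite(self.data)):
            raise ValueError("VoxelGrid intensities must be finite")
        self.spacing = tuple(float(s) for s in self.spacing)
        if len(self.spacing) != 3 or any(s <= 0 for s in self.spacing):
            raise ValueError(f"spacing must be 3 positive values, got {self.spacing}")

    @property
    def voxel_volume(self) -> float:
        """Volume of one voxel in µm³."""
        sz, sy, sx = self.spacing
        return sz * sy * sx

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape


@dataclass
class Image2D:
    """A 2D intensity image with physical pixel size (py, px) in µm."""

    data: np.ndarray
    pixel_size: tuple[float, float] = (1.3, 1.3)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=np.float64)
        if self.data.ndim != 2:
            raise ValueError(f"Image2D needs 2 axes, got {self.data.ndim}")
        self.pixel_size = tuple(float(p) for p in self.pixel_size)
        if len(self.pixel_size) != 2 or any(p <= 0 for p in self.pixel_size):
            raise ValueError(f"pixel_size must be 2 positive values, got {self.pixel_size}")

    @property
    def pixel_area(self) -> float:
        """Area of one pixel in µm²."""
        return self.pixel_size[0] * self.pixel_size[1]


@dataclass
class Mask3D:
    """Binary 3D segmentation mask sharing a source grid's geometry."""

    data: np.ndarray
    spacing: tuple[float, float, float] = DEFAULT_SPACING

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=bool)
        if self.data.ndim != 3:
            raise ValueError(f"Mask3D needs 3 axes, got {self.data.ndim}")
        self.spacing = tuple(float(s) for s in self.spacing)
        if any(s <= 0 for s in self.spacing):
            raise ValueError(f"spacing must be positive, got {self.spacing}")

    @property
    def voxel_volume(self) -> float:
        sz, sy, sx = self.spacing
        return sz * sy * sx

    @property
    def voxel_count(self) -> int:
        return int(self.data.sum())


@dataclass
class Mask2D:
    """Binary 2D mask with physical pixel size (py, px) in µm."""

    data: np.ndarray
    pixel_size: tuple[float, float] = (1.3, 1.3)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=bool)
        if self.data.ndim != 2:
            raise ValueError(f"Mask2D needs 2 axes, got {self.data.ndim}")
        self.pixel_size = tuple(float(p) for p in self.pixel_size)
        if any(p <= 0 for p in self.pixel_size):
            raise ValueError(f"pixel_size must be positive, got {self.pixel_size}")

    @property
    def pixel_area(self) -> float:
        return self.pixel_size[0] * self.pixel_size[1]


def read_stack(
    path: str | Path,
    spacing: tuple[float, float, float] = DEFAULT_SPACING,
    channel_label: str = "",
) -> VoxelGrid:
    """Read a single- or multi-page grayscale TIFF into a :class:`VoxelGrid`.

    Pages are stacked along z in file order.  RGB / multi-sample TIFFs are
    rejected: the pipeline operates on single-channel intensities.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    with tifffile.TiffFile(path) as tf:
        if len(tf.pages) == 0:
            raise StackFormatError(f"{path}: TIFF has no pages")
        page0 = tf.pages[0]
        if page0.samplesperpixel != 1:
            raise StackFormatError(
                f"{path}: expected grayscale, got {page0.samplesperpixel} samples/pixel"
            )
        arr = tf.asarray()
    if arr.ndim == 2:
        arr = arr[np.newaxis]
    if arr.ndim != 3:
        raise StackFormatError(f"{path}: cannot interpret array of shape {arr.shape}")
    return VoxelGrid(arr, spacing=spacing, channel_label=channel_label)


def write_stack(grid: VoxelGrid, path: str | Path) -> None:
    """Write a grid as a multi-page grayscale TIFF.

    Integral data fitting an unsigned 16-bit range is written as uint16 (or
    uint8) so integer stacks round-trip bit-exactly; anything else is written
    as float32.
    """
    data = grid.data
    if np.all(data == np.round(data)) and data.min() >= 0 and data.max() <= 65535:
        dtype = np.uint8 if data.max() <= 255 else np.uint16
        out = data.astype(dtype)
    else:
        out = data.astype(np.float32)
    tifffile.imwrite(Path(path), out, photometric="minisblack")


def write_mask(mask: Mask3D | Mask2D, path: str | Path) -> None:
    """Export a binary mask as an 8-bit TIFF with values 0/255."""
    tifffile.imwrite(Path(path), mask.data.astype(np.uint8) * 255,
                     photometric="minisblack")


def max_projection(grid: VoxelGrid) -> Image2D:
    """Maximum-intensity projection along z (the convention used for the
    per-well 2D read-outs: stacks are combined by maximum projection before
    any area or dye measurement)."""
    if grid.data.size == 0:
        raise ValueError("cannot project an empty grid")
    return Image2D(grid.data.max(axis=0), pixel_size=grid.spacing[1:])


def write_table(records: list[dict], path: str | Path) -> pd.DataFrame:
    """Write metric records to CSV with a deterministic column order.

    All records must share one schema (same keys); columns appear in the key
    order of the first record.  An empty list yields a header-only file with
    no columns.
    """
    if records:
        columns = list(records[0].keys())
        for i, rec in enumerate(records):
            if list(rec.keys()) != columns:
                raise ValueError(
                    f"record {i} keys {list(rec.keys())} do not match schema {columns}"
                )
        df = pd.DataFrame.from_records(records, columns=columns)
    else:
        df = pd.DataFrame()
    df.to_csv(Path(path), index=False)
    return df


def read_table(path: str | Path) -> pd.DataFrame:
    """Read a CSV written by :func:`write_table`."""
    return pd.read_csv(Path(path))
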