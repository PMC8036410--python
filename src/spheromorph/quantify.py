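"""Cell-death and viability read-outs.

Whole-spheroid death is read from a propidium-iodide (PI) fluorescence
projection: the PI-positive area and the background-subtracted PI intensity
are each expressed relative to the bright-field (BF) area of the same
spheroid, and optionally normalized to the mean of untreated controls.
Dissociated-spheroid viability uses the trypan-blue count formula

    viability % = 100 * live / (live + dead).
"""

from __future__ import annotations

from dataclasses import asdict, dataclass

import numpy as np

from .io import Image2D, Mask2D
from .morpho3d import otsu_threshold

UM2_PER_MM2 = 1.0e6


@dataclass
class DeathMetrics:
    """PI-based death read-out for one spheroid."""

    bf_area_mm2: float
    pi_area_mm2: float
    pi_intensity: float  # summed background-subtracted PI, a.u.
    pi_area_ratio: float  # PI area / BF area
    pi_intensity_ratio: float  # a.u. per mm² of BF area

    def as_record(self) -> dict:
        return asdict(self)


@dataclass
class ViabilityCount:
    live: int
    dead: int

    @property
    def viability(self) -> float:
        return viability_percent(self.live, self.dead)


def _resolve_threshold(values: np.ndarray, policy, floor: float) -> float:
    """PI-positivity threshold from a policy: 'otsu', ('fixed', v) or
    ('quantile', q).

    The Otsu estimate is only trusted when the in-mask distribution is
    genuinely bimodal (class-mean separation above 3 robust sigmas of the
    in-mask values); a homogeneous signal — dye-free spheroid, or dye
    covering the whole spheroid — falls back to ``floor`` (background
    median + 3 robust background sigmas), so all-background yields no
    positives and an all-positive spheroid yields only positives.
    """
    if isinstance(policy, tuple):
        kind, arg = policy
        if kind == "fixed":
            return float(arg)
        if kind == "quantile":
            return float(np.quantile(values, arg))
        raise ValueError(f"unknown threshold policy {policy!r}")
    if policy != "otsu":
        raise ValueError(f"unknown threshold policy {policy!r}")
    if np.ptp(values) == 0:
        return floor
    t = otsu_threshold(values)
    lo, hi = values[values < t], values[values >= t]
    if lo.size == 0 or hi.size == 0:
        return floor
    med = np.median(values)
    robust_sigma = 1.4826 * float(np.median(np.abs(values - med)))
    if hi.mean() - lo.mean() < 3.0 * robust_sigma:
        return floor
    return max(t, floor)


def pi_death_metrics(
    bf_mask: Mask2D,
    pi_image: Image2D,
    pi_threshold_policy="otsu",
    background_subtract: bool = True,
) -> DeathMetrics:
    """Quantify PI-positive area and intensity relative to the BF area.

    The PI mask is restricted to the BF mask, so ``pi_area <= bf_area`` by
    construction.  Background (median PI outside the BF mask) is subtracted
    from the summed intensity by default, making the intensity ratio
    insensitive to a constant camera offset.
    """
    if bf_mask.data.shape != pi_image.data.shape:
        raise ValueError(
            f"geometry mismatch: BF {bf_mask.data.shape} vs PI {pi_image.data.shape}"
        )
    if not bf_mask.data.any():
        raise ValueError("empty BF mask")
    inside = pi_image.data[bf_mask.data]
    outside = pi_image.data[~bf_mask.data]
    if outside.size:
        bg = float(np.median(outside))
        bg_sigma = 1.4826 * float(np.median(np.abs(outside - bg)))
    else:
        bg, bg_sigma = 0.0, 0.0
    # strict floor: a noise-free all-background image must yield no positives
    floor = bg + 3.0 * bg_sigma + 1e-9 * (1.0 + abs(bg))
    thr = _resolve_threshold(inside, pi_threshold_policy, floor=floor)

    px_area = pi_image.pixel_area / UM2_PER_MM2
    bf_area = bf_mask.data.sum() * px_area
    pi_pos = inside >= thr
    pi_area = pi_pos.sum() * px_area
    # unclipped sum: zero-mean noise cancels, so a dye-free image reports
    # an intensity near zero instead of a rectified-noise bias
    signal = inside - bg if background_subtract else inside
    intensity = float(signal.sum())
    return DeathMetrics(
        bf_area_mm2=float(bf_area),
        pi_area_mm2=float(pi_area),
        pi_intensity=intensity,
        pi_area_ratio=float(pi_area / bf_area),
        pi_intensity_ratio=float(intensity / bf_area),
    )


def normalize_to_control(value, control_mean: float):
    """Express a metric as fold of the untreated-control mean.

    Accepts a scalar or an array of replicates (returned elementwise).
    """
    if control_mean <= 0:
        raise ValueError(f"control mean must be > 0, got {control_mean}")
    return np.asarray(value) / control_mean if np.ndim(value) else float(value) / control_mean


def viability_percent(live: int, dead: int) -> float:
    """``100 * live / (live + dead)`` — trypan-blue viability."""
    if live < 0 or dead < 0:
        raise ValueError("counts must be non-negative")
    if live + dead == 0:
        raise ValueError("live + dead must be > 0")
    return 100.0 * live / (live + dead)
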