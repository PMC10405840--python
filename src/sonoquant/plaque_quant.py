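"""Amyloid-plaque population and volume quantification.

Plaques are detected on the amyloid (green) channel after normalization by
an out-of-focus reference region: connected components above a fixed
relative threshold become plaque records, each with its boundary, in-plane
area, equivalent radius r = √(area/π) and a sphere-extrapolated volume
(4/3)π·r³.  Group comparisons report percent decreases 100·(1 − A/B)
against a reference group.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from skimage.measure import find_contours, regionprops, label as sk_label

from .core import RasterVolume

__all__ = [
    "PlaqueRecord",
    "PlaqueGroupStats",
    "normalize_channel",
    "detect_plaques",
    "plaque_group_stats",
]


@dataclass
class PlaqueRecord:
    """One detected plaque on a 2D section."""

    location: tuple[float, float]     # centroid, px
    area: float                       # μm^2
    equivalent_radius: float          # μm
    volume: float                     # μm^3, sphere of the equivalent radius
    boundary: np.ndarray | None = None  # closed contour, px coordinates

    @classmethod
    def from_region(cls, region, pixel_size: float, boundary=None) -> "PlaqueRecord":
        area = region.area * pixel_size ** 2
        r = math.sqrt(area / math.pi)
        return cls(
            location=tuple(map(float, region.centroid)),
            area=float(area),
            equivalent_radius=r,
            volume=4.0 / 3.0 * math.pi * r ** 3,
            boundary=boundary,
        )


@dataclass
class PlaqueGroupStats:
    """Population/volume summary of group A against reference group B."""

    population_a: int
    population_b: int
    total_volume_a: float
    total_volume_b: float
    mean_volume_a: float
    mean_volume_b: float
    percent_decrease_population: float | None
    percent_decrease_volume: float | None

    def to_dict(self) -> dict:
        return dict(self.__dict__)


def normalize_channel(
    channel: RasterVolume | np.ndarray, out_of_focus_box
) -> np.ndarray:
    """Divide the channel by the mean of an out-of-focus box.

    The box is ``((row, col), (height, width))`` in pixels; after division
    its mean is 1, so plaque thresholds are contrast ratios.
    """
    img = channel.data if isinstance(channel, RasterVolume) else np.asarray(channel)
    (r0, c0), (h, w) = out_of_focus_box
    if h <= 0 or w <= 0 or r0 < 0 or c0 < 0 or r0 + h > img.shape[0] or c0 + w > img.shape[1]:
        raise ValueError("out-of-focus box must be a non-empty region inside the image")
    ref = float(img[r0:r0 + h, c0:c0 + w].mean())
    if ref <= 0:
        raise ValueError(f"out-of-focus mean is {ref}; needs positive background signal")
    return img / ref


def detect_plaques(
    normalized: np.ndarray,
    fixed_threshold: float = 2.0,
    min_size: float = 20.0,
    pixel_size: float = 1.0,
    with_boundaries: bool = True,
) -> list[PlaqueRecord]:
    """Binarize at a fixed relative threshold and record each component.

    ``fixed_threshold`` is in normalized units (background ≈ 1) and is held
    fixed throughout an analysis; ``min_size`` (px²) drops noise specks.
    Touching plaques are not split — the phantom separability condition
    (≥ 2 px of background between plaques) is the validity assumption.
    """
    if fixed_threshold <= 1.0:
        raise ValueError("fixed_threshold is relative to normalized background; must be > 1")
    if min_size < 0:
        raise ValueError("min_size must be nonnegative")
    binary = np.asarray(normalized) > fixed_threshold
    labels = sk_label(binary, connectivity=2)
    records: list[PlaqueRecord] = []
    for region in regionprops(labels):
        if region.area < min_size:
            continue
        boundary = None
        if with_boundaries:
            component = labels == region.label
            contours = find_contours(component.astype(float), 0.5)
            boundary = max(contours, key=len) if contours else None
        records.append(PlaqueRecord.from_region(region, pixel_size, boundary))
    return records


def _percent_decrease(a: float, b: float) -> float:
    return 100.0 * (1.0 - a / b)


def plaque_group_stats(
    records_a: list[PlaqueRecord], records_b: list[PlaqueRecord]
) -> PlaqueGroupStats:
    """Population and volume statistics of group A versus reference group B.

    Percent decreases are 100·(1 − A/B); with an empty reference group they
    are undefined and returned as ``None``.
    """
    pop_a, pop_b = len(records_a), len(records_b)
    # fsum: exactly rounded, so totals are invariant to record order
    vol_a = math.fsum(r.volume for r in records_a)
    vol_b = math.fsum(r.volume for r in records_b)
    if pop_b == 0:
        pd_pop = pd_vol = None
    else:
        pd_pop = _percent_decrease(pop_a, pop_b)
        pd_vol = _percent_decrease(vol_a, vol_b) if vol_b > 0 else None
    return PlaqueGroupStats(
        population_a=pop_a,
        population_b=pop_b,
        total_volume_a=vol_a,
        total_volume_b=vol_b,
        mean_volume_a=vol_a / pop_a if pop_a else 0.0,
        mean_volume_b=vol_b / pop_b if pop_b else 0.0,
        percent_decrease_population=pd_pop,
        percent_decrease_volume=pd_vol,
    )
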