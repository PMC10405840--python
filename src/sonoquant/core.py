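"""Core data carriers shared by every pipeline stage.

A :class:`RasterVolume` is the single in-memory container for MR volumes,
PET volumes and confocal stacks: a scalar (or multi-channel) grid plus the
physical spacing of its axes.  An :class:`EmpiricalCDF` is the sample-based
distribution object used by the neurite-length statistics.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["RasterVolume", "EmpiricalCDF"]


@dataclass
class RasterVolume:
    """A scalar grid with anisotropic physical spacing.

    Parameters
    ----------
    data
        The voxel/pixel array.  2D for single confocal planes, 3D for MR/PET
        volumes, or ``(channels, y, x)`` for multi-channel confocal fields
        (set ``channel_axis=0`` in that case).
    spacing
        Physical size of one step along each *spatial* axis, in mm (MR/PET)
        or μm (confocal).  Length must equal the number of spatial axes.
    channel_axis
        Axis holding channels, or ``None`` for a plain scalar grid.
    """

    data: np.ndarray
    spacing: tuple[float, ...]
    channel_axis: int | None = None

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        self.spacing = tuple(float(s) for s in self.spacing)
        n_spatial = self.data.ndim - (0 if self.channel_axis is None else 1)
        if len(self.spacing) != n_spatial:
            raise ValueError(
                f"spacing has {len(self.spacing)} entries for {n_spatial} spatial axes"
            )
        if any(s <= 0 for s in self.spacing):
            raise ValueError("voxel/pixel spacing must be strictly positive")

    @property
    def voxel_volume(self) -> float:
        """Physical volume (or area in 2D) of one grid element."""
        return float(np.prod(self.spacing))

    def channel(self, index: int) -> "RasterVolume":
        """Extract one channel as a scalar RasterVolume."""
        if self.channel_axis is None:
            raise ValueError("volume has no channel axis")
        data = np.take(self.data, index, axis=self.channel_axis)
        return RasterVolume(data, self.spacing)


@dataclass
class EmpiricalCDF:
    """Empirical cumulative distribution of a finite sample.

    ``F(x)`` is the fraction of sample values ≤ x (right-continuous, step
    function).  ``quantile(q)`` uses the inverse-CDF (type-1) convention:
    the smallest sample value v with F(v) ≥ q, so quantiles always belong
    to the support.
    """

    sorted_values: np.ndarray = field(default_factory=lambda: np.empty(0))

    @classmethod
    def from_samples(cls, values) -> "EmpiricalCDF":
        arr = np.sort(np.asarray(values, dtype=float))
        if arr.size == 0:
            raise ValueError("cannot build an empirical CDF from an empty sample")
        if np.any(~np.isfinite(arr)):
            raise ValueError("sample contains non-finite values")
        return cls(sorted_values=arr)

    @property
    def n(self) -> int:
        return int(self.sorted_values.size)

    def evaluate(self, x) -> np.ndarray | float:
        """F(x) = fraction of sample values ≤ x."""
        x = np.asarray(x, dtype=float)
        out = np.searchsorted(self.sorted_values, x, side="right") / self.n
        return float(out) if out.ndim == 0 else out

    def quantile(self, q: float) -> float:
        """Smallest sample value v with F(v) ≥ q (type-1 inverse CDF)."""
        if not 0.0 < q <= 1.0:
            raise ValueError("q must lie in (0, 1]")
        k = int(np.ceil(q * self.n)) - 1
        return float(self.sorted_values[max(k, 0)])

    def __call__(self, x):
        return self.evaluate(x)
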