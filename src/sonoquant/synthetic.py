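"""Synthetic phantoms with exact ground truth.

Every downstream stage (MR opening volumetry, tau neurite morphometry,
amyloid plaque quantification, PET SUVr) is validated against phantoms
generated here, since no raw study data is available.  The generators emit
intensity-level phantoms only — no point-spread function, k-space or scatter
modelling — together with a :class:`GroundTruth` record holding the analytic
truth for each drawn object.

Conventions
-----------
* Noise is additive Gaussian with a per-spec standard deviation, clipped at
  zero.  A fixed seed gives a bit-identical phantom; the seed affects noise
  only, never geometry or ground truth.
* Confocal process ground truth is recorded as the soma-center-to-endpoint
  length (soma radius + polyline length), the same convention the tracer
  measures, so phantom truth and pipeline output are directly comparable.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from skimage.draw import disk as draw_disk
from skimage.draw import line as draw_line
from skimage.draw import polygon2mask
from skimage.morphology import dilation, disk as disk_footprint

from .core import RasterVolume

__all__ = [
    "MRPhantomSpec",
    "CellSpec",
    "ConfocalFieldSpec",
    "PETPhantomSpec",
    "GroundTruth",
    "make_mr_phantom",
    "make_confocal_field",
    "make_pet_pair",
    "make_length_samples",
    "straight_process_cell",
    "single_process_field",
    "grid_plaques",
]

CHANNELS = ("nuclei", "tau", "amyloid")


@dataclass
class GroundTruth:
    """Analytic truth attached to a generated phantom.

    Exactly one entry exists per drawn object; counts in here are counts by
    construction, not measurements.
    """

    true_opening_volume: float | None = None          # mm^3
    true_process_lengths: list[float] = field(default_factory=list)  # μm, center→endpoint
    true_polyline_lengths: list[float] = field(default_factory=list)  # μm, boundary→endpoint
    true_cell_centers: list[tuple[float, float]] = field(default_factory=list)
    true_plaque_count: int | None = None
    true_plaque_radii_px: list[float] = field(default_factory=list)
    true_plaque_volumes: list[float] = field(default_factory=list)    # μm^3 (sphere model)
    true_suvr: dict[str, float] = field(default_factory=dict)         # per timepoint

    def to_dict(self) -> dict:
        return {k: v for k, v in self.__dict__.items() if v not in (None, [], {})}


# ---------------------------------------------------------------------------
# MR phantom
# ---------------------------------------------------------------------------

@dataclass
class MRPhantomSpec:
    """Contrast-enhanced T1 phantom: one hyperintense ellipsoid (the BBB
    opening) on a uniform background, plus a disjoint reference box playing
    the role of the out-of-focus normalization structure."""

    grid_shape: tuple[int, int, int]
    voxel_size: tuple[float, float, float]       # mm per axis
    opening_center: tuple[float, float, float]   # mm
    opening_semi_axes: tuple[float, float, float]  # mm; sphere when equal
    opening_intensity: float = 300.0
    background_intensity: float = 100.0
    reference_box: tuple[tuple[int, int, int], tuple[int, int, int]] = (
        (0, 0, 0),
        (10, 10, 10),
    )  # corner + size, voxels
    noise_sd: float = 0.0
    seed: int = 0

    def validate(self) -> None:
        if any(v <= 0 for v in self.voxel_size):
            raise ValueError("voxel size must be strictly positive")
        a = np.asarray(self.opening_semi_axes, dtype=float)
        if np.any(a <= 0):
            raise ValueError("opening semi-axes must all be strictly positive")
        c = np.asarray(self.opening_center, dtype=float)
        extent = np.asarray(self.grid_shape) * np.asarray(self.voxel_size)
        if np.any(c - a <= 0) or np.any(c + a >= extent):
            raise ValueError(
                f"opening (center {tuple(c)}, semi-axes {tuple(a)} mm) must lie "
                f"strictly inside the grid extent {tuple(extent)} mm"
            )
        if self.opening_intensity <= self.background_intensity:
            raise ValueError("opening intensity must exceed background intensity")
        corner, size = self.reference_box
        if any(s <= 0 for s in size):
            raise ValueError("reference box must be non-empty")
        if any(co < 0 or co + s > g for co, s, g in zip(corner, size, self.grid_shape)):
            raise ValueError("reference box must lie inside the grid")


def _ellipsoid_mask(spec: MRPhantomSpec) -> np.ndarray:
    coords = [
        (np.arange(n) + 0.5) * v
        for n, v in zip(spec.grid_shape, spec.voxel_size)
    ]
    xx, yy, zz = np.meshgrid(*coords, indexing="ij")
    cx, cy, cz = spec.opening_center
    ax, ay, az = spec.opening_semi_axes
    return (
        ((xx - cx) / ax) ** 2 + ((yy - cy) / ay) ** 2 + ((zz - cz) / az) ** 2
    ) <= 1.0


def make_mr_phantom(spec: MRPhantomSpec) -> tuple[RasterVolume, GroundTruth]:
    """Rasterize the hyperintense-opening phantom.

    Voxels whose centers fall inside the ellipsoid take the opening
    intensity, everything else the background intensity; Gaussian noise is
    added everywhere and clipped at zero.  The ground truth carries the
    analytic ellipsoid volume (4/3)π·a·b·c in mm³.
    """
    spec.validate()
    inside = _ellipsoid_mask(spec)
    corner, size = spec.reference_box
    box = tuple(slice(c, c + s) for c, s in zip(corner, size))
    if inside[box].any():
        raise ValueError("reference box overlaps the opening; move it")

    data = np.full(spec.grid_shape, spec.background_intensity, dtype=float)
    data[inside] = spec.opening_intensity
    if spec.noise_sd > 0:
        rng = np.random.default_rng(spec.seed)
        data = np.clip(data + rng.normal(0.0, spec.noise_sd, data.shape), 0.0, None)

    a, b, c = spec.opening_semi_axes
    truth = GroundTruth(true_opening_volume=4.0 / 3.0 * math.pi * a * b * c)
    return RasterVolume(data, spec.voxel_size), truth


# ---------------------------------------------------------------------------
# Confocal phantom
# ---------------------------------------------------------------------------

@dataclass
class CellSpec:
    """One soma (filled disk) with its attached process polylines.

    Polylines are pixel-coordinate vertex lists ``[(row, col), ...]`` whose
    first vertex lies on the soma boundary.
    """

    center: tuple[float, float]  # (row, col) px
    radius: float                # px
    processes: list[list[tuple[float, float]]] = field(default_factory=list)


def straight_process_cell(
    center: tuple[float, float],
    soma_radius: float,
    length_um: float,
    pixel_size: float,
    direction: tuple[float, float] = (0.0, 1.0),
) -> CellSpec:
    """Build a cell with one straight process whose *center-to-endpoint*
    length is ``length_um``; the polyline starts on the soma boundary."""
    total_px = length_um / pixel_size
    if total_px <= soma_radius:
        raise ValueError("requested length does not clear the soma radius")
    d = np.asarray(direction, dtype=float)
    d /= np.linalg.norm(d)
    c = np.asarray(center, dtype=float)
    start = c + soma_radius * d
    end = c + total_px * d
    return CellSpec(center=tuple(c), radius=soma_radius,
                    processes=[[tuple(start), tuple(end)]])


def grid_plaques(
    n: int,
    radius_px: float,
    image_shape: tuple[int, int],
    margin: int = 10,
    pitch: float | None = None,
) -> list[tuple[tuple[float, float], float]]:
    """Lay out ``n`` equal plaques on a regular grid with ≥ 2 px separation.

    Centers carry a fixed subpixel offset so the rasterized disks sample the
    generic (off-lattice) geometry; lattice-aligned centers are a degenerate
    case with atypically large pixel-count fluctuations.
    """
    if pitch is None:
        pitch = 2 * radius_px + 6
    per_row = max(1, int((image_shape[1] - 2 * margin) // pitch))
    out = []
    for i in range(n):
        r = margin + (i // per_row) * pitch + 0.37
        c = margin + (i % per_row) * pitch + 0.61
        if r + radius_px + 1 >= image_shape[0]:
            raise ValueError("image too small for the requested plaque count")
        out.append(((float(r), float(c)), float(radius_px)))
    return out


def single_process_field(
    lengths_um: list[float],
    soma_radius: float = 8.0,
    pixel_size: float = 1.0,
    row_pitch: float = 30.0,
    margin: float = 20.0,
    seed: int = 0,
) -> "ConfocalFieldSpec":
    """One row per cell, each with one straight horizontal process.

    ``lengths_um`` are center-to-endpoint lengths; the image is sized to fit
    the longest process plus margins, so well-separated rows keep every
    cell's skeleton disconnected from its neighbors'.
    """
    n = len(lengths_um)
    height = int(2 * margin + row_pitch * (n - 1)) if n else int(2 * margin)
    width = int(max(lengths_um) / pixel_size + 3 * margin)
    cells = [
        straight_process_cell((margin + row_pitch * i, margin), soma_radius,
                              L, pixel_size)
        for i, L in enumerate(lengths_um)
    ]
    return ConfocalFieldSpec(
        image_shape=(height, width),
        pixel_size=pixel_size,
        cells=cells,
        n_scatter_nuclei=0,
        seed=seed,
    )


@dataclass
class ConfocalFieldSpec:
    """Multichannel confocal field: nuclei / tau / amyloid channels over a
    hippocampus-like mask polygon."""

    image_shape: tuple[int, int]
    pixel_size: float = 1.0      # μm per px
    cells: list[CellSpec] = field(default_factory=list)
    plaques: list[tuple[tuple[float, float], float]] = field(default_factory=list)
    channel_gains: dict[str, float] = field(
        default_factory=lambda: {"nuclei": 150.0, "tau": 200.0, "amyloid": 200.0}
    )
    background: float = 10.0
    noise_sd: dict[str, float] = field(
        default_factory=lambda: {"nuclei": 0.0, "tau": 0.0, "amyloid": 0.0}
    )
    mask_polygon: list[tuple[float, float]] | None = None  # (row, col) vertices
    n_scatter_nuclei: int = 60
    nucleus_radius: float = 3.0
    process_width_px: int = 3
    seed: int = 0

    def mask(self) -> np.ndarray:
        if self.mask_polygon is None:
            return np.ones(self.image_shape, dtype=bool)
        return polygon2mask(self.image_shape, np.asarray(self.mask_polygon))


def _polyline_length_px(poly) -> float:
    pts = np.asarray(poly, dtype=float)
    return float(np.sum(np.linalg.norm(np.diff(pts, axis=0), axis=1)))


def _draw_polyline(canvas: np.ndarray, poly, value: float) -> None:
    pts = np.asarray(poly, dtype=float)
    for p, q in zip(pts[:-1], pts[1:]):
        rr, cc = draw_line(int(round(p[0])), int(round(p[1])),
                           int(round(q[0])), int(round(q[1])))
        canvas[rr, cc] = value


def make_confocal_field(spec: ConfocalFieldSpec) -> tuple[RasterVolume, GroundTruth]:
    """Render the three-channel confocal phantom.

    Tau channel: filled somata plus 1-px process polylines dilated to
    ``process_width_px``.  Amyloid channel: filled disks.  Nuclei channel:
    small disks at soma centers plus scattered nuclei inside the mask.
    """
    shape = tuple(spec.image_shape)
    mask = spec.mask()
    rng = np.random.default_rng(spec.seed)

    # --- invariant checks -------------------------------------------------
    for (c1, r1) in spec.plaques:
        rr = np.array(c1)
        if not (0 <= rr[0] - r1 and rr[0] + r1 < shape[0]
                and 0 <= rr[1] - r1 and rr[1] + r1 < shape[1]):
            raise ValueError(f"plaque at {c1} leaves the image")
        if spec.mask_polygon is not None and not mask[int(rr[0]), int(rr[1])]:
            raise ValueError(f"plaque at {c1} lies outside the mask polygon")
    for i, (ci, ri) in enumerate(spec.plaques):
        for cj, rj in spec.plaques[i + 1:]:
            gap = math.dist(ci, cj) - ri - rj
            if gap < 2.0:
                raise ValueError(
                    f"plaques at {ci} and {cj} are separated by {gap:.2f} px "
                    "of background; ≥ 2 px required"
                )
    for cell in spec.cells:
        for poly in cell.processes:
            start = np.asarray(poly[0], dtype=float)
            if abs(math.dist(start, cell.center) - cell.radius) > 1.0:
                raise ValueError("process polyline must start on its soma boundary")
            for p in poly:
                if not (0 <= p[0] < shape[0] and 0 <= p[1] < shape[1]):
                    raise ValueError(f"process vertex {p} leaves the image")

    # --- render -----------------------------------------------------------
    tau = np.zeros(shape, dtype=float)
    amyloid = np.zeros(shape, dtype=float)
    nuclei = np.zeros(shape, dtype=float)

    truth = GroundTruth()
    for cell in spec.cells:
        rr, cc = draw_disk(cell.center, cell.radius, shape=shape)
        tau[rr, cc] = 1.0
        nrr, ncc = draw_disk(cell.center, min(spec.nucleus_radius, cell.radius), shape=shape)
        nuclei[nrr, ncc] = 1.0
        truth.true_cell_centers.append(tuple(map(float, cell.center)))
        for poly in cell.processes:
            length_px = _polyline_length_px(poly)
            truth.true_polyline_lengths.append(length_px * spec.pixel_size)
            truth.true_process_lengths.append(
                (length_px + cell.radius) * spec.pixel_size
            )

    proc = np.zeros(shape, dtype=float)
    for cell in spec.cells:
        for poly in cell.processes:
            _draw_polyline(proc, poly, 1.0)
    if spec.process_width_px > 1:
        proc = dilation(proc, disk_footprint(spec.process_width_px // 2))
    tau = np.maximum(tau, proc)

    truth.true_plaque_count = len(spec.plaques)
    for (center, radius) in spec.plaques:
        rr, cc = draw_disk(center, radius, shape=shape)
        amyloid[rr, cc] = 1.0
        truth.true_plaque_radii_px.append(float(radius))
        r_um = radius * spec.pixel_size
        truth.true_plaque_volumes.append(4.0 / 3.0 * math.pi * r_um ** 3)

    # scattered nuclei for the automatic hippocampal-mask rule
    if spec.n_scatter_nuclei > 0:
        inside = np.argwhere(mask)
        if inside.size:
            idx = rng.integers(0, len(inside), size=spec.n_scatter_nuclei)
            for r, c in inside[idx]:
                rr, cc = draw_disk((float(r), float(c)), spec.nucleus_radius, shape=shape)
                nuclei[rr, cc] = 1.0

    channels = {"nuclei": nuclei, "tau": tau, "amyloid": amyloid}
    stack = np.empty((3,) + shape, dtype=float)
    for i, name in enumerate(CHANNELS):
        img = spec.background + spec.channel_gains[name] * channels[name] * mask
        sd = spec.noise_sd.get(name, 0.0)
        if sd > 0:
            img = np.clip(img + rng.normal(0.0, sd, shape), 0.0, None)
        stack[i] = img

    vol = RasterVolume(stack, (spec.pixel_size, spec.pixel_size), channel_axis=0)
    return vol, truth


# ---------------------------------------------------------------------------
# PET phantom
# ---------------------------------------------------------------------------

@dataclass
class PETPhantomSpec:
    """Paired-timepoint PET phantom over an integer label volume.

    ``regional_means`` maps each label id to its mean uptake per timepoint
    (baseline, follow-up); voxels with labels missing from the map default
    to the ``background_mean``.
    """

    grid_shape: tuple[int, int, int] = (32, 32, 16)
    voxel_size: tuple[float, float, float] = (1.0, 1.0, 4.0)  # mm
    label_volume: np.ndarray | None = None
    roi_id: int = 1
    reference_ids: tuple[int, ...] = (2,)
    regional_means: dict[int, tuple[float, float]] = field(
        default_factory=lambda: {1: (1.4, 1.4), 2: (1.0, 1.0)}
    )
    background_mean: float = 0.2
    noise_sd: float = 0.0
    seed: int = 0

    def labels(self) -> np.ndarray:
        if self.label_volume is not None:
            return np.asarray(self.label_volume)
        # default layout: ROI in the upper half, reference in the lower half
        lab = np.zeros(self.grid_shape, dtype=np.int16)
        h = self.grid_shape[0]
        lab[: h // 3] = self.roi_id
        lab[-(h // 3):] = self.reference_ids[0]
        return lab

    def validate(self) -> None:
        lab = self.labels()
        if not np.any(lab == self.roi_id):
            raise ValueError(f"target label {self.roi_id} absent from label volume")
        if not np.any(np.isin(lab, self.reference_ids)):
            raise ValueError(f"reference labels {self.reference_ids} absent from label volume")
        for lid, means in self.regional_means.items():
            if any(m <= 0 for m in means):
                raise ValueError(f"regional means must be strictly positive (label {lid})")


def make_pet_pair(
    spec: PETPhantomSpec,
) -> tuple[RasterVolume, RasterVolume, RasterVolume, GroundTruth]:
    """Generate (baseline, follow-up, labels, truth).

    Noise-free, each region's voxel mean equals its prescribed regional mean
    exactly; the ground-truth SUVr is target mean / reference mean per
    timepoint.
    """
    spec.validate()
    lab = spec.labels()
    rng = np.random.default_rng(spec.seed)
    vols = []
    for t in range(2):
        data = np.full(spec.grid_shape, spec.background_mean, dtype=float)
        for lid, means in spec.regional_means.items():
            data[lab == lid] = means[t]
        if spec.noise_sd > 0:
            data = np.clip(data + rng.normal(0.0, spec.noise_sd, data.shape), 0.0, None)
        vols.append(RasterVolume(data, spec.voxel_size))

    def _true_suvr(t: int) -> float:
        tgt = spec.regional_means[spec.roi_id][t]
        ref_vals = [spec.regional_means[r][t] for r in spec.reference_ids
                    if r in spec.regional_means]
        # unweighted voxel mean over reference voxels; with equal per-label
        # means this is the voxel-count-weighted mean
        counts = [np.count_nonzero(lab == r) for r in spec.reference_ids
                  if r in spec.regional_means]
        ref = float(np.average(ref_vals, weights=counts))
        return tgt / ref

    truth = GroundTruth(
        true_suvr={"baseline": _true_suvr(0), "followup": _true_suvr(1)}
    )
    return vols[0], vols[1], RasterVolume(lab, spec.voxel_size), truth


# ---------------------------------------------------------------------------
# Direct length samples (bypassing imaging)
# ---------------------------------------------------------------------------

def make_length_samples(
    groups: dict[str, object],
    seed: int = 0,
    n_draw: int = 0,
) -> dict[str, np.ndarray]:
    """Produce labeled length samples for the CDF machinery directly.

    Each group value is either an explicit sequence of lengths, or a mixture
    spec ``{"values": [...], "weights": [...]}``.  A mixture with rational
    weights and ``n_draw == 0`` is expanded exactly into the smallest
    multiset realizing the weights; with ``n_draw > 0`` it is sampled iid.
    """
    if len(groups) != 2:
        raise ValueError("exactly two groups are required")
    out: dict[str, np.ndarray] = {}
    rng = np.random.default_rng(seed)
    for name, g in groups.items():
        if isinstance(g, dict):
            values = np.asarray(g["values"], dtype=float)
            weights = np.asarray(g["weights"], dtype=float)
            if values.size == 0:
                raise ValueError(f"group '{name}' is empty")
            weights = weights / weights.sum()
            if n_draw > 0:
                sample = rng.choice(values, size=n_draw, p=weights)
            else:
                # exact expansion on a common denominator grid of 1000
                counts = np.round(weights * 1000).astype(int)
                from math import gcd
                from functools import reduce
                g_ = reduce(gcd, [c for c in counts if c > 0])
                counts //= g_
                sample = np.repeat(values, counts)
        else:
            sample = np.asarray(g, dtype=float)
        if sample.size == 0:
            raise ValueError(f"group '{name}' is empty")
        if np.any(sample <= 0):
            raise ValueError(f"group '{name}' contains non-positive lengths")
        out[name] = sample
    return out
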