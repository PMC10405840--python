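"""Structural algorithm for tau-affected neuronal processes.

Quantifies, per detected cell, the length of the processes carrying tau
signal, and compares groups through empirical CDFs and a Monte-Carlo
pairwise-difference statistic:

1. a hippocampal mask restricts the analysis (supplied polygon, or Otsu on
   the nuclei channel);
2. k-means intensity clustering isolates the highest-intensity pixels of the
   tau channel;
3. the circular Hough transform detects soma centers;
4. morphological closing plus topological thinning yields the process
   skeleton, read as an 8-connected graph with √2-weighted diagonal steps;
5. from the skeleton node nearest each soma center, geodesic distances to
   every reachable endpoint give the per-cell path lengths, summarized by
   the mean of the longest 5% (``ceil(0.05·n)`` paths, minimum one);
6. group CDFs are compared via their 95th percentiles and via the CDF of
   Monte-Carlo pairwise differences, whose value just below zero is
   P(length_A < length_B).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import dijkstra
from skimage.filters import threshold_otsu
from skimage.morphology import closing as binary_closing, disk as disk_footprint, skeletonize
from skimage.transform import hough_circle, hough_circle_peaks
from sklearn.cluster import KMeans

from .core import EmpiricalCDF, RasterVolume

__all__ = [
    "SkeletonGraph",
    "CellProcessRecord",
    "DifferenceCDFResult",
    "build_hippocampal_mask",
    "segment_tau",
    "detect_cell_centers",
    "skeletonize_processes",
    "trace_processes",
    "length_cdf",
    "mc_difference_cdf",
    "top_fraction_mean",
    "measure_tau_lengths",
]

logger = logging.getLogger(__name__)

_NEIGHBOR_OFFSETS = [(-1, -1), (-1, 0), (-1, 1), (0, -1), (0, 1), (1, -1), (1, 0), (1, 1)]


# ---------------------------------------------------------------------------
# mask and segmentation
# ---------------------------------------------------------------------------

def build_hippocampal_mask(
    composite: RasterVolume | np.ndarray,
    polygon: list[tuple[float, float]] | None = None,
    nuclei_channel: int = 0,
    closing_radius: int = 10,
) -> np.ndarray:
    """Region-of-interest mask restricting all downstream analysis.

    A supplied polygon takes precedence; otherwise the rule is Otsu
    thresholding of the nuclei channel followed by morphological closing and
    hole filling — nuclei are dense inside the hippocampal formation, so
    their envelope approximates it.
    """
    if isinstance(composite, RasterVolume):
        img = (composite.channel(nuclei_channel).data
               if composite.channel_axis is not None else composite.data)
    else:
        img = np.asarray(composite)
        if img.ndim == 3:
            img = img[nuclei_channel]
    if polygon is not None:
        from skimage.draw import polygon2mask

        mask = polygon2mask(img.shape, np.asarray(polygon))
    else:
        if img.max() <= img.min():
            raise ValueError("blank image and no polygon: cannot build a mask")
        rough = img > threshold_otsu(img)
        rough = binary_closing(rough, disk_footprint(closing_radius))
        mask = ndimage.binary_fill_holes(rough)
    if not mask.any():
        raise ValueError("constructed mask is empty")
    return mask


def segment_tau(
    tau: RasterVolume | np.ndarray,
    mask: np.ndarray | None = None,
    k: int = 3,
    seed: int = 0,
) -> np.ndarray:
    """Isolate the highest-intensity pixels of the tau channel by k-means.

    Pixels inside the mask are clustered on intensity with ``k`` clusters;
    the cluster with the largest mean becomes the foreground.  When the
    image has fewer than ``k`` distinct intensity levels, k-means is
    degenerate and the function falls back to thresholding at the top level
    (logged).
    """
    if k < 2:
        raise ValueError("k must be at least 2")
    img = tau.data if isinstance(tau, RasterVolume) else np.asarray(tau)
    if mask is None:
        mask = np.ones(img.shape, dtype=bool)
    vals = img[mask].astype(float)
    levels = np.unique(vals)
    if levels.size < k:
        top = levels[-1]
        logger.warning(
            "segment_tau: only %d distinct levels for k=%d; falling back to "
            "threshold at the top level %.4g", levels.size, k, top
        )
        out = np.zeros(img.shape, dtype=bool)
        if levels.size >= 2:
            out[mask & (img >= top)] = True
        else:
            logger.warning("segment_tau: constant image inside mask; empty foreground")
        return out
    km = KMeans(n_clusters=k, n_init=5, random_state=seed)
    labels = km.fit_predict(vals.reshape(-1, 1))
    top_cluster = int(np.argmax(km.cluster_centers_.ravel()))
    out = np.zeros(img.shape, dtype=bool)
    out[mask] = labels == top_cluster
    return out


def detect_cell_centers(
    binary_map: np.ndarray,
    radius_range: tuple[float, float],
    max_cells: int | None = None,
    accumulator_threshold: float = 0.5,
) -> list[tuple[float, float]]:
    """Detect circular soma centers with the Hough transform.

    Returns ``(row, col)`` centers, one per well-separated circular soma.
    Peaks closer than the minimum radius are merged (the stronger wins).
    """
    r_min, r_max = radius_range
    if r_min <= 0 or r_min >= r_max:
        raise ValueError("radius_range must be positive with min < max")
    img = np.asarray(binary_map).astype(float)
    if not img.any():
        return []
    radii = np.arange(int(math.floor(r_min)), int(math.ceil(r_max)) + 1)
    h = hough_circle(img > 0, radii)
    sep = int(math.ceil(r_min))
    accums, cx, cy, _ = hough_circle_peaks(
        h,
        radii,
        min_xdistance=sep,
        min_ydistance=sep,
        threshold=accumulator_threshold * h.max(),
        num_peaks=np.inf,
        total_num_peaks=max_cells if max_cells is not None else np.inf,
    )
    # hough_circle_peaks enforces separation per radius only; merge across radii
    centers: list[tuple[float, float]] = []
    for _, x, y in sorted(zip(accums, cx, cy), reverse=True):
        if all(math.dist((y, x), c) >= r_min for c in centers):
            centers.append((float(y), float(x)))
    return centers


# ---------------------------------------------------------------------------
# skeleton graph
# ---------------------------------------------------------------------------

@dataclass
class SkeletonGraph:
    """8-connected pixel graph of a skeletonized binary map.

    Edge weights are 1 (axial) or √2 (diagonal) times ``pixel_size``, so
    shortest paths are geodesic lengths in physical units.
    """

    nodes: np.ndarray                 # (N, 2) pixel coordinates (row, col)
    adjacency: csr_matrix             # weighted, symmetric
    pixel_size: float = 1.0
    _degree: np.ndarray = field(init=False, repr=False)

    def __post_init__(self) -> None:
        self._degree = np.diff(self.adjacency.indptr)

    @property
    def endpoints(self) -> np.ndarray:
        """Indices of degree-1 nodes."""
        return np.flatnonzero(self._degree == 1)

    @property
    def branchpoints(self) -> np.ndarray:
        """Indices of degree ≥ 3 nodes."""
        return np.flatnonzero(self._degree >= 3)

    def nearest_node(self, point: tuple[float, float]) -> tuple[int, float]:
        """Nearest skeleton node to a pixel location, with its distance."""
        d = np.linalg.norm(self.nodes - np.asarray(point, dtype=float), axis=1)
        i = int(np.argmin(d))
        return i, float(d[i])


def skeletonize_processes(
    binary_map: np.ndarray,
    closing_radius: int = 2,
    pixel_size: float = 1.0,
) -> SkeletonGraph:
    """Morphological closing, topological thinning, and graph construction.

    Closing (default radius 2 px) bridges small gaps between neighboring
    foreground pixels before thinning, so a fragmented process skeletonizes
    into one connected backbone.
    """
    binary = np.asarray(binary_map).astype(bool)
    if closing_radius > 0:
        binary = binary_closing(binary, disk_footprint(closing_radius))
    skel = skeletonize(binary)
    coords = np.argwhere(skel)
    n = len(coords)
    index = {tuple(c): i for i, c in enumerate(map(tuple, coords))}
    rows, cols, weights = [], [], []
    for (r, c), i in index.items():
        for dr, dc in _NEIGHBOR_OFFSETS:
            j = index.get((r + dr, c + dc))
            if j is not None:
                rows.append(i)
                cols.append(j)
                weights.append(math.sqrt(dr * dr + dc * dc) * pixel_size)
    adj = csr_matrix((weights, (rows, cols)), shape=(n, n))
    return SkeletonGraph(nodes=coords, adjacency=adj, pixel_size=pixel_size)


# ---------------------------------------------------------------------------
# tracing
# ---------------------------------------------------------------------------

def top_fraction_mean(lengths, fraction: float = 0.05) -> float:
    """Mean of the longest ``ceil(fraction·n)`` values (minimum one)."""
    arr = np.sort(np.asarray(lengths, dtype=float))
    if arr.size == 0:
        raise ValueError("no path lengths to summarize")
    m = max(1, math.ceil(fraction * arr.size))
    return float(arr[-m:].mean())


@dataclass
class CellProcessRecord:
    """One detected soma with its traced soma-to-endpoint path lengths (μm)
    and the mean of the longest 5% of those paths."""

    center: tuple[float, float]
    path_lengths: np.ndarray
    top5_mean: float | None
    flagged: bool = False  # True when no skeleton node was within reach

    @property
    def n_paths(self) -> int:
        return int(np.asarray(self.path_lengths).size)


def trace_processes(
    graph: SkeletonGraph,
    centers: list[tuple[float, float]],
    neighborhood_radius: float,
    top_fraction: float = 0.05,
) -> list[CellProcessRecord]:
    """Geodesic tracing from each soma center to all reachable endpoints.

    Each center starts at its nearest skeleton node (within
    ``neighborhood_radius`` pixels; farther → flagged empty record).  Path
    lengths are geodesic distances along the skeleton graph (already in
    physical units).  An endpoint reachable from several centers is assigned
    to the geodesically nearer one; exact ties go to the smaller center
    index, so the assignment is deterministic.
    """
    if not centers:
        raise ValueError("at least one cell center is required")
    n_nodes = len(graph.nodes)
    endpoints = graph.endpoints
    start_nodes: list[int | None] = []
    for center in centers:
        if n_nodes == 0:
            start_nodes.append(None)
            continue
        i, d = graph.nearest_node(center)
        start_nodes.append(i if d <= neighborhood_radius else None)

    valid = [k for k, s in enumerate(start_nodes) if s is not None]
    dist = np.full((len(centers), len(endpoints)), np.inf)
    if valid and endpoints.size:
        dmat = dijkstra(graph.adjacency, directed=False,
                        indices=[start_nodes[k] for k in valid])
        for row, k in enumerate(valid):
            dist[k] = dmat[row][endpoints]

    # nearest-center assignment; ties broken toward the smaller index by argmin
    records: list[CellProcessRecord] = []
    reachable = np.isfinite(dist)
    owner = np.where(reachable.any(axis=0), np.argmin(dist, axis=0), -1)
    for k, center in enumerate(centers):
        if start_nodes[k] is None:
            logger.warning("trace_processes: center %s has no skeleton node within "
                           "%.1f px; flagged", center, neighborhood_radius)
            records.append(CellProcessRecord(center, np.empty(0), None, flagged=True))
            continue
        mine = dist[k][(owner == k) & reachable[k]]
        # a center sitting on an isolated skeleton blob may reach no endpoint
        if mine.size == 0:
            records.append(CellProcessRecord(center, np.empty(0), None, flagged=True))
            continue
        lengths = np.sort(mine)
        records.append(
            CellProcessRecord(center, lengths, top_fraction_mean(lengths, top_fraction))
        )
    return records


# ---------------------------------------------------------------------------
# group statistics
# ---------------------------------------------------------------------------

def length_cdf(records: list[CellProcessRecord], pooled: bool = False) -> EmpiricalCDF:
    """Empirical CDF of a group's per-cell lengths.

    By default one value per cell (its ``top5_mean``); ``pooled=True``
    instead pools every traced path length across cells.
    """
    if pooled:
        values = np.concatenate(
            [r.path_lengths for r in records if r.n_paths > 0] or [np.empty(0)]
        )
    else:
        values = np.array([r.top5_mean for r in records if r.top5_mean is not None])
    if values.size == 0:
        raise ValueError("group has no cells with traced paths")
    return EmpiricalCDF.from_samples(values)


@dataclass
class DifferenceCDFResult:
    """Monte-Carlo CDF of pairwise length differences A − B."""

    diff_cdf: EmpiricalCDF
    p_A_less_B: float
    n_mc: int
    seed: int


def mc_difference_cdf(
    group_a,
    group_b,
    n_mc: int = 100_000,
    seed: int = 0,
) -> DifferenceCDFResult:
    """Monte-Carlo pairwise-difference CDF between two length samples.

    Draws ``n_mc`` iid pairs — one from each group's empirical distribution
    (resampling with replacement) — and forms a − b.  The fraction of
    negative differences estimates P(A < B), the zero-crossing of the
    difference CDF; as n_mc → ∞ it converges to the exact double sum
    Σᵢⱼ 1[aᵢ < bⱼ]/(n_A·n_B).
    """
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both groups must be nonempty")
    if n_mc < 1:
        raise ValueError("n_mc must be at least 1")
    rng = np.random.default_rng(seed)
    diffs = rng.choice(a, size=n_mc) - rng.choice(b, size=n_mc)
    cdf = EmpiricalCDF.from_samples(diffs)
    p = float(np.mean(diffs < 0))
    return DifferenceCDFResult(diff_cdf=cdf, p_A_less_B=p, n_mc=n_mc, seed=seed)


# ---------------------------------------------------------------------------
# end-to-end convenience
# ---------------------------------------------------------------------------

def measure_tau_lengths(
    field: RasterVolume,
    pixel_size: float | None = None,
    tau_channel: int = 1,
    nuclei_channel: int = 0,
    mask_polygon: list[tuple[float, float]] | None = None,
    k: int = 3,
    radius_range: tuple[float, float] = (5.0, 12.0),
    closing_radius: int = 2,
    neighborhood_radius: float | None = None,
    seed: int = 0,
) -> list[CellProcessRecord]:
    """Full per-image pipeline: mask → k-means → Hough → skeleton → tracing.

    ``neighborhood_radius`` defaults to 1.5 × the upper Hough radius.
    """
    if pixel_size is None:
        pixel_size = field.spacing[0]
    mask = build_hippocampal_mask(field, polygon=mask_polygon, nuclei_channel=nuclei_channel)
    tau = field.channel(tau_channel) if field.channel_axis is not None else field
    binary = segment_tau(tau, mask, k=k, seed=seed)
    centers = detect_cell_centers(binary, radius_range)
    if not centers:
        return []
    graph = skeletonize_processes(binary, closing_radius=closing_radius, pixel_size=pixel_size)
    if neighborhood_radius is None:
        neighborhood_radius = 1.5 * radius_range[1]
    return trace_processes(graph, centers, neighborhood_radius)
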