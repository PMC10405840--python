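# Methods

## Scope and design

`sonoquant` re-implements, as a validated library, the measurement chains a
focused-ultrasound BBB-opening study needs: MR opening volumetry, tau
neurite morphometry with Monte-Carlo CDF comparison, amyloid plaque
statistics, and PET SUVr change. Upstream acquisition-side processing
(registration to a template, anatomical segmentation, partial-volume
correction, cavitation control) is deliberately out of scope: published
tools cover those steps, so the SUVr module starts from a co-registered
PET + integer label volume and the volumetry module from a reconstructed
T1 volume.

The package is organized as an importable library with narrative example
scripts under `examples/`; a thin `sonoquant` CLI wraps the same functions
for shell pipelines.

## MR opening volumetry

**Model.** The opening is a contiguous hyperintense region on a
contrast-enhanced T1 volume. Intensities are first divided by the mean of a
caller-chosen out-of-focus reference box, so the background maps to ≈ 1 and
all thresholds are contrast ratios — this makes the measured volume exactly
invariant under global intensity rescaling.

**Segmentation.** Slices along the third array axis are processed
independently. The supra-threshold component (default `init_threshold`
1.3 × normalized background; it must exceed 1) initializes a morphological
Chan–Vese contour (`smoothing=1`, 60 iterations, outer-region weight
λ₂ = 2 to discourage leaking into background). Slices without
supra-threshold pixels yield empty masks. The analyzed slab defaults to all
slices intersecting the supra-threshold component and can be overridden when
an acquisition fixes a slab (e.g. a constant number of consecutive slices
matched to the beam size); voxel geometry is always caller-specified via the
NIfTI header.

**Volume.** V = Σₖ (mask pixel count × in-plane pixel area) × slice
thickness. On a noise-free rasterized sphere of radius 2.3945 mm at 0.05 mm
isotropic spacing the pipeline recovers (4/3)πr³ ≈ 57.5 mm³ to well under
1%; with additive noise at 5% of contrast the error stays below 5%.

## Tau neurite morphometry

**Pipeline.** (1) A region mask — explicit polygon if provided, else Otsu on
the nuclei channel followed by closing (radius 10 px) and hole filling; the
automatic rule assumes nuclei are dense in the region of interest and is not
meaningful on sparse phantoms, where the polygon form is used. (2) k-means
clustering of masked tau intensities (default k = 3, seeded, `n_init=5`);
the cluster with the largest mean is the foreground. Images with fewer than
k distinct levels fall back to thresholding at the top level, with a logged
warning. (3) Circular Hough transform over the caller's soma radius range;
accumulator peaks below 0.5 × the maximum are discarded and peaks closer
than the minimum radius are merged, strongest first. (4) Morphological
closing (default radius 2 px, bridging ≤ ~2 px gaps) then topological
thinning; the skeleton becomes an 8-connected graph with edge weights
1 or √2 × pixel size. (5) From the skeleton node nearest each center
(within a neighborhood of 1.5 × the upper Hough radius; centers farther
away yield flagged empty records), Dijkstra distances to every reachable
degree-1 node are the path lengths. Endpoints reachable from several
centers belong to the geodesically nearest one; exact ties go to the
smaller center index, making results deterministic.

**Why geodesic, not chord.** The straight-line distance from soma to
endpoint under-reports curved processes; path length along the skeleton is
the quantity that tracks neurite extent.

**Per-cell statistic.** The mean of the longest ⌈0.05·n⌉ paths (minimum 1).
With a single process per cell this is the process length itself. Lengths
are center-to-endpoint: the soma radius is not subtracted, and the phantom
generator records its ground truth under the same convention so the two are
directly comparable.

**Group comparison.** The per-group empirical CDF uses the type-1 quantile
(smallest value v with F(v) ≥ q), so "95% probability to find a process
equal or smaller than v" is literally true of the reported v. The
Monte-Carlo difference CDF resamples each group's empirical distribution
with replacement (default 10⁵ seeded draws), forms pairwise differences, and
reports the fraction below zero; this converges to the exact double sum
Σᵢⱼ 1[aᵢ < bⱼ]/(n_A n_B). Resampling the empirical distribution was chosen
over kernel density estimation: it adds no bandwidth parameter and the
zero-crossing probability then has a closed-form target to verify against.
Whether the per-cell value entering the CDFs is the longest-5% mean or all
pooled path lengths is ambiguous in the field's descriptions; the longest-5%
mean is the default, with `pooled=True` available.

## Amyloid plaque quantification

The amyloid channel is normalized by an out-of-focus box, binarized at a
fixed relative threshold (default 2.0; recorded in reports), and connected
components of at least `min_size` (default 20 px², a noise-speck guard) are
measured: area = pixel count × pixel area, equivalent radius r = √(area/π),
volume = (4/3)πr³ (a spherical extrapolation from the in-plane section; an
area × section-thickness alternative is trivially derivable from the
records). Touching plaques are not split — detection counts are exact only
under the ≥ 2 px separation the phantom generator enforces. Group percent
decreases are 100·(1 − A/B); totals use exactly-rounded summation so record
order cannot change a result.

Rasterized-disk areas fluctuate by number-theoretic lattice effects;
phantom plaques are placed at generic subpixel centers, where the
sphere-volume error of a rasterized disk stays below ~3% for radii ≥ 8 px
and vanishes as the radius grows.

## PET SUVr

SUVr = mean uptake over the target label / unweighted mean uptake over all
reference-label voxels. Percent change is 100·(followup/baseline − 1);
negative = reduction. SUVr is invariant under global rescaling of a scan;
the *change* is invariant under independent per-timepoint rescaling only
because the reference region scales with the target — the test suite
asserts exactly this. Voxel anisotropy (e.g. 1×1×4 mm) is carried in the
header but does not weight the mean.

## Statistics plumbing

Two-group comparisons use the classical pooled-variance Student t
(two-sided); regression uses ordinary least squares with the F test for a
nonzero slope. Multiple-endpoint correction is out of scope for
single-endpoint runs. Reports embed the full configuration, seeds and
package version and contain no timestamps, so a rerun is byte-identical.

## Synthetic phantoms: what they do and do not show

The generators produce intensity-level phantoms: an ellipsoidal hyperintense
region with an out-of-focus reference box (MR), three-channel fields with
disk somata, straight-or-polyline processes dilated to 3 px width, disk
plaques and scattered nuclei (confocal), and label-constant regional uptake
(PET). Noise is additive Gaussian clipped at zero; a fixed seed is
bit-reproducible and affects noise only, never geometry or ground truth.
Processes are rendered 3 px wide so the thinning step does real work
(1-px lines are already skeletons).

Default phantom conditions mirror the study readouts they exercise: a
2.3945 mm-radius opening (≈ 57.5 mm³), 21-cell fields with lengths
145 + 25k μm plus one 900 μm outlier (95th percentile 620 μm) and
200 + 50k μm plus one 1400 μm outlier (1150 μm), plaque counts 72 vs 35 and
116 vs 61, and a 1.4000 → 1.3748 target-uptake pair over a unit reference
(−1.8% SUVr).

Passing on phantoms demonstrates the algorithms are implemented correctly —
it does not demonstrate robustness to what real data adds: point-spread
blur, autofluorescence, touching plaques, crossing neurites of different
cells, partial-volume effects, registration error. Blur and extra noise are
available as configurable extras, not defaults. Problem sizes in tests and
in `scripts/acceptance.py` (a 120³ voxel MR grid, 21-cell fields, ≤ 200
plaques, 10⁵ Monte-Carlo draws) were chosen as the smallest that exercise
every code path at the stated tolerances.

## Numerical conventions and edge cases

- Empirical CDFs are right-continuous step functions; quantiles always lie
  in the sample support.
- Ellipsoid rasterization tests voxel centers; the voxel-count volume
  converges to (4/3)πabc as spacing → 0 (< 1% off at 0.05 mm for the
  reference sphere).
- Degenerate inputs are rejected with explicit messages: zero reference
  mean, openings touching the grid boundary, overlapping phantom plaques,
  processes leaving the image, empty groups, constant regressors.
- Chan–Vese can invert phase on nearly constant slices; the bright phase is
  kept by comparing region means.
- All stage seeds derive from one root seed (`numpy.random.SeedSequence`).
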