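"""Measure the volume of a gadolinium-hyperintense BBB opening on a phantom.

Builds a spherical opening of known analytic volume, then runs the full
volumetry pipeline: reference-box normalization, per-slice active-contour
segmentation, and integration over slices.
"""

from sonoquant import MRPhantomSpec, make_mr_phantom, measure_opening

spec = MRPhantomSpec(
    grid_shape=(80, 80, 80),
    voxel_size=(0.1, 0.1, 0.1),          # mm
    opening_center=(4.0, 4.0, 4.0),      # mm
    opening_semi_axes=(2.3945, 2.3945, 2.3945),  # sphere, (4/3)πr³ ≈ 57.5 mm³
    opening_intensity=300.0,
    background_intensity=100.0,
    reference_box=((0, 0, 0), (12, 12, 12)),
    noise_sd=5.0,
    seed=42,
)
volume, truth = make_mr_phantom(spec)
result = measure_opening(volume, spec.reference_box)

print(f"true opening volume : {truth.true_opening_volume:.2f} mm^3")
print(f"measured volume     : {result.volume:.2f} mm^3 over {result.n_slices} slices")
err = 100 * abs(result.volume - truth.true_opening_volume) / truth.true_opening_volume
print(f"relative error      : {err:.2f} %")
# The measured value is the sum of segmented per-slice areas times the slice
# thickness; on a noise-free phantom it matches the analytic sphere volume to
# well under 1%, and stays within a few percent under 5%-of-contrast noise.
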