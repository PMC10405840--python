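"""Trace tau-affected neuronal processes and compare two groups.

Renders two confocal phantoms (one "sonicated-like", one "sham-like"), each
with 21 cells bearing straight processes of prescribed lengths, then runs
the structural algorithm end to end: k-means segmentation, Hough soma
detection, skeletonization, geodesic tracing, and per-group CDFs with the
Monte-Carlo pairwise-difference statistic.
"""

from sonoquant import (
    length_cdf,
    make_confocal_field,
    mc_difference_cdf,
    measure_tau_lengths,
    single_process_field,
)


def measure(lengths, seed):
    spec = single_process_field(lengths, seed=seed)
    vol, _ = make_confocal_field(spec)
    h, w = spec.image_shape
    records = measure_tau_lengths(
        vol, k=2, radius_range=(6.0, 10.0),
        mask_polygon=[(0, 0), (0, w - 1), (h - 1, w - 1), (h - 1, 0)],
    )
    return [r.top5_mean for r in records]


sonicated = measure([145.0 + 25.0 * k for k in range(20)] + [900.0], seed=1)
sham = measure([200.0 + 50.0 * k for k in range(20)] + [1400.0], seed=2)

from sonoquant.core import EmpiricalCDF

cdf_son = EmpiricalCDF.from_samples(sonicated)
cdf_sham = EmpiricalCDF.from_samples(sham)
print(f"sonicated-like group: {len(sonicated)} cells, "
      f"95th percentile {cdf_son.quantile(0.95):.0f} μm")
print(f"sham-like group     : {len(sham)} cells, "
      f"95th percentile {cdf_sham.quantile(0.95):.0f} μm")
# 95% of per-cell process lengths lie at or below these values; shorter
# processes in the first group indicate reduced tau spread along neurites.

diff = mc_difference_cdf(sonicated, sham, n_mc=100_000, seed=3)
print(f"P(sonicated < sham) : {diff.p_A_less_B:.3f}  "
      f"(zero-crossing of the difference CDF, {diff.n_mc} draws)")
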