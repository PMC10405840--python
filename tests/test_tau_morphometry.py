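import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from sonoquant import (
    build_hippocampal_mask,
    detect_cell_centers,
    length_cdf,
    make_confocal_field,
    mc_difference_cdf,
    measure_tau_lengths,
    segment_tau,
    single_process_field,
    skeletonize_processes,
    top_fraction_mean,
    trace_processes,
)
from sonoquant.tau_morphometry import CellProcessRecord

from .conftest import SHAM_LENGTHS, SONICATED_LENGTHS, full_image_polygon


def brute_force_p_less(a, b):
    """Independent enumeration oracle: Σᵢⱼ 1[aᵢ<bⱼ] / (n_A·n_B)."""
    count = 0
    for ai in a:
        for bj in b:
            if ai < bj:
                count += 1
    return count / (len(a) * len(b))


class TestHippocampalMask:
    def test_explicit_polygon_is_exact_rectangle(self):
        img = np.zeros((50, 80))
        poly = [(10, 10), (10, 60), (40, 60), (40, 10)]
        mask = build_hippocampal_mask(img, polygon=poly)
        assert mask[25, 35]
        assert not mask[5, 5]
        rows, cols = np.nonzero(mask)
        assert rows.min() >= 10 and rows.max() <= 40
        assert cols.min() >= 10 and cols.max() <= 60

    def test_automatic_rule_covers_nuclei_disk(self):
        from skimage.draw import disk

        img = np.full((120, 120), 5.0)
        rr, cc = disk((60, 60), 30)
        img[rr, cc] = 200.0
        mask = build_hippocampal_mask(img)
        disk_mask = np.zeros_like(img, dtype=bool)
        disk_mask[rr, cc] = True
        coverage = (mask & disk_mask).sum() / disk_mask.sum()
        assert coverage >= 0.95

    def test_blank_image_without_polygon_rejected(self):
        with pytest.raises(ValueError, match="blank"):
            build_hippocampal_mask(np.zeros((20, 20)))


class TestSegmentTau:
    def test_two_level_image_separates_exactly(self):
        img = np.full((40, 40), 10.0)
        img[10:20, 10:20] = 200.0
        out = segment_tau(img, k=2)
        assert np.array_equal(out, img == 200.0)

    def test_three_level_image_keeps_top_cluster(self):
        img = np.full((60, 60), 5.0)
        img[10:30, 10:30] = 80.0    # halo
        img[15:25, 15:25] = 220.0   # soma + process level
        out = segment_tau(img, k=3)
        assert np.array_equal(out, img == 220.0)

    def test_constant_image_falls_back_and_logs(self, caplog):
        out = segment_tau(np.full((20, 20), 7.0), k=3)
        assert not out.any()
        assert any("falling back" in r.message or "constant" in r.message
                   for r in caplog.records)

    def test_k_below_two_rejected(self):
        with pytest.raises(ValueError):
            segment_tau(np.zeros((10, 10)), k=1)


class TestDetectCellCenters:
    def test_single_disk_center_within_two_px(self):
        from skimage.draw import disk

        img = np.zeros((60, 60), dtype=bool)
        rr, cc = disk((30, 28), 8)
        img[rr, cc] = True
        centers = detect_cell_centers(img, (6, 10))
        assert len(centers) == 1
        assert math.dist(centers[0], (30, 28)) <= 2.0

    def test_reference_phantom_finds_all_cells(self, sonicated_field):
        spec, vol, truth = sonicated_field
        poly = full_image_polygon(spec.image_shape)
        mask = build_hippocampal_mask(vol, polygon=poly)
        binary = segment_tau(vol.channel(1), mask, k=2)
        centers = detect_cell_centers(binary, (6, 10))
        assert len(centers) == len(truth.true_cell_centers)
        for c in centers:
            assert min(math.dist(c, t) for t in truth.true_cell_centers) <= 2.0

    def test_blank_image_yields_empty_list(self):
        assert detect_cell_centers(np.zeros((30, 30), dtype=bool), (4, 8)) == []

    def test_invalid_radius_range_rejected(self):
        with pytest.raises(ValueError):
            detect_cell_centers(np.zeros((10, 10)), (8, 4))


class TestSkeletonize:
    def test_straight_bar_thins_to_single_path(self):
        img = np.zeros((20, 120), dtype=bool)
        img[9:12, 10:110] = True  # 3-px-wide bar of length 100
        graph = skeletonize_processes(img, closing_radius=0)
        assert len(graph.endpoints) == 2
        assert len(graph.branchpoints) == 0

    def test_t_shape_has_three_endpoints_one_branch(self):
        img = np.zeros((60, 60), dtype=bool)
        img[29:32, 10:50] = True
        img[10:30, 29:32] = True
        graph = skeletonize_processes(img, closing_radius=0)
        assert len(graph.endpoints) == 3
        assert len(graph.branchpoints) >= 1

    def test_edge_weights_are_unit_or_diagonal(self):
        img = np.zeros((30, 30), dtype=bool)
        img[5:8, 5:25] = True
        graph = skeletonize_processes(img, closing_radius=0, pixel_size=0.5)
        weights = np.unique(np.round(graph.adjacency.data, 6))
        allowed = {0.5, round(math.sqrt(2) * 0.5, 6)}
        assert set(weights).issubset(allowed)

    def test_closing_bridges_small_gaps(self):
        img = np.zeros((20, 120), dtype=bool)
        img[9:12, 10:60] = True
        img[9:12, 62:110] = True  # 2-px gap, bridged by closing radius 2
        graph = skeletonize_processes(img, closing_radius=2)
        assert len(graph.endpoints) == 2


class TestTopFractionRule:
    @settings(deadline=None, max_examples=100)
    @given(st.integers(min_value=1, max_value=100))
    def test_number_averaged_is_ceil_five_percent(self, n):
        lengths = np.arange(1.0, n + 1.0)  # 1..n, distinct
        m = math.ceil(0.05 * n)
        expected = lengths[-m:].mean() if m >= 1 else lengths[-1]
        assert top_fraction_mean(lengths) == pytest.approx(expected)

    def test_forty_paths_average_two_longest(self):
        lengths = list(range(1, 41))
        assert top_fraction_mean(lengths) == pytest.approx((39 + 40) / 2)

    def test_minimum_one_path(self):
        assert top_fraction_mean([12.0]) == 12.0


class TestTraceProcesses:
    def test_straight_process_length_within_two_um(self):
        spec = single_process_field([100.0])
        vol, truth = make_confocal_field(spec)
        records = measure_tau_lengths(
            vol, k=2, radius_range=(6, 10),
            mask_polygon=full_image_polygon(spec.image_shape),
        )
        assert len(records) == 1
        assert records[0].top5_mean == pytest.approx(100.0, abs=2.0)

    def test_no_cross_assignment_between_disconnected_cells(self, sonicated_field):
        spec, vol, truth = sonicated_field
        records = measure_tau_lengths(
            vol, k=2, radius_range=(6, 10),
            mask_polygon=full_image_polygon(spec.image_shape),
        )
        measured = sorted(r.top5_mean for r in records)
        for m, t in zip(measured, sorted(truth.true_process_lengths)):
            assert m == pytest.approx(t, abs=2.0)

    def test_center_far_from_skeleton_is_flagged(self):
        img = np.zeros((40, 120), dtype=bool)
        img[19:22, 10:110] = True
        graph = skeletonize_processes(img, closing_radius=0)
        records = trace_processes(graph, [(20.0, 20.0), (5.0, 5.0)],
                                  neighborhood_radius=10.0)
        assert not records[0].flagged
        assert records[1].flagged and records[1].n_paths == 0

    def test_requires_at_least_one_center(self):
        img = np.zeros((10, 10), dtype=bool)
        graph = skeletonize_processes(img, closing_radius=0)
        with pytest.raises(ValueError):
            trace_processes(graph, [], neighborhood_radius=5.0)


class TestLengthCDF:
    def test_sonicated_reference_percentile(self):
        records = [CellProcessRecord((0, 0), np.array([v]), v) for v in SONICATED_LENGTHS]
        assert length_cdf(records).quantile(0.95) == 620.0

    def test_sham_reference_percentile(self):
        records = [CellProcessRecord((0, 0), np.array([v]), v) for v in SHAM_LENGTHS]
        assert length_cdf(records).quantile(0.95) == 1150.0

    def test_pooled_mode_uses_all_paths(self):
        records = [
            CellProcessRecord((0, 0), np.array([1.0, 2.0]), 2.0),
            CellProcessRecord((0, 1), np.array([3.0]), 3.0),
        ]
        assert length_cdf(records, pooled=True).n == 3
        assert length_cdf(records).n == 2

    def test_empty_group_rejected(self):
        with pytest.raises(ValueError):
            length_cdf([CellProcessRecord((0, 0), np.empty(0), None, flagged=True)])


class TestMCDifferenceCDF:
    def test_matches_enumeration_on_stated_mixture(self):
        a = [100.0] * 7 + [300.0] * 3
        b = [200.0]
        exact = brute_force_p_less(a, b)
        assert exact == pytest.approx(0.70)
        res = mc_difference_cdf(a, b, n_mc=100_000, seed=0)
        assert res.p_A_less_B == pytest.approx(exact, abs=0.005)

    @pytest.mark.parametrize("seed", range(10))
    def test_within_three_mc_standard_errors(self, seed):
        rng = np.random.default_rng(100 + seed)
        a = rng.uniform(50, 400, size=17)
        b = rng.uniform(100, 500, size=23)
        exact = brute_force_p_less(a, b)
        n_mc = 20_000
        res = mc_difference_cdf(a, b, n_mc=n_mc, seed=seed)
        se = math.sqrt(exact * (1 - exact) / n_mc)
        assert abs(res.p_A_less_B - exact) <= 3 * se + 1e-12

    def test_symmetry_for_identical_groups(self):
        a = [1.0, 2.0, 3.0, 4.0]
        p_ab = mc_difference_cdf(a, a, n_mc=50_000, seed=1).p_A_less_B
        p_ba = mc_difference_cdf(a, a, n_mc=50_000, seed=2).p_A_less_B
        assert p_ab == pytest.approx(p_ba, abs=0.01)

    def test_strict_ordering_gives_probability_one(self):
        res = mc_difference_cdf([1.0], [2.0], n_mc=1000, seed=0)
        assert res.p_A_less_B == 1.0

    def test_reproducible_for_fixed_seed(self):
        a, b = [1.0, 5.0, 9.0], [2.0, 4.0]
        r1 = mc_difference_cdf(a, b, n_mc=10_000, seed=42)
        r2 = mc_difference_cdf(a, b, n_mc=10_000, seed=42)
        assert r1.p_A_less_B == r2.p_A_less_B
        assert np.array_equal(r1.diff_cdf.sorted_values, r2.diff_cdf.sorted_values)

    def test_empty_group_rejected(self):
        with pytest.raises(ValueError):
            mc_difference_cdf([], [1.0])
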