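"""Skeleton graph extraction and the thirteen fiber morphology metrics."""

import math

import numpy as np
import pytest

from tmefib.morphometrics import (
    FiberMetrics,
    combine_regions,
    compute_metrics,
    skeletonize_and_prune,
)
from tmefib.synth import generate_fiber_network
from tmefib.synth.fibers import (
    FiberPhenotypeParams,
    rasterize_polylines,
    segment_orientations,
    circular_variance_axial,
)


class TestSkeletonGraph:
    def test_horizontal_bar(self):
        m = np.zeros((60, 160), bool)
        m[30:33, 20:121] = True
        g = skeletonize_and_prune(m)
        assert g.n_endpoints == 2
        assert g.n_branchpoints == 0
        assert g.total_length == pytest.approx(100, abs=2)

    def test_t_junction(self):
        m = np.zeros((120, 120), bool)
        m[20:100, 58:61] = True
        m[20:23, 30:90] = True
        g = skeletonize_and_prune(m)
        assert g.n_endpoints == 3
        assert g.n_branchpoints == 1
        assert len(g.paths) == 3

    def test_ring_is_single_cycle(self):
        yy, xx = np.mgrid[:120, :120]
        rr = np.hypot(yy - 60, xx - 60)
        g = skeletonize_and_prune((rr >= 37) & (rr <= 43))
        assert g.n_endpoints == 0
        assert g.n_branchpoints == 0
        assert g.total_length == pytest.approx(2 * math.pi * 40, rel=0.05)

    def test_empty_mask_empty_graph(self):
        g = skeletonize_and_prune(np.zeros((64, 64), bool))
        assert g.n_endpoints == 0 and g.total_length == 0 and g.paths == []

    def test_pixel_size_scales_lengths(self):
        m = np.zeros((60, 160), bool)
        m[30:33, 20:121] = True
        g1 = skeletonize_and_prune(m, pixel_size=1.0)
        g2 = skeletonize_and_prune(m, pixel_size=0.5, prune_below=2.5)
        assert g2.total_length == pytest.approx(g1.total_length / 2)


class TestMetricLimits:
    def test_filled_mask(self):
        fm = compute_metrics(np.ones((128, 128), bool))
        assert fm.density == 1.0
        assert fm.lacunarity == pytest.approx(1.0)
        assert fm.fractal_dimension == pytest.approx(2.0, abs=0.05)

    def test_single_straight_fiber(self):
        m = np.zeros((128, 128), bool)
        m[63:66, 10:118] = True
        fm = compute_metrics(m)
        assert fm.alignment >= 0.95
        assert fm.curvature == pytest.approx(0.0, abs=2.0)
        assert fm.fractal_dimension == pytest.approx(1.0, abs=0.1)

    def test_hgu_identity_on_generated_networks(self, network_a, network_b):
        for net in (network_a, network_b):
            fm = compute_metrics(net.mask)
            assert fm.hyphal_growth_unit * fm.n_endpoints == pytest.approx(
                fm.total_length
            )
            assert 0 <= fm.alignment <= 1
            assert 0 <= fm.density <= 1
            assert fm.lacunarity >= 1

    def test_parallel_vs_isotropic_alignment(self):
        base = dict(
            n_fibers=400, mean_length=60.0, length_cv=0.1, step_angle_sd=0.0,
            branching_rate=0.0, crosslink_density=0.0, fiber_width=2.0,
            target_coverage=0.08,
        )
        par = generate_fiber_network(
            FiberPhenotypeParams(orientation_kappa=1e6, **base), shape=(256, 256), seed=1
        )
        iso = generate_fiber_network(
            FiberPhenotypeParams(orientation_kappa=0.0, **base), shape=(256, 256), seed=1
        )
        # oracle: planted polyline orientations confirm the contrast
        assert circular_variance_axial(segment_orientations(par.polylines)) < 0.05
        assert circular_variance_axial(segment_orientations(iso.polylines)) > 0.9
        a_par = compute_metrics(par.mask).alignment
        a_iso = compute_metrics(iso.mask).alignment
        assert a_par > 0.7
        assert a_iso < 0.3

    def test_rotation_invariance(self, network_a):
        fm = compute_metrics(network_a.mask)
        fm_rot = compute_metrics(np.rot90(network_a.mask))
        for name in ("total_length", "density", "lacunarity", "fractal_dimension",
                     "alignment"):
            a, b = getattr(fm, name), getattr(fm_rot, name)
            assert b == pytest.approx(a, rel=0.02, abs=0.02), name


def test_nested_masks_lacunarity_decreases_with_coverage():
    """Gliding-box lacunarity is (statistically) antitone in coverage."""
    params = FiberPhenotypeParams(
        n_fibers=300, mean_length=80.0, length_cv=0.2, orientation_kappa=0.0,
        step_angle_sd=1.0, branching_rate=0.0, crosslink_density=0.0,
        fiber_width=2.0, target_coverage=0.15,
    )
    hold = 0
    n_pairs = 100
    for s in range(n_pairs):
        net = generate_fiber_network(params, shape=(128, 128), seed=100 + s)
        k = max(len(net.polylines) // 2, 1)
        sub = rasterize_polylines(net.polylines[:k], (128, 128), 1.0, 2.0)
        lam_sub = compute_metrics(sub).lacunarity
        lam_full = compute_metrics(net.mask).lacunarity
        hold += lam_sub >= lam_full
    assert hold / n_pairs >= 0.95


class TestCombineRegions:
    def _row(self, **kw):
        base = dict(
            n_endpoints=4, n_branchpoints=2, endpoint_branchpoint_ratio=2.0,
            total_length=200.0, avg_fiber_length=40.0, hyphal_growth_unit=50.0,
            curvature=5.0, alignment=0.2, fractal_dimension=1.4, lacunarity=2.0,
            density=0.1, hdm=0.2, mean_gap_diameter=10.0, mask_area=100.0,
            n_fibers=5,
        )
        base.update(kw)
        return FiberMetrics(**base)

    def test_single_region_identity(self):
        r = self._row()
        assert combine_regions([r]) is r

    def test_area_weighted_patterns_and_additive_sums(self):
        r1 = self._row(mask_area=100.0, alignment=0.2, n_endpoints=4,
                       total_length=200.0)
        r2 = self._row(mask_area=300.0, alignment=0.6, n_endpoints=6,
                       total_length=300.0)
        c = combine_regions([r1, r2])
        assert c.alignment == pytest.approx((100 * 0.2 + 300 * 0.6) / 400)
        assert c.n_endpoints == 10
        assert c.total_length == pytest.approx(500.0)
        assert c.hyphal_growth_unit == pytest.approx(50.0)  # 500 / 10
        assert c.mask_area == pytest.approx(400.0)

    def test_permutation_invariance_and_associativity(self):
        rows = [
            self._row(mask_area=50.0, alignment=0.1, lacunarity=3.0, n_endpoints=2),
            self._row(mask_area=120.0, alignment=0.5, lacunarity=1.5, n_endpoints=7),
            self._row(mask_area=80.0, alignment=0.9, lacunarity=2.2, n_endpoints=3),
        ]
        c1 = combine_regions(rows)
        c2 = combine_regions(rows[::-1])
        c3 = combine_regions([combine_regions(rows[:2]), rows[2]])
        for name in ("alignment", "lacunarity", "density", "hdm", "curvature"):
            assert getattr(c1, name) == pytest.approx(getattr(c2, name), abs=1e-9)
            assert getattr(c1, name) == pytest.approx(getattr(c3, name), abs=1e-9)
        assert c1.n_endpoints == c2.n_endpoints == c3.n_endpoints

    def test_zero_total_area_flags_patterns_missing(self):
        r = self._row(mask_area=0.0)
        c = combine_regions([r, self._row(mask_area=0.0)])
        assert math.isnan(c.alignment)
        assert c.n_endpoints == 8  # additive metrics still defined

    def test_empty_input_refused(self):
        with pytest.raises(ValueError):
            combine_regions([])
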