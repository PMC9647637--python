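"""Positive-pixel IHC scoring and TLS/TIL record assembly."""

import math

import numpy as np
import pytest
from shapely.geometry import box

from tmefib.geometry import Region, RegionSet
from tmefib.quantify import (
    DEFAULT_THRESHOLDS,
    AnnotatedSlide,
    ChromogenClass,
    estimate_counts,
    positive_pixel_areas,
    til_counts,
    tls_properties,
)
from tmefib.synth import CohortGenParams, build_scene, generate_cohort
from tmefib.synth.render import CHROMOGEN_RGB


class TestPositivePixels:
    def test_all_white_region_zero(self):
        img = np.full((50, 50, 3), 255, np.uint8)
        areas = positive_pixel_areas(img, None, DEFAULT_THRESHOLDS)
        assert areas == {"brown_area": 0.0, "pink_area": 0.0, "total_tissue_area": 0.0}

    def test_planted_brown_pixels_exact(self):
        img = np.full((100, 100, 3), 255, np.uint8)
        img[10:20, 0:100] = CHROMOGEN_RGB["brown_t"]  # 1000 px
        areas = positive_pixel_areas(img, None, DEFAULT_THRESHOLDS, pixel_size=1.0)
        assert areas["brown_area"] == 1000.0
        assert areas["pink_area"] == 0.0

    def test_hue_boundary_is_closed(self):
        cls = ChromogenClass(hue_center=0.5, hue_width=0.1, min_saturation=0.0,
                             max_intensity=1.0)
        hsv = np.array([[[0.6, 1.0, 0.5]]])  # hue exactly at center + width
        assert cls.match(hsv)[0, 0]
        hsv[0, 0, 0] = 0.6000001
        assert not cls.match(hsv)[0, 0]

    def test_region_outside_image_fails(self):
        img = np.full((50, 50, 3), 255, np.uint8)
        with pytest.raises(ValueError, match="outside"):
            positive_pixel_areas(img, box(0, 0, 100, 100), DEFAULT_THRESHOLDS)

    def test_areas_additive_over_partition(self):
        img = np.full((60, 60, 3), 255, np.uint8)
        rng = np.random.default_rng(1)
        pts = rng.integers(0, 60, size=(200, 2))
        img[pts[:, 0], pts[:, 1]] = CHROMOGEN_RGB["brown_t"]
        left = np.zeros((60, 60), bool)
        left[:, :30] = True
        a_all = positive_pixel_areas(img, None, DEFAULT_THRESHOLDS)["brown_area"]
        a_l = positive_pixel_areas(img, left, DEFAULT_THRESHOLDS)["brown_area"]
        a_r = positive_pixel_areas(img, ~left, DEFAULT_THRESHOLDS)["brown_area"]
        assert a_l + a_r == pytest.approx(a_all)

    def test_wider_hue_band_never_decreases_area(self):
        img = np.full((40, 40, 3), 255, np.uint8)
        img[5:15, 5:25] = CHROMOGEN_RGB["brown_t"]
        img[20:30, 5:25] = (150, 95, 45)  # near-brown hue
        narrow = DEFAULT_THRESHOLDS
        wide = ChromogenClass(
            narrow.brown_t.hue_center, 0.2, narrow.brown_t.min_saturation,
            narrow.brown_t.max_intensity,
        )
        from dataclasses import replace

        t_wide = replace(narrow, brown_t=wide)
        a_narrow = positive_pixel_areas(img, None, narrow)["brown_area"]
        a_wide = positive_pixel_areas(img, None, t_wide)["brown_area"]
        assert a_wide >= a_narrow


class TestCountEstimation:
    def test_area_to_count_arithmetic(self):
        c = estimate_counts(
            {"brown_area": 3800.0, "pink_area": 0.0}, DEFAULT_THRESHOLDS
        )
        assert c["t_count"] == 100

    def test_b_fraction(self):
        c = estimate_counts(
            {"brown_area": 75 * 38.0, "pink_area": 25 * 38.0}, DEFAULT_THRESHOLDS
        )
        assert c["b_fraction"] == pytest.approx(0.25)

    def test_no_cells_fraction_missing_not_zero(self):
        c = estimate_counts({"brown_area": 0.0, "pink_area": 0.0}, DEFAULT_THRESHOLDS)
        assert math.isnan(c["b_fraction"])


@pytest.fixture(scope="module")
def tls_scene():
    les, tls, tum = generate_cohort(CohortGenParams(n_lesions=6), seed=4)
    lid = les[les.any_tls == 1].lesion_id.iloc[0]
    tls_rows = tls[tls.lesion_id == lid].to_dict("records")
    # plant a known B fraction at comfortable density
    for r in tls_rows:
        r["true_t_count"], r["true_b_count"] = 70, 30
    scene = build_scene(
        lid,
        tum[tum.lesion_id == lid].to_dict("records"),
        tls_rows,
        size=384,
        seed=8,
        max_tumors=3,
        max_tls=2,
    )
    return scene


class TestRecords:
    def test_tls_b_fraction_recovered(self, tls_scene):
        slide = AnnotatedSlide(tls_scene.image_ihc, tls_scene.regions)
        recs = tls_properties(slide)
        assert recs == sorted(recs, key=lambda r: r.tls_id)
        for r in recs:
            truth = tls_scene.truth_counts[r.tls_id]
            planted_bf = truth["b"] / (truth["t"] + truth["b"])
            assert r.b_fraction == pytest.approx(planted_bf, abs=0.05)
            assert r.relative_size == pytest.approx(
                r.area_mm2 * 1e6 / (384 * 383), rel=0.02
            )

    def test_til_counts_recovered_within_ten_percent(self, tls_scene):
        slide = AnnotatedSlide(tls_scene.image_ihc, tls_scene.regions)
        for rec in til_counts(slide):
            truth = tls_scene.truth_counts[rec.tumor_id]
            total = truth["t"] + truth["b"]
            assert rec.til_count == pytest.approx(total, rel=0.10, abs=2)
            assert rec.proximity in ("proximal", "distal", "control")

    def test_control_lesion_records(self):
        les, tls, tum = generate_cohort(CohortGenParams(n_lesions=10), seed=6)
        lid = les[les.any_tls == 0].lesion_id.iloc[0]
        scene = build_scene(lid, tum[tum.lesion_id == lid].to_dict("records"), [],
                            size=256, seed=9, max_tumors=2)
        slide = AnnotatedSlide(scene.image_ihc, scene.regions)
        recs = til_counts(slide)
        assert recs
        for r in recs:
            assert r.proximity == "control"
            assert r.tls_id is None

    def test_empty_tumor_zero_tils(self):
        img = np.full((200, 200, 3), 255, np.uint8)
        rs = RegionSet(
            [Region("t1", "tumor", box(20, 20, 80, 80), lesion_id="L")], 1.0
        )
        recs = til_counts(AnnotatedSlide(img, rs))
        assert recs[0].til_count == 0


def test_primary_tls_exceed_aggregate_on_synthetic_cohort():
    """Direction check: primary-stage TLS are bigger and B-richer."""
    _, tls, _ = generate_cohort(CohortGenParams(n_lesions=60), seed=12)
    prim = tls[tls.stage == "primary"]
    agg = tls[tls.stage == "aggregate"]
    assert prim.true_b_count.median() > agg.true_b_count.median()
    assert (prim.true_t_count + prim.true_b_count).median() > (
        agg.true_t_count + agg.true_b_count
    ).median()
    assert prim.true_area_mm2.median() > agg.true_area_mm2.median()
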