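"""Feature stack, pixel classifier training/prediction and QC gating."""

import numpy as np
import pytest
from scipy import ndimage

from tmefib.classify import (
    LabelScribbles,
    compute_feature_stack,
    feature_names,
    predict_maps,
    qc_eligibility,
    train_classifier,
)
from tmefib.stains import HE_STAINS, separate_stains
from tmefib.synth import build_scene, generate_cohort, CohortGenParams
from tmefib.synth.render import LABEL_CODES


class TestFeatureStack:
    def test_constant_image_flat_features(self):
        f = compute_feature_stack(np.full((64, 64), 3.0), scales=(1.0, 2.0))
        names = feature_names((1.0, 2.0))
        for i, name in enumerate(names):
            band = f[..., i]
            # truncated-kernel float32 filters leave ~1e-4 residuals
            if "gauss" in name or name == "raw":
                assert np.allclose(band, 3.0, atol=1e-3)
            else:
                assert np.allclose(band, 0.0, atol=1e-3), name

    def test_band_count(self):
        f = compute_feature_stack(np.zeros((32, 32)), scales=(1.0, 2.0, 3.0))
        assert f.shape[-1] == 6 * 3 + 1

    def test_ridge_has_larger_hessian_response(self):
        img = np.zeros((64, 64))
        img[30:33, :] = 1.0
        f = compute_feature_stack(img, scales=(2.0,))
        # a bright ridge drives the smaller (most negative) eigenvalue
        e2 = np.abs(f[..., 5])
        assert e2[31, 32] > e2[10, 32] * 5

    def test_oversized_scale_refused(self):
        with pytest.raises(ValueError):
            compute_feature_stack(np.zeros((32, 32)), scales=(16.0,))


def _texture_problem(seed=0):
    """Two linearly separable textures side by side, with scribbles."""
    rng = np.random.default_rng(seed)
    img = np.zeros((64, 128))
    img[:, :64] = rng.normal(0.2, 0.02, (64, 64))
    img[:, 64:] = rng.normal(0.8, 0.02, (64, 64))
    feats = compute_feature_stack(img, scales=(1.0,))
    rows = np.arange(64)
    left = np.stack([np.repeat(rows, 10), np.tile(np.arange(10, 20), 64)], axis=1)
    right = np.stack([np.repeat(rows, 10), np.tile(np.arange(100, 110), 64)], axis=1)
    scrib = LabelScribbles({"background": left, "fibrillary_matrix": right})
    return img, feats, scrib


class TestTraining:
    def test_training_accuracy_on_separable_textures(self):
        _, feats, scrib = _texture_problem()
        clf = train_classifier(feats, scrib, seed=0, n_estimators=20)
        _, labels, fib, _ = predict_maps(feats, clf)
        acc = (labels[:, 100:110] == clf.classes.index("fibrillary_matrix")).mean()
        assert acc >= 0.95

    def test_determinism_and_scribble_permutation(self):
        _, feats, scrib = _texture_problem()
        clf1 = train_classifier(feats, scrib, seed=3, n_estimators=10)
        perm = LabelScribbles(dict(reversed(list(scrib.coords.items()))))
        clf2 = train_classifier(feats, perm, seed=3, n_estimators=10)
        p1 = predict_maps(feats, clf1)[0].maps
        p2 = predict_maps(feats, clf2)[0].maps
        assert np.array_equal(p1, p2)

    def test_single_class_refused(self):
        _, feats, scrib = _texture_problem()
        single = LabelScribbles({"background": scrib.coords["background"]})
        with pytest.raises(ValueError, match="2 classes"):
            train_classifier(feats, single)

    def test_small_class_refused_by_name(self):
        _, feats, scrib = _texture_problem()
        scrib.coords["mucin"] = np.array([[1, 1], [2, 2]])
        with pytest.raises(ValueError, match="mucin"):
            train_classifier(feats, scrib)

    def test_band_mismatch_refused(self):
        _, feats, scrib = _texture_problem()
        clf = train_classifier(feats, scrib, seed=0, n_estimators=5)
        with pytest.raises(ValueError, match="band"):
            predict_maps(feats[..., :3], clf)

    def test_probabilities_sum_to_one(self):
        _, feats, scrib = _texture_problem()
        clf = train_classifier(feats, scrib, seed=0, n_estimators=10)
        maps, *_ = predict_maps(feats, clf)
        assert np.allclose(maps.maps.sum(axis=-1), 1.0, atol=1e-6)


class TestSceneSegmentation:
    def test_fibrillary_dice_on_synthetic_scene(self):
        les, tls, tum = generate_cohort(CohortGenParams(n_lesions=4), seed=2)
        lid = les.lesion_id.iloc[0]
        scene = build_scene(
            lid,
            tum[tum.lesion_id == lid].to_dict("records"),
            tls[tls.lesion_id == lid].to_dict("records"),
            size=256,
            seed=5,
            max_tumors=2,
            max_tls=1,
        )
        eosin = separate_stains(scene.image_he, HE_STAINS)["eosin"]
        feats = compute_feature_stack(eosin, scales=(1.0, 2.0))
        truth = scene.truth_labels
        palette = np.ones_like(truth)  # background + tumor/tls -> class 1
        palette[truth == LABEL_CODES["fibrillary_matrix"]] = 2
        palette[truth == LABEL_CODES["nuclei"]] = 3
        scrib = LabelScribbles.from_label_image(palette, max_per_class=1500, seed=0)
        scrib.coords = {k: v for k, v in scrib.coords.items() if len(v) >= 50}
        clf = train_classifier(feats, scrib, seed=0, n_estimators=30)
        _, _, fib, _ = predict_maps(feats, clf)
        t = scene.truth_mask("fibrillary_matrix")
        dice = 2 * (fib & t).sum() / max(fib.sum() + t.sum(), 1)
        assert dice >= 0.85


class TestQc:
    def test_blurred_copy_becomes_ineligible(self, rng):
        sharp = rng.random((128, 128))
        ok_sharp, _ = qc_eligibility(sharp)
        blurred = ndimage.gaussian_filter(sharp, 12.0)
        ok_blur, reasons = qc_eligibility(blurred)
        assert ok_sharp
        assert not ok_blur and "blur" in reasons

    def test_tiny_image_ineligible_by_resolution(self):
        ok, reasons = qc_eligibility(np.random.default_rng(0).random((10, 10)))
        assert not ok and "resolution" in reasons

    def test_sharp_synthetic_scene_eligible(self):
        les, tls, tum = generate_cohort(CohortGenParams(n_lesions=4), seed=3)
        lid = les.lesion_id.iloc[0]
        scene = build_scene(lid, tum[tum.lesion_id == lid].to_dict("records"),
                            tls[tls.lesion_id == lid].to_dict("records"),
                            size=256, seed=6, max_tumors=2, max_tls=1)
        eosin = separate_stains(scene.image_he, HE_STAINS)["eosin"]
        ok, reasons = qc_eligibility(eosin)
        assert ok, reasons
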