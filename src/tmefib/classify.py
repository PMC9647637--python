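"""Trainable pixel classification of the eosin channel.

A multiscale filter bank (Gaussian smoothing, gradient magnitude, Laplacian,
Hessian eigenvalues, local variance — plus the raw channel) feeds a random
forest trained from sparse user scribbles, in the spirit of interactive
segmentation plugins.  The class vocabulary is fixed: background, fibrillary
matrix, nuclei, mucin, amyloid.  Reticulin, elastin and collagen are not
separable on H&E and are represented by the single merged "fibrillary
matrix" class.

One classifier artifact is trained per project and applied to every eligible
image; ``qc_eligibility`` screens images for blur (variance of the
Laplacian) and minimum resolution first.
"""

from __future__ import annotations

import pickle
from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from skimage.feature import hessian_matrix, hessian_matrix_eigvals
from sklearn.ensemble import RandomForestClassifier

__all__ = [
    "CLASS_NAMES",
    "LabelScribbles",
    "PixelClassifier",
    "ProbabilityMaps",
    "compute_feature_stack",
    "feature_names",
    "train_classifier",
    "predict_maps",
    "qc_eligibility",
]

CLASS_NAMES = ("background", "fibrillary_matrix", "nuclei", "mucin", "amyloid")
DEFAULT_SCALES = (1.0, 2.0, 4.0)
MIN_SCRIBBLE_PX = 50

#: blur threshold on the variance of the Laplacian of a [0, 1]-scaled image,
#: calibrated once on sharp synthetic renders (which score far above it)
DEFAULT_MIN_LAPLACIAN_VAR = 1e-4
DEFAULT_MIN_RESOLUTION = 64


def feature_names(scales=DEFAULT_SCALES):
    names = ["raw"]
    for s in scales:
        names += [
            f"gauss_{s:g}",
            f"gradmag_{s:g}",
            f"laplacian_{s:g}",
            f"hessian_e1_{s:g}",
            f"hessian_e2_{s:g}",
            f"localvar_{s:g}",
        ]
    return names


def compute_feature_stack(channel: np.ndarray, scales=DEFAULT_SCALES) -> np.ndarray:
    """Per-pixel features: raw + 6 filters per scale, band order fixed.

    Bands per scale: Gaussian smooth, gradient magnitude, Laplacian of
    Gaussian, larger/smaller Hessian eigenvalue, local variance.
    """
    if len(scales) == 0:
        raise ValueError("at least one scale required")
    img = np.asarray(channel, dtype=np.float64)
    if img.ndim != 2:
        raise ValueError("feature stack expects a single-channel raster")
    if max(scales) > min(img.shape) / 4:
        raise ValueError("largest scale exceeds image size / 4")
    bands = [img]
    for s in scales:
        smooth = ndimage.gaussian_filter(img, s, mode="nearest")
        gx = ndimage.gaussian_filter(img, s, order=(0, 1), mode="nearest")
        gy = ndimage.gaussian_filter(img, s, order=(1, 0), mode="nearest")
        gradmag = np.hypot(gx, gy)
        lap = ndimage.gaussian_laplace(img, s, mode="nearest")
        h = hessian_matrix(
            img, sigma=s, order="rc", use_gaussian_derivatives=False, mode="nearest"
        )
        e1, e2 = hessian_matrix_eigvals(h)
        mean = smooth
        meansq = ndimage.gaussian_filter(img**2, s, mode="nearest")
        localvar = np.clip(meansq - mean**2, 0.0, None)
        bands += [smooth, gradmag, lap, e1, e2, localvar]
    return np.stack(bands, axis=-1).astype(np.float32)


@dataclass
class LabelScribbles:
    """Sparse per-class training coordinates ((row, col) int arrays)."""

    coords: dict

    def __post_init__(self):
        seen = set()
        for name, pts in self.coords.items():
            if name not in CLASS_NAMES:
                raise ValueError(f"unknown class {name!r}")
            pts = np.asarray(pts, dtype=int)
            if pts.ndim != 2 or pts.shape[1] != 2:
                raise ValueError(f"{name}: coords must be (N, 2)")
            key = set(map(tuple, pts))
            if key & seen:
                raise ValueError("scribble classes must be disjoint")
            seen |= key
            self.coords[name] = pts

    @classmethod
    def from_label_image(cls, labels: np.ndarray, max_per_class: int | None = None, seed: int = 0):
        """Palette-index label raster (0 = unlabelled, i = CLASS_NAMES[i-1])."""
        rng = np.random.default_rng(seed)
        coords = {}
        for i, name in enumerate(CLASS_NAMES, start=1):
            pts = np.argwhere(labels == i)
            if len(pts) == 0:
                continue
            if max_per_class and len(pts) > max_per_class:
                pts = pts[rng.choice(len(pts), max_per_class, replace=False)]
            coords[name] = pts
        return cls(coords)


@dataclass
class PixelClassifier:
    """Serializable random-forest pixel classifier with a band manifest."""

    model: RandomForestClassifier
    classes: tuple
    n_bands: int
    scales: tuple

    def save(self, path):
        with open(path, "wb") as fh:
            pickle.dump(self, fh)

    @classmethod
    def load(cls, path) -> "PixelClassifier":
        with open(path, "rb") as fh:
            obj = pickle.load(fh)
        if not isinstance(obj, cls):
            raise TypeError("not a PixelClassifier artifact")
        return obj


@dataclass
class ProbabilityMaps:
    """Per-class probability rasters (sum to 1 per pixel) in class order."""

    maps: np.ndarray  # (H, W, C)
    classes: tuple

    def __getitem__(self, name):
        return self.maps[..., self.classes.index(name)]


def train_classifier(
    features: np.ndarray,
    scribbles: LabelScribbles,
    seed: int = 0,
    n_estimators: int = 100,
    scales=DEFAULT_SCALES,
) -> PixelClassifier:
    """Fit the forest on scribbled pixels; deterministic given the seed.

    Classes with fewer than 50 scribbled pixels are refused by name; at least
    two classes must be present.  Training rows are ordered canonically
    (class name, then row-major pixel order) so permuting the scribble dict
    leaves the fitted model unchanged.
    """
    present = sorted(scribbles.coords)
    if len(present) < 2:
        raise ValueError("training requires at least 2 classes")
    for name in present:
        if len(scribbles.coords[name]) < MIN_SCRIBBLE_PX:
            raise ValueError(
                f"class {name!r} has {len(scribbles.coords[name])} scribbled px "
                f"(minimum {MIN_SCRIBBLE_PX})"
            )
    xs, ys = [], []
    for ci, name in enumerate(present):
        pts = scribbles.coords[name]
        order = np.lexsort((pts[:, 1], pts[:, 0]))
        pts = pts[order]
        xs.append(features[pts[:, 0], pts[:, 1]])
        ys.append(np.full(len(pts), ci))
    X = np.concatenate(xs)
    y = np.concatenate(ys)
    model = RandomForestClassifier(
        n_estimators=n_estimators, random_state=int(seed), n_jobs=1
    )
    model.fit(X, y)
    return PixelClassifier(
        model=model,
        classes=tuple(present),
        n_bands=features.shape[-1],
        scales=tuple(scales),
    )


def predict_maps(features: np.ndarray, clf: PixelClassifier, pixel_size: float = 1.0):
    """Probability maps, argmax labels and the fibrillary binary mask.

    Returns ``(ProbabilityMaps, label_raster, fibrillary_mask, mask_area_um2)``
    where labels index ``clf.classes``.  Fails when the band count differs
    from the training manifest.
    """
    if features.shape[-1] != clf.n_bands:
        raise ValueError(
            f"feature bands ({features.shape[-1]}) do not match the "
            f"classifier manifest ({clf.n_bands})"
        )
    h, w, b = features.shape
    proba = clf.model.predict_proba(features.reshape(-1, b)).reshape(h, w, -1)
    labels = np.argmax(proba, axis=-1)
    if "fibrillary_matrix" in clf.classes:
        fib = labels == clf.classes.index("fibrillary_matrix")
    else:
        fib = np.zeros((h, w), dtype=bool)
    area = float(fib.sum()) * pixel_size**2
    return ProbabilityMaps(proba, clf.classes), labels, fib, area


def qc_eligibility(
    image: np.ndarray,
    min_laplacian_var: float = DEFAULT_MIN_LAPLACIAN_VAR,
    min_resolution: int = DEFAULT_MIN_RESOLUTION,
):
    """Image-quality gate: blur (variance of Laplacian) and raster size.

    Returns ``(eligible, reasons)``; ``reasons`` lists 'blur' and/or
    'resolution'.  Intensities are rescaled to [0, 1] before the blur metric
    so the threshold is exposure-independent.
    """
    img = np.asarray(image, dtype=float)
    if img.ndim == 3:
        img = img.mean(axis=-1)
    reasons = []
    if min(img.shape) < min_resolution:
        reasons.append("resolution")
    rng_ = np.ptp(img)
    scaled = (img - img.min()) / rng_ if rng_ > 0 else np.zeros_like(img)
    lap_var = float(ndimage.laplace(scaled).var())
    if lap_var < min_laplacian_var:
        reasons.append("blur")
    return len(reasons) == 0, reasons
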