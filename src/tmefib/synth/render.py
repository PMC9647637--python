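"""Rendering of synthetic dual-chromogen IHC and H&E-like images.

IHC: T cells are drawn as brown (DAB-like) disks, B cells as pink
(fast-red-like) disks and nuclei as small blue (hematoxylin-like) disks on a
white background.  The chromogen RGB constants are fixed and documented so
positive-pixel hue/saturation thresholds can be written against known hues.

H&E: per-pixel hematoxylin and eosin concentration maps are assembled from
the ground-truth class raster (fibrillary matrix strongly eosinophilic,
amyloid moderately, mucin palely; nuclei hematoxylin-rich) and pushed
through the Beer-Lambert forward model, so color deconvolution downstream
recovers the planted concentrations.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from skimage.draw import disk as draw_disk

from ..stains import HE_STAINS, od_to_rgb

__all__ = [
    "CHROMOGEN_RGB",
    "CellPlacement",
    "render_ihc",
    "render_he",
    "concentrations_from_labels",
    "LABEL_CODES",
    "NOMINAL_CELL_AREA_UM2",
]

#: fixed chromogen colors (8-bit RGB); hues ~0.075 (brown), ~0.94 (pink),
#: ~0.64 (blue)
CHROMOGEN_RGB = {
    "brown_t": (130, 80, 40),
    "pink_b": (230, 105, 150),
    "blue_nucleus": (70, 85, 160),
}

#: nominal lymphocyte footprint (7-um disk)
NOMINAL_CELL_AREA_UM2 = 38.0

#: truth-raster class codes shared by the whole synthetic stack
LABEL_CODES = {
    "background": 0,
    "tumor": 1,
    "tls": 2,
    "fibrillary_matrix": 3,
    "nuclei": 4,
    "mucin": 5,
    "amyloid": 6,
}

#: region-role precedence when planted regions overlap
_ROLE_PRECEDENCE = {"tumor": 0, "tls": 1, "stroma": 2}


@dataclass
class CellPlacement:
    """Cells to plant in one region: ``n_t`` T cells and ``n_b`` B cells."""

    region_id: str
    mask: np.ndarray  # bool raster of the region
    n_t: int
    n_b: int
    role: str = "stroma"

    def __post_init__(self):
        if self.n_t < 0 or self.n_b < 0:
            raise ValueError("cell counts must be nonnegative")


def _plant_disks(canvas, centers, radius_px, color):
    for r, c in centers:
        rr, cc = draw_disk((r, c), radius_px, shape=canvas.shape[:2])
        canvas[rr, cc] = color


def _spaced_centers(rng, candidates, n, radius_px, shape):
    """Sample ~non-overlapping cell centers (falls back to overlap when the
    region saturates, so planted counts always equal requested counts)."""
    blocked = np.zeros(shape, dtype=bool)
    centers = []
    pool = candidates[rng.permutation(len(candidates))]
    i = 0
    for _ in range(n):
        while i < len(pool) and blocked[pool[i][0], pool[i][1]]:
            i += 1
        if i < len(pool):
            r, c = pool[i]
            i += 1
        else:  # saturated: overlap unavoidable
            r, c = pool[rng.integers(len(pool))]
        centers.append((r, c))
        rr, cc = draw_disk((r, c), 2 * radius_px, shape=shape)
        blocked[rr, cc] = True
    return centers


def render_ihc(
    shape: tuple[int, int],
    placements: list,
    pixel_size: float = 1.0,
    seed: int = 0,
    nucleus_density_per_mm2: float = 300.0,
    tissue_mask: np.ndarray | None = None,
    melanin_density_per_mm2: float = 0.0,
):
    """Render a dual-chromogen IHC-like RGB image with planted cells.

    Overlapping regions are resolved by role precedence (tumor > TLS >
    stroma): a conflicted pixel belongs to the highest-precedence region and
    that region's cells are planted only on pixels it owns.  Returns
    ``(rgb_uint8, truth)`` where ``truth`` maps region_id ->
    ``{"t": planted T, "b": planted B}``; planted counts are the ground
    truth for recovery tests.
    """
    rng = np.random.default_rng(seed)
    img = np.full((*shape, 3), 255, dtype=np.uint8)
    if tissue_mask is None:
        tissue_mask = np.ones(shape, dtype=bool)

    # ownership raster by precedence
    owner = np.full(shape, -1, dtype=int)
    order = sorted(
        range(len(placements)),
        key=lambda i: _ROLE_PRECEDENCE.get(placements[i].role, 3),
    )
    for i in reversed(order):  # lowest precedence first, highest overwrites
        owner[placements[i].mask] = i

    # background nuclei (counterstain) across tissue
    area_mm2 = tissue_mask.sum() * pixel_size**2 / 1e6
    n_nuc = rng.poisson(nucleus_density_per_mm2 * area_mm2)
    cand = np.argwhere(tissue_mask)
    if len(cand) and n_nuc:
        pts = cand[rng.integers(len(cand), size=n_nuc)]
        _plant_disks(img, pts, max(2.5 / pixel_size, 1), CHROMOGEN_RGB["blue_nucleus"])

    # optional melanin contamination: brown speckles that fall inside the
    # T-cell hue band and inflate brown-positive areas
    n_mel = rng.poisson(melanin_density_per_mm2 * area_mm2)
    if len(cand) and n_mel:
        pts = cand[rng.integers(len(cand), size=n_mel)]
        _plant_disks(img, pts, max(1.5 / pixel_size, 1), (110, 70, 35))

    radius_px = max(math.sqrt(NOMINAL_CELL_AREA_UM2 / math.pi) / pixel_size, 1.0)
    truth = {}
    for i, pl in enumerate(placements):
        own_mask = pl.mask & (owner == i)
        # keep whole disks inside the region so planted areas stay recoverable
        eroded = ndimage.binary_erosion(own_mask, iterations=int(round(radius_px)))
        own = np.argwhere(eroded if eroded.any() else own_mask)
        placed_t = placed_b = 0
        if len(own):
            n_total = pl.n_t + pl.n_b
            if n_total:
                centers = _spaced_centers(rng, own, n_total, int(round(radius_px)), shape)
                _plant_disks(img, centers[: pl.n_t], radius_px, CHROMOGEN_RGB["brown_t"])
                _plant_disks(img, centers[pl.n_t :], radius_px, CHROMOGEN_RGB["pink_b"])
                placed_t, placed_b = pl.n_t, pl.n_b
        truth[pl.region_id] = {"t": placed_t, "b": placed_b}
    return img, truth


def concentrations_from_labels(labels: np.ndarray, seed: int = 0):
    """Hematoxylin/eosin concentration maps from a truth class raster.

    Eosin levels: fibrillary matrix 0.9, amyloid 0.55, mucin 0.2, tumor
    cytoplasm 0.15; hematoxylin: nuclei 0.9, tumor 0.55, TLS 0.5 (dense
    lymphocytes).  Mild multiplicative noise keeps textures non-degenerate.
    """
    rng = np.random.default_rng(seed)
    eosin = np.zeros(labels.shape, dtype=float)
    hema = np.zeros(labels.shape, dtype=float)
    eosin[labels == LABEL_CODES["fibrillary_matrix"]] = 0.9
    eosin[labels == LABEL_CODES["amyloid"]] = 0.55
    eosin[labels == LABEL_CODES["mucin"]] = 0.2
    eosin[labels == LABEL_CODES["tumor"]] += 0.15
    hema[labels == LABEL_CODES["nuclei"]] = 0.9
    hema[labels == LABEL_CODES["tumor"]] += 0.55
    hema[labels == LABEL_CODES["tls"]] += 0.5
    noise = rng.normal(1.0, 0.05, labels.shape)
    return hema * noise, eosin * noise


def render_he(hematoxylin: np.ndarray, eosin: np.ndarray, white_level: float = 255.0):
    """Beer-Lambert forward render of concentration maps to RGB uint8."""
    conc = np.stack([hematoxylin, eosin, np.zeros_like(eosin)], axis=-1)
    od = conc @ HE_STAINS.vectors
    return od_to_rgb(od, white_level).astype(np.uint8)
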