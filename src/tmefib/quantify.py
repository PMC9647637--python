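"""Positive-pixel quantification of dual-chromogen IHC.

Pixels are classified as brown (T-cell chromogen), pink (B-cell chromogen)
or counterstain by hue/saturation/intensity thresholds in HSV space; class
areas integrate to cell-count estimates through a nominal lymphocyte
footprint.  Thresholds are held constant across a project run.  Per-TLS
records (T/B counts, B fraction, area, relative size) and per-tumor TIL
records (with TLS proximity class) are assembled from an annotated slide.

The count conversion constant (default 38 um^2, a 7-um disk) is
configurable; it cancels in every fraction and ratio statistic downstream.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from skimage.color import rgb2hsv

from .geometry import (
    PROXIMITY_CUTOFF_UM,
    Region,
    RegionSet,
    classify_proximity,
    rasterize_region,
)

__all__ = [
    "ChromogenClass",
    "ChromogenThresholds",
    "TLSRecord",
    "TumorRecord",
    "AnnotatedSlide",
    "positive_pixel_areas",
    "estimate_counts",
    "tls_properties",
    "til_counts",
    "suggest_stage",
    "DEFAULT_THRESHOLDS",
]

TLS_STAGES = ("aggregate", "primary", "secondary")


@dataclass(frozen=True)
class ChromogenClass:
    """Closed hue interval (circular) plus saturation/intensity gates."""

    hue_center: float
    hue_width: float
    min_saturation: float
    max_intensity: float

    def __post_init__(self):
        if not 0 <= self.hue_center < 1:
            raise ValueError("hue_center must be in [0, 1)")
        if not 0 <= self.hue_width < 0.5:
            raise ValueError("hue_width must be < 0.5")

    def match(self, hsv):
        dh = np.abs(hsv[..., 0] - self.hue_center)
        dh = np.minimum(dh, 1.0 - dh)
        return (
            (dh <= self.hue_width)  # closed interval at the boundary
            & (hsv[..., 1] >= self.min_saturation)
            & (hsv[..., 2] <= self.max_intensity)
        )


@dataclass(frozen=True)
class ChromogenThresholds:
    """Project-constant positive-pixel parameters."""

    brown_t: ChromogenClass
    pink_b: ChromogenClass
    hematoxylin: ChromogenClass
    nominal_cell_area: float = 38.0  # um^2

    def __post_init__(self):
        if self.nominal_cell_area <= 0:
            raise ValueError("nominal_cell_area must be positive")


#: calibrated against the synthetic chromogen constants (render module)
DEFAULT_THRESHOLDS = ChromogenThresholds(
    brown_t=ChromogenClass(0.075, 0.075, 0.25, 0.92),
    pink_b=ChromogenClass(0.94, 0.06, 0.25, 0.95),
    hematoxylin=ChromogenClass(0.64, 0.12, 0.2, 0.95),
)


@dataclass
class TLSRecord:
    tls_id: str
    lesion_id: str | None
    stage: str
    area_mm2: float
    t_count: int
    b_count: int
    b_fraction: float  # NaN when no cells
    relative_size: float  # TLS area / tissue area; NaN when tissue unknown

    def __post_init__(self):
        if self.stage not in TLS_STAGES:
            raise ValueError(f"stage must be one of {TLS_STAGES}")


@dataclass
class TumorRecord:
    tumor_id: str
    lesion_id: str | None
    tls_id: str | None
    proximity: str
    distance_um: float
    til_count: int
    t_count: int
    b_count: int
    tumor_area_um2: float
    killing: bool | None = None
    mucin: bool | None = None
    amyloid: bool | None = None


@dataclass
class AnnotatedSlide:
    """Calibrated RGB image plus role-labelled polygons for one lesion."""

    image: np.ndarray  # (H, W, 3) uint8
    regions: RegionSet
    lesion_id: str | None = None

    @property
    def pixel_size(self) -> float:
        return self.regions.pixel_size


def positive_pixel_areas(
    image: np.ndarray,
    region,
    thresholds: ChromogenThresholds,
    pixel_size: float = 1.0,
    melanin_mask: np.ndarray | None = None,
):
    """Brown/pink/total-tissue areas (um^2) inside one region.

    ``region`` is a shapely polygon, a boolean mask, or None (whole image).
    Classes are exclusive with brown taking precedence on ties (melanin
    contaminates the brown channel; an optional exclusion mask removes
    flagged pixels from all classes).  Total tissue is the hematoxylin-
    positive plus chromogen-positive area.
    """
    img = np.asarray(image)
    if region is None:
        region_mask = np.ones(img.shape[:2], dtype=bool)
    elif isinstance(region, np.ndarray):
        region_mask = region.astype(bool)
    else:
        minx, miny, maxx, maxy = region.bounds
        h, w = img.shape[:2]
        if minx < 0 or miny < 0 or maxx > w or maxy > h:
            raise ValueError(f"region {getattr(region, 'id', '')} outside image bounds")
        region_mask = rasterize_region(region, img.shape[:2])
    hsv = rgb2hsv(img)
    brown = thresholds.brown_t.match(hsv)
    pink = thresholds.pink_b.match(hsv) & ~brown  # brown precedence
    hema = thresholds.hematoxylin.match(hsv) & ~brown & ~pink
    if melanin_mask is not None:
        keep = ~np.asarray(melanin_mask, bool)
        brown, pink, hema = brown & keep, pink & keep, hema & keep
    px2 = pixel_size**2
    return {
        "brown_area": float((brown & region_mask).sum()) * px2,
        "pink_area": float((pink & region_mask).sum()) * px2,
        "total_tissue_area": float(((brown | pink | hema) & region_mask).sum()) * px2,
    }


def estimate_counts(areas: dict, thresholds: ChromogenThresholds):
    """Integrated positive area -> cell-count estimates and B fraction."""
    t = int(round(areas["brown_area"] / thresholds.nominal_cell_area))
    b = int(round(areas["pink_area"] / thresholds.nominal_cell_area))
    bf = b / (t + b) if (t + b) > 0 else float("nan")
    return {"t_count": t, "b_count": b, "b_fraction": bf}


def tls_properties(
    slide: AnnotatedSlide, thresholds: ChromogenThresholds = DEFAULT_THRESHOLDS
) -> list:
    """One TLSRecord per TLS polygon, ordered by id.

    ``relative_size`` uses the tissue polygon when present (NaN with a
    warning otherwise).  Stage comes from the annotation (a pathologist
    call), defaulting to 'aggregate' when absent.
    """
    ps = slide.pixel_size
    tissue = slide.regions.by_role("tissue")
    tissue_area = sum(t.polygon.area for t in tissue) * ps**2 if tissue else None
    records = []
    for reg in sorted(slide.regions.by_role("tls"), key=lambda r: r.region_id):
        areas = positive_pixel_areas(slide.image, reg.polygon, thresholds, ps)
        counts = estimate_counts(areas, thresholds)
        poly_area = reg.polygon.area * ps**2
        records.append(
            TLSRecord(
                tls_id=reg.region_id,
                lesion_id=reg.lesion_id or slide.lesion_id,
                stage=reg.stage or "aggregate",
                area_mm2=poly_area / 1e6,
                t_count=counts["t_count"],
                b_count=counts["b_count"],
                b_fraction=counts["b_fraction"],
                relative_size=(poly_area / tissue_area) if tissue_area else float("nan"),
            )
        )
    return records


def til_counts(
    slide: AnnotatedSlide,
    thresholds: ChromogenThresholds = DEFAULT_THRESHOLDS,
    cutoff: float = PROXIMITY_CUTOFF_UM,
) -> list:
    """One TumorRecord per tumor polygon: TILs and TLS proximity class.

    TIL count = T + B estimated inside the tumor polygon; proximity follows
    the edge-to-edge rule.  Zero-area tumors are skipped with a warning
    entry omitted from the list.
    """
    ps = slide.pixel_size
    tls_regions = sorted(slide.regions.by_role("tls"), key=lambda r: r.region_id)
    tls_polys = [t.polygon for t in tls_regions]
    records = []
    for reg in sorted(slide.regions.by_role("tumor"), key=lambda r: r.region_id):
        if reg.polygon.area == 0:
            continue
        areas = positive_pixel_areas(slide.image, reg.polygon, thresholds, ps)
        counts = estimate_counts(areas, thresholds)
        prox, dist, idx = classify_proximity(reg.polygon, tls_polys, ps, cutoff)
        linked = reg.tls_id or (tls_regions[idx].region_id if idx is not None else None)
        records.append(
            TumorRecord(
                tumor_id=reg.region_id,
                lesion_id=reg.lesion_id or slide.lesion_id,
                tls_id=None if prox == "control" else linked,
                proximity=str(prox),
                distance_um=dist,
                til_count=counts["t_count"] + counts["b_count"],
                t_count=counts["t_count"],
                b_count=counts["b_count"],
                tumor_area_um2=reg.polygon.area * ps**2,
            )
        )
    return records


def suggest_stage(b_count: int, total_count: int, cluster_min_b: int = 50) -> str:
    """Heuristic stage suggestion; never overrides the annotated stage."""
    if b_count >= cluster_min_b:
        return "primary"
    return "aggregate"
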