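"""Mask and polygon algebra for tumor/TLS/stroma spatial relations.

All rules the tumor-level analysis relies on live here: the 30-um
peritumoral stromal band captured around each tumor nest, the
proximal / distal / control classification of tumors by edge-to-edge
distance to the nearest TLS (500-um cutoff), random control fields of view
on TLS-free lesions, and region-set bookkeeping with GeoJSON round-tripping.

Coordinates are pixel-space with origin at the top-left; polygons are
shapely geometries in image (x, y) pixel coordinates and all distances are
reported in micrometres via the raster calibration (um/px).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from shapely.geometry import Polygon, box, mapping, shape as shapely_shape
from skimage.draw import polygon as draw_polygon

__all__ = [
    "Region",
    "RegionSet",
    "ProximityClass",
    "stromal_band",
    "classify_proximity",
    "control_fov",
    "rasterize_region",
    "PROXIMITY_CUTOFF_UM",
    "STROMAL_BAND_UM",
    "CONTROL_FOV_UM",
]

ROLES = ("tumor", "tls", "stroma", "control_fov", "tissue")
PROXIMITY_CUTOFF_UM = 500.0
STROMAL_BAND_UM = 30.0
CONTROL_FOV_UM = 500.0


class ProximityClass(str):
    """'proximal', 'distal' or 'control'."""

    VALUES = ("proximal", "distal", "control")

    def __new__(cls, value):
        if value not in cls.VALUES:
            raise ValueError(f"proximity must be one of {cls.VALUES}")
        return super().__new__(cls, value)


@dataclass
class Region:
    region_id: str
    role: str
    polygon: Polygon
    lesion_id: str | None = None
    tls_id: str | None = None  # link: tumor -> nearest TLS
    stage: str | None = None  # TLS maturation (annotation input)
    phenotype: str | None = None  # ground-truth fiber phenotype (synthetic)

    def __post_init__(self):
        if self.role not in ROLES:
            raise ValueError(f"unknown role {self.role!r}")
        if not self.polygon.is_valid or not self.polygon.is_simple:
            raise ValueError(f"region {self.region_id}: polygon must be simple")


@dataclass
class RegionSet:
    """Role-labelled polygons of one slide plus the raster calibration."""

    regions: list
    pixel_size: float  # um / px

    def __post_init__(self):
        if self.pixel_size <= 0:
            raise ValueError("pixel_size must be positive")
        ids = [r.region_id for r in self.regions]
        if len(set(ids)) != len(ids):
            raise ValueError("duplicate region ids")

    def by_role(self, role) -> list:
        return [r for r in self.regions if r.role == role]

    def get(self, region_id) -> Region:
        for r in self.regions:
            if r.region_id == region_id:
                return r
        raise KeyError(region_id)

    # -- GeoJSON round trip -------------------------------------------------
    def to_geojson(self) -> dict:
        feats = []
        for r in self.regions:
            props = {
                "region_id": r.region_id,
                "role": r.role,
                "lesion_id": r.lesion_id,
                "tls_id": r.tls_id,
                "stage": r.stage,
                "phenotype": r.phenotype,
            }
            feats.append(
                {"type": "Feature", "geometry": mapping(r.polygon), "properties": props}
            )
        return {
            "type": "FeatureCollection",
            "features": feats,
            "pixel_size_um": self.pixel_size,
        }

    def save(self, path):
        with open(path, "w") as fh:
            json.dump(self.to_geojson(), fh)

    @classmethod
    def from_geojson(cls, gj: dict) -> "RegionSet":
        regions = []
        for f in gj["features"]:
            p = f["properties"]
            regions.append(
                Region(
                    region_id=p["region_id"],
                    role=p["role"],
                    polygon=shapely_shape(f["geometry"]),
                    lesion_id=p.get("lesion_id"),
                    tls_id=p.get("tls_id"),
                    stage=p.get("stage"),
                    phenotype=p.get("phenotype"),
                )
            )
        return cls(regions, gj["pixel_size_um"])

    @classmethod
    def load(cls, path) -> "RegionSet":
        with open(path) as fh:
            return cls.from_geojson(json.load(fh))


def rasterize_region(polygon: Polygon, shape) -> np.ndarray:
    """Binary raster of a polygon on an image grid (half-open pixel centers)."""
    mask = np.zeros(shape, dtype=bool)
    geoms = [polygon] if polygon.geom_type == "Polygon" else list(polygon.geoms)
    for g in geoms:
        x, y = g.exterior.xy
        rr, cc = draw_polygon(np.asarray(y), np.asarray(x), shape=shape)
        mask[rr, cc] = True
        for hole in g.interiors:
            hx, hy = hole.xy
            rr, cc = draw_polygon(np.asarray(hy), np.asarray(hx), shape=shape)
            mask[rr, cc] = False
    return mask


def stromal_band(
    tumor: Polygon | np.ndarray,
    stroma_mask: np.ndarray,
    pixel_size: float,
    band_width: float = STROMAL_BAND_UM,
):
    """Peritumoral band: (dilate(tumor, band_width) - tumor) intersect stroma.

    ``tumor`` may be a polygon or a pre-rasterized mask on the same grid as
    ``stroma_mask``.  Dilation is Euclidean (distance transform), radius
    ``band_width`` um.  Returns ``(band_mask, area_um2)``; an empty band
    (tumor fills the stroma) is returned as an empty mask, not an error.
    """
    if band_width <= 0:
        raise ValueError("band_width must be positive")
    if pixel_size <= 0:
        raise ValueError("pixel_size must be positive")
    stroma_mask = np.asarray(stroma_mask, dtype=bool)
    tumor_mask = (
        tumor
        if isinstance(tumor, np.ndarray)
        else rasterize_region(tumor, stroma_mask.shape)
    )
    if not tumor_mask.any():
        return np.zeros_like(stroma_mask), 0.0
    dist_px = ndimage.distance_transform_edt(~tumor_mask)
    radius_px = round(band_width / pixel_size)
    band = (dist_px > 0) & (dist_px <= radius_px) & stroma_mask
    return band, float(band.sum()) * pixel_size**2


def classify_proximity(
    tumor: Polygon,
    tls_polygons: list,
    pixel_size: float,
    cutoff: float = PROXIMITY_CUTOFF_UM,
):
    """Classify a tumor nest by edge-to-edge distance to the nearest TLS.

    Returns ``(ProximityClass, distance_um, nearest_index)``.  With no TLS on
    the lesion the class is ``control`` (distance inf, index None); otherwise
    ``proximal`` iff the minimum edge-to-edge distance is <= cutoff.
    """
    if not tls_polygons:
        return ProximityClass("control"), float("inf"), None
    dists = [tumor.distance(t) * pixel_size for t in tls_polygons]
    i = int(np.argmin(dists))
    d = float(dists[i])
    cls = "proximal" if d <= cutoff else "distal"
    return ProximityClass(cls), d, i


def strict_farthest_distal(tumors: list, tls_polygons: list, pixel_size: float):
    """Index of the single maximum-distance tumor (the manual 'farthest' rule)."""
    if not tumors or not tls_polygons:
        return None
    dists = [
        min(t.distance(s) for s in tls_polygons) * pixel_size for t in tumors
    ]
    return int(np.argmax(dists))


def control_fov(
    tissue_mask: np.ndarray,
    pixel_size: float,
    size: float = CONTROL_FOV_UM,
    seed: int = 0,
    tumor_mask: np.ndarray | None = None,
):
    """Uniformly sample an axis-aligned square FOV fully inside the tissue.

    The square has side ``size`` um and, when ``tumor_mask`` is given, must
    contain at least one tumor pixel.  Deterministic per seed.  Raises
    ``RuntimeError`` when no feasible placement exists.
    """
    tissue_mask = np.asarray(tissue_mask, dtype=bool)
    side = int(round(size / pixel_size))
    h, w = tissue_mask.shape
    if side > h or side > w:
        raise RuntimeError("no feasible control-FOV placement: tissue too small")
    # windows fully inside tissue via box sums
    c = np.pad(np.cumsum(np.cumsum(tissue_mask.astype(np.int64), 0), 1), ((1, 0), (1, 0)))
    win = c[side:, side:] - c[:-side, side:] - c[side:, :-side] + c[:-side, :-side]
    feasible = win == side * side
    if tumor_mask is not None:
        ct = np.pad(
            np.cumsum(np.cumsum(np.asarray(tumor_mask, bool).astype(np.int64), 0), 1),
            ((1, 0), (1, 0)),
        )
        wt = ct[side:, side:] - ct[:-side, side:] - ct[side:, :-side] + ct[:-side, :-side]
        feasible &= wt > 0
    pos = np.argwhere(feasible)
    if len(pos) == 0:
        raise RuntimeError("no feasible control-FOV placement")
    rng = np.random.default_rng(seed)
    r0, c0 = pos[rng.integers(len(pos))]
    return box(float(c0), float(r0), float(c0 + side), float(r0 + side))
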