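"""Whole-slide synthetic scenes: geometry, truth masks and rendered images.

A scene holds one lesion's dual-IHC-like image and H&E-like image on the
same grid, the ground-truth class raster, role-labelled polygon annotations
(tumor nests, TLS, per-tumor stromal neighborhoods, tissue) and the planted
cell counts.  Tumors marked proximal sit near their TLS; distal tumors are
placed beyond the proximity cutoff when the canvas allows it.  Each tumor's
stromal neighborhood carries a fiber network drawn from its phenotype
parameters (A or B), which is what the downstream morphometrics and
clustering are expected to recover.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from shapely.geometry import Point

from ..geometry import PROXIMITY_CUTOFF_UM, Region, RegionSet, rasterize_region
from .fibers import PHENOTYPE_A, PHENOTYPE_B, generate_fiber_network
from .render import (
    LABEL_CODES,
    CellPlacement,
    concentrations_from_labels,
    render_he,
    render_ihc,
)

__all__ = ["SyntheticScene", "build_scene"]

PHENOTYPES = {"A": PHENOTYPE_A, "B": PHENOTYPE_B}


@dataclass
class SyntheticScene:
    lesion_id: str
    image_ihc: np.ndarray
    image_he: np.ndarray
    pixel_size: float
    truth_labels: np.ndarray  # LABEL_CODES raster
    regions: RegionSet
    truth_counts: dict  # region_id -> {"t": .., "b": ..}
    phenotypes: dict  # stromal region_id -> "A" | "B"

    def truth_mask(self, name: str) -> np.ndarray:
        return self.truth_labels == LABEL_CODES[name]


def _disk_poly(x, y, r):
    return Point(x, y).buffer(r, quad_segs=32)


def _ellipse_poly(x, y, rx, ry, rng):
    ang = rng.uniform(0, math.pi)
    pts = []
    for t in np.linspace(0, 2 * math.pi, 48, endpoint=False):
        px = rx * math.cos(t)
        py = ry * math.sin(t)
        pts.append(
            (
                x + px * math.cos(ang) - py * math.sin(ang),
                y + px * math.sin(ang) + py * math.cos(ang),
            )
        )
    from shapely.geometry import Polygon

    return Polygon(pts)


def build_scene(
    lesion_id: str,
    tumor_rows: list,
    tls_rows: list,
    size: int = 512,
    pixel_size: float = 1.0,
    seed: int = 0,
    stroma_radius_um: float = 80.0,
    max_tumors: int | None = None,
    max_tls: int | None = None,
) -> SyntheticScene:
    """Render one lesion into a calibrated synthetic slide.

    ``tumor_rows`` / ``tls_rows`` are cohort-table records (dicts) for this
    lesion; each tumor needs ``tumor_id``, ``proximity``, ``phenotype``,
    ``til_count``, ``tls_id``; each TLS needs ``tls_id``, ``stage``,
    ``true_t_count``, ``true_b_count``.  Distal placement requires a canvas
    larger than the proximity cutoff; otherwise the tumor is placed as
    proximal and its record's proximity should be taken from geometry, not
    from the plan.
    """
    rng = np.random.default_rng(seed)
    shape = (size, size)
    labels = np.zeros(shape, dtype=np.uint8)
    if max_tls is not None:
        tls_rows = tls_rows[:max_tls]
    if max_tumors is not None:
        tumor_rows = tumor_rows[:max_tumors]

    margin = 40
    tls_polys = {}
    for j, row in enumerate(tls_rows):
        r = min(35 + 20 * (row.get("stage") == "primary"), size // 7)
        for _ in range(100):
            x = rng.uniform(margin + r, max(size * 0.35, margin + r + 1))
            y = rng.uniform(margin + r, max(size - margin - r, margin + r + 1))
            cand = _disk_poly(x, y, r)
            if all(cand.distance(p) > 15 for p in tls_polys.values()):
                break
        tls_polys[row["tls_id"]] = cand

    cutoff_px = PROXIMITY_CUTOFF_UM / pixel_size
    tumor_polys = {}
    for k, row in enumerate(tumor_rows):
        rx, ry = rng.uniform(25, 45), rng.uniform(18, 30)
        want_distal = row.get("proximity") == "distal" and tls_polys
        placed = None
        for _ in range(200):
            x = rng.uniform(margin + rx, size - margin - rx)
            y = rng.uniform(margin + ry, size - margin - ry)
            cand = _ellipse_poly(x, y, rx, ry, rng)
            if any(cand.distance(p) < 10 for p in tumor_polys.values()):
                continue
            if tls_polys:
                dmin = min(cand.distance(p) for p in tls_polys.values())
                if want_distal and dmin <= cutoff_px:
                    continue
                if not want_distal and row.get("proximity") == "proximal":
                    tls_poly = tls_polys.get(row.get("tls_id"))
                    if tls_poly is not None and not (
                        10 < cand.distance(tls_poly) < cutoff_px
                    ):
                        continue
                if any(cand.intersects(p) for p in tls_polys.values()):
                    continue
            placed = cand
            break
        if placed is None:  # fall back: anywhere non-overlapping
            placed = _ellipse_poly(
                rng.uniform(margin + rx, size - margin - rx),
                rng.uniform(margin + ry, size - margin - ry),
                rx,
                ry,
                rng,
            )
        tumor_polys[row["tumor_id"]] = placed

    # rasterize truth, precedence tumor > TLS > stroma components
    tls_mask_all = np.zeros(shape, dtype=bool)
    for poly in tls_polys.values():
        tls_mask_all |= rasterize_region(poly, shape)
    tumor_mask_all = np.zeros(shape, dtype=bool)
    for poly in tumor_polys.values():
        tumor_mask_all |= rasterize_region(poly, shape)

    # per-tumor stromal neighborhood with its phenotype's fiber network
    regions = []
    phenotypes = {}
    fib_mask = np.zeros(shape, dtype=bool)
    taken = tumor_mask_all | tls_mask_all
    for k, row in enumerate(tumor_rows):
        poly = tumor_polys[row["tumor_id"]]
        stroma_poly = poly.buffer(stroma_radius_um / pixel_size).difference(poly)
        roi = rasterize_region(stroma_poly, shape) & ~taken
        phen = row.get("phenotype", "A")
        if roi.sum() >= 100 * 100:
            net = generate_fiber_network(
                PHENOTYPES[phen],
                shape=shape,
                pixel_size=pixel_size,
                seed=int(rng.integers(2**31 - 1)),
                roi_mask=roi,
            )
            fib_mask |= net.mask
        sid = f"{row['tumor_id']}_stroma"
        phenotypes[sid] = phen
        regions.append(
            Region(
                region_id=sid,
                role="stroma",
                polygon=stroma_poly.buffer(0),
                lesion_id=lesion_id,
                tls_id=row.get("tls_id"),
                phenotype=phen,
            )
        )

    # mucin / amyloid blobs in free stroma
    free = ~(taken | fib_mask)
    for code, flag_key, n_blobs in (("mucin", "mucin", 2), ("amyloid", "amyloid", 2)):
        if any(r.get(flag_key) for r in tumor_rows):
            cand = np.argwhere(free)
            for _ in range(n_blobs):
                if not len(cand):
                    break
                cy, cx = cand[rng.integers(len(cand))]
                blob = rasterize_region(_disk_poly(cx, cy, rng.uniform(15, 30)), shape)
                labels[blob & free] = LABEL_CODES[code]

    # scattered stromal nuclei
    n_nuc = int(0.0008 * size * size)
    for _ in range(n_nuc):
        cy, cx = rng.integers(0, size, 2)
        blob = rasterize_region(_disk_poly(cx, cy, 3), shape)
        labels[blob & ~taken & ~fib_mask & (labels == 0)] = LABEL_CODES["nuclei"]

    labels[fib_mask & ~taken] = LABEL_CODES["fibrillary_matrix"]
    labels[tls_mask_all] = LABEL_CODES["tls"]
    labels[tumor_mask_all] = LABEL_CODES["tumor"]

    # H&E render from truth concentrations
    hema, eosin = concentrations_from_labels(labels, seed=int(rng.integers(2**31 - 1)))
    image_he = render_he(hema, eosin)

    # IHC render: planted cells per region
    placements = []
    for row in tls_rows:
        m = rasterize_region(tls_polys[row["tls_id"]], shape)
        # cap planted cells to ~45% area coverage so positive-pixel areas
        # stay additive (caps preserve the stage ordering: bigger TLS, more cells)
        cap = int(0.45 * m.sum() * pixel_size**2 / 38.0)
        n_t = int(row.get("true_t_count", 0))
        n_b = int(row.get("true_b_count", 0))
        if n_t + n_b > cap and n_t + n_b > 0:
            f = cap / (n_t + n_b)
            n_t, n_b = int(round(n_t * f)), int(round(n_b * f))
        placements.append(
            CellPlacement(region_id=row["tls_id"], mask=m, n_t=n_t, n_b=n_b, role="tls")
        )
    for row in tumor_rows:
        m = rasterize_region(tumor_polys[row["tumor_id"]], shape)
        til = int(row.get("til_count", 0))
        n_b = int(round(til * 0.2))
        placements.append(
            CellPlacement(
                region_id=row["tumor_id"], mask=m, n_t=til - n_b, n_b=n_b, role="tumor"
            )
        )
    image_ihc, truth_counts = render_ihc(
        shape, placements, pixel_size=pixel_size, seed=int(rng.integers(2**31 - 1))
    )

    from shapely.geometry import box as shapely_box

    regions += [
        Region(
            region_id=row["tumor_id"],
            role="tumor",
            polygon=tumor_polys[row["tumor_id"]],
            lesion_id=lesion_id,
            tls_id=row.get("tls_id"),
        )
        for row in tumor_rows
    ]
    regions += [
        Region(
            region_id=row["tls_id"],
            role="tls",
            polygon=tls_polys[row["tls_id"]],
            lesion_id=lesion_id,
            stage=row.get("stage"),
        )
        for row in tls_rows
    ]
    regions.append(
        Region(
            region_id=f"{lesion_id}_tissue",
            role="tissue",
            polygon=shapely_box(0, 0, size - 1, size - 1),
            lesion_id=lesion_id,
        )
    )
    region_set = RegionSet(regions, pixel_size)
    return SyntheticScene(
        lesion_id=lesion_id,
        image_ihc=image_ihc,
        image_he=image_he,
        pixel_size=pixel_size,
        truth_labels=labels,
        regions=region_set,
        truth_counts=truth_counts,
        phenotypes=phenotypes,
    )
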