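"""Fibrillary-matrix morphometrics from a binary fiber mask.

The mask is thinned to a one-pixel skeleton, short spurs are pruned, and the
skeleton is converted into a graph of endpoints (degree 1) and branchpoints
(degree >= 3) connected by pixel paths.  From the graph and the mask the
thirteen morphology metrics are computed:

==========================  =================================================
n_endpoints                 degree-1 skeleton nodes
n_branchpoints              degree>=3 skeleton nodes (clusters merged)
endpoint_branchpoint_ratio  n_endpoints / max(n_branchpoints, 1)
total_length                sum of skeleton path lengths (um)
avg_fiber_length            total_length / number of paths (um)
hyphal_growth_unit          total_length / n_endpoints (um; NaN if none)
curvature                   mean absolute direction change between successive
                            fixed-length chords along paths (deg per chord)
alignment                   structure-tensor coherence of the mask in [0, 1]
fractal_dimension           box-count slope over dyadic box sizes
lacunarity                  gliding-box mean of 1 + var/mean^2 of occupancy
density                     mask fraction of the ROI
hdm                         high-density matrix: ROI fraction whose stain
                            intensity exceeds a threshold
mean_gap_diameter           2 x mean local maximum of the distance transform
                            of ROI minus mask (um)
==========================  =================================================

plus ``mask_area`` (um^2), carried as the weight used when several stromal
regions of one tumor are combined, and ``n_fibers`` (skeleton path count)
needed to recombine average fiber length.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, asdict, field

import numpy as np
from scipy import ndimage
from skimage.feature import structure_tensor
from skimage.filters import threshold_otsu
from skimage.morphology import skeletonize

__all__ = [
    "SkeletonGraph",
    "SkeletonPath",
    "FiberMetrics",
    "MorphometricsConfig",
    "METRIC_NAMES",
    "skeletonize_and_prune",
    "compute_metrics",
    "combine_regions",
]

METRIC_NAMES = (
    "n_endpoints",
    "n_branchpoints",
    "endpoint_branchpoint_ratio",
    "total_length",
    "avg_fiber_length",
    "hyphal_growth_unit",
    "curvature",
    "alignment",
    "fractal_dimension",
    "lacunarity",
    "density",
    "hdm",
    "mean_gap_diameter",
)

#: metrics summed across regions when combining
ADDITIVE_METRICS = ("n_endpoints", "n_branchpoints", "total_length")
#: metrics recomputed from combined sums
RATIO_METRICS = ("endpoint_branchpoint_ratio", "avg_fiber_length", "hyphal_growth_unit")
#: global pattern metrics combined by fibrillary-mask-area weighted average
PATTERN_METRICS = (
    "curvature",
    "alignment",
    "fractal_dimension",
    "lacunarity",
    "density",
    "hdm",
    "mean_gap_diameter",
)


@dataclass
class SkeletonPath:
    pixels: np.ndarray  # (N, 2) row/col along the path
    length: float  # um
    closed: bool = False


@dataclass
class SkeletonGraph:
    """Pruned skeleton as endpoint/branchpoint nodes joined by pixel paths."""

    skeleton: np.ndarray  # bool raster after pruning
    endpoints: np.ndarray  # (E, 2) row/col
    branchpoints: np.ndarray  # (B, 2) row/col (cluster centroids)
    paths: list  # list[SkeletonPath]
    pixel_size: float

    @property
    def n_endpoints(self) -> int:
        return len(self.endpoints)

    @property
    def n_branchpoints(self) -> int:
        return len(self.branchpoints)

    @property
    def total_length(self) -> float:
        return float(sum(p.length for p in self.paths))


_NEIGH = [(-1, -1), (-1, 0), (-1, 1), (0, -1), (0, 1), (1, -1), (1, 0), (1, 1)]
_STEP_LEN = {(-1, -1): math.sqrt(2), (-1, 1): math.sqrt(2), (1, -1): math.sqrt(2), (1, 1): math.sqrt(2)}


def _neighbor_count(skel):
    k = np.ones((3, 3), dtype=int)
    k[1, 1] = 0
    return ndimage.convolve(skel.astype(int), k, mode="constant")


def _path_length(pixels, pixel_size):
    if len(pixels) < 2:
        return 0.0
    d = np.abs(np.diff(pixels.astype(int), axis=0))
    steps = np.where(d.sum(axis=1) == 2, math.sqrt(2), 1.0)
    return float(steps.sum() * pixel_size)


def _trace_graph(skel, pixel_size):
    """Decompose a 1-px skeleton into node pixels and traced paths.

    Clusters of adjacent branch pixels count as one node: edges internal to a
    cluster are not emitted as paths.
    """
    counts = _neighbor_count(skel) * skel
    node_mask = skel & ((counts == 1) | (counts >= 3) | (counts == 0))
    branch_mask = skel & (counts >= 3)
    cluster_lab, _ = ndimage.label(branch_mask, structure=np.ones((3, 3)))
    paths = []
    skel_set = skel
    visited_edge = np.zeros_like(skel, dtype=bool)

    node_pixels = [tuple(p) for p in np.argwhere(node_mask)]
    node_lookup = node_mask

    def neighbors(p):
        r, c = p
        out = []
        for dr, dc in _NEIGH:
            rr, cc = r + dr, c + dc
            if 0 <= rr < skel.shape[0] and 0 <= cc < skel.shape[1] and skel_set[rr, cc]:
                out.append((rr, cc))
        return out

    # trace paths starting at node pixels
    used_starts = set()
    for start in node_pixels:
        for nb in neighbors(start):
            if node_lookup[nb]:
                # same branch cluster -> internal junction pixel, not a path
                if cluster_lab[start] and cluster_lab[start] == cluster_lab[nb]:
                    continue
                # direct node-to-node edge (length one step); dedupe by order
                if (nb, start) not in used_starts:
                    used_starts.add((start, nb))
                    px = np.array([start, nb])
                    paths.append(SkeletonPath(px, _path_length(px, pixel_size)))
                continue
            if visited_edge[nb]:
                continue
            path = [start, nb]
            visited_edge[nb] = True
            prev, cur = start, nb
            while True:
                nxt = [q for q in neighbors(cur) if q != prev and not (
                    len(path) > 2 and q == path[-3])]
                # prefer unvisited non-node continuation
                cont = [q for q in nxt if not node_lookup[q] and not visited_edge[q]]
                stop = [q for q in nxt if node_lookup[q] and q != start]
                if cont:
                    prev, cur = cur, cont[0]
                    visited_edge[cur] = True
                    path.append(cur)
                elif stop:
                    path.append(stop[0])
                    break
                else:
                    break
            px = np.array(path)
            paths.append(SkeletonPath(px, _path_length(px, pixel_size)))

    # remaining pixels belong to pure cycles (no nodes)
    remaining = skel & ~visited_edge & ~node_mask
    lab, n = ndimage.label(remaining, structure=np.ones((3, 3)))
    for i in range(1, n + 1):
        comp = np.argwhere(lab == i)
        if len(comp) < 3:
            continue
        # walk the cycle from an arbitrary pixel
        start = tuple(comp[0])
        path = [start]
        seen = {start}
        cur, prev = start, None
        while True:
            nxt = [q for q in neighbors(cur) if q != prev and q not in seen]
            if not nxt:
                break
            prev, cur = cur, nxt[0]
            seen.add(cur)
            path.append(cur)
        path.append(start)  # close the loop
        px = np.array(path)
        paths.append(SkeletonPath(px, _path_length(px, pixel_size), closed=True))

    return node_mask, counts, paths


def _merge_branchpoints(branch_pixels, merge_radius_px=2):
    """Merge clusters of branch pixels within a radius into single nodes."""
    if len(branch_pixels) == 0:
        return np.empty((0, 2))
    canvas_min = branch_pixels.min(axis=0) - 1
    local = branch_pixels - canvas_min
    shape = local.max(axis=0) + 2
    img = np.zeros(shape, dtype=bool)
    img[local[:, 0], local[:, 1]] = True
    if merge_radius_px > 1:
        img = ndimage.binary_dilation(img, iterations=merge_radius_px - 1)
    lab, n = ndimage.label(img, structure=np.ones((3, 3)))
    cents = ndimage.center_of_mass(img, lab, range(1, n + 1))
    return np.asarray(cents) + canvas_min


def skeletonize_and_prune(
    mask: np.ndarray, pixel_size: float = 1.0, prune_below: float = 5.0
) -> SkeletonGraph:
    """Thin the mask, prune spurs shorter than ``prune_below`` um, build graph.

    Path length uses 8-connected chain steps (1 px orthogonal, sqrt(2) px
    diagonal) scaled by ``pixel_size``.  An empty mask yields an empty graph.
    """
    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        return SkeletonGraph(
            skeleton=np.zeros_like(mask),
            endpoints=np.empty((0, 2)),
            branchpoints=np.empty((0, 2)),
            paths=[],
            pixel_size=pixel_size,
        )
    skel = skeletonize(mask)
    for _ in range(20):  # iterative spur pruning
        counts = _neighbor_count(skel) * skel
        node_mask, counts, paths = _trace_graph(skel, pixel_size)
        spur_pixels = []
        endpoint_mask = skel & (counts == 1)
        changed = False
        for p in paths:
            if p.closed or p.length >= prune_below:
                continue
            a, b = tuple(p.pixels[0]), tuple(p.pixels[-1])
            a_end = endpoint_mask[a]
            b_end = endpoint_mask[b]
            if a_end or b_end:
                drop = p.pixels if (a_end and b_end) else (
                    p.pixels[:-1] if a_end else p.pixels[1:]
                )
                spur_pixels.append(drop)
                changed = True
        if not changed:
            break
        for drop in spur_pixels:
            skel[drop[:, 0], drop[:, 1]] = False
        skel = skeletonize(skel)  # restore 1-px topology after removal

    counts = _neighbor_count(skel) * skel
    node_mask, counts, paths = _trace_graph(skel, pixel_size)
    endpoints = np.argwhere(skel & ((counts == 1) | (counts == 0)))
    branch_pixels = np.argwhere(skel & (counts >= 3))
    branchpoints = _merge_branchpoints(branch_pixels)
    return SkeletonGraph(
        skeleton=skel,
        endpoints=endpoints,
        branchpoints=branchpoints,
        paths=paths,
        pixel_size=pixel_size,
    )


# ---------------------------------------------------------------------------
# metrics


@dataclass
class MorphometricsConfig:
    curvature_window: float = 20.0  # um chord length
    hdm_threshold: float | None = None  # None -> Otsu on ROI intensities
    tensor_sigma: float = 2.0  # px, structure-tensor smoothing
    min_box: int = 2  # smallest dyadic box (px)


@dataclass
class FiberMetrics:
    """The thirteen morphology metrics plus combination bookkeeping."""

    n_endpoints: float
    n_branchpoints: float
    endpoint_branchpoint_ratio: float
    total_length: float
    avg_fiber_length: float
    hyphal_growth_unit: float
    curvature: float
    alignment: float
    fractal_dimension: float
    lacunarity: float
    density: float
    hdm: float
    mean_gap_diameter: float
    mask_area: float
    n_fibers: float = 0.0
    region_ids: tuple = field(default_factory=tuple)

    def as_dict(self) -> dict:
        d = asdict(self)
        d.pop("region_ids")
        return d


def _box_sizes(shape, min_box=2):
    limit = min(shape) // 4
    sizes = []
    s = min_box
    while s <= max(limit, min_box):
        sizes.append(s)
        s *= 2
    return sizes or [min_box]


def _box_counts(mask, size):
    h, w = mask.shape
    hh, ww = (h // size) * size, (w // size) * size
    if hh == 0 or ww == 0:
        return 1
    m = mask[:hh, :ww].reshape(hh // size, size, ww // size, size)
    return int(m.any(axis=(1, 3)).sum())


def _fractal_dimension(mask, sizes):
    if not mask.any():
        return float("nan")
    ns, ss = [], []
    for s in sizes:
        c = _box_counts(mask, s)
        if c > 0:
            ns.append(c)
            ss.append(s)
    if len(ns) < 2:
        return float("nan")
    slope = np.polyfit(np.log(1.0 / np.asarray(ss)), np.log(ns), 1)[0]
    return float(slope)


def _gliding_box_lacunarity(mask, sizes):
    """Mean over box sizes of 1 + var/mean^2 of gliding-box occupancy."""
    if not mask.any():
        return float("nan")
    m = mask.astype(np.float64)
    c = np.pad(np.cumsum(np.cumsum(m, axis=0), axis=1), ((1, 0), (1, 0)))
    vals = []
    for s in sizes:
        if s > min(mask.shape):
            continue
        tot = c[s:, s:] - c[:-s, s:] - c[s:, :-s] + c[:-s, :-s]
        mu = tot.mean()
        if mu <= 0:
            continue
        vals.append(1.0 + tot.var() / mu**2)
    return float(np.mean(vals)) if vals else float("nan")


def _alignment_coherence(mask, sigma, roi=None):
    img = mask.astype(np.float64)
    Axx, Axy, Ayy = structure_tensor(img, sigma=sigma, order="xy")
    if roi is not None:
        Axx, Axy, Ayy = Axx[roi], Axy[roi], Ayy[roi]
    jxx, jxy, jyy = Axx.sum(), Axy.sum(), Ayy.sum()
    tr = jxx + jyy
    if tr <= 0:
        return 0.0
    return float(np.sqrt((jxx - jyy) ** 2 + 4 * jxy**2) / tr)


def _resample_chords(pixels, pixel_size, window):
    """Points along a pixel path at arc-length spacing ``window`` um."""
    pts = pixels.astype(float) * pixel_size
    seg = np.hypot(*np.diff(pts, axis=0).T)
    arc = np.r_[0.0, np.cumsum(seg)]
    if arc[-1] < 2 * window:
        return None
    targets = np.arange(0.0, arc[-1] + 1e-9, window)
    xs = np.interp(targets, arc, pts[:, 0])
    ys = np.interp(targets, arc, pts[:, 1])
    return np.stack([xs, ys], axis=1)


def _mean_curvature(paths, pixel_size, window):
    """Mean |direction change| in degrees between successive chords."""
    angles = []
    for p in paths:
        ch = _resample_chords(p.pixels, pixel_size, window)
        if ch is None or len(ch) < 3:
            continue
        v = np.diff(ch, axis=0)
        a = np.arctan2(v[:, 1], v[:, 0])
        da = np.diff(a)
        da = (da + math.pi) % (2 * math.pi) - math.pi
        angles.extend(np.degrees(np.abs(da)))
    return float(np.mean(angles)) if angles else 0.0


def _mean_gap_diameter(mask, roi, pixel_size):
    gaps = roi & ~mask
    if not gaps.any():
        return 0.0
    dt = ndimage.distance_transform_edt(gaps) * pixel_size
    footprint = np.ones((3, 3), dtype=bool)
    local_max = (dt == ndimage.maximum_filter(dt, footprint=footprint)) & (dt > 0)
    vals = dt[local_max]
    if vals.size == 0:
        return float(2.0 * dt.max())
    return float(2.0 * vals.mean())


def compute_metrics(
    mask: np.ndarray,
    skeleton: SkeletonGraph | None = None,
    intensity: np.ndarray | None = None,
    roi_mask: np.ndarray | None = None,
    pixel_size: float = 1.0,
    config: MorphometricsConfig | None = None,
    region_id=None,
) -> FiberMetrics:
    """All thirteen metrics for one region.

    ``intensity`` is the eosin concentration raster used only by the HDM
    metric (NaN when absent and no threshold is configured); ``roi_mask``
    restricts the analysis (defaults to the full frame).  Pattern metrics are
    evaluated on the ROI bounding-box crop with the mask intersected with the
    ROI.
    """
    cfg = config or MorphometricsConfig()
    mask = np.asarray(mask, dtype=bool)
    if roi_mask is None:
        roi_mask = np.ones_like(mask)
    roi_mask = np.asarray(roi_mask, dtype=bool)
    roi_area_px = int(roi_mask.sum())
    if roi_area_px == 0:
        raise ValueError("empty ROI")
    mask = mask & roi_mask
    if skeleton is None:
        skeleton = skeletonize_and_prune(mask, pixel_size=pixel_size)

    n_end = skeleton.n_endpoints
    n_branch = skeleton.n_branchpoints
    total_len = skeleton.total_length
    n_paths = len(skeleton.paths)
    avg_len = total_len / n_paths if n_paths else 0.0
    hgu = total_len / n_end if n_end > 0 else float("nan")

    # crop to ROI bounding box for the pattern metrics
    rows = np.any(roi_mask, axis=1)
    cols = np.any(roi_mask, axis=0)
    r0, r1 = np.flatnonzero(rows)[[0, -1]]
    c0, c1 = np.flatnonzero(cols)[[0, -1]]
    crop = np.s_[r0 : r1 + 1, c0 : c1 + 1]
    mask_c = mask[crop]
    roi_c = roi_mask[crop]

    sizes = _box_sizes(mask_c.shape, cfg.min_box)
    density = mask[roi_mask].mean()
    fd = _fractal_dimension(mask_c, sizes)
    lac = _gliding_box_lacunarity(mask_c, sizes)
    align = _alignment_coherence(mask_c, cfg.tensor_sigma)
    curv = _mean_curvature(skeleton.paths, pixel_size, cfg.curvature_window)
    gap = _mean_gap_diameter(mask_c, roi_c, pixel_size)

    if intensity is not None:
        vals = np.asarray(intensity, dtype=float)[roi_mask]
        thr = cfg.hdm_threshold
        if thr is None:
            thr = float(threshold_otsu(vals)) if np.ptp(vals) > 0 else float("inf")
        hdm = float((vals > thr).mean())
    else:
        hdm = float("nan")

    return FiberMetrics(
        n_endpoints=float(n_end),
        n_branchpoints=float(n_branch),
        endpoint_branchpoint_ratio=float(n_end) / max(float(n_branch), 1.0),
        total_length=total_len,
        avg_fiber_length=avg_len,
        hyphal_growth_unit=hgu,
        curvature=curv,
        alignment=align,
        fractal_dimension=fd,
        lacunarity=lac,
        density=float(density),
        hdm=hdm,
        mean_gap_diameter=gap,
        mask_area=float(mask.sum()) * pixel_size**2,
        n_fibers=float(n_paths),
        region_ids=(region_id,) if region_id is not None else (),
    )


def combine_regions(rows: list[FiberMetrics]) -> FiberMetrics:
    """Combine several stromal regions of one tumor into a single record.

    Per-fiber additive metrics (endpoints, branchpoints, total length, path
    count) are summed; the ratio metrics are recomputed from the combined
    sums so the hyphal-growth-unit identity keeps holding; global pattern
    metrics are averaged weighted by fibrillary-mask area.  With a total mask
    area of zero the pattern metrics are flagged missing (NaN).
    """
    if not rows:
        raise ValueError("combine_regions requires at least one region")
    if len(rows) == 1:
        return rows[0]
    n_end = sum(r.n_endpoints for r in rows)
    n_branch = sum(r.n_branchpoints for r in rows)
    total_len = sum(r.total_length for r in rows)
    n_paths = sum(r.n_fibers for r in rows)
    areas = np.array([r.mask_area for r in rows], dtype=float)
    total_area = float(areas.sum())

    def wavg(name):
        if total_area == 0:
            return float("nan")
        vals = np.array([getattr(r, name) for r in rows], dtype=float)
        ok = ~np.isnan(vals) & (areas > 0)
        if not ok.any():
            return float("nan")
        return float((vals[ok] * areas[ok]).sum() / areas[ok].sum())

    ids = tuple(i for r in rows for i in r.region_ids)
    return FiberMetrics(
        n_endpoints=n_end,
        n_branchpoints=n_branch,
        endpoint_branchpoint_ratio=n_end / max(n_branch, 1.0),
        total_length=total_len,
        avg_fiber_length=total_len / n_paths if n_paths else 0.0,
        hyphal_growth_unit=total_len / n_end if n_end > 0 else float("nan"),
        curvature=wavg("curvature"),
        alignment=wavg("alignment"),
        fractal_dimension=wavg("fractal_dimension"),
        lacunarity=wavg("lacunarity"),
        density=wavg("density"),
        hdm=wavg("hdm"),
        mean_gap_diameter=wavg("mean_gap_diameter"),
        mask_area=total_area,
        n_fibers=n_paths,
        region_ids=ids,
    )
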