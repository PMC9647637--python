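"""Synthetic fibrillary-matrix networks.

Fibers are correlated random walks: the initial direction is von Mises
distributed (concentration ``orientation_kappa``; 0 means isotropic), and the
direction then drifts by a normal turn angle whose standard deviation scales
with arc length (``step_angle_sd``, degrees per micrometre walked).  Branches
are spawned along a fiber at ``branching_rate`` per 100 um, and crosslinking
is emulated by seeding a fraction of new fibers from random points of already
drawn fibers.  Polylines are rasterized with a circular brush of diameter
``fiber_width`` until ``target_coverage`` of the region of interest is
occupied.

Two phenotype presets span the morphological contrast the downstream
clustering is designed to detect: ``PHENOTYPE_A`` (long, thin, sparse,
isotropic, gappy networks) and ``PHENOTYPE_B`` (short, thick, dense, aligned,
heavily crosslinked networks).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

import numpy as np

__all__ = [
    "FiberPhenotypeParams",
    "FiberNetwork",
    "CoverageUnreachableError",
    "generate_fiber_network",
    "rasterize_polylines",
    "segment_orientations",
    "circular_variance_axial",
    "PHENOTYPE_A",
    "PHENOTYPE_B",
]


class CoverageUnreachableError(RuntimeError):
    """Raised when the fiber budget cannot reach the requested coverage."""


@dataclass(frozen=True)
class FiberPhenotypeParams:
    """Generative parameters for one fibrillary phenotype.

    Units: lengths and widths in micrometres, ``step_angle_sd`` in degrees
    per um, ``branching_rate`` in branches per 100 um of fiber,
    ``crosslink_density`` in junction seeds per 1000 um^2 of ROI,
    ``target_coverage`` as a mask fraction of the ROI in [0, 1).
    """

    n_fibers: int
    mean_length: float
    length_cv: float
    orientation_kappa: float
    step_angle_sd: float
    branching_rate: float
    crosslink_density: float
    fiber_width: float
    target_coverage: float
    anastomose: bool = False  # walks terminate on contact with existing fibers

    def __post_init__(self):
        vals = {
            "n_fibers": self.n_fibers,
            "mean_length": self.mean_length,
            "length_cv": self.length_cv,
            "orientation_kappa": self.orientation_kappa,
            "step_angle_sd": self.step_angle_sd,
            "branching_rate": self.branching_rate,
            "crosslink_density": self.crosslink_density,
            "fiber_width": self.fiber_width,
            "target_coverage": self.target_coverage,
        }
        for k, v in vals.items():
            if v < 0:
                raise ValueError(f"{k} must be nonnegative, got {v}")
        if not self.target_coverage < 1:
            raise ValueError("target_coverage must be < 1")
        if not self.mean_length > self.fiber_width:
            raise ValueError("mean_length must exceed fiber_width")

    def with_(self, **kw) -> "FiberPhenotypeParams":
        return replace(self, **kw)


#: long, thin, sparse, isotropic, gappy (cluster-1-like morphology)
PHENOTYPE_A = FiberPhenotypeParams(
    n_fibers=2000,
    mean_length=150.0,
    length_cv=0.3,
    orientation_kappa=0.0,
    step_angle_sd=1.0,
    branching_rate=0.1,
    crosslink_density=0.0,
    fiber_width=2.0,
    target_coverage=0.12,
)

#: thick, dense, aligned, crosslinked (cluster-2-like morphology): the dense
#: overgrown mesh has short junction-to-junction segments and few free ends,
#: hence a high hyphal growth unit despite the short measured segments
PHENOTYPE_B = FiberPhenotypeParams(
    n_fibers=20000,
    mean_length=200.0,
    length_cv=0.3,
    orientation_kappa=6.0,
    step_angle_sd=1.0,
    branching_rate=0.3,
    crosslink_density=1.0,
    fiber_width=6.0,
    target_coverage=0.25,
)


@dataclass
class FiberNetwork:
    """Binary raster plus the ground-truth polylines that generated it."""

    mask: np.ndarray  # bool (H, W)
    polylines: list  # list of (N, 2) float arrays, (x, y) in um
    pixel_size: float  # um / px
    coverage: float  # achieved mask fraction of the ROI

    @property
    def total_polyline_length(self) -> float:
        return float(
            sum(np.hypot(*np.diff(p, axis=0).T).sum() for p in self.polylines if len(p) > 1)
        )


def _disk_offsets(radius_px: float):
    r = max(int(round(radius_px)), 0)
    if r == 0:
        return np.zeros((1, 2), dtype=int)
    yy, xx = np.mgrid[-r : r + 1, -r : r + 1]
    keep = yy**2 + xx**2 <= r**2 + 1e-9
    return np.stack([yy[keep], xx[keep]], axis=1)


def _stamp(mask, pts_px, offsets, shape, roi=None):
    """Stamp brush offsets at integer pixel points (ROI-restricted);
    returns the number of newly set pixels."""
    px = (pts_px[:, None, :] + offsets[None, :, :]).reshape(-1, 2)
    np.clip(px[:, 0], 0, shape[0] - 1, out=px[:, 0])
    np.clip(px[:, 1], 0, shape[1] - 1, out=px[:, 1])
    flat = np.unique(px[:, 0] * shape[1] + px[:, 1])
    rows, cols = flat // shape[1], flat % shape[1]
    if roi is not None:
        keep = roi[rows, cols]
        rows, cols = rows[keep], cols[keep]
    n_new = int((~mask[rows, cols]).sum())
    mask[rows, cols] = True
    return n_new


def _walk(rng, start_xy, angle0, length, step, angle_sd_deg_per_um):
    n_steps = max(int(round(length / step)), 1)
    turns = rng.normal(0.0, math.radians(angle_sd_deg_per_um) * step, size=n_steps)
    angles = angle0 + np.cumsum(np.r_[0.0, turns[:-1]])
    dx = np.cos(angles) * step
    dy = np.sin(angles) * step
    pts = np.empty((n_steps + 1, 2))
    pts[0] = start_xy
    pts[1:, 0] = start_xy[0] + np.cumsum(dx)
    pts[1:, 1] = start_xy[1] + np.cumsum(dy)
    return pts, angles


def generate_fiber_network(
    params: FiberPhenotypeParams,
    shape: tuple[int, int] = (512, 512),
    pixel_size: float = 1.0,
    seed: int = 0,
    mean_direction: float = 0.0,
    roi_mask: np.ndarray | None = None,
) -> FiberNetwork:
    """Draw fibers until ``target_coverage`` of the ROI is occupied.

    Deterministic for a fixed seed.  ``shape`` is (rows, cols) in pixels; the
    ROI must contain at least 100x100 px.  Polylines are returned in (x, y)
    micrometre coordinates.  Raises :class:`CoverageUnreachableError` naming
    the limiting parameter when the fiber budget (``n_fibers``, including
    spawned branches) is exhausted before reaching 90% of the target.
    """
    rng = np.random.default_rng(seed)
    if roi_mask is None:
        roi_mask = np.ones(shape, dtype=bool)
    roi_px = int(roi_mask.sum())
    if roi_px < 100 * 100:
        raise ValueError("ROI must contain at least 100x100 px")
    shape = roi_mask.shape
    area_um2 = roi_px * pixel_size**2

    offsets = _disk_offsets(params.fiber_width / 2.0 / pixel_size)
    mask = np.zeros(shape, dtype=bool)
    inside = np.argwhere(roi_mask)
    target_px = params.target_coverage * roi_px
    step = pixel_size  # walk resolution: one pixel

    n_crosslink_target = int(round(params.crosslink_density * area_um2 / 1000.0))
    crosslinks_done = 0
    covered = 0
    polylines: list[np.ndarray] = []
    all_pts: list[np.ndarray] = []  # pool of polyline points for crosslink seeds
    branch_queue: list[tuple[np.ndarray, float]] = []
    drawn = 0

    if params.length_cv > 0:
        shape_k = 1.0 / params.length_cv**2
        scale = params.mean_length / shape_k

    while drawn < params.n_fibers and covered < target_px:
        if branch_queue:
            start_xy, angle0 = branch_queue.pop()
        elif crosslinks_done < n_crosslink_target and all_pts:
            pool = all_pts[rng.integers(len(all_pts))]
            start_xy = pool[rng.integers(len(pool))].astype(float)
            angle0 = (
                rng.vonmises(mean_direction, params.orientation_kappa)
                if params.orientation_kappa > 0
                else rng.uniform(-math.pi, math.pi)
            )
            crosslinks_done += 1
        else:
            ij = inside[rng.integers(len(inside))]
            start_xy = np.array([ij[1], ij[0]], dtype=float) * pixel_size
            angle0 = (
                rng.vonmises(mean_direction, params.orientation_kappa)
                if params.orientation_kappa > 0
                else rng.uniform(-math.pi, math.pi)
            )
        length = (
            rng.gamma(shape_k, scale) if params.length_cv > 0 else params.mean_length
        )
        length = max(length, 2 * step)
        pts, _ = _walk(rng, start_xy, angle0, length, step, params.step_angle_sd)
        if params.anastomose and len(pts) > 6:
            # truncate at the first contact with already-drawn matrix: the
            # tip fuses into a junction instead of terminating free
            chk = np.round(pts[5:, ::-1] / pixel_size).astype(int)
            ok = (
                (chk[:, 0] >= 0) & (chk[:, 0] < shape[0])
                & (chk[:, 1] >= 0) & (chk[:, 1] < shape[1])
            )
            hit = np.zeros(len(chk), dtype=bool)
            hit[ok] = mask[chk[ok, 0], chk[ok, 1]]
            first = np.argmax(hit) if hit.any() else -1
            if first >= 0:
                pts = pts[: 5 + first + 2]

        # spawn branches along the fiber
        if params.branching_rate > 0:
            p_branch = params.branching_rate * step / 100.0
            hits = np.flatnonzero(rng.random(len(pts)) < p_branch)
            for h in hits:
                side = 1.0 if rng.random() < 0.5 else -1.0
                branch_queue.append(
                    (pts[h].copy(), angle0 + side * rng.uniform(math.pi / 6, math.pi / 3))
                )

        pts_px = np.round(pts[:, ::-1] / pixel_size).astype(int)  # (row, col)
        ok = (
            (pts_px[:, 0] >= 0)
            & (pts_px[:, 0] < shape[0])
            & (pts_px[:, 1] >= 0)
            & (pts_px[:, 1] < shape[1])
        )
        pts_px = pts_px[ok]
        if len(pts_px) == 0:
            drawn += 1
            continue
        covered += _stamp(mask, pts_px, offsets, shape, roi=roi_mask)
        polylines.append(pts)
        all_pts.append(pts)
        drawn += 1

    mask &= roi_mask
    coverage = mask[roi_mask].mean() if roi_px else 0.0
    if coverage < 0.9 * params.target_coverage:
        need = params.target_coverage * area_um2
        supply = params.n_fibers * params.mean_length * params.fiber_width
        limiting = "n_fibers" if supply < need else "mean_length/step_angle_sd"
        raise CoverageUnreachableError(
            f"achieved coverage {coverage:.4f} < 90% of target "
            f"{params.target_coverage:.4f}; limiting parameter: {limiting}"
        )
    return FiberNetwork(mask=mask, polylines=polylines, pixel_size=pixel_size, coverage=float(coverage))


def rasterize_polylines(
    polylines, shape, pixel_size: float = 1.0, fiber_width: float = 2.0
) -> np.ndarray:
    """Rasterize polylines ((x, y) um) to a binary mask — used for nested-mask
    constructions where a subset of fibers must yield a subset mask."""
    mask = np.zeros(shape, dtype=bool)
    offsets = _disk_offsets(fiber_width / 2.0 / pixel_size)
    for pts in polylines:
        pts_px = np.round(np.asarray(pts)[:, ::-1] / pixel_size).astype(int)
        ok = (
            (pts_px[:, 0] >= 0)
            & (pts_px[:, 0] < shape[0])
            & (pts_px[:, 1] >= 0)
            & (pts_px[:, 1] < shape[1])
        )
        if ok.any():
            _stamp(mask, pts_px[ok], offsets, shape)
    return mask


def segment_orientations(polylines) -> np.ndarray:
    """Axial orientations (radians in [0, pi)) of every polyline segment."""
    angs = []
    for pts in polylines:
        d = np.diff(np.asarray(pts), axis=0)
        a = np.arctan2(d[:, 1], d[:, 0]) % math.pi
        angs.append(a)
    return np.concatenate(angs) if angs else np.empty(0)


def circular_variance_axial(orientations) -> float:
    """Circular variance 1 - |R| of axial orientations (doubled-angle trick).

    1 for a perfectly isotropic set, 0 for perfectly parallel segments.
    """
    o = np.asarray(orientations, dtype=float)
    if o.size == 0:
        return float("nan")
    r = np.abs(np.exp(2j * o).mean())
    return float(1.0 - r)
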