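"""Pixel-to-well registration: global baseline and diffusion-like local mapping.

A bead-based sequencer reports, for every read, the CCD pixel position of the
well it came from.  Recovering which *physical* well that is requires
registering the pixel domain onto the well-centre map of the chip.  Because
the imaging train introduces a smooth but non-linear distortion, a single
("global") similarity transform fitted from two reference beads is accurate
near the references and drifts towards the chip edges, misassigning a
substantial fraction of reads.

The local algorithm implemented here fixes this by partitioning the pixel
domain into a grid of overlapping subdomains (the distortion is approximately
linear at subdomain scale).  One seed subdomain is anchored by two externally
verified reference beads; its two-point similarity fit assigns the reads in
its core area, and the confidently assigned beads falling in the overlap with
each neighbouring subdomain become that neighbour's reference pair.  The
mapping thus propagates breadth-first across the chip, each subdomain fitting
its own local transform, until every reachable subdomain is mapped.

All transforms are 4-DOF similarities (uniform scale, rotation, translation —
no reflection, which is physically excluded by the fixed chip orientation).
Two point correspondences determine such a transform exactly.
"""

from __future__ import annotations

import math
from collections import deque
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd

from .plate import WellGrid

__all__ = [
    "SimilarityTransform",
    "RefPair",
    "SubdomainGrid",
    "MappingResult",
    "fit_similarity_two_points",
    "fit_similarity_lsq",
    "partition",
    "global_map",
    "choose_refs_in_overlap",
    "diffuse_map",
    "mapping_diagnostics",
]

#: Default assignment threshold in pixels: a mapped point farther than this
#: from any well centre (in pixel units at the local scale) is left
#: unassigned.  The value mirrors the operating point of the platform the
#: algorithm was developed on and is config-overridable.
DEFAULT_THRESHOLD_PX = 13.5

#: Fraction of the assignment threshold a residual must stay below for the
#: assignment to be trusted as a *reference* for a neighbouring subdomain.
REF_RESIDUAL_GATE = 0.25


class InsufficientReferences(Exception):
    """Raised when an overlap region holds fewer than two trusted assignments."""


@dataclass(frozen=True)
class SimilarityTransform:
    """x' = s * R(theta) @ x + t  (no reflection)."""

    scale: float
    rotation: float  # radians
    tx: float
    ty: float

    def __post_init__(self):
        if not self.scale > 0:
            raise ValueError(f"scale must be > 0, got {self.scale}")

    @property
    def matrix(self) -> np.ndarray:
        c, s = math.cos(self.rotation), math.sin(self.rotation)
        return self.scale * np.array([[c, -s], [s, c]])

    def apply(self, points: np.ndarray) -> np.ndarray:
        pts = np.atleast_2d(np.asarray(points, dtype=float))
        out = pts @ self.matrix.T + np.array([self.tx, self.ty])
        return out[0] if np.asarray(points).ndim == 1 else out

    def invert(self) -> "SimilarityTransform":
        inv_scale = 1.0 / self.scale
        c, s = math.cos(-self.rotation), math.sin(-self.rotation)
        m = inv_scale * np.array([[c, -s], [s, c]])
        t = -m @ np.array([self.tx, self.ty])
        return SimilarityTransform(inv_scale, -self.rotation, t[0], t[1])

    def compose(self, inner: "SimilarityTransform") -> "SimilarityTransform":
        """self o inner: apply ``inner`` first, then ``self``."""
        scale = self.scale * inner.scale
        rot = self.rotation + inner.rotation
        t = self.matrix @ np.array([inner.tx, inner.ty]) + np.array([self.tx, self.ty])
        return SimilarityTransform(scale, rot, t[0], t[1])

    @staticmethod
    def identity() -> "SimilarityTransform":
        return SimilarityTransform(1.0, 0.0, 0.0, 0.0)


def fit_similarity_two_points(p1, p2, q1, q2) -> SimilarityTransform:
    """Exact 4-DOF similarity mapping p1 -> q1 and p2 -> q2.

    The scale is |q2-q1| / |p2-p1|, the rotation is the angle between the two
    segments, and the translation pins p1 exactly onto q1 (hence p2 onto q2).
    """
    p1 = np.asarray(p1, dtype=float)
    p2 = np.asarray(p2, dtype=float)
    q1 = np.asarray(q1, dtype=float)
    q2 = np.asarray(q2, dtype=float)
    dp = p2 - p1
    dq = q2 - q1
    np_len = float(np.hypot(*dp))
    nq_len = float(np.hypot(*dq))
    if np_len == 0.0:
        raise ValueError("source reference points are coincident")
    if nq_len == 0.0:
        raise ValueError("target reference points are coincident")
    scale = nq_len / np_len
    rot = math.atan2(dq[1], dq[0]) - math.atan2(dp[1], dp[0])
    c, s = math.cos(rot), math.sin(rot)
    m = scale * np.array([[c, -s], [s, c]])
    t = q1 - m @ p1
    return SimilarityTransform(scale, rot, float(t[0]), float(t[1]))


def fit_similarity_lsq(src: np.ndarray, dst: np.ndarray) -> SimilarityTransform:
    """Least-squares similarity (no reflection) over >= 2 correspondences.

    Closed-form Procrustes solution; with exactly two points it agrees with
    :func:`fit_similarity_two_points`.
    """
    src = np.atleast_2d(np.asarray(src, dtype=float))
    dst = np.atleast_2d(np.asarray(dst, dtype=float))
    if src.shape != dst.shape or src.shape[0] < 2:
        raise ValueError("need >= 2 matched source/target points")
    mu_s = src.mean(axis=0)
    mu_d = dst.mean(axis=0)
    xs = src - mu_s
    xd = dst - mu_d
    var_s = (xs ** 2).sum()
    if var_s == 0:
        raise ValueError("source points are coincident")
    # complex-number form of the 2-D rotation+scale fit
    a = float((xs[:, 0] * xd[:, 0] + xs[:, 1] * xd[:, 1]).sum())
    b = float((xs[:, 0] * xd[:, 1] - xs[:, 1] * xd[:, 0]).sum())
    scale = math.hypot(a, b) / var_s
    if scale == 0:
        raise ValueError("degenerate fit: zero scale")
    rot = math.atan2(b, a)
    c, s = math.cos(rot), math.sin(rot)
    m = scale * np.array([[c, -s], [s, c]])
    t = mu_d - m @ mu_s
    return SimilarityTransform(scale, rot, float(t[0]), float(t[1]))


@dataclass(frozen=True)
class RefPair:
    """Two pixel<->well-centre correspondences anchoring one subdomain."""

    pixels: np.ndarray       # (2, 2) pixel coordinates
    wells: np.ndarray        # (2, 2) well-centre world coordinates
    read_ids: tuple = ("", "")
    well_ids: tuple = ("", "")

    def __post_init__(self):
        object.__setattr__(self, "pixels", np.asarray(self.pixels, dtype=float).reshape(2, 2))
        object.__setattr__(self, "wells", np.asarray(self.wells, dtype=float).reshape(2, 2))
        if np.allclose(self.pixels[0], self.pixels[1]):
            raise ValueError("reference pixel points are coincident")
        if np.allclose(self.wells[0], self.wells[1]):
            raise ValueError("reference wells are coincident")

    def fit(self) -> SimilarityTransform:
        return fit_similarity_two_points(self.pixels[0], self.pixels[1],
                                         self.wells[0], self.wells[1])


@dataclass
class SubdomainGrid:
    """nx x ny partition of the pixel-domain bounding box with edge overlap."""

    bounds: tuple            # (xmin, ymin, xmax, ymax)
    nx: int
    ny: int
    overlap_fraction: float
    core: np.ndarray = field(init=False)      # (n, 4) core bounds
    extended: np.ndarray = field(init=False)  # (n, 4) overlapping bounds

    def __post_init__(self):
        xmin, ymin, xmax, ymax = map(float, self.bounds)
        if not (xmax > xmin and ymax > ymin):
            raise ValueError(f"degenerate pixel bounds {self.bounds}")
        if self.nx < 1 or self.ny < 1:
            raise ValueError("nx and ny must be >= 1")
        if not (0 <= self.overlap_fraction < 0.5):
            raise ValueError("overlap_fraction must be in [0, 0.5)")
        w = (xmax - xmin) / self.nx
        h = (ymax - ymin) / self.ny
        core = []
        ext = []
        ox, oy = self.overlap_fraction * w, self.overlap_fraction * h
        for j in range(self.ny):
            for i in range(self.nx):
                cx0 = xmin + i * w
                cy0 = ymin + j * h
                cx1 = xmin + (i + 1) * w if i < self.nx - 1 else xmax
                cy1 = ymin + (j + 1) * h if j < self.ny - 1 else ymax
                core.append((cx0, cy0, cx1, cy1))
                ext.append((max(xmin, cx0 - ox), max(ymin, cy0 - oy),
                            min(xmax, cx1 + ox), min(ymax, cy1 + oy)))
        self.core = np.array(core)
        self.extended = np.array(ext)

    @property
    def n(self) -> int:
        return self.nx * self.ny

    def neighbours(self, idx: int) -> list[int]:
        """4-connected neighbours in the subdomain lattice."""
        j, i = divmod(idx, self.nx)
        out = []
        for dj, di in ((0, -1), (0, 1), (-1, 0), (1, 0)):
            jj, ii = j + dj, i + di
            if 0 <= jj < self.ny and 0 <= ii < self.nx:
                out.append(jj * self.nx + ii)
        return out

    def core_index(self, points: np.ndarray) -> np.ndarray:
        """Core cell index of each point (points outside are clamped)."""
        xmin, ymin, xmax, ymax = map(float, self.bounds)
        pts = np.atleast_2d(points)
        w = (xmax - xmin) / self.nx
        h = (ymax - ymin) / self.ny
        i = np.clip(((pts[:, 0] - xmin) / w).astype(int), 0, self.nx - 1)
        j = np.clip(((pts[:, 1] - ymin) / h).astype(int), 0, self.ny - 1)
        return j * self.nx + i

    def in_extended(self, idx: int, points: np.ndarray) -> np.ndarray:
        x0, y0, x1, y1 = self.extended[idx]
        pts = np.atleast_2d(points)
        return ((pts[:, 0] >= x0) & (pts[:, 0] <= x1) &
                (pts[:, 1] >= y0) & (pts[:, 1] <= y1))


def partition(pixel_bounds, nx: int = 20, ny: int = 15,
              overlap_fraction: float = 0.10) -> SubdomainGrid:
    """Partition the pixel bounding box into nx*ny overlapping subdomains.

    The defaults give 300 subdomains, the regime in which the distortion of a
    full-chip image is approximately linear per cell; for desk-scale simulated
    chips a coarser grid (tens of beads per cell) is appropriate.
    """
    return SubdomainGrid(tuple(pixel_bounds), nx, ny, overlap_fraction)


# ---------------------------------------------------------------------------
# assignment machinery

FLAG_OK = "ok"
FLAG_OVER = "over_threshold"
FLAG_COLLISION = "collision"
FLAG_FAILED = "subdomain_failed"
FLAG_UNMAPPED = "unmapped"


@dataclass
class MappingResult:
    """Per-read well assignment with residuals and QC flags.

    ``frame`` columns: read_id, well_id (NA when unassigned), residual_px,
    subdomain, flag.  ``subdomain_status`` maps subdomain index to
    mapped/failed for the local algorithm (global mapping uses one pseudo
    subdomain 0).
    """

    frame: pd.DataFrame
    subdomain_status: dict
    transforms: dict

    @property
    def assigned(self) -> pd.DataFrame:
        return self.frame[self.frame["flag"] == FLAG_OK]


def _resolve_collisions(read_ids, well_idx, residual, flag):
    """Keep the smallest-residual read per well; losers become collisions.

    Ties on residual break by lexicographic read id, so resolution is
    deterministic.
    """
    order = np.lexsort((np.asarray(read_ids), residual))
    seen: dict[int, None] = {}
    for i in order:
        if flag[i] != FLAG_OK:
            continue
        w = int(well_idx[i])
        if w in seen:
            flag[i] = FLAG_COLLISION
        else:
            seen[w] = None
    return flag


def _build_frame(read_ids, grid: WellGrid, well_idx, residual, subdomain, flag) -> pd.DataFrame:
    well_ids = np.array([grid.well_id(int(w)) if f in (FLAG_OK, FLAG_COLLISION) and w >= 0 else "NA"
                         for w, f in zip(well_idx, flag)], dtype=object)
    return pd.DataFrame({
        "read_id": np.asarray(read_ids, dtype=object),
        "well_id": well_ids,
        "residual_px": residual,
        "subdomain": subdomain,
        "flag": np.asarray(flag, dtype=object),
    })


def global_map(pixels: pd.DataFrame, refs: RefPair, wells: WellGrid,
               threshold_px: float = DEFAULT_THRESHOLD_PX) -> MappingResult:
    """One-step whole-chip registration from a single two-point fit.

    ``pixels`` needs columns read_id, x_px, y_px.  Every pixel is pushed
    through the single fitted similarity and snapped to the nearest well;
    residuals beyond ``threshold_px`` (expressed in pixel units at the fitted
    scale) are left unassigned.  This is the baseline the local algorithm is
    measured against: exact when the distortion is a pure similarity, and
    increasingly wrong as non-linear distortion grows.
    """
    t = refs.fit()
    pts = pixels[["x_px", "y_px"]].to_numpy(dtype=float)
    read_ids = pixels["read_id"].to_numpy(dtype=object)
    world = t.apply(pts)
    widx, dist = wells.nearest(world)
    residual = dist / t.scale  # well-map distance expressed in pixels
    flag = np.where(residual <= threshold_px, FLAG_OK, FLAG_OVER).astype(object)
    widx = np.where(flag == FLAG_OK, widx, -1)
    flag = _resolve_collisions(read_ids, widx, residual, flag)
    frame = _build_frame(read_ids, wells, widx, residual,
                         np.zeros(len(read_ids), dtype=int), flag)
    return MappingResult(frame, {0: "mapped"}, {0: t})


def choose_refs_in_overlap(cand_read_ids, cand_pixels, cand_wells, cand_residuals,
                           threshold_px: float = DEFAULT_THRESHOLD_PX) -> RefPair:
    """Select the reference pair handed to a neighbouring subdomain.

    Candidates are ok-flagged assignments inside the overlap region; only
    those with residual below ``REF_RESIDUAL_GATE * threshold_px`` are
    trusted.  Among those, the pair with the greatest pixel separation wins
    (wide lever arm minimises the extrapolation error of the neighbour's
    two-point fit); exact separation ties break by lexicographic read id.
    """
    cand_pixels = np.atleast_2d(np.asarray(cand_pixels, dtype=float))
    cand_wells = np.atleast_2d(np.asarray(cand_wells, dtype=float))
    cand_residuals = np.asarray(cand_residuals, dtype=float)
    read_ids = list(cand_read_ids)
    keep = cand_residuals < REF_RESIDUAL_GATE * threshold_px
    if keep.sum() < 2:
        raise InsufficientReferences(
            f"{int(keep.sum())} trusted assignments in overlap (need 2)")
    idx = np.flatnonzero(keep)
    # deterministic scan for the maximally separated pair
    best = None
    for a_pos in range(len(idx)):
        for b_pos in range(a_pos + 1, len(idx)):
            a, b = int(idx[a_pos]), int(idx[b_pos])
            d = float(np.hypot(*(cand_pixels[a] - cand_pixels[b])))
            key = tuple(sorted((str(read_ids[a]), str(read_ids[b]))))
            if best is None or d > best[0] + 1e-12 or (abs(d - best[0]) <= 1e-12 and key < best[1]):
                best = (d, key, a, b)
    _, _, a, b = best
    if np.allclose(cand_wells[a], cand_wells[b]):
        raise InsufficientReferences("trusted assignments collapse onto one well")
    return RefPair(pixels=np.vstack([cand_pixels[a], cand_pixels[b]]),
                   wells=np.vstack([cand_wells[a], cand_wells[b]]),
                   read_ids=(str(read_ids[a]), str(read_ids[b])))


def _find_seed_subdomain(grid: SubdomainGrid, refs: RefPair) -> int:
    core = grid.core_index(refs.pixels)
    if core[0] == core[1]:
        return int(core[0])
    both = [i for i in range(grid.n)
            if grid.in_extended(i, refs.pixels).all()]
    if not both:
        raise ValueError("seed references do not fall inside any one subdomain")
    return both[0]


def diffuse_map(pixels: pd.DataFrame, wells: WellGrid, seed_refs: RefPair,
                grid: SubdomainGrid,
                threshold_px: float = DEFAULT_THRESHOLD_PX) -> MappingResult:
    """Diffusion-like local mapping: propagate two-point fits across subdomains.

    Starting from the subdomain containing ``seed_refs``, a breadth-first
    wave crosses the 4-connected subdomain lattice.  Each visited subdomain
    fits its own similarity from the reference pair handed across the shared
    overlap, assigns the reads whose pixels fall in its *core* cell, and
    exports a fresh reference pair (its most widely separated trusted
    assignments in the overlap) to each not-yet-visited neighbour.
    Subdomains that never receive a trusted pair are flagged failed and their
    reads left unassigned.  The algorithm itself is deterministic: identical
    inputs produce identical results.
    """
    pts = pixels[["x_px", "y_px"]].to_numpy(dtype=float)
    read_ids = pixels["read_id"].to_numpy(dtype=object)
    n_reads = len(read_ids)
    centers = wells.centers()

    core_of = grid.core_index(pts)

    well_idx = np.full(n_reads, -1, dtype=int)
    residual = np.full(n_reads, np.nan)
    subdomain = np.full(n_reads, -1, dtype=int)
    flag = np.full(n_reads, FLAG_UNMAPPED, dtype=object)

    status = {i: "unmapped" for i in range(grid.n)}
    transforms: dict[int, SimilarityTransform] = {}

    seed_idx = _find_seed_subdomain(grid, seed_refs)
    visited = {seed_idx}
    queue: deque[tuple[int, RefPair]] = deque([(seed_idx, seed_refs)])

    while queue:
        idx, refs = queue.popleft()
        try:
            t = refs.fit()
        except ValueError:
            status[idx] = "failed"
            continue
        transforms[idx] = t
        ext_mask = grid.in_extended(idx, pts)
        ext_ids = np.flatnonzero(ext_mask)
        if len(ext_ids) == 0:
            status[idx] = "mapped"
            continue
        world = t.apply(pts[ext_ids])
        widx, dist = wells.nearest(world)
        res = dist / t.scale
        ok = res <= threshold_px

        # final assignment for reads whose pixel lies in this core cell
        core_sel = core_of[ext_ids] == idx
        tgt = ext_ids[core_sel]
        well_idx[tgt] = np.where(ok[core_sel], widx[core_sel], -1)
        residual[tgt] = res[core_sel]
        subdomain[tgt] = idx
        flag[tgt] = np.where(ok[core_sel], FLAG_OK, FLAG_OVER)

        status[idx] = "mapped"

        # hand references to unvisited neighbours via the shared overlap
        for nb in grid.neighbours(idx):
            if nb in visited:
                continue
            in_nb = grid.in_extended(nb, pts[ext_ids]) & ok
            cand = np.flatnonzero(in_nb)
            if len(cand) < 2:
                continue
            gids = ext_ids[cand]
            try:
                nb_refs = choose_refs_in_overlap(
                    read_ids[gids], pts[gids], centers[widx[cand]],
                    res[cand], threshold_px)
            except InsufficientReferences:
                continue
            visited.add(nb)
            queue.append((nb, nb_refs))

    for i in range(grid.n):
        if status[i] == "unmapped":
            status[i] = "failed"
    failed_mask = flag == FLAG_UNMAPPED
    flag[failed_mask] = FLAG_FAILED
    subdomain[failed_mask] = core_of[failed_mask]

    flag = _resolve_collisions(read_ids, well_idx, np.nan_to_num(residual, nan=np.inf), flag)
    frame = _build_frame(read_ids, wells, well_idx, residual, subdomain, flag)
    return MappingResult(frame, status, transforms)


def mapping_diagnostics(result: MappingResult, truth: Optional[pd.DataFrame] = None) -> dict:
    """Summary statistics of a mapping run.

    ``truth``, when given, needs columns read_id and well_id (the true well
    of each read); misassignment is then the fraction of reads *not* ending
    up ok-assigned to their true well (wrong well, collision-displaced and
    unassigned reads all count as losses).
    """
    f = result.frame
    n = len(f)
    ok = f["flag"] == FLAG_OK
    res = f.loc[ok, "residual_px"].to_numpy(dtype=float)
    report = {
        "n_reads": int(n),
        "assigned": int(ok.sum()),
        "assigned_fraction": float(ok.sum() / n) if n else 0.0,
        "flags": {k: int(v) for k, v in f["flag"].value_counts().items()},
        "residual_px": {
            "mean": float(res.mean()) if len(res) else None,
            "median": float(np.median(res)) if len(res) else None,
            "p95": float(np.percentile(res, 95)) if len(res) else None,
            "max": float(res.max()) if len(res) else None,
        },
        "subdomains": {
            "mapped": sum(1 for s in result.subdomain_status.values() if s == "mapped"),
            "failed": sum(1 for s in result.subdomain_status.values() if s == "failed"),
        },
    }
    if truth is not None:
        merged = f.merge(truth[["read_id", "well_id"]], on="read_id",
                         suffixes=("", "_true"))
        correct = (merged["flag"] == FLAG_OK) & (merged["well_id"] == merged["well_id_true"])
        report["correct_fraction"] = float(correct.sum() / n) if n else 0.0
        report["misassignment_fraction"] = 1.0 - report["correct_fraction"]
    return report
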