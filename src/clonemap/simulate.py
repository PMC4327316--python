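"""Synthetic sequencing-run generator with full ground truth.

This module stands in for an instrument run: it fabricates a microarray
design pool, a biased and error-laden molecule population amplified from it,
a bead-occupied microwell plate, pyrosequencing-style reads with per-base
qualities, CCD pixel coordinates produced by a smooth non-linear distortion
of the well map, and (optionally) rendered chip images.  Every stochastic
step is a pure function of its parameters and a seed, and every injected
error is recorded, so downstream algorithms can be scored against truth.

The emulated regime:

* ~120-nt single-stranded oligos, >10^3..10^4 designs per pool;
* per-base synthesis error of the microarray pool ~1/70, with abundance bias
  between designs of up to ~10x;
* clonal beads occupying ~10% of wells, one bead per well;
* homopolymer-biased indel errors in the reads (the dominant pyrosequencing
  failure mode), with Phred-scaled per-base qualities.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field as dc_field
from typing import Optional

import numpy as np
import pandas as pd
from scipy.interpolate import RectBivariateSpline

from .mapping import SimilarityTransform
from .plate import WellGrid

__all__ = [
    "DesignPool", "AbundanceProfile", "SynthesisErrorModel", "PyroErrorModel",
    "DistortionField", "SimulatedPlate", "ReadSet",
    "gen_pool", "sample_abundances", "synthesize_molecules", "populate_plate",
    "simulate_reads", "apply_distortion", "render_image", "render_tiles",
]

_BASES = np.array(list("ACGT"))
_OTHER = {b: [o for o in "ACGT" if o != b] for b in "ACGT"}


# ---------------------------------------------------------------------------
# design pool

@dataclass(frozen=True)
class DesignPool:
    """Ordered collection of intended oligo designs (id -> ACGT sequence)."""

    ids: tuple
    sequences: tuple
    has_duplicates: bool = False

    def __post_init__(self):
        if len(self.ids) != len(set(self.ids)):
            raise ValueError("design ids must be unique")
        for s in self.sequences:
            if not s or set(s) - set("ACGT"):
                raise ValueError("sequences must be non-empty over {A,C,G,T}")

    def __len__(self) -> int:
        return len(self.ids)

    def __getitem__(self, i: int) -> tuple[str, str]:
        return self.ids[i], self.sequences[i]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"design_id": self.ids, "sequence": self.sequences})


def gen_pool(n_designs: int, length: int = 120, seed: int = 0) -> DesignPool:
    """Uniform-random design pool, reproducible under ``seed``.

    Duplicate sequences are possible only when ``n_designs`` exceeds the
    4^length sequence space; the pool is then flagged.
    """
    if n_designs < 1:
        raise ValueError(f"n_designs must be >= 1, got {n_designs}")
    if length < 1:
        raise ValueError(f"length must be >= 1, got {length}")
    rng = np.random.default_rng(seed)
    arr = rng.integers(0, 4, size=(n_designs, length))
    seqs = ["".join(row) for row in _BASES[arr]]
    width = max(5, len(str(n_designs - 1)))
    ids = tuple(f"D{i:0{width}d}" for i in range(n_designs))
    dup = len(set(seqs)) < n_designs
    if dup and n_designs <= 4 ** length:
        # collisions in-range are astronomically unlikely but permitted
        pass
    return DesignPool(ids=ids, sequences=tuple(seqs), has_duplicates=dup)


# ---------------------------------------------------------------------------
# abundance bias

@dataclass(frozen=True)
class AbundanceProfile:
    """Relative abundance per design; bias factor B = max weight / min weight."""

    design_ids: tuple
    weights: np.ndarray

    def __post_init__(self):
        w = np.asarray(self.weights, dtype=float)
        if (w <= 0).any():
            raise ValueError("weights must be positive")
        object.__setattr__(self, "weights", w)

    @property
    def bias(self) -> float:
        return float(self.weights.max() / self.weights.min())

    @property
    def probabilities(self) -> np.ndarray:
        return self.weights / self.weights.sum()


def sample_abundances(pool: DesignPool, bias: float = 10.0,
                      kind: str = "loguniform", seed: int = 0) -> AbundanceProfile:
    """Draw per-design abundance weights with an exact max/min ratio ``bias``.

    ``loguniform`` pins one design at weight 1 and one at weight B and draws
    the rest log-uniformly in [1, B]; ``twoclass`` gives half the designs
    weight 1 and half weight B.  Positions are permuted so no design id is
    systematically favoured.
    """
    if bias < 1:
        raise ValueError(f"bias factor must be >= 1, got {bias}")
    n = len(pool)
    rng = np.random.default_rng(seed)
    if bias == 1 or n == 1:
        w = np.ones(n)
    elif kind == "loguniform":
        w = np.exp(rng.uniform(0.0, math.log(bias), size=n))
        w[0], w[-1] = 1.0, bias          # pin the endpoints, ratio exact
        w = rng.permutation(w)
    elif kind == "twoclass":
        w = np.ones(n)
        w[n // 2:] = bias
        w = rng.permutation(w)
    else:
        raise ValueError(f"unknown abundance kind {kind!r}")
    return AbundanceProfile(design_ids=pool.ids, weights=w)


# ---------------------------------------------------------------------------
# synthesis errors

@dataclass(frozen=True)
class SynthesisErrorModel:
    """Independent per-base substitution / insertion / deletion rates.

    The default total of 1/70 per base matches the typical quality of
    microarray-synthesised oligo pools, split 60/20/20 between substitutions,
    insertions and deletions.
    """

    sub_rate: float = 0.6 / 70.0
    ins_rate: float = 0.2 / 70.0
    del_rate: float = 0.2 / 70.0

    def __post_init__(self):
        for name in ("sub_rate", "ins_rate", "del_rate"):
            r = getattr(self, name)
            if not (0 <= r < 1):
                raise ValueError(f"{name} must be in [0, 1), got {r}")
        if self.total >= 1:
            raise ValueError("summed error rates must stay below 1")

    @property
    def total(self) -> float:
        return self.sub_rate + self.ins_rate + self.del_rate

    @staticmethod
    def error_free() -> "SynthesisErrorModel":
        return SynthesisErrorModel(0.0, 0.0, 0.0)


def _mutate_sequence(seq: str, model: SynthesisErrorModel, rng) -> tuple[str, list]:
    """Apply one independent per-base draw; returns (variant, edits).

    Each edit is (design position, op, base) with op in {S, I, D}; insertions
    add a random base after the design position.
    """
    p1 = model.sub_rate
    p2 = p1 + model.ins_rate
    p3 = p2 + model.del_rate
    u = rng.random(len(seq))
    if (u >= p3).all():
        return seq, []
    out = []
    edits = []
    for i, base in enumerate(seq):
        r = u[i]
        if r < p1:
            new = _OTHER[base][rng.integers(0, 3)]
            out.append(new)
            edits.append((i, "S", new))
        elif r < p2:
            ins = "ACGT"[rng.integers(0, 4)]
            out.append(base)
            out.append(ins)
            edits.append((i, "I", ins))
        elif r < p3:
            edits.append((i, "D", base))
        else:
            out.append(base)
    return "".join(out), edits


def _edits_str(edits: list) -> str:
    return ";".join(f"{pos}{op}{base}" for pos, op, base in edits)


def synthesize_molecules(pool: DesignPool, profile: AbundanceProfile,
                         error_model: SynthesisErrorModel, n_molecules: int,
                         seed: int = 0) -> pd.DataFrame:
    """Draw molecules from the biased pool and inject synthesis errors.

    Returns a DataFrame with one row per molecule: mol_id, design_id,
    sequence (the synthesised variant), n_sub/n_ins/n_del truth counts and a
    compact edit annotation string.
    """
    if n_molecules < 1:
        raise ValueError("n_molecules must be >= 1")
    rng = np.random.default_rng(seed)
    p = profile.probabilities
    design_idx = rng.choice(len(pool), size=n_molecules, p=p)
    rows = []
    for m, di in enumerate(design_idx):
        did, dseq = pool[int(di)]
        variant, edits = _mutate_sequence(dseq, error_model, rng)
        ns = sum(1 for _, op, _ in edits if op == "S")
        ni = sum(1 for _, op, _ in edits if op == "I")
        nd = sum(1 for _, op, _ in edits if op == "D")
        rows.append((f"m{m:06d}", did, variant, ns, ni, nd, _edits_str(edits)))
    return pd.DataFrame(rows, columns=["mol_id", "design_id", "sequence",
                                       "n_sub", "n_ins", "n_del", "edits"])


# ---------------------------------------------------------------------------
# plate population

@dataclass(frozen=True)
class SimulatedPlate:
    """Bead-occupied plate: at most one molecule per well, with truth."""

    grid: WellGrid
    beads: pd.DataFrame  # well_index, well_id, mol_id, design_id, sequence, n_sub, n_ins, n_del, edits

    @property
    def occupancy(self) -> float:
        return len(self.beads) / self.grid.n_wells


def populate_plate(grid: WellGrid, molecules: pd.DataFrame, occupancy: float,
                   seed: int = 0) -> SimulatedPlate:
    """Seat ``floor(occupancy * n_wells)`` molecules in uniformly chosen wells."""
    if not (0 < occupancy <= 1):
        raise ValueError(f"occupancy must be in (0, 1], got {occupancy}")
    n_beads = int(math.floor(occupancy * grid.n_wells))
    if n_beads > len(molecules):
        raise ValueError(
            f"need {n_beads} molecules for occupancy {occupancy} but only "
            f"{len(molecules)} supplied")
    rng = np.random.default_rng(seed)
    wells = np.sort(rng.choice(grid.n_wells, size=n_beads, replace=False))
    mols = rng.choice(len(molecules), size=n_beads, replace=False)
    sub = molecules.iloc[mols].reset_index(drop=True).copy()
    sub.insert(0, "well_index", wells)
    sub.insert(1, "well_id", [grid.well_id(int(w)) for w in wells])
    return SimulatedPlate(grid=grid, beads=sub)


# ---------------------------------------------------------------------------
# pyrosequencing reads

@dataclass(frozen=True)
class PyroErrorModel:
    """Homopolymer-biased sequencing error model with Phred qualities.

    An indel hits a homopolymer run of length L with probability
    ``min(1, indel_rate * multiplier**(L-1))`` — the geometric escalation
    captures the flow-signal saturation that makes long runs hard to call.
    Substitutions are independent per base.  Per-read error-rate variation
    (lognormal with sigma ``read_sigma``) produces the quality spread seen in
    real runs; per-base qualities encode the realised per-base error
    probability on the Phred scale (integer, 0..40) with Gaussian jitter.
    """

    sub_rate: float = 0.001
    indel_rate: float = 0.004
    multiplier: float = 2.0
    read_sigma: float = 0.6
    quality_jitter: float = 1.5
    max_q: int = 40

    def __post_init__(self):
        for name in ("sub_rate", "indel_rate"):
            if not (0 <= getattr(self, name) <= 1):
                raise ValueError(f"{name} must be in [0, 1]")
        if self.multiplier < 1:
            raise ValueError("multiplier must be >= 1")
        if not (0 <= self.max_q <= 40):
            raise ValueError("max_q must be in [0, 40]")

    def run_indel_prob(self, run_length: int, scale: float = 1.0) -> float:
        return min(1.0, scale * self.indel_rate * self.multiplier ** (run_length - 1))

    @staticmethod
    def error_free() -> "PyroErrorModel":
        return PyroErrorModel(0.0, 0.0, 1.0, 0.0, 0.0)


@dataclass(frozen=True)
class ReadSet:
    """One read per bead with qualities, pixel coordinates and truth."""

    reads: pd.DataFrame
    # columns: read_id, sequence, quality (phred+33 string), x_px, y_px,
    #          well_id, design_id, mol_id, pyro_sub, pyro_ins, pyro_del


def _sequence_read(molecule: str, model: PyroErrorModel, scale: float, rng):
    """Run-wise error process; returns (read, per-base error prob, counts)."""
    out = []
    perr = []
    n_sub = n_ins = n_del = 0
    for base, grp in itertools.groupby(molecule):
        run = len(list(grp))
        p_run = model.run_indel_prob(run, scale)
        new_run = run
        if p_run > 0 and rng.random() < p_run:
            if rng.random() < 0.5:
                new_run = run + 1
                n_ins += 1
            elif run >= 1:
                new_run = run - 1
                n_del += 1
        per_base_indel = p_run / run
        for _ in range(new_run):
            b = base
            p_sub = min(1.0, scale * model.sub_rate)
            if p_sub > 0 and rng.random() < p_sub:
                b = _OTHER[base][rng.integers(0, 3)]
                n_sub += 1
            out.append(b)
            perr.append(min(1.0, p_sub + per_base_indel))
    return "".join(out), np.array(perr), (n_sub, n_ins, n_del)


def _phred_string(perr: np.ndarray, model: PyroErrorModel, rng) -> str:
    if len(perr) == 0:
        return ""
    with np.errstate(divide="ignore"):
        q = np.where(perr > 0, -10.0 * np.log10(np.maximum(perr, 1e-12)), float(model.max_q))
    if model.quality_jitter > 0:
        q = q + rng.normal(0.0, model.quality_jitter, size=len(q))
    q = np.clip(np.rint(q), 0, model.max_q).astype(int)
    return "".join(chr(33 + int(v)) for v in q)


def simulate_reads(plate: SimulatedPlate, pyro: PyroErrorModel,
                   field: Optional["DistortionField"] = None,
                   seed: int = 0) -> ReadSet:
    """Sequence every bead once; pixel positions come from the distortion field.

    With a zero-error model each read equals its bead's molecule and all
    qualities sit at ``max_q``.  When ``field`` is omitted pixels equal the
    well-centre world coordinates (an identity camera).
    """
    rng = np.random.default_rng(seed)
    centers = plate.grid.centers()
    world = centers[plate.beads["well_index"].to_numpy()]
    pixels = apply_distortion(field, world) if field is not None else world.copy()
    rows = []
    for i, bead in enumerate(plate.beads.itertuples(index=False)):
        scale = float(np.exp(rng.normal(0.0, pyro.read_sigma))) if pyro.read_sigma > 0 else 1.0
        seq, perr, (ns, ni, nd) = _sequence_read(bead.sequence, pyro, scale, rng)
        qual = _phred_string(perr, pyro, rng)
        rows.append((f"r{i:06d}", seq, qual, pixels[i, 0], pixels[i, 1],
                     bead.well_id, bead.design_id, bead.mol_id, ns, ni, nd))
    frame = pd.DataFrame(rows, columns=["read_id", "sequence", "quality",
                                        "x_px", "y_px", "well_id", "design_id",
                                        "mol_id", "pyro_sub", "pyro_ins", "pyro_del"])
    return ReadSet(reads=frame)


# ---------------------------------------------------------------------------
# distortion field

@dataclass
class DistortionField:
    """World (um) -> CCD pixel map: similarity + radial term + smooth warp.

    ``pixel = S(world) + radial(S(world)) + warp(world)`` where the radial
    term displaces about ``center`` with normalised-radius polynomial
    coefficients ``k1, k2``, and the warp is a random smooth vector field:
    independent N(0,1) node vectors on a coarse grid of spacing
    ``correlation_length`` over ``world_bounds``, cubic-spline interpolated
    and rescaled so its maximum displacement equals ``amplitude`` pixels
    (realised to within <0.5%, the spline overshoot between the dense
    normalisation probes).  Deterministic given ``seed``.
    """

    similarity: SimilarityTransform = dc_field(default_factory=SimilarityTransform.identity)
    k1: float = 0.0
    k2: float = 0.0
    center: tuple = (0.0, 0.0)
    norm_radius: float = 1000.0
    amplitude: float = 0.0
    correlation_length: float = 300.0
    world_bounds: tuple = (0.0, 0.0, 1000.0, 1000.0)
    seed: int = 0
    _warp: tuple = dc_field(default=None, repr=False, compare=False)

    def __post_init__(self):
        if self.amplitude < 0:
            raise ValueError("warp amplitude must be >= 0")
        if not self.correlation_length > 0:
            raise ValueError("correlation length must be > 0")

    def _build_warp(self):
        x0, y0, x1, y1 = self.world_bounds
        rng = np.random.default_rng(self.seed)
        pad = self.correlation_length
        xs = np.arange(x0 - pad, x1 + 2 * pad, self.correlation_length)
        ys = np.arange(y0 - pad, y1 + 2 * pad, self.correlation_length)
        vx = rng.standard_normal((len(ys), len(xs)))
        vy = rng.standard_normal((len(ys), len(xs)))
        deg_x = min(3, len(xs) - 1)
        deg_y = min(3, len(ys) - 1)
        sx = RectBivariateSpline(ys, xs, vx, kx=deg_y, ky=deg_x)
        sy = RectBivariateSpline(ys, xs, vy, kx=deg_y, ky=deg_x)
        # normalise: probe densely so the realised max displacement = amplitude
        px = np.linspace(x0, x1, max(64, int((x1 - x0) / self.correlation_length * 16) + 1))
        py = np.linspace(y0, y1, max(64, int((y1 - y0) / self.correlation_length * 16) + 1))
        mx = sx(py, px)
        my = sy(py, px)
        mag = np.hypot(mx, my).max()
        scale = self.amplitude / mag if mag > 0 else 0.0
        self._warp = (sx, sy, scale)

    def warp_displacement(self, world: np.ndarray) -> np.ndarray:
        if self.amplitude == 0:
            return np.zeros_like(np.atleast_2d(world), dtype=float)
        if self._warp is None:
            self._build_warp()
        sx, sy, scale = self._warp
        pts = np.atleast_2d(world)
        dx = sx(pts[:, 1], pts[:, 0], grid=False) * scale
        dy = sy(pts[:, 1], pts[:, 0], grid=False) * scale
        return np.column_stack([dx, dy])

    def apply(self, world: np.ndarray) -> np.ndarray:
        pts = np.atleast_2d(np.asarray(world, dtype=float))
        pix = self.similarity.apply(pts)
        pix = np.atleast_2d(pix)
        if self.k1 != 0.0 or self.k2 != 0.0:
            d = pix - np.asarray(self.center, dtype=float)
            r2 = (d ** 2).sum(axis=1) / self.norm_radius ** 2
            pix = pix + d * (self.k1 * r2 + self.k2 * r2 ** 2)[:, None]
        pix = pix + self.warp_displacement(pts)
        return pix[0] if np.asarray(world).ndim == 1 else pix


def apply_distortion(field: DistortionField, world_points) -> np.ndarray:
    """Map world points (um) to CCD pixel coordinates through ``field``."""
    return field.apply(np.asarray(world_points, dtype=float))


# ---------------------------------------------------------------------------
# image rendering

def render_image(grid: WellGrid, field: DistortionField, spot_sigma: float = 1.8,
                 noise_sigma: float = 0.0, seed: int = 0,
                 background: float = 1000.0, spot_amplitude: float = 20000.0,
                 margin: int = 16, max_side: int = 4096) -> tuple[np.ndarray, np.ndarray]:
    """Render the substrate: a Gaussian spot at every well's distorted pixel.

    All wells are visible whether occupied or not (the raw chip image shows
    the substrate, not the beads).  Returns ``(image, spot_centres)`` where
    the uint16 image origin is shifted so all spots fit with ``margin``
    pixels of border; ``spot_centres`` are the distorted well centres in the
    image frame (truth for detector tests).
    """
    centers = grid.centers()
    pix = field.apply(centers)
    lo = pix.min(axis=0) - margin
    hi = pix.max(axis=0) + margin
    shape = (int(math.ceil(hi[1] - lo[1])) + 1, int(math.ceil(hi[0] - lo[0])) + 1)
    if max(shape) > max_side:
        raise ValueError(f"requested raster {shape} exceeds maximum side {max_side}")
    img = np.full(shape, background, dtype=float)
    spots = pix - lo
    half = int(math.ceil(4 * spot_sigma))
    win = np.arange(-half, half + 1)
    for cx, cy in spots:
        ix, iy = int(round(cx)), int(round(cy))
        xs = win + ix
        ys = win + iy
        valid_x = (xs >= 0) & (xs < shape[1])
        valid_y = (ys >= 0) & (ys < shape[0])
        gx = np.exp(-((xs[valid_x] - cx) ** 2) / (2 * spot_sigma ** 2))
        gy = np.exp(-((ys[valid_y] - cy) ** 2) / (2 * spot_sigma ** 2))
        img[np.ix_(ys[valid_y], xs[valid_x])] += spot_amplitude * np.outer(gy, gx)
    if noise_sigma > 0:
        rng = np.random.default_rng(seed)
        img = img + rng.normal(0.0, noise_sigma, size=shape)
    return np.clip(img, 0, 65535).astype(np.uint16), spots


def render_tiles(image: np.ndarray, tile_shape: tuple, overlap_fraction: float = 0.10,
                 jitter_px: int = 2, seed: int = 0):
    """Cut an image into overlapping tiles with jittered true offsets.

    Returns a list of ``(tile, nominal_offset_xy, true_offset_xy)``; the
    nominal offsets are what a stage controller would report, the true
    offsets include a per-tile integer jitter of at most ``jitter_px`` pixels
    (the stitching module must recover the difference).
    """
    th, tw = tile_shape
    h, w = image.shape
    step_y = max(1, int(th * (1 - overlap_fraction)))
    step_x = max(1, int(tw * (1 - overlap_fraction)))
    rng = np.random.default_rng(seed)
    tiles = []
    for oy in range(0, max(1, h - th + 1), step_y):
        for ox in range(0, max(1, w - tw + 1), step_x):
            jx = int(rng.integers(-jitter_px, jitter_px + 1)) if jitter_px else 0
            jy = int(rng.integers(-jitter_px, jitter_px + 1)) if jitter_px else 0
            tx = min(max(0, ox + jx), max(0, w - tw))
            ty = min(max(0, oy + jy), max(0, h - th))
            tiles.append((image[ty:ty + th, tx:tx + tw].copy(), (ox, oy), (tx, ty)))
    return tiles
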