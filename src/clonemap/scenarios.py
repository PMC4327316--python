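"""Canonical simulation scenarios for benchmarking the mapping algorithms.

These fix the study conditions under which the registration claims are
checked, so tests and reproduction scripts exercise one shared definition:

* ``similarity_scenario`` — a plate imaged through a *pure* similarity
  camera (uniform scale 1.1, rotation 3 degrees).  Both the global two-point
  fit and the local diffusion algorithm are exact here; any misassignment
  is a bug.
* ``warp_scenario`` — the same plate geometry imaged through a smooth
  non-linear warp on top of the similarity.  The warp amplitude is fixed at
  a level where the one-step global fit misassigns a substantial minority
  (roughly 10-30%) of reads, the regime in which subdomain propagation is
  designed to win.

Scenarios generate only what registration needs (bead positions, pixels,
truth wells); sequence content is irrelevant to the mapping comparison.
"""

from __future__ import annotations

import math

import numpy as np
import pandas as pd

from .mapping import (RefPair, SimilarityTransform, SubdomainGrid, diffuse_map,
                      global_map, mapping_diagnostics, partition)
from .pipeline import choose_seed_refs
from .plate import WellGrid, make_grid
from .simulate import DistortionField

__all__ = ["similarity_scenario", "warp_scenario", "quality_scenario",
           "compare_local_global", "WARP_AMPLITUDE_PX", "RADIAL_K1"]

#: Smooth random-warp amplitude (pixels) of the benchmark scenario: the
#: chip-to-chip part of the imaging distortion.
WARP_AMPLITUDE_PX = 2.0

#: Radial coefficient of the benchmark distortion (normalised-radius
#: convention): the systematic, seed-independent part of the imaging
#: distortion, sized so chip corners displace by roughly one well pitch
#: (12.5 px).  Together with the random warp this calibrates the one-step
#: global fit into its characteristic 10-30% misassignment regime at the
#: default geometry (120x120 wells, 50 um pitch, 0.25 px/um camera).
RADIAL_K1 = 0.016

#: Subdomain grid of the benchmark scenarios: coarse enough that each cell
#: holds tens of beads (reference pairs need >= 2 trusted beads per overlap).
SUBDOMAIN_NX, SUBDOMAIN_NY = 10, 8


def _occupied_pixels(grid: WellGrid, field: DistortionField, occupancy: float,
                     seed: int) -> pd.DataFrame:
    rng = np.random.default_rng(seed)
    n_beads = int(occupancy * grid.n_wells)
    wells = np.sort(rng.choice(grid.n_wells, size=n_beads, replace=False))
    world = grid.centers()[wells]
    pix = field.apply(world)
    return pd.DataFrame({
        "read_id": [f"r{i:06d}" for i in range(n_beads)],
        "x_px": pix[:, 0],
        "y_px": pix[:, 1],
        "well_id": [grid.well_id(int(w)) for w in wells],
    })


#: Desk-scale plates hold far fewer beads per overlap strip than a real chip,
#: so the benchmark subdomains overlap by 0.2 (vs 0.1 at full chip density)
#: to keep >= 2 reference candidates per shared strip.
SUBDOMAIN_OVERLAP = 0.20


def _scenario(grid: WellGrid, field: DistortionField, occupancy: float,
              seed: int, nx: int, ny: int, overlap: float = SUBDOMAIN_OVERLAP):
    reads = _occupied_pixels(grid, field, occupancy, seed)
    pts = reads[["x_px", "y_px"]].to_numpy()
    pad = 1e-6
    bounds = (pts[:, 0].min() - pad, pts[:, 1].min() - pad,
              pts[:, 0].max() + pad, pts[:, 1].max() + pad)
    subgrid = partition(bounds, nx, ny, overlap)
    refs = choose_seed_refs(reads, grid, subgrid)
    return reads, grid, refs, subgrid


def similarity_scenario(seed: int = 0, rows: int = 100, cols: int = 100,
                        occupancy: float = 0.10, scale: float = 1.1,
                        rotation_deg: float = 3.0):
    """Plate under a distortion that is exactly a similarity transform."""
    grid = make_grid(rows, cols, pitch=50.0, layout="hex")
    sim = SimilarityTransform(scale=scale, rotation=math.radians(rotation_deg),
                              tx=100.0, ty=80.0)
    field = DistortionField(similarity=sim, amplitude=0.0)
    return _scenario(grid, field, occupancy, seed,
                     SUBDOMAIN_NX, SUBDOMAIN_NY)


def warp_scenario(seed: int = 0, rows: int = 120, cols: int = 120,
                  occupancy: float = 0.10,
                  amplitude_px: float = WARP_AMPLITUDE_PX,
                  correlation_um: float = 1000.0,
                  k1: float = RADIAL_K1,
                  nx: int = SUBDOMAIN_NX, ny: int = SUBDOMAIN_NY):
    """Plate under similarity + radial + smooth random warp (the stress case).

    The deterministic radial (pincushion-like) term models the systematic
    part of an imaging train's distortion; the seeded random warp models the
    chip-to-chip part.  Together they put the one-step global fit into its
    failure regime while staying locally near-linear at subdomain scale.
    """
    grid = make_grid(rows, cols, pitch=50.0, layout="hex")
    centers = grid.centers()
    x0, y0 = centers.min(axis=0)
    x1, y1 = centers.max(axis=0)
    sim = SimilarityTransform(scale=0.25, rotation=math.radians(2.0),
                              tx=60.0, ty=40.0)
    centre_px = sim.apply(np.array([(x0 + x1) / 2, (y0 + y1) / 2]))
    half_diag = 0.25 * math.hypot(x1 - x0, y1 - y0) / 2
    field = DistortionField(similarity=sim, amplitude=amplitude_px,
                            correlation_length=correlation_um,
                            k1=k1, center=tuple(centre_px),
                            norm_radius=half_diag,
                            world_bounds=(x0, y0, x1 + 1e-6, y1 + 1e-6),
                            seed=seed + 7919)
    return _scenario(grid, field, occupancy, seed, nx, ny)


def quality_scenario(seed: int = 0, n_designs: int = 300, n_molecules: int = 3000,
                     rows: int = 100, cols: int = 100, occupancy: float = 0.10,
                     pyro: "PyroErrorModel | None" = None):
    """Reads for the substitution-vs-indel quality analysis.

    Molecules carry substitution-only synthesis errors at the canonical
    1/70-per-base pool rate, while the sequencer injects homopolymer-biased
    indels (and a few substitutions) whose rate varies read-to-read and is
    encoded in the qualities.  In this regime — synthesis errors appearing
    as substitutions, sequencing errors mostly as indels — the gap between
    the substitution-only ("red") and strict ("blue") correct fractions
    shrinks as read quality rises, because high-quality reads lose their
    sequencing indels while keeping their synthesis substitutions.

    Returns ``(reads, pool, plate)``.
    """
    from .simulate import (PyroErrorModel, SynthesisErrorModel, gen_pool,
                           populate_plate, sample_abundances, simulate_reads,
                           synthesize_molecules)
    rng = np.random.default_rng(seed)
    s = rng.integers(0, 2 ** 31 - 1, size=5)
    pool = gen_pool(n_designs, 120, seed=int(s[0]))
    profile = sample_abundances(pool, 10.0, seed=int(s[1]))
    synth = SynthesisErrorModel(sub_rate=1.0 / 70.0, ins_rate=0.0, del_rate=0.0)
    mols = synthesize_molecules(pool, profile, synth, n_molecules, seed=int(s[2]))
    grid = make_grid(rows, cols, pitch=50.0, layout="hex")
    plate = populate_plate(grid, mols, occupancy, seed=int(s[3]))
    readset = simulate_reads(plate, pyro or PyroErrorModel(), None, seed=int(s[4]))
    return readset.reads, pool, plate


def compare_local_global(seed: int = 0, threshold_px: float = 13.5,
                         **kwargs) -> dict:
    """Run both algorithms on one warp-scenario realisation.

    Returns global/local misassignment fractions (a read counts as lost if
    it does not end ok-assigned to its true well) plus diagnostics.
    """
    reads, grid, refs, subgrid = warp_scenario(seed=seed, **kwargs)
    truth = reads[["read_id", "well_id"]]
    pixels = reads[["read_id", "x_px", "y_px"]]
    g = global_map(pixels, refs, grid, threshold_px)
    l = diffuse_map(pixels, grid, refs, subgrid, threshold_px)
    gd = mapping_diagnostics(g, truth)
    ld = mapping_diagnostics(l, truth)
    return {
        "seed": seed,
        "n_reads": len(reads),
        "global_misassignment": gd["misassignment_fraction"],
        "local_misassignment": ld["misassignment_fraction"],
        "global": gd,
        "local": ld,
    }
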