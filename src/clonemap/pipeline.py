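"""End-to-end orchestration: simulate -> map -> classify/select -> plan -> report.

Every stage writes its artifacts under the output directory and the final
report collects the per-stage counts and rates.  A run is reproducible
bit-for-bit from (config, seed); only the timing block differs between
repeats.
"""

from __future__ import annotations

import json
import math
import time
from decimal import ROUND_HALF_UP, Decimal
from pathlib import Path

import numpy as np
import pandas as pd

from . import io as cio
from .config import RunConfig
from .mapping import (RefPair, diffuse_map, global_map, mapping_diagnostics,
                      partition)
from .planner import build_shotlist, calibrate_stage
from .plate import WellGrid, make_grid, well_map_frame, write_well_map
from .seqselect import (classify_reads, estimate_error_rate, fold_improvement,
                        quality_group_analysis, select_targets)
from .simulate import (DistortionField, PyroErrorModel, SynthesisErrorModel,
                       gen_pool, populate_plate, render_image, sample_abundances,
                       simulate_reads, synthesize_molecules)
from .mapping import SimilarityTransform

__all__ = ["percent", "run_pipeline", "choose_seed_refs", "build_field"]


def percent(numerator: int, denominator: int, decimals: int = 1) -> float:
    """100 * a / b rounded half-up to ``decimals`` places.

    Half-up rounding reproduces how count ratios are conventionally printed
    (e.g. 1060/1108 -> 95.67 at two decimals).
    """
    if denominator <= 0:
        raise ValueError("denominator must be > 0")
    q = Decimal(numerator) * 100 / Decimal(denominator)
    exp = Decimal(1).scaleb(-decimals)
    return float(q.quantize(exp, rounding=ROUND_HALF_UP))


def build_field(config: RunConfig, grid: WellGrid, seed: int) -> DistortionField:
    """Distortion field implied by the config's camera model."""
    d = config.distortion
    centers_bounds = grid.centers()
    x0, y0 = centers_bounds.min(axis=0)
    x1, y1 = centers_bounds.max(axis=0)
    sim = SimilarityTransform(scale=d.scale,
                              rotation=math.radians(d.rotation_deg),
                              tx=d.tx_px, ty=d.ty_px)
    span = max(x1 - x0, y1 - y0, 1.0)
    return DistortionField(
        similarity=sim, k1=d.k1, k2=d.k2,
        center=tuple(sim.apply(np.array([(x0 + x1) / 2, (y0 + y1) / 2]))),
        norm_radius=d.scale * span / 2,
        amplitude=d.warp_amplitude_px,
        correlation_length=d.warp_correlation_um,
        world_bounds=(x0, y0, x1 + 1e-6, y1 + 1e-6),
        seed=seed,
    )


def choose_seed_refs(reads: pd.DataFrame, grid: WellGrid, subgrid) -> RefPair:
    """Pick the two seed reference beads anchoring the diffusion.

    Emulates the instrument workflow, where two beads in one subdomain are
    externally sequence-verified: the subdomain covering the chip centre is
    taken and its two most widely separated beads (by pixel distance) become
    the references, with their true well centres as targets.
    """
    pts = reads[["x_px", "y_px"]].to_numpy(dtype=float)
    cx = (subgrid.bounds[0] + subgrid.bounds[2]) / 2
    cy = (subgrid.bounds[1] + subgrid.bounds[3]) / 2
    centre_idx = int(subgrid.core_index(np.array([[cx, cy]]))[0])
    mask = subgrid.in_extended(centre_idx, pts)
    cand = np.flatnonzero(mask)
    if len(cand) < 2:
        raise ValueError("fewer than two beads in the central subdomain; "
                         "cannot seed the mapping")
    centers = grid.centers()
    best = None
    for a_pos in range(len(cand)):
        for b_pos in range(a_pos + 1, len(cand)):
            a, b = int(cand[a_pos]), int(cand[b_pos])
            d = float(np.hypot(*(pts[a] - pts[b])))
            if best is None or d > best[0]:
                best = (d, a, b)
    _, a, b = best
    wa = grid.index_of(reads["well_id"].iat[a])
    wb = grid.index_of(reads["well_id"].iat[b])
    return RefPair(pixels=np.vstack([pts[a], pts[b]]),
                   wells=np.vstack([centers[wa], centers[wb]]),
                   read_ids=(str(reads["read_id"].iat[a]), str(reads["read_id"].iat[b])),
                   well_ids=(reads["well_id"].iat[a], reads["well_id"].iat[b]))


def _stage(name, timing):
    class _Ctx:
        def __enter__(self):
            self.t0 = time.perf_counter()
            return self

        def __exit__(self, exc_type, exc, tb):
            timing[name] = round(time.perf_counter() - self.t0, 3)
            if exc is not None:
                raise RuntimeError(f"stage '{name}' failed: {exc}") from exc
    return _Ctx()


def run_pipeline(config: RunConfig, outdir) -> dict:
    """Execute the full desk-scale workflow and return the run report.

    Stages: simulate (pool, molecules, plate, reads, pixels), map (global
    baseline + local diffusion), select (classification, targets, quality
    and error-rate analytics), plan (stage shot list), report.  All
    intermediate artifacts are written under ``outdir``; any stage failure
    aborts with the stage named, retaining partial artifacts.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    timing: dict[str, float] = {}
    report: dict = {"config": config.to_dict()}
    rng = np.random.default_rng(config.seed)
    sub_seeds = rng.integers(0, 2 ** 31 - 1, size=8)

    with _stage("simulate", timing):
        grid = make_grid(config.grid.rows, config.grid.cols,
                         config.grid.pitch_um, config.grid.layout)
        pool = gen_pool(config.pool.n_designs, config.pool.length_nt,
                        seed=int(sub_seeds[0]))
        profile = sample_abundances(pool, config.pool.bias,
                                    config.pool.abundance_kind,
                                    seed=int(sub_seeds[1]))
        err = SynthesisErrorModel(config.synthesis.sub_rate,
                                  config.synthesis.ins_rate,
                                  config.synthesis.del_rate)
        molecules = synthesize_molecules(pool, profile, err,
                                         config.synthesis.n_molecules,
                                         seed=int(sub_seeds[2]))
        plate = populate_plate(grid, molecules, config.plate.occupancy,
                               seed=int(sub_seeds[3]))
        field = build_field(config, grid, seed=int(sub_seeds[4]))
        pyro = PyroErrorModel(config.pyro.sub_rate, config.pyro.indel_rate,
                              config.pyro.multiplier, config.pyro.read_sigma,
                              config.pyro.quality_jitter)
        readset = simulate_reads(plate, pyro, field, seed=int(sub_seeds[5]))
        reads = readset.reads
        cio.write_designs_fasta(pool, outdir / "designs.fasta")
        cio.write_reads_fastq(reads, outdir / "reads.fastq")
        cio.write_pixel_table(reads, outdir / "pixels.tsv")
        write_well_map(grid, outdir / "wellmap.tsv")
        plate.beads.to_csv(outdir / "truth_beads.tsv", sep="\t", index=False)
        reads.drop(columns=["sequence", "quality"]).to_csv(
            outdir / "truth_reads.tsv", sep="\t", index=False,
            float_format="%.4f")
        if config.imaging.render:
            img, _ = render_image(grid, field,
                                  spot_sigma=config.imaging.spot_sigma_px,
                                  noise_sigma=config.imaging.noise_sigma,
                                  seed=int(sub_seeds[6]))
            cio.write_image(img, outdir / "chip.png")

    with _stage("map", timing):
        pts = reads[["x_px", "y_px"]].to_numpy(dtype=float)
        pad = 1e-6
        bounds = (pts[:, 0].min() - pad, pts[:, 1].min() - pad,
                  pts[:, 0].max() + pad, pts[:, 1].max() + pad)
        subgrid = partition(bounds, config.mapping.nx, config.mapping.ny,
                            config.mapping.overlap_fraction)
        refs = choose_seed_refs(reads, grid, subgrid)
        gmap = global_map(reads, refs, grid, config.mapping.threshold_px)
        lmap = diffuse_map(reads, grid, refs, subgrid,
                           config.mapping.threshold_px)
        truth = reads[["read_id", "well_id"]]
        gdiag = mapping_diagnostics(gmap, truth)
        ldiag = mapping_diagnostics(lmap, truth)
        lmap.frame.to_csv(outdir / "mapping.tsv", sep="\t", index=False,
                          float_format="%.4f")
        with open(outdir / "mapping_diagnostics.json", "w") as fh:
            json.dump({"global": gdiag, "local": ldiag}, fh, indent=2,
                      sort_keys=True)
        report["mapping"] = {"global": gdiag, "local": ldiag}

    with _stage("select", timing):
        cls = classify_reads(reads[["read_id", "sequence", "quality"]], pool,
                             config.selection.max_edit_distance,
                             adaptors=config.selection.adaptors or None)
        cls.to_csv(outdir / "classification.tsv", sep="\t", index=False,
                   float_format="%.4f")
        selection = select_targets(lmap.frame, cls,
                                   k=config.selection.min_beads_per_design,
                                   design_ids=pool.ids)
        selection.frame.to_csv(outdir / "selection.tsv", sep="\t", index=False,
                               float_format="%.4f")
        qa = quality_group_analysis(cls, config.selection.n_quality_groups)
        matched = cls[cls["cls"] != "unmatched"]
        total_bases = int(reads.set_index("read_id").loc[
            matched["read_id"], "sequence"].str.len().sum())
        rate_obs = estimate_error_rate(cls, total_bases)

        # truth-based before/after synthesis-error rates
        bead_bases = int(plate.beads["sequence"].str.len().sum())
        bead_errors = int((plate.beads[["n_sub", "n_ins", "n_del"]].sum(axis=1)).sum())
        rate_before = bead_errors / bead_bases if bead_bases else 0.0
        sel_reads = set(selection.frame["read_id"])
        sel_beads = plate.beads.merge(
            reads.loc[reads["read_id"].isin(sel_reads), ["well_id"]], on="well_id")
        sel_bases = int(sel_beads["sequence"].str.len().sum())
        sel_errors = int(sel_beads[["n_sub", "n_ins", "n_del"]].sum(axis=1).sum())
        rate_after = sel_errors / sel_bases if sel_bases else 0.0
        fold = (fold_improvement(rate_before, rate_after)
                if rate_before > 0 else None)

        designs_perfect = int(selection.frame["design_id"].nunique())
        quality_report = {
            "reads_total": int(len(reads)),
            "reads_matched": int(len(matched)),
            "reads_perfect": int((cls["cls"] == "perfect").sum()),
            "designs_total": len(pool),
            "designs_with_perfect_bead": designs_perfect,
            "designs_with_perfect_bead_pct": percent(designs_perfect, len(pool), 1),
            "designs_missing": len(selection.missing),
            "beads_selected": int(len(selection.frame)),
            "observed_error_rate": rate_obs.rate,
            "observed_error_text": rate_obs.text,
            "pool_error_rate_truth": rate_before,
            "selected_error_rate_truth": rate_after,
            "fold_improvement": (None if fold is None
                                 else ("inf" if math.isinf(fold) else fold)),
            "quality_groups": qa.to_dict(orient="records"),
        }
        with open(outdir / "quality_report.json", "w") as fh:
            json.dump(quality_report, fh, indent=2, sort_keys=True)
        report["selection"] = quality_report

    with _stage("plan", timing):
        wellmap = well_map_frame(grid)
        corners = wellmap.iloc[[0, grid.cols - 1, len(wellmap) - 1]]
        world = corners[["x_um", "y_um"]].to_numpy(dtype=float)
        calibration = calibrate_stage(world, world, kind="similarity")
        if len(selection.frame):
            shots = build_shotlist(selection, wellmap, calibration,
                                   ordering=config.planner.ordering,
                                   rate=config.planner.rate_wells_per_s)
            shots.frame.to_csv(outdir / "shotlist.tsv", sep="\t", index=False,
                               float_format="%.2f")
            report["plan"] = {
                "shots": len(shots),
                "path_length_um": round(shots.path_length_um, 2),
                "duration_s": round(shots.duration_s, 2),
                "rate_wells_per_s": shots.rate,
                "calibration_rms_um": calibration.rms_residual,
            }
        else:
            report["plan"] = {"shots": 0}

    report["timing"] = timing
    with open(outdir / "report.json", "w") as fh:
        json.dump(report, fh, indent=2, sort_keys=True)
    return report
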