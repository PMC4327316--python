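"""Retrieval planning: stage calibration, shot ordering and laser physics.

Selected wells become an executable plan for a motorised-stage instrument
that ejects one bead at a time with a focused nanosecond laser pulse and
collects it into 96-well destination plates.  The planner handles the
world-to-stage coordinate fit, the visiting order (boustrophedon or greedy
nearest-neighbour), destination-plate layout with rollover, and a duration
estimate at the instrument's retrieval rate (default 2 wells/s).

A small physics utility computes the radiation force a pulse exerts on a
bead: a pulse of energy E and duration tau carries momentum E/c, delivered
as force F = (1 + R) * eta * E / (c * tau) where R is the bead reflectivity
(reflected photons transfer twice their momentum) and eta the fraction of
pulse energy actually coupled through the fibre core onto the bead.  The
impulse J = F * tau = (1 + R) * eta * E / c is independent of the pulse
duration.
"""

from __future__ import annotations

import math
import string
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .mapping import SimilarityTransform, fit_similarity_lsq
from .seqselect import TargetSelection

__all__ = [
    "StageCalibration", "ShotList", "PhysicsParams",
    "calibrate_stage", "build_shotlist", "radiation_force",
]

SPEED_OF_LIGHT = 299_792_458.0  # m/s

#: Default retrieval throughput of the pulsed-laser instrument, wells/second.
DEFAULT_RETRIEVAL_RATE = 2.0


# ---------------------------------------------------------------------------
# stage calibration

@dataclass(frozen=True)
class StageCalibration:
    """World (um) -> stage readout (um) fit with its RMS residual."""

    kind: str                      # "similarity" | "affine"
    similarity: Optional[SimilarityTransform]
    affine: Optional[np.ndarray]   # 2x3 matrix [A | t]
    rms_residual: float

    def apply(self, points: np.ndarray) -> np.ndarray:
        pts = np.atleast_2d(np.asarray(points, dtype=float))
        if self.kind == "similarity":
            out = self.similarity.apply(pts)
        else:
            out = pts @ self.affine[:, :2].T + self.affine[:, 2]
        return out[0] if np.asarray(points).ndim == 1 else out


def calibrate_stage(world: np.ndarray, stage: np.ndarray,
                    kind: str = "similarity") -> StageCalibration:
    """Least-squares world-to-stage fit from fiducial pairs.

    ``similarity`` needs >= 2 distinct fiducials, ``affine`` >= 3
    non-collinear ones (collinear sets leave the fit underdetermined and are
    rejected).
    """
    world = np.atleast_2d(np.asarray(world, dtype=float))
    stage = np.atleast_2d(np.asarray(stage, dtype=float))
    if world.shape != stage.shape:
        raise ValueError("world and stage fiducial arrays differ in shape")
    if kind == "similarity":
        if len(world) < 2:
            raise ValueError("similarity calibration needs >= 2 fiducials")
        t = fit_similarity_lsq(world, stage)
        pred = t.apply(world)
        rms = float(np.sqrt(np.mean(np.sum((pred - stage) ** 2, axis=1))))
        return StageCalibration(kind="similarity", similarity=t, affine=None,
                                rms_residual=rms)
    if kind == "affine":
        if len(world) < 3:
            raise ValueError("affine calibration needs >= 3 fiducials")
        A = np.column_stack([world, np.ones(len(world))])
        if np.linalg.matrix_rank(A) < 3:
            raise ValueError("fiducials are collinear; affine fit rejected")
        coef, *_ = np.linalg.lstsq(A, stage, rcond=None)
        mat = np.column_stack([coef[:2].T, coef[2]])
        pred = world @ mat[:, :2].T + mat[:, 2]
        rms = float(np.sqrt(np.mean(np.sum((pred - stage) ** 2, axis=1))))
        return StageCalibration(kind="affine", similarity=None, affine=mat,
                                rms_residual=rms)
    raise ValueError(f"unknown calibration kind {kind!r}")


# ---------------------------------------------------------------------------
# shot list

@dataclass(frozen=True)
class ShotList:
    """Ordered retrieval plan with destination-plate assignment."""

    frame: pd.DataFrame  # seq, well_id, stage_x_um, stage_y_um, dest_plate, dest_well, design_id
    path_length_um: float
    duration_s: float
    rate: float

    def __len__(self) -> int:
        return len(self.frame)


def _dest_well(i: int, rows: int = 8, cols: int = 12) -> tuple[int, str]:
    """Row-major destination A1..H12 with plate rollover (1-based plates)."""
    per_plate = rows * cols
    plate = i // per_plate + 1
    slot = i % per_plate
    r, c = divmod(slot, cols)
    return plate, f"{string.ascii_uppercase[r]}{c + 1}"


def _serpentine_order(df: pd.DataFrame) -> list[int]:
    order = []
    for r, grp in df.groupby("row", sort=True):
        idx = grp.sort_values(["col", "well_id"]).index.tolist()
        if r % 2 == 1:
            idx = idx[::-1]
        order.extend(idx)
    return order


def _greedy_nn_order(df: pd.DataFrame) -> list[int]:
    pts = df[["x_um", "y_um"]].to_numpy(dtype=float)
    start = df.sort_values(["row", "col", "well_id"]).index[0]
    remaining = set(df.index)
    order = [start]
    remaining.discard(start)
    pos = {i: pts[k] for k, i in enumerate(df.index)}
    cur = start
    while remaining:
        rem = sorted(remaining)
        d = [float(np.hypot(*(pos[i] - pos[cur]))) for i in rem]
        nxt = rem[int(np.argmin(d))]
        order.append(nxt)
        remaining.discard(nxt)
        cur = nxt
    return order


def build_shotlist(selection: TargetSelection, well_map: pd.DataFrame,
                   calibration: Optional[StageCalibration] = None,
                   ordering: str = "serpentine",
                   rate: float = DEFAULT_RETRIEVAL_RATE) -> ShotList:
    """Turn a target selection into an ordered, stage-ready shot list.

    ``well_map`` supplies world coordinates (columns well_id, row, col,
    x_um, y_um); ``calibration`` converts them to stage readout (identity
    when omitted).  Destinations fill 96-well plates row-major A1..H12,
    rolling over to a fresh plate when full.  Duration is shots / rate.
    """
    if len(selection.frame) == 0:
        raise ValueError("selection is empty")
    if ordering not in ("serpentine", "greedy_nn"):
        raise ValueError(f"unknown ordering {ordering!r}")
    wells = selection.frame.merge(well_map, on="well_id", validate="many_to_one")
    if wells["well_id"].duplicated().any():
        dupes = wells.loc[wells["well_id"].duplicated(), "well_id"].tolist()
        raise ValueError(f"wells selected more than once: {dupes[:5]}")
    wells = wells.reset_index(drop=True)
    order = (_serpentine_order(wells) if ordering == "serpentine"
             else _greedy_nn_order(wells))
    ordered = wells.loc[order].reset_index(drop=True)
    world = ordered[["x_um", "y_um"]].to_numpy(dtype=float)
    stage_xy = calibration.apply(world) if calibration is not None else world
    stage_xy = np.atleast_2d(stage_xy)
    plates, dwells = zip(*(_dest_well(i) for i in range(len(ordered))))
    frame = pd.DataFrame({
        "seq": np.arange(1, len(ordered) + 1),
        "well_id": ordered["well_id"],
        "stage_x_um": stage_xy[:, 0],
        "stage_y_um": stage_xy[:, 1],
        "dest_plate": plates,
        "dest_well": dwells,
        "design_id": ordered["design_id"],
    })
    steps = np.diff(world, axis=0)
    path = float(np.hypot(steps[:, 0], steps[:, 1]).sum()) if len(world) > 1 else 0.0
    if rate <= 0:
        raise ValueError("retrieval rate must be > 0")
    return ShotList(frame=frame, path_length_um=path,
                    duration_s=len(ordered) / rate, rate=rate)


# ---------------------------------------------------------------------------
# radiation-pressure utility

@dataclass(frozen=True)
class PhysicsParams:
    """Pulse energy E (J), duration tau (s), reflectivity R, coupling eta."""

    energy_j: float = 50e-6
    duration_s: float = 7e-9
    reflectivity: float = 0.0
    coupling: float = 1.0

    def __post_init__(self):
        if self.energy_j < 0:
            raise ValueError("pulse energy must be >= 0")
        if not self.duration_s > 0:
            raise ValueError("pulse duration must be > 0")
        if not (0 <= self.reflectivity <= 1):
            raise ValueError("reflectivity must be in [0, 1]")
        if not (0 < self.coupling <= 1):
            raise ValueError("coupling efficiency must be in (0, 1]")


def radiation_force(p: PhysicsParams) -> tuple[float, float]:
    """(force N, impulse N*s) of one pulse on a bead.

    F = (1 + R) * eta * E / (c * tau); J = F * tau.  Note the instrument
    literature quotes force/impulse pairs that imply an effective coupling
    well below 1 — eta is therefore an explicit parameter rather than an
    assumption.
    """
    force = (1.0 + p.reflectivity) * p.coupling * p.energy_j / (SPEED_OF_LIGHT * p.duration_s)
    impulse = force * p.duration_s
    return force, impulse
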