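"""Canonical geometry of the sequencing substrate.

The substrate is modelled as a regular grid of microwells, each of which can
hold at most one clonal bead.  Two layouts are supported:

``square``
    centres at ``(col * pitch, row * pitch)``.
``hex``
    hexagonal close packing, the geometry of an etched fibre-optic bundle:
    odd rows are offset by ``pitch / 2`` in x and the row spacing is
    ``pitch * sqrt(3) / 2``, so the distance between any two neighbouring
    centres is exactly ``pitch``.

World coordinates are micrometres, 0-based, with y increasing downward to
match the image raster convention (this avoids sign flips when registering
camera pixels against the well map).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Tuple

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

__all__ = ["WellGrid", "make_grid", "nearest_well", "write_well_map", "read_well_map"]

#: Default centre-to-centre well pitch in micrometres.  The bead scale of the
#: platform is ~30 um, so a 50 um pitch leaves one bead per well with margin;
#: the true substrate pitch is instrument-specific and config-overridable.
DEFAULT_PITCH_UM = 50.0

_SQRT3_2 = np.sqrt(3.0) / 2.0


@dataclass(frozen=True)
class WellGrid:
    """A rows x cols grid of well centres.

    Wells are enumerated row-major: well index ``i = row * cols + col`` and
    well id ``"R{row}C{col}"``.  Both the enumeration and the centre
    coordinates are deterministic functions of the constructor arguments.
    """

    rows: int
    cols: int
    pitch: float
    layout: str = "hex"
    origin: Tuple[float, float] = (0.0, 0.0)
    _tree: cKDTree = field(init=False, repr=False, compare=False, default=None)

    def __post_init__(self):
        if int(self.rows) < 1:
            raise ValueError(f"rows must be >= 1, got {self.rows}")
        if int(self.cols) < 1:
            raise ValueError(f"cols must be >= 1, got {self.cols}")
        if not self.pitch > 0:
            raise ValueError(f"pitch must be > 0, got {self.pitch}")
        if self.layout not in ("hex", "square"):
            raise ValueError(f"layout must be 'hex' or 'square', got {self.layout!r}")
        object.__setattr__(self, "rows", int(self.rows))
        object.__setattr__(self, "cols", int(self.cols))
        object.__setattr__(self, "pitch", float(self.pitch))

    @property
    def n_wells(self) -> int:
        return self.rows * self.cols

    def centers(self) -> np.ndarray:
        """(n_wells, 2) array of well-centre world coordinates, row-major."""
        rows = np.arange(self.rows)
        cols = np.arange(self.cols)
        cc, rr = np.meshgrid(cols, rows)
        x = cc * self.pitch
        if self.layout == "hex":
            x = x + (rr % 2) * (self.pitch / 2.0)
            y = rr * (self.pitch * _SQRT3_2)
        else:
            y = rr * self.pitch
        pts = np.column_stack([x.ravel() + self.origin[0], y.ravel() + self.origin[1]])
        return pts.astype(float)

    def well_id(self, index: int) -> str:
        row, col = divmod(int(index), self.cols)
        return f"R{row}C{col}"

    def well_ids(self) -> list[str]:
        return [f"R{r}C{c}" for r in range(self.rows) for c in range(self.cols)]

    def index_of(self, well_id: str) -> int:
        if not well_id.startswith("R") or "C" not in well_id:
            raise ValueError(f"malformed well id {well_id!r}")
        row_s, col_s = well_id[1:].split("C")
        row, col = int(row_s), int(col_s)
        if not (0 <= row < self.rows and 0 <= col < self.cols):
            raise ValueError(f"well id {well_id!r} outside grid")
        return row * self.cols + col

    def tree(self) -> cKDTree:
        if self._tree is None:
            object.__setattr__(self, "_tree", cKDTree(self.centers()))
        return self._tree

    def nearest(self, points: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """Vectorised nearest-well query.

        Returns ``(indices, distances)`` for an (n, 2) array of world points.
        Exact distance ties are broken toward the smallest well index.
        """
        points = np.asarray(points, dtype=float)
        single = points.ndim == 1
        pts = np.atleast_2d(points)
        k = min(4, self.n_wells)
        d, idx = self.tree().query(pts, k=k)
        if k == 1:
            d = d[:, None]
            idx = idx[:, None]
        # tie-break: among centres within 1e-9 of the minimum, take min index
        tied = d <= d[:, :1] + 1e-9
        idx_masked = np.where(tied, idx, self.n_wells)
        best = idx_masked.min(axis=1)
        dist = d[:, 0]
        if single:
            return best[0], dist[0]
        return best, dist


def make_grid(rows: int, cols: int, pitch: float = DEFAULT_PITCH_UM,
              layout: str = "hex", origin: Tuple[float, float] = (0.0, 0.0)) -> WellGrid:
    """Construct a :class:`WellGrid`; see the module docstring for layouts."""
    return WellGrid(rows=rows, cols=cols, pitch=pitch, layout=layout, origin=origin)


def nearest_well(grid: WellGrid, point) -> tuple[str, float]:
    """Well id whose centre is closest (Euclidean) to ``point``.

    Always returns a well; exact ties go to the smallest well id in the
    row-major enumeration, which makes downstream assignment deterministic.
    """
    idx, dist = grid.nearest(np.asarray(point, dtype=float))
    return grid.well_id(int(idx)), float(dist)


def well_map_frame(grid: WellGrid) -> pd.DataFrame:
    """Well map as a DataFrame (columns well_id, row, col, x_um, y_um)."""
    centers = grid.centers()
    rows = np.repeat(np.arange(grid.rows), grid.cols)
    cols = np.tile(np.arange(grid.cols), grid.rows)
    return pd.DataFrame({
        "well_id": grid.well_ids(),
        "row": rows,
        "col": cols,
        "x_um": centers[:, 0],
        "y_um": centers[:, 1],
    })


def write_well_map(grid: WellGrid, path) -> None:
    well_map_frame(grid).to_csv(path, sep="\t", index=False, float_format="%.4f")


def read_well_map(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    required = {"well_id", "row", "col", "x_um", "y_um"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"well map missing columns: {sorted(missing)}")
    return df
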