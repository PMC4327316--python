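"""Chip-image processing: tile stitching and well-centre recognition.

The stitched whole-chip image provides the physical well-centre map that the
registration module aligns read pixels against.  Stitching is
translation-only — residual rotation and scale are absorbed downstream by
the per-subdomain similarity fits — and centre detection is a smoothed
local-maxima search with sub-pixel centroid refinement.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage
from skimage.feature import peak_local_max
from skimage.registration import phase_cross_correlation

__all__ = ["CentreSet", "stitch_tiles", "detect_well_centers",
           "write_centres", "read_centres"]


@dataclass(frozen=True)
class CentreSet:
    """Detected well centres (sub-pixel) with peak intensity and quality."""

    frame: pd.DataFrame  # centre_id, x_px, y_px, peak, quality

    def __len__(self) -> int:
        return len(self.frame)

    def coordinates(self) -> np.ndarray:
        return self.frame[["x_px", "y_px"]].to_numpy(dtype=float)


def stitch_tiles(tiles, search_radius: int = 5, corr_threshold: float = 0.2):
    """Assemble tiles into one mosaic, refining each nominal offset.

    ``tiles`` is a sequence of ``(tile, (offset_x, offset_y))`` with offsets
    in mosaic pixels.  Each tile after the first is registered against the
    partially built mosaic by phase correlation restricted to
    ``search_radius`` pixels around its nominal offset; when the correlation
    is unusable (no overlap, flat signal, or a shift beyond the radius) the
    nominal offset is kept and a warning is emitted.  Overlapping areas are
    averaged.  Returns ``(mosaic, refined_offsets)``.
    """
    tiles = list(tiles)
    if not tiles:
        raise ValueError("need at least one tile")
    if len(tiles) == 1:
        return np.asarray(tiles[0][0], dtype=float), [tuple(tiles[0][1])]

    max_x = max(int(ox) + t.shape[1] for t, (ox, oy) in tiles) + search_radius
    max_y = max(int(oy) + t.shape[0] for t, (ox, oy) in tiles) + search_radius
    acc = np.zeros((max_y + 1, max_x + 1))
    weight = np.zeros_like(acc)
    offsets = []

    def _paste(tile, ox, oy):
        h, w = tile.shape
        acc[oy:oy + h, ox:ox + w] += tile
        weight[oy:oy + h, ox:ox + w] += 1.0

    for k, (tile, (ox, oy)) in enumerate(tiles):
        tile = np.asarray(tile, dtype=float)
        ox, oy = int(ox), int(oy)
        if k == 0:
            _paste(tile, ox, oy)
            offsets.append((ox, oy))
            continue
        h, w = tile.shape
        ref = np.divide(acc[oy:oy + h, ox:ox + w],
                        weight[oy:oy + h, ox:ox + w],
                        out=np.zeros((h, w)),
                        where=weight[oy:oy + h, ox:ox + w] > 0)
        mask = weight[oy:oy + h, ox:ox + w] > 0
        use_nominal = True
        if mask.sum() > 16 and ref[mask].std() > 0 and tile[mask].std() > 0:
            try:
                shift, error, _ = phase_cross_correlation(
                    ref * mask, tile * mask, upsample_factor=10,
                    normalization=None)
                dy, dx = float(shift[0]), float(shift[1])
                if abs(dx) <= search_radius and abs(dy) <= search_radius and \
                        (1.0 - error) >= corr_threshold:
                    ox = min(max(0, ox + int(round(dx))), acc.shape[1] - w)
                    oy = min(max(0, oy + int(round(dy))), acc.shape[0] - h)
                    use_nominal = False
            except Exception:
                pass
        if use_nominal:
            warnings.warn(f"tile {k}: correlation unusable, keeping nominal "
                          f"offset ({ox}, {oy})", stacklevel=2)
        _paste(tile, ox, oy)
        offsets.append((ox, oy))

    mosaic = np.divide(acc, weight, out=np.zeros_like(acc), where=weight > 0)
    # trim unused border
    used = np.argwhere(weight > 0)
    y0, x0 = used.min(axis=0)
    y1, x1 = used.max(axis=0)
    return mosaic[y0:y1 + 1, x0:x1 + 1], offsets


def detect_well_centers(image: np.ndarray, expected_pitch_px: float,
                        min_separation_fraction: float = 0.6) -> CentreSet:
    """Locate well centres as smoothed local intensity maxima.

    The image is Gaussian-smoothed with sigma ``pitch/6``; maxima must clear
    a robust threshold (background median + 5 MAD) and be separated by at
    least ``min_separation_fraction * pitch``.  Each surviving maximum is
    refined to sub-pixel precision with a 3x3 intensity centroid.  Centres
    are returned row-major (top-to-bottom, left-to-right within a row).
    """
    if expected_pitch_px <= 2:
        raise ValueError("expected_pitch_px must exceed 2")
    img = np.asarray(image, dtype=float)
    if img.size == 0:
        raise ValueError("empty image")
    smoothed = ndimage.gaussian_filter(img, sigma=expected_pitch_px / 6.0)
    med = float(np.median(smoothed))
    mad = float(np.median(np.abs(smoothed - med)))
    threshold = med + 5.0 * mad if mad > 0 else med + 1e-9
    min_dist = max(1, int(round(min_separation_fraction * expected_pitch_px)))
    peaks = peak_local_max(smoothed, min_distance=min_dist,
                           threshold_abs=threshold, exclude_border=False)
    rows = []
    h, w = img.shape
    for py, px in peaks:
        y0, y1 = max(0, py - 1), min(h, py + 2)
        x0, x1 = max(0, px - 1), min(w, px + 2)
        patch = smoothed[y0:y1, x0:x1] - threshold
        patch = np.clip(patch, 0, None)
        tot = patch.sum()
        if tot > 0:
            yy, xx = np.mgrid[y0:y1, x0:x1]
            cy = float((patch * yy).sum() / tot)
            cx = float((patch * xx).sum() / tot)
        else:
            cy, cx = float(py), float(px)
        peak = float(smoothed[py, px])
        quality = (peak - med) / mad if mad > 0 else np.inf
        rows.append((cx, cy, peak, quality))
    if not rows:
        frame = pd.DataFrame(columns=["centre_id", "x_px", "y_px", "peak", "quality"])
        return CentreSet(frame=frame)
    df = pd.DataFrame(rows, columns=["x_px", "y_px", "peak", "quality"])
    # row-major ordering: bin y by half a pitch, then sort by x within rows
    ybin = np.round(df["y_px"] / (expected_pitch_px / 2.0)).astype(int)
    df = df.assign(_ybin=ybin).sort_values(["_ybin", "x_px"]).drop(columns="_ybin")
    df = df.reset_index(drop=True)
    df.insert(0, "centre_id", [f"c{i:05d}" for i in range(len(df))])
    return CentreSet(frame=df)


def write_centres(centres: CentreSet, path) -> None:
    centres.frame.to_csv(path, sep="\t", index=False, float_format="%.4f")


def read_centres(path) -> CentreSet:
    return CentreSet(frame=pd.read_csv(path, sep="\t"))
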