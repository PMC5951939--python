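"""Whole-well mosaic assembly from overlapping microscope tiles.

Registration follows the standard stitching recipe: translation between each
pair of grid neighbours is estimated on their shared overlap strip by
(upsampled) cross-correlation, the pairwise displacements are reconciled by a
global least-squares solve over the tile graph, and overlapping pixels are
blended with linear feathering. When refinement is off, tiles are composited
at their nominal grid offsets. The pixel-to-micron calibration travels with
the mosaic.

Coordinate convention: pixel (0, 0) at the top-left, x rightward, y downward,
0-based; offsets are (x, y). Centers are continuous-valued.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import tifffile
from skimage.registration import phase_cross_correlation

from .synthetic import TileSet, Tile

__all__ = [
    "CalibrationProfile",
    "WellMosaic",
    "stitch",
    "px_to_um",
    "um_to_px",
    "save_mosaic",
    "load_mosaic",
]

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class CalibrationProfile:
    """Pixel-size calibration mapping image pixels to physical microns."""

    um_per_px: float

    def __post_init__(self) -> None:
        if not (np.isfinite(self.um_per_px) and self.um_per_px > 0):
            raise ValueError(f"um_per_px must be positive and finite, got {self.um_per_px}")


def px_to_um(value_px, cal: CalibrationProfile):
    """Convert a pixel length/coordinate to µm (scalar or array)."""
    return np.asarray(value_px, dtype=float) * cal.um_per_px if np.ndim(value_px) else float(value_px) * cal.um_per_px


def um_to_px(value_um, cal: CalibrationProfile):
    """Convert a µm length/coordinate to pixels (inverse of :func:`px_to_um`)."""
    return np.asarray(value_um, dtype=float) / cal.um_per_px if np.ndim(value_um) else float(value_um) / cal.um_per_px


@dataclass
class WellMosaic:
    """Stitched whole-well image with calibration and stitching provenance."""

    raster: np.ndarray  # uint16
    calibration: CalibrationProfile
    well_id: str = "well-0"
    fitted_offsets_px: dict[str, tuple[float, float]] = field(default_factory=dict)


def _neighbor_pairs(tiles: list[Tile]) -> list[tuple[int, int]]:
    index = {(t.row, t.col): i for i, t in enumerate(tiles)}
    pairs = []
    for (r, c), i in index.items():
        for dr, dc in ((0, 1), (1, 0)):
            jj = index.get((r + dr, c + dc))
            if jj is not None:
                pairs.append((i, jj))
    return pairs


def _overlap_strips(a: Tile, b: Tile, margin: int):
    """Extract the nominally shared region from both tiles, grown by margin px."""
    h, w = a.raster.shape
    ax, ay = a.nominal_offset_px
    bx, by = b.nominal_offset_px
    x0, x1 = max(ax, bx), min(ax + w, bx + w)
    y0, y1 = max(ay, by), min(ay + h, by + h)
    if x1 <= x0 or y1 <= y0:
        return None
    x0, y0 = max(x0 - margin, max(ax, bx)), max(y0 - margin, max(ay, by))
    sa = a.raster[y0 - ay : y1 - ay, x0 - ax : x1 - ax]
    sb = b.raster[y0 - by : y1 - by, x0 - bx : x1 - bx]
    return sa, sb


def _estimate_pair_shift(a: Tile, b: Tile, max_shift: float) -> tuple[float, float] | None:
    """Measured displacement correction to b's offset relative to a's, (dx, dy).

    Returns ``None`` when the correlation is unusable (flat strips or a peak
    implying a shift beyond ``max_shift``), in which case the caller falls
    back to the nominal offset for this pair.
    """
    strips = _overlap_strips(a, b, margin=4)
    if strips is None:
        return None
    sa, sb = strips
    if sa.std() == 0 or sb.std() == 0:
        return None
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        shift, error, _ = phase_cross_correlation(
            sa.astype(np.float64), sb.astype(np.float64), upsample_factor=20
        )
    dy, dx = float(shift[0]), float(shift[1])
    if abs(dx) > max_shift or abs(dy) > max_shift:
        return None
    return dx, dy


def _global_offsets(
    tiles: list[Tile],
    measurements: dict[tuple[int, int], tuple[float, float]],
) -> list[tuple[float, float]]:
    """Least-squares reconciliation of pairwise displacements over the grid.

    Unknowns are per-tile offsets; each measured pair (i, j) contributes the
    equation p_j - p_i = d_ij, and the first tile is anchored at its nominal
    offset. x and y are separable and solved independently.
    """
    n = len(tiles)
    rows = []
    rhs_x, rhs_y = [], []
    for (i, j), (dx, dy) in measurements.items():
        nom_dx = tiles[j].nominal_offset_px[0] - tiles[i].nominal_offset_px[0]
        nom_dy = tiles[j].nominal_offset_px[1] - tiles[i].nominal_offset_px[1]
        row = np.zeros(n)
        row[i], row[j] = -1.0, 1.0
        rows.append(row)
        rhs_x.append(nom_dx + dx)
        rhs_y.append(nom_dy + dy)
    anchor = np.zeros(n)
    anchor[0] = 1.0
    rows.append(anchor)
    rhs_x.append(tiles[0].nominal_offset_px[0])
    rhs_y.append(tiles[0].nominal_offset_px[1])
    A = np.vstack(rows)
    ox, *_ = np.linalg.lstsq(A, np.asarray(rhs_x), rcond=None)
    oy, *_ = np.linalg.lstsq(A, np.asarray(rhs_y), rcond=None)
    return [(float(x), float(y)) for x, y in zip(ox, oy)]


def _feather_weights(h: int, w: int) -> np.ndarray:
    # separable linear ramp: weight falls to ~0 at the tile border
    wy = np.minimum(np.arange(h) + 1, h - np.arange(h))
    wx = np.minimum(np.arange(w) + 1, w - np.arange(w))
    return np.outer(wy, wx).astype(np.float64)


def _composite(tiles: list[Tile], offsets_px: list[tuple[int, int]]) -> np.ndarray:
    """Feathered composite on a canvas anchored at offset (0, 0).

    The canvas origin is the grid origin, so mosaic coordinates coincide with
    nominal stage coordinates; any tile content falling at negative offsets
    (stage jitter at the field border) is clipped.
    """
    h, w = tiles[0].raster.shape
    W = max(o[0] for o in offsets_px) + w
    H = max(o[1] for o in offsets_px) + h
    acc = np.zeros((H, W), dtype=np.float64)
    wacc = np.zeros((H, W), dtype=np.float64)
    weights = _feather_weights(h, w)
    for t, (ox, oy) in zip(tiles, offsets_px):
        sx, sy = max(0, -ox), max(0, -oy)
        x0, y0 = ox + sx, oy + sy
        acc[y0 : y0 + h - sy, x0 : x0 + w - sx] += weights[sy:, sx:] * t.raster[sy:, sx:]
        wacc[y0 : y0 + h - sy, x0 : x0 + w - sx] += weights[sy:, sx:]
    out = acc / np.where(wacc > 0, wacc, 1.0)
    uncovered = wacc == 0
    if uncovered.any():
        # stage jitter can leave a few border pixels with no tile content;
        # fill them from the nearest covered pixel instead of leaving black
        from scipy import ndimage

        idx = ndimage.distance_transform_edt(uncovered, return_distances=False,
                                             return_indices=True)
        out = out[tuple(idx)]
    return np.clip(np.rint(out), 0, 65535).astype(np.uint16)


def stitch(tiles: TileSet, refine: bool = True, max_shift_px: float = 5.0) -> WellMosaic:
    """Assemble a tile set into a calibrated whole-well mosaic.

    With ``refine`` the per-tile offsets are estimated from the image content
    (cross-correlation on overlap strips, globally reconciled); otherwise the
    nominal grid offsets are used directly. Compositing places each tile at
    its offset rounded to the nearest pixel and resolves overlaps by linear
    feathering, so refinement on self-consistent (jitter-free) input
    reproduces nominal compositing exactly.
    """
    ts = tiles.tiles
    if not ts:
        raise ValueError("empty tile set")
    shapes = {t.raster.shape for t in ts}
    if len(shapes) != 1:
        raise ValueError(f"inconsistent tile raster sizes: {sorted(shapes)}")

    if refine and len(ts) > 1:
        measurements = {}
        for (i, j) in _neighbor_pairs(ts):
            est = _estimate_pair_shift(ts[i], ts[j], max_shift_px)
            if est is None:
                log.warning(
                    "low-confidence registration for pair %s-%s; using nominal offset",
                    ts[i].tile_id, ts[j].tile_id,
                )
                est = (0.0, 0.0)
            measurements[(i, j)] = est
        fitted = _global_offsets(ts, measurements)
    else:
        fitted = [tuple(map(float, t.nominal_offset_px)) for t in ts]

    int_offsets = [(int(round(x)), int(round(y))) for x, y in fitted]
    raster = _composite(ts, int_offsets)
    return WellMosaic(
        raster=raster,
        calibration=CalibrationProfile(um_per_px=tiles.um_per_px),
        well_id=tiles.well_id,
        fitted_offsets_px={t.tile_id: f for t, f in zip(ts, fitted)},
    )


def save_mosaic(mosaic: WellMosaic, tif_path: str | Path) -> None:
    """Write the mosaic TIFF and a sidecar provenance JSON."""
    tif_path = Path(tif_path)
    tifffile.imwrite(tif_path, mosaic.raster)
    meta = {
        "schema": "spheroquant.mosaic/1",
        "well_id": mosaic.well_id,
        "um_per_px": mosaic.calibration.um_per_px,
        "fitted_offsets_px": {k: list(v) for k, v in mosaic.fitted_offsets_px.items()},
    }
    tif_path.with_suffix(".json").write_text(json.dumps(meta, indent=1))


def load_mosaic(tif_path: str | Path) -> WellMosaic:
    tif_path = Path(tif_path)
    meta = json.loads(tif_path.with_suffix(".json").read_text())
    return WellMosaic(
        raster=tifffile.imread(tif_path),
        calibration=CalibrationProfile(um_per_px=meta["um_per_px"]),
        well_id=meta["well_id"],
        fitted_offsets_px={k: tuple(v) for k, v in meta["fitted_offsets_px"].items()},
    )
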