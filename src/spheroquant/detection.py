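"""Circular-ROI spheroid detection on stitched well mosaics.

The measurement model treats every spheroid as a circle: its fitted radius
drives perimeter, area and volume downstream. Detection proceeds as

1. global foreground/background separation (Otsu threshold; spheroids are
   darker than the well bottom),
2. connected-component labelling,
3. a circularity gate (4πA/P²): sufficiently round components are fitted
   with a single circle, the rest are treated as fused clusters and split
   into overlapping circles seeded from interior distance-transform maxima,
4. a strict minimum-diameter filter (> 50 µm by default) that removes single
   cells and debris aggregates,
5. duplicate suppression by circle-circle overlap, keeping the larger circle.

Single-circle centers and radii are estimated from edge-coverage-weighted
moments: on a brightfield image the one-pixel anti-aliased rim encodes the
subpixel boundary position, so the coverage-weighted area is an unbiased
disk-area estimate and yields subpixel radii.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import ndimage
from skimage.feature import peak_local_max
from skimage.filters import threshold_otsu
from skimage.measure import label as sk_label
from skimage.measure import find_contours, regionprops

from .mosaic import WellMosaic

__all__ = [
    "DetectionParams",
    "SpheroidROI",
    "detect",
    "fit_circle",
    "split_fused",
    "rois_to_frame",
    "write_rois_csv",
    "read_rois_csv",
]


@dataclass
class DetectionParams:
    """Tunable thresholds of the ROI detector (lengths in µm)."""

    min_diameter_um: float = 50.0
    max_diameter_um: float = 700.0
    intensity_threshold_method: str = "otsu"
    min_circularity: float = 0.8
    nms_iou: float = 0.6

    def __post_init__(self) -> None:
        if not 0 < self.min_diameter_um < self.max_diameter_um:
            raise ValueError("need 0 < min_diameter_um < max_diameter_um")
        if not 0 < self.min_circularity <= 1:
            raise ValueError("min_circularity must lie in (0, 1]")


@dataclass
class SpheroidROI:
    """A detected circular region of interest, in physical µm coordinates."""

    roi_id: str
    center_x_um: float
    center_y_um: float
    radius_um: float
    source: str = "single"  # "single" | "split-from-fused"
    well_id: str = "well-0"

    def __post_init__(self) -> None:
        if not (np.isfinite(self.radius_um) and self.radius_um > 0):
            raise ValueError("radius_um must be positive and finite")

    @property
    def diameter_um(self) -> float:
        return 2.0 * self.radius_um


class CollinearPointsError(ValueError):
    """Circle fitting is degenerate: the input points are (near-)collinear."""


def fit_circle(points: np.ndarray) -> tuple[tuple[float, float], float, float]:
    """Fit a circle to boundary points; returns ((cx, cy), radius, rms).

    Exactly three points give the circumscribed circle (exact); more points
    give the algebraic (Kåsa) least-squares circle. The RMS of the radial
    residuals is reported alongside.
    """
    pts = np.asarray(points, dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 2 or len(pts) < 3:
        raise ValueError("need at least 3 (x, y) points")
    x, y = pts[:, 0], pts[:, 1]
    # Kåsa system: 2a·x + 2b·y + c = x² + y²; exact for 3 non-collinear points
    A = np.column_stack([2 * x, 2 * y, np.ones_like(x)])
    b = x**2 + y**2
    # collinearity check: the centered point cloud must span two dimensions
    centered = np.column_stack([x - x.mean(), y - y.mean()])
    sv = np.linalg.svd(centered, compute_uv=False)
    if sv[0] <= 0 or sv[1] / sv[0] < 1e-9:
        raise CollinearPointsError("cannot fit a circle through collinear points")
    sol, *_ = np.linalg.lstsq(A, b, rcond=None)
    a_, b_, c_ = sol
    r2 = c_ + a_**2 + b_**2
    if r2 <= 0:
        raise CollinearPointsError("degenerate circle fit (non-positive radius)")
    r = float(np.sqrt(r2))
    rms = float(np.sqrt(np.mean((np.hypot(x - a_, y - b_) - r) ** 2)))
    return (float(a_), float(b_)), r, rms


def _circle_iou(c1: SpheroidROI, c2: SpheroidROI) -> float:
    d = float(np.hypot(c1.center_x_um - c2.center_x_um, c1.center_y_um - c2.center_y_um))
    r1, r2 = c1.radius_um, c2.radius_um
    if d >= r1 + r2:
        return 0.0
    if d <= abs(r1 - r2):
        inter = np.pi * min(r1, r2) ** 2
    else:
        a1 = r1**2 * np.arccos((d**2 + r1**2 - r2**2) / (2 * d * r1))
        a2 = r2**2 * np.arccos((d**2 + r2**2 - r1**2) / (2 * d * r2))
        tri = 0.5 * np.sqrt(
            max(0.0, (-d + r1 + r2) * (d + r1 - r2) * (d - r1 + r2) * (d + r1 + r2))
        )
        inter = a1 + a2 - tri
    union = np.pi * r1**2 + np.pi * r2**2 - inter
    return float(inter / union)


def split_fused(
    component_mask: np.ndarray,
    params: DetectionParams,
    um_per_px: float,
) -> list[tuple[tuple[float, float], float]]:
    """Split a fused-cluster mask into overlapping circles; px coordinates.

    Seeds are interior maxima of the Euclidean distance transform with a
    minimum separation of half the inclusion diameter; each seed's circle
    starts from the distance-transform value there and is refined by fitting
    to the stretch of component boundary closest (radius-normalised) to that
    seed. Always returns at least one circle.
    """
    mask = np.asarray(component_mask, dtype=bool)
    if not mask.any():
        return []
    edt = ndimage.distance_transform_edt(mask)
    min_sep_px = max(1, int(round((params.min_diameter_um / 2.0) / um_per_px)))
    min_r_px = (params.min_diameter_um / 2.0) / um_per_px
    peaks = peak_local_max(
        edt,
        min_distance=min_sep_px,
        threshold_abs=0.5 * min_r_px,
        exclude_border=False,
        labels=mask,
    )
    if len(peaks) == 0:
        peaks = np.array([np.unravel_index(np.argmax(edt), edt.shape)])

    seeds = [(float(c), float(r)) for r, c in peaks]  # (x, y)
    seed_r = [float(edt[int(y), int(x)]) for x, y in seeds]

    # subpixel component boundary
    padded = np.pad(mask.astype(float), 1)
    contours = find_contours(padded, 0.5)
    if not contours:
        return [((sx, sy), sr) for (sx, sy), sr in zip(seeds, seed_r)]
    boundary = np.vstack(contours) - 1.0  # (row, col) → unpad
    bx, by = boundary[:, 1], boundary[:, 0]

    # assign each boundary point to the seed whose circle it is closest to
    dist = np.stack(
        [np.abs(np.hypot(bx - sx, by - sy) - sr) for (sx, sy), sr in zip(seeds, seed_r)]
    )
    owner = np.argmin(dist, axis=0)

    circles = []
    for k, ((sx, sy), sr) in enumerate(zip(seeds, seed_r)):
        pts = np.column_stack([bx[owner == k], by[owner == k]])
        if len(pts) >= 8:
            try:
                (cx, cy), r, rms = fit_circle(pts)
                # reject wild fits (arc too short / degenerate geometry)
                if rms < 0.25 * r and np.hypot(cx - sx, cy - sy) < max(sr, 1.0):
                    circles.append(((cx, cy), r))
                    continue
            except CollinearPointsError:
                pass
        circles.append(((sx, sy), sr))
    return circles


def _coverage_circle(
    img: np.ndarray, comp_slice, comp_mask: np.ndarray, bg: float, fg: float
) -> tuple[tuple[float, float], float]:
    """Subpixel circle from edge-coverage-weighted moments of one component.

    Each pixel's coverage c = (bg − I)/(bg − fg), clipped to [0, 1], estimates
    the fraction of the pixel covered by the (dark) object, so Σc is the disk
    area and the c-weighted centroid the disk center, both subpixel.
    """
    grown = ndimage.binary_dilation(comp_mask, iterations=2)
    y0, x0 = comp_slice[0].start, comp_slice[1].start
    patch = img[comp_slice].astype(float)
    cov = np.clip((bg - patch) / max(bg - fg, 1e-9), 0.0, 1.0) * grown
    total = cov.sum()
    if total <= 0:
        raise ValueError("empty component")
    yy, xx = np.mgrid[0 : cov.shape[0], 0 : cov.shape[1]]
    cy = float((cov * yy).sum() / total) + y0
    cx = float((cov * xx).sum() / total) + x0
    r = float(np.sqrt(total / np.pi))
    return (cx, cy), r


def detect(mosaic: WellMosaic, params: DetectionParams | None = None) -> list[SpheroidROI]:
    """Detect spheroids as circular ROIs on a calibrated mosaic.

    Returns ROIs sorted by descending radius with ids stable for a fixed
    input. A blank or saturated mosaic yields an empty list (with a warning
    in the saturated case), not an error.
    """
    params = params or DetectionParams()
    img = mosaic.raster
    upp = mosaic.calibration.um_per_px

    if img.size == 0 or np.ptp(img) < 16:  # blank: no contrast to segment
        return []
    thresh = threshold_otsu(img)
    fg = img < thresh
    frac = fg.mean()
    if frac < 1e-6 or frac > 0.9:
        warnings.warn(
            f"mosaic foreground fraction {frac:.3f}: no reliable bimodality; "
            "returning no detections",
            stacklevel=2,
        )
        return []

    # intensity plateaus for coverage weighting
    bg_level = float(np.median(img[~fg]))
    eroded = ndimage.binary_erosion(fg, iterations=2)
    fg_level = float(np.median(img[eroded])) if eroded.any() else float(np.median(img[fg]))

    labels = sk_label(fg, connectivity=2)
    min_r_px = (params.min_diameter_um / 2.0) / upp
    circles: list[tuple[tuple[float, float], float, str]] = []  # ((cx,cy) px, r px, source)

    for prop in regionprops(labels):
        if prop.area < 0.15 * np.pi * min_r_px**2:
            continue  # far below any admissible spheroid
        perim = prop.perimeter_crofton if prop.perimeter_crofton > 0 else prop.perimeter
        circ = 4 * np.pi * prop.area / perim**2 if perim > 0 else 0.0
        comp_mask = labels[prop.slice] == prop.label
        if circ >= params.min_circularity:
            (cx, cy), r = _coverage_circle(img, prop.slice, comp_mask, bg_level, fg_level)
            circles.append(((cx, cy), r, "single"))
        else:
            for (cx, cy), r in split_fused(comp_mask, params, upp):
                circles.append(
                    ((cx + prop.slice[1].start, cy + prop.slice[0].start), r,
                     "split-from-fused")
                )

    rois = [
        SpheroidROI(
            roi_id="",
            center_x_um=cx * upp,
            center_y_um=cy * upp,
            radius_um=r * upp,
            source=src,
            well_id=mosaic.well_id,
        )
        for (cx, cy), r, src in circles
        if 2.0 * r * upp > params.min_diameter_um
    ]

    # duplicate suppression: keep the larger of any overlapping pair
    rois.sort(key=lambda c: (-c.radius_um, c.center_y_um, c.center_x_um))
    kept: list[SpheroidROI] = []
    for c in rois:
        if all(_circle_iou(c, k) <= params.nms_iou for k in kept):
            kept.append(c)
    for i, c in enumerate(kept):
        c.roi_id = f"{mosaic.well_id}-roi{i:04d}"
    return kept


# ---------------------------------------------------------------------------
# tabular I/O

_ROI_COLUMNS = ["well_id", "roi_id", "center_x_um", "center_y_um", "radius_um", "source"]


def rois_to_frame(rois: list[SpheroidROI]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "well_id": r.well_id,
                "roi_id": r.roi_id,
                "center_x_um": r.center_x_um,
                "center_y_um": r.center_y_um,
                "radius_um": r.radius_um,
                "source": r.source,
            }
            for r in rois
        ],
        columns=_ROI_COLUMNS,
    )


def write_rois_csv(rois: list[SpheroidROI], path: str | Path) -> None:
    rois_to_frame(rois).to_csv(path, index=False, float_format="%.6f")


def read_rois_csv(path: str | Path) -> list[SpheroidROI]:
    df = pd.read_csv(path)
    return [
        SpheroidROI(
            roi_id=str(row.roi_id),
            center_x_um=float(row.center_x_um),
            center_y_um=float(row.center_y_um),
            radius_um=float(row.radius_um),
            source=str(row.source),
            well_id=str(row.well_id),
        )
        for row in df.itertuples()
    ]
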