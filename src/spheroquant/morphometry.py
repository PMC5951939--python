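"""Per-spheroid morphometry: perimeter, area, volume, and cell number.

Every measurement derives from the single fitted ROI radius r (µm):
perimeter = 2πr, projected area = πr², and volume = (4/3)πr³, treating the
spheroid as a sphere whose maximal cross-section is the fitted circle. The
cell number estimate divides the spheroid volume by the volume of one cell
assumed spherical — i.e. it assumes cells pack with no void space. A strict
minimum-diameter filter (> 50 µm by default) excludes single cells and small
debris aggregates from analysis.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .detection import SpheroidROI
from .viability import AtpCurve

__all__ = [
    "CellModel",
    "SpheroidMeasurement",
    "measure",
    "measure_all",
    "filter_by_diameter",
    "estimate_cell_number",
    "cells_from_atp",
    "measurements_to_frame",
    "write_measurements_csv",
]

DEFAULT_MIN_DIAMETER_UM = 50.0


@dataclass(frozen=True)
class CellModel:
    """A single cell approximated as a sphere of the measured diameter."""

    cell_diameter_um: float

    def __post_init__(self) -> None:
        if not (np.isfinite(self.cell_diameter_um) and self.cell_diameter_um > 0):
            raise ValueError("cell_diameter_um must be positive and finite")

    @property
    def cell_volume_um3(self) -> float:
        return (4.0 / 3.0) * math.pi * (self.cell_diameter_um / 2.0) ** 3


@dataclass
class SpheroidMeasurement:
    roi_id: str
    well_id: str
    arm: str
    diameter_um: float
    perimeter_um: float
    area_um2: float
    volume_um3: float
    cell_count: float | None  # real-valued; None when no cell model given
    passes_filter: bool

    @property
    def cell_count_rounded(self) -> int | None:
        """Cell count rounded half-up, for display."""
        if self.cell_count is None:
            return None
        return int(math.floor(self.cell_count + 0.5))


def measure(
    roi: SpheroidROI,
    cells: CellModel | None = None,
    min_diameter_um: float = DEFAULT_MIN_DIAMETER_UM,
    arm: str = "",
) -> SpheroidMeasurement:
    """Closed-form circle/sphere measurements for one fitted ROI."""
    r = roi.radius_um
    if not (np.isfinite(r) and r > 0):
        raise ValueError(f"non-finite or non-positive radius: {r}")
    d = 2.0 * r
    volume = (4.0 / 3.0) * math.pi * r**3
    return SpheroidMeasurement(
        roi_id=roi.roi_id,
        well_id=roi.well_id,
        arm=arm,
        diameter_um=d,
        perimeter_um=math.pi * d,
        area_um2=math.pi * r**2,
        volume_um3=volume,
        cell_count=estimate_cell_number(volume, cells) if cells else None,
        passes_filter=d > min_diameter_um,
    )


def measure_all(
    rois: list[SpheroidROI],
    cells: CellModel | None = None,
    min_diameter_um: float = DEFAULT_MIN_DIAMETER_UM,
    arm: str = "",
) -> list[SpheroidMeasurement]:
    return [measure(r, cells, min_diameter_um, arm) for r in rois]


def filter_by_diameter(
    measurements: list[SpheroidMeasurement],
    min_diameter_um: float = DEFAULT_MIN_DIAMETER_UM,
) -> list[SpheroidMeasurement]:
    """Retain measurements with diameter strictly greater than the threshold.

    The inequality is strict: a spheroid of exactly the threshold diameter is
    excluded. Input order is preserved.
    """
    if min_diameter_um < 0:
        raise ValueError("min_diameter_um must be nonnegative")
    return [m for m in measurements if m.diameter_um > min_diameter_um]


def estimate_cell_number(volume_um3: float, cells: CellModel) -> float:
    """Cells per spheroid as the ratio of spheroid to single-cell volume."""
    if volume_um3 < 0:
        raise ValueError("volume_um3 must be nonnegative")
    if cells.cell_volume_um3 <= 0:
        raise ValueError("cell volume must be positive")
    return volume_um3 / cells.cell_volume_um3


def cells_from_atp(rlu: float, curve: AtpCurve) -> float:
    """Invert an ATP-vs-cell-number calibration to a cell count.

    The curve must be fitted in ``vs_cellnumber`` mode; the fitted intercept
    plays the role of the blank. Readings below the blank return 0 with a
    warning rather than a negative count.
    """
    if curve.mode != "vs_cellnumber":
        raise ValueError("cells_from_atp needs a curve fitted vs cell number")
    n = (rlu - curve.intercept_rlu) / curve.slope
    if n < 0:
        warnings.warn(f"RLU {rlu:.3g} below fitted blank; reporting 0 cells", stacklevel=2)
        return 0.0
    return float(n)


# ---------------------------------------------------------------------------
# tabular I/O

_MEAS_COLUMNS = [
    "well_id", "arm", "roi_id", "diameter_um", "perimeter_um",
    "area_um2", "volume_um3", "cell_count", "passes_filter",
]


def measurements_to_frame(measurements: list[SpheroidMeasurement]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "well_id": m.well_id,
                "arm": m.arm,
                "roi_id": m.roi_id,
                "diameter_um": m.diameter_um,
                "perimeter_um": m.perimeter_um,
                "area_um2": m.area_um2,
                "volume_um3": m.volume_um3,
                "cell_count": np.nan if m.cell_count is None else m.cell_count,
                "passes_filter": m.passes_filter,
            }
            for m in measurements
        ],
        columns=_MEAS_COLUMNS,
    )


def write_measurements_csv(measurements: list[SpheroidMeasurement], path: str | Path) -> None:
    measurements_to_frame(measurements).to_csv(path, index=False, float_format="%.6f")
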