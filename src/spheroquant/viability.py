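"""Plate-reader viability layer: ATP standard curves and crystal-violet OD.

ATP luminescence (RLU) is linear both in ATP concentration and — because
cellular ATP content is roughly constant per viable cell — in cell number;
a standard curve fitted in either mode converts raw RLU to µM ATP or to a
cell count. Crystal violet stains the DNA of adherent living cells, so the
optical density at 595 nm is proportional to the number of viable cells and
gives a viability fraction as the ratio of treated to control mean OD.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats as sps

from .synthetic import AssayReadout

__all__ = [
    "AtpCurve",
    "CalibrationError",
    "fit_atp_curve",
    "rlu_to_atp",
    "atp_to_rlu",
    "crystal_violet_summary",
    "read_readouts_csv",
    "write_readouts_csv",
]

MODE_CONCENTRATION = "vs_concentration"
MODE_CELLNUMBER = "vs_cellnumber"


class CalibrationError(ValueError):
    """A standard curve could not be fitted (degenerate design or bad slope)."""


@dataclass(frozen=True)
class AtpCurve:
    """Fitted linear standard curve RLU = slope·level + intercept.

    ``slope`` is RLU per µM ATP in ``vs_concentration`` mode and RLU per cell
    in ``vs_cellnumber`` mode; the fitted intercept is the blank signal.
    """

    slope: float
    intercept_rlu: float
    r_squared: float
    mode: str = MODE_CONCENTRATION

    def __post_init__(self) -> None:
        if self.mode not in (MODE_CONCENTRATION, MODE_CELLNUMBER):
            raise ValueError(f"unknown calibration mode: {self.mode}")
        if self.slope <= 0:
            raise CalibrationError("calibration failure: non-positive slope")
        if not 0.0 <= self.r_squared <= 1.0 + 1e-12:
            raise ValueError("r_squared must lie in [0, 1]")

    @property
    def slope_rlu_per_um(self) -> float:
        if self.mode != MODE_CONCENTRATION:
            raise ValueError("curve was not fitted against concentration")
        return self.slope

    @property
    def slope_rlu_per_cell(self) -> float:
        if self.mode != MODE_CELLNUMBER:
            raise ValueError("curve was not fitted against cell number")
        return self.slope

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps({
            "schema": "spheroquant.atp_curve/1",
            "slope": self.slope,
            "intercept_rlu": self.intercept_rlu,
            "r_squared": self.r_squared,
            "mode": self.mode,
        }, indent=1))

    @classmethod
    def from_json(cls, path: str | Path) -> "AtpCurve":
        d = json.loads(Path(path).read_text())
        return cls(slope=d["slope"], intercept_rlu=d["intercept_rlu"],
                   r_squared=d["r_squared"], mode=d["mode"])


def fit_atp_curve(
    standards: list[tuple[float, float]] | np.ndarray,
    mode: str = MODE_CONCENTRATION,
) -> AtpCurve:
    """Ordinary least-squares line through (known level, RLU) standards.

    Needs at least two distinct levels; the intercept is free (not forced
    through the origin) and doubles as the blank. A non-positive fitted
    slope is rejected as a calibration failure.
    """
    arr = np.asarray(standards, dtype=float)
    if arr.ndim != 2 or arr.shape[1] != 2 or len(arr) < 2:
        raise CalibrationError("need at least 2 (level, RLU) standards")
    levels, rlu = arr[:, 0], arr[:, 1]
    if np.unique(levels).size < 2:
        raise CalibrationError("degenerate design: all standards at one level")
    res = sps.linregress(levels, rlu)
    if res.slope <= 0:
        raise CalibrationError(
            f"calibration failure: fitted slope {res.slope:.4g} is not positive"
        )
    return AtpCurve(
        slope=float(res.slope),
        intercept_rlu=float(res.intercept),
        r_squared=float(min(res.rvalue**2, 1.0)),
        mode=mode,
    )


def rlu_to_atp(rlu: float, curve: AtpCurve) -> float:
    """Convert a raw RLU reading to µM ATP via the standard curve (floored at 0)."""
    if curve.mode != MODE_CONCENTRATION:
        raise ValueError("rlu_to_atp needs a curve fitted vs concentration")
    return max(0.0, (float(rlu) - curve.intercept_rlu) / curve.slope)


def atp_to_rlu(atp_um: float, curve: AtpCurve) -> float:
    """Forward evaluation of the standard curve (inverse of :func:`rlu_to_atp`)."""
    if curve.mode != MODE_CONCENTRATION:
        raise ValueError("atp_to_rlu needs a curve fitted vs concentration")
    return curve.intercept_rlu + curve.slope * float(atp_um)


def crystal_violet_summary(
    readouts: list[AssayReadout],
    arms: tuple[str, str],
):
    """Two-arm crystal-violet comparison; returns a GroupComparison.

    ``arms`` is (control, treated). OD595 replicates are grouped per arm and
    compared with the unpaired two-sided t test; the fractional viability —
    mean(treated) / mean(control) — is the comparison's fold change. At least
    two replicates per arm are required.
    """
    from .stats_report import compare  # local import to avoid a cycle

    control, treated = arms
    vals: dict[str, list[float]] = {control: [], treated: []}
    for r in readouts:
        if r.readout_type == "OD595" and r.arm in vals:
            vals[r.arm].append(r.value)
    for arm_label, v in vals.items():
        if len(v) < 2:
            raise ValueError(
                f"need >= 2 OD595 replicates for arm {arm_label!r}, got {len(v)}"
            )
    return compare(
        np.asarray(vals[control]), np.asarray(vals[treated]),
        arm_a=control, arm_b=treated, variable="OD595",
    )


# ---------------------------------------------------------------------------
# tabular I/O

def write_readouts_csv(readouts: list[AssayReadout], path: str | Path) -> None:
    pd.DataFrame(
        [
            {"well_id": r.well_id, "arm": r.arm,
             "readout_type": r.readout_type, "value": r.value}
            for r in readouts
        ],
        columns=["well_id", "arm", "readout_type", "value"],
    ).to_csv(path, index=False, float_format="%.6f")


def read_readouts_csv(path: str | Path) -> list[AssayReadout]:
    df = pd.read_csv(path)
    return [
        AssayReadout(str(r.well_id), str(r.arm), str(r.readout_type), float(r.value))
        for r in df.itertuples()
    ]
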