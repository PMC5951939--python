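"""End-to-end convenience drivers: simulate → stitch → detect → measure.

These wrappers exist so that multi-arm experiments can be run with one call
each in scripts and tests; every step is the corresponding public module
function and nothing here adds behaviour of its own.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

from .detection import DetectionParams, SpheroidROI, detect
from .morphometry import CellModel, SpheroidMeasurement, filter_by_diameter, measure_all
from .mosaic import WellMosaic, stitch
from .synthetic import (
    GroundTruth,
    SimConfig,
    TileSet,
    TreatmentEffect,
    generate_ground_truth,
    render_tiles,
)

__all__ = ["WellResult", "analyze_well", "simulate_experiment"]


@dataclass
class WellResult:
    """Everything produced for one simulated, fully analysed well."""

    truth: GroundTruth
    tiles: TileSet
    mosaic: WellMosaic
    rois: list[SpheroidROI]
    measurements: list[SpheroidMeasurement]


def analyze_well(
    config: SimConfig,
    effect: TreatmentEffect | None = None,
    params: DetectionParams | None = None,
    cells: CellModel | None = None,
    refine: bool = True,
) -> WellResult:
    """Simulate one well and run the full imaging analysis on it."""
    params = params or DetectionParams()
    truth = generate_ground_truth(config, effect)
    tiles = render_tiles(truth, config)
    mosaic = stitch(tiles, refine=refine)
    rois = detect(mosaic, params)
    arm = effect.arm if effect else "CTR"
    meas = measure_all(rois, cells=cells, min_diameter_um=params.min_diameter_um, arm=arm)
    meas = filter_by_diameter(meas, params.min_diameter_um)
    return WellResult(truth=truth, tiles=tiles, mosaic=mosaic, rois=rois, measurements=meas)


def simulate_experiment(
    config: SimConfig,
    effects: list[TreatmentEffect],
    params: DetectionParams | None = None,
    cells: CellModel | None = None,
    imaging: bool = True,
) -> dict[str, WellResult | GroundTruth]:
    """Run all treatment arms of one experiment from a shared base population.

    Arms share the configuration seed, so they start from the same untreated
    spheroid draw (replicate wells seeded from one suspension) and differ
    only by their applied treatment. With ``imaging=False`` only the ground
    truths are generated (the fast path for effect-recovery studies).
    """
    out: dict[str, WellResult | GroundTruth] = {}
    for effect in effects:
        cfg = replace(config, well_id=f"{config.well_id}-{effect.arm}")
        if imaging:
            out[effect.arm] = analyze_well(cfg, effect, params=params, cells=cells)
        else:
            out[effect.arm] = generate_ground_truth(cfg, effect)
    return out
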