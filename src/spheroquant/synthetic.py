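"""Synthetic well-image generator for 3D spheroid cultures.

Produces the three artefacts the analysis pipeline consumes, together with
the ground truth needed to verify every downstream stage:

* :func:`generate_ground_truth` — per-object records (circles, class labels,
  treatment arm, viability flags) for one culture well;
* :func:`render_tiles` — a set of partly overlapping 16-bit grayscale tiles
  emulating a motorized-stage brightfield scan of the well;
* :func:`generate_assay_readouts` — matched plate-reader values (ATP
  luminescence in RLU, crystal-violet OD at 595 nm) proportional to the
  viable cell number implied by the ground truth.

Spheroids are modelled as dark disks on a brighter well bottom; diameters are
drawn from a truncated log-normal distribution (median 250 µm, log-sd 0.35,
support [50, 600] µm by default, matching day-6 cultures with heterogeneous
day-7 growth). Treatment arms act on a shared base draw: the same
configuration seed yields the same untreated spheroid population, to which an
arm's volume fold and kill fraction are then applied. This mirrors treating
replicate wells seeded from one cell suspension and makes paired
treated/control contrasts exact at the ground-truth level.
"""

from __future__ import annotations

import json
import warnings
import zlib
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np
import tifffile

__all__ = [
    "SimConfig",
    "TreatmentEffect",
    "SimObject",
    "GroundTruth",
    "Tile",
    "TileSet",
    "AssayReadout",
    "generate_ground_truth",
    "render_tiles",
    "generate_assay_readouts",
    "save_tiles",
    "load_tiles",
]

U16_MAX = 65535

#: object classes used in ground-truth records
CLASS_SPHEROID = "spheroid"
CLASS_DEBRIS = "debris"
CLASS_SINGLE_CELL = "single_cell"


class PlacementError(RuntimeError):
    """Raised when rejection sampling cannot place all objects in the field."""


def _arm_stream(seed: int, arm: str, salt: int = 0) -> np.random.Generator:
    # stable across sessions: CRC32 of the arm label, not Python's hash()
    return np.random.default_rng([seed & 0x7FFFFFFF, zlib.crc32(arm.encode()), salt])


@dataclass
class SimConfig:
    """Physical and optical parameters of one simulated culture well.

    Lengths are in µm; intensity levels are fractions of the 16-bit range.
    """

    well_width_um: float = 7000.0
    well_height_um: float = 6200.0
    um_per_px: float = 2.0
    n_spheroids: int = 150
    diameter_median_um: float = 250.0
    diameter_sigma_log: float = 0.35
    diameter_min_um: float = 50.0
    diameter_max_um: float = 600.0
    fused_fraction: float = 0.0
    debris_count: int = 0
    roughness: float = 0.0
    dark_core: bool = False
    dark_core_level: float = 0.6  # core intensity relative to the spheroid body
    tile_rows: int = 7
    tile_cols: int = 7
    overlap_frac: float = 0.25
    noise_sd: float = 300.0  # additive Gaussian noise, 16-bit DN
    jitter_px: int = 2
    background_level: float = 0.60
    spheroid_level: float = 0.25
    cell_diameter_um: float = 15.0
    well_id: str = "well-0"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.um_per_px <= 0 or not np.isfinite(self.um_per_px):
            raise ValueError("um_per_px must be positive and finite")
        if self.diameter_max_um <= 50.0:
            raise ValueError(
                "diameter distribution must admit support above 50 µm "
                f"(diameter_max_um={self.diameter_max_um})"
            )
        if not 0.0 <= self.fused_fraction <= 1.0:
            raise ValueError("fused_fraction must lie in [0, 1]")
        if not 0.0 <= self.roughness <= 0.2:
            raise ValueError("roughness must lie in [0, 0.2]")
        if not 0.15 <= self.overlap_frac <= 0.35:
            warnings.warn(
                f"overlap_frac={self.overlap_frac} outside the usual 15-35% range",
                stacklevel=2,
            )
        if self.cell_diameter_um <= 0:
            raise ValueError("cell_diameter_um must be positive")

    @property
    def width_px(self) -> int:
        return int(round(self.well_width_um / self.um_per_px))

    @property
    def height_px(self) -> int:
        return int(round(self.well_height_um / self.um_per_px))


@dataclass
class TreatmentEffect:
    """Multiplicative treatment model for one arm.

    ``volume_fold`` rescales every spheroid volume (radius scales by its cube
    root); ``kill_fraction`` marks that fraction of spheroids dead, to be
    rendered as scattered sub-threshold fragments rather than intact bodies.
    """

    arm: str = "CTR"
    volume_fold: float = 1.0
    kill_fraction: float = 0.0

    def __post_init__(self) -> None:
        if self.volume_fold <= 0:
            raise ValueError("volume_fold must be > 0")
        if not 0.0 <= self.kill_fraction <= 1.0:
            raise ValueError("kill_fraction must lie in [0, 1]")


@dataclass
class SimObject:
    object_id: int
    klass: str
    center_x_um: float
    center_y_um: float
    radius_um: float
    arm: str
    alive: bool = True
    fused_with: int | None = None  # partner object_id for fused pairs


@dataclass
class GroundTruth:
    """True object annotations for one well plus the config that made them."""

    objects: list[SimObject]
    config: SimConfig
    effect: TreatmentEffect

    def spheroids(self, alive_only: bool = False) -> list[SimObject]:
        out = [o for o in self.objects if o.klass == CLASS_SPHEROID]
        if alive_only:
            out = [o for o in out if o.alive]
        return out

    def to_json(self, path: str | Path) -> None:
        payload = {
            "schema": "spheroquant.ground_truth/1",
            "config": asdict(self.config),
            "effect": asdict(self.effect),
            "objects": [asdict(o) for o in self.objects],
        }
        Path(path).write_text(json.dumps(payload, indent=1))

    @classmethod
    def from_json(cls, path: str | Path) -> "GroundTruth":
        payload = json.loads(Path(path).read_text())
        return cls(
            objects=[SimObject(**o) for o in payload["objects"]],
            config=SimConfig(**payload["config"]),
            effect=TreatmentEffect(**payload["effect"]),
        )


@dataclass
class Tile:
    tile_id: str
    row: int
    col: int
    raster: np.ndarray  # uint16, shape (h, w)
    nominal_offset_px: tuple[int, int]  # (x, y) in mosaic coordinates
    true_offset_px: tuple[int, int] | None = None  # simulator oracle only


@dataclass
class TileSet:
    tiles: list[Tile]
    overlap_frac: float
    um_per_px: float
    well_id: str = "well-0"

    def grid_shape(self) -> tuple[int, int]:
        rows = 1 + max(t.row for t in self.tiles)
        cols = 1 + max(t.col for t in self.tiles)
        return rows, cols


@dataclass
class AssayReadout:
    well_id: str
    arm: str
    readout_type: str  # "RLU" or "OD595"
    value: float

    def __post_init__(self) -> None:
        if self.value < 0:
            raise ValueError("readout value must be nonnegative")


# ---------------------------------------------------------------------------
# ground truth


def _draw_diameters(cfg: SimConfig, rng: np.random.Generator, n: int) -> np.ndarray:
    """Truncated log-normal diameters via rejection; support [min, max] µm."""
    mu = np.log(cfg.diameter_median_um)
    out = np.empty(n)
    filled = 0
    while filled < n:
        cand = np.exp(rng.normal(mu, cfg.diameter_sigma_log, size=2 * (n - filled) + 8))
        cand = cand[(cand >= cfg.diameter_min_um) & (cand <= cfg.diameter_max_um)]
        take = min(cand.size, n - filled)
        out[filled : filled + take] = cand[:take]
        filled += take
    return out


def _no_overlap(x, y, r, placed, margin_um: float = 2.0) -> bool:
    for (px, py, pr) in placed:
        if (x - px) ** 2 + (y - py) ** 2 < (r + pr + margin_um) ** 2:
            return False
    return True


def generate_ground_truth(
    config: SimConfig, effect: TreatmentEffect | None = None, max_tries: int = 5000
) -> GroundTruth:
    """Draw and place all objects of one well under a treatment arm.

    The base diameter draw and placement stream depend only on ``config``
    (including its seed), so two arms generated from the same config are
    paired: identical untreated populations, differing only by the applied
    ``effect``. Non-fused spheroids are placed by rejection sampling with no
    mutual overlap; fused pairs share a boundary overlap of 10–40% of the
    smaller radius. Dead spheroids (per ``kill_fraction``, chosen by an
    arm-specific stream) keep their record but are flagged ``alive=False``.
    """
    effect = effect or TreatmentEffect()
    draw_rng = np.random.default_rng([config.seed & 0x7FFFFFFF, 101])
    place_rng = np.random.default_rng([config.seed & 0x7FFFFFFF, 202])

    n = config.n_spheroids
    diameters = _draw_diameters(config, draw_rng, n) if n else np.empty(0)
    radii = (diameters / 2.0) * effect.volume_fold ** (1.0 / 3.0)

    n_fused_pairs = int(np.floor(config.fused_fraction * n / 2.0))
    n_paired = 2 * n_fused_pairs

    objects: list[SimObject] = []
    placed: list[tuple[float, float, float]] = []
    W, H = config.well_width_um, config.well_height_um

    def _place_one(r: float) -> tuple[float, float]:
        for _ in range(max_tries):
            x = place_rng.uniform(r, W - r)
            y = place_rng.uniform(r, H - r)
            if _no_overlap(x, y, r, placed):
                return x, y
        raise PlacementError(
            f"could not place object of radius {r:.1f} µm after {max_tries} tries; "
            f"field {W:.0f}×{H:.0f} µm too crowded for n={n} spheroids"
        )

    oid = 0
    # fused pairs first (they need the most room)
    for k in range(n_fused_pairs):
        r1, r2 = radii[2 * k], radii[2 * k + 1]
        depth = place_rng.uniform(0.1, 0.4) * min(r1, r2)
        d = r1 + r2 - depth
        for _ in range(max_tries):
            x1 = place_rng.uniform(r1, W - r1)
            y1 = place_rng.uniform(r1, H - r1)
            theta = place_rng.uniform(0, 2 * np.pi)
            x2, y2 = x1 + d * np.cos(theta), y1 + d * np.sin(theta)
            if not (r2 <= x2 <= W - r2 and r2 <= y2 <= H - r2):
                continue
            if _no_overlap(x1, y1, r1, placed) and _no_overlap(x2, y2, r2, placed):
                break
        else:
            raise PlacementError(
                f"could not place fused pair (radii {r1:.0f}/{r2:.0f} µm); field too crowded"
            )
        objects.append(SimObject(oid, CLASS_SPHEROID, x1, y1, r1, effect.arm, fused_with=oid + 1))
        objects.append(SimObject(oid + 1, CLASS_SPHEROID, x2, y2, r2, effect.arm, fused_with=oid))
        placed += [(x1, y1, r1), (x2, y2, r2)]
        oid += 2

    for k in range(n_paired, n):
        r = radii[k]
        x, y = _place_one(r)
        objects.append(SimObject(oid, CLASS_SPHEROID, x, y, r, effect.arm))
        placed.append((x, y, r))
        oid += 1

    # sub-threshold nuisance objects: debris aggregates and single cells
    for _ in range(config.debris_count):
        if place_rng.uniform() < 0.5:
            klass, dia = CLASS_SINGLE_CELL, place_rng.uniform(
                0.8 * config.cell_diameter_um, 1.2 * config.cell_diameter_um
            )
        else:
            klass, dia = CLASS_DEBRIS, place_rng.uniform(20.0, 45.0)
        dia = min(dia, 45.0)
        r = dia / 2.0
        x, y = _place_one(r)
        objects.append(SimObject(oid, klass, x, y, r, effect.arm))
        placed.append((x, y, r))
        oid += 1

    if effect.kill_fraction > 0 and n:
        kill_rng = _arm_stream(config.seed, effect.arm, salt=303)
        sph_idx = [i for i, o in enumerate(objects) if o.klass == CLASS_SPHEROID]
        n_kill = int(round(effect.kill_fraction * len(sph_idx)))
        for i in kill_rng.choice(sph_idx, size=n_kill, replace=False):
            objects[i].alive = False

    return GroundTruth(objects=objects, config=config, effect=effect)


# ---------------------------------------------------------------------------
# rendering


def _tile_geometry(cfg: SimConfig) -> tuple[int, int, list[tuple[int, int, int, int]]]:
    """Return (tile_w, tile_h, [(row, col, off_x, off_y), ...]) in px.

    Nominal offsets form a row-major grid whose strides realise the requested
    overlap fraction; the last row/column is clamped so the grid covers the
    full field.
    """
    W, H = cfg.width_px, cfg.height_px
    rows, cols = cfg.tile_rows, cfg.tile_cols
    f = cfg.overlap_frac

    def _span(total: int, k: int) -> tuple[int, int]:
        if k == 1:
            return total, 0
        w = int(np.ceil(total / (1 + (k - 1) * (1 - f))))
        stride = int(np.ceil((total - w) / (k - 1)))
        return w, stride

    tile_w, stride_x = _span(W, cols)
    tile_h, stride_y = _span(H, rows)
    offsets = []
    for r in range(rows):
        for c in range(cols):
            ox = min(c * stride_x, W - tile_w)
            oy = min(r * stride_y, H - tile_h)
            offsets.append((r, c, ox, oy))
    last = offsets[-1]
    if last[2] + tile_w < W or last[3] + tile_h < H:
        raise ValueError("tile grid does not cover the field")
    return tile_w, tile_h, offsets


def render_field(truth: GroundTruth, config: SimConfig | None = None) -> np.ndarray:
    """Render the whole-well field (no tiling, no noise) as float64 DN.

    Objects are dark disks on a brighter background, composited with an
    anti-aliased (coverage-weighted) edge one pixel wide. Surface roughness
    perturbs the rendered boundary radially (annotations keep the nominal
    circle); an optional darker core disk at half radius emulates crypt-like
    morphology. Dead spheroids are rendered as scattered sub-threshold
    fragments.
    """
    cfg = config or truth.config
    H, W = cfg.height_px, cfg.width_px
    bg = cfg.background_level * U16_MAX
    fg = cfg.spheroid_level * U16_MAX
    img = np.full((H, W), bg, dtype=np.float64)

    frag_rng = np.random.default_rng([cfg.seed & 0x7FFFFFFF, 404])
    rough_rng = np.random.default_rng([cfg.seed & 0x7FFFFFFF, 505])

    def _paint_disk(cx_um, cy_um, r_um, level, rough_amp=0.0):
        cx, cy = cx_um / cfg.um_per_px, cy_um / cfg.um_per_px
        r = r_um / cfg.um_per_px
        pad = int(np.ceil(r * (1 + rough_amp))) + 3
        x0, x1 = max(0, int(cx) - pad), min(W, int(cx) + pad + 1)
        y0, y1 = max(0, int(cy) - pad), min(H, int(cy) + pad + 1)
        if x0 >= x1 or y0 >= y1:
            return
        yy, xx = np.mgrid[y0:y1, x0:x1]
        dx, dy = xx - cx, yy - cy
        dist = np.hypot(dx, dy)
        if rough_amp > 0:
            k = rough_rng.integers(5, 10)
            phi = rough_rng.uniform(0, 2 * np.pi)
            r_eff = r * (1.0 + rough_amp * np.sin(k * np.arctan2(dy, dx) + phi))
        else:
            r_eff = r
        cov = np.clip(r_eff - dist + 0.5, 0.0, 1.0)
        patch = img[y0:y1, x0:x1]
        np.minimum(patch, bg + cov * (level - bg), out=patch)

    for obj in truth.objects:
        if obj.klass == CLASS_SPHEROID and not obj.alive:
            # degraded body: a handful of small fragments inside the old radius
            n_frag = int(frag_rng.integers(4, 9))
            for _ in range(n_frag):
                rho = frag_rng.uniform(0, 0.8 * obj.radius_um)
                ang = frag_rng.uniform(0, 2 * np.pi)
                fr = frag_rng.uniform(5.0, 15.0)
                _paint_disk(
                    obj.center_x_um + rho * np.cos(ang),
                    obj.center_y_um + rho * np.sin(ang),
                    fr,
                    fg,
                )
            continue
        rough = cfg.roughness if obj.klass == CLASS_SPHEROID else 0.0
        _paint_disk(obj.center_x_um, obj.center_y_um, obj.radius_um, fg, rough)
        if cfg.dark_core and obj.klass == CLASS_SPHEROID:
            _paint_disk(
                obj.center_x_um, obj.center_y_um, obj.radius_um / 2.0,
                fg * cfg.dark_core_level,
            )
    return img


def render_tiles(truth: GroundTruth, config: SimConfig | None = None) -> TileSet:
    """Render the well and cut it into a row-major grid of overlapping tiles.

    Noise is applied to the field before cutting, so the duplicated content
    of overlap strips is pixel-identical across neighbouring tiles (as it is
    for a physical scene scanned twice under the same illumination). Each
    tile's true offset is its nominal grid offset plus an integer jitter of
    at most ``jitter_px``, emulating small motorized-stage error; the jitter
    is recorded in ``true_offset_px`` for oracle use only.
    """
    cfg = config or truth.config
    field = render_field(truth, cfg)
    noise_rng = np.random.default_rng([cfg.seed & 0x7FFFFFFF, 606])
    jit_rng = np.random.default_rng([cfg.seed & 0x7FFFFFFF, 707])
    if cfg.noise_sd > 0:
        field = field + noise_rng.normal(0.0, cfg.noise_sd, size=field.shape)
    field = np.clip(np.rint(field), 0, U16_MAX).astype(np.uint16)

    tile_w, tile_h, offsets = _tile_geometry(cfg)
    j = cfg.jitter_px
    pad = np.pad(field, j, mode="edge") if j else field

    tiles: list[Tile] = []
    for (r, c, ox, oy) in offsets:
        # first tile anchors the stage coordinate frame: no jitter there
        anchored = (r, c) == (0, 0)
        jx = int(jit_rng.integers(-j, j + 1)) if j and not anchored else 0
        jy = int(jit_rng.integers(-j, j + 1)) if j and not anchored else 0
        tx, ty = ox + jx, oy + jy
        raster = pad[ty + j : ty + j + tile_h, tx + j : tx + j + tile_w].copy()
        tiles.append(
            Tile(
                tile_id=f"{r}_{c}",
                row=r,
                col=c,
                raster=raster,
                nominal_offset_px=(ox, oy),
                true_offset_px=(tx, ty),
            )
        )
    return TileSet(tiles=tiles, overlap_frac=cfg.overlap_frac,
                   um_per_px=cfg.um_per_px, well_id=cfg.well_id)


# ---------------------------------------------------------------------------
# plate-reader readouts


def true_cell_count(truth: GroundTruth, alive_only: bool = True) -> float:
    """Viable cell number implied by the truth: Σ spheroid volume / cell volume."""
    cfg = truth.config
    cell_vol = (4.0 / 3.0) * np.pi * (cfg.cell_diameter_um / 2.0) ** 3
    vols = [
        (4.0 / 3.0) * np.pi * o.radius_um ** 3
        for o in truth.spheroids(alive_only=alive_only)
    ]
    return float(np.sum(vols) / cell_vol) if vols else 0.0


def generate_assay_readouts(
    truth: GroundTruth,
    atp_amol_per_cell: float = 10_000.0,
    rlu_per_um_atp: float = 1_000.0,
    od_per_cell: float = 1e-6,
    noise_cv: float = 0.0,
    well_volume_ul: float = 200.0,
    blank_rlu: float = 50.0,
    blank_od: float = 0.04,
    effector_cells: float = 0.0,
    effector_atp_amol_per_cell: float | None = None,
) -> list[AssayReadout]:
    """Simulate ATP-luminescence (RLU) and crystal-violet (OD595) readouts.

    Both readouts are linear in the viable tumor-cell number implied by the
    ground truth (total spheroid volume over single-cell volume), with
    multiplicative Gaussian noise of coefficient of variation ``noise_cv``.
    Effector lymphocytes added to a co-culture contribute their own ATP to
    the luminescence signal but, being non-adherent, nothing to the
    crystal-violet OD — the documented confound of ATP-based viability in
    co-cultures.
    """
    for name, v in [
        ("atp_amol_per_cell", atp_amol_per_cell),
        ("rlu_per_um_atp", rlu_per_um_atp),
        ("od_per_cell", od_per_cell),
        ("well_volume_ul", well_volume_ul),
    ]:
        if v <= 0:
            raise ValueError(f"{name} must be positive")
    if noise_cv < 0:
        raise ValueError("noise_cv must be nonnegative")

    n_cells = true_cell_count(truth, alive_only=True)
    eff_atp = effector_atp_amol_per_cell if effector_atp_amol_per_cell is not None else atp_amol_per_cell

    # amol → µM in the well: amol * 1e-18 mol / (µl * 1e-6 L) * 1e6 µM/M
    atp_um = (n_cells * atp_amol_per_cell + effector_cells * eff_atp) * 1e-18 / (
        well_volume_ul * 1e-6
    ) * 1e6
    rlu = blank_rlu + rlu_per_um_atp * atp_um
    od = blank_od + od_per_cell * n_cells

    if noise_cv > 0:
        # replicate wells of one arm must draw distinct noise: key on well_id too
        rng = np.random.default_rng(
            [truth.config.seed & 0x7FFFFFFF,
             zlib.crc32(truth.effect.arm.encode()),
             zlib.crc32(truth.config.well_id.encode()), 808]
        )
        rlu *= max(0.0, 1.0 + noise_cv * rng.standard_normal())
        od *= max(0.0, 1.0 + noise_cv * rng.standard_normal())

    wid, arm = truth.config.well_id, truth.effect.arm
    return [
        AssayReadout(wid, arm, "RLU", float(rlu)),
        AssayReadout(wid, arm, "OD595", float(od)),
    ]


# ---------------------------------------------------------------------------
# disk I/O


def save_tiles(tileset: TileSet, out_dir: str | Path) -> None:
    """Write one 16-bit TIFF per tile plus a layout JSON (schema versioned)."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    layout = {
        "schema": "spheroquant.tile_layout/1",
        "well_id": tileset.well_id,
        "overlap_frac": tileset.overlap_frac,
        "um_per_px": tileset.um_per_px,
        "tiles": [],
    }
    for t in tileset.tiles:
        fname = f"tile_{t.row}_{t.col}.tif"
        tifffile.imwrite(out / fname, t.raster)
        layout["tiles"].append(
            {
                "tile_id": t.tile_id,
                "row": t.row,
                "col": t.col,
                "file": fname,
                "nominal_offset_px": list(t.nominal_offset_px),
            }
        )
    (out / "layout.json").write_text(json.dumps(layout, indent=1))


def load_tiles(tile_dir: str | Path) -> TileSet:
    tile_dir = Path(tile_dir)
    layout = json.loads((tile_dir / "layout.json").read_text())
    tiles = [
        Tile(
            tile_id=rec["tile_id"],
            row=rec["row"],
            col=rec["col"],
            raster=tifffile.imread(tile_dir / rec["file"]),
            nominal_offset_px=tuple(rec["nominal_offset_px"]),
        )
        for rec in layout["tiles"]
    ]
    return TileSet(
        tiles=tiles,
        overlap_frac=layout["overlap_frac"],
        um_per_px=layout["um_per_px"],
        well_id=layout["well_id"],
    )
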