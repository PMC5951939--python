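# Methods

## Measurement model

A spheroid observed in 2D brightfield projection is modelled as a circle;
its fitted radius r (µm) determines every size measure in closed form:
perimeter P = 2πr, projected area A = πr², and volume V = (4/3)πr³ — the
volume of the sphere whose maximal cross-section is the fitted circle. The
cell number per spheroid is the volume ratio N = V / V_cell with
V_cell = (4/3)π(d_cell/2)³ for a single cell of measured diameter d_cell,
assumed spherical. This deliberately assumes cells fill the spheroid with no
void space; no packing-fraction correction is applied. d_cell is a required
parameter with no default — it must come from a measurement of the cell line
at hand (15 µm is used throughout the tests and examples as a typical
epithelial value).

Objects with diameter ≤ 50 µm (strict inequality) are excluded from
analysis: they are single cells or small cell/debris aggregates, not
spheroids. A 50 µm-diameter object is excluded.

## Synthetic wells

The generator emulates a motorized-stage brightfield scan of one
ultra-low-attachment well and is the oracle for every pipeline stage.

* **Field and optics.** Default 7000 × 6200 µm at 2 µm/pixel, scanned as a
  7 × 7 grid (49 tiles ≈ a typical whole-well scan) with 25% nominal overlap
  (valid range 15–35%, warned outside). Background sits at 60% of the 16-bit
  range, spheroid bodies at 25% (dark objects on a bright well bottom);
  additive Gaussian sensor noise (default sd 300 DN) is applied to the scene
  before tiling so overlap strips carry identical content, as a physical
  scene does. Tile offsets get integer stage jitter of at most ±2 px; the
  first tile is jitter-free and anchors the coordinate frame, because a
  mosaic's global translation is not identifiable from image content.
* **Spheroid population.** Diameters are log-normal, median 250 µm (a day-6
  culture) with log-sd 0.35, truncated to [50, 600] µm to span the observed
  heterogeneity of later-day cultures. Non-fused spheroids are placed by
  rejection sampling with no mutual overlap (an explicit density error names
  the limit when the field is too crowded); a configurable fraction is
  placed as fused pairs whose boundary overlap is 10–40% of the smaller
  radius. Debris and single cells (< 50 µm) exercise the size filter.
  Surface roughness is a radial sinusoid on the rendered boundary only —
  annotations keep the nominal circle. An optional darker core disk at half
  radius emulates crypt-like morphology. Disks are rendered with a
  one-pixel anti-aliased (coverage) edge.
* **Treatment arms.** An arm applies a multiplicative volume fold
  (radius × fold^(1/3)) and a kill fraction. The base diameter draw and
  placement depend only on the configuration (including its seed), so arms
  generated from one config are paired — the same untreated population with
  the effect applied — which models treating replicate wells seeded from one
  cell suspension on day 6. Replicate wells are modelled with distinct
  seeds. Killed spheroids keep their record (alive = false) and are rendered
  as scattered sub-threshold fragments rather than intact bodies.
* **Plate-reader readouts.** Both readouts are linear in the viable cell
  number implied by the truth (Σ V_i / V_cell over living spheroids):
  RLU = blank + slope · [ATP] with cellular ATP at 10 000 amol/cell in a
  200 µl well, and OD₅₉₅ = blank + k · N. Multiplicative Gaussian noise with
  a configurable CV. Effector lymphocytes added to a co-culture contribute
  ATP but no crystal-violet signal (they do not adhere), reproducing the
  known upward bias of ATP-based viability in co-cultures; the OD-based
  estimate stays unbiased.

What the generator does **not** emulate: optics (PSF, depth of field,
defocus), illumination gradients across tiles, multi-z acquisition,
non-circular spheroid shapes, growth over time, and biological coupling
between size and treatment response. Passing tests therefore demonstrate
correctness of the measurement chain under the circular-object model, not
robustness to every property of real micrographs.

## Stitching

Pairwise translations between grid neighbours are estimated on their
nominal overlap strips by upsampled phase correlation (1/20 px grid), then
reconciled by a linear least-squares solve over the tile graph with the
first tile anchored at its nominal offset; x and y are separable. Pairs with
a flat strip or an implausible shift (> 5 px by default) fall back to the
nominal offset with a logged warning. Compositing places each tile at its
fitted offset rounded to the nearest pixel and blends overlaps with a
separable linear feather; border pixels left uncovered by jitter are filled
from the nearest covered pixel. Rounding to integer placement makes
refinement on jitter-free input reproduce nominal compositing bit-exactly,
and keeps the output uint16 grid-aligned. Rotation, scaling and flat-field
correction are out of scope.

## Detection

1. Global Otsu threshold on the mosaic histogram (dark foreground); chosen
   because the rendered scenes are bimodal by construction. A blank mosaic
   (contrast < 16 DN) returns no detections; a degenerate segmentation
   (foreground fraction > 0.9 or ~0) warns and returns none.
2. Connected components (8-connectivity); components far below the
   admissible area (15% of the minimum-diameter disk) are skipped.
3. Circularity gate 4πA/P² ≥ 0.8 with the Crofton perimeter estimate.
   Analytically, two equal fused disks whose centers sit 1.6 r apart score
   ≈ 0.75, safely below the gate, while digitised single disks score near 1.
4. Round components: center and radius come from edge-coverage-weighted
   moments — each pixel's coverage c = (bg − I)/(bg − fg) clipped to [0, 1]
   estimates the covered pixel fraction, so Σc is an unbiased disk area and
   the c-weighted centroid the subpixel center. On default wells this
   yields radius errors well under 1% and center errors under 1 µm.
5. Non-round components are split: seeds are interior maxima of the
   Euclidean distance transform (minimum separation = half the inclusion
   diameter, height ≥ half the minimum radius), each seed's radius starts at
   the distance value and is refined by a Kåsa least-squares circle fit to
   the stretch of component boundary nearest that seed's circle; wild fits
   (RMS ≥ 25% of radius, or center drift beyond the seed radius) revert to
   the seed estimate. A single-seed fallback guarantees ≥ 1 circle.
6. Circles with diameter ≤ the threshold are discarded (strict); remaining
   circles are de-duplicated by circle-circle IoU (> 0.6 suppressed),
   keeping the larger — consistent with measuring the maximal radius.
   Output is sorted by descending radius with stable ids.

Edge-touching objects are kept as fitted; the simulator places whole
spheroids inside the field, so the clipped-arc case is exercised only
lightly.

## Statistics

Group summaries report n, mean, SD (n−1) and SEM = SD/√n; groups of n < 2
keep NaN moments rather than being dropped. The two-arm comparison is the
classical pooled-variance unpaired t statistic with n_a + n_b − 2 degrees of
freedom and a two-sided p from the t distribution (Student's form is the
default because it is the field's stated convention; Welch is available via
``welch=True``). Within-group variances below the square of 10⁻¹² × data
scale are treated as zero: equal means then give t = 0, p = 1, and unequal
means are flagged degenerate with p reported as the smallest positive float.
Fold change is the ratio of group means (medians optional). No
multiple-testing correction is applied — comparisons are pairwise and
reported raw, and the comparisons CSV footer states this. Significance
labels default to *, **, *** at p < 0.01, 0.001, 0.0001 and are
configurable. Measurements from replicate wells/donors are pooled at the
spheroid level; per-well stratification is available through
``summarize(..., group_by="well")``.

## Problem sizes and tolerances

The default verification well carries 150 spheroids — comfortable for the
non-overlap placement at the default field size (≈ 22% disk packing) and
large enough that mean-volume contrasts are tight. Monte-Carlo checks use
100 draws (calibration, circle-fit bias, effect recovery) or 10 000
(type-I error calibration of the t test, checked against the [0.04, 0.06]
band at α = 0.05). Detection accuracy is asserted at < 3 µm center error
and < 3% radius error; measured performance is an order of magnitude
better. The acceptance script scales the four-arm recovery to 50 seeds and
the viability Monte-Carlo to 30 experiments of 6 replicate wells per arm.

## Known limitations

* The circular-ROI model undersizes genuinely elliptical or irregular
  spheroids; non-circular segmentation is explicitly out of scope.
* Heavily fused clusters (> 3 bodies, deep overlap) can merge distance
  ridges and return fewer circles than bodies; the union-coverage guarantee
  (≥ 90% of the pair's area) is what the splitter is tested to.
* The cell-number model ignores packing voids and any radial density
  gradient, so absolute counts inherit those assumptions even when the
  volume is exact.
* ATP-based viability is only trustworthy without effector cells in the
  well; the package reproduces that bias in simulation and the crystal
  violet path is the recommended viability readout for co-cultures.
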