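# Methods

`zfxquant` quantifies zebrafish larval tumor-xenograft micrographs.  In this
assay, dye-labeled (CM-DiI) human cancer cells are injected into the
perivitelline space of 2-dpf larvae and imaged a few days later.  Three
per-larva readouts carry the biology:

- **yolk tumor area** — total CM-DiI-positive area inside the yolk region,
  a proxy for proliferation of the transplanted cells;
- **trunk tumor area** — positive area inside the trunk, a proxy for
  invasion/dissemination;
- **migration index** — area of the coverage polygon through the peripheral
  tumor cells divided by the tumor area itself, a dimensionless dispersion
  score that removes the dependence on cell number.

Groups (e.g. negative-control siRNA vs knockdown, with or without a drug
bath) are compared by unpaired two-sided Student's t-tests and reported as
mean ± SEM, the convention of the field.  Companion modules implement the
matching in-vitro analytics: 2^−ΔΔCt relative expression with knockdown
efficiency, and CCK-8 viability time-courses.

## Segmentation and debris exclusion

The tumor channel is binarized either at a fixed intensity or by Otsu's
method computed on the pixels inside the union of the ROI masks (restricting
the histogram to the larva keeps the empty background from dominating).  A
degenerate automatic threshold — an all-background or all-foreground result,
as happens on blank negative-control larvae — raises an error, or falls back
to a configured fixed threshold with a warning.  Connected components are
8-connected by default because anti-aliased disk edges fragment under
4-connectivity; 4-connectivity is available.

CM-DiI also labels sub-cellular debris (apoptotic bodies, exosomes), which
appears as isolated bright spots much smaller than a cell and would inflate
the area readouts.  Debris exclusion is a size rule: objects with pixel area
strictly below `min_cell_area_um2` are flagged and excluded from every area
and hull computation, but kept in the object table for audit.  The default
cutoff is 25 % of the cross-section implied by the configured cell diameter
(10 µm ⇒ ~19.6 µm²), a relative rule that behaves identically across
acquisition dialects; it is a configuration knob, not a constant.  Whether a
human analyst would have excluded a given spot by eye cannot be recovered;
the size rule is the reproducible surrogate, and the flag threshold is the
sensitivity knob to vary.

## Regions

ROIs are simple closed polygons in continuous pixel-corner coordinates,
0-based (row, col), origin top-left.  A pixel belongs to a polygon iff its
center lies strictly inside (centers exactly on the boundary count as
outside).  Rasterization uses vectorized point-in-polygon tests;
self-intersecting polygons are rejected.  "yolk" and "trunk" are required
and must be disjoint, asserted at load time.

Region areas are pixel-accounted — non-debris foreground intersected with
each mask — so `yolk + trunk + outside` equals the total non-debris
foreground exactly, and the identity is asserted on every measurement.  The
per-object majority-region assignment table is a convenience output only;
ties go to "outside" and are logged.

## Coverage hull and migration index

The coverage polygon is the convex hull of the pixel *squares* (all four
corners of every non-debris foreground pixel) in the analysis region, by
default the yolk.  This convention makes a single-pixel tumor well defined
(unit square, index 1), guarantees the hull contains the tumor pixel set,
and hence `migration_index = hull_area / tumor_area ≥ 1`, with equality iff
the tumor pixel union is convex.  The hull area is evaluated by the shoelace
formula on the hull's integer corner coordinates, which is exact in double
precision: the area is bit-identical under integer translation and 90°
rotation.  A hand-drawn coverage polygon could be concave; the convex hull
is the reproducible choice, and a concave (alpha-shape) option is explicitly
out of scope for v1.  Zero non-debris pixels in the analysis region is an
*empty-tumor* condition: the hull and index are reported missing (NaN with a
status flag), never zero.

## Synthetic larvae

No public image data exist for this assay, so the package ships a simulator
whose ground truth is exact.  One field consists of a canonical larva
geometry (elliptical yolk + tapered trunk, scaled to the dialect's image
shape — 1600×1200 "stereo" or 1024×1024 "confocal"), disk-rendered cells and
debris, diffuse yolk autofluorescence, and additive Gaussian read noise on a
16-bit scale.  Defaults (confocal dialect, 0.62 µm/px, 400 cells of radius
5 ± 0.6 µm, intensity 10000 ± 1500, 12 debris spots of radius 1.2 µm,
autofluorescence 600, noise sd 80) model a realistic acquisition of the
assay's ~400-cell inoculum.

Design choices that matter:

- **Two-scale placement.** Yolk cells are a mixture: a dense inoculum core
  (`core_sigma_um`, default 25 µm) plus a migrating fraction (default 0.3)
  scattered at `dispersion_sigma_um` (default 80 µm).  With a single
  placement scale, hull area and union tumor area both grow with the scale
  squared, so their ratio — the migration index — is scale-invariant and the
  index would not respond to dispersion at all.  The mixture matches what a
  migrated xenograft looks like (compact mass plus peripheral escapees) and
  makes the index a genuine dispersion readout.  Group dispersion
  multipliers scale the migrating component's sigma.
- **Debris rendered like cells.** Debris uses the same disk renderer and
  intensity distribution as cells, only with a much smaller radius, so that
  size is the *only* discriminator available to the filter — intensity gives
  nothing away.  Debris is placed uniformly over the yolk with a clearance
  of 2 px from every cell and every other debris spot: debris presents as
  separate spots, and contact would merge components and make "the flagged
  set equals the true debris set" ill-posed.
- **Additive ground-truth areas.** `true_yolk_area_px` / `true_trunk_area_px`
  sum, over cells, the pixel count of each independently rasterized disk
  intersected with the region mask.  This is exactly linear in cell count
  (what effect-recovery checks need) and equals the measured union area
  whenever no two disks overlap; at the dense defaults the measured union is
  smaller than the additive truth, which is a property of the scene, not an
  error.
- **Max compositing.** Overlapping disks composite by maximum, mimicking a
  saturating dye signal rather than summing to non-physical intensities.
- **Determinism.** One integer seed drives everything; identical parameters
  and seed give bit-identical rasters.  Cohorts derive per-larva seeds via
  `SeedSequence(design_seed, spawn_key=(group_index, larva_index))`, so any
  larva can be regenerated in isolation and results do not depend on
  generation order.
- **Truncated radius draws.** Gaussian radius/intensity draws are clipped
  away from zero (radius at 20 % of its mean, intensity at 1) to keep
  degenerate disks out of the render.

What the simulator does *not* emulate: optical point-spread blur, 3-D
stacks, vignetting and illumination gradients, autofluorescence texture,
cell-shape irregularity, or attrition of the inoculum between injection and
imaging (`n_cells` is the count at imaging time, exposed directly).  Passing
tests therefore demonstrate that the measurement chain is correct and well
calibrated on fields with known truth — not that segmentation is robust to
every artifact of real micrographs.  On real data the fixed/Otsu threshold
and the debris cutoff are the knobs that must be validated per dataset.

## Statistics

Pooled-variance (equal-variance) Student's t with `n_a + n_b − 2` degrees of
freedom is the default, matching the assay's convention; Welch's correction
is behind a flag.  Two constant samples with equal means give t = 0, p = 1;
with unequal means the statistic is undefined and raises.  SEM uses the
n−1 sample standard deviation.  Stars: \*\*\* p<0.001, \*\* p<0.01,
\* p<0.05, else "ns".  No multiple-testing correction is applied by default
(Holm adjustment is available).  For the 2×2 knockdown-by-drug design the
pairwise comparisons are reported uncorrected, as conventionally done, plus
an additive-scale interaction estimate with a pooled-variance standard error
— labeled exploratory, because the underlying biology is claimed from the
pairwise comparisons, not from a factorial model.

## Assay analytics

ΔCt = Ct_target − Ct_reference per sample; the ΔΔCt baseline is the
arithmetic mean ΔCt of the control group (per-sample pairing orders are
unknowable from a plain Ct table); folds are averaged on the fold scale.
Knockdown efficiency is `(1 − mean treated fold / mean control fold) · 100`:
dividing by the control mean fold keeps the identity
`efficiency + 100·fold_rel = 100` exact even when control replicates
scatter (their arithmetic-mean fold then slightly exceeds 1), and it reduces
to `(1 − mean treated fold)·100` when control replicates are identical.
Amplification-efficiency (Pfaffl) correction is out of scope.  CCK-8
correction subtracts the mean blank OD at the same timepoint; normalized
mode divides each sample's corrected series by its corrected t=0 value, and
samples with non-positive t=0 are flagged and dropped with a warning.

## Problem sizes used by the validation suite

The test suite and `scripts/acceptance.py` run everything they assert:
oracle checks use 100–500 small random scenes against test-only brute-force
implementations (flood fill, gift-wrap hull, per-pixel ray cast);
effect-recovery cohorts use 100–200 larvae per group for the truth-level
0.5-multiplier recovery, 20–40 larvae per level for dispersion sweeps, and
an end-to-end demo of 20 larvae per arm; statistical calibration uses 2,000
null t-tests.  These sizes give Monte-Carlo standard errors comfortably
below the effects being checked while keeping a full run to a few minutes on
one CPU.
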