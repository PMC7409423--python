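"""Synthetic larva micrograph simulator with ground truth.

No public image data exist for this assay, so every downstream stage is
exercised against simulated fields whose truth is known exactly.  The
simulator emulates what a 4-days-post-injection larva field looks like to the
quantification code:

* a larva-shaped pair of regions — an elliptical *yolk* and an elongated,
  tapered *trunk* — scaled to the acquisition dialect's image shape;
* a few hundred dye-labeled tumor cells rendered as anti-aliased bright
  disks.  Yolk cells are placed as a two-scale mixture around the yolk
  centroid (the perivitelline injection site): a dense inoculum core plus a
  *migrating fraction* scattered at a wider scale, ``dispersion_sigma_um``.
  This is what a migrated xenograft looks like — a compact mass with
  peripheral escapees — and it is what makes the coverage-hull migration
  index respond to dispersion: with a single placement scale, hull area and
  union tumor area both grow with the scale squared and their ratio is
  scale-invariant.  A small fraction of cells is seeded into the trunk;
* sub-cell-size bright debris spots confined to the yolk, rendered with the
  same intensity model as cells so that *size is the only discriminator*, and
  placed so they touch neither cells nor each other (debris presents as
  separate spots, not halos on cells);
* diffuse yolk autofluorescence and additive Gaussian read noise on a 16-bit
  intensity scale.

Group-level biology is expressed as multiplicative effects on the simulation
parameters: proliferation scales the cell count, invasion scales the trunk
fraction, migration scales the dispersion of cell placement.

Everything is driven by one integer seed; identical parameters and seed give
bit-identical rasters.  Cohorts derive per-larva seeds from the design seed
via ``numpy.random.SeedSequence(design_seed, spawn_key=(group_index,
larva_index))``, so a larva's field does not depend on generation order.
"""

from __future__ import annotations

import json
import math
from dataclasses import asdict, dataclass, field, replace
from pathlib import Path

import numpy as np
import shapely
from scipy.spatial import ConvexHull
from shapely.geometry import Polygon

from .image import DIALECT_SHAPES, TUMOR, VASCULATURE, LarvaImage
from .regions import RoiSet

MAX_16BIT = 65535.0


# ---------------------------------------------------------------------------
# parameters


@dataclass(frozen=True)
class SimulationParams:
    """Knobs of one simulated larva field.

    Defaults model a confocal acquisition (1024 x 1024 px, 0.62 µm/px) of a
    larva carrying ~400 injected cells — the inoculum size of the assay —
    with a handful of sub-cellular debris spots in the yolk.  Mean/sd pairs
    are (mean, sd) tuples in the stated units.

    Yolk-cell placement has two scales: ``core_sigma_um`` for the
    ``1 - migrating_fraction`` of cells forming the inoculum mass, and
    ``dispersion_sigma_um`` for the migrating fraction — the knob group
    dispersion multipliers act on.
    """

    image_shape: tuple[int, int] = DIALECT_SHAPES["confocal"]
    pixel_size_um: float = 0.62
    n_cells: int = 400
    cell_radius_um: tuple[float, float] = (5.0, 0.6)
    cell_intensity: tuple[float, float] = (10000.0, 1500.0)
    dispersion_sigma_um: float = 80.0
    core_sigma_um: float = 25.0
    migrating_fraction: float = 0.3
    trunk_fraction: float = 0.05
    n_debris: int = 12
    debris_radius_um: float = 1.2
    yolk_autofluor_level: float = 600.0
    noise_sd: float = 80.0
    seed: int = 0
    dialect: str = "confocal"

    #: debris radius sd as a fraction of its mean (debris are rendered with
    #: the same disk model as cells, just from the small-radius distribution)
    DEBRIS_RADIUS_CV = 0.15
    #: clearance (px) kept between a debris disk and any cell or other debris
    DEBRIS_CLEARANCE_PX = 2.0

    def __post_init__(self):
        r, c = self.image_shape
        if r <= 0 or c <= 0:
            raise ValueError("image dimensions must be positive")
        if self.n_cells < 0 or self.n_debris < 0:
            raise ValueError("n_cells and n_debris must be >= 0")
        if not 0.0 <= self.trunk_fraction <= 1.0:
            raise ValueError("trunk_fraction must lie in [0, 1]")
        if not 0.0 <= self.migrating_fraction <= 1.0:
            raise ValueError("migrating_fraction must lie in [0, 1]")
        if self.core_sigma_um <= 0 or self.dispersion_sigma_um <= 0:
            raise ValueError("placement sigmas must be positive")
        if self.cell_radius_um[0] <= 0:
            raise ValueError("cell radius must be positive")
        if not self.debris_radius_um < self.cell_radius_um[0]:
            raise ValueError("debris must be smaller than cells on average")
        if self.pixel_size_um <= 0:
            raise ValueError("pixel_size_um must be positive")
        if self.noise_sd < 0 or self.yolk_autofluor_level < 0:
            raise ValueError("noise and autofluorescence levels must be >= 0")

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(asdict(self), indent=1))

    @classmethod
    def from_json(cls, path: str | Path) -> "SimulationParams":
        d = json.loads(Path(path).read_text())
        d["image_shape"] = tuple(d["image_shape"])
        for key in ("cell_radius_um", "cell_intensity"):
            d[key] = tuple(d[key])
        return cls(**d)


@dataclass(frozen=True)
class GroupSpec:
    """One cohort arm and its programmed biology.

    Multipliers abstract the group's biological effect: ``proliferation``
    scales the cell count, ``invasion`` the trunk fraction, ``dispersion``
    the placement sigma.  All must be positive; 1.0 means no effect.
    """

    name: str
    n_larvae: int
    proliferation: float = 1.0
    invasion: float = 1.0
    dispersion: float = 1.0

    def __post_init__(self):
        if self.n_larvae < 1:
            raise ValueError("each group needs at least one larva")
        if min(self.proliferation, self.invasion, self.dispersion) <= 0:
            raise ValueError("group multipliers must be positive")


@dataclass(frozen=True)
class CohortDesign:
    """A multi-group simulated experiment."""

    groups: tuple[GroupSpec, ...]
    base_params: SimulationParams = SimulationParams()
    seed: int = 0

    def __post_init__(self):
        if not self.groups:
            raise ValueError("cohort design needs at least one group")


@dataclass
class GroundTruth:
    """Simulator sidecar: what is actually in the field.

    ``cells`` and ``debris`` are lists of ``(row, col, radius_px)`` (cells
    additionally carry their region label); coordinates are continuous
    pixel-corner coordinates, matching the ROI polygon convention.

    True region areas are *additive*: each cell disk is rasterized on its own
    (pixel-center containment) and its pixel count inside the region mask is
    summed over cells.  This equals the union foreground area whenever no two
    disks overlap, and is exactly linear in cell count, which is what makes
    the truth usable for effect-recovery checks.  ``true_hull_area_px`` is
    the pixel-square convex-hull area of the union of cell pixels inside the
    yolk (the analysis region of the migration readout).
    """

    cells: list[tuple[float, float, float, str]]
    debris: list[tuple[float, float, float]]
    params: SimulationParams
    true_yolk_area_px: int
    true_trunk_area_px: int
    true_hull_area_px: float

    def to_json(self, path: str | Path) -> None:
        payload = {
            "cells": [[r, c, rad, lab] for r, c, rad, lab in self.cells],
            "debris": [[r, c, rad] for r, c, rad in self.debris],
            "params": asdict(self.params),
            "true_yolk_area_px": self.true_yolk_area_px,
            "true_trunk_area_px": self.true_trunk_area_px,
            "true_hull_area_px": self.true_hull_area_px,
        }
        Path(path).write_text(json.dumps(payload, indent=1))

    @classmethod
    def from_json(cls, path: str | Path) -> "GroundTruth":
        d = json.loads(Path(path).read_text())
        p = d["params"]
        p["image_shape"] = tuple(p["image_shape"])
        for key in ("cell_radius_um", "cell_intensity"):
            p[key] = tuple(p[key])
        return cls(
            cells=[(r, c, rad, lab) for r, c, rad, lab in d["cells"]],
            debris=[(r, c, rad) for r, c, rad in d["debris"]],
            params=SimulationParams(**p),
            true_yolk_area_px=d["true_yolk_area_px"],
            true_trunk_area_px=d["true_trunk_area_px"],
            true_hull_area_px=d["true_hull_area_px"],
        )


# ---------------------------------------------------------------------------
# larva geometry template

#: template geometry in unit coordinates (fractions of image rows/cols):
#: yolk ellipse center/semi-axes and trunk quadrilateral taper
_YOLK_CENTER = (0.60, 0.30)
_YOLK_SEMI = (0.22, 0.20)
_TRUNK_COLS = (0.52, 0.97)
_TRUNK_ROWS_LEFT = (0.30, 0.46)
_TRUNK_ROWS_RIGHT = (0.34, 0.40)


def template_polygons(image_shape: tuple[int, int]) -> dict[str, np.ndarray]:
    """Canonical yolk + trunk polygon pair scaled to an image shape.

    The larva lies horizontally: an elliptical yolk sac on the left, the
    tapering trunk extending to the right, the two regions disjoint.  The
    template stands in for the hand-drawn region curves of a real analysis;
    a user-supplied RoiSet always overrides it.
    """
    nr, nc = image_shape
    theta = np.linspace(0.0, 2.0 * math.pi, 64, endpoint=False)
    yolk = np.stack(
        [
            _YOLK_CENTER[0] * nr + _YOLK_SEMI[0] * nr * np.sin(theta),
            _YOLK_CENTER[1] * nc + _YOLK_SEMI[1] * nc * np.cos(theta),
        ],
        axis=1,
    )
    (c0, c1) = _TRUNK_COLS
    (lt, lb) = _TRUNK_ROWS_LEFT
    (rt, rb) = _TRUNK_ROWS_RIGHT
    trunk = np.array(
        [
            [lt * nr, c0 * nc],
            [rt * nr, c1 * nc],
            [rb * nr, c1 * nc],
            [lb * nr, c0 * nc],
        ]
    )
    return {"yolk": yolk, "trunk": trunk}


def template_rois(image_shape: tuple[int, int]) -> RoiSet:
    """Rasterized canonical ROI template for an image shape."""
    return RoiSet.from_polygons(template_polygons(image_shape), image_shape)


# ---------------------------------------------------------------------------
# rendering primitives


def _render_disk(img: np.ndarray, r0: float, c0: float, radius: float, value: float):
    """Max-composite one anti-aliased filled disk into a float raster.

    Pixel coverage is approximated by ``clip(radius + 0.5 - d, 0, 1)`` where
    ``d`` is the distance from the pixel center to the disk center; disks
    composite by maximum, which mimics a saturating dye signal where cells
    overlap rather than summing to non-physical intensities.
    """
    nr, nc = img.shape
    rmin = max(int(math.floor(r0 - radius - 1.0)), 0)
    rmax = min(int(math.ceil(r0 + radius + 1.0)) + 1, nr)
    cmin = max(int(math.floor(c0 - radius - 1.0)), 0)
    cmax = min(int(math.ceil(c0 + radius + 1.0)) + 1, nc)
    if rmin >= rmax or cmin >= cmax:
        return
    rr = np.arange(rmin, rmax)[:, None] + 0.5
    cc = np.arange(cmin, cmax)[None, :] + 0.5
    d = np.hypot(rr - r0, cc - c0)
    cov = np.clip(radius + 0.5 - d, 0.0, 1.0)
    patch = img[rmin:rmax, cmin:cmax]
    np.maximum(patch, cov * value, out=patch)


def rasterize_disk_pixels(
    r0: float, c0: float, radius: float, image_shape: tuple[int, int]
) -> tuple[np.ndarray, np.ndarray]:
    """Pixel indices whose centers lie within ``radius`` of the disk center."""
    nr, nc = image_shape
    rmin = max(int(math.floor(r0 - radius - 1.0)), 0)
    rmax = min(int(math.ceil(r0 + radius + 1.0)) + 1, nr)
    cmin = max(int(math.floor(c0 - radius - 1.0)), 0)
    cmax = min(int(math.ceil(c0 + radius + 1.0)) + 1, nc)
    if rmin >= rmax or cmin >= cmax:
        return np.empty(0, int), np.empty(0, int)
    rr = np.arange(rmin, rmax)[:, None] + 0.5
    cc = np.arange(cmin, cmax)[None, :] + 0.5
    inside = np.hypot(rr - r0, cc - c0) <= radius
    ii, jj = np.nonzero(inside)
    return ii + rmin, jj + cmin


# ---------------------------------------------------------------------------
# placement


def _sample_in_polygon_gaussian(
    rng: np.random.Generator, poly: Polygon, center_rc, sigma: float, n: int
) -> np.ndarray:
    """Isotropic Gaussian samples rejected to the polygon interior."""
    out = np.empty((n, 2))
    got = 0
    attempts = 0
    while got < n:
        attempts += 1
        if attempts > 1000:
            raise RuntimeError("cell placement rejection sampling did not converge")
        m = max(4 * (n - got), 64)
        cand = rng.normal(loc=center_rc, scale=sigma, size=(m, 2))
        ok = shapely.contains_xy(poly, cand[:, 1], cand[:, 0])
        take = min(int(ok.sum()), n - got)
        out[got : got + take] = cand[ok][:take]
        got += take
    return out


def _sample_in_mask_uniform(
    rng: np.random.Generator, mask: np.ndarray, n: int
) -> np.ndarray:
    """Uniform samples over a mask's pixel centers (corner coordinates)."""
    rr, cc = np.nonzero(mask)
    if len(rr) == 0 and n > 0:
        raise RuntimeError("cannot place cells: region mask is empty")
    idx = rng.integers(0, len(rr), size=n)
    return np.stack([rr[idx] + 0.5, cc[idx] + 0.5], axis=1)


def _truncated_normal(rng, mean, sd, n, lo_frac=0.2):
    """Normal draws with the lower tail clipped away from zero."""
    return np.maximum(rng.normal(mean, sd, size=n), lo_frac * mean)


# ---------------------------------------------------------------------------
# main generators


def generate_larva(
    params: SimulationParams, rois: RoiSet | None = None
) -> tuple[LarvaImage, GroundTruth, RoiSet]:
    """Simulate one larva field.

    Returns the rendered two-channel image (tumor + decorative vasculature),
    the ground-truth sidecar, and the ROI set used (the canonical template
    unless ``rois`` is supplied).
    """
    rng = np.random.default_rng(params.seed)
    shape = params.image_shape
    if rois is None:
        rois = template_rois(shape)
    rois.require("yolk", "trunk")
    yolk_poly = Polygon(np.asarray(rois["yolk"].vertices)[:, ::-1])
    px = params.pixel_size_um

    # -- cell placement ----------------------------------------------------
    n_trunk = int(round(params.n_cells * params.trunk_fraction))
    n_yolk = params.n_cells - n_trunk
    n_migrating = int(round(n_yolk * params.migrating_fraction))
    yolk_center = (yolk_poly.centroid.y, yolk_poly.centroid.x)
    pos_core = _sample_in_polygon_gaussian(
        rng, yolk_poly, yolk_center, params.core_sigma_um / px, n_yolk - n_migrating
    )
    pos_migrating = _sample_in_polygon_gaussian(
        rng, yolk_poly, yolk_center, params.dispersion_sigma_um / px, n_migrating
    )
    pos_yolk = np.concatenate([pos_core, pos_migrating])
    pos_trunk = _sample_in_mask_uniform(rng, rois["trunk"].mask, n_trunk)
    positions = np.concatenate([pos_yolk, pos_trunk]) if params.n_cells else np.empty((0, 2))
    labels = ["yolk"] * n_yolk + ["trunk"] * n_trunk

    radii_px = _truncated_normal(
        rng, params.cell_radius_um[0] / px, params.cell_radius_um[1] / px, params.n_cells
    )
    cell_vals = np.clip(
        rng.normal(params.cell_intensity[0], params.cell_intensity[1], params.n_cells),
        1.0,
        MAX_16BIT,
    )

    # -- debris placement (yolk only, clear of every cell and each other) --
    debris_radii_px = _truncated_normal(
        rng,
        params.debris_radius_um / px,
        params.DEBRIS_RADIUS_CV * params.debris_radius_um / px,
        params.n_debris,
    )
    debris_pos = _place_debris(
        rng, rois["yolk"].mask, positions, radii_px, debris_radii_px,
        params.DEBRIS_CLEARANCE_PX,
    )
    debris_vals = np.clip(
        rng.normal(params.cell_intensity[0], params.cell_intensity[1], params.n_debris),
        1.0,
        MAX_16BIT,
    )

    # -- render tumor channel ----------------------------------------------
    tumor = np.zeros(shape, dtype=np.float64)
    for (r0, c0), rad, val in zip(positions, radii_px, cell_vals):
        _render_disk(tumor, r0, c0, rad, val)
    for (r0, c0), rad, val in zip(debris_pos, debris_radii_px, debris_vals):
        _render_disk(tumor, r0, c0, rad, val)
    if params.yolk_autofluor_level > 0:
        tumor[rois["yolk"].mask] += params.yolk_autofluor_level
    if params.noise_sd > 0:
        tumor += rng.normal(0.0, params.noise_sd, size=shape)
    tumor = np.clip(tumor, 0.0, MAX_16BIT).astype(np.uint16)

    vasculature = _render_vasculature(rng, shape, rois)

    # -- ground truth -------------------------------------------------------
    yolk_mask = rois["yolk"].mask
    trunk_mask = rois["trunk"].mask
    true_yolk = 0
    true_trunk = 0
    cell_union = np.zeros(shape, dtype=bool)
    for (r0, c0), rad in zip(positions, radii_px):
        ii, jj = rasterize_disk_pixels(r0, c0, rad, shape)
        true_yolk += int(yolk_mask[ii, jj].sum())
        true_trunk += int(trunk_mask[ii, jj].sum())
        cell_union[ii, jj] = True
    true_hull = _hull_area(cell_union & yolk_mask)

    truth = GroundTruth(
        cells=[
            (float(r), float(c), float(rad), lab)
            for (r, c), rad, lab in zip(positions, radii_px, labels)
        ],
        debris=[
            (float(r), float(c), float(rad))
            for (r, c), rad in zip(debris_pos, debris_radii_px)
        ],
        params=params,
        true_yolk_area_px=true_yolk,
        true_trunk_area_px=true_trunk,
        true_hull_area_px=true_hull,
    )
    image = LarvaImage(
        channels={TUMOR: tumor, VASCULATURE: vasculature},
        pixel_size_um=px,
        dialect=params.dialect,
    )
    return image, truth, rois


def _place_debris(
    rng, yolk_mask, cell_pos, cell_radii, debris_radii, clearance
) -> np.ndarray:
    """Debris scattered uniformly over the yolk, clear of cells and debris."""
    rr, cc = np.nonzero(yolk_mask)
    out = np.empty((len(debris_radii), 2))
    placed_pos: list[np.ndarray] = []
    placed_rad: list[float] = []
    for k, rad in enumerate(debris_radii):
        for _ in range(2000):
            i = rng.integers(0, len(rr))
            cand = np.array([rr[i] + 0.5, cc[i] + 0.5])
            if len(cell_pos):
                d = np.hypot(*(cell_pos - cand).T)
                if np.any(d < cell_radii + rad + clearance):
                    continue
            if placed_pos:
                d = np.hypot(*(np.asarray(placed_pos) - cand).T)
                if np.any(d < np.asarray(placed_rad) + rad + clearance):
                    continue
            out[k] = cand
            break
        else:
            raise RuntimeError(
                "could not place debris clear of cells; scene too crowded"
            )
        placed_pos.append(out[k])
        placed_rad.append(float(rad))
    return out


def _render_vasculature(rng, shape, rois) -> np.ndarray:
    """Static decorative vessel-like raster for the EGFP channel."""
    nr, nc = shape
    img = np.zeros(shape, dtype=np.float64)
    cols = np.arange(nc)
    for frac, amp in ((0.32, 0.015), (0.40, 0.012), (0.44, 0.018)):
        rows = frac * nr + amp * nr * np.sin(cols / nc * 6.0 * math.pi)
        for dr in (-1, 0, 1):
            rr = np.clip(np.round(rows).astype(int) + dr, 0, nr - 1)
            img[rr, cols] = 3000.0
    img += rng.normal(0.0, 30.0, size=shape)
    return np.clip(img, 0.0, MAX_16BIT).astype(np.uint16)


def _hull_area(mask: np.ndarray) -> float:
    """Pixel-square convex hull area of a boolean mask (0.0 when empty)."""
    if not mask.any():
        return 0.0
    rr, cc = np.nonzero(mask)
    pts = np.concatenate(
        [
            np.stack([rr, cc], axis=1),
            np.stack([rr + 1, cc], axis=1),
            np.stack([rr, cc + 1], axis=1),
            np.stack([rr + 1, cc + 1], axis=1),
        ]
    ).astype(float)
    return float(ConvexHull(pts).volume)


@dataclass
class CohortSample:
    """One simulated larva of a cohort."""

    larva_id: str
    group_label: str
    image: LarvaImage
    truth: GroundTruth
    rois: RoiSet


def larva_seed(design_seed: int, group_index: int, larva_index: int) -> int:
    """Deterministic per-larva child seed (independent of generation order)."""
    ss = np.random.SeedSequence(design_seed, spawn_key=(group_index, larva_index))
    return int(ss.generate_state(1)[0])


def group_params(base: SimulationParams, group: GroupSpec, seed: int) -> SimulationParams:
    """Apply a group's effect multipliers to the base parameters."""
    return replace(
        base,
        n_cells=int(round(base.n_cells * group.proliferation)),
        trunk_fraction=min(base.trunk_fraction * group.invasion, 1.0),
        dispersion_sigma_um=base.dispersion_sigma_um * group.dispersion,
        seed=seed,
    )


def generate_cohort(design: CohortDesign, rois: RoiSet | None = None):
    """Generate every larva of a cohort design.

    Yields :class:`CohortSample` in group order.  Larva ids are
    ``"<group>-<index>"``; seeds come from :func:`larva_seed`, so any single
    larva can be regenerated in isolation.
    """
    if rois is None:
        rois = template_rois(design.base_params.image_shape)
    for gi, group in enumerate(design.groups):
        for li in range(group.n_larvae):
            params = group_params(design.base_params, group, larva_seed(design.seed, gi, li))
            image, truth, used_rois = generate_larva(params, rois)
            yield CohortSample(
                larva_id=f"{group.name}-{li:03d}",
                group_label=group.name,
                image=image,
                truth=truth,
                rois=used_rois,
            )
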