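"""Regions of interest and per-region tumor-area readouts.

The in-vivo assay reads two anatomical regions of each larva: CM-DiI-positive
area inside the *yolk* proxies proliferation of the transplanted cells, and
area inside the *trunk* proxies invasion/dissemination.  Regions are closed
polygons drawn in image coordinates (the field's equivalent of the dashed
curves an analyst traces on the micrograph) and are rasterized to boolean
masks with an explicit pixel-center containment convention.

Coordinate convention
---------------------
0-based ``(row, col)``, origin at the top-left image corner.  Polygon vertices
live in continuous *pixel-corner* coordinates: the pixel at index ``(r, c)``
spans ``[r, r+1) x [c, c+1)`` and its center sits at ``(r+0.5, c+0.5)``.  A
pixel belongs to a polygon iff its center is strictly inside; centers exactly
on the boundary are outside (half-open rule).  An axis-aligned rectangle with
corners (0,0)-(10,20) therefore covers exactly 200 pixels.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import shapely
from shapely.geometry import Polygon

log = logging.getLogger(__name__)

#: region names every quantification run requires
REQUIRED_ROIS = ("yolk", "trunk")


class GeometryError(ValueError):
    """Raised for degenerate or self-intersecting ROI polygons."""


def _as_polygon(vertices: np.ndarray) -> Polygon:
    vertices = np.asarray(vertices, dtype=float)
    if vertices.ndim != 2 or vertices.shape[1] != 2 or len(vertices) < 3:
        raise GeometryError("polygon needs at least 3 (row, col) vertices")
    # shapely works in (x, y); map col->x, row->y
    poly = Polygon(vertices[:, ::-1])
    if not poly.is_valid or not poly.is_simple:
        raise GeometryError("polygon is self-intersecting or degenerate")
    if poly.area == 0:
        raise GeometryError("polygon has zero area")
    return poly


def rasterize_polygon(vertices, image_shape: tuple[int, int]) -> np.ndarray:
    """Rasterize a simple closed polygon to a boolean mask.

    The mask contains exactly the pixels whose centers lie strictly inside the
    polygon (see module docstring for the boundary rule).

    Parameters
    ----------
    vertices
        ``(n, 2)`` array of (row, col) pixel-corner coordinates.
    image_shape
        (rows, cols) of the target raster.

    Raises
    ------
    GeometryError
        If the polygon is empty, degenerate, or self-intersecting.
    """
    nrow, ncol = image_shape
    if nrow <= 0 or ncol <= 0:
        raise ValueError("image_shape must be positive")
    poly = _as_polygon(vertices)

    rmin = max(int(np.floor(poly.bounds[1])), 0)
    rmax = min(int(np.ceil(poly.bounds[3])) + 1, nrow)
    cmin = max(int(np.floor(poly.bounds[0])), 0)
    cmax = min(int(np.ceil(poly.bounds[2])) + 1, ncol)
    mask = np.zeros((nrow, ncol), dtype=bool)
    if rmin >= rmax or cmin >= cmax:
        return mask

    rr, cc = np.meshgrid(
        np.arange(rmin, rmax) + 0.5, np.arange(cmin, cmax) + 0.5, indexing="ij"
    )
    inside = shapely.contains_xy(poly, cc.ravel(), rr.ravel()).reshape(rr.shape)
    mask[rmin:rmax, cmin:cmax] = inside
    return mask


@dataclass(frozen=True)
class Roi:
    """A named closed polygon with its rasterized mask."""

    name: str
    vertices: np.ndarray  # (n, 2) float, (row, col) pixel-corner coords
    mask: np.ndarray  # boolean, image shape

    @property
    def area_px(self) -> int:
        return int(self.mask.sum())


class RoiSet:
    """Named ROI polygons for one image.

    Quantification requires "yolk" and "trunk"; their masks must be disjoint
    (asserted at construction, mirroring the fact that the two anatomical
    readouts never share pixels).
    """

    def __init__(self, rois: dict[str, Roi]):
        self.rois = dict(rois)
        if REQUIRED_ROIS[0] in self.rois and REQUIRED_ROIS[1] in self.rois:
            overlap = self.rois["yolk"].mask & self.rois["trunk"].mask
            if overlap.any():
                raise GeometryError(
                    f"yolk and trunk masks overlap on {int(overlap.sum())} px"
                )

    @classmethod
    def from_polygons(
        cls, polygons: dict[str, np.ndarray], image_shape: tuple[int, int]
    ) -> "RoiSet":
        return cls(
            {
                name: Roi(name, np.asarray(v, dtype=float), rasterize_polygon(v, image_shape))
                for name, v in polygons.items()
            }
        )

    def __getitem__(self, name: str) -> Roi:
        return self.rois[name]

    def __contains__(self, name: str) -> bool:
        return name in self.rois

    def names(self) -> list[str]:
        return sorted(self.rois)

    def require(self, *names: str) -> None:
        missing = [n for n in names if n not in self.rois]
        if missing:
            raise KeyError(f"RoiSet is missing required region(s): {missing}")

    def union_mask(self) -> np.ndarray:
        out = np.zeros_like(next(iter(self.rois.values())).mask)
        for roi in self.rois.values():
            out |= roi.mask
        return out

    # -- JSON round trip ---------------------------------------------------
    # Schema: {"rois": [{"name": "yolk", "vertices": [[r, c], ...]}, ...]}

    def to_json(self, path: str | Path) -> None:
        payload = {
            "rois": [
                {"name": roi.name, "vertices": np.asarray(roi.vertices).tolist()}
                for roi in self.rois.values()
            ]
        }
        Path(path).write_text(json.dumps(payload, indent=1))

    @classmethod
    def from_json(cls, path: str | Path, image_shape: tuple[int, int]) -> "RoiSet":
        payload = json.loads(Path(path).read_text())
        return cls.from_polygons(
            {r["name"]: np.asarray(r["vertices"], dtype=float) for r in payload["rois"]},
            image_shape,
        )


@dataclass
class RegionAreas:
    """Per-region CM-DiI-positive area of one larva.

    Areas are pixel-accounted: the non-debris foreground is intersected with
    each region mask, so ``yolk + trunk + outside`` pixel counts equal the
    total non-debris foreground exactly.  ``assignments`` is a per-object
    convenience table (majority-region rule); it never feeds the area sums.
    """

    yolk_area_px: int
    trunk_area_px: int
    outside_area_px: int
    pixel_size_um: float
    assignments: pd.DataFrame

    @property
    def yolk_area_um2(self) -> float:
        return self.yolk_area_px * self.pixel_size_um**2

    @property
    def trunk_area_um2(self) -> float:
        return self.trunk_area_px * self.pixel_size_um**2

    @property
    def outside_area_um2(self) -> float:
        return self.outside_area_px * self.pixel_size_um**2


def measure_region_areas(objects, rois: RoiSet, pixel_size_um: float) -> RegionAreas:
    """Measure per-region non-debris tumor area.

    Parameters
    ----------
    objects
        :class:`~zfxquant.segmentation.CellObjects` with debris already
        flagged (an unfiltered set simply has no flags).
    rois
        Must contain "yolk" and "trunk" with masks of the label-raster shape.
    pixel_size_um
        Pixel edge length, for µm² conversion.

    Returns
    -------
    RegionAreas
        Pixel-exact region areas plus the per-object assignment table with
        columns ``label, region, area_px, is_debris``.  Objects straddling
        regions are assigned to the region holding the majority of their
        pixels; ties go to "outside" and are logged.
    """
    rois.require(*REQUIRED_ROIS)
    yolk = rois["yolk"].mask
    trunk = rois["trunk"].mask
    if yolk.shape != objects.label_raster.shape:
        raise ValueError("ROI masks and label raster disagree on shape")

    fg = objects.foreground_mask(include_debris=False)
    n_fg = int(fg.sum())
    n_yolk = int((fg & yolk).sum())
    n_trunk = int((fg & trunk).sum())
    n_outside = n_fg - n_yolk - n_trunk
    # pixel conservation is structural; guard against regressions anyway
    assert n_outside >= 0 and n_yolk + n_trunk + n_outside == n_fg

    labels = objects.table["label"].to_numpy()
    flags = objects.table["is_debris"].to_numpy()
    # per-object pixel counts within each region, in one pass via bincount
    nbins = int(objects.label_raster.max()) + 1
    total_c = np.bincount(objects.label_raster.ravel(), minlength=nbins)
    yolk_c = np.bincount(objects.label_raster[yolk].ravel(), minlength=nbins)
    trunk_c = np.bincount(objects.label_raster[trunk].ravel(), minlength=nbins)
    outside_c = total_c - yolk_c - trunk_c

    rows = []
    for lab, debris in zip(labels, flags):
        counts = {
            "yolk": int(yolk_c[lab]),
            "trunk": int(trunk_c[lab]),
            "outside": int(outside_c[lab]),
        }
        best = max(counts.values())
        winners = [k for k, v in counts.items() if v == best]
        if len(winners) > 1:
            region = "outside"
            log.info("object %d ties between %s; assigned 'outside'", lab, winners)
        else:
            region = winners[0]
        rows.append(
            {
                "label": int(lab),
                "region": region,
                "area_px": int(total_c[lab]),
                "is_debris": bool(debris),
            }
        )
    assignments = pd.DataFrame(
        rows, columns=["label", "region", "area_px", "is_debris"]
    )

    return RegionAreas(
        yolk_area_px=n_yolk,
        trunk_area_px=n_trunk,
        outside_area_px=n_outside,
        pixel_size_um=pixel_size_um,
        assignments=assignments,
    )
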