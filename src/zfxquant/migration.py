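"""Coverage polygon and migration index.

Single-timepoint xenograft images cannot track individual cells, so dispersion
is scored geometrically: the *coverage polygon* through the peripheral tumor
cells measures the total range the cells have spread over, and dividing its
area by the tumor area itself removes the dependence on how many cells were
injected.  The resulting migration index is dimensionless and, under the
convention used here, always >= 1, with equality exactly when the tumor pixel
set is convex (a compact, un-migrated cell mass).

Convention: the coverage polygon is the convex hull of the *pixel squares* of
all non-debris foreground pixels — every pixel contributes its four corners.
This makes a single-pixel tumor well defined (its hull is the unit square,
index 1) and guarantees the hull contains the whole tumor pixel set.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy.spatial import ConvexHull

from .regions import RoiSet, measure_region_areas
from .segmentation import CellObjects

log = logging.getLogger(__name__)


class EmptyTumorError(ValueError):
    """No non-debris tumor pixels in the analysis region.

    Downstream metrics treat this as *missing*, never as zero: an empty
    region says the readout is unavailable, not that the cells covered zero
    area.
    """


def pixel_corner_points(mask: np.ndarray) -> np.ndarray:
    """Corner coordinates (row, col) of every true pixel's unit square."""
    rr, cc = np.nonzero(mask)
    corners = np.concatenate(
        [
            np.stack([rr, cc], axis=1),
            np.stack([rr + 1, cc], axis=1),
            np.stack([rr, cc + 1], axis=1),
            np.stack([rr + 1, cc + 1], axis=1),
        ]
    )
    return np.unique(corners, axis=0).astype(float)


def coverage_hull(
    objects: CellObjects,
    region_mask: np.ndarray | None = None,
    pixel_size_um: float = 1.0,
) -> tuple[np.ndarray, float]:
    """Convex hull of the non-debris tumor pixels in a region.

    Parameters
    ----------
    objects
        Segmented, debris-flagged objects.
    region_mask
        Boolean analysis region; ``None`` means the whole field.
    pixel_size_um
        Pixel edge length for µm² conversion.

    Returns
    -------
    (polygon, area_um2)
        Hull vertices as an ``(n, 2)`` (row, col) array in pixel-corner
        coordinates, counter-clockwise, and the enclosed area.

    Raises
    ------
    EmptyTumorError
        If no non-debris foreground pixel lies inside the region.
    """
    fg = objects.foreground_mask(include_debris=False)
    if region_mask is not None:
        fg = fg & region_mask
    if not fg.any():
        raise EmptyTumorError("no non-debris tumor pixels in the analysis region")

    pts = pixel_corner_points(fg)
    hull = ConvexHull(pts)
    polygon = pts[hull.vertices]
    # shoelace on the (integer) corner coordinates: exact in float64, so the
    # area is bit-identical under integer translation and 90-degree rotation
    area_px2 = _shoelace(polygon)
    return polygon, area_px2 * pixel_size_um**2


def _shoelace(vertices: np.ndarray) -> float:
    x, y = vertices[:, 0], vertices[:, 1]
    return 0.5 * abs(float(np.dot(x, np.roll(y, -1)) - np.dot(np.roll(x, -1), y)))


def migration_index(coverage_area_um2: float, tumor_area_um2: float) -> float:
    """Coverage-polygon area divided by tumor area.

    Raises :class:`EmptyTumorError` for zero tumor area — the index is then
    missing, with the reason logged by the caller.
    """
    if tumor_area_um2 <= 0:
        raise EmptyTumorError("tumor area is zero; migration index undefined")
    return coverage_area_um2 / tumor_area_um2


@dataclass
class XenograftMetrics:
    """Per-larva quantification record.

    ``tumor_area_um2`` is the non-debris foreground area inside the analysis
    region (the denominator of the migration index).  Fields are NaN with
    ``status != "ok"`` when the larva had no usable tumor signal.
    """

    larva_id: str
    group_label: str = ""
    yolk_area_um2: float = float("nan")
    trunk_area_um2: float = float("nan")
    tumor_area_um2: float = float("nan")
    coverage_hull_area_um2: float = float("nan")
    migration_index: float = float("nan")
    n_objects: int = 0
    n_debris: int = 0
    status: str = "ok"
    hull_polygon: np.ndarray | None = field(default=None, repr=False, compare=False)

    #: columns written to the metrics CSV, in order
    CSV_COLUMNS = (
        "larva_id",
        "group_label",
        "yolk_area_um2",
        "trunk_area_um2",
        "tumor_area_um2",
        "coverage_hull_area_um2",
        "migration_index",
        "n_objects",
        "n_debris",
        "status",
    )

    def as_row(self) -> dict:
        return {k: getattr(self, k) for k in self.CSV_COLUMNS}


def compute_metrics(
    objects: CellObjects,
    rois: RoiSet,
    pixel_size_um: float,
    larva_id: str = "",
    group_label: str = "",
    analysis_region: str = "yolk",
) -> XenograftMetrics:
    """Assemble the per-larva readouts.

    Region areas come from :func:`~zfxquant.regions.measure_region_areas`;
    the coverage hull and migration index are computed over the configured
    analysis region ("yolk" by default — the migration analysis is a
    yolk-region readout — or "all" for the whole field).

    An empty analysis region yields a record whose hull/index fields are
    missing and whose status is ``"empty_tumor"``.
    """
    areas = measure_region_areas(objects, rois, pixel_size_um)
    metrics = XenograftMetrics(
        larva_id=larva_id,
        group_label=group_label,
        yolk_area_um2=areas.yolk_area_um2,
        trunk_area_um2=areas.trunk_area_um2,
        n_objects=len(objects),
        n_debris=int(objects.table["is_debris"].sum()),
    )

    if analysis_region == "all":
        region_mask = None
    else:
        rois.require(analysis_region)
        region_mask = rois[analysis_region].mask

    fg = objects.foreground_mask(include_debris=False)
    if region_mask is not None:
        fg = fg & region_mask
    tumor_area_um2 = float(fg.sum()) * pixel_size_um**2

    try:
        polygon, hull_area = coverage_hull(objects, region_mask, pixel_size_um)
        metrics.tumor_area_um2 = tumor_area_um2
        metrics.coverage_hull_area_um2 = hull_area
        metrics.migration_index = migration_index(hull_area, tumor_area_um2)
        metrics.hull_polygon = polygon
    except EmptyTumorError as exc:
        log.info("larva %s: %s", larva_id or "<unnamed>", exc)
        metrics.status = "empty_tumor"
    return metrics
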