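"""Tumor-channel segmentation and size-based debris exclusion.

CM-DiI is a lipophilic membrane dye: besides intact labeled cancer cells it
also lights up sub-cellular debris (apoptotic bodies, exosomes, nonspecific
aggregates), which appears as isolated bright spots much smaller than a cell,
concentrated in the yolk.  Counting that signal as tumor inflates the
proliferation readout, so segmentation here is a two-stage contract: threshold
and label connected components first, then flag sub-cell-size objects as
debris.  Flagged objects are excluded from every downstream area and hull
computation but kept in the object table for audit.
"""

from __future__ import annotations

import logging
import math
import warnings
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from scipy import ndimage
from skimage.filters import threshold_otsu

from .image import LarvaImage
from .regions import RoiSet

log = logging.getLogger(__name__)


class DegenerateThresholdError(ValueError):
    """Automatic thresholding found no usable foreground/background split."""


@dataclass(frozen=True)
class ThresholdSpec:
    """How to binarize the tumor channel.

    method
        ``"fixed"`` uses ``value`` as the intensity cutoff (pixels strictly
        above are foreground).  ``"otsu"`` picks the cutoff by Otsu's method
        on the tumor channel restricted to the union of the ROI masks, which
        keeps background outside the larva from skewing the histogram.
    fallback
        Fixed cutoff used (with a warning) when the automatic method is
        degenerate — e.g. a blank negative-control larva whose histogram is
        unimodal.  Without a fallback the degenerate case raises.
    """

    method: str = "otsu"
    value: float | None = None
    fallback: float | None = None

    def __post_init__(self):
        if self.method not in ("fixed", "otsu"):
            raise ValueError(f"unknown threshold method {self.method!r}")
        if self.method == "fixed" and self.value is None:
            raise ValueError("fixed threshold needs a value")

    @classmethod
    def coerce(cls, spec) -> "ThresholdSpec":
        """Accept a ThresholdSpec, a bare number (fixed), or ``"otsu"``."""
        if isinstance(spec, cls):
            return spec
        if isinstance(spec, (int, float)) and not isinstance(spec, bool):
            return cls(method="fixed", value=float(spec))
        if spec == "otsu":
            return cls(method="otsu")
        raise ValueError(f"cannot interpret threshold spec {spec!r}")


#: columns of the per-object table, in output order
OBJECT_COLUMNS = [
    "label",
    "area_px",
    "centroid_row",
    "centroid_col",
    "bbox_rmin",
    "bbox_cmin",
    "bbox_rmax",
    "bbox_cmax",
    "mean_intensity",
    "is_debris",
]


@dataclass
class CellObjects:
    """Labeled connected foreground components of one tumor channel.

    ``label_raster`` assigns every foreground pixel to exactly one object
    (0 = background, labels 1..K contiguous).  ``table`` holds one row per
    object (see :data:`OBJECT_COLUMNS`); ``is_debris`` marks objects excluded
    from downstream quantification.
    """

    label_raster: np.ndarray
    table: pd.DataFrame
    threshold_used: float
    connectivity: int  # 1 = 4-connected, 2 = 8-connected

    def __post_init__(self):
        n_fg = int((self.label_raster > 0).sum())
        if int(self.table["area_px"].sum()) != n_fg:
            raise ValueError("object areas do not sum to the foreground pixel count")

    def __len__(self) -> int:
        return len(self.table)

    def foreground_mask(self, include_debris: bool = False) -> np.ndarray:
        """Boolean mask of object pixels, excluding debris by default."""
        if include_debris or self.table.empty:
            return self.label_raster > 0
        keep = self.table.loc[~self.table["is_debris"], "label"].to_numpy()
        return np.isin(self.label_raster, keep)

    def to_csv(self, path, pixel_size_um: float | None = None) -> None:
        out = self.table.copy()
        if pixel_size_um is not None:
            out.insert(2, "area_um2", out["area_px"] * pixel_size_um**2)
        out.to_csv(path, index=False)


def _connectivity_structure(connectivity: int) -> np.ndarray:
    if connectivity not in (1, 2):
        raise ValueError("connectivity must be 1 (4-conn) or 2 (8-conn)")
    return ndimage.generate_binary_structure(2, connectivity)


def label_mask(mask: np.ndarray, connectivity: int = 2) -> np.ndarray:
    """Label connected components of a boolean mask (labels 1..K)."""
    labeled, _ = ndimage.label(mask, structure=_connectivity_structure(connectivity))
    return labeled


def segment_tumor_channel(
    image: LarvaImage,
    threshold_spec=ThresholdSpec(),
    rois: RoiSet | None = None,
    connectivity: int = 2,
) -> CellObjects:
    """Segment CM-DiI-positive objects in the tumor channel.

    Pixels strictly above the threshold form the foreground, which is split
    into connected components (8-connected by default: anti-aliased disk
    edges fragment under 4-connectivity).  No debris flags are set here; see
    :func:`filter_debris`.

    Parameters
    ----------
    image
        Field with a ``"tumor"`` channel.
    threshold_spec
        A :class:`ThresholdSpec`, a number (fixed cutoff) or ``"otsu"``.
    rois
        When given and the method is automatic, the threshold is computed on
        tumor-channel pixels inside the union of the ROI masks only.
    connectivity
        1 for 4-connectivity, 2 for 8-connectivity.

    Raises
    ------
    DegenerateThresholdError
        If automatic thresholding yields an all-background or all-foreground
        image and the spec has no fixed fallback.
    """
    spec = ThresholdSpec.coerce(threshold_spec)
    tumor = image.tumor

    if spec.method == "fixed":
        thr = float(spec.value)
    else:
        sample = tumor[rois.union_mask()] if rois is not None else tumor.ravel()
        thr = _auto_threshold(sample, spec)

    mask = tumor > thr
    if spec.method != "fixed" and (not mask.any() or mask.all()):
        thr = _degenerate(spec, "thresholded image is all background or all foreground")
        mask = tumor > thr

    labeled = label_mask(mask, connectivity)
    table = _object_table(labeled, tumor)
    return CellObjects(
        label_raster=labeled, table=table, threshold_used=thr, connectivity=connectivity
    )


def _auto_threshold(sample: np.ndarray, spec: ThresholdSpec) -> float:
    if sample.size == 0:
        return _degenerate(spec, "empty ROI sample for automatic threshold")
    if sample.min() == sample.max():
        return _degenerate(spec, "constant-intensity image (unimodal histogram)")
    return float(threshold_otsu(sample))


def _degenerate(spec: ThresholdSpec, reason: str) -> float:
    if spec.fallback is None:
        raise DegenerateThresholdError(f"{reason}; no fixed fallback configured")
    warnings.warn(
        f"automatic threshold degenerate ({reason}); "
        f"falling back to fixed threshold {spec.fallback}",
        stacklevel=3,
    )
    return float(spec.fallback)


def _object_table(labeled: np.ndarray, intensity: np.ndarray) -> pd.DataFrame:
    n = int(labeled.max())
    if n == 0:
        return pd.DataFrame(columns=OBJECT_COLUMNS).astype(
            {"label": int, "area_px": int, "is_debris": bool}
        )
    idx = np.arange(1, n + 1)
    areas = ndimage.sum_labels(np.ones_like(labeled), labeled, idx).astype(int)
    centroids = ndimage.center_of_mass(np.ones_like(labeled), labeled, idx)
    means = ndimage.mean(intensity, labeled, idx)
    slices = ndimage.find_objects(labeled)
    rows = []
    for i, lab in enumerate(idx):
        sl = slices[lab - 1]
        rows.append(
            {
                "label": int(lab),
                "area_px": int(areas[i]),
                "centroid_row": float(centroids[i][0]),
                "centroid_col": float(centroids[i][1]),
                "bbox_rmin": sl[0].start,
                "bbox_cmin": sl[1].start,
                "bbox_rmax": sl[0].stop,
                "bbox_cmax": sl[1].stop,
                "mean_intensity": float(means[i]),
                "is_debris": False,
            }
        )
    return pd.DataFrame(rows, columns=OBJECT_COLUMNS)


def filter_debris(
    objects: CellObjects, min_cell_area_um2: float, pixel_size_um: float
) -> CellObjects:
    """Flag sub-cell-size objects as debris.

    Objects whose pixel area falls strictly below
    ``min_cell_area_um2 / pixel_size_um**2`` get ``is_debris = True``.  The
    raster and table are otherwise untouched, so flagged spots stay auditable.
    """
    if min_cell_area_um2 < 0:
        raise ValueError("min_cell_area_um2 must be >= 0")
    min_px = min_cell_area_um2 / pixel_size_um**2
    table = objects.table.copy()
    table["is_debris"] = table["area_px"] < min_px
    n = int(table["is_debris"].sum())
    if n:
        log.info("flagged %d/%d objects as debris (< %.1f px)", n, len(table), min_px)
    return replace(objects, table=table)


def default_min_cell_area_um2(cell_diameter_um: float, fraction: float = 0.25) -> float:
    """Default debris cutoff: a fraction of the nominal cell cross-section.

    With the default ``fraction`` of 0.25, anything smaller than a quarter of
    the area implied by the configured cell diameter is treated as debris —
    a relative rule, so the behavior is independent of the acquisition
    dialect's pixel size.
    """
    if cell_diameter_um <= 0:
        raise ValueError("cell_diameter_um must be positive")
    return fraction * math.pi * (cell_diameter_um / 2.0) ** 2
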