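"""Image container and TIFF input/output.

A :class:`LarvaImage` holds the named 2-D channel rasters of one acquired (or
simulated) larva field together with its physical pixel size and an acquisition
dialect tag.  The tumor channel carries the CM-DiI (red membrane dye) signal of
the transplanted cells; an optional vasculature channel carries EGFP signal from
endothelial reporter lines.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import tifffile

TUMOR = "tumor"
VASCULATURE = "vasculature"

#: (rows, cols) of the two acquisition dialects: stereomicroscope fields and
#: confocal fields.
DIALECT_SHAPES = {
    "stereo": (1200, 1600),
    "confocal": (1024, 1024),
}


@dataclass
class LarvaImage:
    """One two-dimensional multi-channel larva field.

    Parameters
    ----------
    channels
        Mapping of channel name to 2-D raster (uint8 or uint16).  Must contain
        at least the ``"tumor"`` channel for quantification.
    pixel_size_um
        Physical edge length of one pixel in micrometres.
    dialect
        Acquisition tag: ``"stereo"``, ``"confocal"`` or ``"custom"``.
    """

    channels: dict[str, np.ndarray]
    pixel_size_um: float
    dialect: str = "custom"
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.channels:
            raise ValueError("LarvaImage needs at least one channel")
        shapes = {ch.shape for ch in self.channels.values()}
        if len(shapes) != 1:
            raise ValueError(f"channels disagree on shape: {shapes}")
        if any(ch.ndim != 2 for ch in self.channels.values()):
            raise ValueError("channels must be 2-D rasters")
        if not self.pixel_size_um > 0:
            raise ValueError("pixel_size_um must be positive")

    @property
    def shape(self) -> tuple[int, int]:
        return next(iter(self.channels.values())).shape

    @property
    def tumor(self) -> np.ndarray:
        try:
            return self.channels[TUMOR]
        except KeyError:
            raise KeyError("image has no 'tumor' channel") from None


def write_larva_tiff(image: LarvaImage, path: str | Path) -> None:
    """Write a :class:`LarvaImage` as a multi-page TIFF, one page per channel.

    Channel names, pixel size and dialect are stored in the ImageDescription
    tag as JSON so the file round-trips through :func:`read_larva_tiff`.
    """
    path = Path(path)
    names = sorted(image.channels)
    stack = np.stack([image.channels[n] for n in names])
    desc = json.dumps(
        {
            "channels": names,
            "pixel_size_um": image.pixel_size_um,
            "dialect": image.dialect,
        }
    )
    tifffile.imwrite(path, stack, description=desc)


def read_larva_tiff(
    path: str | Path,
    pixel_size_um: float | None = None,
    dialect: str | None = None,
) -> LarvaImage:
    """Read a larva field from TIFF.

    Files written by :func:`write_larva_tiff` restore channel names and pixel
    size from their metadata.  For third-party TIFFs the first page (or a lone
    2-D image) is taken as the tumor channel, a second page as vasculature, and
    ``pixel_size_um`` must be given.
    """
    path = Path(path)
    with tifffile.TiffFile(path) as tf:
        arr = tf.asarray()
        desc = tf.pages[0].description

    meta = {}
    if desc:
        try:
            meta = json.loads(desc)
        except (json.JSONDecodeError, TypeError):
            meta = {}

    if arr.ndim == 2:
        arr = arr[None]
    names = meta.get("channels")
    if not names or len(names) != arr.shape[0]:
        names = [TUMOR, VASCULATURE][: arr.shape[0]]
        names += [f"channel{i}" for i in range(len(names), arr.shape[0])]
    px = pixel_size_um if pixel_size_um is not None else meta.get("pixel_size_um")
    if px is None:
        raise ValueError(f"{path}: pixel size not in metadata; pass pixel_size_um")
    return LarvaImage(
        channels={n: arr[i] for i, n in enumerate(names)},
        pixel_size_um=float(px),
        dialect=dialect or meta.get("dialect", "custom"),
    )
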