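"""Run orchestration: simulation/manifest input -> metrics CSV -> comparisons.

A run is described by a :class:`RunConfig` that round-trips losslessly through
JSON, so every emitted run log can reconstruct its run.  Per-larva failures
are recorded as error rows and never abort a cohort.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import synthetic
from .image import LarvaImage, read_larva_tiff
from .migration import XenograftMetrics, compute_metrics
from .regions import RoiSet
from .segmentation import (
    ThresholdSpec,
    default_min_cell_area_um2,
    filter_debris,
    segment_tumor_channel,
)
from .stats import compare_groups, summarize_groups

log = logging.getLogger(__name__)

METRICS_CSV = "metrics.csv"
RUN_LOG_JSON = "run_log.json"


@dataclass
class RunConfig:
    """Everything needed to reproduce one quantification run.

    Exactly one of ``design`` (a simulated cohort) or ``manifest`` (a list of
    records with ``larva_id, group_label, image_path`` and optional
    ``roi_path, pixel_size_um``) drives the run.
    """

    design: synthetic.CohortDesign | None = None
    manifest: list[dict] | None = None
    threshold_method: str = "otsu"
    threshold_value: float | None = None
    threshold_fallback: float | None = None
    cell_diameter_um: float = 10.0
    min_cell_area_um2: float | None = None  # None -> default rule
    analysis_region: str = "yolk"
    connectivity: int = 2
    pixel_size_um: float | None = None  # manifest fallback
    out_dir: str | None = None
    write_overlays: bool = False
    seed: int = 0

    def threshold_spec(self) -> ThresholdSpec:
        return ThresholdSpec(
            method=self.threshold_method,
            value=self.threshold_value,
            fallback=self.threshold_fallback,
        )

    def resolved_min_cell_area_um2(self) -> float:
        if self.min_cell_area_um2 is not None:
            return self.min_cell_area_um2
        return default_min_cell_area_um2(self.cell_diameter_um)

    # -- lossless JSON round trip -----------------------------------------

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        if self.design is not None:
            d["design"] = dataclasses.asdict(self.design)
        return d

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=1))

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        d = dict(d)
        if d.get("design") is not None:
            dd = dict(d["design"])
            bp = dict(dd["base_params"])
            bp["image_shape"] = tuple(bp["image_shape"])
            for key in ("cell_radius_um", "cell_intensity"):
                bp[key] = tuple(bp[key])
            dd["base_params"] = synthetic.SimulationParams(**bp)
            dd["groups"] = tuple(
                synthetic.GroupSpec(**g) for g in dd["groups"]
            )
            d["design"] = synthetic.CohortDesign(**dd)
        return cls(**d)

    @classmethod
    def from_json(cls, path: str | Path) -> "RunConfig":
        return cls.from_dict(json.loads(Path(path).read_text()))

    def config_hash(self) -> str:
        return hashlib.sha256(
            json.dumps(self.to_dict(), sort_keys=True).encode()
        ).hexdigest()[:16]


def quantify_larva(
    image: LarvaImage,
    rois: RoiSet,
    config: RunConfig,
    larva_id: str = "",
    group_label: str = "",
) -> XenograftMetrics:
    """Segment, debris-filter, and measure one larva field."""
    objects = segment_tumor_channel(
        image, config.threshold_spec(), rois=rois, connectivity=config.connectivity
    )
    objects = filter_debris(
        objects, config.resolved_min_cell_area_um2(), image.pixel_size_um
    )
    return compute_metrics(
        objects,
        rois,
        image.pixel_size_um,
        larva_id=larva_id,
        group_label=group_label,
        analysis_region=config.analysis_region,
    )


def _iter_inputs(config: RunConfig):
    """Yield (larva_id, group_label, loader) per input larva.

    The loader defers image/ROI acquisition so that a broken input file is a
    per-larva failure inside :func:`run_quantify`, not a cohort abort.
    """
    if (config.design is None) == (config.manifest is None):
        raise ValueError("config needs exactly one of design or manifest")
    if config.design is not None:
        for sample in synthetic.generate_cohort(config.design):
            yield (
                sample.larva_id,
                sample.group_label,
                lambda s=sample: (s.image, s.rois),
            )
    else:
        for rec in config.manifest:
            larva_id = str(rec.get("larva_id", rec["image_path"]))
            group = str(rec.get("group_label", ""))

            def load(rec=rec):
                image = read_larva_tiff(
                    rec["image_path"],
                    pixel_size_um=rec.get("pixel_size_um", config.pixel_size_um),
                )
                roi_path = rec.get("roi_path")
                if roi_path:
                    rois = RoiSet.from_json(roi_path, image.shape)
                else:
                    rois = synthetic.template_rois(image.shape)
                return image, rois

            yield larva_id, group, load


def run_quantify(config: RunConfig) -> pd.DataFrame:
    """Quantify every larva of a run; returns (and optionally writes) metrics.

    One row per larva (columns per :class:`XenograftMetrics`); larvae whose
    processing raised are kept as rows with ``status = "error: ..."`` and
    missing metric fields.  With ``config.out_dir`` set, writes
    ``metrics.csv``, a machine-readable ``run_log.json`` (config echo, config
    hash, seed, per-larva status) and optional QC overlay PNGs.
    """
    out_dir = Path(config.out_dir) if config.out_dir else None
    if out_dir:
        out_dir.mkdir(parents=True, exist_ok=True)

    rows = []
    statuses = []
    for larva_id, group, load in _iter_inputs(config):
        try:
            image, rois = load()
            metrics = quantify_larva(image, rois, config, larva_id, group)
            if out_dir and config.write_overlays:
                _write_overlay(out_dir / f"{larva_id}_overlay.png", image, rois, config, metrics)
        except Exception as exc:  # per-larva isolation is the contract
            log.error("larva %s failed: %s", larva_id, exc)
            metrics = XenograftMetrics(
                larva_id=larva_id, group_label=group, status=f"error: {exc}"
            )
        rows.append(metrics.as_row())
        statuses.append({"larva_id": larva_id, "status": metrics.status})

    table = pd.DataFrame(rows, columns=list(XenograftMetrics.CSV_COLUMNS))
    if out_dir:
        table.to_csv(out_dir / METRICS_CSV, index=False)
        run_log = {
            "config": config.to_dict(),
            "config_hash": config.config_hash(),
            "seed": config.seed,
            "larvae": statuses,
        }
        (out_dir / RUN_LOG_JSON).write_text(json.dumps(run_log, indent=1))
    return table


def _write_overlay(path, image, rois, config, metrics) -> None:
    """QC overlay: tumor channel with object outlines, hull, ROI boundaries."""
    import imageio.v3 as iio
    from skimage.draw import polygon_perimeter
    from skimage.segmentation import find_boundaries

    tumor = image.tumor.astype(float)
    hi = max(tumor.max(), 1.0)
    rgb = np.stack([(tumor / hi * 255).astype(np.uint8)] * 3, axis=-1)

    objects = segment_tumor_channel(
        image, config.threshold_spec(), rois=rois, connectivity=config.connectivity
    )
    objects = filter_debris(
        objects, config.resolved_min_cell_area_um2(), image.pixel_size_um
    )
    rgb[find_boundaries(objects.foreground_mask(include_debris=False))] = (0, 255, 0)
    rgb[find_boundaries(objects.foreground_mask(include_debris=True) & ~objects.foreground_mask())] = (80, 120, 255)
    for roi in rois.rois.values():
        rr, cc = polygon_perimeter(
            roi.vertices[:, 0], roi.vertices[:, 1], shape=rgb.shape[:2], clip=True
        )
        rgb[rr, cc] = (255, 255, 0)
    if metrics.hull_polygon is not None:
        rr, cc = polygon_perimeter(
            metrics.hull_polygon[:, 0],
            metrics.hull_polygon[:, 1],
            shape=rgb.shape[:2],
            clip=True,
        )
        rgb[rr, cc] = (255, 0, 0)
    iio.imwrite(path, rgb)


# ---------------------------------------------------------------------------
# end-to-end demo


DEMO_METRICS = ("yolk_area_um2", "trunk_area_um2", "migration_index")


def run_end_to_end_demo(
    seed: int = 0,
    out_dir: str | Path | None = None,
    n_per_group: int = 20,
    proliferation: float = 0.6,
    invasion: float = 0.6,
    dispersion: float = 0.5,
    base_params: synthetic.SimulationParams | None = None,
) -> dict:
    """Simulate an NC-vs-knockdown cohort, quantify it, compare the groups.

    The knockdown arm carries the given effect multipliers (< 1 = inhibition).
    Returns a report dict with per-group summaries, Student's t comparisons
    and, for each metric, whether the programmed direction of effect
    (knockdown lower) was recovered.  With ``out_dir``, the metrics CSV, run
    log and ``report.json`` are written.
    """
    design = synthetic.CohortDesign(
        groups=(
            synthetic.GroupSpec("NC", n_per_group),
            synthetic.GroupSpec(
                "si",
                n_per_group,
                proliferation=proliferation,
                invasion=invasion,
                dispersion=dispersion,
            ),
        ),
        base_params=base_params or synthetic.SimulationParams(),
        seed=seed,
    )
    config = RunConfig(design=design, seed=seed, out_dir=str(out_dir) if out_dir else None)
    table = run_quantify(config)

    report: dict = {"seed": seed, "n_per_group": n_per_group, "metrics": {}}
    ok = table[table["status"] == "ok"]
    for metric in DEMO_METRICS:
        summaries = {s.group_name: s for s in summarize_groups(ok, metric)}
        cmp_res = compare_groups(ok, metric, "NC", "si")
        report["metrics"][metric] = {
            "NC_mean": summaries["NC"].mean,
            "NC_sem": summaries["NC"].sem,
            "si_mean": summaries["si"].mean,
            "si_sem": summaries["si"].sem,
            "t": cmp_res.t_statistic,
            "df": cmp_res.degrees_of_freedom,
            "p": cmp_res.p_value,
            "stars": cmp_res.stars,
            "knockdown_lower": bool(summaries["si"].mean < summaries["NC"].mean),
        }
    if out_dir:
        (Path(out_dir) / "report.json").write_text(json.dumps(report, indent=1))
    return report
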