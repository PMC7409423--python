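"""ROI rasterization vs ray-cast oracle; pixel-exact region accounting."""

import dataclasses

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from oracles import raycast_mask
from zfxquant import (
    GeometryError,
    LarvaImage,
    RoiSet,
    filter_debris,
    generate_larva,
    measure_region_areas,
    rasterize_polygon,
    segment_tumor_channel,
    template_rois,
)
from zfxquant.synthetic import rasterize_disk_pixels


def test_axis_aligned_rectangle_covers_exact_pixel_count():
    rect = np.array([[0, 0], [0, 20], [10, 20], [10, 0]])
    mask = rasterize_polygon(rect, (32, 32))
    assert mask.sum() == 200
    assert mask[:10, :20].all()


def test_degenerate_polygons_rejected():
    with pytest.raises(GeometryError):
        rasterize_polygon(np.empty((0, 2)), (16, 16))
    with pytest.raises(GeometryError):
        rasterize_polygon(np.array([[0, 0], [5, 5]]), (16, 16))
    bowtie = np.array([[0, 0], [10, 10], [0, 10], [10, 0]])
    with pytest.raises(GeometryError):
        rasterize_polygon(bowtie, (16, 16))


@given(seed=st.integers(0, 10_000))
def test_random_simple_polygon_matches_raycast_oracle(seed):
    """Star-shaped random polygons (always simple) rasterize identically to
    an exhaustive per-pixel even-odd ray-cast."""
    rng = np.random.default_rng(seed)
    n = rng.integers(3, 12)
    angles = np.sort(rng.uniform(0, 2 * np.pi, n))
    radii = rng.uniform(3.0, 14.0, n)
    center = rng.uniform(10.0, 22.0, 2)
    verts = np.stack(
        [center[0] + radii * np.sin(angles), center[1] + radii * np.cos(angles)], axis=1
    )
    mask = rasterize_polygon(verts, (32, 32))
    assert np.array_equal(mask, raycast_mask(verts, (32, 32)))


def test_roiset_requires_disjoint_yolk_and_trunk():
    a = np.array([[0, 0], [0, 10], [10, 10], [10, 0]])
    b = np.array([[5, 5], [5, 15], [15, 15], [15, 5]])
    with pytest.raises(GeometryError, match="overlap"):
        RoiSet.from_polygons({"yolk": a, "trunk": b}, (20, 20))


def test_roiset_json_round_trip(tmp_path):
    rois = template_rois((64, 64))
    rois.to_json(tmp_path / "rois.json")
    back = RoiSet.from_json(tmp_path / "rois.json", (64, 64))
    for name in ("yolk", "trunk"):
        assert np.array_equal(back[name].mask, rois[name].mask)


def _objects_from_mask(mask, intensity=1000.0, min_area=0.0):
    img = LarvaImage(
        channels={"tumor": (mask * intensity).astype(np.uint16)}, pixel_size_um=1.0
    )
    objs = segment_tumor_channel(img, threshold_spec=intensity / 2)
    return filter_debris(objs, min_area, 1.0)


def test_no_objects_gives_zero_region_areas():
    rois = template_rois((64, 64))
    areas = measure_region_areas(_objects_from_mask(np.zeros((64, 64), bool)), rois, 2.0)
    assert areas.yolk_area_um2 == 0 and areas.trunk_area_um2 == 0
    assert areas.assignments.empty


def test_single_object_inside_yolk_scales_by_pixel_size():
    rois = template_rois((64, 64))
    rr, cc = np.nonzero(rois["yolk"].mask)
    r0, c0 = int(rr.mean()) - 5, int(cc.mean()) - 5  # block at the yolk center
    mask = np.zeros((64, 64), bool)
    mask[r0 : r0 + 10, c0 : c0 + 10] = True
    assert (mask <= rois["yolk"].mask).all()  # fully inside yolk
    areas = measure_region_areas(_objects_from_mask(mask), rois, pixel_size_um=2.0)
    assert areas.yolk_area_px == 100
    assert areas.yolk_area_um2 == 400.0
    assert areas.assignments["region"].tolist() == ["yolk"]


def test_pixel_conservation_across_regions(fast_params):
    image, _, rois = generate_larva(fast_params)
    objs = filter_debris(segment_tumor_channel(image, threshold_spec=4000.0), 20.0, 1.0)
    areas = measure_region_areas(objs, rois, 1.0)
    n_fg = int(objs.foreground_mask().sum())
    assert areas.yolk_area_px + areas.trunk_area_px + areas.outside_area_px == n_fg


def test_measured_yolk_area_matches_truth_in_overlap_free_scene(fast_params):
    """With no disk overlap, pixel-exact union area equals the additive truth."""
    params = dataclasses.replace(
        fast_params,
        n_cells=15,
        cell_radius_um=(3.5, 0.2),
        cell_intensity=(10000.0, 0.0),
        dispersion_sigma_um=60.0,
        migrating_fraction=1.0,  # spread everything out: no disk contact
        trunk_fraction=0.0,
        n_debris=0,
        yolk_autofluor_level=0.0,
        noise_sd=0.0,
        seed=12,
    )
    image, truth, rois = generate_larva(params)
    union = np.zeros(params.image_shape, bool)
    total = 0
    for r, c, rad, _ in truth.cells:
        ii, jj = rasterize_disk_pixels(r, c, rad, params.image_shape)
        union[ii, jj] = True
        total += len(ii)
    assert union.sum() == total  # scene guard: no overlapping disks

    objs = segment_tumor_channel(image, threshold_spec=5000.0)
    areas = measure_region_areas(objs, rois, params.pixel_size_um)
    assert areas.trunk_area_px == truth.true_trunk_area_px == 0
    assert areas.yolk_area_px == truth.true_yolk_area_px


def test_translation_equivariance_of_region_areas():
    rois = template_rois((96, 96))
    mask = np.zeros((96, 96), bool)
    mask[40:50, 20:32] = True
    base = measure_region_areas(_objects_from_mask(mask), rois, 1.0)

    dr, dc = 7, 5
    shifted_mask = np.roll(np.roll(mask, dr, axis=0), dc, axis=1)
    shifted_polys = {
        name: np.asarray(rois[name].vertices) + [dr, dc] for name in ("yolk", "trunk")
    }
    shifted_rois = RoiSet.from_polygons(shifted_polys, (96, 96))
    moved = measure_region_areas(_objects_from_mask(shifted_mask), shifted_rois, 1.0)
    assert (moved.yolk_area_px, moved.trunk_area_px, moved.outside_area_px) == (
        base.yolk_area_px,
        base.trunk_area_px,
        base.outside_area_px,
    )


def test_missing_required_roi_is_a_configuration_error():
    square = np.array([[0, 0], [0, 10], [10, 10], [10, 0]])
    rois = RoiSet.from_polygons({"yolk": square}, (32, 32))
    with pytest.raises(KeyError, match="trunk"):
        measure_region_areas(_objects_from_mask(np.zeros((32, 32), bool)), rois, 1.0)


def test_object_straddling_tie_goes_to_outside():
    # object half inside yolk, half outside, equal pixel counts -> "outside"
    yolk = np.array([[0, 0], [0, 8], [16, 8], [16, 0]])
    trunk = np.array([[0, 20], [0, 30], [16, 30], [16, 20]])
    rois = RoiSet.from_polygons({"yolk": yolk, "trunk": trunk}, (16, 32))
    mask = np.zeros((16, 32), bool)
    mask[4:8, 6:10] = True  # 8 px in yolk (cols 6,7), 8 px outside (cols 8,9)
    areas = measure_region_areas(_objects_from_mask(mask), rois, 1.0)
    assert areas.assignments["region"].tolist() == ["outside"]
    assert areas.yolk_area_px == 8 and areas.outside_area_px == 8
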