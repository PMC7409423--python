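"""Simulator: determinism, placement constraints, ground-truth consistency."""

import dataclasses

import numpy as np
import pytest

from zfxquant import (
    CohortDesign,
    GroundTruth,
    GroupSpec,
    SimulationParams,
    generate_cohort,
    generate_larva,
    template_rois,
)
from zfxquant.synthetic import group_params, larva_seed, rasterize_disk_pixels


def test_empty_scene_renders_identically_zero(fast_params):
    params = dataclasses.replace(
        fast_params, n_cells=0, n_debris=0, yolk_autofluor_level=0.0, noise_sd=0.0
    )
    image, truth, _ = generate_larva(params)
    assert not image.tumor.any()
    assert truth.cells == [] and truth.debris == []
    assert truth.true_yolk_area_px == 0 and truth.true_trunk_area_px == 0


def test_zero_trunk_fraction_places_all_cells_in_yolk(fast_params):
    params = dataclasses.replace(fast_params, n_cells=50, trunk_fraction=0.0)
    _, truth, rois = generate_larva(params)
    assert len(truth.cells) == 50
    assert all(lab == "yolk" for *_, lab in truth.cells)
    # placement invariant: every centroid lies inside its region's polygon
    import shapely
    from shapely.geometry import Polygon

    for r, c, _, lab in truth.cells:
        poly = Polygon(np.asarray(rois[lab].vertices)[:, ::-1])
        assert shapely.contains_xy(poly, c, r)


def test_same_params_and_seed_reproduce_bit_identical_output(fast_params):
    img1, truth1, _ = generate_larva(fast_params)
    img2, truth2, _ = generate_larva(fast_params)
    for ch in img1.channels:
        assert np.array_equal(img1.channels[ch], img2.channels[ch])
    assert truth1.cells == truth2.cells
    assert truth1.debris == truth2.debris
    assert truth1.true_hull_area_px == truth2.true_hull_area_px


def test_different_seeds_differ(fast_params):
    img1, _, _ = generate_larva(fast_params)
    img2, _, _ = generate_larva(dataclasses.replace(fast_params, seed=99))
    assert not np.array_equal(img1.tumor, img2.tumor)


def test_truth_areas_match_independent_per_cell_rasterization(fast_params):
    """Re-rasterizing each listed cell disk reproduces the true areas exactly."""
    _, truth, rois = generate_larva(fast_params)
    yolk, trunk = rois["yolk"].mask, rois["trunk"].mask
    got_yolk = got_trunk = 0
    for r, c, rad, _ in truth.cells:
        # brute force, whole-field pixel-center containment
        rr, cc = np.meshgrid(
            np.arange(yolk.shape[0]) + 0.5, np.arange(yolk.shape[1]) + 0.5, indexing="ij"
        )
        disk = np.hypot(rr - r, cc - c) <= rad
        got_yolk += int((disk & yolk).sum())
        got_trunk += int((disk & trunk).sum())
    assert got_yolk == truth.true_yolk_area_px
    assert got_trunk == truth.true_trunk_area_px


def test_debris_disks_are_separate_from_cells_and_each_other(fast_params):
    _, truth, _ = generate_larva(fast_params)
    cells = np.array([[r, c, rad] for r, c, rad, _ in truth.cells])
    debris = np.array(truth.debris)
    assert len(debris) == fast_params.n_debris
    for r, c, rad in debris:
        d = np.hypot(cells[:, 0] - r, cells[:, 1] - c)
        assert np.all(d > cells[:, 2] + rad)
    for i in range(len(debris)):
        for j in range(i + 1, len(debris)):
            d = np.hypot(debris[i, 0] - debris[j, 0], debris[i, 1] - debris[j, 1])
            assert d > debris[i, 2] + debris[j, 2]


@pytest.mark.parametrize(
    "bad",
    [
        dict(image_shape=(0, 256)),
        dict(n_cells=-1),
        dict(trunk_fraction=1.5),
        dict(cell_radius_um=(-1.0, 0.1)),
        dict(debris_radius_um=10.0),  # not smaller than cells
        dict(pixel_size_um=0.0),
    ],
)
def test_invalid_params_rejected(fast_params, bad):
    with pytest.raises(ValueError):
        dataclasses.replace(fast_params, **bad)


def test_params_and_truth_json_round_trip(tmp_path, fast_params):
    fast_params.to_json(tmp_path / "p.json")
    assert SimulationParams.from_json(tmp_path / "p.json") == fast_params
    _, truth, _ = generate_larva(fast_params)
    truth.to_json(tmp_path / "t.json")
    back = GroundTruth.from_json(tmp_path / "t.json")
    assert back.cells == truth.cells
    assert back.true_hull_area_px == truth.true_hull_area_px
    assert back.params == fast_params


def test_cohort_bookkeeping_counts_and_labels(fast_params):
    design = CohortDesign(
        groups=(GroupSpec("A", 3), GroupSpec("B", 4, proliferation=0.5)),
        base_params=fast_params,
        seed=5,
    )
    samples = list(generate_cohort(design))
    assert [s.group_label for s in samples] == ["A"] * 3 + ["B"] * 4
    assert len({s.larva_id for s in samples}) == 7
    # proliferation multiplier scales the realized cell count
    assert all(len(s.truth.cells) == fast_params.n_cells for s in samples[:3])
    assert all(len(s.truth.cells) == fast_params.n_cells // 2 for s in samples[3:])


def test_empty_cohort_rejected(fast_params):
    with pytest.raises(ValueError):
        CohortDesign(groups=(), base_params=fast_params)


def test_per_larva_seeds_are_order_independent():
    assert larva_seed(3, 1, 5) == larva_seed(3, 1, 5)
    seeds = {larva_seed(3, g, i) for g in range(3) for i in range(10)}
    assert len(seeds) == 30


def test_group_params_scale_the_programmed_knobs(fast_params):
    g = GroupSpec("si", 1, proliferation=0.5, invasion=2.0, dispersion=0.5)
    p = group_params(fast_params, g, seed=11)
    assert p.n_cells == round(fast_params.n_cells * 0.5)
    assert p.trunk_fraction == pytest.approx(fast_params.trunk_fraction * 2.0)
    assert p.dispersion_sigma_um == pytest.approx(fast_params.dispersion_sigma_um * 0.5)
    assert p.seed == 11


def test_template_rois_are_disjoint_and_scale_with_shape():
    for shape in [(256, 256), (1200, 1600)]:
        rois = template_rois(shape)
        assert not (rois["yolk"].mask & rois["trunk"].mask).any()
        assert rois["yolk"].area_px > 0 and rois["trunk"].area_px > 0
        assert rois["yolk"].mask.shape == shape


def test_rasterize_disk_pixels_matches_analytic_counts():
    # radius 0.9 captures only the center pixel; 1.2 adds the 4-neighborhood
    # (diagonal centers sit at distance sqrt(2) and stay outside)
    ii, jj = rasterize_disk_pixels(10.5, 10.5, 0.9, (21, 21))
    assert len(ii) == 1
    ii, jj = rasterize_disk_pixels(10.5, 10.5, 1.2, (21, 21))
    assert len(ii) == 5
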