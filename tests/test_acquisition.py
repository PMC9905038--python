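"""Position planning, stitching, flat-field correction, pyramid export and
annotation geometry."""

import dataclasses
import json

import numpy as np
import pytest

import autoscope as a


# ---------------------------------------------------------------------------
# position lists
# ---------------------------------------------------------------------------


def test_prescan_grid_matches_ceiling_arithmetic():
    """10 x 10 mm slide at the 4x FOV with no overlap: 9 x 7 = 63 tiles."""
    s4 = a.ScanSettings.bf_4x()
    pos = a.generate_position_list((0, 0, 10_000, 10_000), s4, 0.0)
    nx = int(np.ceil(10_000 / s4.fov_width_um))
    ny = int(np.ceil(10_000 / s4.fov_height_um))
    assert (nx, ny) == (9, 7)
    assert len(pos.entries) == 63


def test_grid_covers_bounds():
    s4 = a.ScanSettings.bf_4x()
    bounds = (100, 200, 8000, 9000)
    pos = a.generate_position_list(bounds, s4, 0.0)
    x0 = min(e.x_um - s4.fov_width_um / 2 for e in pos.entries)
    x1 = max(e.x_um + s4.fov_width_um / 2 for e in pos.entries)
    y0 = min(e.y_um - s4.fov_height_um / 2 for e in pos.entries)
    y1 = max(e.y_um + s4.fov_height_um / 2 for e in pos.entries)
    assert x0 <= bounds[0] and y0 <= bounds[1]
    assert x1 >= bounds[2] and y1 >= bounds[3]


def test_grid_serpentine_order():
    s4 = a.ScanSettings.bf_4x()
    pos = a.generate_position_list((0, 0, 4000, 4000), s4, 0.0)
    rows = {}
    for i, e in enumerate(pos.entries):
        rows.setdefault(round(e.y_um, 3), []).append((i, e.x_um))
    for r, (y, items) in enumerate(sorted(rows.items())):
        xs = [x for _, x in items]
        assert xs == sorted(xs, reverse=bool(r % 2))


def test_overlap_shrinks_step():
    s4 = a.ScanSettings.bf_4x()
    p0 = a.generate_position_list((0, 0, 10_000, 10_000), s4, 0.0)
    p1 = a.generate_position_list((0, 0, 10_000, 10_000), s4, 0.2)
    assert len(p1.entries) > len(p0.entries)


def test_bounds_smaller_than_fov_single_center():
    s4 = a.ScanSettings.bf_4x()
    pos = a.generate_position_list((0, 0, 500, 500), s4, 0.0)
    assert len(pos.entries) == 1
    assert pos.entries[0].x_um == pytest.approx(250.0)


def test_position_list_dedupe_and_csv_round_trip(tmp_path):
    entries = [a.PositionEntry(1.0, 2.0, 3.0, "a"),
               a.PositionEntry(1.0, 2.0, 3.0, "a"),  # exact duplicate
               a.PositionEntry(1.0, 2.0, 3.0, "b")]  # distinct tag survives
    plist = a.PositionList(entries)
    assert len(plist.entries) == 2
    path = tmp_path / "pos.csv"
    plist.to_csv(path)
    assert path.read_text().splitlines()[0] == "x_um,y_um,z_um,tag"
    back = a.PositionList.from_csv(path)
    assert [(e.x_um, e.y_um, e.z_um, e.tag) for e in back.entries] == \
           [(1.0, 2.0, 3.0, "a"), (1.0, 2.0, 3.0, "b")]


# ---------------------------------------------------------------------------
# background / flat-field
# ---------------------------------------------------------------------------


def test_estimate_background_selects_low_saturation_frames(small_phantom):
    st = a.ScanSettings.bf_4x().with_z(50.0)
    core = small_phantom.cores[0]
    bg_frame = a.render_bf(small_phantom, st, 150.0, 150.0, seed=0)
    tissue = a.render_bf(small_phantom, st, core.cx, core.cy, seed=0)
    bg = a.estimate_background([bg_frame, tissue])
    np.testing.assert_allclose(bg, bg_frame.pixels)  # only the empty frame kept


def test_estimate_background_raises_without_background(small_phantom):
    core = small_phantom.cores[0]
    st = a.ScanSettings.bf_20x().with_z(a.true_focus(small_phantom, core.cx, core.cy))
    tissue = a.render_bf(small_phantom, st, core.cx, core.cy, seed=0)
    with pytest.raises(ValueError, match="saturation threshold"):
        a.estimate_background([tissue])


def test_flatfield_correction_flattens_vignette(small_phantom):
    st = a.ScanSettings.bf_4x().with_z(50.0)
    frame = a.render_bf(small_phantom, st, 150.0, 150.0, seed=1)
    bg = a.estimate_background([a.render_bf(small_phantom, st, 150.0, 150.0, seed=s)
                                for s in range(4)])
    corrected = a.flatfield_correct(frame, bg)
    pix = corrected.pixels if hasattr(corrected, "pixels") else corrected
    # background maps to ~1 and the vignette gradient is removed
    assert pix.mean() == pytest.approx(1.0, abs=0.02)
    g = pix.mean(axis=2)
    assert abs(g[0, 0] - g[g.shape[0] // 2, g.shape[1] // 2]) < 0.02


# ---------------------------------------------------------------------------
# mosaic geometry, stitching, pyramid
# ---------------------------------------------------------------------------


def test_pixel_stage_round_trip_sub_half_pixel():
    mosaic = a.Mosaic(np.zeros((10, 10)), (7.2, 7.3), (100.0, 200.0))
    rng = np.random.default_rng(0)
    rows = rng.uniform(0, 9, 20)
    cols = rng.uniform(0, 9, 20)
    r2, c2 = mosaic.stage_to_pixel(*mosaic.pixel_to_stage(rows, cols))
    np.testing.assert_allclose(r2, rows, atol=1e-9)
    np.testing.assert_allclose(c2, cols, atol=1e-9)


def _stitch_and_whole(phantom):
    s4 = a.ScanSettings.bf_4x()
    w, h = phantom.width_um, phantom.height_um
    pos = a.generate_position_list((0, 0, w, h), s4, 0.0)
    frames = [a.render_bf(phantom, s4.with_z(50.0), e.x_um, e.y_um,
                          seed=0, noise=False) for e in pos.entries]
    mosaic = a.stitch(frames, pos, (s4.pixel_size_x_um, s4.pixel_size_y_um))
    W, H = mosaic.image.shape[1], mosaic.image.shape[0]
    big = a.ScanSettings("BF", "4x", W * s4.pixel_size_x_um,
                         H * s4.pixel_size_y_um, W, H, z_um=50.0)
    cx = mosaic.origin_um[0] + W * s4.pixel_size_x_um / 2
    cy = mosaic.origin_um[1] + H * s4.pixel_size_y_um / 2
    whole = a.render_bf(phantom, big, cx, cy, seed=0, noise=False)
    return mosaic, whole


def test_stitch_equals_whole_region_render(flat_phantom):
    mosaic, whole = _stitch_and_whole(flat_phantom)
    assert np.abs(whole.pixels - mosaic.image).max() <= 1e-6


def test_pyramid_export_read_round_trip(flat_phantom, tmp_path):
    mosaic, _ = _stitch_and_whole(flat_phantom)
    path = tmp_path / "m.ome.tif"
    a.export_pyramid(mosaic, path, levels=3)
    levels, meta = a.read_pyramid(path)
    assert len(levels) == 3
    np.testing.assert_array_equal(levels[0], mosaic.image)
    assert meta["psx"] == pytest.approx(mosaic.pixel_size_um[0])
    assert meta["psy"] == pytest.approx(mosaic.pixel_size_um[1])
    for lo, hi in zip(levels[1:], levels):
        assert lo.shape[0] == (hi.shape[0] + 1) // 2


# ---------------------------------------------------------------------------
# annotations
# ---------------------------------------------------------------------------


def test_annotation_requires_three_vertices():
    with pytest.raises(ValueError):
        a.Annotation(np.array([[0, 0], [1, 1]]))


def test_geojson_round_trip(tmp_path):
    ann = a.Annotation(np.array([[0, 0], [10, 0], [10, 10], [0, 10]], float),
                       label="roi")
    path = tmp_path / "ann.geojson"
    a.annotations_to_geojson([ann], path)
    data = json.loads(path.read_text())
    assert data["type"] == "FeatureCollection"
    back = a.annotations_from_geojson(path)
    assert len(back) == 1
    assert back[0].label == "roi"
    assert back[0].polygon().equals(ann.polygon())


def test_rectangle_annotation_tiles_exactly():
    """A rectangle exactly 2 x 3 target FOVs on a grid-aligned mosaic
    produces exactly 6 tiles."""
    s20 = a.ScanSettings.bf_20x()
    ps = (1.0, 1.0)  # 1 um/px mosaic for easy arithmetic
    mosaic = a.Mosaic(np.zeros((2000, 2000, 3)), ps, (0.0, 0.0))
    w, h = 2 * s20.fov_width_um, 3 * s20.fov_height_um
    rect = np.array([[100, 100], [100 + w, 100], [100 + w, 100 + h], [100, 100 + h]])
    ann = a.Annotation(rect)
    lists = a.annotations_to_positions([ann], mosaic, s20)
    assert len(lists) == 1
    assert len(lists[0].entries) == 6


def test_annotation_tiles_cover_polygon():
    s20 = a.ScanSettings.bf_20x()
    mosaic = a.Mosaic(np.zeros((2000, 2000, 3)), (1.0, 1.0), (0.0, 0.0))
    tri = np.array([[200, 200], [900, 300], [500, 1100]], float)
    ann = a.Annotation(tri)
    (plist,) = a.annotations_to_positions([ann], mosaic, s20)
    # rasterize: every polygon point must fall inside some tile
    from shapely.geometry import Point
    poly = ann.polygon()
    rng = np.random.default_rng(0)
    minx, miny, maxx, maxy = poly.bounds
    pts = []
    while len(pts) < 200:
        p = Point(rng.uniform(minx, maxx), rng.uniform(miny, maxy))
        if poly.contains(p):
            pts.append(p)
    half_w, half_h = s20.fov_width_um / 2, s20.fov_height_um / 2
    for p in pts:
        assert any(abs(p.x - e.x_um) <= half_w and abs(p.y - e.y_um) <= half_h
                   for e in plist.entries)


def test_degenerate_annotation_raises():
    line = a.Annotation(np.array([[0, 0], [10, 10], [20, 20]], float))
    mosaic = a.Mosaic(np.zeros((100, 100, 3)), (1.0, 1.0), (0.0, 0.0))
    with pytest.raises(ValueError, match="degenerate"):
        a.annotations_to_positions([line], mosaic, a.ScanSettings.bf_20x())


# ---------------------------------------------------------------------------
# workflow (fast path)
# ---------------------------------------------------------------------------


def test_workflow_prescan_only(small_phantom, tmp_path):
    cfg = a.WorkflowConfig(seed=1, slide_bounds=(0, 0, 3000, 3000),
                           out_dir=str(tmp_path), export_ome=False)
    result = a.run_workflow(small_phantom, cfg)
    assert result.status == "prescan_only"
    assert result.mosaic is not None
    assert (tmp_path / "prescan_positions.csv").exists()
    stages = [e["stage"] for e in result.logs]
    assert "prescan" in stages and "stitch" in stages
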