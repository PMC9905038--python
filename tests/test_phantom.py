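"""Virtual slide generator: determinism, parameter validation, focus surface,
and the brightfield / laser-scanning noise models."""

import dataclasses

import numpy as np
import pytest

import autoscope as a


def test_phantom_generation_is_deterministic():
    cfg = a.PhantomConfig()
    p1 = a.make_phantom(cfg, seed=5)
    p2 = a.make_phantom(cfg, seed=5)
    assert len(p1.cores) == len(p2.cores)
    for c1, c2 in zip(p1.cores, p2.cores):
        assert (c1.cx, c1.cy, c1.radius, c1.label) == (c2.cx, c2.cy, c2.radius, c2.label)
        np.testing.assert_array_equal(np.asarray(c1.fibers), np.asarray(c2.fibers))


def test_different_seeds_differ():
    cfg = a.PhantomConfig()
    p1 = a.make_phantom(cfg, seed=5)
    p2 = a.make_phantom(cfg, seed=6)
    assert any((c1.cx, c1.cy) != (c2.cx, c2.cy)
               for c1, c2 in zip(p1.cores, p2.cores))


@pytest.mark.parametrize("bad", [
    {"width_um": -1}, {"height_um": 0}, {"n_benign": -1},
    {"core_radius_um": -5}, {"vignette_strength": -0.1},
])
def test_invalid_config_raises(bad):
    cfg = dataclasses.replace(a.PhantomConfig(), **bad)
    with pytest.raises(ValueError):
        a.make_phantom(cfg, seed=0)


def test_focus_surface_amplitude_and_continuity(default_phantom):
    p = default_phantom
    xs = np.linspace(0, p.width_um, 21)
    ys = np.linspace(0, p.height_um, 21)
    z = np.array([[a.true_focus(p, x, y) for x in xs] for y in ys])
    off = p.config.focus_offset_um
    amp = p.config.focus_amplitude_um
    assert np.all(z >= off - amp - 1e-9) and np.all(z <= off + amp + 1e-9)
    # smooth: neighbouring samples (500 um apart) differ by far less than 2*amp
    assert np.abs(np.diff(z, axis=0)).max() < amp
    with pytest.raises(ValueError):
        a.true_focus(p, -1.0, 0.0)


def test_cores_stay_inside_slide(default_phantom):
    for c in default_phantom.cores:
        assert c.radius <= c.cx <= default_phantom.width_um - c.radius
        assert c.radius <= c.cy <= default_phantom.height_um - c.radius


def test_core_label_lookup(default_phantom):
    c = default_phantom.cores[0]
    cid, label = a.core_label_at(default_phantom, c.cx, c.cy)
    assert cid == c.core_id and label == c.label
    assert a.core_label_at(default_phantom, 1.0, 1.0) == (None, None)


def test_scan_settings_presets_match_published_geometry():
    s20 = a.ScanSettings.bf_20x()
    assert (s20.fov_width_um, s20.fov_height_um) == (230.9, 309.0)
    s4 = a.ScanSettings.bf_4x()
    assert s4.fov_width_um == pytest.approx(5 * s20.fov_width_um)
    assert s4.fov_height_um == pytest.approx(5 * s20.fov_height_um)
    lq = a.ScanSettings.shg_low_quality()
    hq = a.ScanSettings.shg_high_quality()
    assert lq.fov_width_um == hq.fov_width_um == 130.6
    assert (lq.nx, hq.nx) == (256, 512)
    assert lq.scan_rate_hz == 500_000 and hq.scan_rate_hz == 100_000
    assert lq.pixel_size_x_um == pytest.approx(0.51, abs=0.01)


def test_render_bf_deterministic_and_in_range(small_phantom):
    c = small_phantom.cores[0]
    st = a.ScanSettings.bf_20x().with_z(a.true_focus(small_phantom, c.cx, c.cy))
    f1 = a.render_bf(small_phantom, st, c.cx, c.cy, seed=2)
    f2 = a.render_bf(small_phantom, st, c.cx, c.cy, seed=2)
    f3 = a.render_bf(small_phantom, st, c.cx, c.cy, seed=3)
    np.testing.assert_array_equal(f1.pixels, f2.pixels)
    assert not np.array_equal(f1.pixels, f3.pixels)
    assert f1.pixels.shape == (st.ny, st.nx, 3)
    assert f1.pixels.min() >= 0.0 and f1.pixels.max() <= 1.0


def test_defocus_blurs_the_image(small_phantom):
    c = small_phantom.cores[0]
    z = a.true_focus(small_phantom, c.cx, c.cy)
    sharp = a.render_bf(small_phantom, a.ScanSettings.bf_20x().with_z(z),
                        c.cx, c.cy, seed=0, noise=False)
    blurred = a.render_bf(small_phantom, a.ScanSettings.bf_20x().with_z(z + 10),
                          c.cx, c.cy, seed=0, noise=False)
    assert np.var(np.diff(blurred.pixels, axis=1)) < np.var(np.diff(sharp.pixels, axis=1))


def test_vignette_darkens_corners(small_phantom):
    # background region: vignette is the dominant spatial effect
    st = a.ScanSettings.bf_4x().with_z(50.0)
    f = a.render_bf(small_phantom, st, 200.0, 200.0, seed=0, noise=False)
    g = f.pixels.mean(axis=2)
    assert g[0, 0] < g[g.shape[0] // 2, g.shape[1] // 2]


def test_shg_noise_scales_with_dwell_time(default_phantom):
    """Photon-limited model: noise std scales ~1/sqrt(dwell); the 0.5 MHz and
    0.1 MHz settings differ by 5x dwell, so the ratio approaches sqrt(5)."""
    p = default_phantom
    c = p.cores[0]
    z = a.true_focus(p, c.cx, c.cy)
    lq = a.ScanSettings.shg_low_quality().with_z(z)
    slow = dataclasses.replace(lq, scan_rate_hz=a.ScanSettings.shg_high_quality().scan_rate_hz)

    def resid_std(st):
        clean = a.render_shg_clean(p, st, c.cx, c.cy).pixels
        out = []
        for s in range(4):
            noisy = a.render_shg(p, st, c.cx, c.cy, seed=s).pixels
            out.append((noisy - clean)[clean > 0.2].std())
        return np.mean(out)

    ratio = resid_std(lq) / resid_std(slow)
    assert ratio == pytest.approx(np.sqrt(5.0), rel=0.15)


def test_shg_render_range_and_determinism(default_phantom):
    c = default_phantom.cores[0]
    st = a.ScanSettings.shg_low_quality().with_z(a.true_focus(default_phantom, c.cx, c.cy))
    f1 = a.render_shg(default_phantom, st, c.cx, c.cy, seed=1)
    f2 = a.render_shg(default_phantom, st, c.cx, c.cy, seed=1)
    np.testing.assert_array_equal(f1.pixels, f2.pixels)
    assert f1.pixels.min() >= 0.0 and f1.pixels.max() <= 1.0
    assert f1.pixels.shape == (256, 256)


def test_fiber_ground_truth_alignment_tracks_kappa():
    values = []
    for i, kappa in enumerate([0.5, 4.0, 32.0]):
        cfg = dataclasses.replace(a.PhantomConfig(), fiber_kappa=(kappa, kappa))
        p = a.make_phantom(cfg, seed=30 + i)
        c = p.cores[0]
        region = (c.cx - 300, c.cy - 300, c.cx + 300, c.cy + 300)
        align, density = a.fiber_ground_truth(p, region)
        assert 0.0 <= align <= 1.0 and 0.0 <= density <= 1.0
        values.append(align)
    assert values[0] < values[1] < values[2]


def test_config_yaml_round_trip(tmp_path):
    cfg = dataclasses.replace(a.PhantomConfig(), width_um=1234.0,
                              fiber_kappa=(2.0, 5.0))
    path = tmp_path / "cfg.yaml"
    cfg.to_yaml(path)
    cfg2 = a.PhantomConfig.from_yaml(path)
    assert cfg2.width_um == 1234.0
    assert tuple(cfg2.fiber_kappa) == (2.0, 5.0)


def test_frame_bounds_centered_on_stage_position():
    st = a.ScanSettings.bf_20x().with_z(0.0)
    x0, y0, x1, y1 = a.frame_bounds(st, 1000.0, 2000.0)
    assert (x0 + x1) / 2 == pytest.approx(1000.0)
    assert (y0 + y1) / 2 == pytest.approx(2000.0)
    assert x1 - x0 == pytest.approx(st.fov_width_um)
    assert y1 - y0 == pytest.approx(st.fov_height_um)
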