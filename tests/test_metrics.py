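"""Quality metrics: PSNR/SSIM against reference implementations, Frechet
distance against a closed-form Gaussian oracle, fiber statistics and the
error-ratio summaries."""

import json

import numpy as np
import pytest
from scipy.ndimage import gaussian_filter
from skimage.metrics import peak_signal_noise_ratio, structural_similarity

import autoscope as a
from autoscope import nn


# ---------------------------------------------------------------------------
# PSNR / SSIM
# ---------------------------------------------------------------------------


def test_psnr_matches_reference(rng):
    for _ in range(5):
        x = rng.random((32, 32))
        y = rng.random((32, 32))
        ref = peak_signal_noise_ratio(x, y, data_range=1.0)
        assert a.psnr(x, y) == pytest.approx(ref, abs=1e-6)


def test_psnr_identical_images_infinite():
    x = np.full((16, 16), 0.3)
    assert a.psnr(x, x) == float("inf")


def test_psnr_shape_mismatch_raises():
    with pytest.raises(ValueError):
        a.psnr(np.zeros((8, 8)), np.zeros((8, 9)))


def test_ssim_matches_reference(rng):
    for _ in range(5):
        x = rng.random((48, 48))
        y = np.clip(x + 0.1 * rng.standard_normal((48, 48)), 0, 1)
        ref = structural_similarity(x, y, data_range=1.0, gaussian_weights=True,
                                    sigma=1.5, win_size=11,
                                    use_sample_covariance=True)
        assert a.ssim(x, y) == pytest.approx(ref, abs=1e-6)


def test_ssim_identical_images_is_one(rng):
    x = rng.random((32, 32))
    assert a.ssim(x, x) == pytest.approx(1.0, abs=1e-9)


def test_ssim_rejects_small_images():
    with pytest.raises(ValueError, match="window"):
        a.ssim(np.zeros((8, 8)), np.zeros((8, 8)))


# ---------------------------------------------------------------------------
# Frechet distance
# ---------------------------------------------------------------------------


def test_fid_identical_sets_is_zero(rng):
    imgs = [rng.random((32, 32)).astype(np.float32) for _ in range(4)]
    assert a.fid(imgs, imgs) == pytest.approx(0.0, abs=1e-6)


def test_fid_symmetric_and_positive(rng):
    A = [rng.random((32, 32)) for _ in range(4)]
    B = [np.clip(x + 0.3, 0, 1) for x in A]
    d_ab = a.fid(A, B)
    d_ba = a.fid(B, A)
    assert d_ab > 0
    assert d_ab == pytest.approx(d_ba, rel=1e-6)


def closed_form_frechet(mu_a, ca, mu_b, cb):
    """Independent oracle: trace term via eigenvalues of the product."""
    eig = np.linalg.eigvals(ca @ cb)
    tr = np.sqrt(np.clip(eig.real, 0, None)).sum()
    return float(((mu_a - mu_b) ** 2).sum() + np.trace(ca) + np.trace(cb) - 2 * tr)


def test_fid_matches_closed_form_gaussian_oracle():
    rng = np.random.default_rng(0)
    d = 4
    fa = rng.standard_normal((200, d)) @ rng.standard_normal((d, d)) + 1.0
    fb = rng.standard_normal((200, d)) @ rng.standard_normal((d, d)) - 0.5
    # plug the *sample* moments (plus the same eps regulariser) into the
    # closed form computed by an independent eigenvalue route
    eps = 1e-6
    ca = np.cov(fa, rowvar=False) + eps * np.eye(d)
    cb = np.cov(fb, rowvar=False) + eps * np.eye(d)
    expected = closed_form_frechet(fa.mean(axis=0), ca, fb.mean(axis=0), cb)
    assert a.fid(fa, fb) == pytest.approx(expected, rel=1e-6)


def test_fid_diagonal_covariance_hand_formula():
    rng = np.random.default_rng(1)
    sa, sb = np.array([1.0, 4.0]), np.array([9.0, 1.0])
    fa = rng.standard_normal((500, 2)) * np.sqrt(sa)
    fb = rng.standard_normal((500, 2)) * np.sqrt(sb) + np.array([2.0, 0.0])
    mu_a, mu_b = fa.mean(axis=0), fb.mean(axis=0)
    va = np.cov(fa, rowvar=False) + 1e-6 * np.eye(2)
    vb = np.cov(fb, rowvar=False) + 1e-6 * np.eye(2)
    expected = closed_form_frechet(mu_a, va, mu_b, vb)
    assert a.fid(fa, fb) == pytest.approx(expected, rel=1e-4)


def test_fid_requires_two_samples():
    with pytest.raises(ValueError):
        a.fid([np.zeros(4)], [np.zeros(4), np.ones(4)])


# ---------------------------------------------------------------------------
# fiber statistics
# ---------------------------------------------------------------------------


def _parallel_stripes(angle_deg=0.0, size=128, period=8):
    yy, xx = np.mgrid[0:size, 0:size].astype(float)
    t = np.deg2rad(angle_deg)
    coord = xx * np.cos(t) + yy * np.sin(t)
    return 0.5 + 0.5 * np.sin(2 * np.pi * coord / period)


def test_alignment_high_for_parallel_fibers():
    for angle in (0.0, 30.0, 90.0):
        st = a.fiber_stats(_parallel_stripes(angle))
        assert st.alignment >= 0.95
        assert not st.undefined


def test_alignment_low_for_isotropic_field():
    rng = np.random.default_rng(0)
    iso = gaussian_filter(rng.random((256, 256)), 2.0)
    st = a.fiber_stats(iso)
    assert st.alignment <= 0.1


def test_density_is_foreground_fraction():
    img = np.zeros((64, 64))
    img[:16, :] = 1.0  # exactly a quarter bright
    st = a.fiber_stats(img)
    assert st.density == pytest.approx(0.25, abs=0.02)


def test_fiber_stats_constant_image_flagged_undefined():
    st = a.fiber_stats(np.full((32, 32), 0.5))
    assert st.undefined
    assert (st.alignment, st.density) == (0.0, 0.0)


def test_fiber_stats_rejects_multichannel():
    with pytest.raises(ValueError):
        a.fiber_stats(np.zeros((8, 8, 3)))


# ---------------------------------------------------------------------------
# error ratios
# ---------------------------------------------------------------------------


def test_error_ratios_hand_computed():
    truth = [a.FiberStats(0.8, 0.4), a.FiberStats(0.4, 0.2)]
    proc = [a.FiberStats(0.6, 0.3), a.FiberStats(0.5, 0.1)]
    # max truth alignment 0.8, max truth density 0.4
    # alignment ratios: 0.2/0.8, 0.1/0.8 -> mean 0.1875 -> 18.75 %
    # density ratios:   0.1/0.4, 0.1/0.4 -> mean 0.25
    align_pct, dens = a.error_ratios(proc, truth)
    assert align_pct == pytest.approx(18.75)
    assert dens == pytest.approx(0.25)


def test_error_ratios_perfect_recovery_is_zero():
    truth = [a.FiberStats(0.9, 0.3), a.FiberStats(0.5, 0.1)]
    assert a.error_ratios(truth, truth) == (0.0, 0.0)


def test_error_ratios_validation():
    with pytest.raises(ValueError):
        a.error_ratios([], [])
    with pytest.raises(ValueError):
        a.error_ratios([a.FiberStats(0.5, 0.2)],
                       [a.FiberStats(0.0, 0.0)])  # zero truth maximum


# ---------------------------------------------------------------------------
# evaluation report
# ---------------------------------------------------------------------------


def test_evaluate_pipeline_report(tmp_path, rng):
    truth = [_parallel_stripes(angle) for angle in (0.0, 45.0, 90.0)]
    noisy = [np.clip(t + 0.05 * rng.standard_normal(t.shape), 0, 1)
             for t in truth]
    report = a.evaluate_pipeline(noisy, truth)
    assert list(report.per_image.columns[:4]) == \
        ["psnr_db", "ssim", "alignment", "density"]
    assert len(report.per_image) == 3
    s = report.summary()
    assert set(s) == {"psnr_db", "ssim", "fid", "alignment_error_pct",
                      "density_error"}
    assert 0 < s["ssim"] < 1 and np.isfinite(s["psnr_db"])
    assert report.extractor_id != ""
    report.to_json(tmp_path / "r.json")
    loaded = json.loads((tmp_path / "r.json").read_text())
    assert loaded["summary"] == s
    report.to_csv(tmp_path / "r.csv")
    assert (tmp_path / "r.csv").read_text().startswith("psnr_db,")


def test_evaluate_pipeline_deterministic(rng):
    truth = [rng.random((32, 32)) for _ in range(2)]
    noisy = [np.clip(t + 0.1, 0, 1) for t in truth]
    s1 = a.evaluate_pipeline(noisy, truth).summary()
    s2 = a.evaluate_pipeline(noisy, truth).summary()
    assert s1 == s2


def test_evaluate_pipeline_rejects_mismatched_sets():
    x = [np.zeros((16, 16))]
    with pytest.raises(ValueError):
        a.evaluate_pipeline(x, [])
    with pytest.raises(ValueError):
        a.evaluate_pipeline([np.zeros((16, 16))], [np.zeros((16, 17))])


def test_random_feature_extractor_is_seed_stable():
    e1 = nn.RandomFeatureExtractor(seed=0)
    e2 = nn.RandomFeatureExtractor(seed=0)
    img = np.random.default_rng(3).random((32, 32)).astype(np.float32)
    np.testing.assert_array_equal(e1.feature_vector(img), e2.feature_vector(img))
    assert e1.identifier == e2.identifier
    assert nn.RandomFeatureExtractor(seed=1).identifier != e1.identifier
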