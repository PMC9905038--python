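"""Shared fixtures: small, fast phantoms and scan settings."""

import dataclasses

import numpy as np
import pytest

import autoscope as a


@pytest.fixture(scope="session")
def default_phantom():
    """Full-size default phantom (expensive pieces are rendered lazily)."""
    return a.make_phantom(a.PhantomConfig(), seed=7)


@pytest.fixture(scope="session")
def small_phantom():
    """A 3 x 3 mm two-core slide for fast rendering tests."""
    cfg = dataclasses.replace(a.PhantomConfig(), width_um=3000, height_um=3000,
                              n_benign=1, n_malignant=1, core_radius_um=600)
    return a.make_phantom(cfg, seed=3)


@pytest.fixture(scope="session")
def flat_phantom():
    """Noise-free, vignette-free, flat-focus slide: the stitching oracle."""
    s4 = a.ScanSettings.bf_4x()
    w, h = 2 * s4.fov_width_um, 2 * s4.fov_height_um
    cfg = dataclasses.replace(a.PhantomConfig(), width_um=w, height_um=h,
                              n_benign=1, n_malignant=1, core_radius_um=500,
                              vignette_strength=0.0, focus_amplitude_um=0.0,
                              bf_noise_sigma=0.0)
    return a.make_phantom(cfg, seed=3)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(0)
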