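"""Virtual microscope: a seeded slide phantom plus brightfield / laser-scanning
renderers.

The phantom stands in for a physical instrument scanning a tissue-microarray
slide. It owns the ground truth that every downstream stage is tested against:

* circular tissue cores of two classes (benign / malignant) whose procedural
  textures differ only in statistics (grating spatial frequency, spot density),
* a smooth focus surface z(x, y) emulating slide terrain, so autofocus has
  something to recover,
* per-core collagen-like fiber fields (mean orientation, von Mises
  concentration kappa, coverage density) rendered by the laser-scanning path,
* a camera-fixed vignette and seeded noise models: Gaussian camera noise for
  brightfield, Poisson photon counting plus Gaussian read noise for laser
  scanning, where the photon count per pixel scales with the dwell time
  (1 / scan rate) so slower scans have higher SNR.

All rendering is a pure function of (phantom, settings, position, seed):
textures and fibers are stored explicitly at phantom creation and evaluated as
deterministic functions of stage coordinates, so a feature appears at the same
physical location in every frame that contains it.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import tifffile
import yaml
from scipy.ndimage import gaussian_filter

__all__ = [
    "ScanSettings",
    "Frame",
    "Core",
    "SlidePhantom",
    "PhantomConfig",
    "make_phantom",
    "true_focus",
    "render_bf",
    "render_shg",
    "render_shg_clean",
    "fiber_ground_truth",
    "frame_bounds",
    "frame_to_tiff",
]


# ---------------------------------------------------------------------------
# scan settings / frames
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ScanSettings:
    """Acquisition geometry and timing for one modality/magnification."""

    modality: str  # "BF" or "LSM"
    objective: str  # "4x" or "20x"
    fov_width_um: float
    fov_height_um: float
    nx: int
    ny: int
    scan_rate_hz: float | None = None
    z_um: float = 0.0

    def __post_init__(self) -> None:
        if self.modality not in ("BF", "LSM"):
            raise ValueError(f"unknown modality {self.modality!r}")
        if self.fov_width_um <= 0 or self.fov_height_um <= 0:
            raise ValueError("FOV dimensions must be positive")
        if self.nx <= 0 or self.ny <= 0:
            raise ValueError("pixel counts must be positive")
        if self.modality == "LSM":
            if not self.scan_rate_hz or self.scan_rate_hz <= 0:
                raise ValueError("LSM settings require scan_rate_hz > 0")

    @property
    def pixel_size_x_um(self) -> float:
        return self.fov_width_um / self.nx

    @property
    def pixel_size_y_um(self) -> float:
        return self.fov_height_um / self.ny

    @property
    def dwell_time_s(self) -> float:
        if self.scan_rate_hz is None:
            raise ValueError("dwell time is defined for LSM settings only")
        return 1.0 / self.scan_rate_hz

    def with_z(self, z_um: float) -> "ScanSettings":
        return replace(self, z_um=float(z_um))

    # -- presets ------------------------------------------------------------
    # 20x brightfield FOV is 230.9 x 309.0 um; the 4x FOV scales it by 20/4
    # on the same camera sensor. Laser-scanning FOV is 130.6 x 130.6 um with
    # a fast 0.5 MHz / 256x256 setting (0.51 um/px) and a slow 0.1 MHz /
    # 512x512 setting (0.26 um/px).

    @staticmethod
    def bf_20x(nx: int = 160, ny: int = 214, z_um: float = 0.0) -> "ScanSettings":
        return ScanSettings("BF", "20x", 230.9, 309.0, nx, ny, z_um=z_um)

    @staticmethod
    def bf_4x(nx: int = 160, ny: int = 214, z_um: float = 0.0) -> "ScanSettings":
        return ScanSettings("BF", "4x", 1154.5, 1545.0, nx, ny, z_um=z_um)

    @staticmethod
    def shg_low_quality(n: int = 256, z_um: float = 0.0) -> "ScanSettings":
        return ScanSettings("LSM", "20x", 130.6, 130.6, n, n,
                            scan_rate_hz=500_000.0, z_um=z_um)

    @staticmethod
    def shg_high_quality(n: int = 512, z_um: float = 0.0) -> "ScanSettings":
        return ScanSettings("LSM", "20x", 130.6, 130.6, n, n,
                            scan_rate_hz=100_000.0, z_um=z_um)


@dataclass
class Frame:
    """One acquired image: pixels plus stage/acquisition metadata.

    BF frames are (ny, nx, 3) RGB in [0, 1]; LSM frames are (ny, nx) in [0, 1].
    The frame center sits at the stage position.
    """

    pixels: np.ndarray
    settings: ScanSettings
    stage_x_um: float
    stage_y_um: float
    acquired_z_um: float

    def __post_init__(self) -> None:
        expect = (self.settings.ny, self.settings.nx)
        if self.settings.modality == "BF":
            if self.pixels.shape != expect + (3,):
                raise ValueError(f"BF frame shape {self.pixels.shape} != {expect + (3,)}")
        else:
            if self.pixels.shape != expect:
                raise ValueError(f"LSM frame shape {self.pixels.shape} != {expect}")


def frame_bounds(settings: ScanSettings, x_um: float, y_um: float
                 ) -> tuple[float, float, float, float]:
    """(x0, y0, x1, y1) stage bounds of the FOV centred at (x_um, y_um)."""
    return (x_um - settings.fov_width_um / 2, y_um - settings.fov_height_um / 2,
            x_um + settings.fov_width_um / 2, y_um + settings.fov_height_um / 2)


def frame_to_tiff(frame: Frame, path) -> None:
    """Debug export of a single frame as TIFF with pixel-size metadata."""
    tifffile.imwrite(path, frame.pixels.astype(np.float32),
                     metadata={"pixel_size_x_um": frame.settings.pixel_size_x_um,
                               "pixel_size_y_um": frame.settings.pixel_size_y_um,
                               "stage_x_um": frame.stage_x_um,
                               "stage_y_um": frame.stage_y_um,
                               "z_um": frame.acquired_z_um})


# ---------------------------------------------------------------------------
# phantom config / construction
# ---------------------------------------------------------------------------


@dataclass
class PhantomConfig:
    """Parameters of the synthetic slide.

    Defaults emulate a tissue-microarray slide: ~2 mm diameter cores
    (radius 1000 um) on a 10 x 10 mm scanned area, terrain height variations
    of +/- 20 um, and near-achromatic bright background so background tiles
    fall below the 0.15 mean-saturation rule.
    """

    width_um: float = 10_000.0
    height_um: float = 10_000.0
    n_benign: int = 2
    n_malignant: int = 2
    core_radius_um: float = 1000.0
    core_radius_jitter: float = 0.1
    max_core_overlap_fraction: float = 0.0
    # focus surface
    focus_amplitude_um: float = 20.0
    focus_offset_um: float = 50.0
    focus_coeffs: list | None = None  # explicit 3x3 polynomial (overrides random)
    # brightfield appearance / noise
    background_rgb: tuple = (0.92, 0.92, 0.90)
    tissue_rgb: tuple = (0.72, 0.50, 0.66)
    vignette_strength: float = 0.25
    bf_noise_sigma: float = 0.01
    blur_gain_um_per_um: float = 0.8
    core_edge_um: float = 3.0
    # class-conditional textures (separable by construction)
    benign_freq_per_um: float = 0.015
    malignant_freq_per_um: float = 0.045
    benign_spot_density_per_um2: float = 2e-4
    malignant_spot_density_per_um2: float = 8e-4
    benign_spot_sigma_um: float = 7.0
    malignant_spot_sigma_um: float = 4.0
    # fibers (laser-scanning ground truth)
    fiber_kappa: tuple | float = (1.0, 8.0)
    fiber_density: tuple | float = (0.2, 0.4)
    fiber_length_um: tuple = (40.0, 80.0)
    fiber_sigma_um: float = 1.0
    # laser-scanning noise model
    photon_rate_hz: float = 2e7  # photons/s at unit signal
    read_noise_counts: float = 2.0
    z_attenuation_um: float = 15.0
    shg_full_scale: float = 0.8  # unit signal maps to this normalized level

    @staticmethod
    def from_dict(d: dict) -> "PhantomConfig":
        # YAML has no tuple type; coerce list-valued fields
        return PhantomConfig(**{k: (tuple(v) if isinstance(v, list) else v)
                                for k, v in d.items()})

    @staticmethod
    def from_yaml(path) -> "PhantomConfig":
        with open(path) as fh:
            return PhantomConfig.from_dict(yaml.safe_load(fh) or {})

    def to_yaml(self, path) -> None:
        d = {k: (list(v) if isinstance(v, tuple) else v)
             for k, v in self.__dict__.items()}
        with open(path, "w") as fh:
            yaml.safe_dump(d, fh)


@dataclass
class Core:
    cx: float
    cy: float
    radius: float
    label: str  # "benign" | "malignant"
    gratings: np.ndarray  # (n, 4): angle, freq_per_um, phase, weight
    spots: np.ndarray  # (n, 3): x, y, amplitude
    spot_sigma_um: float
    fiber_theta_mean: float
    fiber_kappa: float
    fiber_density: float
    fibers: np.ndarray  # (n, 5): x, y, theta, length, amplitude
    core_id: int = 0


@dataclass
class SlidePhantom:
    """Ground-truth synthetic scene; all renderers read from this."""

    config: PhantomConfig
    cores: list
    focus_coeffs: np.ndarray  # 3x3, z = sum c[i,j] * x**i * y**j (um)
    rng_seed: int

    @property
    def width_um(self) -> float:
        return self.config.width_um

    @property
    def height_um(self) -> float:
        return self.config.height_um

    def cores_near(self, x0, y0, x1, y1, pad=0.0):
        out = []
        for c in self.cores:
            if (c.cx + c.radius + pad >= x0 and c.cx - c.radius - pad <= x1 and
                    c.cy + c.radius + pad >= y0 and c.cy - c.radius - pad <= y1):
                out.append(c)
        return out


def _sample_range(rng: np.random.Generator, spec) -> float:
    if isinstance(spec, (tuple, list)):
        return float(rng.uniform(spec[0], spec[1]))
    return float(spec)


def make_phantom(config: PhantomConfig, seed: int) -> SlidePhantom:
    """Build a deterministic phantom from a config and a seed."""
    cfg = config
    if cfg.width_um <= 0 or cfg.height_um <= 0:
        raise ValueError("slide extents must be positive")
    if cfg.n_benign < 0 or cfg.n_malignant < 0:
        raise ValueError("core counts must be non-negative")
    if cfg.core_radius_um <= 0:
        raise ValueError("core radius must be positive")
    if not 0.0 <= cfg.vignette_strength < 1.0:
        raise ValueError("vignette strength must be in [0, 1)")
    if cfg.bf_noise_sigma < 0 or cfg.blur_gain_um_per_um < 0:
        raise ValueError("noise sigma and blur gain must be non-negative")
    if cfg.photon_rate_hz <= 0:
        raise ValueError("photon rate must be positive")
    rng = np.random.default_rng(seed)

    # focus surface: low-order polynomial over normalised coordinates,
    # scaled so its range matches focus_amplitude_um
    if cfg.focus_coeffs is not None:
        coeffs = np.asarray(cfg.focus_coeffs, dtype=float)
        if coeffs.shape != (3, 3):
            raise ValueError("focus_coeffs must be 3x3")
    else:
        cn = rng.uniform(-1.0, 1.0, size=(3, 3))
        cn[0, 0] = 0.0
        cn[2, 2] = cn[2, 1] = cn[1, 2] = 0.0  # keep total order <= 2
        # normalise so |z - offset| <= amplitude over the slide
        u = np.linspace(0, 1, 21)
        uu, vv = np.meshgrid(u, u, indexing="ij")
        zz = sum(cn[i, j] * uu ** i * vv ** j
                 for i in range(3) for j in range(3))
        span = max(float(np.abs(zz).max()), 1e-9)
        cn *= cfg.focus_amplitude_um / span
        # convert from normalised (x/W, y/H) to physical um coordinates
        coeffs = np.zeros((3, 3))
        for i in range(3):
            for j in range(3):
                coeffs[i, j] = cn[i, j] / cfg.width_um ** i / cfg.height_um ** j
        coeffs[0, 0] += cfg.focus_offset_um

    # place cores without overlap (up to the configured bound)
    cores: list[Core] = []
    labels = ["benign"] * cfg.n_benign + ["malignant"] * cfg.n_malignant
    for idx, label in enumerate(labels):
        radius = cfg.core_radius_um * (
            1.0 + rng.uniform(-cfg.core_radius_jitter, cfg.core_radius_jitter))
        if radius <= 0:
            raise ValueError("core radius must be positive")
        if 2 * radius > min(cfg.width_um, cfg.height_um):
            raise ValueError("core does not fit inside the slide")
        placed = False
        for _ in range(2000):
            cx = rng.uniform(radius, cfg.width_um - radius)
            cy = rng.uniform(radius, cfg.height_um - radius)
            ok = True
            for other in cores:
                d = np.hypot(cx - other.cx, cy - other.cy)
                min_d = (radius + other.radius) * (1.0 - cfg.max_core_overlap_fraction)
                if d < min_d:
                    ok = False
                    break
            if ok:
                placed = True
                break
        if not placed:
            raise ValueError("could not place cores within the overlap bound; "
                             "reduce core count/radius or raise the bound")

        if label == "benign":
            freq = cfg.benign_freq_per_um
            spot_density = cfg.benign_spot_density_per_um2
            spot_sigma = cfg.benign_spot_sigma_um
        else:
            freq = cfg.malignant_freq_per_um
            spot_density = cfg.malignant_spot_density_per_um2
            spot_sigma = cfg.malignant_spot_sigma_um

        gratings = np.stack([
            rng.uniform(0, np.pi, size=2),
            freq * rng.uniform(0.8, 1.2, size=2),
            rng.uniform(0, 2 * np.pi, size=2),
            np.full(2, 0.5),
        ], axis=1)

        area = np.pi * radius ** 2
        n_spots = int(rng.poisson(spot_density * area))
        if n_spots:
            rr = radius * 0.95 * np.sqrt(rng.uniform(0, 1, n_spots))
            aa = rng.uniform(0, 2 * np.pi, n_spots)
            amp = rng.uniform(0.25, 0.45, n_spots)
            spots = np.stack([cx + rr * np.cos(aa), cy + rr * np.sin(aa), amp], axis=1)
        else:
            spots = np.zeros((0, 3))

        theta_mean = float(rng.uniform(0, np.pi))
        kappa = _sample_range(rng, cfg.fiber_kappa)
        density = _sample_range(rng, cfg.fiber_density)
        if not 0.0 <= density <= 1.0:
            raise ValueError("fiber density must be in [0, 1]")
        mean_len = 0.5 * (cfg.fiber_length_um[0] + cfg.fiber_length_um[1])
        w_eff = 2.355 * cfg.fiber_sigma_um  # FWHM of the Gaussian profile
        n_fibers = int(round(density * area / (mean_len * w_eff)))
        if n_fibers:
            rr = radius * 0.95 * np.sqrt(rng.uniform(0, 1, n_fibers))
            aa = rng.uniform(0, 2 * np.pi, n_fibers)
            fx = cx + rr * np.cos(aa)
            fy = cy + rr * np.sin(aa)
            if kappa > 0:
                theta = np.mod(rng.vonmises(2 * theta_mean, kappa, n_fibers) / 2, np.pi)
            else:
                theta = rng.uniform(0, np.pi, n_fibers)
            length = rng.uniform(*cfg.fiber_length_um, n_fibers)
            amp = rng.uniform(0.6, 1.0, n_fibers)
            fibers = np.stack([fx, fy, theta, length, amp], axis=1)
        else:
            fibers = np.zeros((0, 5))

        cores.append(Core(cx, cy, radius, label, gratings, spots, spot_sigma,
                          theta_mean, kappa, density, fibers, core_id=idx))

    return SlidePhantom(config=cfg, cores=cores, focus_coeffs=coeffs,
                        rng_seed=int(seed))


# ---------------------------------------------------------------------------
# ground-truth queries
# ---------------------------------------------------------------------------


def true_focus(phantom: SlidePhantom, x_um, y_um):
    """Evaluate the focus surface z(x, y); vectorised over array inputs."""
    x = np.asarray(x_um, dtype=float)
    y = np.asarray(y_um, dtype=float)
    if np.any(x < 0) or np.any(x > phantom.width_um) or \
            np.any(y < 0) or np.any(y > phantom.height_um):
        raise ValueError("query outside slide bounds")
    c = phantom.focus_coeffs
    z = sum(c[i, j] * x ** i * y ** j for i in range(3) for j in range(3))
    return float(z) if np.isscalar(x_um) and np.isscalar(y_um) else z


def core_label_at(phantom: SlidePhantom, x_um: float, y_um: float):
    """(core_id, label) of the core containing the point, or (None, None)."""
    for c in phantom.cores:
        if (x_um - c.cx) ** 2 + (y_um - c.cy) ** 2 <= c.radius ** 2:
            return c.core_id, c.label
    return None, None


def fiber_ground_truth(phantom: SlidePhantom, region,
                       raster_um: float = 0.5,
                       density_threshold: float = 0.1) -> tuple[float, float]:
    """Ground-truth (alignment, density) for a stage-coordinate region.

    `region` is (x0, y0, x1, y1) in um. Alignment is the circular mean
    resultant length of doubled fiber orientations over fibers centred in the
    region; density is the fraction of pixels whose noise-free fiber signal
    exceeds `density_threshold`, rasterised at `raster_um` per pixel. Both are
    computed from the phantom's generating parameters, never from rendered
    (noisy) images.
    """
    x0, y0, x1, y1 = region
    if x1 <= x0 or y1 <= y0:
        raise ValueError("empty region")
    thetas = []
    for c in phantom.cores_near(x0, y0, x1, y1):
        f = c.fibers
        if len(f) == 0:
            continue
        inside = (f[:, 0] >= x0) & (f[:, 0] <= x1) & (f[:, 1] >= y0) & (f[:, 1] <= y1)
        thetas.append(f[inside, 2])
    if thetas:
        theta = np.concatenate(thetas)
    else:
        theta = np.zeros(0)
    if len(theta) == 0:
        alignment = 0.0
    else:
        alignment = float(np.abs(np.exp(2j * theta).mean()))
    xs = np.arange(x0, x1, raster_um) + raster_um / 2
    ys = np.arange(y0, y1, raster_um) + raster_um / 2
    signal = _shg_signal(phantom, xs, ys)
    density = float((signal > density_threshold).mean())
    return alignment, density


# ---------------------------------------------------------------------------
# scene evaluation (deterministic functions of stage coordinates)
# ---------------------------------------------------------------------------


def _grid(settings: ScanSettings, x_um: float, y_um: float, margin: int = 0):
    psx, psy = settings.pixel_size_x_um, settings.pixel_size_y_um
    xs = x_um - settings.fov_width_um / 2 + (np.arange(-margin, settings.nx + margin) + 0.5) * psx
    ys = y_um - settings.fov_height_um / 2 + (np.arange(-margin, settings.ny + margin) + 0.5) * psy
    return xs, ys


def _bf_scene(phantom: SlidePhantom, xs: np.ndarray, ys: np.ndarray) -> np.ndarray:
    """Noise-free RGB reflectance over the stage-coordinate grid (ys, xs)."""
    cfg = phantom.config
    h, w = len(ys), len(xs)
    img = np.empty((h, w, 3), dtype=np.float64)
    img[:] = np.asarray(cfg.background_rgb)
    tissue = np.asarray(cfg.tissue_rgb)
    psx = xs[1] - xs[0] if w > 1 else 1.0
    psy = ys[1] - ys[0] if h > 1 else 1.0
    for core in phantom.cores_near(xs[0], ys[0], xs[-1], ys[-1], pad=cfg.core_edge_um):
        # bounding slice of the grid covering the core
        j0 = int(np.searchsorted(xs, core.cx - core.radius - cfg.core_edge_um))
        j1 = min(int(np.searchsorted(xs, core.cx + core.radius + cfg.core_edge_um)) + 1, w)
        i0 = int(np.searchsorted(ys, core.cy - core.radius - cfg.core_edge_um))
        i1 = min(int(np.searchsorted(ys, core.cy + core.radius + cfg.core_edge_um)) + 1, h)
        if j1 <= j0 or i1 <= i0:
            continue
        X, Y = np.meshgrid(xs[j0:j1], ys[i0:i1])
        dist = np.hypot(X - core.cx, Y - core.cy)
        mask = np.clip((core.radius - dist) / cfg.core_edge_um, 0.0, 1.0)
        if not np.any(mask > 0):
            continue
        t = np.zeros_like(X)
        for ang, freq, phase, weight in core.gratings:
            t += weight * np.sin(2 * np.pi * freq * (X * np.cos(ang) + Y * np.sin(ang)) + phase)
        t *= 0.2
        # darker spots (nuclei-like), each stamped on its local window
        sig = core.spot_sigma_um
        reach = 3.0 * sig
        for sx, sy, amp in core.spots:
            if sx + reach < xs[j0] or sx - reach > xs[j1 - 1] or \
                    sy + reach < ys[i0] or sy - reach > ys[i1 - 1]:
                continue
            # inclusion is purely coordinate-based (pixels whose centre lies
            # within the reach window) so tiled and whole-region renders of
            # the same scene agree exactly
            ja = max(j0, int(np.searchsorted(xs, sx - reach, side="left")))
            jb = min(j1, int(np.searchsorted(xs, sx + reach, side="right")))
            ia = max(i0, int(np.searchsorted(ys, sy - reach, side="left")))
            ib = min(i1, int(np.searchsorted(ys, sy + reach, side="right")))
            if jb <= ja or ib <= ia:
                continue
            d2 = ((xs[ja:jb][None, :] - sx) ** 2 + (ys[ia:ib][:, None] - sy) ** 2)
            t[ia - i0:ib - i0, ja - j0:jb - j0] -= amp * np.exp(-d2 / (2 * sig ** 2))
        value = np.clip(0.7 + t, 0.15, 1.0)
        color = tissue[None, None, :] * value[..., None]
        m3 = mask[..., None]
        img[i0:i1, j0:j1] = img[i0:i1, j0:j1] * (1 - m3) + color * m3
    return img


def _shg_signal(phantom: SlidePhantom, xs: np.ndarray, ys: np.ndarray) -> np.ndarray:
    """Noise-free fiber signal in [0, 1] over the grid (ys, xs)."""
    cfg = phantom.config
    h, w = len(ys), len(xs)
    s = np.zeros((h, w), dtype=np.float64)
    sigma = cfg.fiber_sigma_um
    reach = 4.0 * sigma
    for core in phantom.cores_near(xs[0], ys[0], xs[-1], ys[-1],
                                   pad=cfg.fiber_length_um[1]):
        for fx, fy, theta, length, amp in core.fibers:
            half = length / 2
            ex = half * np.cos(theta)
            ey = half * np.sin(theta)
            x_lo, x_hi = fx - abs(ex) - reach, fx + abs(ex) + reach
            y_lo, y_hi = fy - abs(ey) - reach, fy + abs(ey) + reach
            if x_hi < xs[0] or x_lo > xs[-1] or y_hi < ys[0] or y_lo > ys[-1]:
                continue
            # coordinate-based inclusion (see the brightfield spot stamp)
            ja = int(np.searchsorted(xs, x_lo, side="left"))
            jb = int(np.searchsorted(xs, x_hi, side="right"))
            ia = int(np.searchsorted(ys, y_lo, side="left"))
            ib = int(np.searchsorted(ys, y_hi, side="right"))
            if jb <= ja or ib <= ia:
                continue
            dx = xs[ja:jb][None, :] - fx
            dy = ys[ia:ib][:, None] - fy
            t = np.clip(dx * np.cos(theta) + dy * np.sin(theta), -half, half)
            d2 = (dx - t * np.cos(theta)) ** 2 + (dy - t * np.sin(theta)) ** 2
            s[ia:ib, ja:jb] += amp * np.exp(-d2 / (2 * sigma ** 2))
    return np.minimum(s, 1.0)


# ---------------------------------------------------------------------------
# renderers
# ---------------------------------------------------------------------------


def _defocus(phantom: SlidePhantom, settings: ScanSettings,
             x_um: float, y_um: float) -> tuple[float, float]:
    """(|dz|, blur sigma in px) for the FOV centre; out-of-bounds centres see
    the nearest in-bounds focus value.

    The blur kernel width is physical (microns of blur per micron of
    defocus) and converted to pixels with the detector's sampling, so a
    low-magnification prescan naturally shows a larger depth of field than
    a high-magnification scan of the same slide."""
    xq = float(np.clip(x_um, 0, phantom.width_um))
    yq = float(np.clip(y_um, 0, phantom.height_um))
    dz = abs(settings.z_um - true_focus(phantom, xq, yq))
    ps = min(settings.pixel_size_x_um, settings.pixel_size_y_um)
    return dz, phantom.config.blur_gain_um_per_um * dz / ps


def _vignette(settings: ScanSettings, strength: float) -> np.ndarray:
    if strength <= 0:
        return np.ones((settings.ny, settings.nx))
    u = np.linspace(-1, 1, settings.nx)[None, :]
    v = np.linspace(-1, 1, settings.ny)[:, None]
    return 1.0 - strength * (u ** 2 + v ** 2) / 2.0


def render_bf(phantom: SlidePhantom, settings: ScanSettings,
              x_um: float, y_um: float, seed: int, noise: bool = True) -> Frame:
    """Render a brightfield frame: scene + defocus blur + vignette + noise.

    A FOV entirely outside the slide renders as pure background (not an
    error). Blur is computed with a grid margin so frame edges match what a
    larger render of the same region would contain.
    """
    if settings.modality != "BF":
        raise ValueError("render_bf requires BF settings")
    cfg = phantom.config
    dz, sigma_px = _defocus(phantom, settings, x_um, y_um)
    margin = int(np.ceil(3 * sigma_px)) if sigma_px > 0 else 0
    xs, ys = _grid(settings, x_um, y_um, margin)
    img = _bf_scene(phantom, xs, ys)
    if sigma_px > 0:
        img = gaussian_filter(img, (sigma_px, sigma_px, 0), mode="nearest")
    if margin:
        img = img[margin:-margin, margin:-margin]
    img = img * _vignette(settings, cfg.vignette_strength)[..., None]
    if noise and cfg.bf_noise_sigma > 0:
        rng = np.random.default_rng(seed)
        img = img + rng.normal(0.0, cfg.bf_noise_sigma, size=img.shape)
    img = np.clip(img, 0.0, 1.0).astype(np.float32)
    return Frame(img, settings, float(x_um), float(y_um), settings.z_um)


def _shg_expected_counts(phantom: SlidePhantom, settings: ScanSettings,
                         x_um: float, y_um: float) -> tuple[np.ndarray, float]:
    cfg = phantom.config
    dz, sigma_px = _defocus(phantom, settings, x_um, y_um)
    atten = float(np.exp(-(dz / cfg.z_attenuation_um) ** 2))
    margin = int(np.ceil(3 * sigma_px)) if sigma_px > 0 else 0
    xs, ys = _grid(settings, x_um, y_um, margin)
    s = _shg_signal(phantom, xs, ys) * atten
    if sigma_px > 0:
        s = gaussian_filter(s, sigma_px, mode="nearest")
    if margin:
        s = s[margin:-margin, margin:-margin]
    full_scale = cfg.photon_rate_hz * settings.dwell_time_s / cfg.shg_full_scale
    return s * cfg.photon_rate_hz * settings.dwell_time_s, full_scale


def render_shg(phantom: SlidePhantom, settings: ScanSettings,
               x_um: float, y_um: float, seed: int) -> Frame:
    """Render a laser-scanning frame with dwell-time-dependent shot noise.

    Per-pixel photon counts are Poisson with mean signal * photon_rate *
    dwell_time, plus Gaussian read noise; counts are normalised by a fixed
    full-scale count (so the expected level is independent of scan rate while
    the relative noise scales as 1/sqrt(dwell time)) and clipped to [0, 1].
    """
    if settings.modality != "LSM":
        raise ValueError("render_shg requires LSM settings")
    lam, full_scale = _shg_expected_counts(phantom, settings, x_um, y_um)
    rng = np.random.default_rng(seed)
    counts = rng.poisson(lam).astype(np.float64)
    counts += rng.normal(0.0, phantom.config.read_noise_counts, size=counts.shape)
    img = np.clip(counts / full_scale, 0.0, 1.0).astype(np.float32)
    return Frame(img, settings, float(x_um), float(y_um), settings.z_um)


def render_shg_clean(phantom: SlidePhantom, settings: ScanSettings,
                     x_um: float, y_um: float) -> Frame:
    """Noise-free expected image on the same normalised scale as render_shg;
    the simulator's clean reference for evaluating denoisers."""
    if settings.modality != "LSM":
        raise ValueError("render_shg_clean requires LSM settings")
    lam, full_scale = _shg_expected_counts(phantom, settings, x_um, y_um)
    img = np.clip(lam / full_scale, 0.0, 1.0).astype(np.float32)
    return Frame(img, settings, float(x_um), float(y_um), settings.z_um)
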