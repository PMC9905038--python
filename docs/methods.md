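# Methods and design notes

This note records the modeling assumptions, parameter choices, and numerical
decisions behind `autoscope`, and where the simulator is (deliberately) less
realistic than a physical instrument.

## 1. The virtual microscope

### Scan settings

Two brightfield and two laser-scanning presets anchor all geometry:

| Preset | FOV (µm) | Pixels | Pixel size (µm) | Notes |
| --- | --- | --- | --- | --- |
| `bf_20x` | 230.9 × 309.0 | 160 × 214 | ≈1.44 | navigation/diagnostic brightfield |
| `bf_4x` | 1154.5 × 1545.0 | 160 × 214 | ≈7.22 | prescan; 5× the 20× FOV |
| `shg_low_quality` | 130.6 × 130.6 | 256² | 0.51 | 0.5 MHz pixel rate (fast, noisy) |
| `shg_high_quality` | 130.6 × 130.6 | 512² | 0.255 | 0.1 MHz pixel rate (slow, clean) |

The low/high-quality pair differs by 2× in sampling and 5× in dwell time, so
the photon-limited SNR ratio is √5 ≈ 2.24 — verified against the renderer in
the unit suite.

### Slide phantom

`make_phantom(PhantomConfig, seed)` lays out non-overlapping circular tissue
cores (default radius 1000 µm ± 10 % jitter) on a bright, nearly achromatic
background chosen so empty tiles fall below the 0.15 mean-saturation tissue
rule. Each core carries:

- **class-conditional texture** — sinusoidal gratings plus Gaussian spots
  whose spatial frequency and density differ between `benign` (0.015 /µm,
  2·10⁻⁴ spots/µm²) and `malignant` (0.045 /µm, 8·10⁻⁴ spots/µm²). The
  classes are separable by construction; the detector's job is to recover
  that separability from rendered pixels.
- **fibers** — line segments with von-Mises-distributed orientations around a
  per-core mean; the concentration κ (default range 1–8) and density are the
  ground truth that the fiber metrics must track.

Scene evaluation is a deterministic function of stage coordinates, so any two
renders of overlapping regions agree exactly where they overlap. Stamp
windows (spots, fibers) are resolved by `searchsorted` against the pixel
coordinate arrays rather than rounded pixel offsets, which is what makes
stitched tiles and a single whole-region render agree to 0 ULP on noise-free,
vignette-free scenes (the stitch-equivalence oracle).

### Focus terrain and defocus blur

The true focus surface z(x, y) is a random 2nd-order polynomial with ±20 µm
amplitude about a 50 µm offset. Defocus by dz µm blurs the scene with a
Gaussian of σ = 0.8·|dz| / pixel_size — a physical gain in µm of blur per µm
of defocus, converted to pixels by each objective's sampling. An earlier
per-pixel gain made the low-magnification prescan *more* defocus-sensitive
than 20× (backwards: low-NA objectives have the larger depth of field) and
destabilised the coarse search; the physical model fixed that, giving the
4× single-pass search a median error of ≈0.3 µm.

Laser-scanning frames add depth attenuation exp(−(dz/15 µm)²), Poisson photon
counts with mean signal · photon_rate · dwell_time, and Gaussian read noise
(σ = 2 counts), normalised by a fixed full-scale count so the expected level
is rate-independent while relative noise scales as 1/√dwell.

### Known unrealism

No stage positioning error or backlash, no illumination drift, no chromatic
effects, no tissue z-thickness (a single focus surface), fibers are straight
segments, and brightfield noise is i.i.d. Gaussian rather than sensor-shaped.
These omissions are deliberate: each would blur an oracle that the test suite
relies on, without changing the software contracts being validated.

## 2. Autofocus

The focus score is the **sum of the binary Canny edge map** (σ = 1.0) of the
grayscale frame. Hysteresis thresholds are fixed at 0.03/0.08 absolute
gradient magnitude for [0, 1] images, and configurable. Quantile-adaptive
thresholds were evaluated and rejected: they re-normalise to each frame's own
gradient distribution, so a defocused, noise-dominated frame still produces
many "edges" and the score can *minimise* at true focus. Fixed thresholds
keep the score a comparable sharpness measure across a z sweep; the curve is
unimodal about true focus at both magnifications on both core classes.

`search_focus` acquires 5 frames on a symmetric grid (default full range
40 µm), fits a cubic spline through the 5 scores, and returns the argmax of
the spline on a 100×-upsampled grid; ties resolve to the smallest z, and a
uniformly zero score (featureless region) returns the centre z flagged
`no_texture`. On exact quadratic profiles the interpolated argmax is correct
to the fine-grid resolution (0.1 µm at defaults). The workflow runs this
per prescan tile (seeding each search from the previous tile's result), then
re-searches a 20 µm range at 20× seeded from the interpolated prescan focus
map. The 20 µm refinement range is deliberately wide: the 20× focus curve
plateaus within ±2 µm, so a narrower range can sample only the plateau and
add error rather than remove it.

## 3. Acquisition geometry

Position lists are serpentine ceil-coverage grids: `ceil(extent / step)`
tiles per axis with the grid centred on the requested bounds, so coverage is
guaranteed for any bounds/overlap. Stitching places each frame by its stage
position on a canvas at the tile pixel pitch, feathering overlaps linearly;
`Mosaic.pixel_to_stage` / `stage_to_pixel` are exact affine inverses
(pixel-centre convention). Pyramids are OME-TIFF with 2× nearest-neighbour
levels and `PhysicalSizeX/Y` metadata; level-0 pixels round-trip exactly.
Polygon annotations (shapely-backed, GeoJSON-serialisable) convert to tile
lists by gridding their bounding box at the target FOV and keeping tiles that
intersect the polygon — coverage is guaranteed, at the cost of some slack at
the polygon boundary.

## 4. ROI detection

Tiles are kept if mean HSV-style saturation ≥ 0.15 (the background is nearly
achromatic; tissue is not). The patch classifier is a small strided CNN
(`nn.SmallCNN`) trained with Adam + cosine annealing on per-channel
standardised patches. Splits are **core-stratified**: no core contributes to
both train and validation, because patches from one core are strongly
correlated and patch-level splits leak. Core-level predictions average the
patch probabilities. Desk scale: 64-px patches, width 8, 40 epochs, batch 32,
lr 2·10⁻⁴.

## 5. Blind-spot denoising (SSD)

Training sees **only noisy frames**: each step masks a random fraction
p = 0.1 of pixels (zero-filled), the U-Net predicts the full frame from the
masked input, and the MSE loss is evaluated **only at the masked sites** — the
network cannot learn the identity because the pixel it must predict is absent
from its input. The `loss_on_all_pixels` ablation switch removes the
restriction and demonstrably collapses the model toward identity (it
reproduces the input noise and yields no PSNR gain), which the acceptance
suite pins as a property.

Inference runs k stochastic passes (default k = ⌈64/p⌉ = 640): each pass
masks a fresh random p-fraction, and each pixel's output is the mean of its
predictions over the passes where it was masked. Pixels never masked fall
back to the input value (and trigger a warning when (1−p)^k > 10⁻⁶). The
per-pass mask seeds are drawn from one seeded stream, so increasing k refines
the same averages — MSE-to-clean is non-increasing in k.

## 6. 2× super-resolution (SISR)

Paired data renders the same in-focus fiber scene twice: fast/low-resolution
(0.5 MHz, 0.51 µm/px) and slow/high-resolution (0.1 MHz, 0.255 µm/px) with
independent noise. Desk scale uses 64→128-px tiles spanning a quarter of the
130.6 µm FOV — the tile size shrinks but the per-pixel sampling of the full
256²/512² scans is preserved, so models trained on tiles transfer to full
frames (and the blind-spot denoiser, trained at the same 0.51 µm/px, applies
directly to the fast tiles). Tiles with mean signal < 0.1 are filtered out. The generator is the same U-Net with a 2× upsampling head,
trained on L1 pixel loss with optional perceptual (frozen random-feature
extractor) and adversarial (5-conv discriminator) terms weighted λp, λg.
With λp = λg = 0 the trainer degenerates to a pure pixel regressor — that
configuration already beats bicubic upsampling, which the acceptance suite
requires. Tiled inference uses a halo of real context per tile; the halo
(default 24 px) exceeds the generator's ≈18-px receptive-field radius, so
tiled and whole-image processing agree to float precision.

## 7. Metrics

PSNR and SSIM (Gaussian 11×11 window, σ = 1.5, K1 = 0.01, K2 = 0.03, sample
covariance) match `skimage` to 10⁻⁶. The Fréchet distance
‖µa−µb‖² + Tr(Σa+Σb−2(ΣaΣb)^{1/2}) is computed on features from a pluggable
extractor (default: the bundled seeded random-filter stack; values are only
comparable within one extractor, and reports record its identifier). Fiber
**density** is the fraction of pixels above an Otsu threshold; **alignment**
is the coherence-weighted circular mean resultant length of doubled
structure-tensor orientations over the foreground — 1 for parallel fibers,
→0 for isotropic fields, and monotone in the simulator's κ (Spearman ρ ≈ 1
against ground truth). Error-ratio summaries divide per-image |processed −
truth| by the set-maximum truth statistic and average; alignment is reported
as a percentage, density as a fraction.

## 8. Desk-scale training hyperparameters

The reference training recipe (Adam, lr 2·10⁻⁴, cosine annealing) assumes
GPU-scale budgets (10⁵–10⁶ steps). At desk scale (10²–10³ steps on one CPU)
that learning rate cannot leave the initialisation basin, so training runs
here use **lr 10⁻³** with cosine annealing: SSD 800 steps (+3.5 dB held-out
gain), SISR 2000 steps (≈30.3 dB vs. 22.7 dB bicubic on held-out pairs),
detector 40 epochs (core accuracy 1.0). Widths stay small (base 8) to keep each im2col forward
pass affordable. These numbers are training-budget adaptations, not claims
about optimal hyperparameters at scale.

## 9. Determinism

Every stochastic component takes an explicit seed; the workflow derives all
per-stage seeds from one `default_rng(seed)` stream. Re-running any
configuration reproduces CSV and TIFF outputs byte-for-byte; OME-TIFF
containers embed a fresh UUID and timestamp, but their pixel data and
pixel-size metadata are identical across runs.
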