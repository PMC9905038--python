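"""Acquisition orchestration: position lists, background/flat-field
correction, stitching, pyramid export, annotation handling, and the
end-to-end multimodal workflow.

The workflow mirrors an automated slide scanner: a fast low-magnification
brightfield prescan with software autofocus builds a stitched overview and a
focus map; regions of interest come either from user annotations (GeoJSON
polygons or CSV tile lists in prescan pixel coordinates) or from a trained
detector; the annotated regions are then re-acquired at high magnification
(brightfield with narrow-range autofocus refinement, then laser-scanning
z-stacks seeded from the refined focus map), with an optional run-time
enhancement hook applied to every laser-scanning frame before it is stored.
"""

from __future__ import annotations

import csv
import json
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import tifffile
from shapely.geometry import Polygon, box, shape, mapping

from .autofocus import build_focus_map, plan_zstack, resample_focus, search_focus
from .phantom import Frame, ScanSettings, SlidePhantom, render_bf, render_shg

__all__ = [
    "PositionEntry",
    "PositionList",
    "Annotation",
    "Mosaic",
    "generate_position_list",
    "estimate_background",
    "flatfield_correct",
    "stitch",
    "export_pyramid",
    "read_pyramid",
    "annotations_to_positions",
    "annotations_from_geojson",
    "annotations_to_geojson",
    "positions_from_csv_tiles",
    "WorkflowConfig",
    "WorkflowResult",
    "run_workflow",
]


# ---------------------------------------------------------------------------
# position lists
# ---------------------------------------------------------------------------


@dataclass
class PositionEntry:
    x_um: float
    y_um: float
    z_um: float | None = None
    tag: str | None = None


@dataclass
class PositionList:
    """Ordered stage targets for one acquisition pass."""

    entries: list
    settings: ScanSettings | None = None

    def __post_init__(self) -> None:
        seen = set()
        unique = []
        for e in self.entries:
            key = (round(e.x_um, 3), round(e.y_um, 3), e.tag)
            if key not in seen:
                seen.add(key)
                unique.append(e)
        self.entries = unique

    def __len__(self) -> int:
        return len(self.entries)

    def __iter__(self):
        return iter(self.entries)

    def xy(self) -> np.ndarray:
        return np.array([[e.x_um, e.y_um] for e in self.entries], dtype=float)

    def to_csv(self, path) -> None:
        with open(path, "w", newline="") as fh:
            writer = csv.writer(fh)
            writer.writerow(["x_um", "y_um", "z_um", "tag"])
            for e in self.entries:
                z = "" if e.z_um is None else f"{e.z_um:.3f}"
                writer.writerow([f"{e.x_um:.3f}", f"{e.y_um:.3f}", z, e.tag or ""])

    @staticmethod
    def from_csv(path, settings: ScanSettings | None = None) -> "PositionList":
        entries = []
        with open(path, newline="") as fh:
            for row in csv.DictReader(fh):
                z = row.get("z_um", "")
                entries.append(PositionEntry(
                    float(row["x_um"]), float(row["y_um"]),
                    float(z) if z not in ("", None) else None,
                    row.get("tag") or None))
        return PositionList(entries, settings=settings)


def generate_position_list(slide_bounds, settings: ScanSettings,
                           overlap_fraction: float = 0.0) -> PositionList:
    """Serpentine grid of FOV centres covering the bounds.

    Effective step is fov * (1 - overlap); edge tiles are clamped inside the
    bounds so the union of FOVs covers them. Bounds smaller than one FOV give
    a single centred position.
    """
    x0, y0, x1, y1 = slide_bounds
    w, h = x1 - x0, y1 - y0
    if w <= 0 or h <= 0:
        raise ValueError("slide bounds must be positive")
    if not 0 <= overlap_fraction < 1:
        raise ValueError("overlap_fraction must be in [0, 1)")
    fw, fh = settings.fov_width_um, settings.fov_height_um

    def centres(extent, lo, fov):
        if fov >= extent:
            return np.array([lo + extent / 2])
        step = fov * (1 - overlap_fraction)
        n = int(np.ceil(extent / step))
        c = lo + fov / 2 + np.arange(n) * step
        return np.clip(c, lo + fov / 2, lo + extent - fov / 2)

    cx = centres(w, x0, fw)
    cy = centres(h, y0, fh)
    entries = []
    for i, y in enumerate(cy):
        xs = cx if i % 2 == 0 else cx[::-1]  # boustrophedon
        for x in xs:
            entries.append(PositionEntry(float(x), float(y), tag=f"r{i}"))
    return PositionList(entries, settings=settings)


# ---------------------------------------------------------------------------
# background / flat-field
# ---------------------------------------------------------------------------


def estimate_background(frames, sat_threshold: float = 0.15) -> np.ndarray:
    """Pixel-wise mean of the frames classified as background (mean HSB
    saturation below the threshold)."""
    from .detection import mean_saturation  # local import: avoid module cycle
    bg = [f.pixels if isinstance(f, Frame) else np.asarray(f) for f in frames]
    bg = [p for p in bg if mean_saturation(p) < sat_threshold]
    if not bg:
        raise ValueError("no background frames found; lower the saturation "
                         "threshold or scan empty slide regions")
    return np.mean(np.stack(bg, axis=0), axis=0)


def flatfield_correct(frame, background, eps: float = 1e-3,
                      clip_max: float = 2.0):
    """Divide by the background so that background regions map to 1.0."""
    pixels = frame.pixels if isinstance(frame, Frame) else np.asarray(frame)
    bg = np.maximum(np.asarray(background, dtype=np.float64), eps)
    if pixels.shape != bg.shape:
        raise ValueError("frame/background shape mismatch")
    out = np.clip(pixels / bg, 0.0, clip_max).astype(np.float32)
    if isinstance(frame, Frame):
        return Frame(out, frame.settings, frame.stage_x_um, frame.stage_y_um,
                     frame.acquired_z_um)
    return out


# ---------------------------------------------------------------------------
# stitching / pyramid export
# ---------------------------------------------------------------------------


@dataclass
class Mosaic:
    """Stitched overview image with its stage-coordinate georeferencing.

    `origin_um` is the stage coordinate of the top-left corner of pixel (0, 0);
    pixel (row, col) is centred at origin + ((col + .5) * psx, (row + .5) * psy).
    """

    image: np.ndarray
    pixel_size_um: tuple  # (psx, psy)
    origin_um: tuple  # (x, y)

    def pixel_to_stage(self, row, col):
        psx, psy = self.pixel_size_um
        return (self.origin_um[0] + (np.asarray(col) + 0.5) * psx,
                self.origin_um[1] + (np.asarray(row) + 0.5) * psy)

    def stage_to_pixel(self, x_um, y_um):
        psx, psy = self.pixel_size_um
        return ((np.asarray(y_um) - self.origin_um[1]) / psy - 0.5,
                (np.asarray(x_um) - self.origin_um[0]) / psx - 0.5)

    @property
    def height(self) -> int:
        return self.image.shape[0]

    @property
    def width(self) -> int:
        return self.image.shape[1]


def _feather_weights(ny: int, nx: int, feather_px: int) -> np.ndarray:
    if feather_px <= 0:
        return np.ones((ny, nx))
    r = np.minimum(np.arange(ny) + 1, np.arange(ny)[::-1] + 1)[:, None]
    c = np.minimum(np.arange(nx) + 1, np.arange(nx)[::-1] + 1)[None, :]
    return np.minimum(np.minimum(r, c), feather_px).astype(np.float64)


def stitch(frames, positions=None, pixel_size_um=None,
           feather_px: int = 16) -> Mosaic:
    """Position-based placement of frames onto a shared canvas; overlapping
    regions are blended with linear feathering.

    Positions default to each frame's stage metadata. All frames must share
    pixel dimensions and pixel size.
    """
    frames = list(frames)
    if not frames:
        raise ValueError("no frames to stitch")
    settings = frames[0].settings
    shape0 = frames[0].pixels.shape
    for f in frames:
        if f.pixels.shape != shape0:
            raise ValueError("inconsistent frame sizes")
    if positions is not None:
        xy = positions.xy() if isinstance(positions, PositionList) else np.asarray(positions, float)
    else:
        xy = np.array([[f.stage_x_um, f.stage_y_um] for f in frames])
    psx = pixel_size_um[0] if isinstance(pixel_size_um, (tuple, list)) else (
        pixel_size_um or settings.pixel_size_x_um)
    psy = pixel_size_um[1] if isinstance(pixel_size_um, (tuple, list)) else (
        pixel_size_um or settings.pixel_size_y_um)
    ny, nx = shape0[0], shape0[1]
    x_lo = xy[:, 0] - nx * psx / 2
    y_lo = xy[:, 1] - ny * psy / 2
    origin = (float(x_lo.min()), float(y_lo.min()))
    cols = np.round((x_lo - origin[0]) / psx).astype(int)
    rows = np.round((y_lo - origin[1]) / psy).astype(int)
    H = int(rows.max()) + ny
    W = int(cols.max()) + nx
    nch = shape0[2] if len(shape0) == 3 else 1
    accum = np.zeros((H, W, nch), dtype=np.float64)
    norm = np.zeros((H, W, 1), dtype=np.float64)
    wts = _feather_weights(ny, nx, feather_px)[..., None]
    for f, r, c in zip(frames, rows, cols):
        img = f.pixels.astype(np.float64)
        if img.ndim == 2:
            img = img[..., None]
        accum[r:r + ny, c:c + nx] += img * wts
        norm[r:r + ny, c:c + nx] += wts
    out = np.divide(accum, norm, out=np.zeros_like(accum), where=norm > 0)
    if nch == 1:
        out = out[..., 0]
    return Mosaic(out.astype(np.float32), (float(psx), float(psy)), origin)


def _downsample2(img: np.ndarray) -> np.ndarray:
    """2x mean-pool with edge replication so dims become ceil(dim / 2)."""
    h, w = img.shape[:2]
    ph, pw = h % 2, w % 2
    if ph or pw:
        pads = ((0, ph), (0, pw)) + ((0, 0),) * (img.ndim - 2)
        img = np.pad(img, pads, mode="edge")
    h2, w2 = img.shape[0] // 2, img.shape[1] // 2
    if img.ndim == 3:
        return img.reshape(h2, 2, w2, 2, -1).mean(axis=(1, 3))
    return img.reshape(h2, 2, w2, 2).mean(axis=(1, 3))


def export_pyramid(mosaic: Mosaic, path, metadata: dict | None = None,
                   levels: int = 3, tile: int = 256) -> Path:
    """Write a tiled multi-resolution OME-TIFF (2x downsampling per level)
    carrying the XY pixel size; level 0 round-trips bit-identically."""
    path = Path(path)
    img = mosaic.image
    rgb = img.ndim == 3
    meta = {
        "axes": "YXS" if rgb else "YX",
        "PhysicalSizeX": mosaic.pixel_size_um[0], "PhysicalSizeXUnit": "µm",
        "PhysicalSizeY": mosaic.pixel_size_um[1], "PhysicalSizeYUnit": "µm",
    }
    if metadata:
        meta.update(metadata)
    opts = dict(tile=(tile, tile), photometric="rgb" if rgb else "minisblack")
    with tifffile.TiffWriter(path, ome=True, bigtiff=False) as tw:
        tw.write(img, subifds=levels - 1, metadata=meta, **opts)
        level = img
        for _ in range(levels - 1):
            level = _downsample2(level)
            tw.write(level.astype(img.dtype), subfiletype=1, **opts)
    return path


def read_pyramid(path) -> tuple[list, dict]:
    """Read back an exported pyramid: ([level arrays], {psx, psy})."""
    with tifffile.TiffFile(path) as tf:
        series = tf.series[0]
        arrays = [lvl.asarray() for lvl in series.levels]
        meta = {}
        if tf.ome_metadata:
            d = tifffile.xml2dict(tf.ome_metadata)
            px = d["OME"]["Image"]["Pixels"]
            meta["psx"] = float(px.get("PhysicalSizeX", 0.0))
            meta["psy"] = float(px.get("PhysicalSizeY", 0.0))
    return arrays, meta


# ---------------------------------------------------------------------------
# annotations
# ---------------------------------------------------------------------------


@dataclass
class Annotation:
    """Closed polygon in prescan pixel coordinates ((x_px, y_px) vertices)."""

    vertices: np.ndarray
    label: str = ""
    source: str = "manual"  # "manual" | "detector"

    def __post_init__(self) -> None:
        v = np.asarray(self.vertices, dtype=float)
        if v.ndim != 2 or v.shape[1] != 2 or len(v) < 3:
            raise ValueError("annotation needs >= 3 (x, y) vertices")
        self.vertices = v

    def polygon(self) -> Polygon:
        poly = Polygon(self.vertices)
        if not poly.is_valid:
            poly = poly.buffer(0)
        return poly


def annotations_from_geojson(path) -> list:
    with open(path) as fh:
        data = json.load(fh)
    features = data["features"] if data.get("type") == "FeatureCollection" else [data]
    out = []
    for feat in features:
        geom = shape(feat["geometry"])
        polys = [geom] if geom.geom_type == "Polygon" else list(geom.geoms)
        props = feat.get("properties") or {}
        for poly in polys:
            out.append(Annotation(np.asarray(poly.exterior.coords)[:-1],
                                  label=props.get("label", ""),
                                  source=props.get("source", "manual")))
    return out


def annotations_to_geojson(annotations, path) -> None:
    features = []
    for ann in annotations:
        features.append({
            "type": "Feature",
            "geometry": mapping(ann.polygon()),
            "properties": {"label": ann.label, "source": ann.source},
        })
    with open(path, "w") as fh:
        json.dump({"type": "FeatureCollection", "features": features}, fh)


def positions_from_csv_tiles(path, mosaic: Mosaic,
                             settings: ScanSettings) -> PositionList:
    """Read a CSV of tile pixel coordinates (x_px, y_px tile centres on the
    prescan) and convert to stage positions."""
    entries = []
    with open(path, newline="") as fh:
        for row in csv.DictReader(fh):
            x, y = mosaic.pixel_to_stage(float(row["y_px"]) - 0.5,
                                         float(row["x_px"]) - 0.5)
            entries.append(PositionEntry(float(x), float(y)))
    return PositionList(entries, settings=settings)


def annotations_to_positions(annotations, mosaic: Mosaic,
                             settings: ScanSettings) -> list:
    """Convert annotations to per-annotation PositionLists of target-FOV
    tiles: the minimal axis-aligned grid anchored at each polygon's bounding
    box, keeping every tile that intersects the polygon."""
    fw, fh = settings.fov_width_um, settings.fov_height_um
    out = []
    for ann in annotations:
        poly_px = ann.polygon()
        if poly_px.area == 0:
            raise ValueError("degenerate annotation polygon (area 0)")
        xs_px, ys_px = poly_px.exterior.coords.xy
        sx, sy = mosaic.pixel_to_stage(np.asarray(ys_px) - 0.5, np.asarray(xs_px) - 0.5)
        poly = Polygon(np.stack([sx, sy], axis=1))
        if not poly.is_valid:
            poly = poly.buffer(0)
        minx, miny, maxx, maxy = poly.bounds
        n_x = max(1, int(np.ceil((maxx - minx) / fw - 1e-9)))
        n_y = max(1, int(np.ceil((maxy - miny) / fh - 1e-9)))
        entries = []
        for i in range(n_y):
            js = range(n_x) if i % 2 == 0 else range(n_x - 1, -1, -1)
            for j in js:
                tile = box(minx + j * fw, miny + i * fh,
                           minx + (j + 1) * fw, miny + (i + 1) * fh)
                if tile.intersection(poly).area > 0:
                    entries.append(PositionEntry(
                        minx + (j + 0.5) * fw, miny + (i + 0.5) * fh,
                        tag=ann.label or None))
        out.append(PositionList(entries, settings=settings))
    return out


# ---------------------------------------------------------------------------
# workflow
# ---------------------------------------------------------------------------


@dataclass
class WorkflowConfig:
    """Configuration of the end-to-end scan (see run_workflow)."""

    seed: int = 0
    prescan_settings: ScanSettings = field(default_factory=ScanSettings.bf_4x)
    hires_settings: ScanSettings = field(default_factory=ScanSettings.bf_20x)
    shg_settings: ScanSettings = field(default_factory=ScanSettings.shg_low_quality)
    slide_bounds: tuple | None = None  # defaults to the full slide
    overlap_fraction: float = 0.0
    sat_threshold: float = 0.15
    initial_z_um: float = 50.0
    prescan_z_range_um: float = 40.0
    hires_z_range_um: float = 20.0  # refinement range at 20x (spans the
    # region where the sharper high-mag focus curve still has curvature)
    autofocus_steps: int = 5
    zstack_step_um: float = 5.0
    zstack_slices: int = 3
    lsm_z_offset_um: float = 0.0
    annotations: list | None = None  # programmatic Annotation objects
    annotation_geojson: str | None = None
    detector: object = None  # trained DetectorModel (optional)
    enhancer_hook: object = None  # callable Frame.pixels -> ndarray (optional)
    max_tiles_per_annotation: int | None = None
    out_dir: str | None = None
    export_ome: bool = True


@dataclass
class WorkflowResult:
    status: str
    prescan_positions: PositionList | None = None
    background: np.ndarray | None = None
    mosaic: Mosaic | None = None
    ome_path: Path | None = None
    focus_map_prescan: object = None
    focus_map_hires: object = None
    annotations: list = field(default_factory=list)
    bf_positions: list = field(default_factory=list)
    bf_tiles: list = field(default_factory=list)
    shg_positions: list = field(default_factory=list)
    shg_stacks: list = field(default_factory=list)
    logs: list = field(default_factory=list)


def run_workflow(phantom: SlidePhantom, config: WorkflowConfig) -> WorkflowResult:
    """Execute the full scan against the virtual microscope.

    Stages: low-magnification prescan with autofocus, background estimation and
    flat-field correction, stitching (+ optional OME-TIFF pyramid export),
    annotation/detection, high-magnification brightfield with focus-map-seeded
    narrow-range autofocus, and laser-scanning z-stacks with the enhancement
    hook applied per frame. Re-running with the same config and seed
    reproduces every output bit-identically.
    """
    cfg = config
    result = WorkflowResult(status="running")
    rs = np.random.default_rng(cfg.seed)

    def next_seed() -> int:
        return int(rs.integers(0, 2 ** 31))

    def log(stage: str, t0: float, **info) -> None:
        result.logs.append({"stage": stage, "elapsed_s": time.perf_counter() - t0,
                            **info})

    out_dir = Path(cfg.out_dir) if cfg.out_dir else None
    if out_dir:
        out_dir.mkdir(parents=True, exist_ok=True)

    # -- stage 1: prescan with autofocus -------------------------------------
    t0 = time.perf_counter()
    bounds = cfg.slide_bounds or (0.0, 0.0, phantom.width_um, phantom.height_um)
    positions = generate_position_list(bounds, cfg.prescan_settings,
                                       cfg.overlap_fraction)
    result.prescan_positions = positions
    frames, focus_records = [], []
    z_prev = cfg.initial_z_um  # persists across tiles within the pass
    for entry in positions:
        res = search_focus(
            lambda z: render_bf(phantom, cfg.prescan_settings.with_z(z),
                                entry.x_um, entry.y_um, seed=next_seed()),
            z_center_um=z_prev, z_range_um=cfg.prescan_z_range_um,
            n_steps=cfg.autofocus_steps)
        if not res.no_texture:
            z_prev = res.z_best_um
        entry.z_um = res.z_best_um
        focus_records.append((entry.x_um, entry.y_um, res.z_best_um))
        frames.append(render_bf(phantom, cfg.prescan_settings.with_z(res.z_best_um),
                                entry.x_um, entry.y_um, seed=next_seed()))
    result.focus_map_prescan = build_focus_map(focus_records)
    log("prescan", t0, n_tiles=len(frames))

    # -- stage 2: background + flat-field + stitch ----------------------------
    t0 = time.perf_counter()
    try:
        background = estimate_background(frames, cfg.sat_threshold)
        corrected = [flatfield_correct(f, background) for f in frames]
        result.background = background
    except ValueError:
        corrected = frames
        result.logs.append({"stage": "background", "note": "no background tiles; "
                            "flat-field correction skipped"})
    result.mosaic = stitch(corrected, positions)
    if out_dir and cfg.export_ome:
        result.ome_path = export_pyramid(result.mosaic, out_dir / "prescan.ome.tif")
    if out_dir:
        positions.to_csv(out_dir / "prescan_positions.csv")
        result.focus_map_prescan.to_csv(out_dir / "focus_map_prescan.csv")
    log("stitch", t0, shape=list(result.mosaic.image.shape))

    # -- stage 3: annotations ---------------------------------------------------
    t0 = time.perf_counter()
    annotations = list(cfg.annotations or [])
    if cfg.annotation_geojson:
        annotations.extend(annotations_from_geojson(cfg.annotation_geojson))
    if cfg.detector is not None:
        from .detection import detect_rois
        _, detected = detect_rois(cfg.detector, result.mosaic,
                                  sat_threshold=cfg.sat_threshold)
        annotations.extend(detected)
    result.annotations = annotations
    log("annotate", t0, n_annotations=len(annotations))
    if not annotations:
        result.status = "prescan_only"
        return result

    # -- stage 4: 20x brightfield with narrow-range autofocus ----------------
    t0 = time.perf_counter()
    bf_groups = annotations_to_positions(annotations, result.mosaic,
                                         cfg.hires_settings)
    hires_records = []
    for group in bf_groups:
        entries = group.entries
        if cfg.max_tiles_per_annotation is not None:
            entries = entries[:cfg.max_tiles_per_annotation]
            group.entries = entries
        seeded = resample_focus(result.focus_map_prescan, group)
        tiles = []
        for entry in seeded:
            res = search_focus(
                lambda z: render_bf(phantom, cfg.hires_settings.with_z(z),
                                    entry.x_um, entry.y_um, seed=next_seed()),
                z_center_um=entry.z_um, z_range_um=cfg.hires_z_range_um,
                n_steps=cfg.autofocus_steps)
            entry.z_um = res.z_best_um
            hires_records.append((entry.x_um, entry.y_um, res.z_best_um))
            tiles.append(render_bf(phantom, cfg.hires_settings.with_z(res.z_best_um),
                                   entry.x_um, entry.y_um, seed=next_seed()))
        result.bf_positions.append(PositionList(list(seeded.entries),
                                                settings=cfg.hires_settings))
        result.bf_tiles.append(tiles)
    result.focus_map_hires = build_focus_map(hires_records)
    if out_dir:
        result.focus_map_hires.to_csv(out_dir / "focus_map_hires.csv")
        for i, group in enumerate(result.bf_positions):
            group.to_csv(out_dir / f"bf_positions_{i}.csv")
    log("bf_hires", t0, n_tiles=len(hires_records))

    # -- stage 5: laser-scanning z-stacks with enhancement hook ---------------
    t0 = time.perf_counter()
    shg_groups = annotations_to_positions(annotations, result.mosaic,
                                          cfg.shg_settings)
    hook = cfg.enhancer_hook
    n_frames = 0
    for gi, group in enumerate(shg_groups):
        entries = group.entries
        if cfg.max_tiles_per_annotation is not None:
            entries = entries[:cfg.max_tiles_per_annotation]
            group.entries = entries
        seeded = resample_focus(result.focus_map_hires, group,
                                z_offset_um=cfg.lsm_z_offset_um)
        stacks = []
        for entry in seeded:
            zs = plan_zstack(entry.z_um, cfg.zstack_step_um, cfg.zstack_slices)
            stack = []
            for z in zs:
                frame = render_shg(phantom, cfg.shg_settings.with_z(z),
                                   entry.x_um, entry.y_um, seed=next_seed())
                pixels = hook(frame.pixels) if hook is not None else frame.pixels
                stack.append(pixels)
                n_frames += 1
            stacks.append(np.stack(stack, axis=0))
            if out_dir:
                tifffile.imwrite(
                    out_dir / f"shg_{gi:02d}_{entry.x_um:.0f}_{entry.y_um:.0f}.tif",
                    stacks[-1])
        result.shg_positions.append(PositionList(list(seeded.entries),
                                                 settings=cfg.shg_settings))
        result.shg_stacks.append(stacks)
        if out_dir:
            result.shg_positions[-1].to_csv(out_dir / f"shg_positions_{gi}.csv")
    log("lsm", t0, n_frames=n_frames, enhanced=hook is not None)

    result.status = "complete"
    return result
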