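"""Software autofocus and focus maps.

The focus score of a frame is the sum of its binary Canny edge map. The search
acquires five frames at equally spaced z positions symmetric about the current
estimate, cubic-interpolates the five scores on an upsampled z grid, and
returns the z of the interpolated maximum. In-focus z values recorded during a
scan form a FocusMap that is interpolated (piecewise-linear on scattered
nodes, nearest-node outside their hull) to seed focus for later
higher-magnification or laser-scanning passes, optionally with a constant
z offset between modalities.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Sequence

import numpy as np
from scipy.interpolate import (CubicSpline, LinearNDInterpolator,
                               NearestNDInterpolator, interp1d)
from skimage.color import rgb2gray
from skimage.feature import canny

from .phantom import Frame

__all__ = [
    "focus_score",
    "FocusSearchResult",
    "search_focus",
    "FocusMap",
    "build_focus_map",
    "resample_focus",
    "plan_zstack",
]


def focus_score(frame, sigma: float = 1.0,
                low_threshold: float = 0.03, high_threshold: float = 0.08) -> float:
    """Canny edge count of a frame (RGB frames are converted to grayscale).

    Hysteresis thresholds are absolute gradient magnitudes for images in
    [0, 1]. Quantile thresholds adapt to each frame's own gradient
    distribution, which lets sensor noise pass as edges in defocused frames
    and destroys the peak at best focus; fixed thresholds keep the score a
    comparable sharpness measure across a z sweep. A constant frame scores 0.
    """
    pixels = frame.pixels if isinstance(frame, Frame) else np.asarray(frame)
    if pixels.ndim == 3:
        pixels = rgb2gray(pixels)
    pixels = pixels.astype(np.float64)
    if pixels.size == 0:
        raise ValueError("empty frame")
    if np.ptp(pixels) == 0:
        return 0.0
    edges = canny(pixels, sigma=sigma, low_threshold=low_threshold,
                  high_threshold=high_threshold)
    return float(edges.sum())


@dataclass
class FocusSearchResult:
    z_best_um: float
    z_positions: np.ndarray
    scores: np.ndarray
    no_texture: bool = False

    def __float__(self) -> float:
        return self.z_best_um


def search_focus(acquire: Callable[[float], object], z_center_um: float,
                 z_range_um: float, n_steps: int = 5,
                 upsample_factor: int = 100,
                 score_fn: Callable = focus_score) -> FocusSearchResult:
    """Acquire n_steps frames on a symmetric z grid and return the z of the
    maximum of the cubic-interpolated score array.

    Ties in the upsampled argmax resolve to the smallest z. If every score is
    zero (no texture), the centre z is returned with ``no_texture=True``.
    """
    if n_steps < 3 or n_steps % 2 == 0:
        raise ValueError("n_steps must be an odd integer >= 3")
    if z_range_um <= 0:
        raise ValueError("z_range_um must be positive")
    zs = z_center_um + np.linspace(-z_range_um / 2, z_range_um / 2, n_steps)
    scores = np.array([score_fn(acquire(float(z))) for z in zs], dtype=float)
    if np.all(scores == 0):
        return FocusSearchResult(float(z_center_um), zs, scores, no_texture=True)
    spline = CubicSpline(zs, scores)
    fine = np.linspace(zs[0], zs[-1], (n_steps - 1) * upsample_factor + 1)
    vals = spline(fine)
    z_best = float(fine[int(np.argmax(vals))])  # argmax takes the first (smallest z)
    return FocusSearchResult(z_best, zs, scores)


@dataclass
class FocusMap:
    """Sparse (x, y) -> z mapping with linear interpolation inside the node
    hull and nearest-node extrapolation outside it.

    Queries at a node's exact (x, y) return the recorded z. Duplicate (x, y)
    records resolve last-write-wins at construction.
    """

    nodes: np.ndarray  # (n, 3): x_um, y_um, z_um
    modality_z_offset_um: float = 0.0
    _linear: object = field(default=None, repr=False, compare=False)
    _nearest: object = field(default=None, repr=False, compare=False)

    def __post_init__(self) -> None:
        nodes = np.asarray(self.nodes, dtype=float)
        if nodes.ndim != 2 or nodes.shape[1] != 3 or len(nodes) == 0:
            raise ValueError("nodes must be a non-empty (n, 3) array")
        self.nodes = nodes
        xy, z = nodes[:, :2], nodes[:, 2]
        self._nearest = NearestNDInterpolator(xy, z)
        self._linear = None
        if len(nodes) >= 3:
            try:
                self._linear = LinearNDInterpolator(xy, z)
            except Exception:  # collinear nodes: fall back below
                self._linear = None
        if self._linear is None and len(nodes) >= 2:
            # collinear or 1-D arrangements: linear interpolation along the
            # dominant axis when the nodes are axis-monotone
            for axis in (0, 1):
                vals, idx = np.unique(xy[:, axis], return_index=True)
                if len(vals) == len(nodes) and np.allclose(
                        xy[:, 1 - axis], xy[0, 1 - axis]):
                    f = interp1d(vals, z[idx], kind="linear",
                                 bounds_error=False, fill_value=(z[idx][0], z[idx][-1]))
                    self._linear = ("1d", axis, f)
                    break

    def query(self, x_um, y_um) -> np.ndarray:
        x = np.atleast_1d(np.asarray(x_um, dtype=float))
        y = np.atleast_1d(np.asarray(y_um, dtype=float))
        if isinstance(self._linear, tuple):
            _, axis, f = self._linear
            z = f(x if axis == 0 else y)
        elif self._linear is not None:
            z = self._linear(x, y)
        else:
            z = np.full(x.shape, np.nan)
        z = np.asarray(z, dtype=float)
        bad = ~np.isfinite(z)
        if np.any(bad):
            z[bad] = self._nearest(x[bad], y[bad])
        out = z + self.modality_z_offset_um
        if np.isscalar(x_um) and np.isscalar(y_um):
            return float(out[0])
        return out

    def extrapolated(self, x_um, y_um) -> np.ndarray:
        """Boolean mask of queries outside the node hull (nearest-node used)."""
        x = np.atleast_1d(np.asarray(x_um, dtype=float))
        y = np.atleast_1d(np.asarray(y_um, dtype=float))
        if isinstance(self._linear, tuple) or self._linear is None:
            mins = self.nodes[:, :2].min(axis=0)
            maxs = self.nodes[:, :2].max(axis=0)
            return ~((x >= mins[0]) & (x <= maxs[0]) & (y >= mins[1]) & (y <= maxs[1]))
        return ~np.isfinite(np.asarray(self._linear(x, y), dtype=float))

    # -- serialization -------------------------------------------------------

    def to_csv(self, path) -> None:
        with open(path, "w", newline="") as fh:
            writer = csv.writer(fh)
            writer.writerow(["x_um", "y_um", "z_um"])
            for x, y, z in self.nodes:
                writer.writerow([f"{x:.3f}", f"{y:.3f}", f"{z:.3f}"])

    @staticmethod
    def from_csv(path, modality_z_offset_um: float = 0.0) -> "FocusMap":
        rows = []
        with open(path, newline="") as fh:
            reader = csv.DictReader(fh)
            for row in reader:
                rows.append((float(row["x_um"]), float(row["y_um"]), float(row["z_um"])))
        return FocusMap(np.array(rows), modality_z_offset_um)


def build_focus_map(records: Sequence[tuple], modality_z_offset_um: float = 0.0
                    ) -> FocusMap:
    """Build a FocusMap from (x_um, y_um, z_um) records; duplicates of the
    same (x, y) resolve last-write-wins."""
    if len(records) == 0:
        raise ValueError("at least one focus record is required")
    seen: dict[tuple, float] = {}
    order: list[tuple] = []
    for x, y, z in records:
        key = (float(x), float(y))
        if key not in seen:
            order.append(key)
        seen[key] = float(z)
    nodes = np.array([[x, y, seen[(x, y)]] for x, y in order])
    return FocusMap(nodes, modality_z_offset_um)


def resample_focus(focus_map: FocusMap, positions, z_offset_um: float = 0.0):
    """Annotate a PositionList with interpolated z + offset (order preserved).

    Returns a new PositionList; entries outside the map's node hull receive
    nearest-node z and are tagged 'extrapolated' in their per-entry flags.
    """
    from .acquisition import PositionEntry, PositionList  # local: avoid cycle
    xs = np.array([e.x_um for e in positions.entries])
    ys = np.array([e.y_um for e in positions.entries])
    if len(xs) == 0:
        return PositionList([], settings=positions.settings)
    zs = np.atleast_1d(focus_map.query(xs, ys)) + z_offset_um
    extrap = focus_map.extrapolated(xs, ys)
    entries = [PositionEntry(e.x_um, e.y_um, float(z),
                             tag=e.tag if not ex else (e.tag or "") + "|extrapolated")
               for e, z, ex in zip(positions.entries, zs, extrap)]
    return PositionList(entries, settings=positions.settings)


def plan_zstack(center_z_um: float, step_um: float, n_slices: int) -> list[float]:
    """n z-values with the given spacing, symmetric about the centre (which is
    included when n is odd)."""
    if n_slices < 1:
        raise ValueError("n_slices must be >= 1")
    if step_um <= 0:
        raise ValueError("step_um must be positive")
    offsets = (np.arange(n_slices) - (n_slices - 1) / 2) * step_um
    return [float(center_z_um + o) for o in offsets]
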