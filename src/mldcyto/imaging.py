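"""Focal-plane fusion, background thresholding and spot detection.

Converts a stack of focal-plane fluorescence images into a per-frame
*binary element map*: the pixel coordinates of the intensity peaks that
mark nanoparticle-loaded vesicles.  These light points are the only
information carried forward by the rest of the pipeline.

Coordinate convention: 0-based, ``x`` = column index, ``y`` = row index.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.ndimage import maximum_filter1d

log = logging.getLogger(__name__)


@dataclass
class FrameStack:
    """Focal-plane images for one timepoint on a shared pixel grid.

    ``planes`` has shape ``(n_planes, height, width)``; intensities are
    arbitrary detector units.
    """

    planes: np.ndarray
    frame_index: int
    timestamp_min: float
    pixel_size_um: float = 0.25

    def __post_init__(self) -> None:
        self.planes = np.asarray(self.planes)
        if self.planes.ndim == 2:
            self.planes = self.planes[None]
        if self.planes.ndim != 3:
            raise ValueError("planes must be a (n_planes, H, W) array")
        if self.planes.shape[0] == 0:
            raise ValueError("FrameStack needs at least one plane")
        if self.pixel_size_um <= 0:
            raise ValueError("pixel_size_um must be positive")

    @property
    def shape(self) -> tuple[int, int]:
        return self.planes.shape[1], self.planes.shape[2]


@dataclass
class CompositeImage:
    """All-in-focus composite with the plane chosen for each region."""

    intensity: np.ndarray
    source_plane: np.ndarray

    def __post_init__(self) -> None:
        self.intensity = np.asarray(self.intensity, dtype=float)
        self.source_plane = np.asarray(self.source_plane, dtype=int)
        if self.intensity.shape != self.source_plane.shape:
            raise ValueError("intensity and source_plane shapes differ")


@dataclass
class BinaryElementMap:
    """Detected light points ("binary elements") of one frame.

    ``elements`` is an ``(n, 2)`` float array of ``(x, y)`` pixel
    coordinates, duplicate-free and inside the image bounds.
    """

    frame_index: int
    elements: np.ndarray
    threshold_used: float

    def __post_init__(self) -> None:
        self.elements = np.asarray(self.elements, dtype=float).reshape(-1, 2)

    def __len__(self) -> int:
        return len(self.elements)


def _block_edges(n: int, size: int) -> np.ndarray:
    """Start offsets of size-``size`` tiles covering ``[0, n)`` (last may be partial)."""
    return np.arange(0, n, size)


def _gradient_energy(plane: np.ndarray) -> np.ndarray:
    """Per-pixel absolute-gradient magnitude |dI/dx| + |dI/dy|.

    Forward differences; the final row/column of each difference is
    padded with zero so the map keeps the image shape and a block sum
    counts every interior difference exactly once.
    """
    p = plane.astype(float)
    gx = np.zeros_like(p)
    gy = np.zeros_like(p)
    gx[:, :-1] = np.abs(np.diff(p, axis=1))
    gy[:-1, :] = np.abs(np.diff(p, axis=0))
    return gx + gy


def fuse_focal_planes(stack: FrameStack, region_px: int = 32) -> CompositeImage:
    """Fuse focal planes into a best-contrast composite.

    The field is tiled into ``region_px`` x ``region_px`` blocks (edge
    blocks may be partial).  For each block the plane with the largest
    sum of absolute horizontal plus vertical intensity differences is
    copied into the composite; ties go to the lowest plane index.
    """
    if region_px < 2:
        raise ValueError("region_px must be >= 2")
    planes = stack.planes
    n_planes, h, w = planes.shape
    if region_px > max(h, w):
        log.warning(
            "fusion region %d px exceeds image size %dx%d; using one whole-image region",
            region_px, h, w,
        )
        region_px = max(h, w)

    if n_planes == 1:
        return CompositeImage(planes[0].astype(float), np.zeros((h, w), dtype=int))

    ys = _block_edges(h, region_px)
    xs = _block_edges(w, region_px)
    y_ends = np.minimum(ys + region_px, h)
    x_ends = np.minimum(xs + region_px, w)
    block_sums = np.empty((n_planes, len(ys), len(xs)))
    for pi, plane in enumerate(planes):
        p = plane.astype(float)
        gx = np.zeros_like(p)
        gy = np.zeros_like(p)
        gx[:, :-1] = np.abs(np.diff(p, axis=1))
        gy[:-1, :] = np.abs(np.diff(p, axis=0))
        # Only differences internal to a block count: subtract the
        # boundary column/row terms that reduceat would carry across.
        gx_rows = np.add.reduceat(gx, ys, axis=0)          # (nby, W)
        sx = np.add.reduceat(gx_rows, xs, axis=1) - gx_rows[:, x_ends - 1]
        gy_cols = np.add.reduceat(gy, xs, axis=1)          # (H, nbx)
        sy = np.add.reduceat(gy_cols, ys, axis=0) - gy_cols[y_ends - 1, :]
        block_sums[pi] = sx + sy
    best = np.argmax(block_sums, axis=0)  # ties -> lowest plane index (argmax contract)

    intensity = np.empty((h, w), dtype=float)
    source = np.empty((h, w), dtype=int)
    for i, y0 in enumerate(ys):
        y1 = min(y0 + region_px, h)
        for j, x0 in enumerate(xs):
            x1 = min(x0 + region_px, w)
            p = int(best[i, j])
            intensity[y0:y1, x0:x1] = planes[p, y0:y1, x0:x1]
            source[y0:y1, x0:x1] = p
    return CompositeImage(intensity, source)


def compute_threshold(image: CompositeImage, sigma_mult: float = 1.0,
                      population: bool = True) -> float:
    """Background threshold theta = mu + sigma over all composite pixels.

    mu is the mean intensity and sigma the (population, by default)
    standard deviation; the sigma term absorbs background variability.
    """
    data = image.intensity
    if data.size == 0:
        raise ValueError("empty image")
    ddof = 0 if population else 1
    return float(data.mean() + sigma_mult * data.std(ddof=ddof))


def apply_threshold(image: CompositeImage, theta: float) -> np.ndarray:
    """Binary step function: 1 where intensity > theta, else 0.

    Negative thresholds are clamped to zero.
    """
    theta = max(float(theta), 0.0)
    return image.intensity > theta


def detect_peaks(image: CompositeImage, mask: np.ndarray,
                 window_px: int = 5, frame_index: int = 0) -> BinaryElementMap:
    """Locate intensity peaks by cross-referencing row and column profiles.

    A pixel is a peak when it is simultaneously the maximum of its row
    profile and of its column profile within a ``window_px`` window and
    lies inside ``mask``.  Plateaus of equal maxima yield exactly one
    element, at the lowest ``y`` then lowest ``x`` of the plateau.
    """
    if window_px < 3 or window_px % 2 == 0:
        raise ValueError("window_px must be odd and >= 3")
    data = image.intensity
    mask = np.asarray(mask, dtype=bool)
    if mask.shape != data.shape:
        raise ValueError("mask shape does not match image")

    row_max = maximum_filter1d(data, size=window_px, axis=1, mode="nearest")
    col_max = maximum_filter1d(data, size=window_px, axis=0, mode="nearest")
    qualifies = mask & (data >= row_max) & (data >= col_max)

    # One element per 4-connected plateau of qualifying pixels.  Two
    # qualifying pixels that are 4-adjacent necessarily share a row or a
    # column profile and hence an intensity, so each component is a
    # constant plateau; emit its lowest (y, x).
    ys, xs = np.nonzero(qualifies)
    if len(ys) == 0:
        return BinaryElementMap(frame_index, np.empty((0, 2)), 0.0)
    elements = _plateau_representatives(qualifies, ys, xs)
    return BinaryElementMap(frame_index, elements, 0.0)


def _plateau_representatives(qualifies: np.ndarray, ys: np.ndarray,
                             xs: np.ndarray) -> np.ndarray:
    """Collapse 4-connected plateaus to one (x, y) each via union-find."""
    h, w = qualifies.shape
    idx = {(y, x): i for i, (y, x) in enumerate(zip(ys.tolist(), xs.tolist()))}
    parent = list(range(len(ys)))

    def find(a: int) -> int:
        while parent[a] != a:
            parent[a] = parent[parent[a]]
            a = parent[a]
        return a

    for i, (y, x) in enumerate(zip(ys.tolist(), xs.tolist())):
        for ny, nx in ((y + 1, x), (y, x + 1)):
            j = idx.get((ny, nx))
            if j is not None:
                ra, rb = find(i), find(j)
                if ra != rb:
                    parent[rb] = ra
    groups: dict[int, tuple[int, int]] = {}
    for i, (y, x) in enumerate(zip(ys.tolist(), xs.tolist())):
        r = find(i)
        if r not in groups or (y, x) < groups[r]:
            groups[r] = (y, x)
    pts = sorted(groups.values())
    return np.array([[x, y] for (y, x) in pts], dtype=float)


def detect_elements(stack: FrameStack, region_px: int = 32, window_px: int = 5,
                    sigma_mult: float = 1.0, population: bool = True,
                    theta: float | None = None) -> tuple[CompositeImage, BinaryElementMap]:
    """Full imaging stage: fuse, threshold and peak-find one frame.

    ``theta`` overrides the automatic mu+sigma threshold (used by the
    operational-range sweep).
    """
    composite = fuse_focal_planes(stack, region_px)
    if theta is None:
        theta = compute_threshold(composite, sigma_mult, population)
    mask = apply_threshold(composite, theta)
    emap = detect_peaks(composite, mask, window_px, frame_index=stack.frame_index)
    emap.threshold_used = float(max(theta, 0.0))
    return composite, emap
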