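"""Cell detection, crop stabilization, segmentation and center alignment.

The experimental workflow detects the cell in full-field frames, crops a
fixed-size window around it, separates cell from background, and removes
lateral drift by centering the minimal enclosing circle of the cell contour
in every frame.  Detection and segmentation are deterministic classical
operators (Otsu threshold, morphology, connected components) behind small
functional interfaces, so that trained detectors/segmenters can be plugged
in for experimental data.

Coordinates are 0-based, row-major; bounding boxes are half-open
``[min, max)``; subpixel positions are pixel-center coordinates.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from skimage.filters import threshold_otsu
from skimage.morphology import disk

from .errors import NoCellFound, SegmentationEmpty, ValidationError
from .phantom import ProjectionFrame, ProjectionStack

__all__ = [
    "BoundingBox",
    "CellMask",
    "EnclosingCircle",
    "detect_cell",
    "crop_stabilize",
    "segment_cell",
    "min_enclosing_circle",
    "smooth_circles",
    "center_align",
]


@dataclass(frozen=True)
class BoundingBox:
    row_min: int
    col_min: int
    row_max: int
    col_max: int

    def __post_init__(self) -> None:
        if self.row_max <= self.row_min or self.col_max <= self.col_min:
            raise ValidationError("bounding box must have positive extent")

    @property
    def center(self) -> tuple[float, float]:
        return ((self.row_min + self.row_max - 1) / 2.0,
                (self.col_min + self.col_max - 1) / 2.0)

    @property
    def shape(self) -> tuple[int, int]:
        return (self.row_max - self.row_min, self.col_max - self.col_min)


@dataclass
class CellMask:
    pixels: np.ndarray  # bool, same shape as its frame

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels, dtype=bool)
        if self.pixels.ndim != 2:
            raise ValidationError("mask must be 2-dimensional")


@dataclass(frozen=True)
class EnclosingCircle:
    center_row: float
    center_col: float
    radius: float

    def __post_init__(self) -> None:
        if self.radius < 0:
            raise ValidationError("radius must be nonnegative")


def _foreground(pixels: np.ndarray, polarity: str) -> np.ndarray:
    """Otsu-threshold a frame; ``polarity='dark'`` inverts first (brightfield)."""
    img = np.asarray(pixels, dtype=float)
    if polarity == "dark":
        img = img.max() - img
    elif polarity != "bright":
        raise ValidationError(f"polarity must be 'bright' or 'dark', got {polarity!r}")
    if np.ptp(img) == 0:
        return np.zeros(img.shape, dtype=bool)
    return img > threshold_otsu(img)


def detect_cell(
    frame: ProjectionFrame,
    min_area: float = 50.0,
    margin: int = 4,
    polarity: str = "bright",
) -> BoundingBox:
    """Bounding box of the largest connected foreground component.

    Global Otsu thresholding, connected-component labelling, largest
    component by area; the box is padded by ``margin`` pixels and clipped to
    the frame.  Raises :class:`NoCellFound` when no component reaches
    ``min_area`` pixels².
    """
    fg = _foreground(frame.pixels, polarity)
    labels, n = ndimage.label(fg)
    if n == 0:
        raise NoCellFound("no foreground component found")
    sizes = ndimage.sum_labels(np.ones_like(labels), labels, index=np.arange(1, n + 1))
    best = int(np.argmax(sizes)) + 1
    if sizes[best - 1] < min_area:
        raise NoCellFound(
            f"largest component has area {sizes[best - 1]:.0f} px² < {min_area}"
        )
    rows, cols = np.nonzero(labels == best)
    h, w = frame.pixels.shape
    return BoundingBox(
        row_min=max(0, int(rows.min()) - margin),
        col_min=max(0, int(cols.min()) - margin),
        row_max=min(h, int(rows.max()) + 1 + margin),
        col_max=min(w, int(cols.max()) + 1 + margin),
    )


def _smooth_centers(centers: np.ndarray, window: int) -> np.ndarray:
    """Centered moving average with reflected ends, per coordinate."""
    if window <= 1 or len(centers) == 1:
        return centers.astype(float)
    pad = window // 2
    padded = np.pad(centers, ((pad, pad), (0, 0)), mode="reflect")
    kernel = np.ones(window) / window
    out = np.column_stack(
        [np.convolve(padded[:, k], kernel, mode="valid") for k in range(2)]
    )
    return out[: len(centers)]


def crop_stabilize(
    stack: ProjectionStack,
    boxes: list[BoundingBox],
    size: int,
    smooth_window: int = 9,
) -> ProjectionStack:
    """Crop every frame to a ``size``×``size`` window that drifts smoothly.

    Per-frame box centers are smoothed by a centered moving average
    (reflected ends) before cropping, so detection jitter does not shake the
    cropped video.  Out-of-frame pixels are zero-padded.
    """
    if size % 2 != 0:
        raise ValidationError("crop size must be even")
    if len(boxes) != len(stack):
        raise ValidationError("one bounding box per frame is required")
    h, w = stack.frames[0].pixels.shape
    for b in boxes:
        if b.shape[0] > size or b.shape[1] > size:
            raise ValidationError("crop size must cover every bounding box")

    centers = np.array([b.center for b in boxes])
    centers = _smooth_centers(centers, smooth_window)

    out_frames = []
    half = size // 2
    for i, frame in enumerate(stack.frames):
        r0 = int(round(centers[i, 0] - half + 0.5))
        c0 = int(round(centers[i, 1] - half + 0.5))
        window = np.zeros((size, size), dtype=frame.pixels.dtype)
        rs, re = max(r0, 0), min(r0 + size, h)
        cs, ce = max(c0, 0), min(c0 + size, w)
        if rs < re and cs < ce:
            window[rs - r0 : re - r0, cs - c0 : ce - c0] = frame.pixels[rs:re, cs:ce]
        out_frames.append(
            ProjectionFrame(pixels=window, pixel_size=frame.pixel_size, index=frame.index)
        )
    return ProjectionStack(frames=out_frames, truth_angles=stack.truth_angles)


def segment_cell(
    frame: ProjectionFrame,
    polarity: str = "bright",
    closing_radius: int = 3,
) -> CellMask:
    """Binary cell mask: Otsu threshold, closing, hole fill, largest component."""
    fg = _foreground(frame.pixels, polarity)
    if closing_radius > 0:
        fg = ndimage.binary_closing(fg, structure=disk(closing_radius))
    fg = ndimage.binary_fill_holes(fg)
    labels, n = ndimage.label(fg)
    if n == 0:
        raise SegmentationEmpty("segmentation produced an empty mask")
    sizes = ndimage.sum_labels(np.ones_like(labels), labels, index=np.arange(1, n + 1))
    best = int(np.argmax(sizes)) + 1
    return CellMask(pixels=labels == best)


def _circle_from(points: np.ndarray) -> tuple[float, float, float]:
    """Exact circle through 0–3 boundary points (helper for Welzl)."""
    if len(points) == 0:
        return (0.0, 0.0, 0.0)
    if len(points) == 1:
        return (points[0][0], points[0][1], 0.0)
    if len(points) == 2:
        c = (points[0] + points[1]) / 2.0
        r = float(np.linalg.norm(points[0] - c))
        return (c[0], c[1], r)
    (ax, ay), (bx, by), (cx, cy) = points
    d = 2.0 * (ax * (by - cy) + bx * (cy - ay) + cx * (ay - by))
    if abs(d) < 1e-12:
        # collinear: fall back to the farthest pair
        best = max(
            ((i, j) for i in range(3) for j in range(i + 1, 3)),
            key=lambda ij: np.linalg.norm(points[ij[0]] - points[ij[1]]),
        )
        return _circle_from(points[list(best)])
    ux = ((ax**2 + ay**2) * (by - cy) + (bx**2 + by**2) * (cy - ay)
          + (cx**2 + cy**2) * (ay - by)) / d
    uy = ((ax**2 + ay**2) * (cx - bx) + (bx**2 + by**2) * (ax - cx)
          + (cx**2 + cy**2) * (bx - ax)) / d
    center = np.array([ux, uy])
    r = float(np.linalg.norm(points[0] - center))
    return (ux, uy, r)


def _welzl(points: np.ndarray, rng: np.random.Generator) -> tuple[float, float, float]:
    """Welzl's move-to-front algorithm, iterative over a shuffled point list."""
    pts = points[rng.permutation(len(points))]
    cx, cy, r = _circle_from(pts[:1])
    for i in range(1, len(pts)):
        if np.hypot(pts[i, 0] - cx, pts[i, 1] - cy) <= r + 1e-9:
            continue
        cx, cy, r = _circle_from(pts[i : i + 1])
        for j in range(i):
            if np.hypot(pts[j, 0] - cx, pts[j, 1] - cy) <= r + 1e-9:
                continue
            c = (pts[i] + pts[j]) / 2.0
            cx, cy = c
            r = float(np.linalg.norm(pts[i] - c))
            for k in range(j):
                if np.hypot(pts[k, 0] - cx, pts[k, 1] - cy) <= r + 1e-9:
                    continue
                cx, cy, r = _circle_from(np.array([pts[i], pts[j], pts[k]]))
    return cx, cy, r


def min_enclosing_circle(mask: CellMask) -> EnclosingCircle:
    """Smallest circle containing all foreground pixel centers (exact).

    Runs Welzl's algorithm on the convex hull of the boundary pixels; the
    result is the true minimax circle of the full foreground point set.
    """
    coords = np.argwhere(mask.pixels)
    if len(coords) == 0:
        raise SegmentationEmpty("cannot enclose an empty mask")
    if len(coords) == 1:
        return EnclosingCircle(float(coords[0, 0]), float(coords[0, 1]), 0.0)
    # boundary pixels suffice (interior points never support the circle)
    eroded = ndimage.binary_erosion(mask.pixels)
    boundary = np.argwhere(mask.pixels & ~eroded)
    pts = boundary.astype(float) if len(boundary) else coords.astype(float)
    try:
        from scipy.spatial import ConvexHull

        if len(pts) > 3:
            pts = pts[ConvexHull(pts).vertices]
    except Exception:
        pass  # degenerate (collinear) point sets: Welzl handles them directly
    cx, cy, r = _welzl(pts, np.random.default_rng(0))
    return EnclosingCircle(cx, cy, r)


def smooth_circles(
    circles: list[EnclosingCircle], window: int = 9
) -> list[EnclosingCircle]:
    """Moving-average smoothing of per-frame circle centers (radii kept).

    The optically trapped cell drifts smoothly, while per-frame minimal
    enclosing circles inherit pixel-level jitter from mask-boundary
    quantization; smoothing the center trajectory removes that jitter before
    alignment so it does not become common-mode noise in feature tracks.
    """
    if len(circles) <= 2 or window <= 1:
        return list(circles)
    centers = np.array([[c.center_row, c.center_col] for c in circles])
    sm = _smooth_centers(centers, min(window, len(circles)))
    return [
        EnclosingCircle(float(sm[i, 0]), float(sm[i, 1]), c.radius)
        for i, c in enumerate(circles)
    ]


def center_align(
    stack: ProjectionStack, circles: list[EnclosingCircle]
) -> ProjectionStack:
    """Translate each frame so its enclosing-circle center sits at the frame center.

    Subpixel shifts use bilinear interpolation with zero fill; integer shifts
    are exact.  The frame center is ``((H-1)/2, (W-1)/2)`` in pixel-center
    coordinates, matching the detector center used in reconstruction.
    """
    if len(circles) != len(stack):
        raise ValidationError("one enclosing circle per frame is required")
    h, w = stack.frames[0].pixels.shape
    target = ((h - 1) / 2.0, (w - 1) / 2.0)
    out = []
    for frame, circ in zip(stack.frames, circles):
        shift = (target[0] - circ.center_row, target[1] - circ.center_col)
        pixels = ndimage.shift(
            np.asarray(frame.pixels, dtype=float), shift, order=1,
            mode="constant", cval=0.0, prefilter=False,
        )
        out.append(ProjectionFrame(pixels=pixels, pixel_size=frame.pixel_size,
                                   index=frame.index))
    return ProjectionStack(frames=out, truth_angles=stack.truth_angles)
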