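"""Marker detection, pixel-to-cm calibration, segmentation, measurement.

The physical rig places four high-contrast markers at the corners of the
board at a known spacing (40 cm horizontally, 30 cm vertically between
marker centers).  Because the scale is recovered from the inter-marker pixel
distance, the camera-to-board distance never needs to be fixed: measures in
centimeters are distance-free.  Markers are blue and the object green, so
both are found by color-dominance thresholding, which is deterministic and
robust on the controlled white-board scene.

Coordinates are 0-based, x right / y down; bounding boxes are half-open
``(row0, col0, row1, col1)`` as used by scikit-image.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from skimage.measure import label, regionprops

from .errors import CalibrationError, MarkerDetectionError, SegmentationError

#: Color-dominance thresholds (intensity units) for marker / object pixels.
TAU_BLUE = 40
TAU_GREEN = 40


@dataclass(frozen=True)
class MarkerSet:
    """Centers of the four corner markers, labeled by quadrant.

    Each center is an (x, y) pixel position.  ``half_size_px`` is the
    half-extent of the marker squares, used to erode the working region so
    that no marker pixel can be mistaken for the object.
    """

    top_left: tuple[float, float]
    top_right: tuple[float, float]
    bottom_left: tuple[float, float]
    bottom_right: tuple[float, float]
    half_size_px: float = 0.0

    @property
    def centers(self) -> dict[str, tuple[float, float]]:
        return {
            "top_left": self.top_left,
            "top_right": self.top_right,
            "bottom_left": self.bottom_left,
            "bottom_right": self.bottom_right,
        }


@dataclass(frozen=True)
class Calibration:
    """Pixel-per-centimeter scales recovered from the marker spacing."""

    px_per_cm_x: float
    px_per_cm_y: float


@dataclass(frozen=True)
class SegmentationResult:
    mask: np.ndarray
    bbox: tuple[int, int, int, int]  # (row0, col0, row1, col1), half-open
    n_pixels: int


@dataclass(frozen=True)
class Measure:
    """Calibrated object measures: bbox extents and pixel-count area."""

    height_cm: float
    width_cm: float
    area_cm2: float


def _dominance(image: np.ndarray, channel: int, tau: int) -> np.ndarray:
    """Pixels where one channel exceeds the max of the other two by > tau."""
    img = image.astype(np.int16)
    others = [c for c in range(3) if c != channel]
    return img[..., channel] - np.maximum(img[..., others[0]], img[..., others[1]]) > tau


def detect_markers(image: np.ndarray, tau_b: int = TAU_BLUE) -> MarkerSet:
    """Locate the four corner markers as blue-dominant components.

    The centroids of the four largest blue-dominant connected components are
    assigned to corners by their quadrant relative to the joint centroid.

    Raises :class:`MarkerDetectionError` if fewer than four components are
    found or two land in the same quadrant.
    """
    blue = _dominance(image, 2, tau_b)
    lab = label(blue)
    props = sorted(regionprops(lab), key=lambda p: p.area, reverse=True)
    if len(props) < 4:
        raise MarkerDetectionError(
            f"found {len(props)} blue marker region(s), need 4"
        )
    props = props[:4]
    pts = [(p.centroid[1], p.centroid[0]) for p in props]  # (x, y)
    cx = sum(x for x, _ in pts) / 4
    cy = sum(y for _, y in pts) / 4
    corners: dict[str, tuple[float, float]] = {}
    for (x, y), p in zip(pts, props):
        key = ("top" if y < cy else "bottom") + ("_left" if x < cx else "_right")
        if key in corners:
            raise MarkerDetectionError(f"two marker centers in the {key} quadrant")
        corners[key] = (x, y)
    # half-extent of the marker squares from their bounding boxes
    halves = [
        ((p.bbox[2] - p.bbox[0] - 1) / 2 + (p.bbox[3] - p.bbox[1] - 1) / 2) / 2
        for p in props
    ]
    return MarkerSet(
        top_left=corners["top_left"],
        top_right=corners["top_right"],
        bottom_left=corners["bottom_left"],
        bottom_right=corners["bottom_right"],
        half_size_px=float(np.mean(halves)),
    )


def compute_calibration(
    markers: MarkerSet, board_width_cm: float = 40.0, board_height_cm: float = 30.0
) -> Calibration:
    """Derive pixel-per-cm scales from the known marker spacing.

    The horizontal scale is the mean of the top and bottom inter-center
    distances divided by the board width; vertically likewise.
    """
    c = markers.centers

    def dist(a: str, b: str) -> float:
        (x0, y0), (x1, y1) = c[a], c[b]
        return float(np.hypot(x1 - x0, y1 - y0))

    top = dist("top_left", "top_right")
    bottom = dist("bottom_left", "bottom_right")
    left = dist("top_left", "bottom_left")
    right = dist("top_right", "bottom_right")
    if min(top, bottom, left, right) <= 0:
        raise CalibrationError("degenerate marker quadrilateral")
    return Calibration(
        px_per_cm_x=(top + bottom) / 2 / board_width_cm,
        px_per_cm_y=(left + right) / 2 / board_height_cm,
    )


def _interior_region(markers: MarkerSet, shape: tuple[int, int]) -> np.ndarray:
    """Boolean raster of the marker-quadrilateral interior eroded by the
    marker half-size (keeps marker pixels out of the object mask)."""
    h = markers.half_size_px
    xs = [p[0] for p in markers.centers.values()]
    ys = [p[1] for p in markers.centers.values()]
    rows = np.arange(shape[0])[:, None]
    cols = np.arange(shape[1])[None, :]
    return (
        (cols > min(xs) + h)
        & (cols < max(xs) - h)
        & (rows > min(ys) + h)
        & (rows < max(ys) - h)
    )


def segment_cucumber(
    image: np.ndarray, markers: MarkerSet, tau_g: int = TAU_GREEN
) -> SegmentationResult:
    """Segment the cucumber as the largest green-dominant component inside
    the (eroded) marker quadrilateral.

    Raises :class:`SegmentationError` when no green pixels survive.
    """
    green = _dominance(image, 1, tau_g) & _interior_region(markers, image.shape[:2])
    if not green.any():
        raise SegmentationError("no green object inside the marker quadrilateral")
    lab = label(green)
    props = max(regionprops(lab), key=lambda p: p.area)
    mask = lab == props.label
    r0, c0, r1, c1 = props.bbox
    return SegmentationResult(mask=mask, bbox=(r0, c0, r1, c1), n_pixels=int(props.area))


def measure_cucumber(seg: SegmentationResult, cal: Calibration) -> Measure:
    """Calibrated height/width (bbox extents) and area (pixel count)."""
    r0, c0, r1, c1 = seg.bbox
    return Measure(
        height_cm=(r1 - r0) / cal.px_per_cm_y,
        width_cm=(c1 - c0) / cal.px_per_cm_x,
        area_cm2=seg.n_pixels / (cal.px_per_cm_x * cal.px_per_cm_y),
    )


def measure_scene(
    image: np.ndarray, board_width_cm: float = 40.0, board_height_cm: float = 30.0
) -> tuple[MarkerSet, Calibration, SegmentationResult, Measure]:
    """Full vision pass: detect markers, calibrate, segment, measure."""
    markers = detect_markers(image)
    cal = compute_calibration(markers, board_width_cm, board_height_cm)
    seg = segment_cucumber(image, markers)
    return markers, cal, seg, measure_cucumber(seg, cal)
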