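"""Training-canvas construction and RGB background size-encoding.

Training images are built by pasting the segmented cucumber, resampled to a
fixed physical scale, onto a fixed 100 x 340 canvas.  The fixed canvas
preserves absolute size: a long cucumber occupies more canvas pixels than a
short one, which a naive tight-crop-and-resize would destroy.

The core idea implemented here goes one step further: the calibrated
height, width, and area are normalized to [0, 1] and written into the
canvas *background* as the blue, green, and red channels respectively.  The
background color then varies with the cucumber's length, bend (via bbox
width), and thickness (via area), so a CNN receives the size metadata as
pixels rather than as a numeric side channel.  The baseline black background
is exactly the encoding of (0, 0, 0), so both flavors share one code path.
"""

from __future__ import annotations

from dataclasses import dataclass
import logging

import numpy as np
from skimage.transform import resize

from .errors import ConfigurationError, CropOverflowError, DecodeError
from .vision import (
    Calibration,
    Measure,
    SegmentationResult,
    compute_calibration,
    detect_markers,
    measure_cucumber,
    segment_cucumber,
)

logger = logging.getLogger(__name__)

#: Canvas dimensions: 100 px wide x 340 px tall (portrait).
CANVAS_W = 100
CANVAS_H = 340
#: Physical scale of the canvas.
CANVAS_PX_PER_CM = 10.0

VARIANTS = ("with_rgb", "without_rgb")


@dataclass(frozen=True)
class NormRanges:
    """Denominators normalizing measures to [0, 1].

    Defaults are fixed physical maxima — the canvas's physical extent at
    10 px/cm (34 cm tall, 10 cm wide) and a generous area bound — so the
    encoding is stable across datasets rather than tied to a dataset's
    min/max.
    """

    height_max_cm: float = 34.0
    width_max_cm: float = 10.0
    area_max_cm2: float = 170.0

    def __post_init__(self) -> None:
        if min(self.height_max_cm, self.width_max_cm, self.area_max_cm2) <= 0:
            raise ConfigurationError("normalization ranges must be positive")


@dataclass
class Canvas:
    """The fixed-size composite training image."""

    pixels: np.ndarray  # (CANVAS_H, CANVAS_W, 3) uint8
    bg_color: tuple[int, int, int]
    label: str | None = None


def normalize_measures(m: Measure, r: NormRanges | None = None) -> tuple[float, float, float]:
    """Normalize (height, width, area) by the fixed ranges, clipped to [0, 1]."""
    r = r or NormRanges()
    raw = (
        m.height_cm / r.height_max_cm,
        m.width_cm / r.width_max_cm,
        m.area_cm2 / r.area_max_cm2,
    )
    if any(v > 1 or v < 0 for v in raw):
        logger.warning("normalized measures clipped: %s", raw)
    return tuple(min(1.0, max(0.0, v)) for v in raw)


def encode_bg(t: tuple[float, float, float]) -> tuple[int, int, int]:
    """Encode a normalized (height, width, area) triplet as an RGB color.

    Height goes to the blue channel, width to green, area to red; each is
    quantized to 8 bits by round-half-up.
    """
    if any(v < 0 or v > 1 for v in t):
        raise ConfigurationError(f"normalized triplet outside [0,1]: {t}")
    h, w, a = t
    q = lambda v: int(np.floor(255 * v + 0.5))
    return (q(a), q(w), q(h))  # (R, G, B)


def decode_bg(c: Canvas) -> tuple[float, float, float]:
    """Recover the normalized triplet from the canvas background.

    Reads a corner pixel (corners are never object pixels: the crop is
    centered and bounded by the canvas); all four corners must agree.
    """
    px = c.pixels
    corners = [px[0, 0], px[0, -1], px[-1, 0], px[-1, -1]]
    if not all(np.array_equal(corners[0], q) for q in corners[1:]):
        raise DecodeError("canvas corner pixels disagree; background not uniform")
    r, g, b = (int(v) for v in corners[0])
    return (b / 255.0, g / 255.0, r / 255.0)


def rescale_crop(
    image: np.ndarray,
    seg: SegmentationResult,
    cal: Calibration,
    canvas_px_per_cm: float = CANVAS_PX_PER_CM,
) -> tuple[np.ndarray, np.ndarray]:
    """Resample the object's bbox crop (and its mask) to the canvas scale.

    The per-axis factor ``canvas_px_per_cm / px_per_cm`` renders the object
    at a fixed physical scale regardless of the camera distance at capture.
    Bilinear for the image, nearest for the mask (stays boolean).
    """
    r0, c0, r1, c1 = seg.bbox
    crop = image[r0:r1, c0:c1]
    mask = seg.mask[r0:r1, c0:c1]
    fy = canvas_px_per_cm / cal.px_per_cm_y
    fx = canvas_px_per_cm / cal.px_per_cm_x
    out_h = max(1, round(crop.shape[0] * fy))
    out_w = max(1, round(crop.shape[1] * fx))
    if out_h > CANVAS_H or out_w > CANVAS_W:
        raise CropOverflowError(
            f"rescaled crop {out_w}x{out_h} exceeds the {CANVAS_W}x{CANVAS_H} canvas"
        )
    if (out_h, out_w) == crop.shape[:2]:
        return crop.copy(), mask.copy()
    img_r = resize(
        crop.astype(np.float64),
        (out_h, out_w),
        order=1,
        anti_aliasing=fy < 1 or fx < 1,
        preserve_range=True,
    )
    mask_r = resize(mask, (out_h, out_w), order=0, anti_aliasing=False)
    return np.clip(img_r + 0.5, 0, 255).astype(np.uint8), mask_r.astype(bool)


def compose_canvas(
    crop: np.ndarray,
    crop_mask: np.ndarray,
    bg_color: tuple[int, int, int],
    label: str | None = None,
) -> Canvas:
    """Paste the masked crop, centered, onto a uniform-background canvas.

    Only pixels where ``crop_mask`` is true are copied, so the crop's own
    bbox background never leaks onto the canvas: every non-object pixel
    equals ``bg_color`` exactly.
    """
    h, w = crop.shape[:2]
    if h > CANVAS_H or w > CANVAS_W:
        raise CropOverflowError(f"crop {w}x{h} exceeds the canvas")
    pixels = np.empty((CANVAS_H, CANVAS_W, 3), dtype=np.uint8)
    pixels[...] = bg_color
    r0 = (CANVAS_H - h) // 2
    c0 = (CANVAS_W - w) // 2
    region = pixels[r0 : r0 + h, c0 : c0 + w]
    region[crop_mask] = crop[crop_mask]
    return Canvas(pixels=pixels, bg_color=tuple(int(v) for v in bg_color), label=label)


def build_sample(
    image: np.ndarray,
    variant: str = "with_rgb",
    ranges: NormRanges | None = None,
    canvas_px_per_cm: float = CANVAS_PX_PER_CM,
    board_width_cm: float = 40.0,
    board_height_cm: float = 30.0,
    label: str | None = None,
) -> tuple[Canvas, Measure]:
    """Scene image -> training canvas + calibrated measures.

    Runs detect markers -> calibrate -> segment -> measure -> rescale ->
    compose.  ``with_rgb`` encodes the normalized measures into the
    background; ``without_rgb`` uses black (the (0,0,0) encoding).  The raw
    Measure is returned either way — the baseline model consumes it as a
    numeric side channel.
    """
    if variant not in VARIANTS:
        raise ConfigurationError(f"variant must be one of {VARIANTS}, got {variant!r}")
    ranges = ranges or NormRanges()
    markers = detect_markers(image)
    cal = compute_calibration(markers, board_width_cm, board_height_cm)
    seg = segment_cucumber(image, markers)
    measure = measure_cucumber(seg, cal)
    crop, mask = rescale_crop(image, seg, cal, canvas_px_per_cm)
    if variant == "with_rgb":
        bg = encode_bg(normalize_measures(measure, ranges))
    else:
        bg = (0, 0, 0)
    return compose_canvas(crop, mask, bg, label=label), measure
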