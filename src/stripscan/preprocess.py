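"""Standardisation and test/control-line segmentation of strip images.

Reader frames are downsized to a uniform 500x128 (width x height) grid, then
split into two 250-column halves.  Because illumination varies along the
strip, a single global threshold cannot isolate both lines; instead an
automatic between-class-variance (Otsu) threshold is selected independently
per half — the per-window selection is what adapts to the intensity
variation.  The largest dark connected component in each half is taken as
that half's line ROI.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from PIL import Image
from skimage.filters import threshold_otsu
from skimage.measure import label as cc_label, regionprops

from .synthetic import LFAImage

__all__ = [
    "SegmentationError",
    "BinaryMask",
    "ROI",
    "standardise",
    "split_halves",
    "threshold_half",
    "detect_roi",
    "merge_masks",
    "segment_image",
]

TARGET_WIDTH = 500
TARGET_HEIGHT = 128


class SegmentationError(RuntimeError):
    """Raised when no line can be isolated in an image half."""


@dataclass
class BinaryMask:
    """Boolean grid where foreground marks detected line pixels."""

    pixels: np.ndarray

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels, dtype=bool)

    @property
    def count(self) -> int:
        return int(self.pixels.sum())


@dataclass(frozen=True)
class ROI:
    """A detected line region in full-image coordinates.

    ``bbox`` is (row_min, col_min, row_max, col_max), half-open; ``centroid``
    is the (row, col) pixel centroid of the component, fractional.
    """

    bbox: tuple[int, int, int, int]
    centroid: tuple[float, float]
    side: str

    def __post_init__(self) -> None:
        r0, c0, r1, c1 = self.bbox
        cr, cc = self.centroid
        if not (r0 <= cr < r1 and c0 <= cc < c1):
            raise ValueError(f"centroid {self.centroid} outside bbox {self.bbox}")

    @property
    def center_col(self) -> float:
        return self.centroid[1]


def _as_array(image) -> np.ndarray:
    if isinstance(image, LFAImage):
        return image.pixels
    return np.asarray(image, dtype=np.float64)


def standardise(image, allow_upscale: bool = False):
    """Resize a strip image to 500 wide x 128 high with area-weighted resampling.

    Orientation is normalised first (long axis becomes the width).  Inputs
    already at the target size pass through unchanged; smaller inputs are
    refused unless ``allow_upscale`` is set, since upsampling fabricates
    texture.
    """
    arr = _as_array(image)
    if arr.shape[0] > arr.shape[1]:  # long axis becomes the width
        arr = np.swapaxes(arr, 0, 1)
    h, w = arr.shape[:2]
    if (h, w) == (TARGET_HEIGHT, TARGET_WIDTH):
        out = arr
    else:
        if (h < TARGET_HEIGHT or w < TARGET_WIDTH) and not allow_upscale:
            raise ValueError(
                f"input {w}x{h} smaller than target {TARGET_WIDTH}x{TARGET_HEIGHT}; "
                "pass allow_upscale=True to permit upsampling"
            )
        out = _resize_area(arr, TARGET_HEIGHT, TARGET_WIDTH)
    if isinstance(image, LFAImage):
        return LFAImage(pixels=out, label=image.label, source=image.source)
    return out


def _resize_area(arr: np.ndarray, th: int, tw: int) -> np.ndarray:
    """Area-weighted (box-filter) resize via Pillow float images."""

    def one(chan: np.ndarray) -> np.ndarray:
        im = Image.fromarray(chan.astype(np.float32), mode="F")
        im = im.resize((tw, th), resample=Image.Resampling.BOX)
        return np.asarray(im, dtype=np.float64)

    if arr.ndim == 2:
        out = one(arr)
    else:
        out = np.stack([one(arr[..., c]) for c in range(arr.shape[-1])], axis=-1)
    return np.clip(out, 0.0, 255.0)


def split_halves(image) -> tuple[np.ndarray, np.ndarray]:
    """Split a standardised image into left/right halves along the width."""
    arr = _as_array(image)
    h, w = arr.shape[:2]
    if w % 2:
        raise ValueError(f"image width {w} is odd; cannot split into equal halves")
    return arr[:, : w // 2], arr[:, w // 2 :]


def threshold_half(half: np.ndarray, method: str = "otsu", polarity: str = "dark") -> BinaryMask:
    """Segment one image half with an automatically selected threshold.

    Foreground is the line: pixels *darker* than the Otsu threshold for the
    default dark-on-light (colorimetric) polarity, or lighter for
    ``polarity='light'``.
    """
    if method != "otsu":
        raise ValueError(f"unknown thresholding method {method!r}")
    arr = np.asarray(half, dtype=np.float64)
    if np.ptp(arr) == 0:
        raise SegmentationError("constant image half: no line found")
    t = threshold_otsu(arr)
    fg = arr <= t if polarity == "dark" else arr > t
    return BinaryMask(pixels=fg)


def detect_roi(
    mask: BinaryMask,
    side: str,
    col_offset: int = 0,
) -> ROI:
    """Locate the line in a half-mask as its largest 8-connected component.

    ``col_offset`` shifts the reported coordinates into the full-image frame
    (250 for the right half).  Ties on component size break toward the
    leftmost bounding box so detection is deterministic.
    """
    pix = mask.pixels
    if not pix.any():
        raise SegmentationError(f"empty mask: no {side} line found")
    lab = cc_label(pix, connectivity=2)
    props = regionprops(lab)
    props.sort(key=lambda p: (-p.area, p.bbox[1]))
    best = props[0]
    r0, c0, r1, c1 = best.bbox
    cr, cc = best.centroid
    return ROI(
        bbox=(r0, c0 + col_offset, r1, c1 + col_offset),
        centroid=(float(cr), float(cc) + col_offset),
        side=side,
    )


def merge_masks(left: BinaryMask, right: BinaryMask) -> BinaryMask:
    """Concatenate half-masks back into a full-width mask."""
    if left.pixels.shape != right.pixels.shape:
        raise ValueError(
            f"half shapes differ: {left.pixels.shape} vs {right.pixels.shape}"
        )
    return BinaryMask(pixels=np.concatenate([left.pixels, right.pixels], axis=1))


def segment_image(
    image,
    polarity: str = "dark",
    control_half: int = 0,
) -> tuple[LFAImage, dict[str, ROI], BinaryMask]:
    """Standardise an image and detect both line ROIs.

    ``control_half`` names which half (0 = left, nearer the sample pad)
    holds the control line; the other half holds the test line.  Returns the
    standardised image, a ``{'test': ROI, 'control': ROI}`` mapping in
    full-image coordinates, and the merged binary mask.
    """
    std = standardise(image)
    arr = _as_array(std)
    if arr.ndim == 3:
        from .glcm import to_grayscale

        arr = to_grayscale(arr)
    left, right = split_halves(arr)
    half_w = arr.shape[1] // 2
    sides = {0: "control", 1: "test"} if control_half == 0 else {0: "test", 1: "control"}
    masks = [threshold_half(left, polarity=polarity), threshold_half(right, polarity=polarity)]
    rois = {
        sides[0]: detect_roi(masks[0], sides[0], col_offset=0),
        sides[1]: detect_roi(masks[1], sides[1], col_offset=half_w),
    }
    return (std if isinstance(std, LFAImage) else LFAImage(arr, np.nan)), rois, merge_masks(*masks)
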