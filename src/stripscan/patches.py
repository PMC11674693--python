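"""Expansion of segmented strip images into labelled line patches.

Each standardised 500x128 image yields four 128x32 patches — two per
detected line, horizontally centred on the line's centroid with column
offsets of -8 and +8 px so every patch captures the line core plus flanking
membrane background.  Patches are bitwise sub-grids of the source image:
no resampling is involved, so texture statistics are untouched.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .preprocess import ROI, SegmentationError, segment_image
from .synthetic import LFAImage, save_png

__all__ = ["Patch", "extract_patches", "expand_dataset"]

PATCH_ROWS = 128
PATCH_COLS = 32
DEFAULT_OFFSETS = (-8, 8)


@dataclass
class Patch:
    """A 128x32 labelled sub-image cut from a test or control line ROI."""

    pixels: np.ndarray
    label: float
    source_image: int | str
    source_side: str
    patch_index: int

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels, dtype=np.float64)
        if self.pixels.shape != (PATCH_ROWS, PATCH_COLS):
            raise ValueError(
                f"patch must be {PATCH_ROWS}x{PATCH_COLS}, got {self.pixels.shape}"
            )


def extract_patches(
    image,
    rois: dict[str, ROI],
    n_patches: int = 4,
    offsets: tuple[int, ...] = DEFAULT_OFFSETS,
    source_id: int | str = 0,
) -> list[Patch]:
    """Cut ``n_patches`` full-height 32-column patches around the line ROIs.

    With ``n_patches=4`` each ROI contributes two patches at the configured
    column offsets from its centroid; ``n_patches=2`` takes one centred
    patch per ROI.  Column windows are clamped to the image bounds; an ROI
    too close to the border for a full 32-column crop raises
    :class:`SegmentationError`.
    """
    arr = image.pixels if isinstance(image, LFAImage) else np.asarray(image, dtype=np.float64)
    label = image.label if isinstance(image, LFAImage) else np.nan
    h, w = arr.shape[:2]
    if h != PATCH_ROWS:
        raise ValueError(f"expected standardised image of height {PATCH_ROWS}, got {h}")
    if n_patches == 4:
        per_roi_offsets = offsets
    elif n_patches == 2:
        per_roi_offsets = (0,)
    else:
        raise ValueError(f"n_patches must be 2 or 4, got {n_patches}")
    if w < PATCH_COLS:
        raise SegmentationError(f"image of width {w} cannot host a {PATCH_COLS}-column patch")

    out: list[Patch] = []
    idx = 0
    for side in ("test", "control"):
        roi = rois[side]
        base = int(np.floor(roi.center_col)) - PATCH_COLS // 2
        for off in per_roi_offsets:
            c0 = int(np.clip(base + off, 0, w - PATCH_COLS))
            sub = arr[:, c0 : c0 + PATCH_COLS]
            out.append(
                Patch(
                    pixels=sub,
                    label=label,
                    source_image=source_id,
                    source_side=side,
                    patch_index=idx,
                )
            )
            idx += 1
    return out


def expand_dataset(
    images: list[LFAImage],
    n_patches: int = 4,
    offsets: tuple[int, ...] = DEFAULT_OFFSETS,
    polarity: str = "dark",
    control_half: int = 0,
    out_dir: str | Path | None = None,
    max_skip_fraction: float = 0.01,
) -> list[Patch]:
    """Segment every image and expand it into patches.

    Per-image segmentation failures are recorded and the image skipped; if
    more than ``max_skip_fraction`` of images fail, the expansion itself
    fails.  When ``out_dir`` is given, patch PNGs and a manifest CSV
    (``patch_path,label,source_image,side,patch_index``) are written.
    """
    patches: list[Patch] = []
    failures: list[tuple[int, str]] = []
    for i, im in enumerate(images):
        try:
            std, rois, _ = segment_image(im, polarity=polarity, control_half=control_half)
            patches.extend(
                extract_patches(std, rois, n_patches=n_patches, offsets=offsets, source_id=i)
            )
        except (SegmentationError, ValueError) as exc:
            failures.append((i, str(exc)))
    if images and len(failures) > max_skip_fraction * len(images):
        detail = "; ".join(f"image {i}: {msg}" for i, msg in failures[:5])
        raise SegmentationError(
            f"{len(failures)}/{len(images)} images failed segmentation: {detail}"
        )

    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        rows = []
        for j, p in enumerate(patches):
            name = f"patch_{j:05d}.png"
            save_png(p.pixels, out / name)
            rows.append((name, p.label, p.source_image, p.source_side, p.patch_index))
        with open(out / "patches.csv", "w", newline="") as fh:
            wr = csv.writer(fh)
            wr.writerow(["patch_path", "label", "source_image", "side", "patch_index"])
            wr.writerows(rows)
    return patches
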