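"""Averaged horizontal multi-offset gray-level co-occurrence matrices.

The texture operator at the heart of the package: a patch is converted to
grayscale, quantised to ``Ng`` (default 64) levels, co-occurrence matrices
are counted for horizontal pixel-pair offsets d = 1..d_max (default 25),
each offset's matrix is normalised to a probability distribution, and the
normalised matrices are averaged with equal weights into a single matrix
p(i, j) that summarises texture across spatial scales.

Normalising before averaging gives every offset equal weight; averaging raw
counts first would overweight small offsets, which contribute more pixel
pairs (rows x (cols - d)).  The alternative order is available via
``normalise_first=False``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "QuantisedPatch",
    "AHMOMatrix",
    "to_grayscale",
    "quantise",
    "glcm_single_offset",
    "ahmo",
    "ahmo_batch",
]

LUMA_WEIGHTS = (0.2989, 0.5870, 0.1140)


@dataclass
class QuantisedPatch:
    """Integer level grid in [0, Ng-1] plus the gray range it was mapped from."""

    levels: np.ndarray
    Ng: int
    mapping: tuple[float, float]

    def __post_init__(self) -> None:
        self.levels = np.asarray(self.levels)
        if self.Ng < 2:
            raise ValueError(f"Ng must be >= 2, got {self.Ng}")
        if self.levels.size and (self.levels.min() < 0 or self.levels.max() > self.Ng - 1):
            raise ValueError("quantised levels outside [0, Ng-1]")


@dataclass
class AHMOMatrix:
    """Averaged normalised co-occurrence matrix p(i, j), entries sum to 1."""

    p: np.ndarray
    Ng: int
    d_max: int
    symmetric: bool = False

    def __post_init__(self) -> None:
        self.p = np.asarray(self.p, dtype=np.float64)
        if self.p.shape != (self.Ng, self.Ng):
            raise ValueError(f"matrix shape {self.p.shape} != ({self.Ng}, {self.Ng})")
        s = self.p.sum()
        if abs(s - 1.0) > 1e-9:
            raise ValueError(f"AHMO matrix must sum to 1, got {s}")


def to_grayscale(image: np.ndarray) -> np.ndarray:
    """Collapse an RGB image to one channel with ITU-R 601 luma weights.

    Single-channel input passes through unchanged.
    """
    arr = np.asarray(image, dtype=np.float64)
    if arr.ndim == 2:
        return arr
    if arr.ndim == 3 and arr.shape[-1] == 3:
        w = np.asarray(LUMA_WEIGHTS)
        return arr @ w
    raise ValueError(f"expected 1- or 3-channel image, got shape {arr.shape}")


def quantise(gray: np.ndarray, Ng: int = 64, range_mode: str = "per_image") -> QuantisedPatch:
    """Map gray values onto ``Ng`` discrete levels.

    ``per_image`` maps the patch's own [gmin, gmax] linearly onto levels
    0..Ng-1 (each value goes to its closest level); a constant patch maps to
    level 0.  ``fixed_0_255`` uses the full 8-bit range instead, preserving
    cross-image comparability of absolute intensity.
    """
    if Ng < 2:
        raise ValueError(f"Ng must be >= 2, got {Ng}")
    arr = np.asarray(gray, dtype=np.float64)
    if range_mode == "per_image":
        gmin, gmax = float(arr.min()), float(arr.max())
    elif range_mode == "fixed_0_255":
        gmin, gmax = 0.0, 255.0
    else:
        raise ValueError(f"unknown range_mode {range_mode!r}")
    if gmax == gmin:
        levels = np.zeros(arr.shape, dtype=np.intp)
    else:
        scaled = (arr - gmin) / (gmax - gmin) * (Ng - 1)
        levels = np.clip(np.rint(scaled).astype(np.intp), 0, Ng - 1)
    return QuantisedPatch(levels=levels, Ng=Ng, mapping=(gmin, gmax))


def glcm_single_offset(q: QuantisedPatch, d: int, symmetric: bool = False) -> np.ndarray:
    """Count horizontal co-occurrences of level pairs at column offset ``d``.

    Entry (i, j) counts ordered pairs ``(q[r, c], q[r, c + d])`` over every
    valid position; symmetric mode adds the transpose.  The total count in
    non-symmetric mode is rows x (cols - d).
    """
    lv = q.levels
    rows, cols = lv.shape
    if not (1 <= d < cols):
        raise ValueError(f"offset d={d} must satisfy 1 <= d < cols={cols}")
    left = lv[:, : cols - d].ravel()
    right = lv[:, d:].ravel()
    counts = np.bincount(left * q.Ng + right, minlength=q.Ng * q.Ng).reshape(q.Ng, q.Ng)
    counts = counts.astype(np.float64)
    if symmetric:
        counts = counts + counts.T
    return counts


def ahmo(
    q: QuantisedPatch,
    d_max: int = 25,
    symmetric: bool = False,
    normalise_first: bool = True,
) -> AHMOMatrix:
    """Average the normalised GLCMs over offsets d = 1..d_max."""
    cols = q.levels.shape[1]
    if not (1 <= d_max < cols):
        raise ValueError(
            f"d_max={d_max} exceeds the patch width; maximum legal offset is {cols - 1}"
        )
    acc = np.zeros((q.Ng, q.Ng), dtype=np.float64)
    for d in range(1, d_max + 1):
        counts = glcm_single_offset(q, d, symmetric=symmetric)
        if normalise_first:
            acc += counts / counts.sum()
        else:
            acc += counts
    p = acc / d_max if normalise_first else acc / acc.sum()
    return AHMOMatrix(p=p, Ng=q.Ng, d_max=d_max, symmetric=symmetric)


def ahmo_batch(
    patches: np.ndarray,
    Ng: int = 64,
    d_max: int = 25,
    symmetric: bool = False,
    range_mode: str = "per_image",
    normalise_first: bool = True,
) -> np.ndarray:
    """Vectorised AHMO over a stack of patches.

    ``patches`` is (n, rows, cols) gray values; returns (n, Ng, Ng)
    probability matrices.  Equivalent to mapping :func:`quantise` +
    :func:`ahmo` over the stack, but counts all patches per offset with one
    ``bincount``, which is what makes whole-dataset feature extraction cheap.
    """
    x = np.asarray(patches, dtype=np.float64)
    n, rows, cols = x.shape
    if not (1 <= d_max < cols):
        raise ValueError(
            f"d_max={d_max} exceeds the patch width; maximum legal offset is {cols - 1}"
        )
    if range_mode == "per_image":
        gmin = x.min(axis=(1, 2), keepdims=True)
        gmax = x.max(axis=(1, 2), keepdims=True)
    else:
        gmin = np.zeros((n, 1, 1))
        gmax = np.full((n, 1, 1), 255.0)
    span = np.where(gmax > gmin, gmax - gmin, 1.0)
    lv = np.clip(np.rint((x - gmin) / span * (Ng - 1)).astype(np.intp), 0, Ng - 1)

    base = (np.arange(n, dtype=np.intp) * (Ng * Ng))[:, None, None]
    acc = np.zeros((n, Ng * Ng), dtype=np.float64)
    for d in range(1, d_max + 1):
        codes = lv[:, :, : cols - d] * Ng + lv[:, :, d:]
        flat = (codes + base).ravel()
        counts = np.bincount(flat, minlength=n * Ng * Ng).reshape(n, Ng * Ng).astype(np.float64)
        if symmetric:
            counts = counts + counts.reshape(n, Ng, Ng).transpose(0, 2, 1).reshape(n, Ng * Ng)
        if normalise_first:
            acc += counts / counts.sum(axis=1, keepdims=True)
        else:
            acc += counts
    if normalise_first:
        acc /= d_max
    else:
        acc /= acc.sum(axis=1, keepdims=True)
    return acc.reshape(n, Ng, Ng)
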