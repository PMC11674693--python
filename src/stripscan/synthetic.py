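"""Synthetic lateral-flow-assay strip image generator.

Emulates the output of a benchtop LFA reader imaging colorimetric
(gold-nanoparticle) test strips: a light nitrocellulose-membrane background
with grain noise, and control/test reagent lines whose darkness and texture
vary monotonically with the analyte (TSH) concentration label: the test line
darkens with concentration while the control line lightens as gold conjugate
is depleted at the test line (sandwich-assay behaviour).  Every downstream stage of the pipeline is testable
against these images without any external data.

Coordinate convention: arrays are row-major ``(row, col)``, 0-based, with the
strip's long axis along the columns (width).  All crop intervals are
half-open.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np
from PIL import Image
from scipy.ndimage import gaussian_filter

__all__ = [
    "CONCENTRATION_LABELS",
    "StripParams",
    "LFAImage",
    "generate_strip",
    "generate_dataset",
    "null_params",
]

#: The eight TSH concentration labels (mIU/L), in increasing order.
CONCENTRATION_LABELS: tuple[float, ...] = (0.5, 1.0, 2.5, 5.0, 10.0, 25.0, 50.0, 100.0)


def _default_depth_map() -> dict[float, float]:
    # Strictly increasing darkness drop (gray levels) with concentration.
    return {
        0.5: 18.0,
        1.0: 26.0,
        2.5: 34.0,
        5.0: 42.0,
        10.0: 50.0,
        25.0: 58.0,
        50.0: 66.0,
        100.0: 74.0,
    }


@dataclass(frozen=True)
class StripParams:
    """Geometry and appearance parameters of a synthetic strip image.

    Defaults mirror the reader output the pipeline expects: 700x145 px
    frames, dark lines on a light membrane, control line in the left half
    (the sample-pad end) and test line in the right half.

    Parameters
    ----------
    image_width, image_height : int
        Frame size in pixels (width is the strip's long axis).
    control_line_center, test_line_center : int
        Column coordinate of each line's centre.
    line_width : int
        Nominal full width of the test-line band in pixels.
    control_line_width : int
        Width of the control band; printed wider than the test line (as is
        common practice to guarantee control visibility), which also lets a
        patch reveal which line it came from.
    background_mean : float
        Membrane gray level, in [0, 255].
    background_grain_sd : float
        Standard deviation of the i.i.d. membrane grain noise (gray levels).
    test_line_depth_map : mapping label -> float
        Mean darkness drop of the test line per concentration label; must be
        strictly monotone over the ordered labels.
    control_line_depth : float
        Darkness drop of the control line (gray levels) at the lowest
        concentration, before depletion.
    control_depletion : float
        Conjugate-depletion factor per concentration rank.  In a sandwich
        assay the analyte captured at the test line consumes gold
        conjugate, so less reaches the control line at high concentrations:
        control darkness = control_line_depth * control_depletion**rank,
        a first-order (geometric) decay.  Set to 1 for a
        concentration-independent control line.
    illumination_gradient_amplitude : float
        Peak-to-peak amplitude of a linear illumination ramp along the strip
        axis (gray levels); the ramp direction is randomised per image.
    brightness_jitter_sd : float
        Per-image global brightness offset SD (gray levels), emulating
        frame-to-frame exposure variation.
    texture_roughness : float
        Scale of the concentration-dependent speckle (nanoparticle grain)
        added inside the line bands.  At the test line the speckle SD grows
        geometrically with the label rank (more bound particles),
        SD = roughness * texture_growth**rank; at the control line it
        shrinks with rank as conjugate is depleted.  Set to 0 to remove the
        textural class signal entirely (aggregates included).
    speckle_correlation_px : float
        Gaussian correlation length of the speckle field in pixels.
    """

    image_width: int = 700
    image_height: int = 145
    control_line_center: int = 175
    test_line_center: int = 525
    line_width: int = 24
    control_line_width: int = 34
    background_mean: float = 200.0
    background_grain_sd: float = 6.0
    test_line_depth_map: Mapping[float, float] = field(default_factory=_default_depth_map)
    control_line_depth: float = 72.0
    control_depletion: float = 0.80
    illumination_gradient_amplitude: float = 8.0
    brightness_jitter_sd: float = 2.0
    texture_roughness: float = 1.5
    speckle_correlation_px: float = 1.5
    aggregate_density_base: float = 0.03
    aggregate_depth: float = 50.0
    aggregate_size_base: float = 0.5
    aggregate_size_growth: float = 1.25
    texture_growth: float = 1.5
    rgb: bool = False

    def __post_init__(self) -> None:
        if self.image_width <= 0 or self.image_height <= 0:
            raise ValueError(
                f"image dimensions must be positive, got "
                f"{self.image_width}x{self.image_height}"
            )
        if not (0 < self.line_width < self.image_width / 4):
            raise ValueError(
                f"line_width must satisfy 0 < w < image_width/4, got {self.line_width}"
            )
        for name, c in (
            ("control_line_center", self.control_line_center),
            ("test_line_center", self.test_line_center),
        ):
            if not (0 <= c < self.image_width):
                raise ValueError(f"{name}={c} outside image width {self.image_width}")
        if abs(self.test_line_center - self.control_line_center) < 2 * self.line_width:
            raise ValueError("line centers must be at least 2*line_width apart")
        labels = tuple(self.test_line_depth_map)
        if list(labels) != sorted(labels):
            raise ValueError("test_line_depth_map labels must be in increasing order")

    @property
    def labels(self) -> tuple[float, ...]:
        return tuple(self.test_line_depth_map)

    def is_monotone(self) -> bool:
        depths = list(self.test_line_depth_map.values())
        return all(b > a for a, b in zip(depths, depths[1:]))


def null_params(**overrides) -> StripParams:
    """Parameters with *no* class signal: constant depth map, no speckle.

    Per-label image distributions are then exchangeable, so any downstream
    classifier should perform at chance (1/8 for the default label set).
    """
    flat = {lab: 45.0 for lab in CONCENTRATION_LABELS}
    return StripParams(
        test_line_depth_map=flat,
        texture_roughness=0.0,
        control_depletion=1.0,
        **overrides,
    )


@dataclass
class LFAImage:
    """A strip image: a gray-level pixel grid plus its concentration label.

    ``pixels`` is float64 in [0, 255], shape (height, width) or
    (height, width, 3) in RGB mode.  ``source`` records provenance: either
    the generating parameters or a file path.
    """

    pixels: np.ndarray
    label: float
    source: object = None

    def __post_init__(self) -> None:
        p = np.asarray(self.pixels, dtype=np.float64)
        if p.min() < 0 or p.max() > 255:
            raise ValueError("pixel values must lie in [0, 255]")
        self.pixels = p

    @property
    def shape(self) -> tuple[int, ...]:
        return self.pixels.shape


def _line_profile(width: int, center: int, line_width: int) -> np.ndarray:
    """Flat-topped band profile along the column axis, peak value 1.

    A super-Gaussian (exponent 4) gives a flat core with smooth shoulders,
    like a printed reagent line after wicking.
    """
    cols = np.arange(width, dtype=np.float64)
    half = line_width / 2.0
    return np.exp(-(((cols - center) / half) ** 4))


def generate_strip(label: float, params: StripParams, seed: int) -> LFAImage:
    """Render one synthetic strip image for a concentration ``label``.

    Deterministic for fixed ``(label, params, seed)``.  The image carries a
    grainy membrane background, an optional linear illumination ramp, a
    control band of fixed depth and a test band whose depth is
    ``params.test_line_depth_map[label]`` and whose speckle variance grows
    with the label's rank.
    """
    if label not in params.test_line_depth_map:
        raise KeyError(
            f"unknown concentration label {label!r}; "
            f"known labels: {list(params.test_line_depth_map)}"
        )
    rng = np.random.default_rng(np.random.SeedSequence([int(seed) & 0x7FFFFFFF, _label_key(label)]))
    h, w = params.image_height, params.image_width

    img = np.full((h, w), params.background_mean, dtype=np.float64)
    if params.background_grain_sd > 0:
        img += rng.normal(0.0, params.background_grain_sd, size=(h, w))
    if params.illumination_gradient_amplitude > 0:
        ramp = np.linspace(-0.5, 0.5, w)[None, :] * params.illumination_gradient_amplitude
        img += ramp * rng.choice((-1.0, 1.0))
    if params.brightness_jitter_sd > 0:
        img += rng.normal(0.0, params.brightness_jitter_sd)

    rank = list(params.test_line_depth_map).index(label)
    n_labels = len(params.test_line_depth_map)

    control = _line_profile(w, params.control_line_center, params.control_line_width)
    control_depth = params.control_line_depth * params.control_depletion**rank
    img -= control_depth * control[None, :]

    test = _line_profile(w, params.test_line_center, params.line_width)
    img -= params.test_line_depth_map[label] * test[None, :]

    if params.texture_roughness > 0:
        # Both the speckle amplitude and its correlation length scale with
        # the amount of bound conjugate: increasing with rank at the test
        # line, decreasing at the control line (depletion).
        def speckle(sd_level: float) -> np.ndarray:
            field_ = gaussian_filter(
                rng.standard_normal((h, w)), sigma=params.speckle_correlation_px
            )
            s = field_.std()
            return sd_level * (field_ / s if s > 0 else field_)

        # Geometric ladders: the concentration labels are log-spaced, and a
        # constant adjacent-rank ratio keeps neighbouring classes equally
        # distinguishable across the whole range.
        g = params.texture_growth
        img += speckle(params.texture_roughness * g**rank) * test[None, :]
        img += speckle(params.texture_roughness * g ** (n_labels - 1 - rank)) * control[None, :]

        # Discrete nanoparticle aggregates: dark dots whose areal density
        # grows with bound conjugate.  Dot density is invariant to any
        # per-image gray rescaling, so it survives range-normalised
        # quantisation downstream.
        def dots(density: float, size_px: float) -> np.ndarray:
            mask = (rng.random((h, w)) < density).astype(np.float64)
            blob = gaussian_filter(mask, sigma=size_px)
            peak = blob.max()
            return params.aggregate_depth * blob / peak if peak > 0 else blob

        r_test, r_ctrl = rank, n_labels - 1 - rank
        img -= dots(
            params.aggregate_density_base * g**r_test,
            params.aggregate_size_base * params.aggregate_size_growth**r_test,
        ) * test[None, :]
        img -= dots(
            params.aggregate_density_base * g**r_ctrl,
            params.aggregate_size_base * params.aggregate_size_growth**r_ctrl,
        ) * control[None, :]

    img = np.clip(np.round(img), 0, 255)
    if params.rgb:
        img = _sepia(img)
    return LFAImage(pixels=img, label=label, source=params)


def _label_key(label: float) -> int:
    # Stable small integer per label for seed spawning.
    return int(round(float(label) * 10))


def _sepia(gray: np.ndarray) -> np.ndarray:
    """Tint a gray image into 3 channels (exercises grayscale conversion)."""
    r = np.clip(gray * 1.07, 0, 255)
    g = np.clip(gray * 0.95, 0, 255)
    b = np.clip(gray * 0.82, 0, 255)
    return np.round(np.stack([r, g, b], axis=-1))


def generate_dataset(
    params: StripParams,
    n_per_label: int,
    seed: int,
    out_dir: str | Path | None = None,
) -> list[LFAImage]:
    """Generate a balanced dataset of ``n_per_label`` images per label.

    Returns ``len(params.labels) * n_per_label`` images in label-major order.
    When ``out_dir`` is given, 8-bit PNGs and a ``manifest.csv`` with header
    ``path,label`` are written there.
    """
    if n_per_label < 1:
        raise ValueError(f"n_per_label must be >= 1, got {n_per_label}")
    ss = np.random.SeedSequence(int(seed) & 0x7FFFFFFF)
    child_seeds = ss.generate_state(len(params.labels) * n_per_label) % (2**31)

    images: list[LFAImage] = []
    k = 0
    for label in params.labels:
        for _ in range(n_per_label):
            images.append(generate_strip(label, params, int(child_seeds[k])))
            k += 1

    if out_dir is not None:
        out = Path(out_dir)
        try:
            out.mkdir(parents=True, exist_ok=True)
            rows = []
            for i, im in enumerate(images):
                name = f"strip_{i:05d}_lab{im.label:g}.png"
                save_png(im.pixels, out / name)
                rows.append((name, im.label))
            with open(out / "manifest.csv", "w", newline="") as fh:
                wr = csv.writer(fh)
                wr.writerow(["path", "label"])
                wr.writerows(rows)
        except OSError as exc:
            raise OSError(f"cannot write dataset to {out}: {exc}") from exc
    return images


def save_png(pixels: np.ndarray, path: str | Path) -> None:
    """Write a [0,255] pixel grid as an 8-bit PNG."""
    arr = np.asarray(np.round(pixels), dtype=np.uint8)
    Image.fromarray(arr).save(str(path))


def load_png(path: str | Path, label: float | None = None) -> LFAImage:
    """Read a PNG/TIFF strip image back as an :class:`LFAImage`."""
    arr = np.asarray(Image.open(str(path)), dtype=np.float64)
    return LFAImage(pixels=arr, label=label if label is not None else np.nan, source=str(path))


def load_dataset(manifest: str | Path) -> list[LFAImage]:
    """Load a dataset from a ``manifest.csv`` written by :func:`generate_dataset`."""
    root = Path(manifest).parent
    images = []
    with open(manifest, newline="") as fh:
        for row in csv.DictReader(fh):
            images.append(load_png(root / row["path"], float(row["label"])))
    return images
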