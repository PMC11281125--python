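"""Fundus photograph preprocessing.

The chain mirrors standard fundus-CNN practice: segment the black camera
background by a gray-level threshold, repaint it with the mean foreground
color so it cannot dominate histogram equalization, enhance the luminance
(L) channel of CIELab with CLAHE, convert back to RGB, and finally restore
the black background.  Rotation augmentation and the train/validation
split used for the classifier also live here.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from skimage import color, exposure, transform

from .images import BinaryMask, FundusImage, GrayImage, to_gray


class DegenerateInputError(ValueError):
    """The input leaves a stage with nothing to operate on (e.g. no foreground)."""


@dataclass
class PreprocessParams:
    """Tunables of the preprocessing chain.

    background_threshold: gray level separating eye region from the black
        camera background (strict inequality: gray > threshold is kept).
    clahe_clip_limit: contrast limit as the conventional multiple of the
        mean histogram-bin height (the OpenCV-style scale).
    clahe_tile_grid: CLAHE tile grid edge count (grid x grid tiles).
    classifier_size: edge length of the square classifier input.
    """

    background_threshold: int = 40
    clahe_clip_limit: float = 2.0
    clahe_tile_grid: int = 8
    classifier_size: int = 64

    def __post_init__(self):
        if not 0 < self.background_threshold < 255:
            raise ValueError("background_threshold must be in (0, 255)")
        if self.clahe_clip_limit <= 0:
            raise ValueError("clahe_clip_limit must be positive")
        if self.classifier_size < 8:
            raise ValueError("classifier_size must be at least 8")


@dataclass
class AugmentedSet:
    """Rotation-augmented train/validation images."""

    train: list
    val: list
    step_deg: float = 10.0


def compute_background_mask(img: FundusImage, params: PreprocessParams | None = None) -> BinaryMask:
    """1 where the luma gray level exceeds the threshold (eye region), else 0."""
    params = params or PreprocessParams()
    gray = to_gray(img).pixels
    return BinaryMask((gray > params.background_threshold).astype(np.uint8),
                      semantics="background-mask")


def fill_background_mean(img: FundusImage, mask: BinaryMask) -> FundusImage:
    """Repaint background pixels with the per-channel mean of the foreground."""
    if mask.shape != img.shape:
        raise ValueError(f"mask shape {mask.shape} != image shape {img.shape}")
    fg = mask.pixels.astype(bool)
    if not fg.any():
        raise DegenerateInputError("background fill impossible: mask has no foreground")
    out = img.pixels.copy()
    mean = np.rint(img.pixels[fg].mean(axis=0)).astype(np.uint8)
    out[~fg] = mean
    return FundusImage(out, meta=dict(img.meta))


def _skimage_clip_limit(clip_limit: float) -> float:
    # OpenCV-style clip (multiple of mean bin height over 256 bins) ->
    # skimage's normalized fraction-of-tile clip.
    return min(1.0, clip_limit / 256.0)


def clahe_on_luminance(img: FundusImage, params: PreprocessParams | None = None) -> FundusImage:
    """CLAHE on the CIELab L channel only; a/b are untouched."""
    params = params or PreprocessParams()
    rgb = img.pixels.astype(np.float64) / 255.0
    lab = color.rgb2lab(rgb)
    h, w = lab.shape[:2]
    grid = params.clahe_tile_grid
    kernel = (max(1, h // grid), max(1, w // grid))
    enhanced = exposure.equalize_adapthist(
        lab[:, :, 0] / 100.0,
        kernel_size=kernel,
        clip_limit=_skimage_clip_limit(params.clahe_clip_limit),
    )
    lab[:, :, 0] = enhanced * 100.0
    out = np.clip(color.lab2rgb(lab), 0.0, 1.0)
    return FundusImage(np.rint(out * 255.0).astype(np.uint8), meta=dict(img.meta))


def reapply_black_background(img: FundusImage, mask: BinaryMask) -> FundusImage:
    """Set every background pixel (mask==0) to pure black."""
    if mask.shape != img.shape:
        raise ValueError(f"mask shape {mask.shape} != image shape {img.shape}")
    out = img.pixels.copy()
    out[mask.pixels == 0] = 0
    return FundusImage(out, meta=dict(img.meta))


def preprocess_fundus(img: FundusImage,
                      params: PreprocessParams | None = None) -> tuple[FundusImage, BinaryMask]:
    """Full chain: mask -> mean fill -> Lab/CLAHE -> RGB -> black background.

    Returns the enhanced image together with the background mask so
    downstream stages can reuse it.
    """
    params = params or PreprocessParams()
    mask = compute_background_mask(img, params)
    filled = fill_background_mean(img, mask)
    enhanced = clahe_on_luminance(filled, params)
    return reapply_black_background(enhanced, mask), mask


def _resize_gray(arr: np.ndarray, size: int) -> np.ndarray:
    if arr.shape == (size, size):
        return arr.copy()
    out = transform.resize(arr.astype(np.float64), (size, size), order=1,
                           anti_aliasing=False, preserve_range=True)
    return np.clip(np.rint(out), 0, 255).astype(np.uint8)


def to_classifier_input(img: FundusImage | GrayImage,
                        params: PreprocessParams | None = None) -> GrayImage:
    """Grayscale (if needed) and bilinear-resize to the classifier edge size."""
    params = params or PreprocessParams()
    gray = to_gray(img) if isinstance(img, FundusImage) else img
    return GrayImage(_resize_gray(gray.pixels, params.classifier_size), meta=dict(gray.meta))


def _rotate_array(arr: np.ndarray, angle: float) -> np.ndarray:
    if angle % 90 == 0:
        # right-angle rotations are exact grid permutations; keep them lossless
        return np.ascontiguousarray(np.rot90(arr, k=int(angle // 90) % 4, axes=(0, 1)))
    out = transform.rotate(arr.astype(np.float64), angle, resize=False, order=1,
                           mode="constant", cval=0.0, preserve_range=True)
    return np.clip(np.rint(out), 0, 255).astype(np.uint8)


def rotate_raster(img: FundusImage | GrayImage, angle: float):
    rotated = _rotate_array(img.pixels, angle)
    cls = FundusImage if isinstance(img, FundusImage) else GrayImage
    return cls(rotated, meta=dict(img.meta))


def rotation_augment(images: list, step_deg: float = 10.0) -> list:
    """Every rotation of every image in `step_deg` increments, 0 included.

    Output is image-major then increasing angle, so the length is
    len(images) * 360 / step_deg.
    """
    if step_deg <= 0 or 360 % step_deg != 0:
        raise ValueError(f"rotation step {step_deg} must divide 360")
    angles = np.arange(0, 360, step_deg)
    return [rotate_raster(img, float(a)) for img in images for a in angles]


def split_train_val(images: list, n_val: int = 2, seed: int = 0) -> tuple[list, list]:
    """Seeded disjoint split; augmentation must run after this, never before."""
    if n_val >= len(images):
        raise ValueError(f"n_val={n_val} must be smaller than the {len(images)} images")
    rng = np.random.default_rng(seed)
    val_idx = set(rng.choice(len(images), size=n_val, replace=False).tolist())
    train = [img for i, img in enumerate(images) if i not in val_idx]
    val = [img for i, img in enumerate(images) if i in val_idx]
    return train, val
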