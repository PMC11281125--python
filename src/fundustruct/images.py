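"""Raster types and file I/O shared by every pipeline stage.

The pipeline passes three raster types around: `FundusImage` (8-bit RGB
photograph), `GrayImage` (8-bit single channel) and `BinaryMask` ({0,1}
with a semantics tag).  All are thin validated wrappers over numpy arrays;
coordinates are (row, col), 0-based, with half-open crop ranges.
Internally masks hold {0,1}; on disk they are written as {0,255} PNG so
they are viewable.  Channel order is RGB everywhere.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from PIL import Image

VALID_LABELS = ("glaucoma", "normal")


class FormatError(ValueError):
    """An input file or raster violates a format expectation."""


@dataclass
class FundusImage:
    """An 8-bit RGB fundus photograph, canonically 512x512."""

    pixels: np.ndarray
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        self.pixels = np.asarray(self.pixels)
        if self.pixels.ndim != 3 or self.pixels.shape[2] != 3:
            raise FormatError(f"expected 3 channels, got array of shape {self.pixels.shape}")
        h, w = self.pixels.shape[:2]
        if h < 64 or w < 64:
            raise FormatError(f"image too small ({h}x{w}); need at least 64x64")
        if self.pixels.min() < 0 or self.pixels.max() > 255:
            raise FormatError("pixel values must lie in 0..255")
        self.pixels = self.pixels.astype(np.uint8)

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape[:2]


@dataclass
class GrayImage:
    """An 8-bit single-channel raster."""

    pixels: np.ndarray
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        self.pixels = np.asarray(self.pixels)
        if self.pixels.ndim != 2:
            raise FormatError(f"expected single channel, got shape {self.pixels.shape}")
        if self.pixels.min() < 0 or self.pixels.max() > 255:
            raise FormatError("pixel values must lie in 0..255")
        self.pixels = self.pixels.astype(np.uint8)

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape


@dataclass
class BinaryMask:
    """A {0,1} raster paired with the image it describes.

    `semantics` records what the mask means: "background-mask" (1 = eye
    region), "vessel-mask" (1 = vessel) or "brightness-mask" (1 = bright
    pixel retained for disc detection).
    """

    pixels: np.ndarray
    semantics: str = "background-mask"

    def __post_init__(self):
        self.pixels = np.asarray(self.pixels)
        if self.pixels.ndim != 2:
            raise FormatError(f"mask must be 2-D, got shape {self.pixels.shape}")
        values = np.unique(self.pixels)
        if not np.all(np.isin(values, (0, 1))):
            raise FormatError("mask values must be exactly 0 or 1")
        self.pixels = self.pixels.astype(np.uint8)

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape


@dataclass
class LabelTable:
    """image_id -> {glaucoma, normal} mapping."""

    frame: pd.DataFrame

    def __post_init__(self):
        required = {"image_id", "label"}
        if not required.issubset(self.frame.columns):
            raise FormatError(f"label table needs columns {sorted(required)}")
        self.frame = self.frame.copy()
        self.frame["label"] = self.frame["label"].str.lower()
        bad = self.frame.loc[~self.frame["label"].isin(VALID_LABELS)]
        if len(bad):
            raise FormatError(f"unknown labels in rows: {bad.to_dict('records')}")
        dup = self.frame.loc[self.frame["image_id"].duplicated()]
        if len(dup):
            raise FormatError(f"duplicate image_ids: {sorted(dup['image_id'])}")

    def __len__(self) -> int:
        return len(self.frame)

    def label_of(self, image_id: str) -> str:
        row = self.frame.loc[self.frame["image_id"] == image_id]
        if not len(row):
            raise KeyError(image_id)
        return row["label"].iloc[0]

    @property
    def image_ids(self) -> list[str]:
        return list(self.frame["image_id"])


def read_image(path: str | os.PathLike) -> FundusImage:
    """Decode an 8-bit color PNG/JPEG as an RGB `FundusImage`."""
    with Image.open(path) as im:
        if im.mode not in ("RGB", "RGBA"):
            if im.mode in ("L", "I;16", "I", "P", "LA"):
                raise FormatError(f"expected 3 channels, file {path} decodes as mode {im.mode}")
            raise FormatError(f"unsupported image mode {im.mode} in {path}")
        arr = np.asarray(im.convert("RGB"))
    return FundusImage(arr, meta={"source": str(path)})


def read_gray(path: str | os.PathLike) -> GrayImage:
    with Image.open(path) as im:
        arr = np.asarray(im.convert("L"))
    return GrayImage(arr, meta={"source": str(path)})


def read_mask(path: str | os.PathLike, semantics: str = "vessel-mask") -> BinaryMask:
    """Read a mask written by `write_image` ({0,255} on disk -> {0,1})."""
    with Image.open(path) as im:
        arr = np.asarray(im.convert("L"))
    return BinaryMask((arr > 127).astype(np.uint8), semantics=semantics)


def write_image(img: FundusImage | GrayImage | BinaryMask, path: str | os.PathLike) -> None:
    """Write losslessly as PNG; masks are scaled to {0,255}."""
    if isinstance(img, BinaryMask):
        arr = img.pixels * np.uint8(255)
    else:
        arr = img.pixels
    Image.fromarray(arr).save(path, format="PNG")


def read_label_table(path: str | os.PathLike) -> LabelTable:
    frame = pd.read_csv(path, dtype={"image_id": str, "label": str})
    return LabelTable(frame)


def write_label_table(table: LabelTable, path: str | os.PathLike) -> None:
    table.frame.to_csv(path, index=False)


def to_gray(img: FundusImage) -> GrayImage:
    """RGB -> gray by the 0.299/0.587/0.114 luma weighting, rounded."""
    weights = np.array([0.299, 0.587, 0.114])
    gray = np.rint(img.pixels.astype(np.float64) @ weights)
    return GrayImage(np.clip(gray, 0, 255).astype(np.uint8), meta=dict(img.meta))
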