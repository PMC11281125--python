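"""Optic-disc localization and extraction.

The optic disc is the brightest roughly circular region of a fundus
photograph, and in right-eye images it sits in the temporal (right) half.
The extraction chain: crop the right half, keep the brightest few percent
of CIELab-L pixels, find the best circle through those pixels with a
circular Hough transform, widen the detected radius by a safety margin so
the rim is never clipped, black out everything outside the circle, and
resize the crop to the classifier input size.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage as ndi
from skimage import color
from skimage.transform import hough_circle

from .images import BinaryMask, FundusImage, GrayImage
from .preprocess import PreprocessParams, to_classifier_input


class DetectionError(RuntimeError):
    """Disc detection received an input it cannot work with."""


def _disk_struct(radius: int) -> np.ndarray:
    y, x = np.ogrid[-radius:radius + 1, -radius:radius + 1]
    return x ** 2 + y ** 2 <= radius ** 2


@dataclass
class DiscParams:
    """Disc-extraction tunables.

    top_percent: share of brightest L-channel pixels kept for detection.
    radius_extension: pixels added to the detected radius so the full disc
        rim stays inside the crop.
    min_radius / max_radius: Hough search range, in pixels at 512-row
        scale (rescaled linearly for other raster heights).
    radius_step: spacing of the Hough radius sweep in pixels.
    accumulator_threshold: minimum normalized perimeter-vote fraction
        (0..1) for a circle to count as detected; below it the detector
        falls back to the bright-pixel centroid.
    """

    top_percent: float = 3.5
    radius_extension: int = 40
    min_radius: int = 15
    max_radius: int = 120
    radius_step: int = 2
    accumulator_threshold: float = 0.4
    closing_radius: int = 3
    boundary_tolerance: float = 0.85

    def __post_init__(self):
        if not 0 < self.top_percent < 100:
            raise ValueError("top_percent must be in (0, 100)")
        if self.radius_extension < 0:
            raise ValueError("radius_extension must be nonnegative")
        if self.min_radius >= self.max_radius:
            raise ValueError("min_radius must be below max_radius")


@dataclass
class DiscCircle:
    """A detected disc circle in right-half coordinates.

    `radius` already includes the extension; `detected_radius` is the raw
    Hough (or centroid-equivalent) radius.  `source` records whether the
    circle came from the Hough transform or the centroid fallback.
    """

    center_row: float
    center_col: float
    radius: float
    detected_radius: float
    source: str  # "hough" | "centroid-fallback"
    vote_fraction: float = 0.0


def crop_right_half(img: FundusImage) -> FundusImage:
    """Columns [floor(W/2), W); the column offset is recorded in meta."""
    h, w = img.shape
    offset = w // 2
    out = FundusImage(np.ascontiguousarray(img.pixels[:, offset:, :]), meta=dict(img.meta))
    out.meta["col_offset"] = offset
    return out


def brightness_top_mask(img: FundusImage, params: DiscParams | None = None) -> BinaryMask:
    """1 for pixels in the top `top_percent` of CIELab L; ties all kept."""
    params = params or DiscParams()
    lab_l = color.rgb2lab(img.pixels.astype(np.float64) / 255.0)[:, :, 0]
    threshold = np.percentile(lab_l, 100.0 - params.top_percent)
    return BinaryMask((lab_l >= threshold).astype(np.uint8), semantics="brightness-mask")


def _centroid_circle(points: np.ndarray, params: DiscParams, votes: float) -> DiscCircle:
    rr, cc = np.nonzero(points)
    r_eq = float(np.sqrt(len(rr) / np.pi))
    return DiscCircle(center_row=float(rr.mean()), center_col=float(cc.mean()),
                      radius=r_eq + params.radius_extension, detected_radius=r_eq,
                      source="centroid-fallback", vote_fraction=votes)


def detect_disc_circle(mask: BinaryMask, params: DiscParams | None = None) -> DiscCircle:
    """Best Hough circle through the mask, radius widened by the extension.

    The mask is first morphologically closed: in-disc percentile speckle
    (when the disc holds more pixels than the brightness budget keeps)
    solidifies into the disc shape, while sparse stray bright pixels
    vanish.  The accumulator is perimeter-normalized, so 1.0 means every
    perimeter pixel of a candidate circle is lit.  Because a filled blob
    lights every circle it contains, the disc boundary is the *largest*
    radius whose peak vote is still within `boundary_tolerance` of the
    global maximum; smaller interior circles are ignored.  If the best
    vote falls below `accumulator_threshold` (or closing empties the
    mask) the detector falls back to the bright-pixel centroid.
    """
    params = params or DiscParams()
    raw = mask.pixels.astype(bool)
    if not raw.any():
        raise DetectionError("no bright pixels: brightness mask is empty")
    points = raw
    if params.closing_radius > 0:
        struct = _disk_struct(params.closing_radius)
        points = ndi.binary_erosion(ndi.binary_dilation(raw, struct), struct)
        if not points.any():
            return _centroid_circle(raw, params, 0.0)
    h = mask.shape[0]
    scale = h / 512.0
    lo = max(3, int(round(params.min_radius * scale)))
    hi = max(lo + 1, int(round(params.max_radius * scale)))
    radii = np.arange(lo, hi + 1, params.radius_step)
    accums = hough_circle(points, radii, normalize=True)

    flat = accums.reshape(len(radii), -1)
    peak_votes = flat.max(axis=1)
    best_votes = float(peak_votes.max())
    if best_votes < params.accumulator_threshold:
        return _centroid_circle(raw, params, best_votes)
    eligible = np.nonzero(peak_votes >= params.boundary_tolerance * best_votes)[0]
    k = int(eligible.max())
    row, col = np.unravel_index(int(flat[k].argmax()), accums[k].shape)
    return DiscCircle(center_row=float(row), center_col=float(col),
                      radius=float(radii[k]) + params.radius_extension,
                      detected_radius=float(radii[k]), source="hough",
                      vote_fraction=float(peak_votes[k]))


def blackout_outside_circle(img: FundusImage, circle: DiscCircle) -> FundusImage:
    """Zero every pixel whose Euclidean distance from the center exceeds the radius."""
    h, w = img.shape
    rows, cols = np.ogrid[:h, :w]
    dist2 = (rows - circle.center_row) ** 2 + (cols - circle.center_col) ** 2
    out = img.pixels.copy()
    out[dist2 > circle.radius ** 2] = 0
    return FundusImage(out, meta=dict(img.meta))


def crop_circle_box(img: FundusImage, circle: DiscCircle) -> FundusImage:
    """Square bounding box of the (extended) circle, clipped to the raster.

    Cropping to the detected circle centers and scale-normalizes the disc
    before the classifier resize, so the cup-to-disc geometry lands at a
    canonical position instead of wherever the disc sat in the half-image.
    """
    h, w = img.shape
    r = int(np.ceil(circle.radius))
    side = 2 * r + 1
    out = np.zeros((side, side, 3), dtype=np.uint8)   # zero-padded at raster edges
    cr, cc = int(round(circle.center_row)), int(round(circle.center_col))
    r0, r1 = max(0, cr - r), min(h, cr + r + 1)
    c0, c1 = max(0, cc - r), min(w, cc + r + 1)
    out[r0 - (cr - r):r1 - (cr - r), c0 - (cc - r):c1 - (cc - r)] = img.pixels[r0:r1, c0:c1]
    return FundusImage(out, meta=dict(img.meta))


def extract_disc_region(img: FundusImage, params: DiscParams | None = None,
                        preprocess_params: PreprocessParams | None = None) -> GrayImage:
    """Full chain: right-half crop, bright-pixel Hough, blackout, disc-box
    crop, gray 64x64.

    The detected circle is recorded in the result's meta under
    "disc_circle" for introspection and reporting.
    """
    params = params or DiscParams()
    half = crop_right_half(img)
    mask = brightness_top_mask(half, params)
    circle = detect_disc_circle(mask, params)
    focused = blackout_outside_circle(half, circle)
    boxed = crop_circle_box(focused, circle)
    out = to_classifier_input(boxed, preprocess_params or PreprocessParams())
    out.meta["disc_circle"] = circle
    return out
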