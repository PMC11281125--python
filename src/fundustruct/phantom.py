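"""Seeded phantom fundus generator.

Renders simplified right-eye fundus photographs with known ground truth,
so every pipeline stage can be exercised and measured without clinical
data: a black camera background, a circular orange eye field with gentle
radial shading and sensor noise, a bright optic disc in the temporal
(right) half whose concentric dark cup encodes the class signal
(glaucoma = high cup-to-disc ratio, normal = low), and a branching tree
of dark vessels radiating from the disc, rasterized into both the image
and a binary vessel mask.

The geometry, not texture, carries the class signal: that mirrors how
clinicians grade glaucoma from the cup-to-disc ratio and gives the
disc branch of the classifier a genuine, checkable advantage.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage as ndi
from skimage import draw, transform

from .images import BinaryMask, FundusImage, GrayImage, LabelTable, to_gray

import pandas as pd


@dataclass
class PhantomParams:
    """Generator ranges; per-sample values are drawn uniformly from them."""

    size: int = 512
    eye_radius_frac: float = 0.47
    disc_radius_px: tuple = (20, 60)
    cup_to_disc_normal: tuple = (0.2, 0.4)
    cup_to_disc_glaucoma: tuple = (0.7, 0.9)
    n_vessel_branches: tuple = (6, 12)
    vessel_width_px: tuple = (2, 6)
    noise_sd: float = 3.0
    field_rgb: tuple = (190, 95, 45)
    disc_rgb: tuple = (225, 205, 160)
    # the cup is rendered dark (CIELab L below the field): the class
    # geometry then sits in well-separated one-sided intensity bands, and
    # the bright-pixel mask sees the disc as a bright annulus whose outer
    # boundary is exactly the disc radius the Hough stage must recover
    cup_rgb: tuple = (70, 40, 35)
    vessel_rgb: tuple = (110, 35, 30)
    # flash-reflection rim: CIELab L between field and disc, so whatever
    # part of the top-brightness budget the disc does not use lands on a
    # thin annulus that cannot host a spurious Hough circle
    rim_rgb: tuple = (220, 150, 90)
    rim_radii_frac: tuple = (0.93, 0.965)

    def __post_init__(self):
        for rng_ in (self.cup_to_disc_normal, self.cup_to_disc_glaucoma):
            if not (0 < rng_[0] <= rng_[1] < 1):
                raise ValueError("cup_to_disc ranges must lie inside (0, 1)")
        if self.cup_to_disc_normal[1] >= self.cup_to_disc_glaucoma[0]:
            raise ValueError("class cup_to_disc ranges must be disjoint")
        if self.disc_radius_px[0] > self.disc_radius_px[1]:
            raise ValueError("disc_radius_px range is empty")


@dataclass
class PhantomSample:
    image: FundusImage
    vessel_mask: BinaryMask
    disc_center: tuple          # (row, col) in full-image coordinates
    disc_radius: float
    cup_radius: float
    label: str
    seed: int


def _eye_geometry(params: PhantomParams) -> tuple[tuple[int, int], float]:
    c = params.size // 2
    return (c, c), params.eye_radius_frac * params.size


def generate_phantom(label: str, params: PhantomParams | None = None,
                     seed: int = 0) -> PhantomSample:
    """Render one phantom; fully deterministic given (label, params, seed)."""
    if label not in ("glaucoma", "normal"):
        raise ValueError(f"unknown label {label!r}")
    params = params or PhantomParams()
    rng = np.random.default_rng(seed)
    size = params.size
    (ec_r, ec_c), eye_r = _eye_geometry(params)

    rows, cols = np.ogrid[:size, :size]
    dist = np.sqrt((rows - ec_r) ** 2 + (cols - ec_c) ** 2)
    eye = dist <= eye_r

    img = np.zeros((size, size, 3), dtype=np.float64)
    # vignette is kept gentle (a few luma levels) so the brightest field
    # pixels stay noise-scattered instead of forming a compact dome
    shade = 1.0 - 0.06 * (dist / eye_r) ** 2
    for ch in range(3):
        img[:, :, ch] = params.field_rgb[ch] * shade
    rim = (dist >= params.rim_radii_frac[0] * eye_r) & (dist <= params.rim_radii_frac[1] * eye_r)
    img[rim] = params.rim_rgb

    # optic disc in the temporal (right) half, cup-to-disc ratio per class
    disc_r = rng.uniform(*params.disc_radius_px)
    cdr_range = (params.cup_to_disc_glaucoma if label == "glaucoma"
                 else params.cup_to_disc_normal)
    cdr = rng.uniform(*cdr_range)
    cup_r = cdr * disc_r
    margin = disc_r + 8
    disc_row = rng.uniform(0.38 * size, 0.62 * size)
    disc_col = rng.uniform(0.62 * size, min(0.82 * size, ec_c + eye_r - margin))
    rr, cc = draw.disk((disc_row, disc_col), disc_r, shape=(size, size))
    img[rr, cc] = params.disc_rgb
    rr, cc = draw.disk((disc_row, disc_col), cup_r, shape=(size, size))
    img[rr, cc] = params.cup_rgb

    # vessel tree: random-walk polylines radiating from the disc center
    vessel = np.zeros((size, size), dtype=bool)
    n_branches = rng.integers(params.n_vessel_branches[0], params.n_vessel_branches[1] + 1)
    for _ in range(n_branches):
        width = rng.uniform(*params.vessel_width_px)
        angle = rng.uniform(0.55 * np.pi, 1.45 * np.pi)   # head into the nasal half
        if rng.random() < 0.3:
            angle = rng.uniform(-0.45 * np.pi, 0.45 * np.pi)
        pos = np.array([disc_row, disc_col], dtype=float)
        centerline = np.zeros((size, size), dtype=bool)
        for _ in range(220):
            step = np.array([np.sin(angle), np.cos(angle)]) * 4.0
            nxt = pos + step
            rr, cc = draw.line(int(round(pos[0])), int(round(pos[1])),
                               int(round(nxt[0])), int(round(nxt[1])))
            keep = (rr >= 0) & (rr < size) & (cc >= 0) & (cc < size)
            centerline[rr[keep], cc[keep]] = True
            pos = nxt
            angle += rng.normal(0.0, 0.12)
            if np.hypot(pos[0] - ec_r, pos[1] - ec_c) > 0.93 * eye_r:
                break
        radius = max(1, int(round(width / 2)))
        branch = ndi.binary_dilation(centerline, structure=_disk_struct(radius))
        vessel |= branch
    vessel &= eye
    img[vessel] = params.vessel_rgb

    noisy = img + rng.normal(0.0, params.noise_sd, img.shape)
    noisy = np.clip(noisy, 0, 255)
    noisy[~eye] = 0.0
    image = FundusImage(np.rint(noisy).astype(np.uint8),
                        meta={"synthetic_seed": seed, "label": label})
    return PhantomSample(image=image,
                         vessel_mask=BinaryMask(vessel.astype(np.uint8), semantics="vessel-mask"),
                         disc_center=(disc_row, disc_col), disc_radius=float(disc_r),
                         cup_radius=float(cup_r), label=label, seed=seed)


def _disk_struct(radius: int) -> np.ndarray:
    y, x = np.ogrid[-radius:radius + 1, -radius:radius + 1]
    return x ** 2 + y ** 2 <= radius ** 2


def generate_dataset(n_per_class: int, params: PhantomParams | None = None,
                     seed: int = 0) -> tuple[list[PhantomSample], LabelTable]:
    """Balanced dataset; per-sample seeds derive from the master seed."""
    if n_per_class < 1:
        raise ValueError("n_per_class must be >= 1")
    params = params or PhantomParams()
    root = np.random.default_rng(seed)
    child_seeds = root.integers(0, 2 ** 31 - 1, size=2 * n_per_class)
    samples, rows = [], []
    for i in range(n_per_class):
        for j, label in enumerate(("glaucoma", "normal")):
            s = generate_phantom(label, params, seed=int(child_seeds[2 * i + j]))
            image_id = f"{label}_{i:03d}"
            s.image.meta["image_id"] = image_id
            samples.append(s)
            rows.append({"image_id": image_id, "label": label})
    return samples, LabelTable(pd.DataFrame(rows))


def vessel_patch_pairs(samples: list[PhantomSample], n_patches: int,
                       seed: int = 0) -> list[tuple[GrayImage, BinaryMask]]:
    """Aligned 64x64 (gray image, vessel mask) crops at 256x256 working scale.

    Each phantom is preprocessed (the segmentation network's inference
    input) and grayscaled to 256x256 before cropping; rejection sampling
    keeps at least half the patches with >= 1% vessel pixels so training
    batches are never vessel-free.
    """
    from .preprocess import preprocess_fundus

    if not samples:
        raise ValueError("need at least one phantom sample")
    rng = np.random.default_rng(seed)
    scaled = []
    for s in samples:
        enhanced, _ = preprocess_fundus(s.image)
        gray = to_gray(enhanced).pixels.astype(np.float64) / 255.0
        g256 = transform.resize(gray, (256, 256), order=1, anti_aliasing=False,
                                preserve_range=True)
        m256 = transform.resize(s.vessel_mask.pixels.astype(float), (256, 256),
                                order=0, anti_aliasing=False, preserve_range=True)
        scaled.append((np.rint(g256 * 255).astype(np.uint8), (m256 > 0.5).astype(np.uint8)))

    pairs: list[tuple[GrayImage, BinaryMask]] = []
    need_vessels = (n_patches + 1) // 2
    while len(pairs) < n_patches:
        g, m = scaled[rng.integers(len(scaled))]
        r0 = int(rng.integers(0, 256 - 64 + 1))
        c0 = int(rng.integers(0, 256 - 64 + 1))
        mc = m[r0:r0 + 64, c0:c0 + 64]
        vessel_frac = mc.mean()
        remaining_quota = need_vessels - sum(1 for _, mm in pairs if mm.pixels.mean() >= 0.01)
        if vessel_frac < 0.01 and remaining_quota >= n_patches - len(pairs):
            continue   # must spend the remaining slots on vessel-bearing patches
        pairs.append((GrayImage(g[r0:r0 + 64, c0:c0 + 64].copy()),
                      BinaryMask(mc.copy(), semantics="vessel-mask")))
    return pairs
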