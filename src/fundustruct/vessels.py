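"""Patch-based retinal-vessel segmentation with a residual U-Net.

A fundus image is grayscaled, resized to 256x256, cut into sixteen 64x64
patches on a 4x4 grid, pushed through a ResU-Net (three residual encoder
blocks, a bridge block, three residual decoder blocks with skip
concatenations — six residual blocks in total), and the sixteen
probability maps are stitched back to 256x256 and resized to the 64x64
classifier input.  The tiling is exact and non-overlapping, so
stitch(tile(x)) == x bit-for-bit.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from skimage import transform as sktransform

from . import nn
from .images import BinaryMask, FundusImage, GrayImage, to_gray

PATCH = 64
SOURCE = 256


@dataclass
class PatchGrid:
    """Ordered row-major 4x4 grid of 64x64 tiles from a 256x256 raster."""

    patches: list
    source_size: int = SOURCE

    def __post_init__(self):
        n = (self.source_size // PATCH) ** 2
        if len(self.patches) != n:
            raise ValueError(f"expected {n} patches, got {len(self.patches)}")
        for p in self.patches:
            if p.shape != (PATCH, PATCH):
                raise ValueError(f"every patch must be {PATCH}x{PATCH}, got {p.shape}")

    @property
    def grid_edge(self) -> int:
        return self.source_size // PATCH


def tile_image(img: GrayImage | np.ndarray) -> PatchGrid:
    """Cut a 256x256 raster into sixteen 64x64 tiles, row-major.

    Patch (i, j) covers rows [64i, 64i+64) and cols [64j, 64j+64).
    """
    arr = img.pixels if isinstance(img, GrayImage) else np.asarray(img)
    if arr.shape != (SOURCE, SOURCE):
        raise ValueError(f"tiling requires a {SOURCE}x{SOURCE} raster, got {arr.shape}")
    patches = [arr[i * PATCH:(i + 1) * PATCH, j * PATCH:(j + 1) * PATCH].copy()
               for i in range(SOURCE // PATCH) for j in range(SOURCE // PATCH)]
    return PatchGrid(patches)


def stitch_patches(grid: PatchGrid) -> np.ndarray:
    """Reassemble the tiles; exact inverse of `tile_image`."""
    edge = grid.grid_edge
    rows = [np.concatenate(grid.patches[i * edge:(i + 1) * edge], axis=1) for i in range(edge)]
    return np.concatenate(rows, axis=0)


@dataclass
class ResUNetSpec:
    """Topology of the segmentation network.

    Six residual blocks in total: one per encoder level, one bridge, one
    per decoder level, with a skip concatenation joining each
    encoder/decoder pair.
    """

    encoder_filters: tuple = (16, 32, 64)
    bridge_filters: int = 128
    input_size: int = 64

    def __post_init__(self):
        if len(self.encoder_filters) < 1:
            raise ValueError("need at least one encoder level")
        if self.input_size % (2 ** len(self.encoder_filters)) != 0:
            raise ValueError("input_size must be divisible by 2^levels")

    @property
    def n_residual_blocks(self) -> int:
        return 2 * len(self.encoder_filters)   # encoder + decoder levels

    @property
    def n_skip_connections(self) -> int:
        return len(self.encoder_filters)


class ResidualBlock(nn.Module):
    """conv-BN-ReLU, conv-BN, identity shortcut (1x1 projection on channel
    mismatch), final ReLU."""

    def __init__(self, in_ch: int, out_ch: int, rng: np.random.Generator):
        super().__init__()
        self.conv1 = nn.Conv2d(in_ch, out_ch, 3, rng)
        self.bn1 = nn.BatchNorm2d(out_ch)
        self.conv2 = nn.Conv2d(out_ch, out_ch, 3, rng)
        self.bn2 = nn.BatchNorm2d(out_ch)
        self.projection = nn.Conv2d(in_ch, out_ch, 1, rng) if in_ch != out_ch else None

    def forward(self, x):
        y = self.bn1(self.conv1(x)).relu()
        y = self.bn2(self.conv2(y))
        shortcut = self.projection(x) if self.projection is not None else x
        return (y + shortcut).relu()


class ResUNet(nn.Module):
    """Residual U-Net; bridge counts as the bottleneck block, not a
    residual block (the residual-block tally covers encoder + decoder)."""

    def __init__(self, spec: ResUNetSpec, rng: np.random.Generator):
        super().__init__()
        self.spec = spec
        filters = list(spec.encoder_filters)
        self.encoder = []
        in_ch = 1
        for f in filters:
            self.encoder.append(ResidualBlock(in_ch, f, rng))
            in_ch = f
        self.bridge = ResidualBlock(in_ch, spec.bridge_filters, rng)
        self.decoder = []
        self.up_convs = []
        in_ch = spec.bridge_filters
        for f in reversed(filters):
            self.up_convs.append(nn.Conv2d(in_ch, f, 3, rng))
            self.decoder.append(ResidualBlock(2 * f, f, rng))
            in_ch = f
        self.head = nn.Conv2d(in_ch, 1, 1, rng)

    def forward(self, x: nn.Tensor) -> nn.Tensor:
        skips = []
        for block in self.encoder:
            x = block(x)
            skips.append(x)
            x = x.max_pool2d(2)
        x = self.bridge(x)
        for up, block, skip in zip(self.up_convs, self.decoder, reversed(skips)):
            x = up(x.upsample_nearest(2))
            x = nn.Tensor.concatenate([x, skip], axis=1)
            x = block(x)
        return self.head(x).sigmoid()

    # -- introspection --------------------------------------------------------

    def describe(self) -> dict:
        return {
            "n_residual_blocks": len(self.encoder) + len(self.decoder),
            "n_skip_connections": len(self.decoder),
            "encoder_filters": [b.conv1.out_channels for b in self.encoder],
            "bridge_filters": self.bridge.conv1.out_channels,
            "decoder_filters": [b.conv1.out_channels for b in self.decoder],
        }


def build_resunet(spec: ResUNetSpec | None = None, seed: int = 0) -> ResUNet:
    spec = spec or ResUNetSpec()
    model = ResUNet(spec, np.random.default_rng(seed))
    desc = model.describe()
    if desc["n_residual_blocks"] != spec.n_residual_blocks:
        raise ValueError("constructed block count disagrees with spec")
    return model


@dataclass
class VesselTrainConfig:
    epochs: int = 15
    batch_size: int = 8
    learning_rate: float = 5e-4
    loss: str = "dice"   # soft-Dice handles the vessel/background imbalance
    seed: int = 0

    def __post_init__(self):
        if self.epochs < 1:
            raise ValueError("epochs must be >= 1")
        if self.loss not in ("binary-cross-entropy", "dice"):
            raise ValueError(f"unknown loss {self.loss!r}")


def _loss_fn(cfg: VesselTrainConfig, probs: nn.Tensor, targets: np.ndarray) -> nn.Tensor:
    if cfg.loss == "binary-cross-entropy":
        return nn.binary_cross_entropy(probs, targets)
    t = nn.Tensor(targets)
    inter = (probs * t).sum()
    denom = probs.sum() + t.sum() + 1e-6
    return 1.0 - (2.0 * inter) / denom


def train_vessel_model(pairs: list[tuple[GrayImage, BinaryMask]],
                       cfg: VesselTrainConfig | None = None,
                       spec: ResUNetSpec | None = None) -> tuple[ResUNet, list[float]]:
    """Train a ResU-Net on aligned (patch, mask) pairs.

    Returns the trained model and the per-epoch mean loss history; the
    config seed fixes initialization and shuffling, so identical calls
    give identical histories.
    """
    if not pairs:
        raise ValueError("training requires at least one (image, mask) pair")
    cfg = cfg or VesselTrainConfig()
    spec = spec or ResUNetSpec()
    rng = np.random.default_rng(cfg.seed)
    model = ResUNet(spec, rng)
    opt = nn.Adam(model.parameters(), lr=cfg.learning_rate)

    xs = np.stack([p[0].pixels for p in pairs]).astype(np.float32)[:, None] / 255.0
    ys = np.stack([p[1].pixels for p in pairs]).astype(np.float32)[:, None]
    history: list[float] = []
    n = len(pairs)
    for _ in range(cfg.epochs):
        order = rng.permutation(n)
        losses = []
        for start in range(0, n, cfg.batch_size):
            idx = order[start:start + cfg.batch_size]
            probs = model(nn.Tensor(xs[idx], requires_grad=False))
            loss = _loss_fn(cfg, probs, ys[idx])
            opt.zero_grad()
            loss.backward()
            opt.step()
            losses.append(float(loss.data))
        history.append(float(np.mean(losses)))
    chunk = max(cfg.batch_size, 16)
    nn.recalibrate_batchnorm(model, (
        (lambda s=s: model(nn.Tensor(xs[s:s + chunk]))) for s in range(0, n, chunk)))
    model.eval()
    return model, history


def segment_patch_grid(grid_array: np.ndarray, model: ResUNet) -> np.ndarray:
    """Run the model on all sixteen tiles of a 256x256 float array in [0,1]."""
    grid = tile_image(grid_array)
    batch = np.stack(grid.patches).astype(np.float32)[:, None]
    model.eval()
    probs = model(nn.Tensor(batch)).data[:, 0]
    return stitch_patches(PatchGrid([p for p in probs]))


def segment_vessels(img: FundusImage | GrayImage, model: ResUNet,
                    classifier_size: int = 64) -> np.ndarray:
    """Gray -> 256x256 -> tile -> per-patch inference -> stitch -> resize.

    Returns a float32 probability map of shape (classifier_size,
    classifier_size) with values in [0, 1].
    """
    gray = to_gray(img) if isinstance(img, FundusImage) else img
    arr = gray.pixels.astype(np.float64) / 255.0
    if arr.shape != (SOURCE, SOURCE):
        arr = sktransform.resize(arr, (SOURCE, SOURCE), order=1,
                                 anti_aliasing=False, preserve_range=True)
    full = segment_patch_grid(arr.astype(np.float32), model)
    out = sktransform.resize(full.astype(np.float64), (classifier_size, classifier_size),
                             order=1, anti_aliasing=False, preserve_range=True)
    return np.clip(out, 0.0, 1.0).astype(np.float32)


def dice_coefficient(pred: np.ndarray, truth: np.ndarray, threshold: float = 0.5) -> float:
    """Dice overlap between a thresholded probability map and a binary mask."""
    p = np.asarray(pred) >= threshold
    t = np.asarray(truth) > 0.5
    denom = p.sum() + t.sum()
    if denom == 0:
        return 1.0
    return float(2.0 * np.logical_and(p, t).sum() / denom)
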