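"""Three-branch CNN glaucoma classifier with attention fusion.

Three 64x64 single-channel inputs — the preprocessed fundus image, the
vessel probability map, and the optic-disc crop — each pass through an
identical CNN branch (four 3x3 convolutions with ReLU; BatchNorm +
2x2 max-pool after the second and fourth, so 64x64 -> 16x16 with the last
filter count as channels).  In attention mode the image-branch features
act as queries into each structure branch (scaled dot-product over the
flattened spatial positions); the two attended maps are concatenated,
normalized, pooled and passed to a convolutional head (final 1x1 kernel)
and dense layers ending in a two-way softmax over {glaucoma, normal}.
The ablation variant concatenates the three branch outputs directly with
no attention, keeping the identical head.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import nn

CLASSES = ("glaucoma", "normal")


@dataclass
class BranchSpec:
    """Per-branch CNN: four convolutions, BN + max-pool after layers 2 and 4."""

    conv_filters: tuple = (64, 128, 256, 512)
    kernel: int = 3
    input_size: int = 64

    def __post_init__(self):
        if len(self.conv_filters) != 4:
            raise ValueError("branch requires exactly four convolution layers")
        if self.input_size % 4 != 0:
            raise ValueError("input_size must be divisible by 4 (two pooling halvings)")

    @property
    def output_spatial(self) -> int:
        return self.input_size // 4

    @property
    def output_channels(self) -> int:
        return self.conv_filters[-1]


@dataclass
class HeadSpec:
    """Post-fusion head: three convolutions (last 1x1) then dense layers."""

    conv_filters: tuple = (2048, 4096, 4096)
    final_kernel: int = 1
    dense_units: tuple = (256, 2)
    # aggregate conv maps by global average pooling before the FC layers;
    # count-like pooled features generalize where a raw flatten memorizes
    # spatial positions on small datasets
    global_pool: bool = True

    def __post_init__(self):
        if len(self.conv_filters) != 3:
            raise ValueError("head requires exactly three convolution layers")
        if self.final_kernel != 1:
            raise ValueError("final head convolution must be 1x1")
        if self.dense_units[-1] != 2:
            raise ValueError("final dense layer must have width 2 (two classes)")


@dataclass
class FusionMode:
    mode: str = "attention"   # "attention" | "concat-ablation"

    def __post_init__(self):
        if self.mode not in ("attention", "concat-ablation"):
            raise ValueError(f"unknown fusion mode {self.mode!r}")


@dataclass
class ClassifierTrainConfig:
    epochs: int = 20
    batch_size: int = 8
    learning_rate: float = 2e-3
    optimizer: str = "adam"
    seed: int = 0

    def __post_init__(self):
        if self.epochs < 1:
            raise ValueError("epochs must be >= 1")
        if self.optimizer != "adam":
            raise ValueError("only adam is supported")


class Branch(nn.Module):
    """One CNN branch: conv-ReLU x2, BN, pool, conv-ReLU x2, BN, pool."""

    def __init__(self, spec: BranchSpec, rng: np.random.Generator):
        super().__init__()
        self.spec = spec
        f1, f2, f3, f4 = spec.conv_filters
        k = spec.kernel
        self.conv1 = nn.Conv2d(1, f1, k, rng)
        self.conv2 = nn.Conv2d(f1, f2, k, rng)
        self.bn1 = nn.BatchNorm2d(f2)
        self.conv3 = nn.Conv2d(f2, f3, k, rng)
        self.conv4 = nn.Conv2d(f3, f4, k, rng)
        self.bn2 = nn.BatchNorm2d(f4)

    def forward(self, x: nn.Tensor) -> nn.Tensor:
        x = self.conv2(self.conv1(x).relu()).relu()
        x = self.bn1(x).max_pool2d(2)
        x = self.conv4(self.conv3(x).relu()).relu()
        return self.bn2(x).max_pool2d(2)

    def describe(self) -> dict:
        convs = [self.conv1, self.conv2, self.conv3, self.conv4]
        return {
            "n_conv_layers": len(convs),
            "conv_filters": [c.out_channels for c in convs],
            "kernel": self.spec.kernel,
            "n_norm_pool_stages": 2,
            "output_spatial": self.spec.output_spatial,
            "output_channels": self.spec.output_channels,
        }


def build_branch(spec: BranchSpec | None = None, seed: int = 0) -> Branch:
    return Branch(spec or BranchSpec(), np.random.default_rng(seed))


def attention_fuse(query_feats: nn.Tensor, key_value_feats: nn.Tensor) -> tuple[nn.Tensor, nn.Tensor]:
    """Scaled dot-product attention between two (N, C, H, W) feature maps.

    Queries come from the image branch, keys and values from a structure
    branch; attention runs over the H*W flattened spatial positions.
    Returns (attended map with the key/value shape, attention weights of
    shape (N, P, P) whose rows sum to 1).
    """
    if query_feats.shape != key_value_feats.shape:
        raise ValueError(f"attention shape mismatch: {query_feats.shape} vs {key_value_feats.shape}")
    n, c, h, w = query_feats.shape
    p = h * w
    q = query_feats.reshape(n, c, p).transpose(0, 2, 1)          # (N, P, C)
    k = key_value_feats.reshape(n, c, p).transpose(0, 2, 1)
    v = k
    logits = q.matmul(k.transpose(0, 2, 1)) * (1.0 / np.sqrt(c))  # (N, P, P)
    weights = logits.softmax(axis=-1)
    attended = weights.matmul(v)                                  # (N, P, C)
    attended = attended.transpose(0, 2, 1).reshape(n, c, h, w)
    return attended, weights


class Head(nn.Module):
    def __init__(self, in_channels: int, spec: HeadSpec, spatial: int, rng: np.random.Generator):
        super().__init__()
        f1, f2, f3 = spec.conv_filters
        self.spec = spec
        self.bn_in = nn.BatchNorm2d(in_channels)
        self.conv1 = nn.Conv2d(in_channels, f1, 3, rng)
        self.conv2 = nn.Conv2d(f1, f2, 3, rng)
        self.conv3 = nn.Conv2d(f2, f3, spec.final_kernel, rng)
        self.bn_out = nn.BatchNorm2d(f3)
        pooled = spatial // 2
        self.dense = []
        in_features = f3 if spec.global_pool else f3 * pooled * pooled
        for units in spec.dense_units:
            self.dense.append(nn.Dense(in_features, units, rng))
            in_features = units

    def forward(self, x: nn.Tensor) -> nn.Tensor:
        x = self.bn_in(x).max_pool2d(2)
        x = self.conv2(self.conv1(x).relu()).relu()
        x = self.bn_out(self.conv3(x).relu())
        n = x.shape[0]
        if self.spec.global_pool:
            x = x.mean(axis=(2, 3))
        else:
            x = x.reshape(n, int(np.prod(x.shape[1:])))
        for layer in self.dense[:-1]:
            x = layer(x).relu()
        return self.dense[-1](x)   # logits; softmax applied by the caller

    def describe(self) -> dict:
        return {
            "conv_filters": [self.conv1.out_channels, self.conv2.out_channels,
                             self.conv3.out_channels],
            "final_kernel": self.conv3.kernel_size,
            "dense_units": [d.out_features for d in self.dense],
        }


class GlaucomaModel(nn.Module):
    """Multi-input classifier over (image, vessel, disc) 64x64 triples."""

    def __init__(self, branch_spec: BranchSpec, head_spec: HeadSpec,
                 fusion: FusionMode, rng: np.random.Generator):
        super().__init__()
        self.branch_spec = branch_spec
        self.head_spec = head_spec
        self.fusion = fusion
        self.image_branch = Branch(branch_spec, rng)
        self.vessel_branch = Branch(branch_spec, rng)
        self.disc_branch = Branch(branch_spec, rng)
        c = branch_spec.output_channels
        self.pre_head_channels = 2 * c if fusion.mode == "attention" else 3 * c
        self.head = Head(self.pre_head_channels, head_spec, branch_spec.output_spatial, rng)
        self.last_attention: tuple[np.ndarray, np.ndarray] | None = None

    def forward(self, image: nn.Tensor, vessel: nn.Tensor, disc: nn.Tensor) -> nn.Tensor:
        fi = self.image_branch(image)
        fv = self.vessel_branch(vessel)
        fd = self.disc_branch(disc)
        if self.fusion.mode == "attention":
            av, wv = attention_fuse(fi, fv)
            ad, wd = attention_fuse(fi, fd)
            self.last_attention = (wv.data, wd.data)
            fused = nn.Tensor.concatenate([av, ad], axis=1)
        else:
            fused = nn.Tensor.concatenate([fi, fv, fd], axis=1)
        return self.head(fused)

    def predict_proba(self, image: np.ndarray, vessel: np.ndarray, disc: np.ndarray) -> np.ndarray:
        """Probabilities over CLASSES for a batch of (N, 64, 64) inputs."""
        self.eval()
        logits = self.forward(nn.Tensor(_to_batch(image)), nn.Tensor(_to_batch(vessel)),
                              nn.Tensor(_to_batch(disc)))
        return logits.softmax(axis=-1).data

    def describe(self) -> dict:
        return {
            "fusion": self.fusion.mode,
            "branch": self.image_branch.describe(),
            "head": self.head.describe(),
            "pre_head_channels": self.pre_head_channels,
            "n_branches": 3,
            "classes": list(CLASSES),
        }


def _to_batch(arr: np.ndarray) -> np.ndarray:
    arr = np.asarray(arr, dtype=np.float32)
    if arr.ndim == 2:
        arr = arr[None]
    if arr.max() > 1.5:
        arr = arr / 255.0
    return arr[:, None]


def build_glaucoma_model(branch: BranchSpec | None = None, head: HeadSpec | None = None,
                         fusion: FusionMode | None = None, seed: int = 0) -> GlaucomaModel:
    return GlaucomaModel(branch or BranchSpec(), head or HeadSpec(),
                         fusion or FusionMode(), np.random.default_rng(seed))


def _onehot(labels: list[str]) -> np.ndarray:
    out = np.zeros((len(labels), len(CLASSES)), dtype=np.float32)
    for i, lab in enumerate(labels):
        out[i, CLASSES.index(lab)] = 1.0
    return out


def train_classifier(train_set: list[tuple[tuple, str]],
                     cfg: ClassifierTrainConfig | None = None,
                     fusion: FusionMode | None = None,
                     val_set: list[tuple[tuple, str]] | None = None,
                     branch_spec: BranchSpec | None = None,
                     head_spec: HeadSpec | None = None) -> tuple[GlaucomaModel, dict]:
    """Train a classifier on ((image, vessel, disc), label) samples.

    Both classes must be present.  The config seed fixes initialization
    and shuffling; the history dict records per-epoch train loss and
    accuracy, plus validation accuracy when a validation set is given.
    """
    cfg = cfg or ClassifierTrainConfig()
    fusion = fusion or FusionMode()
    labels = [lab for _, lab in train_set]
    if len(set(labels)) < 2:
        raise ValueError("training set must contain both classes")
    rng = np.random.default_rng(cfg.seed)
    model = GlaucomaModel(branch_spec or BranchSpec(), head_spec or HeadSpec(), fusion, rng)
    opt = nn.Adam(model.parameters(), lr=cfg.learning_rate)

    imgs, vess, discs = (np.stack([_as_float(t[i]) for t, _ in train_set]) for i in range(3))
    targets = _onehot(labels)
    history = {"train_loss": [], "train_accuracy": [], "val_accuracy": []}
    n = len(train_set)
    for _ in range(cfg.epochs):
        model.train()
        order = rng.permutation(n)
        losses, correct = [], 0
        for start in range(0, n, cfg.batch_size):
            idx = order[start:start + cfg.batch_size]
            logits = model(nn.Tensor(imgs[idx][:, None]), nn.Tensor(vess[idx][:, None]),
                           nn.Tensor(discs[idx][:, None]))
            loss = nn.softmax_cross_entropy(logits, targets[idx])
            opt.zero_grad()
            loss.backward()
            opt.step()
            losses.append(float(loss.data) * len(idx))
            correct += int((logits.data.argmax(axis=1) == targets[idx].argmax(axis=1)).sum())
        history["train_loss"].append(float(np.sum(losses) / n))
        history["train_accuracy"].append(correct / n)
        if val_set:
            _recalibrate(model, imgs, vess, discs, cfg.batch_size)
            acc, _ = evaluate_accuracy(model, val_set)
            history["val_accuracy"].append(acc)
    _recalibrate(model, imgs, vess, discs, cfg.batch_size)
    model.eval()
    return model, history


def _recalibrate(model: GlaucomaModel, imgs, vess, discs, batch_size: int) -> None:
    """Reset BatchNorm running stats to the training-set statistics."""
    chunk = max(batch_size, 32)
    starts = range(0, len(imgs), chunk)
    nn.recalibrate_batchnorm(model, (
        (lambda s=s: model(nn.Tensor(imgs[s:s + chunk][:, None]),
                           nn.Tensor(vess[s:s + chunk][:, None]),
                           nn.Tensor(discs[s:s + chunk][:, None])))
        for s in starts))


def _as_float(arr: np.ndarray) -> np.ndarray:
    arr = np.asarray(arr, dtype=np.float32)
    if arr.max() > 1.5:
        arr = arr / 255.0
    return arr


def evaluate_accuracy(model: GlaucomaModel,
                      samples: list[tuple[tuple, str]]) -> tuple[float, np.ndarray]:
    """Accuracy and per-sample probability matrix over CLASSES."""
    imgs = np.stack([_as_float(t[0]) for t, _ in samples])
    vess = np.stack([_as_float(t[1]) for t, _ in samples])
    discs = np.stack([_as_float(t[2]) for t, _ in samples])
    probs = model.predict_proba(imgs, vess, discs)
    preds = [CLASSES[i] for i in probs.argmax(axis=1)]
    acc = float(np.mean([p == lab for p, (_, lab) in zip(preds, samples)]))
    return acc, probs


def predict(model: GlaucomaModel, triple: tuple) -> tuple[str, np.ndarray]:
    """Classify one (image, vessel, disc) triple -> (label, probability 2-vector)."""
    probs = model.predict_proba(_as_float(triple[0]), _as_float(triple[1]),
                                _as_float(triple[2]))[0]
    return CLASSES[int(probs.argmax())], probs
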