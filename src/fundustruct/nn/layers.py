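"""Layer modules built on the autograd tensor.

Layout convention is NCHW.  Every module owns its parameters as `Tensor`s
with `requires_grad=True`; initialization draws from a caller-supplied
`numpy.random.Generator` so whole networks are reproducible from one seed.
"""

from __future__ import annotations

import numpy as np

from .tensor import Tensor


class Module:
    """Base class: parameter collection and train/eval mode switching."""

    def __init__(self):
        self.training = True

    def parameters(self) -> list[Tensor]:
        params: list[Tensor] = []
        for value in self.__dict__.values():
            if isinstance(value, Tensor) and value.requires_grad:
                params.append(value)
            elif isinstance(value, Module):
                params.extend(value.parameters())
            elif isinstance(value, (list, tuple)):
                for item in value:
                    if isinstance(item, Module):
                        params.extend(item.parameters())
        return params

    def modules(self) -> list["Module"]:
        mods: list[Module] = [self]
        for value in self.__dict__.values():
            if isinstance(value, Module):
                mods.extend(value.modules())
            elif isinstance(value, (list, tuple)):
                for item in value:
                    if isinstance(item, Module):
                        mods.extend(item.modules())
        return mods

    def train(self) -> None:
        for m in self.modules():
            m.training = True

    def eval(self) -> None:
        for m in self.modules():
            m.training = False

    def zero_grad(self) -> None:
        for p in self.parameters():
            p.grad = None

    def state_arrays(self) -> list[np.ndarray]:
        """Parameter + buffer arrays, in stable traversal order (for saving)."""
        arrays = [p.data for p in self.parameters()]
        for m in self.modules():
            if isinstance(m, BatchNorm2d):
                arrays.extend([m.running_mean, m.running_var])
        return arrays

    def load_state_arrays(self, arrays: list[np.ndarray]) -> None:
        it = iter(arrays)
        for p in self.parameters():
            p.data = np.asarray(next(it), dtype=np.float32).reshape(p.shape)
        for m in self.modules():
            if isinstance(m, BatchNorm2d):
                m.running_mean = np.asarray(next(it), dtype=np.float32)
                m.running_var = np.asarray(next(it), dtype=np.float32)

    def __call__(self, *args, **kwargs):
        return self.forward(*args, **kwargs)


def he_init(rng: np.random.Generator, shape: tuple[int, ...], fan_in: int) -> np.ndarray:
    return (rng.standard_normal(shape) * np.sqrt(2.0 / fan_in)).astype(np.float32)


class Conv2d(Module):
    """3x3 (or any odd-kernel) stride-1 same-padded convolution."""

    def __init__(self, in_channels: int, out_channels: int, kernel_size: int,
                 rng: np.random.Generator, padding: int | None = None):
        super().__init__()
        self.in_channels = in_channels
        self.out_channels = out_channels
        self.kernel_size = kernel_size
        self.padding = kernel_size // 2 if padding is None else padding
        fan_in = in_channels * kernel_size * kernel_size
        self.weight = Tensor(he_init(rng, (out_channels, in_channels, kernel_size, kernel_size), fan_in),
                             requires_grad=True)
        self.bias = Tensor(np.zeros(out_channels, dtype=np.float32), requires_grad=True)

    def forward(self, x: Tensor) -> Tensor:
        return x.conv2d(self.weight, self.bias, padding=self.padding)


class Dense(Module):
    def __init__(self, in_features: int, out_features: int, rng: np.random.Generator):
        super().__init__()
        self.in_features = in_features
        self.out_features = out_features
        self.weight = Tensor(he_init(rng, (in_features, out_features), in_features), requires_grad=True)
        self.bias = Tensor(np.zeros(out_features, dtype=np.float32), requires_grad=True)

    def forward(self, x: Tensor) -> Tensor:
        return x.matmul(self.weight) + self.bias


class BatchNorm2d(Module):
    """Per-channel batch normalization with running statistics for eval mode."""

    def __init__(self, channels: int, momentum: float = 0.1, eps: float = 1e-5):
        super().__init__()
        self.channels = channels
        self.momentum = momentum
        self.eps = eps
        self.gamma = Tensor(np.ones((1, channels, 1, 1), dtype=np.float32), requires_grad=True)
        self.beta = Tensor(np.zeros((1, channels, 1, 1), dtype=np.float32), requires_grad=True)
        self.running_mean = np.zeros((1, channels, 1, 1), dtype=np.float32)
        self.running_var = np.ones((1, channels, 1, 1), dtype=np.float32)

    def forward(self, x: Tensor) -> Tensor:
        if self.training:
            mu = x.mean(axis=(0, 2, 3), keepdims=True)
            centered = x - mu
            var = (centered * centered).mean(axis=(0, 2, 3), keepdims=True)
            self.running_mean = ((1 - self.momentum) * self.running_mean
                                 + self.momentum * mu.data).astype(np.float32)
            self.running_var = ((1 - self.momentum) * self.running_var
                                + self.momentum * var.data).astype(np.float32)
            inv = (var + self.eps)._pow_const(-0.5)
            return self.gamma * (centered * inv) + self.beta
        inv = 1.0 / np.sqrt(self.running_var + self.eps)
        return self.gamma * ((x - Tensor(self.running_mean)) * Tensor(inv)) + self.beta


class ReLU(Module):
    def forward(self, x: Tensor) -> Tensor:
        return x.relu()


class MaxPool2d(Module):
    def __init__(self, size: int = 2):
        super().__init__()
        self.size = size

    def forward(self, x: Tensor) -> Tensor:
        return x.max_pool2d(self.size)


class Sequential(Module):
    def __init__(self, *layers: Module):
        super().__init__()
        self.layers = list(layers)

    def forward(self, x: Tensor) -> Tensor:
        for layer in self.layers:
            x = layer(x)
        return x


def recalibrate_batchnorm(model: Module, forward_batches) -> None:
    """Refresh BatchNorm running statistics after training.

    Short trainings with small batches leave the exponentially-averaged
    running statistics far from the dataset statistics, which skews
    eval-mode outputs.  `forward_batches` is an iterable of zero-argument
    callables, each running one forward pass in training mode; batches
    are blended with cumulative (equal) weights so the running stats end
    as the average over all recalibration batches.
    """
    bns = [m for m in model.modules() if isinstance(m, BatchNorm2d)]
    saved = [m.momentum for m in bns]
    model.train()
    for k, run in enumerate(forward_batches, start=1):
        for m in bns:
            m.momentum = 1.0 / k
        run()
    for m, mom in zip(bns, saved):
        m.momentum = mom


def softmax_cross_entropy(logits: Tensor, onehot: np.ndarray) -> Tensor:
    """Mean categorical cross-entropy; `onehot` is (N, K) target indicators."""
    logp = logits.log_softmax(axis=-1)
    return -(logp * Tensor(onehot)).sum() * (1.0 / logits.shape[0])


def binary_cross_entropy(probs: Tensor, targets: np.ndarray) -> Tensor:
    """Mean BCE on probabilities already squashed to (0, 1)."""
    t = Tensor(targets)
    eps = 1e-7
    clipped = probs * (1 - 2 * eps) + eps
    loss = -(t * clipped.log() + (1.0 - t) * (1.0 - clipped).log())
    return loss.mean()
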