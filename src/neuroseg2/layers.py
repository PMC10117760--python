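"""Neural-network building blocks used by the segmentation model.

Modules follow the familiar container pattern: attributes that are
:class:`Parameter` or :class:`Module` (or lists of modules) are discovered
recursively, so optimizers and freeze/thaw logic can address parameter groups
by name.
"""

from __future__ import annotations

import numpy as np

from .autograd import Parameter, Tensor, concat, conv2d

__all__ = [
    "Module",
    "Conv2d",
    "Linear",
    "ECA",
    "CBAM",
    "CSPLayer",
    "BasicBlock",
    "Sequential",
    "SGD",
    "upsample2x",
]


class Module:
    def parameters(self):
        return [p for _, p in self.named_parameters()]

    def named_parameters(self, prefix: str = ""):
        out = []
        for name, value in vars(self).items():
            full = f"{prefix}{name}" if prefix else name
            if isinstance(value, Parameter):
                out.append((full, value))
            elif isinstance(value, Module):
                out.extend(value.named_parameters(full + "."))
            elif isinstance(value, (list, tuple)):
                for i, item in enumerate(value):
                    if isinstance(item, Module):
                        out.extend(item.named_parameters(f"{full}.{i}."))
                    elif isinstance(item, Parameter):
                        out.append((f"{full}.{i}", item))
        return out

    def num_parameters(self) -> int:
        return int(sum(p.data.size for p in self.parameters()))

    def state_dict(self):
        return {name: p.data.copy() for name, p in self.named_parameters()}

    def load_state_dict(self, state):
        for name, p in self.named_parameters():
            p.data[...] = state[name]

    def __call__(self, *args, **kwargs):
        return self.forward(*args, **kwargs)


def _he_init(rng: np.random.Generator, shape, fan_in: int) -> np.ndarray:
    std = np.sqrt(2.0 / max(fan_in, 1))
    return rng.normal(0.0, std, size=shape).astype(np.float32)


class Conv2d(Module):
    def __init__(self, cin, cout, k, rng, stride=1, pad=None, bias=True):
        self.stride = stride
        self.pad = k // 2 if pad is None else pad
        self.weight = Parameter(_he_init(rng, (cout, cin, k, k), cin * k * k))
        self.bias = Parameter(np.zeros(cout, dtype=np.float32)) if bias else None

    def forward(self, x):
        return conv2d(x, self.weight, self.bias, stride=self.stride, pad=self.pad)


class Linear(Module):
    def __init__(self, cin, cout, rng):
        self.weight = Parameter(_he_init(rng, (cin, cout), cin))
        self.bias = Parameter(np.zeros(cout, dtype=np.float32))

    def forward(self, x):
        return x @ self.weight + self.bias


class ECA(Module):
    """Efficient channel attention.

    Global average pooling over the spatial axes gives a C-length descriptor;
    a short bias-free 1-D convolution over that vector followed by a logistic
    produces per-channel gates in (0, 1) that rescale the input.  Adds exactly
    ``kernel`` parameters per instance.
    """

    def __init__(self, kernel: int, rng: np.random.Generator | None = None):
        if kernel < 1 or kernel % 2 == 0:
            raise ValueError(f"ECA kernel must be a positive odd integer, got {kernel}")
        self.kernel = kernel
        if rng is None:
            weight = np.zeros(kernel, dtype=np.float32)
            weight[kernel // 2] = 1.0  # identity-ish start: gate = sigmoid(gap)
        else:
            weight = rng.normal(0.0, 0.1, size=kernel).astype(np.float32)
            weight[kernel // 2] += 1.0
        self.weight = Parameter(weight)

    def channel_weights(self, x: Tensor) -> Tensor:
        n, c = x.shape[0], x.shape[1]
        gap = x.mean(axis=(2, 3))  # (N, C)
        half = self.kernel // 2
        padded = gap.pad_last(half, half)
        acc = None
        for j in range(self.kernel):
            term = padded[:, j : j + c] * self.weight[j]
            acc = term if acc is None else acc + term
        return acc.sigmoid()

    def forward(self, x: Tensor) -> Tensor:
        w = self.channel_weights(x)
        n, c = x.shape[0], x.shape[1]
        return x * w.reshape(n, c, 1, 1)


class CBAM(Module):
    """Convolutional block attention: channel gate (bottleneck MLP on the
    pooled descriptor) followed by a spatial gate (conv over the channel mean
    map).  Provided as a comparison arm; not tuned."""

    def __init__(self, channels: int, rng, reduction: int = 4, spatial_k: int = 7):
        hidden = max(channels // reduction, 1)
        self.fc1 = Linear(channels, hidden, rng)
        self.fc2 = Linear(hidden, channels, rng)
        self.spatial = Conv2d(1, 1, spatial_k, rng, bias=True)

    def forward(self, x: Tensor) -> Tensor:
        n, c = x.shape[0], x.shape[1]
        gate_c = self.fc2(self.fc1(x.mean(axis=(2, 3))).relu()).sigmoid()
        x = x * gate_c.reshape(n, c, 1, 1)
        mean_map = x.mean(axis=1, keepdims=True)
        gate_s = self.spatial(mean_map).sigmoid()
        return x * gate_s


class Bottleneck(Module):
    def __init__(self, channels, rng):
        self.conv1 = Conv2d(channels, channels, 1, rng)
        self.conv2 = Conv2d(channels, channels, 3, rng)

    def forward(self, x):
        return x + self.conv2(self.conv1(x).relu())


class CSPLayer(Module):
    """Cross-stage-partial block: split into two half-width branches, run one
    through ``depth`` bottlenecks, re-concatenate, and project to ``cout``.
    Applied after every 'Concatenate' feature fusion."""

    def __init__(self, cin, cout, rng, depth: int = 1):
        half = max(cout // 2, 1)
        self.branch_a = Conv2d(cin, half, 1, rng)
        self.branch_b = Conv2d(cin, half, 1, rng)
        self.blocks = [Bottleneck(half, rng) for _ in range(depth)]
        self.project = Conv2d(2 * half, cout, 1, rng)

    def forward(self, x):
        a = self.branch_a(x).relu()
        b = self.branch_b(x).relu()
        for blk in self.blocks:
            b = blk(b)
        return self.project(concat([a, b], axis=1)).relu()


class BasicBlock(Module):
    """Two 3x3 convolutions with a residual connection (ResNet basic block);
    the first convolution carries the stride, the shortcut uses a 1x1
    projection whenever shape changes."""

    def __init__(self, cin, cout, rng, stride=1):
        self.conv1 = Conv2d(cin, cout, 3, rng, stride=stride)
        self.conv2 = Conv2d(cout, cout, 3, rng)
        if stride != 1 or cin != cout:
            self.shortcut = Conv2d(cin, cout, 1, rng, stride=stride)
        else:
            self.shortcut = None

    def forward(self, x):
        identity = x if self.shortcut is None else self.shortcut(x)
        out = self.conv2(self.conv1(x).relu())
        return (out + identity).relu()


class Sequential(Module):
    def __init__(self, *modules):
        self.modules = list(modules)

    def forward(self, x):
        for m in self.modules:
            x = m(x)
        return x


def upsample2x(x: Tensor) -> Tensor:
    """Nearest-neighbour 2x spatial upsampling via index gather."""
    h, w = x.shape[2], x.shape[3]
    ri = np.arange(h).repeat(2)
    ci = np.arange(w).repeat(2)
    return x[:, :, ri, :][:, :, :, ci]


class SGD:
    """Stochastic gradient descent with momentum and decoupled weight decay."""

    def __init__(self, params, lr: float, momentum: float = 0.9, weight_decay: float = 1e-4):
        self.params = list(params)
        self.lr = lr
        self.momentum = momentum
        self.weight_decay = weight_decay
        self.velocity = [np.zeros_like(p.data) for p in self.params]

    def zero_grad(self):
        for p in self.params:
            p.grad = None

    def step(self):
        for p, v in zip(self.params, self.velocity):
            if p.grad is None:
                continue
            g = p.grad + self.weight_decay * p.data
            v *= self.momentum
            v -= self.lr * g
            p.data += v
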