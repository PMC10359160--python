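"""Conv-net building blocks and the generator/discriminator architectures.

Layout is channel-first without a batch axis: one sample per optimization
step (the effective Pix2Pix setting at volumetric patch sizes). Batch
normalization therefore reduces to per-channel (instance) normalization
computed from the current sample, which is deterministic given the input.
"""

from __future__ import annotations

import numpy as np

from . import autograd as ag
from .autograd import Tensor

__all__ = ["Module", "Conv3", "ChannelNorm", "UNetGenerator",
           "PatchDiscriminator", "Adam"]


class Module:
    """Base class: tracks parameters and submodules in registration order."""

    def __init__(self):
        self._params: list[Tensor] = []
        self._modules: list[Module] = []

    def register(self, array: np.ndarray) -> Tensor:
        p = Tensor(np.asarray(array, dtype=np.float32), requires_grad=True)
        self._params.append(p)
        return p

    def add_module(self, module: "Module") -> "Module":
        self._modules.append(module)
        return module

    def parameters(self) -> list[Tensor]:
        out = list(self._params)
        for m in self._modules:
            out.extend(m.parameters())
        return out

    def state_arrays(self) -> list[np.ndarray]:
        return [p.data.copy() for p in self.parameters()]

    def load_state_arrays(self, arrays) -> None:
        params = self.parameters()
        if len(arrays) != len(params):
            raise ValueError(
                f"checkpoint has {len(arrays)} arrays, model expects {len(params)}"
            )
        for p, a in zip(params, arrays):
            a = np.asarray(a, dtype=np.float32)
            if a.shape != p.data.shape:
                raise ValueError(
                    f"checkpoint array shape {a.shape} != parameter {p.data.shape}"
                )
            p.data = a.copy()


class Conv3(Module):
    """3x3x3 same-padding convolution with bias (He-normal init)."""

    def __init__(self, cin: int, cout: int, rng: np.random.Generator,
                 k: int = 3, init_std: float | None = None):
        super().__init__()
        std = init_std if init_std is not None else np.sqrt(2.0 / (cin * k**3))
        self.weight = self.register(rng.normal(0.0, std, (cout, cin, k, k, k)))
        self.bias = self.register(np.zeros(cout))

    def __call__(self, x: Tensor) -> Tensor:
        return ag.conv3d(x, self.weight, self.bias)


class ChannelNorm(Module):
    """Per-channel normalization with learnable gain and bias."""

    def __init__(self, channels: int):
        super().__init__()
        self.gain = self.register(np.ones((channels, 1, 1, 1)))
        self.bias = self.register(np.zeros((channels, 1, 1, 1)))

    def __call__(self, x: Tensor) -> Tensor:
        return ag.add(ag.mul(ag.channel_norm(x), self.gain), self.bias)


class _ConvBlock(Module):
    def __init__(self, cin, cout, rng, activation: str):
        super().__init__()
        self.conv = self.add_module(Conv3(cin, cout, rng))
        self.norm = self.add_module(ChannelNorm(cout))
        self.activation = activation

    def __call__(self, x: Tensor) -> Tensor:
        h = self.norm(self.conv(x))
        if self.activation == "leaky-relu":
            return ag.leaky_relu(h, 0.2)
        return ag.relu(h)


class UNetGenerator(Module):
    """U-Net mapping a 1-channel patch to a 3-channel stationary velocity.

    ``levels`` resolution scales (downsampling by 2 between scales), skip
    connections by channel concatenation, leaky-ReLU encoder / ReLU decoder
    activations, and an unbounded small-init output head scaled to mm by a
    fixed ``velocity_scale``.
    """

    def __init__(self, levels: int = 7, base_channels: int = 16,
                 velocity_scale: float = 10.0, max_channels: int = 64,
                 rng: np.random.Generator | None = None):
        super().__init__()
        if levels < 1:
            raise ValueError("levels must be >= 1")
        rng = rng or np.random.default_rng(0)
        self.levels = levels
        self.velocity_scale = float(velocity_scale)
        ch = [min(base_channels * 2**l, max_channels) for l in range(levels)]
        self.channels = ch
        self.enc = [
            self.add_module(_ConvBlock(1 if l == 0 else ch[l - 1], ch[l], rng,
                                       "leaky-relu"))
            for l in range(levels)
        ]
        self.dec = [
            self.add_module(_ConvBlock(ch[l] + ch[l + 1], ch[l], rng, "relu"))
            for l in range(levels - 1)
        ]
        self.head = self.add_module(Conv3(ch[0], 3, rng, init_std=1e-2))

    def required_divisor(self) -> int:
        return 2 ** (self.levels - 1)

    def __call__(self, x: Tensor) -> Tensor:
        div = self.required_divisor()
        if x.data.ndim != 4 or x.data.shape[0] != 1:
            raise ValueError(f"generator expects a (1, X, Y, Z) patch, got "
                             f"{x.data.shape}")
        if any(s % div or s // div < 2 for s in x.data.shape[1:]):
            raise ValueError(
                f"patch spatial dims {x.data.shape[1:]} must be divisible by "
                f"2^(levels-1) = {div} with at least 2 voxels at the bottom "
                f"level"
            )
        skips = []
        h = x
        for l in range(self.levels):
            h = self.enc[l](h)
            if l < self.levels - 1:
                skips.append(h)
                h = ag.avgpool2(h)
        for l in range(self.levels - 2, -1, -1):
            h = ag.upsample2(h)
            h = self.dec[l](ag.concat([skips[l], h], axis=0))
        v = self.head(h)
        return ag.mul(v, ag.constant(np.asarray(self.velocity_scale,
                                                dtype=v.data.dtype)))


class PatchDiscriminator(Module):
    """Conditional convolutional encoder producing a patchwise logit map.

    Input is the 2-channel (condition, candidate) pair; each layer halves
    resolution. Output logits (pre-sigmoid), one per receptive-field patch.
    """

    def __init__(self, layers: int = 4, base_channels: int = 32,
                 max_channels: int = 64,
                 rng: np.random.Generator | None = None):
        super().__init__()
        if layers < 1:
            raise ValueError("layers must be >= 1")
        rng = rng or np.random.default_rng(0)
        self.layers = layers
        ch = [min(base_channels * 2**l, max_channels) for l in range(layers)]
        self.blocks = [
            self.add_module(_ConvBlock(2 if l == 0 else ch[l - 1], ch[l], rng,
                                       "leaky-relu"))
            for l in range(layers)
        ]
        self.head = self.add_module(Conv3(ch[-1], 1, rng))

    def __call__(self, pair: Tensor) -> Tensor:
        if pair.data.ndim != 4 or pair.data.shape[0] != 2:
            raise ValueError(f"discriminator expects a (2, X, Y, Z) pair, got "
                             f"{pair.data.shape}")
        h = pair
        for l, block in enumerate(self.blocks):
            h = block(h)
            if l < self.layers - 1 and all(s % 2 == 0 for s in h.data.shape[1:]):
                h = ag.avgpool2(h)
        return self.head(h)


class Adam:
    """Adaptive-moment optimizer over a parameter list."""

    def __init__(self, params: list[Tensor], lr: float = 2e-4,
                 beta1: float = 0.5, beta2: float = 0.999, eps: float = 1e-8):
        self.params = list(params)
        self.lr = lr
        self.beta1, self.beta2, self.eps = beta1, beta2, eps
        self.t = 0
        self.m = [np.zeros_like(p.data) for p in self.params]
        self.v = [np.zeros_like(p.data) for p in self.params]

    def zero_grad(self):
        for p in self.params:
            p.grad = None

    def step(self):
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        for i, p in enumerate(self.params):
            if p.grad is None:
                continue
            g = p.grad.astype(p.data.dtype)
            self.m[i] = b1 * self.m[i] + (1 - b1) * g
            self.v[i] = b2 * self.v[i] + (1 - b2) * g * g
            mhat = self.m[i] / (1 - b1**self.t)
            vhat = self.v[i] / (1 - b2**self.t)
            p.data = p.data - self.lr * mhat / (np.sqrt(vhat) + self.eps)
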