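"""U-Net encoder-decoder for leaf segmentation, with optional squeeze-and-
excitation (SE) channel attention on the encoder skip features.

The encoder has ``depth`` levels of two same-padded 3x3 convolutions + ReLU,
each level followed by 2x2 max pooling (halving the resolution).  The decoder
mirrors it with bilinear 2x upsampling, concatenation of the corresponding
encoder skip feature, and two 3x3 convolutions.  A final 1x1 convolution and
a two-class softmax produce a per-pixel leaf-probability map.

With ``use_attention=True`` every skip feature is rescaled channel-wise by an
SE block before concatenation: gates = sigmoid(FC2(ReLU(FC1(GAP(f))))) with
FC1 reducing the channel count by ``se_reduction``.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass

import numpy as np

from . import autograd as ag
from .autograd import Module, Parameter, Tensor


@dataclass(frozen=True)
class SegModelConfig:
    """Architecture hyperparameters for the (attention) U-Net.

    ``base_channels`` doubles at every encoder level; 64 matches the
    full-scale VGG16-style network, 16 is the reduced CPU-friendly width.
    """

    depth: int = 5
    base_channels: int = 16
    use_attention: bool = True
    se_reduction: int = 16
    input_channels: int = 3
    output_classes: int = 2
    upsampling: str = "bilinear"

    def __post_init__(self):
        if self.depth < 2:
            raise ValueError("depth must be >= 2")
        if self.base_channels < 4:
            raise ValueError("base_channels must be >= 4")
        if self.se_reduction < 1:
            raise ValueError("se_reduction must be >= 1")
        if self.output_classes != 2:
            raise ValueError("only two-class (leaf/background) output supported")
        if self.upsampling != "bilinear":
            raise ValueError("only bilinear upsampling is implemented")

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "SegModelConfig":
        return cls(**d)


def _he_init(rng: np.random.Generator, shape: tuple, fan_in: int) -> np.ndarray:
    return (rng.standard_normal(shape) * np.sqrt(2.0 / fan_in)).astype(np.float32)


class Conv(Module):
    def __init__(self, rng, c_in: int, c_out: int, k: int = 3):
        self.w = Parameter(_he_init(rng, (c_out, c_in, k, k), c_in * k * k))
        self.b = Parameter(np.zeros(c_out, dtype=np.float32))

    def __call__(self, x: Tensor) -> Tensor:
        return ag.conv2d(x, self.w, self.b)


class Dense(Module):
    def __init__(self, rng, n_in: int, n_out: int):
        self.w = Parameter(_he_init(rng, (n_in, n_out), n_in))
        self.b = Parameter(np.zeros(n_out, dtype=np.float32))

    def __call__(self, x: Tensor) -> Tensor:
        return ag.matmul(x, self.w) + self.b


class SEBlock(Module):
    """Squeeze-and-excitation channel attention.

    Global average pooling squeezes each channel to a scalar; two fully
    connected layers (bottleneck of ``channels // reduction``, floored at 1)
    and a sigmoid produce per-channel gates in (0, 1) that rescale the input.

    ``pin_gates=True`` bypasses the gating (gate = 1 for every channel),
    which makes the attention network reproduce the plain U-Net exactly —
    useful as an equivalence check.
    """

    def __init__(self, rng, channels: int, reduction: int):
        hidden = max(1, channels // reduction)
        self.fc1 = Dense(rng, channels, hidden)
        self.fc2 = Dense(rng, hidden, channels)
        self.pin_gates = False

    def gates(self, x: Tensor) -> Tensor:
        return ag.sigmoid(self.fc2(ag.relu(self.fc1(ag.global_avg_pool(x)))))

    def __call__(self, x: Tensor) -> Tensor:
        if self.pin_gates:
            return x
        return ag.scale_channels(x, self.gates(x))


class UNet(Module):
    """See module docstring.  Input NCHW float32; output N x H x W leaf
    probabilities (the foreground channel of a two-class softmax)."""

    def __init__(self, config: SegModelConfig, rng: np.random.Generator):
        self.config = config
        d, base = config.depth, config.base_channels
        chans = [base * 2 ** i for i in range(d)]
        self.enc: list[list[Conv]] = []
        c_prev = config.input_channels
        for c in chans:
            self.enc.append([Conv(rng, c_prev, c), Conv(rng, c, c)])
            c_prev = c
        self.se: list[SEBlock] = []
        if config.use_attention:
            self.se = [SEBlock(rng, c, config.se_reduction) for c in chans[:-1]]
        self.dec: list[list[Conv]] = []
        for i in reversed(range(d - 1)):
            c_skip, c_up = chans[i], chans[i + 1]
            self.dec.append([Conv(rng, c_skip + c_up, c_skip),
                             Conv(rng, c_skip, c_skip)])
        self.head = Conv(rng, chans[0], config.output_classes, k=1)

    def pin_attention_gates(self, pinned: bool = True) -> None:
        for blk in self.se:
            blk.pin_gates = pinned

    def _check_input(self, x: np.ndarray) -> None:
        h, w = x.shape[2], x.shape[3]
        f = 2 ** (self.config.depth - 1)
        if h % f or w % f:
            raise ValueError(
                f"input spatial dims {h}x{w} must be divisible by "
                f"2^(depth-1) = {f} for depth {self.config.depth}")

    def forward(self, x) -> Tensor:
        """Return the two-class softmax output, shape (N, 2, H, W)."""
        if not isinstance(x, Tensor):
            x = Tensor(x)
        self._check_input(x.data)
        skips: list[Tensor] = []
        h = x
        for i, (c1, c2) in enumerate(self.enc):
            h = ag.relu(c2(ag.relu(c1(h))))
            if i < len(self.enc) - 1:
                skips.append(h)
                h = ag.maxpool2(h)
        for j, (c1, c2) in enumerate(self.dec):
            level = self.config.depth - 2 - j
            s = skips[level]
            if self.se:
                s = self.se[level](s)
            h = ag.concat_channels(s, ag.upsample2(h))
            h = ag.relu(c2(ag.relu(c1(h))))
        return ag.softmax_channels(self.head(h))

    def predict_proba(self, image: np.ndarray) -> np.ndarray:
        """Leaf-probability map for one H x W x 3 image in [0, 255]."""
        x = np.ascontiguousarray(
            image.astype(np.float32).transpose(2, 0, 1)[None] / 255.0)
        with ag.no_grad():
            p = self.forward(x)
        return p.data[0, 1]


def build_model(config: SegModelConfig, seed: int = 0) -> UNet:
    """Construct a seeded U-Net (attention variant per ``config``)."""
    return UNet(config, np.random.default_rng(seed))
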