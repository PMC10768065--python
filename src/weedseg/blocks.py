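"""Building blocks of the lightweight crop/weed segmentation network.

Four operators, all differentiable and shape-preserving in space:

* :class:`ConvBlock` — 3x3 convolution + batch norm + GELU, the basic unit.
* :class:`DualAttention` — external attention against two learnable memory
  matrices shared across the dataset, plus a channel gate (global average
  pool -> shared 3-tap 1-D convolution -> sigmoid), summed with an identity
  path under a GELU.
* :class:`RefinementDilatedConv` — the input is split into four channel
  groups, each filtered depthwise by a 3x3 kernel at dilation rate 1, 2, 5
  or 8, then the groups are re-fused by a pointwise convolution.
* :class:`SpatialConnectivityAttention` — a single 7x7 dilation-3 kernel,
  shared by every encoder stage, turns channel-wise max/average maps into a
  sigmoid spatial gate applied residually to each skip connection.

Normalisation inside the attention/refinement blocks is affine-free group
normalisation (4 groups); each such block instead carries one learnable
per-channel shift applied after normalisation.  Batch norms in conv blocks
are affine as usual.
"""

from __future__ import annotations

import numpy as np

from .autodiff import (
    Module,
    Parameter,
    Tensor,
    channel_conv1d,
    concat,
    conv2d,
    maxpool2x2,
    upsample_bilinear2x,
)

__all__ = [
    "BatchNorm2d",
    "GroupNorm",
    "ConvBlock",
    "DualAttention",
    "RefinementDilatedConv",
    "SpatialConnectivityAttention",
]

GN_GROUPS = 4
GN_EPS = 1e-5
BN_EPS = 1e-5
BN_MOMENTUM = 0.1
RDC_DILATION_RATES = (1, 2, 5, 8)
SCA_KERNEL = 7
SCA_DILATION = 3


def _uniform_fan_in(rng: np.random.Generator, shape, fan_in: int) -> np.ndarray:
    """Fan-based default initialisation: U(-1/sqrt(fan_in), 1/sqrt(fan_in))."""
    bound = 1.0 / np.sqrt(fan_in)
    return rng.uniform(-bound, bound, size=shape)


class BatchNorm2d(Module):
    def __init__(self, channels: int):
        super().__init__()
        self.channels = channels
        self.weight = Parameter(np.ones(channels))
        self.bias = Parameter(np.zeros(channels))
        self.register_buffer("running_mean", np.zeros(channels))
        self.register_buffer("running_var", np.ones(channels))

    def forward(self, x: Tensor) -> Tensor:
        c = self.channels
        if self.training:
            mu = x.mean(axis=(0, 2, 3), keepdims=True)
            var = ((x - mu) ** 2.0).mean(axis=(0, 2, 3), keepdims=True)
            n = x.data.shape[0] * x.data.shape[2] * x.data.shape[3]
            unbiased = var.data.reshape(c) * (n / max(n - 1, 1))
            self.set_buffer("running_mean",
                            (1 - BN_MOMENTUM) * self.get_buffer("running_mean")
                            + BN_MOMENTUM * mu.data.reshape(c))
            self.set_buffer("running_var",
                            (1 - BN_MOMENTUM) * self.get_buffer("running_var")
                            + BN_MOMENTUM * unbiased)
            xhat = (x - mu) * (var + BN_EPS) ** -0.5
        else:
            mu = Tensor(self.get_buffer("running_mean").reshape(1, c, 1, 1))
            var = Tensor(self.get_buffer("running_var").reshape(1, c, 1, 1))
            xhat = (x - mu) * (var + BN_EPS) ** -0.5
        return xhat * self.weight.reshape(1, c, 1, 1) + self.bias.reshape(1, c, 1, 1)


class GroupNorm(Module):
    """Affine-free group normalisation over ``GN_GROUPS`` channel groups."""

    def __init__(self, channels: int, groups: int = GN_GROUPS):
        super().__init__()
        if channels % groups:
            raise ValueError(
                f"group norm needs channels divisible by {groups}, got {channels}")
        self.channels = channels
        self.groups = groups

    def forward(self, x: Tensor) -> Tensor:
        b, c, h, w = x.shape
        g = self.groups
        xg = x.reshape(b, g, c // g * h * w)
        mu = xg.mean(axis=2, keepdims=True)
        var = ((xg - mu) ** 2.0).mean(axis=2, keepdims=True)
        xhat = (xg - mu) * (var + GN_EPS) ** -0.5
        return xhat.reshape(b, c, h, w)


class ConvBlock(Module):
    """3x3 convolution (stride 1, size-preserving) + batch norm + GELU."""

    def __init__(self, in_channels: int, out_channels: int,
                 rng: np.random.Generator, *, bias: bool = False):
        super().__init__()
        if out_channels <= 0:
            raise ValueError(f"out_channels must be positive, got {out_channels}")
        self.in_channels = in_channels
        self.out_channels = out_channels
        fan_in = in_channels * 9
        self.weight = Parameter(
            _uniform_fan_in(rng, (out_channels, in_channels, 3, 3), fan_in))
        self.bias = Parameter(_uniform_fan_in(rng, out_channels, fan_in)) if bias else None
        self.norm = BatchNorm2d(out_channels)

    def forward(self, x: Tensor) -> Tensor:
        return self.norm(conv2d(x, self.weight, self.bias)).gelu()


class DualAttention(Module):
    """External-attention memory units plus a channel gate, under a GELU.

    Branch 1 projects the input pointwise, normalises, computes per-pixel
    attention over the rows of a key memory (4C x C), forms a convex
    combination of the value memory's rows (softmax over the 4C memory slots),
    and projects back.  Branch 2 rescales channels by a sigmoid gate derived
    from a global average pool passed through a 3-tap shared 1-D convolution.
    The output is ``GELU(branch1 + branch2 + x)``.
    """

    def __init__(self, channels: int, rng: np.random.Generator):
        super().__init__()
        if channels % 4:
            raise ValueError(
                f"dual attention needs channels divisible by 4, got {channels}")
        c = channels
        self.channels = c
        self.proj_in_weight = Parameter(
            _uniform_fan_in(rng, (c, c, 1, 1), c))
        self.gn_in = GroupNorm(c)
        self.mem_k = Parameter(rng.normal(0.0, 1.0 / np.sqrt(c), (4 * c, c)))
        self.mem_v = Parameter(rng.normal(0.0, 1.0 / np.sqrt(c), (4 * c, c)))
        self.proj_out_weight = Parameter(
            _uniform_fan_in(rng, (c, c, 1, 1), c))
        self.gn_out = GroupNorm(c)
        self.out_shift = Parameter(np.zeros(c))  # learnable shift after the
        # affine-free norm (the branch's only bias)
        self.chan_kernel = Parameter(_uniform_fan_in(rng, 3, 3))

    def _memory_branch(self, x: Tensor) -> Tensor:
        b, c, h, w = x.shape
        t = self.gn_in(conv2d(x, self.proj_in_weight))
        flat = t.transpose(0, 2, 3, 1).reshape(b * h * w, c)        # (BN, C)
        scores = flat @ self.mem_k.transpose(1, 0)                   # (BN, 4C)
        attn = scores.softmax(axis=1)
        y = attn @ self.mem_v                                        # (BN, C)
        y = y.reshape(b, h, w, c).transpose(0, 3, 1, 2)
        y = self.gn_out(conv2d(y, self.proj_out_weight))
        return y + self.out_shift.reshape(1, c, 1, 1)

    def _channel_branch(self, x: Tensor) -> Tensor:
        b, c, _, _ = x.shape
        pooled = x.mean(axis=(2, 3))                                 # (B, C)
        gate = channel_conv1d(pooled, self.chan_kernel).sigmoid()
        return gate.reshape(b, c, 1, 1) * x

    def forward(self, x: Tensor) -> Tensor:
        return (self._memory_branch(x) + self._channel_branch(x) + x).gelu()

    def attention_weights(self, x: Tensor) -> np.ndarray:
        """Per-pixel softmax weights over the 4C memory slots (for inspection)."""
        b, c, h, w = x.shape
        t = self.gn_in(conv2d(x, self.proj_in_weight))
        flat = t.transpose(0, 2, 3, 1).reshape(b * h * w, c)
        return (flat @ self.mem_k.transpose(1, 0)).softmax(axis=1).numpy()


class RefinementDilatedConv(Module):
    """Multi-rate dilated refinement: split -> dilated depthwise -> fuse.

    The input's channels are split into four equal groups; group ``k`` is
    filtered depthwise (one 3x3 kernel per channel) at dilation rate
    ``(1, 2, 5, 8)[k]`` with padding equal to the rate, so spatial size is
    preserved.  The groups are concatenated and fused by a pointwise
    convolution to ``out_channels``, followed by affine-free group norm, a
    learnable per-channel shift and GELU.
    """

    def __init__(self, in_channels: int, out_channels: int,
                 rng: np.random.Generator):
        super().__init__()
        if in_channels % 4:
            raise ValueError(
                f"refinement dilated conv needs input channels divisible by 4, "
                f"got {in_channels}")
        if out_channels <= 0:
            raise ValueError(f"out_channels must be positive, got {out_channels}")
        self.in_channels = in_channels
        self.out_channels = out_channels
        q = in_channels // 4
        self.branch_weights = [
            Parameter(_uniform_fan_in(rng, (q, 1, 3, 3), 9))
            for _ in RDC_DILATION_RATES
        ]
        self.fuse_weight = Parameter(
            _uniform_fan_in(rng, (out_channels, in_channels, 1, 1), in_channels))
        self.norm = GroupNorm(out_channels)
        self.out_shift = Parameter(np.zeros(out_channels))

    def forward(self, x: Tensor) -> Tensor:
        c = self.in_channels
        q = c // 4
        parts = []
        for k, rate in enumerate(RDC_DILATION_RATES):
            xk = x[:, k * q:(k + 1) * q]
            parts.append(conv2d(xk, self.branch_weights[k],
                                dilation=rate, padding=rate, groups=q))
        fused = conv2d(concat(parts, axis=1), self.fuse_weight)
        y = self.norm(fused) + self.out_shift.reshape(1, self.out_channels, 1, 1)
        return y.gelu()

    def named_parameters(self, prefix: str = ""):
        for i, wk in enumerate(self.branch_weights):
            yield f"{prefix}branch_weights.{i}", wk
        yield prefix + "fuse_weight", self.fuse_weight
        yield prefix + "out_shift", self.out_shift


class SpatialConnectivityAttention(Module):
    """One shared 7x7 dilation-3 spatial gate for all encoder stages.

    For each stage output, the channel-wise max map and average map are
    concatenated (2 channels), convolved by the single shared kernel (padding
    9 preserves spatial size), squashed by a sigmoid into a gate in (0, 1),
    and applied residually: ``out = gate * x + x``.  The block has exactly
    2*7*7 + 1 = 99 trainable scalars however many stages it serves.
    """

    def __init__(self, rng: np.random.Generator):
        super().__init__()
        fan_in = 2 * SCA_KERNEL * SCA_KERNEL
        self.weight = Parameter(
            _uniform_fan_in(rng, (1, 2, SCA_KERNEL, SCA_KERNEL), fan_in))
        self.bias = Parameter(_uniform_fan_in(rng, 1, fan_in))

    def gate(self, x: Tensor) -> Tensor:
        mx = x.max(axis=1, keepdims=True)
        av = x.mean(axis=1, keepdims=True)
        pooled = concat([mx, av], axis=1)
        return conv2d(pooled, self.weight, self.bias,
                      dilation=SCA_DILATION).sigmoid()

    def forward(self, stage_outputs: list[Tensor]) -> list[Tensor]:
        if not stage_outputs:
            raise ValueError("spatial connectivity attention needs at least one stage")
        batches = {t.shape[0] for t in stage_outputs}
        if len(batches) != 1:
            raise ValueError(f"mismatched batch sizes across stages: {sorted(batches)}")
        return [self.gate(x) * x + x for x in stage_outputs]
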