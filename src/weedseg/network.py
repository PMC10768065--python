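"""Six-stage U-shaped encoder-decoder assembly and its ablation variants.

The encoder has six stages with channel plan {8, 16, 24, 32, 48, 64}.  Stage 1
is a plain conv block at full resolution; each later stage optionally applies
dual attention to the incoming features (at the incoming resolution and
channel count), halves the resolution with 2x2 max pooling, and extracts
features with either a conv block or, in the deep stages, the refinement
dilated conv.  The decoder mirrors the ladder: a conv block reduces channels
at the coarse resolution, bilinear interpolation doubles the resolution, and
the matching encoder output is added element-wise (never concatenated),
optionally gated by the weight-shared spatial connectivity attention.  A bare
3x3 convolution maps the 8 recovered channels to class logits; softmax over
classes is applied only at inference/metric time.

Encoder convolutions carry a bias term; decoder conv blocks and the head do
not (their shift is supplied by the batch norm, and logits need none).
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np

from .autodiff import Module, Parameter, Tensor, conv2d, maxpool2x2, upsample_bilinear2x
from .blocks import (
    ConvBlock,
    DualAttention,
    RefinementDilatedConv,
    SpatialConnectivityAttention,
    _uniform_fan_in,
)

__all__ = ["ArchConfig", "Network", "build_network", "build_variant", "VARIANTS"]

DEFAULT_CHANNELS = (8, 16, 24, 32, 48, 64)

#: Ablation variants: which blocks are active.  ``U_VI`` is the bare
#: six-stage U-shaped baseline.
VARIANTS: dict[str, dict] = {
    "U_VI": dict(da_stages=(), rdc_stages=(), use_sca=False),
    "U_VI+RDC": dict(da_stages=(), rdc_stages=(4, 5, 6), use_sca=False),
    "U_VI+DA": dict(da_stages=(2, 3, 4, 5, 6), rdc_stages=(), use_sca=False),
    "U_VI+SCA": dict(da_stages=(), rdc_stages=(), use_sca=True),
    "U_VI+RDC+DA": dict(da_stages=(2, 3, 4, 5, 6), rdc_stages=(4, 5, 6),
                        use_sca=False),
    "full": dict(da_stages=(2, 3, 4, 5, 6), rdc_stages=(4, 5, 6), use_sca=True),
}
VARIANT_ALIASES = {"U_VI+RDC+DA+SCA": "full"}


@dataclass(frozen=True)
class ArchConfig:
    """Architecture hyper-parameters; the default is the full network."""

    stage_channels: tuple[int, ...] = DEFAULT_CHANNELS
    in_channels: int = 3
    num_classes: int = 3
    da_stages: tuple[int, ...] = (2, 3, 4, 5, 6)
    rdc_stages: tuple[int, ...] = (4, 5, 6)
    use_sca: bool = True
    input_size: tuple[int, int] = (256, 256)

    def __post_init__(self):
        object.__setattr__(self, "stage_channels", tuple(self.stage_channels))
        object.__setattr__(self, "da_stages", tuple(sorted(self.da_stages)))
        object.__setattr__(self, "rdc_stages", tuple(sorted(self.rdc_stages)))
        object.__setattr__(self, "input_size", tuple(self.input_size))
        self.validate()

    @property
    def n_stages(self) -> int:
        return len(self.stage_channels)

    def incoming_channels(self, stage: int) -> int:
        """Channels entering ``stage`` (1-based)."""
        return self.in_channels if stage == 1 else self.stage_channels[stage - 2]

    def validate(self) -> None:
        if any(c <= 0 for c in self.stage_channels):
            raise ValueError("stage channels must be positive")
        if self.num_classes < 2:
            raise ValueError("need at least two classes")
        for s in self.da_stages:
            if not 2 <= s <= self.n_stages:
                raise ValueError(f"dual-attention stage {s} out of range 2..{self.n_stages}")
            if self.incoming_channels(s) % 4:
                raise ValueError(
                    f"dual attention at stage {s} needs incoming channels divisible "
                    f"by 4, got {self.incoming_channels(s)}")
        for s in self.rdc_stages:
            if not 2 <= s <= self.n_stages:
                raise ValueError(f"refinement stage {s} out of range 2..{self.n_stages}")
            if self.incoming_channels(s) % 4 or self.stage_channels[s - 1] % 4:
                raise ValueError(
                    f"refinement dilated conv at stage {s} needs channels divisible by 4")

    def to_dict(self) -> dict:
        d = asdict(self)
        return {k: list(v) if isinstance(v, tuple) else v for k, v in d.items()}

    @classmethod
    def from_dict(cls, d: dict) -> "ArchConfig":
        return cls(**d)


class Network(Module):
    """The assembled encoder-decoder (see module docstring)."""

    def __init__(self, config: ArchConfig, rng: np.random.Generator):
        super().__init__()
        config.validate()
        self.config = config
        ch = config.stage_channels
        n = config.n_stages

        self.enc_blocks: list[Module] = [
            ConvBlock(config.in_channels, ch[0], rng, bias=True)]
        self.da_blocks: list[Module] = []
        for stage in range(2, n + 1):
            cin = ch[stage - 2]
            if stage in config.da_stages:
                self.da_blocks.append(DualAttention(cin, rng))
            if stage in config.rdc_stages:
                self.enc_blocks.append(RefinementDilatedConv(cin, ch[stage - 1], rng))
            else:
                self.enc_blocks.append(ConvBlock(cin, ch[stage - 1], rng, bias=True))
        self._da_index = {s: i for i, s in enumerate(config.da_stages)}

        self.sca = SpatialConnectivityAttention(rng) if config.use_sca else None

        self.dec_blocks: list[Module] = [
            ConvBlock(ch[i], ch[i - 1], rng, bias=False)
            for i in range(n - 1, 0, -1)]

        fan_in = ch[0] * 9
        self.head_weight = Parameter(
            _uniform_fan_in(rng, (config.num_classes, ch[0], 3, 3), fan_in))

    # -- forward --------------------------------------------------------------
    def encode(self, x: Tensor) -> list[Tensor]:
        """Run the encoder, returning the per-stage outputs (skip sources)."""
        cfg = self.config
        h, w = x.shape[2], x.shape[3]
        stride = 2 ** (cfg.n_stages - 1)
        if h % stride or w % stride:
            raise ValueError(
                f"input spatial size ({h}x{w}) must be divisible by {stride} "
                f"({cfg.n_stages - 1} halvings)")
        feats = [self.enc_blocks[0](x)]
        t = feats[0]
        for stage in range(2, cfg.n_stages + 1):
            if stage in self._da_index:
                t = self.da_blocks[self._da_index[stage]](t)
            t = maxpool2x2(t)
            t = self.enc_blocks[stage - 1](t)
            feats.append(t)
        return feats

    def forward(self, x: Tensor) -> Tensor:
        feats = self.encode(x)
        skips = self.sca(feats) if self.sca is not None else feats
        t = skips[-1]
        for i, block in enumerate(self.dec_blocks):
            t = block(t)
            t = upsample_bilinear2x(t)
            t = t + skips[-(i + 2)]
        return conv2d(t, self.head_weight)

    def predict(self, images: np.ndarray) -> np.ndarray:
        """Argmax class labels for a (B, C, H, W) image batch (eval mode)."""
        was_training = self.training
        self.eval()
        try:
            logits = self.forward(Tensor(images)).numpy()
        finally:
            self.train(was_training)
        return logits.argmax(axis=1)


def build_network(config: ArchConfig, seed: int = 0) -> Network:
    """Construct a network with deterministic, seeded initialisation."""
    return Network(config, np.random.default_rng(seed))


def build_variant(name: str, seed: int = 0, **overrides) -> Network:
    """Construct a named ablation variant (see :data:`VARIANTS`)."""
    key = VARIANT_ALIASES.get(name, name)
    if key not in VARIANTS:
        valid = sorted(VARIANTS) + sorted(VARIANT_ALIASES)
        raise ValueError(f"unknown variant {name!r}; valid names: {valid}")
    kwargs = dict(VARIANTS[key])
    kwargs.update(overrides)
    return build_network(ArchConfig(**kwargs), seed=seed)
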