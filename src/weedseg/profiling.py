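"""Trainable-parameter and operation counting for the segmentation network.

Parameters are counted exactly by enumerating every learnable array.
Operation counts ("FLOPs" in the loose sense common for convolutional
networks) follow a fixed cost table, applied structurally to the
architecture at a stated input size:

==============================  =======================================
operation                       cost
==============================  =======================================
2-D convolution / matmul        K^2 * C_in/groups * C_out * H * W MACs
1-D channel convolution         3 * C MACs
batch normalisation             2 ops per element (scale + shift)
2x2 max pooling                 1 op per output element
global average pooling          1 op per input element
class-probability softmax       1 op per logit (inference head)
group norm, GELU, sigmoid,
bias add, interpolation, adds   free
==============================  =======================================

One MAC is reported as one FLOP.  The table is the convention under which
the counts for this family of models reproduce the complexity figures
published for it; see docs/methods.md for the calibration discussion.
"""

from __future__ import annotations

import json
from dataclasses import dataclass

from .blocks import (
    ConvBlock,
    DualAttention,
    RefinementDilatedConv,
    SpatialConnectivityAttention,
)
from .network import Network

__all__ = ["ComplexityReport", "count_parameters", "count_flops", "profile_network"]


@dataclass
class ComplexityReport:
    param_count: int
    flops: int
    input_size: tuple[int, int]
    modules: list[dict]  # per-module rows: name, params, flops

    @property
    def params_M(self) -> float:
        return self.param_count / 1e6

    @property
    def flops_G(self) -> float:
        return self.flops / 1e9

    def to_json(self, indent: int | None = 2) -> str:
        return json.dumps({
            "param_count": self.param_count,
            "params_M": round(self.params_M, 4),
            "flops": self.flops,
            "flops_G": round(self.flops_G, 4),
            "input_size": list(self.input_size),
            "modules": self.modules,
        }, indent=indent)

    def table(self) -> str:
        lines = [f"{'module':<28s}{'params':>10s}{'flops':>14s}"]
        for row in self.modules:
            lines.append(f"{row['name']:<28s}{row['params']:>10d}{row['flops']:>14d}")
        lines.append(f"{'TOTAL':<28s}{self.param_count:>10d}{self.flops:>14d}")
        lines.append(f"params {self.params_M:.4f} M   flops {self.flops_G:.4f} G")
        return "\n".join(lines)


def count_parameters(module) -> int:
    """Exact number of learnable scalars in a module."""
    return sum(p.data.size for p in module.parameters())


def _conv_block_flops(blk: ConvBlock, h: int, w: int) -> int:
    macs = 9 * blk.in_channels * blk.out_channels * h * w
    norm = 2 * blk.out_channels * h * w
    return macs + norm


def _da_flops(blk: DualAttention, h: int, w: int) -> int:
    c, n = blk.channels, h * w
    projections = 2 * c * c * n            # two pointwise convolutions
    memory = 2 * n * c * (4 * c)           # scores and value mixing matmuls
    pool = n * c                           # global average pool
    chan = 3 * c                           # shared 3-tap 1-D convolution
    return projections + memory + pool + chan


def _rdc_flops(blk: RefinementDilatedConv, h: int, w: int) -> int:
    branches = 9 * blk.in_channels * h * w         # depthwise 3x3 per channel
    fuse = blk.in_channels * blk.out_channels * h * w
    return branches + fuse                         # group norm is free


def _sca_flops(sizes: list[tuple[int, int]]) -> int:
    return sum(2 * 49 * h * w for h, w in sizes)


def count_flops(net: Network, input_size: tuple[int, int] | None = None) -> int:
    """Operation count for one forward pass at batch size 1."""
    return profile_network(net, input_size).flops


def profile_network(net: Network, input_size: tuple[int, int] | None = None
                    ) -> ComplexityReport:
    """Per-module parameter and operation table for ``net``."""
    cfg = net.config
    h, w = input_size if input_size is not None else cfg.input_size
    stride = 2 ** (cfg.n_stages - 1)
    if h % stride or w % stride:
        raise ValueError(f"input size {h}x{w} must be divisible by {stride}")

    rows: list[dict] = []

    def add(name, module_or_params, flops):
        params = (module_or_params if isinstance(module_or_params, int)
                  else count_parameters(module_or_params))
        rows.append({"name": name, "params": params, "flops": int(flops)})

    sizes = [(h // 2 ** i, w // 2 ** i) for i in range(cfg.n_stages)]

    # encoder
    add("encoder.stage1.conv", net.enc_blocks[0],
        _conv_block_flops(net.enc_blocks[0], *sizes[0]))
    for stage in range(2, cfg.n_stages + 1):
        hin, win = sizes[stage - 2]
        hout, wout = sizes[stage - 1]
        if stage in net._da_index:
            da = net.da_blocks[net._da_index[stage]]
            add(f"encoder.stage{stage}.da", da, _da_flops(da, hin, win))
        add(f"encoder.stage{stage}.pool", 0, hout * wout * cfg.incoming_channels(stage))
        blk = net.enc_blocks[stage - 1]
        if isinstance(blk, RefinementDilatedConv):
            add(f"encoder.stage{stage}.rdc", blk, _rdc_flops(blk, hout, wout))
        else:
            add(f"encoder.stage{stage}.conv", blk, _conv_block_flops(blk, hout, wout))

    if net.sca is not None:
        add("sca", net.sca, _sca_flops(sizes))

    # decoder: conv at the coarse resolution, then (free) bilinear upsample
    for i, blk in enumerate(net.dec_blocks):
        hs, ws = sizes[cfg.n_stages - 1 - i]
        add(f"decoder.stage{cfg.n_stages - i}.conv", blk,
            _conv_block_flops(blk, hs, ws))

    head_macs = 9 * cfg.stage_channels[0] * cfg.num_classes * h * w
    add("head.conv", net.head_weight.data.size, head_macs)
    add("head.softmax", 0, cfg.num_classes * h * w)

    total_params = count_parameters(net)
    assert total_params == sum(r["params"] for r in rows), \
        "per-module parameter rows do not cover the network"
    total_flops = sum(r["flops"] for r in rows)
    return ComplexityReport(total_params, total_flops, (h, w), rows)
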