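"""Independent dense-loop reference implementations of the block equations.

These deliberately avoid the package's autodiff/vectorised code paths: every
convolution and attention product is written as explicit Python loops over
numpy scalars, so they can serve as oracles for the production blocks on
tiny inputs.
"""

import math

import numpy as np

GN_EPS = 1e-5
BN_EPS = 1e-5


def gelu_scalar(v: float) -> float:
    return 0.5 * v * (1.0 + math.erf(v / math.sqrt(2.0)))


def conv2d_loops(x, w, b=None, dilation=1, padding=None):
    """Naive stride-1 2-D convolution; x (C,H,W), w (O,C,kh,kw)."""
    cout, cin, kh, kw = w.shape
    c, h, wd = x.shape
    assert c == cin
    if padding is None:
        padding = dilation * (kh - 1) // 2
    out = np.zeros((cout, h + 2 * padding - (kh - 1) * dilation,
                    wd + 2 * padding - (kw - 1) * dilation))
    xp = np.pad(x, ((0, 0), (padding, padding), (padding, padding)))
    for o in range(cout):
        for i in range(out.shape[1]):
            for j in range(out.shape[2]):
                acc = 0.0
                for ci in range(cin):
                    for ki in range(kh):
                        for kj in range(kw):
                            acc += w[o, ci, ki, kj] * xp[ci, i + ki * dilation,
                                                         j + kj * dilation]
                out[o, i, j] = acc + (b[o] if b is not None else 0.0)
    return out


def depthwise_conv2d_loops(x, w, dilation, padding):
    """x (C,H,W), w (C,1,3,3): one kernel per channel."""
    c, h, wd = x.shape
    out = np.zeros_like(x)
    xp = np.pad(x, ((0, 0), (padding, padding), (padding, padding)))
    for ci in range(c):
        for i in range(h):
            for j in range(wd):
                acc = 0.0
                for ki in range(3):
                    for kj in range(3):
                        acc += w[ci, 0, ki, kj] * xp[ci, i + ki * dilation,
                                                     j + kj * dilation]
                out[ci, i, j] = acc
    return out


def groupnorm4_loops(x):
    """Affine-free group norm with 4 groups; x (C,H,W)."""
    c = x.shape[0]
    out = np.zeros_like(x)
    gsize = c // 4
    for g in range(4):
        sl = x[g * gsize:(g + 1) * gsize]
        mu = sl.mean()
        var = ((sl - mu) ** 2).mean()
        out[g * gsize:(g + 1) * gsize] = (sl - mu) / math.sqrt(var + GN_EPS)
    return out


def dual_attention_loops(block, x):
    """Reference evaluation of the dual-attention equations; x (C,H,W)."""
    c, h, w = x.shape
    mk = block.mem_k.numpy()
    mv = block.mem_v.numpy()
    # branch 1: project, attend over memory rows, re-project
    t = groupnorm4_loops(conv2d_loops(x, block.proj_in_weight.numpy()))
    y = np.zeros((c, h, w))
    for i in range(h):
        for j in range(w):
            scores = np.array([sum(t[ci, i, j] * mk[s, ci] for ci in range(c))
                               for s in range(4 * c)])
            e = np.exp(scores - scores.max())
            attn = e / e.sum()
            for ci in range(c):
                y[ci, i, j] = sum(attn[s] * mv[s, ci] for s in range(4 * c))
    b1 = groupnorm4_loops(conv2d_loops(y, block.proj_out_weight.numpy()))
    b1 = b1 + block.out_shift.numpy()[:, None, None]
    # branch 2: global average pool -> shared 3-tap conv -> sigmoid gate
    pooled = np.array([x[ci].mean() for ci in range(c)])
    k = block.chan_kernel.numpy()
    padded = np.concatenate([[0.0], pooled, [0.0]])
    gate = np.array([1.0 / (1.0 + math.exp(-(k[0] * padded[ci] + k[1] * padded[ci + 1]
                                             + k[2] * padded[ci + 2])))
                     for ci in range(c)])
    b2 = gate[:, None, None] * x
    out = b1 + b2 + x
    return np.vectorize(gelu_scalar)(out)


def rdc_loops(block, x):
    """Reference evaluation of the refinement dilated conv; x (C,H,W)."""
    c = x.shape[0]
    q = c // 4
    parts = []
    for k, rate in enumerate((1, 2, 5, 8)):
        parts.append(depthwise_conv2d_loops(
            x[k * q:(k + 1) * q], block.branch_weights[k].numpy(),
            dilation=rate, padding=rate))
    fused = conv2d_loops(np.concatenate(parts, axis=0), block.fuse_weight.numpy())
    y = groupnorm4_loops(fused) + block.out_shift.numpy()[:, None, None]
    return np.vectorize(gelu_scalar)(y)


def sca_loops(block, x):
    """Reference evaluation of the shared spatial gate; x (C,H,W)."""
    c, h, w = x.shape
    mx = x.max(axis=0)
    av = x.mean(axis=0)
    pooled = np.stack([mx, av])
    conv = conv2d_loops(pooled, block.weight.numpy(), block.bias.numpy(),
                        dilation=3, padding=9)[0]
    gate = 1.0 / (1.0 + np.exp(-conv))
    return gate[None] * x + x


def conv_block_eval_loops(block, x):
    """Conv block in inference mode with default (identity) running stats."""
    w = block.weight.numpy()
    b = block.bias.numpy() if block.bias is not None else None
    y = conv2d_loops(x, w, b)
    rm = block.norm.get_buffer("running_mean")
    rv = block.norm.get_buffer("running_var")
    gamma = block.norm.weight.numpy()
    beta = block.norm.bias.numpy()
    y = (y - rm[:, None, None]) / np.sqrt(rv[:, None, None] + BN_EPS)
    y = gamma[:, None, None] * y + beta[:, None, None]
    return np.vectorize(gelu_scalar)(y)
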