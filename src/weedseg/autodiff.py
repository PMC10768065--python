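"""Minimal reverse-mode automatic differentiation on numpy arrays.

The segmentation network in this package is small (~0.1 M parameters), so a
compact tape-based engine is sufficient: each :class:`Tensor` records the
operation that produced it and a closure that propagates gradients to its
parents.  Convolution, pooling and bilinear interpolation are primitives with
hand-derived adjoints; everything else (normalisation layers, attention
arithmetic, losses) is composed from elementwise/matmul primitives so its
backward pass comes for free.

All arithmetic is float64.  The engine is deterministic: identical inputs and
parameters produce bit-identical outputs and gradients on a single machine.
"""

from __future__ import annotations

import numpy as np
from scipy.special import erf as _erf

__all__ = [
    "Tensor",
    "Parameter",
    "Module",
    "concat",
    "conv2d",
    "channel_conv1d",
    "maxpool2x2",
    "upsample_bilinear2x",
]

_SQRT2 = np.sqrt(2.0)
_INV_SQRT_2PI = 1.0 / np.sqrt(2.0 * np.pi)


def _unbroadcast(grad: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Reduce ``grad`` back to ``shape`` after numpy broadcasting."""
    if grad.shape == shape:
        return grad
    # sum over leading axes added by broadcasting
    while grad.ndim > len(shape):
        grad = grad.sum(axis=0)
    for ax, n in enumerate(shape):
        if n == 1 and grad.shape[ax] != 1:
            grad = grad.sum(axis=ax, keepdims=True)
    return grad


class Tensor:
    """A numpy array plus the tape bookkeeping needed for backprop."""

    __slots__ = ("data", "grad", "requires_grad", "_backward", "_parents")
    __array_priority__ = 100  # make ndarray defer to our __radd__ etc.

    def __init__(self, data, requires_grad: bool = False):
        self.data = np.asarray(data, dtype=np.float64)
        self.grad: np.ndarray | None = None
        self.requires_grad = bool(requires_grad)
        self._backward = None
        self._parents: tuple[Tensor, ...] = ()

    # -- construction helpers -------------------------------------------------
    @staticmethod
    def _lift(other) -> "Tensor":
        return other if isinstance(other, Tensor) else Tensor(other)

    @property
    def shape(self) -> tuple[int, ...]:
        return self.data.shape

    @property
    def ndim(self) -> int:
        return self.data.ndim

    def item(self) -> float:
        return float(self.data)

    def detach(self) -> "Tensor":
        return Tensor(self.data)

    def numpy(self) -> np.ndarray:
        return self.data

    def __repr__(self) -> str:  # pragma: no cover - debugging aid
        return f"Tensor(shape={self.shape}, requires_grad={self.requires_grad})"

    # -- tape -----------------------------------------------------------------
    def _make(self, data: np.ndarray, parents: tuple["Tensor", ...], backward):
        out = Tensor(data)
        if any(p.requires_grad for p in parents):
            out.requires_grad = True
            out._parents = tuple(p for p in parents if p.requires_grad)
            out._backward = backward
        return out

    def backward(self, grad: np.ndarray | None = None) -> None:
        """Accumulate gradients of ``self`` (a scalar unless ``grad`` given)."""
        if grad is None:
            if self.data.size != 1:
                raise ValueError("backward() without grad requires a scalar")
            grad = np.ones_like(self.data)
        # topological order over the tape
        topo: list[Tensor] = []
        seen: set[int] = set()
        stack: list[tuple[Tensor, bool]] = [(self, False)]
        while stack:
            node, processed = stack.pop()
            if processed:
                topo.append(node)
                continue
            if id(node) in seen or not node.requires_grad:
                continue
            seen.add(id(node))
            stack.append((node, True))
            for p in node._parents:
                stack.append((p, False))
        self.grad = np.asarray(grad, dtype=np.float64).reshape(self.data.shape)
        for node in reversed(topo):
            if node._backward is not None:
                node._backward(node.grad)

    def _accum(self, grad: np.ndarray) -> None:
        grad = _unbroadcast(np.asarray(grad, dtype=np.float64), self.data.shape)
        if self.grad is None:
            self.grad = grad.copy()
        else:
            self.grad += grad

    def zero_grad(self) -> None:
        self.grad = None

    # -- elementwise arithmetic ----------------------------------------------
    def __add__(self, other):
        other = self._lift(other)
        def backward(g):
            self._accum(g)
            other._accum(g)
        return self._make(self.data + other.data, (self, other), backward)

    __radd__ = __add__

    def __neg__(self):
        def backward(g):
            self._accum(-g)
        return self._make(-self.data, (self,), backward)

    def __sub__(self, other):
        return self + (-self._lift(other))

    def __rsub__(self, other):
        return self._lift(other) + (-self)

    def __mul__(self, other):
        other = self._lift(other)
        def backward(g):
            self._accum(g * other.data)
            other._accum(g * self.data)
        return self._make(self.data * other.data, (self, other), backward)

    __rmul__ = __mul__

    def __truediv__(self, other):
        return self * self._lift(other) ** -1.0

    def __rtruediv__(self, other):
        return self._lift(other) * self ** -1.0

    def __pow__(self, exponent: float):
        e = float(exponent)
        def backward(g):
            self._accum(g * e * self.data ** (e - 1.0))
        return self._make(self.data ** e, (self,), backward)

    # -- transcendental -------------------------------------------------------
    def exp(self):
        out_data = np.exp(self.data)
        def backward(g):
            self._accum(g * out_data)
        return self._make(out_data, (self,), backward)

    def log(self):
        def backward(g):
            self._accum(g / self.data)
        return self._make(np.log(self.data), (self,), backward)

    def sigmoid(self):
        s = 1.0 / (1.0 + np.exp(-self.data))
        def backward(g):
            self._accum(g * s * (1.0 - s))
        return self._make(s, (self,), backward)

    def gelu(self):
        """Exact (erf-based) Gaussian error linear unit."""
        x = self.data
        cdf = 0.5 * (1.0 + _erf(x / _SQRT2))
        def backward(g):
            pdf = _INV_SQRT_2PI * np.exp(-0.5 * x * x)
            self._accum(g * (cdf + x * pdf))
        return self._make(x * cdf, (self,), backward)

    # -- shape ops ------------------------------------------------------------
    def reshape(self, *shape):
        if len(shape) == 1 and isinstance(shape[0], (tuple, list)):
            shape = tuple(shape[0])
        old = self.data.shape
        def backward(g):
            self._accum(g.reshape(old))
        return self._make(self.data.reshape(shape), (self,), backward)

    def transpose(self, *axes):
        if len(axes) == 1 and isinstance(axes[0], (tuple, list)):
            axes = tuple(axes[0])
        inv = np.argsort(axes)
        def backward(g):
            self._accum(g.transpose(inv))
        return self._make(self.data.transpose(axes), (self,), backward)

    def __getitem__(self, idx):
        def backward(g):
            full = np.zeros_like(self.data)
            full[idx] = g
            self._accum(full)
        return self._make(self.data[idx], (self,), backward)

    # -- reductions -----------------------------------------------------------
    def sum(self, axis=None, keepdims: bool = False):
        def backward(g):
            if axis is None:
                self._accum(np.broadcast_to(g, self.data.shape))
                return
            gg = g
            if not keepdims:
                gg = np.expand_dims(gg, axis)
            self._accum(np.broadcast_to(gg, self.data.shape))
        return self._make(self.data.sum(axis=axis, keepdims=keepdims), (self,), backward)

    def mean(self, axis=None, keepdims: bool = False):
        if axis is None:
            n = self.data.size
        elif isinstance(axis, tuple):
            n = int(np.prod([self.data.shape[a] for a in axis]))
        else:
            n = self.data.shape[axis]
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / n)

    def max(self, axis: int, keepdims: bool = False):
        """Max reduction; on ties the gradient is split among the maxima."""
        out_data = self.data.max(axis=axis, keepdims=True)
        mask = (self.data == out_data).astype(np.float64)
        mask /= mask.sum(axis=axis, keepdims=True)
        def backward(g):
            gg = g if keepdims else np.expand_dims(g, axis)
            self._accum(mask * gg)
        res = out_data if keepdims else out_data.squeeze(axis=axis)
        return self._make(res, (self,), backward)

    # -- linear algebra -------------------------------------------------------
    def matmul(self, other: "Tensor"):
        other = self._lift(other)
        a, b = self.data, other.data
        def backward(g):
            self._accum(g @ b.T)
            other._accum(a.T @ g)
        return self._make(a @ b, (self, other), backward)

    __matmul__ = matmul

    # -- composites -----------------------------------------------------------
    def softmax(self, axis: int):
        shifted = self - Tensor(self.data.max(axis=axis, keepdims=True))
        e = shifted.exp()
        return e / e.sum(axis=axis, keepdims=True)

    def log_softmax(self, axis: int):
        shifted = self - Tensor(self.data.max(axis=axis, keepdims=True))
        return shifted - shifted.exp().sum(axis=axis, keepdims=True).log()


class Parameter(Tensor):
    """A trainable tensor."""

    def __init__(self, data):
        super().__init__(data, requires_grad=True)


# ---------------------------------------------------------------------------
# free functions
# ---------------------------------------------------------------------------

def concat(tensors: list[Tensor], axis: int = 1) -> Tensor:
    tensors = [Tensor._lift(t) for t in tensors]
    sizes = [t.data.shape[axis] for t in tensors]
    offsets = np.cumsum([0] + sizes)
    out_data = np.concatenate([t.data for t in tensors], axis=axis)
    def backward(g):
        for t, lo, hi in zip(tensors, offsets[:-1], offsets[1:]):
            idx = [slice(None)] * g.ndim
            idx[axis] = slice(lo, hi)
            t._accum(g[tuple(idx)])
    out = Tensor(out_data)
    if any(t.requires_grad for t in tensors):
        out.requires_grad = True
        out._parents = tuple(t for t in tensors if t.requires_grad)
        out._backward = backward
    return out


def _im2col(x: np.ndarray, kh: int, kw: int, dil: int, pad: int):
    """Return (cols, oh, ow): cols has shape (B, C*kh*kw, oh*ow)."""
    b, c, h, w = x.shape
    xp = np.pad(x, ((0, 0), (0, 0), (pad, pad), (pad, pad)))
    eff_h, eff_w = (kh - 1) * dil + 1, (kw - 1) * dil + 1
    oh, ow = xp.shape[2] - eff_h + 1, xp.shape[3] - eff_w + 1
    win = np.lib.stride_tricks.sliding_window_view(xp, (eff_h, eff_w), axis=(2, 3))
    # (B, C, oh, ow, eff_h, eff_w) -> pick dilated taps
    win = win[:, :, :, :, ::dil, ::dil]  # (B, C, oh, ow, kh, kw)
    cols = win.transpose(0, 1, 4, 5, 2, 3).reshape(b, c * kh * kw, oh * ow)
    return np.ascontiguousarray(cols), oh, ow


def _col2im(gcols: np.ndarray, xshape, kh: int, kw: int, dil: int, pad: int,
            oh: int, ow: int) -> np.ndarray:
    b, c, h, w = xshape
    gx = np.zeros((b, c, h + 2 * pad, w + 2 * pad))
    g = gcols.reshape(b, c, kh, kw, oh, ow)
    for i in range(kh):
        for j in range(kw):
            gx[:, :, i * dil:i * dil + oh, j * dil:j * dil + ow] += g[:, :, i, j]
    if pad:
        gx = gx[:, :, pad:-pad, pad:-pad]
    return gx


def conv2d(x: Tensor, weight: Tensor, bias: Tensor | None = None, *,
           dilation: int = 1, padding: int | None = None, groups: int = 1) -> Tensor:
    """2-D convolution (stride 1).  ``padding`` defaults to size-preserving.

    weight: (C_out, C_in // groups, kh, kw).
    """
    cout, cin_g, kh, kw = weight.shape
    b, cin, h, w = x.shape
    if cin % groups or cout % groups:
        raise ValueError("channel counts must be divisible by groups")
    if cin // groups != cin_g:
        raise ValueError(
            f"weight expects {cin_g} input channels per group, got {cin // groups}")
    if padding is None:
        padding = dilation * (kh - 1) // 2
    xs = [x] if groups == 1 else [
        x[:, g * (cin // groups):(g + 1) * (cin // groups)] for g in range(groups)]
    ws = [weight] if groups == 1 else [
        weight[g * (cout // groups):(g + 1) * (cout // groups)] for g in range(groups)]
    outs = []
    for xg, wg in zip(xs, ws):
        outs.append(_conv2d_single(xg, wg, dilation, padding))
    out = outs[0] if groups == 1 else concat(outs, axis=1)
    if bias is not None:
        out = out + bias.reshape(1, cout, 1, 1)
    return out


def _conv2d_single(x: Tensor, weight: Tensor, dilation: int, padding: int) -> Tensor:
    cout, cin, kh, kw = weight.shape
    b = x.shape[0]
    cols, oh, ow = _im2col(x.data, kh, kw, dilation, padding)
    wmat = weight.data.reshape(cout, cin * kh * kw)
    y = np.einsum("ok,bkn->bon", wmat, cols, optimize=True).reshape(b, cout, oh, ow)

    def backward(g):
        gm = g.reshape(b, cout, oh * ow)
        if weight.requires_grad:
            gw = np.einsum("bon,bkn->ok", gm, cols, optimize=True)
            weight._accum(gw.reshape(weight.shape))
        if x.requires_grad:
            gcols = np.einsum("ok,bon->bkn", wmat, gm, optimize=True)
            x._accum(_col2im(gcols, x.shape, kh, kw, dilation, padding, oh, ow))

    out = Tensor(y)
    if x.requires_grad or weight.requires_grad:
        out.requires_grad = True
        out._parents = tuple(t for t in (x, weight) if t.requires_grad)
        out._backward = backward
    return out


def channel_conv1d(x: Tensor, weight: Tensor) -> Tensor:
    """1-D convolution of kernel length 3 across the channel axis.

    ``x``: (B, C) per-channel descriptors; ``weight``: (3,) shared by all
    channels; zero padding of 1 keeps length C.
    """
    if weight.shape != (3,):
        raise ValueError("channel_conv1d expects a length-3 kernel")
    xp = np.pad(x.data, ((0, 0), (1, 1)))
    y = (weight.data[0] * xp[:, :-2] + weight.data[1] * xp[:, 1:-1]
         + weight.data[2] * xp[:, 2:])

    def backward(g):
        if weight.requires_grad:
            gw = np.array([
                (g * xp[:, :-2]).sum(),
                (g * xp[:, 1:-1]).sum(),
                (g * xp[:, 2:]).sum(),
            ])
            weight._accum(gw)
        if x.requires_grad:
            gp = np.pad(g, ((0, 0), (1, 1)))
            gx = (weight.data[0] * gp[:, 2:] + weight.data[1] * gp[:, 1:-1]
                  + weight.data[2] * gp[:, :-2])
            x._accum(gx)

    out = Tensor(y)
    if x.requires_grad or weight.requires_grad:
        out.requires_grad = True
        out._parents = tuple(t for t in (x, weight) if t.requires_grad)
        out._backward = backward
    return out


def maxpool2x2(x: Tensor) -> Tensor:
    b, c, h, w = x.shape
    if h % 2 or w % 2:
        raise ValueError("maxpool2x2 requires even spatial size")
    xr = x.data.reshape(b, c, h // 2, 2, w // 2, 2)
    y = xr.max(axis=(3, 5))
    mask = (xr == y[:, :, :, None, :, None]).astype(np.float64)
    mask /= mask.sum(axis=(3, 5), keepdims=True)  # split gradient on ties

    def backward(g):
        gx = mask * g[:, :, :, None, :, None]
        x._accum(gx.reshape(b, c, h, w))

    out = Tensor(y)
    if x.requires_grad:
        out.requires_grad = True
        out._parents = (x,)
        out._backward = backward
    return out


_BILINEAR_CACHE: dict[int, tuple] = {}


def _bilinear_weights(n_out: int):
    """Half-pixel (align_corners=False) source indices/weights for 2x upsample."""
    if n_out in _BILINEAR_CACHE:
        return _BILINEAR_CACHE[n_out]
    n_in = n_out // 2
    src = (np.arange(n_out) + 0.5) / 2.0 - 0.5
    i0 = np.clip(np.floor(src).astype(int), 0, n_in - 1)
    i1 = np.clip(i0 + 1, 0, n_in - 1)
    frac = np.clip(src - np.floor(src), 0.0, 1.0)
    frac = np.where(src < 0, 0.0, frac)
    w1 = frac
    w0 = 1.0 - frac
    _BILINEAR_CACHE[n_out] = (i0, i1, w0, w1)
    return _BILINEAR_CACHE[n_out]


def upsample_bilinear2x(x: Tensor) -> Tensor:
    """Bilinear 2x spatial upsampling with half-pixel alignment."""
    b, c, h, w = x.shape
    r0, r1, rw0, rw1 = _bilinear_weights(2 * h)
    c0, c1, cw0, cw1 = _bilinear_weights(2 * w)
    xd = x.data
    rows = xd[:, :, r0, :] * rw0[None, None, :, None] \
        + xd[:, :, r1, :] * rw1[None, None, :, None]
    y = rows[:, :, :, c0] * cw0 + rows[:, :, :, c1] * cw1

    def backward(g):
        grows = np.zeros((b, c, 2 * h, w))
        np.add.at(grows, (slice(None), slice(None), slice(None), c0), g * cw0)
        np.add.at(grows, (slice(None), slice(None), slice(None), c1), g * cw1)
        gx = np.zeros((b, c, h, w))
        np.add.at(gx, (slice(None), slice(None), r0, slice(None)),
                  grows * rw0[None, None, :, None])
        np.add.at(gx, (slice(None), slice(None), r1, slice(None)),
                  grows * rw1[None, None, :, None])
        x._accum(gx)

    out = Tensor(y)
    if x.requires_grad:
        out.requires_grad = True
        out._parents = (x,)
        out._backward = backward
    return out


# ---------------------------------------------------------------------------
# modules
# ---------------------------------------------------------------------------

class Module:
    """Base class providing parameter/buffer traversal and train/eval modes."""

    def __init__(self):
        self.training = True

    def forward(self, *args, **kwargs):  # pragma: no cover - abstract
        raise NotImplementedError

    def __call__(self, *args, **kwargs):
        return self.forward(*args, **kwargs)

    # traversal ---------------------------------------------------------------
    def _children(self):
        for name, value in vars(self).items():
            if isinstance(value, Module):
                yield name, value
            elif isinstance(value, (list, tuple)):
                for i, v in enumerate(value):
                    if isinstance(v, Module):
                        yield f"{name}.{i}", v

    def named_parameters(self, prefix: str = ""):
        for name, value in vars(self).items():
            if isinstance(value, Parameter):
                yield prefix + name, value
        for cname, child in self._children():
            yield from child.named_parameters(prefix + cname + ".")

    def parameters(self):
        return [p for _, p in self.named_parameters()]

    def named_buffers(self, prefix: str = ""):
        buffers = getattr(self, "_buffers", {})
        for name in buffers:
            yield prefix + name, buffers[name]
        for cname, child in self._children():
            yield from child.named_buffers(prefix + cname + ".")

    def register_buffer(self, name: str, value: np.ndarray):
        if not hasattr(self, "_buffers"):
            self._buffers: dict[str, np.ndarray] = {}
        self._buffers[name] = np.asarray(value, dtype=np.float64)

    def get_buffer(self, name: str) -> np.ndarray:
        return self._buffers[name]

    def set_buffer(self, name: str, value: np.ndarray) -> None:
        self._buffers[name] = np.asarray(value, dtype=np.float64)

    # modes -------------------------------------------------------------------
    def train(self, mode: bool = True):
        self.training = mode
        for _, child in self._children():
            child.train(mode)
        return self

    def eval(self):
        return self.train(False)

    # state -------------------------------------------------------------------
    def state_dict(self) -> dict[str, np.ndarray]:
        state = {f"param:{k}": v.data.copy() for k, v in self.named_parameters()}
        state.update({f"buffer:{k}": v.copy() for k, v in self.named_buffers()})
        return state

    def load_state_dict(self, state: dict[str, np.ndarray]) -> None:
        params = dict(self.named_parameters())
        own_buffers = {k for k, _ in self.named_buffers()}
        for key, value in state.items():
            kind, _, name = key.partition(":")
            if kind == "param":
                if name not in params:
                    raise KeyError(f"unexpected parameter {name!r}")
                if params[name].data.shape != value.shape:
                    raise ValueError(f"shape mismatch for parameter {name!r}")
                params[name].data = np.asarray(value, dtype=np.float64).copy()
            elif kind == "buffer":
                if name not in own_buffers:
                    raise KeyError(f"unexpected buffer {name!r}")
                self._set_buffer_by_path(name, value)
            else:
                raise KeyError(f"malformed state key {key!r}")
        missing = set(params) - {k.partition(":")[2] for k in state
                                 if k.startswith("param:")}
        if missing:
            raise KeyError(f"missing parameters in state: {sorted(missing)}")

    def _set_buffer_by_path(self, path: str, value: np.ndarray) -> None:
        obj: Module = self
        parts = path.split(".")
        i = 0
        while i < len(parts) - 1:
            attr = getattr(obj, parts[i], None)
            if isinstance(attr, Module):
                obj = attr
                i += 1
            elif isinstance(attr, (list, tuple)):
                obj = attr[int(parts[i + 1])]
                i += 2
            else:
                break
        obj.set_buffer(parts[-1], value)

    def zero_grad(self) -> None:
        for p in self.parameters():
            p.zero_grad()
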