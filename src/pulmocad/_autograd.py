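"""Compact reverse-mode autodiff on numpy arrays.

Implements exactly the primitives the U-Net family here needs: stride-1
"same" 3D convolution (with dilation), max pooling, nearest-neighbour
upsampling, channel concatenation, ReLU/sigmoid, dropout and a masked
binary cross-entropy.  Tensors are float32; gradients are accumulated by a
topological backward pass.

Convolutions are evaluated as im2col + matmul; the input gradient of a
stride-1 same-padded convolution is itself a same-padded convolution with
the spatially flipped, channel-transposed kernel, so backward reuses the
forward path and no scatter-add is needed.
"""

from __future__ import annotations

from typing import Optional, Sequence

import numpy as np

__all__ = [
    "Tensor",
    "conv3d",
    "maxpool3d",
    "upsample_nearest",
    "concat",
    "relu",
    "sigmoid",
    "dropout",
    "masked_bce",
]


class Tensor:
    """A node in the computation graph wrapping a float32 numpy array."""

    __slots__ = ("data", "grad", "requires_grad", "_parents")

    def __init__(self, data, requires_grad: bool = False):
        data = np.asarray(data, dtype=np.float32)
        self.data = np.ascontiguousarray(data) if data.ndim else data
        self.requires_grad = requires_grad
        self.grad: Optional[np.ndarray] = None
        # list of (parent Tensor, function upstream_grad -> parent grad)
        self._parents: list = []

    @property
    def shape(self):
        return self.data.shape

    def _needs_graph(self) -> bool:
        return self.requires_grad or bool(self._parents)

    def backward(self) -> None:
        """Backpropagate from this (scalar) tensor through the graph."""
        if self.data.size != 1:
            raise ValueError("backward() requires a scalar loss tensor")
        topo: list = []
        seen = set()

        def visit(t: "Tensor"):
            if id(t) in seen:
                return
            seen.add(id(t))
            for p, _ in t._parents:
                visit(p)
            topo.append(t)

        visit(self)
        grads = {id(self): np.ones_like(self.data)}
        for t in reversed(topo):
            g = grads.pop(id(t), None)
            if g is None:
                continue
            if t.requires_grad:
                t.grad = g if t.grad is None else t.grad + g
            for p, fn in t._parents:
                if not p._needs_graph():
                    continue
                pg = fn(g)
                if id(p) in grads:
                    grads[id(p)] = grads[id(p)] + pg
                else:
                    grads[id(p)] = pg


def _result(data, parents) -> Tensor:
    out = Tensor(data)
    out._parents = [(p, fn) for p, fn in parents if p._needs_graph()]
    return out


# ---------------------------------------------------------------------------
# convolution
# ---------------------------------------------------------------------------

def _pad_channels_last(x: np.ndarray, w_shape, dilation) -> np.ndarray:
    """NCDHW -> padded NDHWC copy (same padding for the given kernel)."""
    _, _, kd, kh, kw = w_shape
    dd, dh, dw = dilation
    pd, ph, pw = dd * (kd - 1) // 2, dh * (kh - 1) // 2, dw * (kw - 1) // 2
    xl = np.ascontiguousarray(x.transpose(0, 2, 3, 4, 1))
    if pd or ph or pw:
        xl = np.pad(xl, ((0, 0), (pd, pd), (ph, ph), (pw, pw), (0, 0)))
    return xl


def _conv_raw(x: np.ndarray, w: np.ndarray, dilation) -> tuple:
    """Stride-1 same-padded correlation, evaluated channels-last as a
    shift-and-matmul sum over kernel offsets.

    Returns (out NCDHW, padded NDHWC input) — the padded copy is retained
    for the weight gradient.
    """
    n, c, d, h, wd = x.shape
    o, _, kd, kh, kw = w.shape
    dd, dh, dw = dilation
    xl = _pad_channels_last(x, w.shape, dilation)
    out = np.zeros((n * d * h * wd, o), dtype=np.float32)
    for i in range(kd):
        for j in range(kh):
            for k in range(kw):
                v = xl[:, i * dd : i * dd + d, j * dh : j * dh + h, k * dw : k * dw + wd, :]
                vc = v.reshape(-1, c) if v.flags.c_contiguous else np.ascontiguousarray(v).reshape(-1, c)
                out += vc @ w[:, :, i, j, k].T
    out = out.reshape(n, d, h, wd, o)
    return np.ascontiguousarray(out.transpose(0, 4, 1, 2, 3)), xl


def conv3d(x: Tensor, w: Tensor, b: Optional[Tensor], dilation=(1, 1, 1)) -> Tensor:
    """Same-padded stride-1 3D convolution; kernels must have odd extents."""
    out, xl = _conv_raw(x.data, w.data, dilation)
    if b is not None:
        out = out + b.data.reshape(1, -1, 1, 1, 1)
    n, _, d, h, wd = x.data.shape
    o, _, kd, kh, kw = w.data.shape
    dd, dh, dw = dilation

    def grad_x(g):
        # flip spatially, swap in/out channels
        w_t = np.ascontiguousarray(
            w.data[:, :, ::-1, ::-1, ::-1].transpose(1, 0, 2, 3, 4)
        )
        gx, _ = _conv_raw(np.ascontiguousarray(g), w_t, dilation)
        return gx

    def grad_w(g):
        gl = np.ascontiguousarray(g.transpose(0, 2, 3, 4, 1)).reshape(-1, o)
        dw_out = np.empty_like(w.data)
        for i in range(kd):
            for j in range(kh):
                for k in range(kw):
                    v = xl[:, i * dd : i * dd + d, j * dh : j * dh + h,
                           k * dw : k * dw + wd, :]
                    dw_out[:, :, i, j, k] = gl.T @ v.reshape(-1, v.shape[-1])
        return dw_out

    parents = [(x, grad_x), (w, grad_w)]
    if b is not None:
        parents.append((b, lambda g: g.sum(axis=(0, 2, 3, 4))))
    return _result(out, parents)


# ---------------------------------------------------------------------------
# pooling / upsampling
# ---------------------------------------------------------------------------

def maxpool3d(x: Tensor, pool=(2, 2, 2)) -> Tensor:
    n, c, d, h, w = x.data.shape
    pd, ph, pw = pool
    if d % pd or h % ph or w % pw:
        raise ValueError(f"dims {(d, h, w)} not divisible by pool {pool}")
    blocks = x.data.reshape(n, c, d // pd, pd, h // ph, ph, w // pw, pw)
    blocks = blocks.transpose(0, 1, 2, 4, 6, 3, 5, 7).reshape(
        n, c, d // pd, h // ph, w // pw, pd * ph * pw
    )
    idx = blocks.argmax(axis=-1)
    out = np.take_along_axis(blocks, idx[..., None], axis=-1)[..., 0]

    def grad_x(g):
        gb = np.zeros((n, c, d // pd, h // ph, w // pw, pd * ph * pw), dtype=np.float32)
        np.put_along_axis(gb, idx[..., None], g[..., None], axis=-1)
        gb = gb.reshape(n, c, d // pd, h // ph, w // pw, pd, ph, pw)
        gb = gb.transpose(0, 1, 2, 5, 3, 6, 4, 7).reshape(n, c, d, h, w)
        return gb

    return _result(out, [(x, grad_x)])


def upsample_nearest(x: Tensor, factor=(2, 2, 2)) -> Tensor:
    fd, fh, fw = factor
    out = x.data
    for ax, f in zip((2, 3, 4), (fd, fh, fw)):
        if f > 1:
            out = np.repeat(out, f, axis=ax)

    def grad_x(g):
        n, c, d, h, w = x.data.shape
        gb = g.reshape(n, c, d, fd, h, fh, w, fw)
        return gb.sum(axis=(3, 5, 7))

    return _result(out, [(x, grad_x)])


# ---------------------------------------------------------------------------
# pointwise ops
# ---------------------------------------------------------------------------

def concat(tensors: Sequence[Tensor], axis: int = 1) -> Tensor:
    data = np.concatenate([t.data for t in tensors], axis=axis)
    parents = []
    start = 0
    for t in tensors:
        size = t.data.shape[axis]
        sl = [slice(None)] * data.ndim
        sl[axis] = slice(start, start + size)
        parents.append((t, (lambda s: (lambda g: g[tuple(s)]))(tuple(sl))))
        start += size
    return _result(data, parents)


def relu(x: Tensor) -> Tensor:
    out = np.maximum(x.data, 0.0)
    mask = (x.data > 0).astype(np.float32)
    return _result(out, [(x, lambda g: g * mask)])


def sigmoid(x: Tensor) -> Tensor:
    z = np.clip(x.data, -30.0, 30.0)
    s = 1.0 / (1.0 + np.exp(-z))
    return _result(s, [(x, lambda g: g * s * (1.0 - s))])


def dropout(x: Tensor, rate: float, rng: np.random.Generator, training: bool) -> Tensor:
    if not training or rate <= 0.0:
        return x
    if rate >= 1.0:
        raise ValueError("dropout rate must be < 1")
    mask = (rng.random(x.data.shape) >= rate).astype(np.float32) / (1.0 - rate)
    return _result(x.data * mask, [(x, lambda g: g * mask)])


# ---------------------------------------------------------------------------
# loss
# ---------------------------------------------------------------------------

def masked_bce(
    pred: Tensor, target: np.ndarray, ignore_mask: Optional[np.ndarray] = None
) -> Tensor:
    """Mean binary cross-entropy over voxels not covered by ignore_mask.

    pred holds probabilities in (0, 1); values are clamped away from 0/1
    for numerical safety.
    """
    t = np.asarray(target, dtype=np.float32)
    if t.shape != pred.data.shape:
        raise ValueError(f"target shape {t.shape} != pred shape {pred.data.shape}")
    if ignore_mask is None:
        kept = np.ones_like(t, dtype=np.float32)
    else:
        kept = (~np.asarray(ignore_mask, dtype=bool)).astype(np.float32)
        if kept.shape != t.shape:
            raise ValueError("ignore mask shape mismatch")
    n = float(kept.sum())
    if n == 0:
        raise ValueError("all voxels ignored: loss undefined")
    eps = 1e-7
    p = np.clip(pred.data, eps, 1.0 - eps)
    loss = -(t * np.log(p) + (1.0 - t) * np.log(1.0 - p)) * kept
    value = np.asarray(loss.sum() / n, dtype=np.float32)

    def grad_pred(g):
        return g * kept * (p - t) / (p * (1.0 - p)) / n

    return _result(value, [(pred, grad_pred)])
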