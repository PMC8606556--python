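"""Minimal reverse-mode autodiff on numpy arrays.

Just enough machinery for a small encoder-decoder pixel classifier and a
two-layer graph network: 2-D correlation, pooling/upsampling, concatenation,
rectifier, dropout, dense/sparse matrix products and a fused
softmax-cross-entropy.  Single-example (unbatched) tensors; images are
(H, W, C), node matrices are (N, C).
"""

from __future__ import annotations

import numpy as np

# float32 keeps full-image training fast on one CPU; exactness-sensitive
# oracles elsewhere in the package use plain float64 numpy, not this engine.
DTYPE = np.float32


class Tensor:
    """A numpy array plus gradient bookkeeping."""

    __slots__ = ("data", "grad", "requires_grad", "_backward", "_parents")

    def __init__(self, data: np.ndarray, requires_grad: bool = False, dtype=None):
        self.data = np.asarray(data, dtype=DTYPE if dtype is None else dtype)
        self.grad: np.ndarray | None = None
        self.requires_grad = requires_grad
        self._backward = None
        self._parents: tuple[Tensor, ...] = ()

    @property
    def shape(self):
        return self.data.shape

    def _accumulate(self, g: np.ndarray) -> None:
        if self.grad is None:
            self.grad = np.zeros_like(self.data)
        self.grad += g

    def _accumulate_at(self, idx, g: np.ndarray) -> None:
        if self.grad is None:
            self.grad = np.zeros_like(self.data)
        self.grad[idx] += g

    def backward(self) -> None:
        """Backpropagate from this (scalar) tensor through the graph."""
        order: list[Tensor] = []
        seen: set[int] = set()

        def visit(t: Tensor) -> None:
            if id(t) in seen:
                return
            seen.add(id(t))
            for p in t._parents:
                visit(p)
            order.append(t)

        visit(self)
        self.grad = np.ones_like(self.data)
        for t in reversed(order):
            if t._backward is not None and t.grad is not None:
                t._backward(t.grad)

    def zero_grad(self) -> None:
        self.grad = None


def _node(data, parents, backward) -> Tensor:
    data = np.asarray(data)
    out = Tensor(
        data, requires_grad=any(p.requires_grad for p in parents), dtype=data.dtype
    )
    if out.requires_grad:
        out._parents = tuple(parents)
        out._backward = backward
    return out


def conv2d(x: Tensor, w: Tensor, b: Tensor, pad: int) -> Tensor:
    """Correlation with bias; pad chosen by the caller (k//2 keeps size).

    Computed as a sum of channel matmuls over kernel offsets, which is much
    faster than im2col for the small kernels used here.
    """
    kh, kw, cin, cout = w.shape
    xd = x.data
    if pad:
        xd = np.pad(xd, ((pad, pad), (pad, pad), (0, 0)))
    ho, wo = xd.shape[0] - kh + 1, xd.shape[1] - kw + 1
    if ho < 1 or wo < 1:
        raise ValueError("input smaller than kernel")
    shifts = []
    y = np.broadcast_to(b.data, (ho * wo, cout)).copy()
    for di in range(kh):
        for dj in range(kw):
            patch = np.ascontiguousarray(xd[di : di + ho, dj : dj + wo]).reshape(
                ho * wo, cin
            )
            shifts.append(patch)
            y += patch @ w.data[di, dj]
    y = y.reshape(ho, wo, cout)

    def backward(gy: np.ndarray) -> None:
        g2 = gy.reshape(ho * wo, cout)
        if b.requires_grad:
            b._accumulate(g2.sum(axis=0))
        need_gx = x.requires_grad
        if need_gx:
            gxp = np.zeros_like(xd)
        for idx, (di, dj) in enumerate(
            (i, j) for i in range(kh) for j in range(kw)
        ):
            if w.requires_grad:
                w._accumulate_at((di, dj), shifts[idx].T @ g2)
            if need_gx:
                gxp[di : di + ho, dj : dj + wo] += (g2 @ w.data[di, dj].T).reshape(
                    ho, wo, cin
                )
        if need_gx:
            h, wd = x.data.shape[:2]
            x._accumulate(gxp[pad : pad + h, pad : pad + wd])

    return _node(y, (x, w, b), backward)


def relu(x: Tensor) -> Tensor:
    mask = x.data > 0

    def backward(gy):
        if x.requires_grad:
            x._accumulate(gy * mask)

    return _node(x.data * mask, (x,), backward)


def maxpool2(x: Tensor) -> Tensor:
    h, w, c = x.data.shape
    if h % 2 or w % 2:
        raise ValueError(f"maxpool2 needs even spatial dims, got {h}x{w}")
    blocks = x.data.reshape(h // 2, 2, w // 2, 2, c).transpose(0, 2, 4, 1, 3)
    flat = blocks.reshape(h // 2, w // 2, c, 4)
    idx = np.argmax(flat, axis=-1)
    y = np.take_along_axis(flat, idx[..., None], axis=-1)[..., 0]

    def backward(gy):
        if x.requires_grad:
            gflat = np.zeros_like(flat)
            np.put_along_axis(gflat, idx[..., None], gy[..., None], axis=-1)
            gx = gflat.reshape(h // 2, w // 2, c, 2, 2).transpose(0, 3, 1, 4, 2)
            x._accumulate(gx.reshape(h, w, c))

    return _node(y, (x,), backward)


def upsample2(x: Tensor) -> Tensor:
    """Nearest-neighbor 2x spatial upsampling."""
    y = np.repeat(np.repeat(x.data, 2, axis=0), 2, axis=1)

    def backward(gy):
        if x.requires_grad:
            h, w, c = x.data.shape
            gx = gy.reshape(h, 2, w, 2, c).sum(axis=(1, 3))
            x._accumulate(gx)

    return _node(y, (x,), backward)


def concat_channels(a: Tensor, b: Tensor) -> Tensor:
    ca = a.data.shape[-1]

    def backward(gy):
        if a.requires_grad:
            a._accumulate(gy[..., :ca])
        if b.requires_grad:
            b._accumulate(gy[..., ca:])

    return _node(np.concatenate([a.data, b.data], axis=-1), (a, b), backward)


def matmul(x: Tensor, w: Tensor) -> Tensor:
    def backward(gy):
        if x.requires_grad:
            x._accumulate(gy @ w.data.T)
        if w.requires_grad:
            w._accumulate(x.data.T @ gy)

    return _node(x.data @ w.data, (x, w), backward)


def spmm(s, x: Tensor) -> Tensor:
    """Sparse constant matrix times tensor; s must be symmetric or its
    transpose handled by the caller (backward uses s.T)."""

    def backward(gy):
        if x.requires_grad:
            x._accumulate(s.T @ gy)

    return _node(s @ x.data, (x,), backward)


def dropout(x: Tensor, rate: float, rng: np.random.Generator) -> Tensor:
    """Inverted dropout (training mode)."""
    if not 0.0 <= rate < 1.0:
        raise ValueError("dropout rate must be in [0, 1)")
    if rate == 0.0:
        return x
    mask = (rng.random(x.data.shape) >= rate) / (1.0 - rate)

    def backward(gy):
        if x.requires_grad:
            x._accumulate(gy * mask)

    return _node(x.data * mask, (x,), backward)


def softmax(z: np.ndarray) -> np.ndarray:
    """Numerically stable softmax over the trailing axis (plain numpy)."""
    m = z - z.max(axis=-1, keepdims=True)
    e = np.exp(m)
    return e / e.sum(axis=-1, keepdims=True)


def softmax_cross_entropy(
    logits: Tensor, labels: np.ndarray, weights: np.ndarray | None = None
) -> tuple[Tensor, np.ndarray]:
    """Mean cross-entropy over all positions; returns (loss, probabilities).

    ``logits`` has class channels on the trailing axis; ``labels`` holds
    integer class ids with matching leading shape.  Optional ``weights``
    (same shape as labels) reweight each position's contribution.
    """
    probs = softmax(logits.data)
    flatp = probs.reshape(-1, probs.shape[-1])
    flatl = labels.reshape(-1)
    if weights is None:
        wts = np.ones(flatl.shape[0])
    else:
        wts = weights.reshape(-1).astype(np.float64)
    denom = wts.sum()
    if denom <= 0:
        raise ValueError("loss weights sum to zero")
    picked = flatp[np.arange(flatl.size), flatl]
    loss = -(wts * np.log(np.clip(picked.astype(np.float64), 1e-30, None))).sum() / denom

    def backward(gy):
        if logits.requires_grad:
            g = flatp.copy()
            g[np.arange(flatl.size), flatl] -= 1.0
            g *= (wts / denom)[:, None]
            logits._accumulate(gy * g.reshape(logits.data.shape))

    out = _node(np.array(loss), (logits,), backward)
    return out, probs


class Adam:
    """Adam optimizer over a list of parameter Tensors."""

    def __init__(
        self,
        params: list[Tensor],
        lr: float,
        beta1: float = 0.9,
        beta2: float = 0.999,
        eps: float = 1e-8,
    ):
        self.params = params
        self.lr = lr
        self.beta1, self.beta2, self.eps = beta1, beta2, eps
        self.m = [np.zeros_like(p.data) for p in params]
        self.v = [np.zeros_like(p.data) for p in params]
        self.t = 0

    def step(self) -> None:
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        for i, p in enumerate(self.params):
            if p.grad is None:
                continue
            self.m[i] = b1 * self.m[i] + (1 - b1) * p.grad
            self.v[i] = b2 * self.v[i] + (1 - b2) * p.grad**2
            mhat = self.m[i] / (1 - b1**self.t)
            vhat = self.v[i] / (1 - b2**self.t)
            p.data -= self.lr * mhat / (np.sqrt(vhat) + self.eps)

    def zero_grad(self) -> None:
        for p in self.params:
            p.zero_grad()
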