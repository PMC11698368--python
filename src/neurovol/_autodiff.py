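"""Minimal reverse-mode automatic differentiation over numpy arrays.

Supports exactly the operations the coordinate networks need: broadcasting
arithmetic, 2-D matmul, sine/ReLU/abs nonlinearities, reductions, reshapes,
3-D convolution and trilinear grid sampling. Gradients flow only into
tensors created with ``requires_grad=True``; everything runs in float64.
"""

from __future__ import annotations

import numpy as np

__all__ = ["Tensor", "concat", "conv3d", "trilinear_sample", "Adam"]


def _unbroadcast(grad: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Sum `grad` down to `shape` (inverse of numpy broadcasting)."""
    extra = grad.ndim - len(shape)
    if extra > 0:
        grad = grad.sum(axis=tuple(range(extra)))
    axes = tuple(i for i, s in enumerate(shape) if s == 1 and grad.shape[i] != 1)
    if axes:
        grad = grad.sum(axis=axes, keepdims=True)
    return grad.reshape(shape)


class Tensor:
    __slots__ = ("data", "grad", "requires_grad", "_backward", "_parents")

    def __init__(self, data, requires_grad: bool = False):
        self.data = np.asarray(data, dtype=np.float64)
        self.requires_grad = bool(requires_grad)
        self.grad: np.ndarray | None = None
        self._backward = None
        self._parents: tuple[Tensor, ...] = ()

    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    # -- graph construction -------------------------------------------------

    @staticmethod
    def _result(data, parents, backward):
        out = Tensor(data)
        if any(p.requires_grad for p in parents):
            out.requires_grad = True
            out._parents = tuple(parents)
            out._backward = backward
        return out

    def backward(self):
        if self.data.size != 1:
            raise ValueError("backward() requires a scalar loss")
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
        self.grad = np.ones_like(self.data)
        for node in reversed(topo):
            if node._backward is not None:
                node._backward(node.grad)
                node._backward = None  # free closures

    def _accum(self, g: np.ndarray, owned: bool = False):
        # `owned` marks freshly allocated gradient arrays that may be adopted
        # without a defensive copy (views / shared buffers must copy).
        if self.grad is None:
            self.grad = g if owned else g.copy()
        else:
            self.grad += g

    # -- arithmetic ---------------------------------------------------------

    @staticmethod
    def _coerce(other) -> "Tensor":
        return other if isinstance(other, Tensor) else Tensor(other)

    def __add__(self, other):
        other = self._coerce(other)
        a, b = self, other

        def backward(g):
            if a.requires_grad:
                ga = _unbroadcast(g, a.shape)
                a._accum(ga, owned=ga is not g)
            if b.requires_grad:
                gb = _unbroadcast(g, b.shape)
                b._accum(gb, owned=gb is not g)

        return self._result(a.data + b.data, (a, b), backward)

    __radd__ = __add__

    def __mul__(self, other):
        other = self._coerce(other)
        a, b = self, other

        def backward(g):
            if a.requires_grad:
                a._accum(_unbroadcast(g * b.data, a.shape), owned=True)
            if b.requires_grad:
                b._accum(_unbroadcast(g * a.data, b.shape), owned=True)

        return self._result(a.data * b.data, (a, b), backward)

    __rmul__ = __mul__

    def __neg__(self):
        return self * -1.0

    def __sub__(self, other):
        return self + (-self._coerce(other))

    def __rsub__(self, other):
        return self._coerce(other) + (-self)

    def __truediv__(self, other):
        other = self._coerce(other)
        return self * other ** -1.0

    def __pow__(self, p: float):
        a = self

        def backward(g):
            if a.requires_grad:
                a._accum(g * p * a.data ** (p - 1.0), owned=True)

        return self._result(a.data ** p, (a,), backward)

    def __matmul__(self, other):
        other = self._coerce(other)
        a, b = self, other

        def backward(g):
            if a.requires_grad:
                a._accum(g @ b.data.T, owned=True)
            if b.requires_grad:
                b._accum(a.data.T @ g, owned=True)

        return self._result(a.data @ b.data, (a, b), backward)

    # -- nonlinearities -----------------------------------------------------

    def sin(self):
        a = self

        def backward(g):
            if a.requires_grad:
                a._accum(g * np.cos(a.data), owned=True)

        return self._result(np.sin(a.data), (a,), backward)

    def relu(self):
        a = self
        mask = a.data > 0

        def backward(g):
            if a.requires_grad:
                a._accum(g * mask, owned=True)

        return self._result(a.data * mask, (a,), backward)

    def abs(self):
        a = self
        sign = np.sign(a.data)

        def backward(g):
            if a.requires_grad:
                a._accum(g * sign, owned=True)

        return self._result(np.abs(a.data), (a,), backward)

    # -- reductions and reshapes --------------------------------------------

    def sum(self, axis=None, keepdims=False):
        a = self

        def backward(g):
            if not a.requires_grad:
                return
            if axis is None:
                a._accum(np.broadcast_to(g, a.shape).copy())
            else:
                gg = g if keepdims else np.expand_dims(g, axis)
                a._accum(np.broadcast_to(gg, a.shape).copy())

        return self._result(a.data.sum(axis=axis, keepdims=keepdims), (a,), backward)

    def mean(self, axis=None, keepdims=False):
        if axis is None:
            n = self.data.size
        else:
            n = self.data.shape[axis]
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / n)

    def reshape(self, *shape):
        if len(shape) == 1 and isinstance(shape[0], (tuple, list)):
            shape = tuple(shape[0])
        a = self
        old = a.shape

        def backward(g):
            if a.requires_grad:
                a._accum(g.reshape(old))

        return self._result(a.data.reshape(shape), (a,), backward)

    @property
    def T(self):
        a = self

        def backward(g):
            if a.requires_grad:
                a._accum(g.T)

        return self._result(a.data.T, (a,), backward)


def concat(tensors: list[Tensor], axis: int = 1) -> Tensor:
    tensors = [Tensor._coerce(t) for t in tensors]
    sizes = [t.shape[axis] for t in tensors]
    offsets = np.cumsum([0] + sizes)

    def backward(g):
        for t, lo, hi in zip(tensors, offsets[:-1], offsets[1:]):
            if t.requires_grad:
                idx = [slice(None)] * g.ndim
                idx[axis] = slice(lo, hi)
                t._accum(g[tuple(idx)])

    data = np.concatenate([t.data for t in tensors], axis=axis)
    return Tensor._result(data, tensors, backward)


def conv3d(x: Tensor, w: Tensor, b: Tensor, padding: str = "zeros") -> Tensor:
    """Same-size 3-D convolution.

    x: (Cin, D, H, W); w: (Cout, Cin, k, k, k) with odd k; b: (Cout,).
    `padding` is "zeros" or "periodic"; output is (Cout, D, H, W).
    """
    cin, D, H, W = x.shape
    cout, cin2, k, _, _ = w.shape
    if cin != cin2 or k % 2 != 1:
        raise ValueError("kernel/channel mismatch or even kernel size")
    p = k // 2
    mode = {"zeros": "constant", "periodic": "wrap"}[padding]
    xp = np.pad(x.data, ((0, 0), (p, p), (p, p), (p, p)), mode=mode)
    # im2col: windows (D, H, W, Cin, k, k, k)
    win = np.lib.stride_tricks.sliding_window_view(xp, (k, k, k), axis=(1, 2, 3))
    win = win.transpose(1, 2, 3, 0, 4, 5, 6)
    cols = win.reshape(D * H * W, cin * k * k * k)
    wm = w.data.reshape(cout, cin * k * k * k)
    out = cols @ wm.T + b.data  # (N, Cout)
    out = out.T.reshape(cout, D, H, W)

    def backward(g):
        gm = g.reshape(cout, -1).T  # (N, Cout)
        if w.requires_grad:
            w._accum((gm.T @ cols).reshape(w.shape))
        if b.requires_grad:
            b._accum(gm.sum(axis=0))
        if x.requires_grad:
            gcols = (gm @ wm).reshape(D, H, W, cin, k, k, k)
            gpad = np.zeros_like(xp)
            for i in range(k):
                for j in range(k):
                    for l in range(k):
                        gpad[:, i:i + D, j:j + H, l:l + W] += np.moveaxis(
                            gcols[:, :, :, :, i, j, l], 3, 0)
            if padding == "zeros":
                gx = gpad[:, p:p + D, p:p + H, p:p + W]
            else:  # fold wrapped borders back onto the core
                gx = np.zeros_like(x.data)
                ii = (np.arange(D + 2 * p) - p) % D
                jj = (np.arange(H + 2 * p) - p) % H
                ll = (np.arange(W + 2 * p) - p) % W
                np.add.at(gx, (slice(None),) + np.ix_(ii, jj, ll), gpad)
            x._accum(gx)

    return Tensor._result(out, (x, w, b), backward)


def trilinear_sample(feat: Tensor, idx: np.ndarray) -> Tensor:
    """Sample a channel-last feature grid at fractional grid indices.

    feat: (dx, dy, dz, C); idx: (N, 3) float positions in index space,
    clamped to the grid. Returns (N, C). Gradient flows into `feat` only
    (sampling positions are fixed query coordinates, never trained).
    """
    dx, dy, dz, C = feat.shape
    pos = np.clip(idx, 0, np.array([dx - 1, dy - 1, dz - 1], dtype=float))
    i0 = np.minimum(np.floor(pos).astype(int), np.array([dx - 2, dy - 2, dz - 2]).clip(min=0))
    f = pos - i0
    i1 = np.minimum(i0 + 1, np.array([dx - 1, dy - 1, dz - 1]))
    corners = []
    for cx in (0, 1):
        for cy in (0, 1):
            for cz in (0, 1):
                ix = i1[:, 0] if cx else i0[:, 0]
                iy = i1[:, 1] if cy else i0[:, 1]
                iz = i1[:, 2] if cz else i0[:, 2]
                wx = f[:, 0] if cx else 1 - f[:, 0]
                wy = f[:, 1] if cy else 1 - f[:, 1]
                wz = f[:, 2] if cz else 1 - f[:, 2]
                corners.append((ix, iy, iz, wx * wy * wz))
    out = np.zeros((idx.shape[0], C))
    for ix, iy, iz, w in corners:
        out += feat.data[ix, iy, iz, :] * w[:, None]

    def backward(g):
        if feat.requires_grad:
            gf = np.zeros_like(feat.data)
            for ix, iy, iz, w in corners:
                np.add.at(gf, (ix, iy, iz), g * w[:, None])
            feat._accum(gf)

    return Tensor._result(out, (feat,), backward)


class Adam:
    """Adam optimizer over a list of parameter Tensors."""

    def __init__(self, params: list[Tensor], lr: float,
                 betas: tuple[float, float] = (0.9, 0.999), eps: float = 1e-8):
        self.params = list(params)
        self.lr = float(lr)
        self.b1, self.b2 = betas
        self.eps = eps
        self.t = 0
        self.m = [np.zeros_like(p.data) for p in self.params]
        self.v = [np.zeros_like(p.data) for p in self.params]

    def zero_grad(self):
        for p in self.params:
            p.grad = None

    def step(self):
        self.t += 1
        for p, m, v in zip(self.params, self.m, self.v):
            if p.grad is None:
                continue
            g = p.grad
            m *= self.b1
            m += (1 - self.b1) * g
            v *= self.b2
            v += (1 - self.b2) * g * g
            mhat = m / (1 - self.b1 ** self.t)
            vhat = v / (1 - self.b2 ** self.t)
            p.data -= self.lr * mhat / (np.sqrt(vhat) + self.eps)
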