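"""Minimal reverse-mode automatic differentiation on numpy arrays.

The joint gaze-strategy + perception training needs gradients that flow
from a classification loss, through convolutional feature extraction and
Gaussian attention masks, back into the parameters of the fixation
model (ROI means and covariance factors, via the reparameterization
trick).  This module provides exactly the operations that computation
graph needs: broadcasting arithmetic, matmul, exp/log, ReLU, clipping,
element-wise maximum (for the visual short-term memory), valid-mode 2-D
convolution, and a fused softmax cross-entropy.  Arrays use a
channels-last (B, H, W, C) layout for images.

It is intentionally small: dynamic graph, first-order gradients only.
The working precision is the module-level ``DTYPE`` (float32 by
default: the training loop is memory-bandwidth bound and single
precision is ample for stochastic gradient training; set it to
``np.float64`` before building a graph when verifying gradients
against finite differences).
"""

from __future__ import annotations

import numpy as np

DTYPE = np.float32

__all__ = ["Tensor", "concat", "maximum", "conv2d_valid", "softmax_cross_entropy", "build_tril", "Adam"]


def _unbroadcast(grad: np.ndarray, shape: tuple) -> np.ndarray:
    """Sum-reduce ``grad`` so that it has ``shape`` (inverse of broadcasting)."""
    if grad.shape == shape:
        return grad
    # sum over leading axes added by broadcasting
    while grad.ndim > len(shape):
        grad = grad.sum(axis=0)
    for axis, size in enumerate(shape):
        if size == 1 and grad.shape[axis] != 1:
            grad = grad.sum(axis=axis, keepdims=True)
    return grad


class Tensor:
    """A numpy array with an optional gradient and a backward closure."""

    __slots__ = ("data", "grad", "requires_grad", "_parents", "_bwd")

    def __init__(self, data, requires_grad: bool = False, parents=(), bwd=None):
        self.data = np.asarray(data, dtype=DTYPE)
        self.grad = None
        self.requires_grad = bool(requires_grad) or any(p.requires_grad for p in parents)
        self._parents = parents
        self._bwd = bwd

    # -- basic protocol ------------------------------------------------
    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    def __repr__(self):
        return f"Tensor(shape={self.data.shape}, requires_grad={self.requires_grad})"

    def zero_grad(self):
        self.grad = None

    # -- graph construction helpers ------------------------------------
    @staticmethod
    def _lift(x) -> "Tensor":
        return x if isinstance(x, Tensor) else Tensor(x)

    def _accum(self, g: np.ndarray):
        # closures always hand over freshly computed arrays, so the first
        # accumulation can alias; later ones allocate via +
        if self.grad is None:
            self.grad = g if g.shape == self.data.shape else np.broadcast_to(g, self.data.shape).copy()
        else:
            self.grad = self.grad + g

    # -- arithmetic ----------------------------------------------------
    def __add__(self, other):
        other = self._lift(other)
        out = Tensor(self.data + other.data, parents=(self, other))

        def bwd(g):
            if self.requires_grad:
                self._accum(_unbroadcast(g, self.data.shape))
            if other.requires_grad:
                other._accum(_unbroadcast(g, other.data.shape))

        out._bwd = bwd
        return out

    __radd__ = __add__

    def __neg__(self):
        out = Tensor(-self.data, parents=(self,))

        def bwd(g):
            if self.requires_grad:
                self._accum(-g)

        out._bwd = bwd
        return out

    def __sub__(self, other):
        return self + (-self._lift(other))

    def __rsub__(self, other):
        return self._lift(other) + (-self)

    def __mul__(self, other):
        other = self._lift(other)
        out = Tensor(self.data * other.data, parents=(self, other))

        def bwd(g):
            if self.requires_grad:
                self._accum(_unbroadcast(g * other.data, self.data.shape))
            if other.requires_grad:
                other._accum(_unbroadcast(g * self.data, other.data.shape))

        out._bwd = bwd
        return out

    __rmul__ = __mul__

    def __truediv__(self, other):
        other = self._lift(other)
        out = Tensor(self.data / other.data, parents=(self, other))

        def bwd(g):
            if self.requires_grad:
                self._accum(_unbroadcast(g / other.data, self.data.shape))
            if other.requires_grad:
                other._accum(_unbroadcast(-g * self.data / other.data**2, other.data.shape))

        out._bwd = bwd
        return out

    def __rtruediv__(self, other):
        return self._lift(other) / self

    def __matmul__(self, other):
        other = self._lift(other)
        out = Tensor(self.data @ other.data, parents=(self, other))
        a, b = self.data, other.data

        def bwd(g):
            if self.requires_grad:
                self._accum(_unbroadcast(g @ np.swapaxes(b, -1, -2), a.shape))
            if other.requires_grad:
                other._accum(_unbroadcast(np.swapaxes(a, -1, -2) @ g, b.shape))

        out._bwd = bwd
        return out

    def __pow__(self, p: float):
        out = Tensor(self.data**p, parents=(self,))

        def bwd(g):
            if self.requires_grad:
                self._accum(g * p * self.data ** (p - 1))

        out._bwd = bwd
        return out

    # -- elementwise non-linearities ------------------------------------
    def exp(self):
        out = Tensor(np.exp(self.data), parents=(self,))

        def bwd(g):
            if self.requires_grad:
                self._accum(g * out.data)

        out._bwd = bwd
        return out

    def log(self):
        out = Tensor(np.log(self.data), parents=(self,))

        def bwd(g):
            if self.requires_grad:
                self._accum(g / self.data)

        out._bwd = bwd
        return out

    def relu(self):
        mask = self.data > 0
        out = Tensor(np.where(mask, self.data, 0.0), parents=(self,))

        def bwd(g):
            if self.requires_grad:
                self._accum(g * mask)

        out._bwd = bwd
        return out

    def clip(self, lo: float, hi: float):
        """Clip values; gradient is passed through where no clipping occurred."""
        inside = (self.data >= lo) & (self.data <= hi)
        out = Tensor(np.clip(self.data, lo, hi), parents=(self,))

        def bwd(g):
            if self.requires_grad:
                self._accum(g * inside)

        out._bwd = bwd
        return out

    # -- shape ops -------------------------------------------------------
    def reshape(self, *shape):
        out = Tensor(self.data.reshape(*shape), parents=(self,))

        def bwd(g):
            if self.requires_grad:
                self._accum(g.reshape(self.data.shape))

        out._bwd = bwd
        return out

    def transpose(self):
        out = Tensor(self.data.T, parents=(self,))

        def bwd(g):
            if self.requires_grad:
                self._accum(g.T)

        out._bwd = bwd
        return out

    @property
    def T(self):
        return self.transpose()

    def __getitem__(self, idx):
        out = Tensor(self.data[idx], parents=(self,))
        basic = isinstance(idx, (int, slice)) or (
            isinstance(idx, tuple) and all(isinstance(i, (int, slice)) for i in idx)
        )

        def bwd(g):
            if self.requires_grad:
                full = np.zeros_like(self.data)
                if basic:  # unique positions: plain in-place add
                    full[idx] += g
                else:
                    np.add.at(full, idx, g)
                self._accum(full)

        out._bwd = bwd
        return out

    def sum(self, axis=None, keepdims: bool = False):
        out = Tensor(self.data.sum(axis=axis, keepdims=keepdims), parents=(self,))

        def bwd(g):
            if not self.requires_grad:
                return
            if axis is None:
                self._accum(np.broadcast_to(g, self.data.shape).copy())
                return
            if not keepdims:
                g = np.expand_dims(g, axis)
            self._accum(np.broadcast_to(g, self.data.shape).copy())

        out._bwd = bwd
        return out

    def sumsq(self):
        """Sum of squared entries as a scalar (cheaper than (t**2).sum())."""
        out = Tensor(float(np.dot(self.data.reshape(-1), self.data.reshape(-1))), parents=(self,))

        def bwd(g):
            if self.requires_grad:
                self._accum((2.0 * g) * self.data)

        out._bwd = bwd
        return out

    def mean(self, axis=None, keepdims: bool = False):
        n = self.data.size if axis is None else self.data.shape[axis]
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / n)

    # -- autodiff driver --------------------------------------------------
    def backward(self, grad=None):
        if grad is None:
            grad = np.ones_like(self.data)
        topo, seen = [], set()

        def visit(node):
            if id(node) in seen or not node.requires_grad:
                return
            seen.add(id(node))
            for p in node._parents:
                visit(p)
            topo.append(node)

        visit(self)
        self._accum(np.asarray(grad, dtype=DTYPE))
        for node in reversed(topo):
            if node._bwd is not None and node.grad is not None:
                node._bwd(node.grad)


# ---------------------------------------------------------------------------
# free functions
# ---------------------------------------------------------------------------

def concat(tensors, axis: int = 0) -> Tensor:
    tensors = [Tensor._lift(t) for t in tensors]
    out = Tensor(np.concatenate([t.data for t in tensors], axis=axis), parents=tuple(tensors))
    sizes = [t.data.shape[axis] for t in tensors]
    offsets = np.cumsum([0] + sizes)

    def bwd(g):
        for t, lo, hi in zip(tensors, offsets[:-1], offsets[1:]):
            if t.requires_grad:
                sl = [slice(None)] * g.ndim
                sl[axis] = slice(lo, hi)
                t._accum(g[tuple(sl)])

    out._bwd = bwd
    return out


def maximum(a: Tensor, b: Tensor) -> Tensor:
    """Element-wise max; on ties the gradient goes to the first argument."""
    a, b = Tensor._lift(a), Tensor._lift(b)
    a_wins = a.data >= b.data
    out = Tensor(np.where(a_wins, a.data, b.data), parents=(a, b))

    def bwd(g):
        if a.requires_grad:
            a._accum(_unbroadcast(g * a_wins, a.data.shape))
        if b.requires_grad:
            b._accum(_unbroadcast(g * ~a_wins, b.data.shape))

    out._bwd = bwd
    return out


def conv2d_valid(x: Tensor, w: Tensor, b: Tensor) -> Tensor:
    """Valid-mode 2-D convolution (cross-correlation), channels last.

    x: (B, H, W, Cin), w: (kh, kw, Cin, Cout), b: (Cout,).
    Output: (B, H-kh+1, W-kw+1, Cout).  Implemented as a sum of kh*kw
    shifted matmuls, which is fast for the small 3x3 kernels used here.
    """
    x, w, b = Tensor._lift(x), Tensor._lift(w), Tensor._lift(b)
    kh, kw = w.data.shape[:2]
    cin, cout = w.data.shape[2:]
    B, H, W, _ = x.data.shape
    Ho, Wo = H - kh + 1, W - kw + 1
    if Ho < 1 or Wo < 1:
        raise ValueError(f"input spatial size {(H, W)} too small for {kh}x{kw} valid convolution")
    # im2col: one large GEMM instead of kh*kw small ones
    windows = np.lib.stride_tricks.sliding_window_view(x.data, (kh, kw), axis=(1, 2))
    # windows: (B, Ho, Wo, Cin, kh, kw) -> (B*Ho*Wo, kh*kw*Cin), index order (u, v, cin)
    patches = np.ascontiguousarray(windows.transpose(0, 1, 2, 4, 5, 3)).reshape(-1, kh * kw * cin)
    wmat = w.data.reshape(kh * kw * cin, cout)
    out = Tensor((patches @ wmat + b.data).reshape(B, Ho, Wo, cout), parents=(x, w, b))

    def bwd(g):
        gmat = g.reshape(-1, cout)
        if b.requires_grad:
            b._accum(gmat.sum(axis=0))
        if w.requires_grad:
            w._accum((patches.T @ gmat).reshape(w.data.shape))
        if x.requires_grad:
            dpatch = (gmat @ wmat.T).reshape(B, Ho, Wo, kh, kw, cin)
            dx = np.zeros_like(x.data)
            for u in range(kh):
                for v in range(kw):
                    dx[:, u : u + Ho, v : v + Wo, :] += dpatch[:, :, :, u, v, :]
            x._accum(dx)

    out._bwd = bwd
    return out


def softmax_cross_entropy(logits: Tensor, labels: np.ndarray) -> Tensor:
    """Mean cross-entropy (natural log) between softmax(logits) and integer labels.

    logits: (B, C); labels: (B,) ints.  Returns a scalar Tensor.
    """
    labels = np.asarray(labels, dtype=np.intp)
    z = logits.data - logits.data.max(axis=1, keepdims=True)
    ez = np.exp(z)
    probs = ez / ez.sum(axis=1, keepdims=True)
    B = z.shape[0]
    nll = -(z[np.arange(B), labels] - np.log(ez.sum(axis=1)))
    out = Tensor(nll.mean(), parents=(logits,))

    def bwd(g):
        if logits.requires_grad:
            d = probs.copy()
            d[np.arange(B), labels] -= 1.0
            logits._accum(g * d / B)

    out._bwd = bwd
    return out


def build_tril(params: Tensor, dim: int = 3) -> Tensor:
    """Lower-triangular Cholesky-like factor from unconstrained parameters.

    ``params`` holds the ``dim`` log-diagonal entries followed by the
    ``dim*(dim-1)/2`` strictly-lower entries (row-major).  The factor
    L = tril(params) has exp() applied to its diagonal, which keeps
    L @ L.T positive definite for any parameter value.
    """
    params = Tensor._lift(params)
    p = params.data
    L = np.zeros((dim, dim))
    diag = np.exp(p[:dim])
    L[np.diag_indices(dim)] = diag
    rows, cols = np.tril_indices(dim, -1)
    L[rows, cols] = p[dim:]
    out = Tensor(L, parents=(params,))

    def bwd(g):
        if params.requires_grad:
            dp = np.empty_like(p)
            dp[:dim] = np.diag(g) * diag
            dp[dim:] = g[rows, cols]
            params._accum(dp)

    out._bwd = bwd
    return out


class Adam:
    """Adam optimiser over a list of parameter Tensors."""

    def __init__(self, params, lr=1e-3, betas=(0.9, 0.999), eps=1e-8):
        self.params = list(params)
        self.lr = float(lr)
        self.b1, self.b2 = betas
        self.eps = eps
        self.t = 0
        self._m = [np.zeros_like(p.data) for p in self.params]
        self._v = [np.zeros_like(p.data) for p in self.params]

    def zero_grad(self):
        for p in self.params:
            p.grad = None

    def step(self):
        self.t += 1
        for i, p in enumerate(self.params):
            if p.grad is None:
                continue
            g = p.grad
            self._m[i] = self.b1 * self._m[i] + (1 - self.b1) * g
            self._v[i] = self.b2 * self._v[i] + (1 - self.b2) * g * g
            mhat = self._m[i] / (1 - self.b1**self.t)
            vhat = self._v[i] / (1 - self.b2**self.t)
            p.data -= self.lr * mhat / (np.sqrt(vhat) + self.eps)
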