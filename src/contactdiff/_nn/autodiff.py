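"""Minimal reverse-mode automatic differentiation on NumPy arrays.

Supports exactly the operations the denoiser U-Net needs: broadcasting
arithmetic, (batched) matmul, strided 2-D convolution, nearest-neighbour
upsampling, group-wise reductions, softmax, SiLU, abs, reshape/transpose,
concatenation and slicing.  Gradients accumulate into ``Tensor.grad`` after
``backward()`` on a scalar loss.
"""

from __future__ import annotations

from typing import Callable, Optional, Sequence, Tuple

import numpy as np

__all__ = ["Tensor", "Parameter", "no_grad"]

# module-level switch: inside a no_grad() block, ops record no graph
_GRAD_ENABLED = True


class no_grad:
    """Context manager disabling graph construction (inference mode)."""

    def __enter__(self):
        global _GRAD_ENABLED
        self._prev = _GRAD_ENABLED
        _GRAD_ENABLED = False
        return self

    def __exit__(self, *exc):
        global _GRAD_ENABLED
        _GRAD_ENABLED = self._prev
        return False


def _unbroadcast(grad: np.ndarray, shape: Tuple[int, ...]) -> np.ndarray:
    """Sum ``grad`` down to ``shape`` (inverse of NumPy broadcasting)."""
    if grad.shape == shape:
        return grad
    ndiff = grad.ndim - len(shape)
    if ndiff > 0:
        grad = grad.sum(axis=tuple(range(ndiff)))
    axes = tuple(i for i, s in enumerate(shape) if s == 1 and grad.shape[i] != 1)
    if axes:
        grad = grad.sum(axis=axes, keepdims=True)
    return grad


class Tensor:
    __slots__ = ("data", "grad", "requires_grad", "_parents", "_backward")

    def __init__(self, data, requires_grad: bool = False,
                 parents: Sequence["Tensor"] = (),
                 backward: Optional[Callable[[np.ndarray], None]] = None):
        self.data = np.asarray(data, dtype=np.float32)
        self.grad: Optional[np.ndarray] = None
        if _GRAD_ENABLED:
            self.requires_grad = requires_grad or any(
                p.requires_grad for p in parents
            )
            self._parents = tuple(parents)
            self._backward = backward
        else:
            self.requires_grad = requires_grad
            self._parents = ()
            self._backward = None

    # -- graph ------------------------------------------------------------

    @property
    def shape(self):
        return self.data.shape

    def backward(self) -> None:
        if self.data.size != 1:
            raise ValueError("backward() requires a scalar")
        topo: list[Tensor] = []
        seen = set()
        stack = [(self, False)]
        while stack:
            node, done = stack.pop()
            if done:
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
            if node._backward is not None and node.grad is not None:
                node._backward(node.grad)

    def _accum(self, grad: np.ndarray) -> None:
        grad = _unbroadcast(np.asarray(grad, dtype=np.float32), self.data.shape)
        if self.grad is None:
            self.grad = grad.copy()
        else:
            self.grad += grad

    def _register(self, fn: Callable[[np.ndarray], None]) -> None:
        # store the backward closure only when a graph is being recorded
        if self.requires_grad and self._parents:
            self._backward = fn

    def zero_grad(self) -> None:
        self.grad = None

    def item(self) -> float:
        return float(self.data)

    # -- arithmetic -------------------------------------------------------

    @staticmethod
    def _lift(x) -> "Tensor":
        return x if isinstance(x, Tensor) else Tensor(np.asarray(x))

    def __add__(self, other):
        other = Tensor._lift(other)
        out = Tensor(self.data + other.data, parents=(self, other))

        def bwd(g):
            if self.requires_grad:
                self._accum(g)
            if other.requires_grad:
                other._accum(g)

        out._register(bwd)
        return out

    __radd__ = __add__

    def __neg__(self):
        out = Tensor(-self.data, parents=(self,))
        out._register(lambda g: self._accum(-g))
        return out

    def __sub__(self, other):
        return self + (-Tensor._lift(other))

    def __rsub__(self, other):
        return Tensor._lift(other) + (-self)

    def __mul__(self, other):
        other = Tensor._lift(other)
        out = Tensor(self.data * other.data, parents=(self, other))

        def bwd(g):
            if self.requires_grad:
                self._accum(g * other.data)
            if other.requires_grad:
                other._accum(g * self.data)

        out._register(bwd)
        return out

    __rmul__ = __mul__

    def pow_const(self, p: float):
        out = Tensor(np.power(self.data, p), parents=(self,))

        def bwd(g):
            if self.requires_grad:
                self._accum(g * p * np.power(self.data, p - 1))

        out._register(bwd)
        return out

    def matmul(self, other: "Tensor"):
        other = Tensor._lift(other)
        out = Tensor(self.data @ other.data, parents=(self, other))

        def bwd(g):
            if self.requires_grad:
                self._accum(g @ np.swapaxes(other.data, -1, -2))
            if other.requires_grad:
                other._accum(np.swapaxes(self.data, -1, -2) @ g)

        out._register(bwd)
        return out

    __matmul__ = matmul

    # -- shape ops --------------------------------------------------------

    def reshape(self, *shape):
        orig = self.data.shape
        out = Tensor(self.data.reshape(shape), parents=(self,))
        out._register(lambda g: self._accum(g.reshape(orig)))
        return out

    def transpose(self, *axes):
        inv = np.argsort(axes)
        out = Tensor(self.data.transpose(axes), parents=(self,))
        out._register(lambda g: self._accum(g.transpose(inv)))
        return out

    def narrow(self, axis: int, start: int, length: int):
        idx = [slice(None)] * self.data.ndim
        idx[axis] = slice(start, start + length)
        idx = tuple(idx)
        out = Tensor(self.data[idx], parents=(self,))

        def bwd(g):
            if self.requires_grad:
                full = np.zeros_like(self.data)
                full[idx] = g
                self._accum(full)

        out._register(bwd)
        return out

    # -- reductions -------------------------------------------------------

    def sum(self, axis=None, keepdims: bool = False):
        out = Tensor(self.data.sum(axis=axis, keepdims=keepdims),
                     parents=(self,))

        def bwd(g):
            if not self.requires_grad:
                return
            if axis is not None and not keepdims:
                g = np.expand_dims(g, axis)
            self._accum(np.broadcast_to(g, self.data.shape))

        out._register(bwd)
        return out

    def mean(self, axis=None, keepdims: bool = False):
        if axis is None:
            n = self.data.size
        else:
            axes = axis if isinstance(axis, tuple) else (axis,)
            n = int(np.prod([self.data.shape[a] for a in axes]))
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / n)

    # -- nonlinearities ---------------------------------------------------

    def silu(self):
        sig = 1.0 / (1.0 + np.exp(-self.data))
        out = Tensor(self.data * sig, parents=(self,))

        def bwd(g):
            if self.requires_grad:
                self._accum(g * sig * (1.0 + self.data * (1.0 - sig)))

        out._register(bwd)
        return out

    def abs(self):
        out = Tensor(np.abs(self.data), parents=(self,))
        out._register(lambda g: self._accum(g * np.sign(self.data)))
        return out

    def softmax(self, axis: int):
        z = self.data - self.data.max(axis=axis, keepdims=True)
        e = np.exp(z)
        s = e / e.sum(axis=axis, keepdims=True)
        out = Tensor(s, parents=(self,))

        def bwd(g):
            if self.requires_grad:
                self._accum(s * (g - (g * s).sum(axis=axis, keepdims=True)))

        out._register(bwd)
        return out

    # -- structured ops ---------------------------------------------------

    @staticmethod
    def concat(tensors: Sequence["Tensor"], axis: int = 1):
        tensors = [Tensor._lift(t) for t in tensors]
        out = Tensor(np.concatenate([t.data for t in tensors], axis=axis),
                     parents=tuple(tensors))
        sizes = [t.data.shape[axis] for t in tensors]
        offsets = np.cumsum([0] + sizes)

        def bwd(g):
            for t, a, b in zip(tensors, offsets[:-1], offsets[1:]):
                if t.requires_grad:
                    idx = [slice(None)] * g.ndim
                    idx[axis] = slice(a, b)
                    t._accum(g[tuple(idx)])

        out._register(bwd)
        return out

    def upsample2(self):
        """Nearest-neighbour x2 upsampling on (B, C, H, W)."""
        out_data = self.data.repeat(2, axis=2).repeat(2, axis=3)
        out = Tensor(out_data, parents=(self,))
        b, c, h, w = self.data.shape

        def bwd(g):
            if self.requires_grad:
                self._accum(g.reshape(b, c, h, 2, w, 2).sum(axis=(3, 5)))

        out._register(bwd)
        return out

    def conv2d(self, weight: "Tensor", bias: Optional["Tensor"] = None,
               stride: int = 1, padding: int = 0):
        """2-D convolution; x (B,C,H,W), weight (OC,C,kh,kw)."""
        x = self.data
        w = weight.data
        oc, c, kh, kw = w.shape
        b, cin, h, wd = x.shape
        if cin != c:
            raise ValueError(f"conv channel mismatch: input {cin}, weight {c}")
        s, p = stride, padding
        if p:
            xp = np.zeros((b, cin, h + 2 * p, wd + 2 * p), dtype=x.dtype)
            xp[:, :, p:p + h, p:p + wd] = x
        else:
            xp = x
        oh = (xp.shape[2] - kh) // s + 1
        ow = (xp.shape[3] - kw) // s + 1
        n_out = b * oh * ow
        taps = kh * kw
        # im2col in (C, taps, B*oh*ow) layout, then one BLAS matmul
        col = np.empty((c, taps, b, oh, ow), dtype=x.dtype)
        for ki in range(kh):
            for kj in range(kw):
                col[:, ki * kw + kj] = xp[
                    :, :, ki:ki + s * oh:s, kj:kj + s * ow:s
                ].transpose(1, 0, 2, 3)
        col2d = col.reshape(c * taps, n_out)
        wmat = w.reshape(oc, c * taps)
        out_data = (wmat @ col2d).reshape(oc, b, oh, ow).transpose(1, 0, 2, 3)
        if bias is not None:
            out_data += bias.data[None, :, None, None]
        parents = (self, weight) + ((bias,) if bias is not None else ())
        out = Tensor(out_data, parents=parents)

        def bwd(g):
            g2d = np.ascontiguousarray(g.transpose(1, 0, 2, 3)).reshape(
                oc, n_out
            )
            if weight.requires_grad:
                weight._accum((g2d @ col2d.T).reshape(oc, c, kh, kw))
            if bias is not None and bias.requires_grad:
                bias._accum(g.sum(axis=(0, 2, 3)))
            if self.requires_grad:
                gcol = (wmat.T @ g2d).reshape(c, taps, b, oh, ow)
                gxp = np.zeros_like(xp)
                for ki in range(kh):
                    for kj in range(kw):
                        gxp[:, :, ki:ki + s * oh:s, kj:kj + s * ow:s] += \
                            gcol[:, ki * kw + kj].transpose(1, 0, 2, 3)
                gx = gxp[:, :, p:p + h, p:p + wd] if p else gxp
                self._accum(gx)

        out._register(bwd)
        return out

    def groupnorm(self, gain: "Tensor", bias: "Tensor", groups: int,
                  eps: float = 1e-5):
        """Fused group normalization on (B, C, H, W) with learned affine."""
        b, c, h, w = self.data.shape
        xg = self.data.reshape(b, groups, -1)
        n = xg.shape[2]
        mu = xg.mean(axis=2, keepdims=True)
        xc = xg - mu
        var = np.einsum("bgn,bgn->bg", xc, xc)[:, :, None] / n
        inv = 1.0 / np.sqrt(var + eps)
        xhat = (xc * inv).reshape(b, c, h, w)
        out_data = xhat * gain.data + bias.data
        out = Tensor(out_data, parents=(self, gain, bias))

        def bwd(g):
            if gain.requires_grad:
                gain._accum((g * xhat).sum(axis=(0, 2, 3))
                            .reshape(gain.data.shape))
            if bias.requires_grad:
                bias._accum(g.sum(axis=(0, 2, 3)).reshape(bias.data.shape))
            if self.requires_grad:
                dxh = (g * gain.data).reshape(b, groups, n)
                xh = xhat.reshape(b, groups, n)
                m1 = dxh.mean(axis=2, keepdims=True)
                m2 = np.einsum("bgn,bgn->bg", dxh, xh)[:, :, None] / n
                dx = inv * (dxh - m1 - xh * m2)
                self._accum(dx.reshape(b, c, h, w))

        out._register(bwd)
        return out


class Parameter(Tensor):
    """A tensor that is updated by the optimizer."""

    def __init__(self, data):
        super().__init__(data, requires_grad=True)
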