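"""A compact reverse-mode automatic differentiation engine on numpy arrays.

Provides exactly the operator set the reconstruction networks need —
broadcasting arithmetic, ReLU/sigmoid, reductions, reshape/concat, strided
2-D convolution and transposed convolution — with gradients checked against
finite differences in the test suite.  Convolutions are evaluated as
im2col-style contractions so the heavy lifting happens inside BLAS.
"""

from __future__ import annotations

import numpy as np

__all__ = ["Tensor", "concat", "conv2d", "conv_transpose2d", "corr1d_valid"]


def _unbroadcast(grad: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Sum a broadcast gradient back down to ``shape``."""
    if grad.shape == shape:
        return grad
    extra = grad.ndim - len(shape)
    if extra > 0:
        grad = grad.sum(axis=tuple(range(extra)))
    axes = tuple(i for i, s in enumerate(shape) if s == 1 and grad.shape[i] != 1)
    if axes:
        grad = grad.sum(axis=axes, keepdims=True)
    return grad


class Tensor:
    """An array node in the computation graph."""

    __slots__ = ("data", "grad", "requires_grad", "_parents", "_backward")

    def __init__(self, data, requires_grad: bool = False):
        self.data = np.asarray(data)
        self.grad: np.ndarray | None = None
        self.requires_grad = bool(requires_grad)
        self._parents: tuple["Tensor", ...] = ()
        self._backward = None

    # -- graph plumbing ---------------------------------------------------
    @staticmethod
    def _result(data, parents, backward) -> "Tensor":
        requires = any(p.requires_grad for p in parents)
        out = Tensor(data, requires)
        if requires:
            out._parents = parents
            out._backward = backward
        return out

    def _accumulate(self, grad: np.ndarray) -> None:
        if self.grad is None:
            self.grad = grad.astype(self.data.dtype, copy=True)
        else:
            self.grad += grad

    def backward(self, grad=None) -> None:
        """Backpropagate from this (typically scalar) node."""
        if grad is None:
            grad = np.ones_like(self.data)
        topo: list[Tensor] = []
        seen: set[int] = set()
        stack = [(self, False)]
        while stack:
            node, processed = stack.pop()
            if processed:
                topo.append(node)
                continue
            if id(node) in seen or not node.requires_grad:
                continue
            seen.add(id(node))
            stack.append((node, True))
            for parent in node._parents:
                stack.append((parent, False))
        self._accumulate(np.asarray(grad))
        for node in reversed(topo):
            if node._backward is not None:
                node._backward(node.grad)

    # -- helpers ----------------------------------------------------------
    @property
    def shape(self):
        return self.data.shape

    def _wrap(self, other) -> "Tensor":
        if isinstance(other, Tensor):
            return other
        # keep the graph in this tensor's dtype (no silent float64 promotion)
        return Tensor(np.asarray(other, dtype=self.data.dtype))

    def item(self) -> float:
        return float(self.data)

    # -- arithmetic -------------------------------------------------------
    def __add__(self, other):
        other = self._wrap(other)

        def backward(grad):
            if self.requires_grad:
                self._accumulate(_unbroadcast(grad, self.data.shape))
            if other.requires_grad:
                other._accumulate(_unbroadcast(grad, other.data.shape))

        return self._result(self.data + other.data, (self, other), backward)

    __radd__ = __add__

    def __neg__(self):
        def backward(grad):
            if self.requires_grad:
                self._accumulate(-grad)

        return self._result(-self.data, (self,), backward)

    def __sub__(self, other):
        return self + (-self._wrap(other))

    def __rsub__(self, other):
        return self._wrap(other) + (-self)

    def __mul__(self, other):
        other = self._wrap(other)

        def backward(grad):
            if self.requires_grad:
                self._accumulate(_unbroadcast(grad * other.data, self.data.shape))
            if other.requires_grad:
                other._accumulate(_unbroadcast(grad * self.data, other.data.shape))

        return self._result(self.data * other.data, (self, other), backward)

    __rmul__ = __mul__

    def __truediv__(self, other):
        other = self._wrap(other)

        def backward(grad):
            if self.requires_grad:
                self._accumulate(_unbroadcast(grad / other.data, self.data.shape))
            if other.requires_grad:
                other._accumulate(
                    _unbroadcast(-grad * self.data / other.data**2, other.data.shape)
                )

        return self._result(self.data / other.data, (self, other), backward)

    def __rtruediv__(self, other):
        return self._wrap(other) / self

    def __pow__(self, exponent: float):
        def backward(grad):
            if self.requires_grad:
                self._accumulate(grad * exponent * self.data ** (exponent - 1))

        return self._result(self.data**exponent, (self,), backward)

    # -- elementwise nonlinearities --------------------------------------
    def relu(self):
        mask = self.data > 0

        def backward(grad):
            if self.requires_grad:
                self._accumulate(grad * mask)

        return self._result(self.data * mask, (self,), backward)

    def sigmoid(self):
        out_data = 1.0 / (1.0 + np.exp(-np.clip(self.data, -60, 60)))

        def backward(grad):
            if self.requires_grad:
                self._accumulate(grad * out_data * (1 - out_data))

        return self._result(out_data, (self,), backward)

    def sqrt(self):
        root = np.sqrt(self.data)

        def backward(grad):
            if self.requires_grad:
                self._accumulate(grad * 0.5 / root)

        return self._result(root, (self,), backward)

    # -- reductions -------------------------------------------------------
    def sum(self, axis=None, keepdims: bool = False):
        def backward(grad):
            if not self.requires_grad:
                return
            g = np.asarray(grad)
            if axis is not None and not keepdims:
                g = np.expand_dims(g, axis)
            self._accumulate(np.broadcast_to(g, self.data.shape).copy())

        return self._result(self.data.sum(axis=axis, keepdims=keepdims), (self,), backward)

    def mean(self, axis=None, keepdims: bool = False):
        if axis is None:
            count = self.data.size
        else:
            axes = axis if isinstance(axis, tuple) else (axis,)
            count = int(np.prod([self.data.shape[a] for a in axes]))
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / count)

    def max(self, axis: int, keepdims: bool = False):
        out_data = self.data.max(axis=axis, keepdims=True)
        mask = self.data == out_data
        counts = mask.sum(axis=axis, keepdims=True)

        def backward(grad):
            if not self.requires_grad:
                return
            g = np.asarray(grad)
            if not keepdims:
                g = np.expand_dims(g, axis)
            self._accumulate(mask * g / counts)

        result_data = out_data if keepdims else out_data.squeeze(axis=axis)
        return self._result(result_data, (self,), backward)

    # -- shape ops --------------------------------------------------------
    def reshape(self, *shape):
        original = self.data.shape

        def backward(grad):
            if self.requires_grad:
                self._accumulate(grad.reshape(original))

        return self._result(self.data.reshape(*shape), (self,), backward)

    def transpose(self, *axes):
        inverse = np.argsort(axes)

        def backward(grad):
            if self.requires_grad:
                self._accumulate(grad.transpose(*inverse))

        return self._result(self.data.transpose(*axes), (self,), backward)

    def broadcast_to(self, shape):
        def backward(grad):
            if self.requires_grad:
                self._accumulate(_unbroadcast(grad, self.data.shape))

        return self._result(np.broadcast_to(self.data, shape).copy(), (self,), backward)


def concat(tensors: list[Tensor], axis: int = 1) -> Tensor:
    """Concatenate tensors along an axis."""
    sizes = [t.data.shape[axis] for t in tensors]
    offsets = np.cumsum([0] + sizes)

    def backward(grad):
        for t, start, stop in zip(tensors, offsets[:-1], offsets[1:]):
            if t.requires_grad:
                sl = [slice(None)] * grad.ndim
                sl[axis] = slice(start, stop)
                t._accumulate(grad[tuple(sl)])

    data = np.concatenate([t.data for t in tensors], axis=axis)
    return Tensor._result(data, tuple(tensors), backward)


def _windows(x: np.ndarray, kh: int, kw: int, sh: int, sw: int) -> np.ndarray:
    """(N, C, Ho, Wo, kh, kw) strided view of all kernel-sized patches."""
    v = np.lib.stride_tricks.sliding_window_view(x, (kh, kw), axis=(2, 3))
    return v[:, :, ::sh, ::sw]


def conv2d(x: Tensor, w: Tensor, b: Tensor | None = None,
           stride: int = 1, padding: int = 0) -> Tensor:
    """2-D cross-correlation: x (N,Cin,H,W) with w (Cout,Cin,kh,kw).

    Evaluated as one im2col matrix product; the column matrix is materialised
    once and shared between the forward pass and both weight/input gradients.
    """
    n, cin, h, wd = x.data.shape
    cout, cin_w, kh, kw = w.data.shape
    if cin != cin_w:
        raise ValueError(f"conv2d channel mismatch: input {cin}, weight {cin_w}")
    xp = x.data
    if padding:
        xp = np.pad(xp, ((0, 0), (0, 0), (padding, padding), (padding, padding)))
    if xp.shape[2] < kh or xp.shape[3] < kw:
        raise ValueError("input smaller than kernel after padding")
    patches = _windows(xp, kh, kw, stride, stride)
    ho, wo = patches.shape[2], patches.shape[3]
    cols = np.ascontiguousarray(patches.transpose(0, 2, 3, 1, 4, 5)).reshape(
        n * ho * wo, cin * kh * kw
    )
    out_flat = cols @ w.data.reshape(cout, -1).T  # (N·Ho·Wo, Cout)
    out_data = out_flat.reshape(n, ho, wo, cout).transpose(0, 3, 1, 2)
    if b is not None:
        out_data = out_data + b.data[None, :, None, None]

    def backward(grad):
        grad_flat = np.ascontiguousarray(grad.transpose(0, 2, 3, 1)).reshape(
            n * ho * wo, cout
        )
        if w.requires_grad:
            w._accumulate((grad_flat.T @ cols).reshape(w.data.shape))
        if b is not None and b.requires_grad:
            b._accumulate(grad.sum(axis=(0, 2, 3)))
        if x.requires_grad:
            if stride == 1:
                # full correlation of the padded gradient with the rotated,
                # channel-transposed kernel — one matrix product
                gp = np.pad(grad, ((0, 0), (0, 0), (kh - 1, kh - 1),
                                   (kw - 1, kw - 1)))
                gwin = _windows(gp, kh, kw, 1, 1)
                gcols = np.ascontiguousarray(
                    gwin.transpose(0, 2, 3, 1, 4, 5)
                ).reshape(n * xp.shape[2] * xp.shape[3], cout * kh * kw)
                wrot = np.ascontiguousarray(
                    w.data[:, :, ::-1, ::-1].transpose(1, 0, 2, 3)
                ).reshape(cin, -1)
                dxp = (gcols @ wrot.T).reshape(
                    n, xp.shape[2], xp.shape[3], cin
                ).transpose(0, 3, 1, 2)
            else:
                dcols = (grad_flat @ w.data.reshape(cout, -1)).reshape(
                    n, ho, wo, cin, kh, kw
                )
                dxp = np.zeros_like(xp)
                for i in range(kh):
                    for j in range(kw):
                        dxp[:, :, i : i + ho * stride : stride,
                            j : j + wo * stride : stride] += dcols[
                            :, :, :, :, i, j].transpose(0, 3, 1, 2)
            if padding:
                dxp = dxp[:, :, padding:-padding, padding:-padding]
            x._accumulate(dxp)

    parents = (x, w) if b is None else (x, w, b)
    return Tensor._result(out_data, parents, backward)


def corr1d_valid(x: Tensor, kernel: np.ndarray, axis: int) -> Tensor:
    """Valid-mode 1-D correlation with a fixed kernel along one axis.

    The workhorse of separable window filtering (e.g. Gaussian SSIM windows):
    applying it along both spatial axes equals a valid 2-D correlation with
    the kernel's outer product, at 2k instead of k² multiplies per pixel.
    """
    k = np.asarray(kernel, dtype=x.data.dtype)
    taps = k.size
    v = np.lib.stride_tricks.sliding_window_view(x.data, taps, axis=axis)
    out_data = v @ k  # windows are the trailing axis

    def backward(grad):
        if not x.requires_grad:
            return
        dx = np.zeros_like(x.data)
        length = grad.shape[axis]
        sl = [slice(None)] * dx.ndim
        for j in range(taps):
            sl[axis] = slice(j, j + length)
            dx[tuple(sl)] += k[j] * grad
        x._accumulate(dx)

    return Tensor._result(out_data, (x,), backward)


def conv_transpose2d(x: Tensor, w: Tensor, b: Tensor | None = None,
                     stride: int = 2) -> Tensor:
    """Transposed 2-D convolution: x (N,Cin,H,W) with w (Cin,Cout,kh,kw).

    Output spatial size is ``(H−1)·stride + k`` (no output padding).
    """
    n, cin, h, wd = x.data.shape
    cin_w, cout, kh, kw = w.data.shape
    if cin != cin_w:
        raise ValueError(f"conv_transpose2d channel mismatch: {cin} vs {cin_w}")
    ho, wo = (h - 1) * stride + kh, (wd - 1) * stride + kw
    out_data = np.zeros((n, cout, ho, wo), dtype=x.data.dtype)
    for i in range(kh):
        for j in range(kw):
            out_data[:, :, i : i + h * stride : stride,
                     j : j + wd * stride : stride] += np.einsum(
                "nchw,co->nohw", x.data, w.data[:, :, i, j], optimize=True
            )
    if b is not None:
        out_data = out_data + b.data[None, :, None, None]

    def backward(grad):
        if b is not None and b.requires_grad:
            b._accumulate(grad.sum(axis=(0, 2, 3)))
        for i in range(kh):
            for j in range(kw):
                g_ij = grad[:, :, i : i + h * stride : stride,
                            j : j + wd * stride : stride]
                if w.requires_grad:
                    w.grad = w.grad if w.grad is not None else np.zeros_like(w.data)
                    w.grad[:, :, i, j] += np.einsum(
                        "nchw,nohw->co", x.data, g_ij, optimize=True
                    )
                if x.requires_grad:
                    if x.grad is None:
                        x.grad = np.zeros_like(x.data)
                    x.grad += np.einsum(
                        "nohw,co->nchw", g_ij, w.data[:, :, i, j], optimize=True
                    )

    parents = (x, w) if b is None else (x, w, b)
    return Tensor._result(out_data, parents, backward)
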