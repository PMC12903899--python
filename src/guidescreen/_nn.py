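"""Minimal reverse-mode automatic differentiation on numpy arrays.

A deliberately small, dependency-light backend sufficient for the hybrid
convolutional/recurrent regressor: dense, 1-D convolution, max pooling,
LeakyReLU, sigmoid/tanh, dropout, slicing/concatenation, and a GRU cell
built from these primitives.  Gradients are accumulated by topological
traversal of the recorded graph; everything is float64 and fully
deterministic given a seeded ``numpy.random.Generator``.
"""

from __future__ import annotations

import numpy as np

__all__ = ["Tensor", "Adam", "backward"]


class Tensor:
    __slots__ = ("data", "grad", "requires_grad", "_parents", "_backward")

    def __init__(self, data, parents=(), requires_grad=False, backward_fn=None):
        self.data = data if isinstance(data, np.ndarray) else np.asarray(data, dtype=np.float64)
        self.grad = None
        self._parents = tuple(parents)
        self.requires_grad = requires_grad or any(p.requires_grad for p in self._parents)
        self._backward = backward_fn

    @property
    def shape(self):
        return self.data.shape

    def __repr__(self):
        return f"Tensor(shape={self.data.shape}, grad={'yes' if self.requires_grad else 'no'})"


def _unbroadcast(grad: np.ndarray, shape: tuple) -> np.ndarray:
    while grad.ndim > len(shape):
        grad = grad.sum(axis=0)
    for axis, size in enumerate(shape):
        if size == 1 and grad.shape[axis] != 1:
            grad = grad.sum(axis=axis, keepdims=True)
    return grad


def _accum(t: Tensor, grad: np.ndarray) -> None:
    if not t.requires_grad:
        return
    t.grad = grad if t.grad is None else t.grad + grad


def add(a: Tensor, b: Tensor) -> Tensor:
    out = Tensor(a.data + b.data, (a, b))

    def back():
        _accum(a, _unbroadcast(out.grad, a.data.shape))
        _accum(b, _unbroadcast(out.grad, b.data.shape))

    out._backward = back
    return out


def sub(a: Tensor, b: Tensor) -> Tensor:
    out = Tensor(a.data - b.data, (a, b))

    def back():
        _accum(a, _unbroadcast(out.grad, a.data.shape))
        _accum(b, _unbroadcast(-out.grad, b.data.shape))

    out._backward = back
    return out


def mul(a: Tensor, b: Tensor) -> Tensor:
    out = Tensor(a.data * b.data, (a, b))

    def back():
        _accum(a, _unbroadcast(out.grad * b.data, a.data.shape))
        _accum(b, _unbroadcast(out.grad * a.data, b.data.shape))

    out._backward = back
    return out


def matmul(a: Tensor, b: Tensor) -> Tensor:
    out = Tensor(a.data @ b.data, (a, b))

    def back():
        _accum(a, out.grad @ b.data.T)
        _accum(b, a.data.T @ out.grad)

    out._backward = back
    return out


def sigmoid(a: Tensor) -> Tensor:
    s = 1.0 / (1.0 + np.exp(-a.data))
    out = Tensor(s, (a,))

    def back():
        _accum(a, out.grad * s * (1.0 - s))

    out._backward = back
    return out


def tanh(a: Tensor) -> Tensor:
    t = np.tanh(a.data)
    out = Tensor(t, (a,))

    def back():
        _accum(a, out.grad * (1.0 - t * t))

    out._backward = back
    return out


def leaky_relu(a: Tensor, alpha: float = 0.1) -> Tensor:
    mask = a.data > 0
    out = Tensor(np.where(mask, a.data, alpha * a.data), (a,))

    def back():
        _accum(a, out.grad * np.where(mask, 1.0, alpha))

    out._backward = back
    return out


def one_minus(a: Tensor) -> Tensor:
    out = Tensor(1.0 - a.data, (a,))

    def back():
        _accum(a, -out.grad)

    out._backward = back
    return out


def reshape(a: Tensor, shape) -> Tensor:
    out = Tensor(a.data.reshape(shape), (a,))

    def back():
        _accum(a, out.grad.reshape(a.data.shape))

    out._backward = back
    return out


def take(a: Tensor, index) -> Tensor:
    """Static indexing (slices / ints); gradients scatter back into place."""
    out = Tensor(a.data[index], (a,))

    def back():
        g = np.zeros_like(a.data)
        g[index] = out.grad
        _accum(a, g)

    out._backward = back
    return out


def concat(tensors, axis: int) -> Tensor:
    out = Tensor(np.concatenate([t.data for t in tensors], axis=axis), tuple(tensors))
    sizes = [t.data.shape[axis] for t in tensors]

    def back():
        offsets = np.cumsum([0] + sizes)
        for t, lo, hi in zip(tensors, offsets[:-1], offsets[1:]):
            idx = [slice(None)] * out.grad.ndim
            idx[axis] = slice(lo, hi)
            _accum(t, out.grad[tuple(idx)])

    out._backward = back
    return out


def mean_all(a: Tensor) -> Tensor:
    out = Tensor(np.asarray(a.data.mean()), (a,))

    def back():
        _accum(a, np.full_like(a.data, out.grad / a.data.size))

    out._backward = back
    return out


def conv1d(x: Tensor, w: Tensor, b: Tensor) -> Tensor:
    """Valid 1-D convolution: x (B, Cin, L), w (Cout, Cin, K), b (Cout,)."""
    K = w.data.shape[2]
    xw = np.lib.stride_tricks.sliding_window_view(x.data, K, axis=2)  # (B, Cin, Lout, K)
    out_data = np.einsum("ock,bclk->bol", w.data, xw, optimize=True) + b.data[None, :, None]
    out = Tensor(out_data, (x, w, b))
    l_out = out_data.shape[2]

    def back():
        g = out.grad
        _accum(w, np.einsum("bol,bclk->ock", g, xw, optimize=True))
        _accum(b, g.sum(axis=(0, 2)))
        if x.requires_grad:
            gx = np.zeros_like(x.data)
            for k in range(K):
                gx[:, :, k : k + l_out] += np.einsum("bol,oc->bcl", g, w.data[:, :, k], optimize=True)
            _accum(x, gx)

    out._backward = back
    return out


def maxpool1d(x: Tensor, pool: int) -> Tensor:
    """Non-overlapping max pooling along the last axis; trailing remainder dropped."""
    B, C, L = x.data.shape
    l_out = L // pool
    if l_out < 1:
        raise ValueError(f"pool width {pool} exhausts sequence of length {L}")
    xt = x.data[:, :, : l_out * pool].reshape(B, C, l_out, pool)
    arg = xt.argmax(axis=3)
    out = Tensor(xt.max(axis=3), (x,))

    def back():
        g4 = np.zeros_like(xt)
        np.put_along_axis(g4, arg[..., None], out.grad[..., None], axis=3)
        gx = np.zeros_like(x.data)
        gx[:, :, : l_out * pool] = g4.reshape(B, C, l_out * pool)
        _accum(x, gx)

    out._backward = back
    return out


def dropout(x: Tensor, rate: float, rng: np.random.Generator, training: bool) -> Tensor:
    if not training or rate <= 0.0:
        return x
    mask = (rng.random(x.data.shape) >= rate) / (1.0 - rate)
    return mul(x, Tensor(mask))


def backward(loss: Tensor) -> None:
    """Reverse accumulation from a scalar loss over the recorded graph."""
    topo: list[Tensor] = []
    visited: set[int] = set()
    stack: list[tuple[Tensor, bool]] = [(loss, False)]
    while stack:
        node, processed = stack.pop()
        if processed:
            topo.append(node)
            continue
        if id(node) in visited:
            continue
        visited.add(id(node))
        stack.append((node, True))
        for p in node._parents:
            if id(p) not in visited and p.requires_grad:
                stack.append((p, False))
    loss.grad = np.asarray(1.0)
    for node in reversed(topo):
        if node._backward is not None and node.grad is not None:
            node._backward()


class Adam:
    """Adam optimizer with the standard bias-corrected moment estimates."""

    def __init__(self, params: list[Tensor], lr: float, betas=(0.9, 0.999), eps: float = 1e-8):
        self.params = params
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
        self.t = 0
        self.m = [np.zeros_like(p.data) for p in params]
        self.v = [np.zeros_like(p.data) for p in params]

    def zero_grad(self) -> None:
        for p in self.params:
            p.grad = None

    def step(self) -> None:
        self.t += 1
        for p, m, v in zip(self.params, self.m, self.v):
            if p.grad is None:
                continue
            g = p.grad
            m *= self.b1
            m += (1 - self.b1) * g
            v *= self.b2
            v += (1 - self.b2) * g * g
            m_hat = m / (1 - self.b1 ** self.t)
            v_hat = v / (1 - self.b2 ** self.t)
            p.data -= self.lr * m_hat / (np.sqrt(v_hat) + self.eps)


def glorot(rng: np.random.Generator, shape: tuple, fan_in: int, fan_out: int) -> Tensor:
    limit = np.sqrt(6.0 / (fan_in + fan_out))
    return Tensor(rng.uniform(-limit, limit, size=shape), requires_grad=True)


def zeros(shape) -> Tensor:
    return Tensor(np.zeros(shape), requires_grad=True)


class GRUCell:
    """Gated recurrent unit: one parameter set applied step-wise over a sequence."""

    def __init__(self, rng: np.random.Generator, input_size: int, hidden: int):
        self.hidden = hidden
        self.wx = glorot(rng, (input_size, 3 * hidden), input_size, hidden)
        self.wh = glorot(rng, (hidden, 3 * hidden), hidden, hidden)
        self.bx = zeros((3 * hidden,))

    @property
    def params(self) -> list[Tensor]:
        return [self.wx, self.wh, self.bx]

    def run(self, steps: list[Tensor]) -> Tensor:
        """Consume a list of (B, input_size) tensors; return the final hidden state."""
        h_dim = self.hidden
        batch = steps[0].data.shape[0]
        h = Tensor(np.zeros((batch, h_dim)))
        for x_t in steps:
            gx = add(matmul(x_t, self.wx), self.bx)
            gh = matmul(h, self.wh)
            z = sigmoid(add(take(gx, (slice(None), slice(0, h_dim))),
                            take(gh, (slice(None), slice(0, h_dim)))))
            r = sigmoid(add(take(gx, (slice(None), slice(h_dim, 2 * h_dim))),
                            take(gh, (slice(None), slice(h_dim, 2 * h_dim)))))
            n = tanh(add(take(gx, (slice(None), slice(2 * h_dim, 3 * h_dim))),
                         mul(r, take(gh, (slice(None), slice(2 * h_dim, 3 * h_dim))))))
            h = add(mul(z, h), mul(one_minus(z), n))
        return h
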