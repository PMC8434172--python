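"""Minimal CNN building blocks with explicit backpropagation.

A small, dependency-free (numpy-only) stack of convolutional layers with
hand-written forward/backward passes and an SGD-with-momentum optimizer.
Keeping the autodiff explicit has two benefits for this package: the
gradient of a class score with respect to any intermediate feature map —
the quantity Grad-CAM is built from — is directly accessible, and it can
be validated against a finite-difference oracle without framework magic.

Layers operate on batched arrays of shape ``(N, C, H, W)`` (dense layers on
``(N, C)``). All parameters are float64 for reproducibility across runs.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np


class Layer:
    """Base layer: forward caches whatever backward needs."""

    params: list[np.ndarray]
    grads: list[np.ndarray]

    def __init__(self) -> None:
        self.params = []
        self.grads = []

    def forward(self, x: np.ndarray) -> np.ndarray:  # pragma: no cover - abstract
        raise NotImplementedError

    def backward(self, grad_out: np.ndarray) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError

    @property
    def spatial(self) -> bool:
        """Whether the layer's output retains spatial extent."""
        return True


class Conv2D(Layer):
    """Same-padded 2-D convolution (cross-correlation), stride 1.

    Kernel size 3 or 1. Implemented with sliding windows + tensordot; the
    backward pass computes both weight gradients and the gradient with
    respect to the input.
    """

    def __init__(self, in_ch: int, out_ch: int, ksize: int = 3, rng=None) -> None:
        super().__init__()
        if ksize not in (1, 3):
            raise ValueError("ksize must be 1 or 3")
        rng = rng or np.random.default_rng()
        # He initialization for ReLU nets
        std = np.sqrt(2.0 / (in_ch * ksize * ksize))
        self.W = rng.normal(0.0, std, size=(out_ch, in_ch, ksize, ksize))
        self.b = np.zeros(out_ch)
        self.ksize = ksize
        self.params = [self.W, self.b]
        self.grads = [np.zeros_like(self.W), np.zeros_like(self.b)]
        self._xpad: np.ndarray | None = None

    def _pad(self, x: np.ndarray) -> np.ndarray:
        if self.ksize == 1:
            return x
        return np.pad(x, ((0, 0), (0, 0), (1, 1), (1, 1)))

    def forward(self, x: np.ndarray) -> np.ndarray:
        xpad = self._pad(x)
        self._xpad = xpad
        k = self.ksize
        win = np.lib.stride_tricks.sliding_window_view(xpad, (k, k), axis=(2, 3))
        # win: (N, C, H, W, k, k); W: (O, C, k, k) -> out (N, H, W, O)
        out = np.tensordot(win, self.W, axes=([1, 4, 5], [1, 2, 3]))
        out = np.moveaxis(out, 3, 1) + self.b[None, :, None, None]
        return out

    def backward(self, grad_out: np.ndarray) -> np.ndarray:
        k = self.ksize
        xpad = self._xpad
        win = np.lib.stride_tricks.sliding_window_view(xpad, (k, k), axis=(2, 3))
        # dW[o,c,u,v] = sum_{n,i,j} g[n,o,i,j] * xpad[n,c,i+u,j+v]
        dW = np.tensordot(grad_out, win, axes=([0, 2, 3], [0, 2, 3]))
        self.grads[0][...] = dW
        self.grads[1][...] = grad_out.sum(axis=(0, 2, 3))
        # dx: full correlation of grad_out with spatially flipped W
        if k == 1:
            dx = np.tensordot(grad_out, self.W[:, :, 0, 0], axes=([1], [0]))
            return np.moveaxis(dx, 3, 1)
        gpad = np.pad(grad_out, ((0, 0), (0, 0), (1, 1), (1, 1)))
        gwin = np.lib.stride_tricks.sliding_window_view(gpad, (k, k), axis=(2, 3))
        Wflip = self.W[:, :, ::-1, ::-1]
        dx = np.tensordot(gwin, Wflip, axes=([1, 4, 5], [0, 2, 3]))
        return np.moveaxis(dx, 3, 1)


class ReLU(Layer):
    def forward(self, x: np.ndarray) -> np.ndarray:
        self._mask = x > 0
        return x * self._mask

    def backward(self, grad_out: np.ndarray) -> np.ndarray:
        return grad_out * self._mask


class MaxPool2(Layer):
    """2x2 max pooling, stride 2. Input H, W must be even."""

    def forward(self, x: np.ndarray) -> np.ndarray:
        n, c, h, w = x.shape
        if h % 2 or w % 2:
            raise ValueError("MaxPool2 needs even spatial dims")
        xr = x.reshape(n, c, h // 2, 2, w // 2, 2)
        blocks = xr.transpose(0, 1, 2, 4, 3, 5).reshape(n, c, h // 2, w // 2, 4)
        self._arg = blocks.argmax(axis=-1)
        self._in_shape = x.shape
        return blocks.max(axis=-1)

    def backward(self, grad_out: np.ndarray) -> np.ndarray:
        n, c, h, w = self._in_shape
        dx_blocks = np.zeros((n, c, h // 2, w // 2, 4))
        np.put_along_axis(dx_blocks, self._arg[..., None], grad_out[..., None], axis=-1)
        dx = dx_blocks.reshape(n, c, h // 2, w // 2, 2, 2)
        return dx.transpose(0, 1, 2, 4, 3, 5).reshape(n, c, h, w)


class Upsample2(Layer):
    """Nearest-neighbour x2 upsampling."""

    def forward(self, x: np.ndarray) -> np.ndarray:
        return x.repeat(2, axis=2).repeat(2, axis=3)

    def backward(self, grad_out: np.ndarray) -> np.ndarray:
        n, c, h, w = grad_out.shape
        return grad_out.reshape(n, c, h // 2, 2, w // 2, 2).sum(axis=(3, 5))


class GlobalAvgPool(Layer):
    def forward(self, x: np.ndarray) -> np.ndarray:
        self._in_shape = x.shape
        return x.mean(axis=(2, 3))

    def backward(self, grad_out: np.ndarray) -> np.ndarray:
        n, c, h, w = self._in_shape
        return np.broadcast_to(grad_out[:, :, None, None], self._in_shape) / (h * w)

    @property
    def spatial(self) -> bool:
        return False


class Linear(Layer):
    def __init__(self, in_dim: int, out_dim: int, rng=None) -> None:
        super().__init__()
        rng = rng or np.random.default_rng()
        std = np.sqrt(2.0 / in_dim)
        self.W = rng.normal(0.0, std, size=(out_dim, in_dim))
        self.b = np.zeros(out_dim)
        self.params = [self.W, self.b]
        self.grads = [np.zeros_like(self.W), np.zeros_like(self.b)]

    def forward(self, x: np.ndarray) -> np.ndarray:
        self._x = x
        return x @ self.W.T + self.b

    def backward(self, grad_out: np.ndarray) -> np.ndarray:
        self.grads[0][...] = grad_out.T @ self._x
        self.grads[1][...] = grad_out.sum(axis=0)
        return grad_out @ self.W

    @property
    def spatial(self) -> bool:
        return False


class Sequential:
    """A plain layer stack with full-activation caching.

    ``forward`` caches every intermediate activation so that gradients with
    respect to any layer's output can be requested afterwards
    (:meth:`grad_wrt_activation`) and so that the tail of the network can be
    re-run from a perturbed intermediate activation
    (:meth:`forward_from`) — both are what Grad-CAM and its
    finite-difference validation need.
    """

    def __init__(self, layers: list[Layer]) -> None:
        self.layers = layers
        self.activations: list[np.ndarray] = []

    def forward(self, x: np.ndarray) -> np.ndarray:
        self.activations = [x]
        for layer in self.layers:
            x = layer.forward(x)
            self.activations.append(x)
        return x

    def forward_from(self, layer_idx: int, activation: np.ndarray) -> np.ndarray:
        """Run layers ``layer_idx+1 ...`` on a given activation (no caching)."""
        x = activation
        for layer in self.layers[layer_idx + 1:]:
            x = layer.forward(x)
        return x

    def backward(self, grad_out: np.ndarray, down_to: int = 0) -> np.ndarray:
        """Backpropagate; returns gradient w.r.t. output of layer ``down_to - 1``
        (i.e. the input of layer ``down_to``)."""
        g = grad_out
        for layer in reversed(self.layers[down_to:]):
            g = layer.backward(g)
        return g

    def grad_wrt_activation(self, layer_idx: int, grad_out: np.ndarray) -> np.ndarray:
        """Gradient of a scalar (seeded by ``grad_out`` at the network output)
        with respect to the output activation of layer ``layer_idx``.
        Requires a prior :meth:`forward`."""
        g = grad_out
        for layer in reversed(self.layers[layer_idx + 1:]):
            g = layer.backward(g)
        return g

    def parameters(self) -> list[tuple[np.ndarray, np.ndarray]]:
        out = []
        for layer in self.layers:
            out.extend(zip(layer.params, layer.grads))
        return out

    def last_spatial_index(self) -> int:
        """Index of the last layer whose output retains spatial extent —
        the default Grad-CAM target layer."""
        idx = -1
        for i, layer in enumerate(self.layers):
            if layer.spatial:
                idx = i
            else:
                break
        if idx < 0:
            raise ValueError("network has no spatial layers")
        return idx

    def save(self, path: str | Path) -> None:
        arrays = {}
        for i, layer in enumerate(self.layers):
            for j, p in enumerate(layer.params):
                arrays[f"layer{i}_p{j}"] = p
        np.savez(Path(path), **arrays)

    def load(self, path: str | Path) -> None:
        data = np.load(Path(path))
        for i, layer in enumerate(self.layers):
            for j, p in enumerate(layer.params):
                p[...] = data[f"layer{i}_p{j}"]


class SGDMomentum:
    """Stochastic gradient descent with classical momentum."""

    def __init__(self, params: list[tuple[np.ndarray, np.ndarray]],
                 lr: float = 0.01, momentum: float = 0.9) -> None:
        self.params = params
        self.lr = lr
        self.momentum = momentum
        self.velocity = [np.zeros_like(p) for p, _ in params]

    def step(self) -> None:
        for (p, g), v in zip(self.params, self.velocity):
            v *= self.momentum
            v -= self.lr * g
            p += v


def softmax(logits: np.ndarray) -> np.ndarray:
    z = logits - logits.max(axis=-1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=-1, keepdims=True)


def cross_entropy_grad(logits: np.ndarray, targets: np.ndarray) -> tuple[float, np.ndarray]:
    """Mean cross-entropy over a batch and its gradient w.r.t. logits.

    ``targets`` are integer class indices of shape (N,).
    """
    p = softmax(logits)
    n = logits.shape[0]
    loss = -np.mean(np.log(p[np.arange(n), targets] + 1e-12))
    grad = p.copy()
    grad[np.arange(n), targets] -= 1.0
    return float(loss), grad / n
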