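"""Small CPU neural-network engine: layers with explicit forward/backward passes.

Every layer follows the same contract: ``forward(x, ...)`` returns
``(output, cache)`` and ``backward(grad_out, cache)`` returns ``grad_in``
while *accumulating* parameter gradients into ``.dw`` / ``.db``.  Caches are
passed explicitly so that one layer object can appear several times in a
network (weight tying across paths) without clobbering its own state.

All convolutions are 3x3, stride 1, padding 1, and all spatial pooling is
2x2 stride-2 max pooling — the building blocks of a VGG-style backbone.
Inputs are single images laid out channel-first ``(C, H, W)``; there is no
batch axis because the classifier is trained one subject at a time on
arbitrarily sized images.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "Conv3x3",
    "ReLU",
    "MaxPool2",
    "Linear",
    "Dropout",
    "softmax",
    "cross_entropy",
    "SGD",
]


def _im2col3(x: np.ndarray) -> np.ndarray:
    """Unfold 3x3 neighbourhoods (pad 1) of a (C,H,W) array into (C*9, H*W)."""
    c, h, w = x.shape
    xp = np.zeros((c, h + 2, w + 2), dtype=x.dtype)
    xp[:, 1:-1, 1:-1] = x
    cols = np.empty((c, 9, h, w), dtype=x.dtype)
    for u in range(3):
        for v in range(3):
            cols[:, 3 * u + v] = xp[:, u: u + h, v: v + w]
    return cols.reshape(c * 9, h * w)


class Conv3x3:
    """3x3 convolution, stride 1, padding 1 (spatial dims preserved)."""

    def __init__(self, c_in: int, c_out: int, rng: np.random.Generator,
                 dtype=np.float32):
        # He initialisation for ReLU networks; zero biases.
        std = np.sqrt(2.0 / (9 * c_in))
        self.w = (rng.standard_normal((c_out, c_in, 3, 3)) * std).astype(dtype)
        self.b = np.zeros(c_out, dtype=dtype)
        self.dw = np.zeros_like(self.w)
        self.db = np.zeros_like(self.b)

    @property
    def n_params(self) -> int:
        return self.w.size + self.b.size

    def params(self):
        return [(self.w, self.dw), (self.b, self.db)]

    def forward(self, x: np.ndarray):
        c_out = self.w.shape[0]
        _, h, w = x.shape
        cols = _im2col3(x)
        out = self.w.reshape(c_out, -1) @ cols + self.b[:, None]
        return out.reshape(c_out, h, w), (cols, x.shape)

    def backward(self, dout: np.ndarray, cache):
        cols, xshape = cache
        c_out = self.w.shape[0]
        dmat = dout.reshape(c_out, -1)
        self.dw += (dmat @ cols.T).reshape(self.w.shape)
        self.db += dmat.sum(axis=1)
        # grad wrt input = correlation of dout with spatially flipped,
        # in/out-transposed kernels (stride 1, pad 1 is self-adjoint in shape)
        wb = np.ascontiguousarray(self.w.transpose(1, 0, 2, 3)[:, :, ::-1, ::-1])
        c_in = wb.shape[0]
        dcols = _im2col3(dout)
        return (wb.reshape(c_in, -1) @ dcols).reshape(xshape)


class ReLU:
    def params(self):
        return []

    def forward(self, x):
        mask = x > 0
        return x * mask, mask

    def backward(self, dout, mask):
        return dout * mask


class MaxPool2:
    """2x2 max pooling with stride 2; odd trailing rows/columns are dropped,
    so the output extent is floor(H/2) x floor(W/2)."""

    def params(self):
        return []

    def forward(self, x):
        c, h, w = x.shape
        h2, w2 = h // 2, w // 2
        xc = x[:, : h2 * 2, : w2 * 2]
        xw = xc.reshape(c, h2, 2, w2, 2).transpose(0, 1, 3, 2, 4).reshape(c, h2, w2, 4)
        idx = xw.argmax(axis=-1)
        out = np.take_along_axis(xw, idx[..., None], axis=-1)[..., 0]
        return out, (idx, x.shape)

    def backward(self, dout, cache):
        idx, xshape = cache
        c, h, w = xshape
        h2, w2 = h // 2, w // 2
        dxw = np.zeros((c, h2, w2, 4), dtype=dout.dtype)
        np.put_along_axis(dxw, idx[..., None], dout[..., None], axis=-1)
        dxc = dxw.reshape(c, h2, w2, 2, 2).transpose(0, 1, 3, 2, 4).reshape(c, h2 * 2, w2 * 2)
        if h2 * 2 == h and w2 * 2 == w:
            return dxc
        dx = np.zeros(xshape, dtype=dout.dtype)
        dx[:, : h2 * 2, : w2 * 2] = dxc
        return dx


class Linear:
    """Fully connected layer on 1-D vectors: y = W x + b."""

    def __init__(self, d_in: int, d_out: int, rng: np.random.Generator,
                 dtype=np.float32):
        std = np.sqrt(2.0 / d_in)
        self.w = (rng.standard_normal((d_out, d_in)) * std).astype(dtype)
        self.b = np.zeros(d_out, dtype=dtype)
        self.dw = np.zeros_like(self.w)
        self.db = np.zeros_like(self.b)

    @property
    def n_params(self) -> int:
        return self.w.size + self.b.size

    def params(self):
        return [(self.w, self.dw), (self.b, self.db)]

    def forward(self, x):
        return self.w @ x + self.b, x

    def backward(self, dout, x):
        self.dw += np.outer(dout, x)
        self.db += dout
        return self.w.T @ dout


class Dropout:
    """Inverted dropout with retention probability ``p``.

    Training mode multiplies activations by a Bernoulli(p) mask and rescales
    the survivors by 1/p, so inference mode is the plain identity and needs
    no expectation correction.
    """

    def __init__(self, p: float):
        if not 0.0 <= p <= 1.0:
            raise ValueError(f"retention probability must be in [0, 1], got {p}")
        self.p = p

    def params(self):
        return []

    def forward(self, x, train: bool = False, rng: np.random.Generator | None = None):
        if not train or self.p == 1.0:
            return x, None
        if self.p == 0.0:
            return np.zeros_like(x), np.zeros_like(x)
        if rng is None:
            raise ValueError("training-mode dropout needs a random generator")
        mask = (rng.random(x.shape) < self.p).astype(x.dtype) / self.p
        return x * mask, mask

    def backward(self, dout, mask):
        if mask is None:
            return dout
        return dout * mask


def softmax(z: np.ndarray) -> np.ndarray:
    e = np.exp(z - z.max())
    return e / e.sum()


def cross_entropy(logits: np.ndarray, label: int):
    """Softmax cross-entropy for a single sample.

    Returns ``(loss, dlogits, probs)`` where ``dlogits`` is the gradient of
    the loss with respect to the raw class scores.
    """
    p = softmax(logits.astype(np.float64))
    loss = -np.log(max(p[label], 1e-300))
    dlogits = p.copy()
    dlogits[label] -= 1.0
    return float(loss), dlogits.astype(logits.dtype), p


class SGD:
    """Stochastic gradient descent with classical momentum.

    ``params`` is a list of (array, grad) pairs; tied arrays may appear only
    once (deduplicate by identity before constructing the optimizer).
    """

    def __init__(self, params, momentum: float = 0.9):
        seen, unique = set(), []
        for w, g in params:
            if id(w) not in seen:
                seen.add(id(w))
                unique.append((w, g))
        self._params = unique
        self.momentum = momentum
        self._vel = [np.zeros_like(w) for w, _ in unique]

    def zero_grad(self):
        for _, g in self._params:
            g[...] = 0

    def step(self, lr: float):
        for (w, g), v in zip(self._params, self._vel):
            v *= self.momentum
            v += g
            w -= lr * v
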