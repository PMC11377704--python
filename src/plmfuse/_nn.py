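"""Minimal 1-D convolutional network in numpy: forward, backprop, Adam.

Shapes: inputs are (B, L, C_in) batches of residue tracks; convolutions use
same-padding with odd kernels, so every layer preserves L. Padded positions
are zeroed after every layer so real-residue outputs are independent of how
far a chain was padded.
"""

from __future__ import annotations

import numpy as np


def conv1d_forward(X: np.ndarray, W: np.ndarray, b: np.ndarray) -> np.ndarray:
    """X (B,L,Cin), W (k,Cin,Cout), b (Cout) -> (B,L,Cout), same padding."""
    k = W.shape[0]
    pad = k // 2
    B, L, Cin = X.shape
    Xp = np.zeros((B, L + 2 * pad, Cin), dtype=X.dtype)
    Xp[:, pad:pad + L] = X
    Y = np.broadcast_to(b, (B, L, W.shape[2])).copy()
    for j in range(k):
        Y += Xp[:, j:j + L] @ W[j]
    return Y


def conv1d_backward(X: np.ndarray, W: np.ndarray, dY: np.ndarray):
    """Gradients of conv1d_forward. Returns (dX, dW, db)."""
    k = W.shape[0]
    pad = k // 2
    B, L, Cin = X.shape
    Xp = np.zeros((B, L + 2 * pad, Cin), dtype=X.dtype)
    Xp[:, pad:pad + L] = X
    dW = np.empty_like(W)
    dXp = np.zeros_like(Xp)
    flat_dY = dY.reshape(-1, dY.shape[2])
    for j in range(k):
        dW[j] = Xp[:, j:j + L].reshape(-1, Cin).T @ flat_dY
        dXp[:, j:j + L] += dY @ W[j].T
    db = flat_dY.sum(axis=0)
    return dXp[:, pad:pad + L], dW, db


def leaky_relu(x: np.ndarray, slope: float) -> np.ndarray:
    return np.where(x >= 0, x, slope * x)


def leaky_relu_grad(x: np.ndarray, slope: float) -> np.ndarray:
    return np.where(x >= 0, 1.0, slope)


def softmax(z: np.ndarray) -> np.ndarray:
    z = z - z.max(axis=-1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=-1, keepdims=True)


class ConvStack:
    """A chain of same-padding 1-D convolutions with leaky-ReLU activations.

    ``activate_last`` controls whether the final layer is followed by an
    activation (True for branch stacks feeding a merge, False for heads).
    """

    def __init__(self, widths, kernel_size: int, slope: float,
                 activate_last: bool, rng: np.random.Generator):
        if kernel_size % 2 == 0:
            raise ValueError("kernel_size must be odd")
        self.widths = list(widths)
        self.kernel_size = kernel_size
        self.slope = slope
        self.activate_last = activate_last
        self.W = []
        self.b = []
        for cin, cout in zip(self.widths[:-1], self.widths[1:]):
            scale = np.sqrt(2.0 / (kernel_size * cin))
            self.W.append(rng.normal(0.0, scale, size=(kernel_size, cin, cout)))
            self.b.append(np.zeros(cout))

    @property
    def n_layers(self) -> int:
        return len(self.W)

    def parameters(self):
        return self.W + self.b

    def n_parameters(self) -> int:
        return sum(w.size for w in self.W) + sum(b.size for b in self.b)

    def forward(self, X: np.ndarray, mask: np.ndarray):
        """Returns (output, cache). ``mask`` is (B, L, 1) in {0, 1}."""
        cache = []
        h = X
        for i in range(self.n_layers):
            z = conv1d_forward(h, self.W[i], self.b[i]) * mask
            act = i < self.n_layers - 1 or self.activate_last
            cache.append((h, z, act))
            h = leaky_relu(z, self.slope) * mask if act else z
        return h, cache

    def backward(self, dY: np.ndarray, mask: np.ndarray, cache):
        """Returns (dX, grads) with grads ordered as ``parameters()``."""
        dW_all = [None] * self.n_layers
        db_all = [None] * self.n_layers
        d = dY
        for i in reversed(range(self.n_layers)):
            h, z, act = cache[i]
            if act:
                d = d * leaky_relu_grad(z, self.slope)
            d = d * mask
            d, dW_all[i], db_all[i] = conv1d_backward(h, self.W[i], d)
        return d, dW_all + db_all


class Adam:
    """Adam optimizer over a flat list of parameter arrays (updated in place)."""

    def __init__(self, params, lr: float = 1e-3, beta1: float = 0.9,
                 beta2: float = 0.999, eps: float = 1e-8):
        self.params = params
        self.lr, self.beta1, self.beta2, self.eps = lr, beta1, beta2, eps
        self.m = [np.zeros_like(p) for p in params]
        self.v = [np.zeros_like(p) for p in params]
        self.t = 0

    def step(self, grads) -> None:
        self.t += 1
        b1t = 1 - self.beta1 ** self.t
        b2t = 1 - self.beta2 ** self.t
        for p, g, m, v in zip(self.params, grads, self.m, self.v):
            m *= self.beta1
            m += (1 - self.beta1) * g
            v *= self.beta2
            v += (1 - self.beta2) * g * g
            p -= self.lr * (m / b1t) / (np.sqrt(v / b2t) + self.eps)


def masked_softmax_xent(logits, targets, mask2d, class_weights=None):
    """Mean cross-entropy over unmasked positions; returns (loss, dlogits).

    ``targets`` are integer class indices (B, L); masked positions may hold
    any index. ``dlogits`` already includes the 1/n normalization.
    """
    probs = softmax(logits)
    B, L, K = logits.shape
    idx = (np.arange(B)[:, None], np.arange(L)[None, :], targets)
    picked = np.clip(probs[idx], 1e-12, None)
    w = mask2d.astype(float)
    if class_weights is not None:
        w = w * np.asarray(class_weights)[targets]
    n = w.sum()
    loss = -(w * np.log(picked)).sum() / n
    dlogits = probs * w[..., None]
    dlogits[idx] -= w
    return loss, dlogits / n


def masked_mse(pred, targets, mask2d):
    """Mean squared error over unmasked positions; returns (loss, dpred)."""
    diff = (pred[..., 0] - targets) * mask2d
    n = mask2d.sum()
    loss = float((diff ** 2).sum() / n)
    return loss, (2.0 * diff / n)[..., None]
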