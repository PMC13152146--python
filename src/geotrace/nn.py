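"""Minimal feed-forward network for coordinate regression.

A deliberately small, dependency-free multilayer perceptron: ELU hidden
units, inverted dropout during training, full-batch Adam on a squared
Euclidean loss, and early stopping on a held-out validation split with
best-weight restoration. All randomness flows through a caller-supplied
numpy Generator, so fixed seeds give bit-identical weights.
"""

from __future__ import annotations

import numpy as np


def _elu(x):
    return np.where(x > 0, x, np.expm1(np.minimum(x, 0.0)))


def _elu_grad(x, fx):
    return np.where(x > 0, 1.0, fx + 1.0)


class MLPRegressor:
    """Fully connected regressor: d_in -> hidden*depth -> d_out."""

    def __init__(self, d_in: int, d_out: int, hidden_layers: int, hidden_width: int,
                 rng: np.random.Generator):
        sizes = [d_in] + [hidden_width] * hidden_layers + [d_out]
        self.W = [
            rng.normal(0.0, np.sqrt(2.0 / sizes[i]), size=(sizes[i], sizes[i + 1]))
            for i in range(len(sizes) - 1)
        ]
        self.b = [np.zeros(sizes[i + 1]) for i in range(len(sizes) - 1)]

    def forward(self, X, dropout_rate: float = 0.0, rng: np.random.Generator | None = None):
        """Forward pass; returns (output, cache) for backprop."""
        a = X
        cache = []
        n_layers = len(self.W)
        for i, (W, b) in enumerate(zip(self.W, self.b)):
            z = a @ W + b
            if i < n_layers - 1:
                h = _elu(z)
                if dropout_rate > 0.0 and rng is not None:
                    keep = (rng.random(h.shape) >= dropout_rate) / (1.0 - dropout_rate)
                    h = h * keep
                else:
                    keep = None
                cache.append((a, z, h, keep))
                a = h
            else:
                cache.append((a, z, z, None))
                a = z
        return a, cache

    def predict(self, X):
        out, _ = self.forward(X)
        return out

    def _backward(self, cache, d_out):
        grads_W, grads_b = [], []
        delta = d_out
        for i in reversed(range(len(self.W))):
            a_in, z, h, keep = cache[i]
            if i < len(self.W) - 1:
                if keep is not None:
                    delta = delta * keep
                delta = delta * _elu_grad(z, _elu(z))
            grads_W.append(a_in.T @ delta)
            grads_b.append(delta.sum(axis=0))
            if i > 0:
                delta = delta @ self.W[i].T
        return grads_W[::-1], grads_b[::-1]

    def fit(self, X, Y, X_val, Y_val, max_epochs: int = 1000, patience: int = 100,
            learning_rate: float = 1e-3, dropout_rate: float = 0.25,
            rng: np.random.Generator | None = None):
        """Full-batch Adam with early stopping on validation loss.

        Returns (best validation loss, epochs run). Weights are restored
        to the best-validation snapshot.
        """
        rng = rng or np.random.default_rng()
        mW = [np.zeros_like(W) for W in self.W]
        vW = [np.zeros_like(W) for W in self.W]
        mb = [np.zeros_like(b) for b in self.b]
        vb = [np.zeros_like(b) for b in self.b]
        b1, b2, eps = 0.9, 0.999, 1e-8
        n = X.shape[0]
        best = np.inf
        best_snapshot = None
        since_best = 0
        epoch = 0
        for epoch in range(1, max_epochs + 1):
            out, cache = self.forward(X, dropout_rate=dropout_rate, rng=rng)
            d_out = 2.0 * (out - Y) / n
            gW, gb = self._backward(cache, d_out)
            t = epoch
            for i in range(len(self.W)):
                mW[i] = b1 * mW[i] + (1 - b1) * gW[i]
                vW[i] = b2 * vW[i] + (1 - b2) * gW[i] ** 2
                mb[i] = b1 * mb[i] + (1 - b1) * gb[i]
                vb[i] = b2 * vb[i] + (1 - b2) * gb[i] ** 2
                mhW = mW[i] / (1 - b1**t)
                vhW = vW[i] / (1 - b2**t)
                mhb = mb[i] / (1 - b1**t)
                vhb = vb[i] / (1 - b2**t)
                self.W[i] -= learning_rate * mhW / (np.sqrt(vhW) + eps)
                self.b[i] -= learning_rate * mhb / (np.sqrt(vhb) + eps)
            val_loss = float(np.mean(np.sum((self.predict(X_val) - Y_val) ** 2, axis=1)))
            if val_loss < best - 1e-12:
                best = val_loss
                best_snapshot = ([W.copy() for W in self.W], [b.copy() for b in self.b])
                since_best = 0
            else:
                since_best += 1
                if since_best >= patience:
                    break
        if best_snapshot is not None:
            self.W, self.b = best_snapshot
        return best, epoch
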