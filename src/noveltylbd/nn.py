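"""A small, fully seeded feed-forward network on numpy.

Shared numeric core for the two importance classifiers: the halving-width
feature network (ReLU hidden layers, one sigmoid output, binary cross
entropy) and the masked-element triple language model (softmax output over
the token vocabulary).  Everything is deterministic under a fixed seed:
initialisation, mini-batch shuffling and dropout masks all draw from one
``numpy.random.Generator``.

The low-level ``forward``/``backward`` pair is exposed so a caller can train
parameters *upstream* of the network (the LM's token embedding table):
``backward`` returns the gradient with respect to the input batch.
"""

from __future__ import annotations

from typing import Literal, Sequence

import numpy as np

__all__ = ["Adam", "DenseNet"]


class Adam:
    """Adam optimiser state over a list of parameter arrays."""

    def __init__(self, params: Sequence[np.ndarray], lr: float = 1e-3,
                 beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-8):
        self.lr = lr
        self.beta1, self.beta2, self.eps = beta1, beta2, eps
        self.t = 0
        self.m = [np.zeros_like(p) for p in params]
        self.v = [np.zeros_like(p) for p in params]

    def step(self, params: Sequence[np.ndarray], grads: Sequence[np.ndarray]) -> None:
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        for i, (p, g) in enumerate(zip(params, grads)):
            self.m[i] = b1 * self.m[i] + (1 - b1) * g
            self.v[i] = b2 * self.v[i] + (1 - b2) * g * g
            mhat = self.m[i] / (1 - b1 ** self.t)
            vhat = self.v[i] / (1 - b2 ** self.t)
            p -= self.lr * mhat / (np.sqrt(vhat) + self.eps)


class DenseNet:
    """Fully connected net: ReLU hidden layers, sigmoid or softmax output."""

    def __init__(
        self,
        layer_sizes: Sequence[int],
        out_activation: Literal["sigmoid", "softmax"] = "sigmoid",
        dropout: float = 0.0,
        seed: int = 0,
    ):
        if len(layer_sizes) < 2:
            raise ValueError("need at least input and output sizes")
        if not 0.0 <= dropout < 1.0:
            raise ValueError("dropout must be in [0, 1)")
        self.sizes = list(int(s) for s in layer_sizes)
        self.out_activation = out_activation
        self.dropout = float(dropout)
        self.rng = np.random.default_rng(seed)
        self.W: list[np.ndarray] = []
        self.b: list[np.ndarray] = []
        for n_in, n_out in zip(self.sizes[:-1], self.sizes[1:]):
            # He initialisation, suited to the ReLU hidden layers
            scale = np.sqrt(2.0 / n_in)
            self.W.append(self.rng.normal(0.0, scale, size=(n_in, n_out)))
            self.b.append(np.zeros(n_out))

    # -- low-level API -----------------------------------------------------

    def forward(self, X: np.ndarray, train: bool = False):
        """Return (output, cache).  Dropout is applied only when training."""
        A = np.asarray(X, dtype=np.float64)
        activations = [A]
        masks: list[np.ndarray | None] = []
        L = len(self.W)
        for i in range(L):
            Z = A @ self.W[i] + self.b[i]
            if i < L - 1:
                A = np.maximum(Z, 0.0)
                if train and self.dropout > 0.0:
                    mask = (self.rng.random(A.shape) >= self.dropout) / (1.0 - self.dropout)
                    A = A * mask
                    masks.append(mask)
                else:
                    masks.append(None)
            else:
                if self.out_activation == "sigmoid":
                    A = 1.0 / (1.0 + np.exp(-Z))
                else:
                    Zs = Z - Z.max(axis=1, keepdims=True)
                    e = np.exp(Zs)
                    A = e / e.sum(axis=1, keepdims=True)
            activations.append(A)
        return activations[-1], (activations, masks)

    def backward(self, cache, delta_out: np.ndarray):
        """Backpropagate from d(loss)/d(pre-activation of output layer).

        Returns ``(grads_W, grads_b, dX)``.
        """
        activations, masks = cache
        grads_W = [np.empty(0)] * len(self.W)
        grads_b = [np.empty(0)] * len(self.b)
        delta = delta_out
        for i in range(len(self.W) - 1, -1, -1):
            A_prev = activations[i]
            grads_W[i] = A_prev.T @ delta
            grads_b[i] = delta.sum(axis=0)
            if i > 0:
                delta = delta @ self.W[i].T
                if masks[i - 1] is not None:
                    delta = delta * masks[i - 1]
                delta = delta * (activations[i] > 0.0)
        dX = delta @ self.W[0].T
        return grads_W, grads_b, dX

    def loss_and_delta(self, out: np.ndarray, y: np.ndarray):
        """Mean loss and output-layer delta for BCE (sigmoid) or CE (softmax)."""
        n = out.shape[0]
        eps = 1e-12
        if self.out_activation == "sigmoid":
            y = np.asarray(y, dtype=np.float64).reshape(out.shape)
            loss = -np.mean(y * np.log(out + eps) + (1 - y) * np.log(1 - out + eps))
            delta = (out - y) / n
        else:
            y = np.asarray(y, dtype=np.int64)
            loss = -np.mean(np.log(out[np.arange(n), y] + eps))
            delta = out.copy()
            delta[np.arange(n), y] -= 1.0
            delta /= n
        return loss, delta

    def params(self) -> list[np.ndarray]:
        return self.W + self.b

    # -- training ----------------------------------------------------------

    def fit(
        self,
        X: np.ndarray,
        y: np.ndarray,
        epochs: int = 200,
        lr: float = 1e-3,
        batch_size: int = 32,
    ) -> list[float]:
        """Mini-batch Adam training; returns the per-epoch mean loss."""
        X = np.asarray(X, dtype=np.float64)
        y = np.asarray(y)
        n = X.shape[0]
        opt = Adam(self.params(), lr=lr)
        history: list[float] = []
        for _ in range(epochs):
            order = self.rng.permutation(n)
            losses = []
            for start in range(0, n, batch_size):
                idx = order[start : start + batch_size]
                out, cache = self.forward(X[idx], train=True)
                loss, delta = self.loss_and_delta(out, y[idx])
                gW, gb, _ = self.backward(cache, delta)
                opt.step(self.params(), gW + gb)
                losses.append(loss)
            history.append(float(np.mean(losses)))
        return history

    def predict_proba(self, X: np.ndarray) -> np.ndarray:
        out, _ = self.forward(np.asarray(X, dtype=np.float64), train=False)
        return out
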