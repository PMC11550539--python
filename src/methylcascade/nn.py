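"""Minimal deterministic feed-forward networks.

Fully-connected MLPs with ReLU hidden activations, inverted dropout, L1
weight penalty and Adam, trained full- or mini-batch. Written directly on
numpy so that every weight is reproducible from the seed alone: all
randomness (initialization, shuffling, dropout masks) comes from one
``numpy.random.Generator``.

Output heads: ``sigmoid`` (binary, binary cross-entropy) or ``softmax``
(multiclass, categorical cross-entropy).
"""

from __future__ import annotations

import numpy as np


def _relu(x):
    return np.maximum(x, 0.0)


def _sigmoid(x):
    return 0.5 * (1.0 + np.tanh(0.5 * x))  # numerically stable


def _softmax(x):
    z = x - x.max(axis=1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=1, keepdims=True)


class MlpNet:
    """One feed-forward network.

    Parameters mirror the training recipe of the cascade: hidden layer
    widths, learning rate, epochs, dropout fraction, L1 penalty, output
    head and seed.
    """

    def __init__(
        self,
        hidden_widths,
        out_dim: int,
        output: str = "softmax",
        learning_rate: float = 1e-3,
        epochs: int = 100,
        dropout: float = 0.0,
        l1: float = 0.0,
        batch_size: int | None = 64,
        seed: int = 0,
    ):
        if output not in ("sigmoid", "softmax"):
            raise ValueError("output must be 'sigmoid' or 'softmax'")
        if not (0 <= dropout < 1):
            raise ValueError("dropout must be in [0, 1)")
        if epochs < 1:
            raise ValueError("epochs must be >= 1")
        if any(w <= 0 for w in hidden_widths):
            raise ValueError("hidden widths must be positive")
        self.hidden_widths = list(hidden_widths)
        self.out_dim = out_dim
        self.output = output
        self.learning_rate = learning_rate
        self.epochs = epochs
        self.dropout = dropout
        self.l1 = l1
        self.batch_size = batch_size
        self.seed = seed

    # -- core ------------------------------------------------------------

    def _init_params(self, n_in: int, rng: np.random.Generator):
        dims = [n_in] + self.hidden_widths + [self.out_dim]
        self.weights_ = []
        self.biases_ = []
        for d_in, d_out in zip(dims[:-1], dims[1:]):
            scale = np.sqrt(2.0 / d_in)  # He init for ReLU stacks
            self.weights_.append(rng.normal(0.0, scale, size=(d_in, d_out)))
            self.biases_.append(np.zeros(d_out))

    def _forward(self, X, rng=None):
        """Forward pass; if ``rng`` is given, apply inverted dropout to
        hidden activations and return caches for backprop."""
        acts = [X]
        masks = []
        h = X
        for i, (W, b) in enumerate(zip(self.weights_, self.biases_)):
            z = h @ W + b
            if i < len(self.weights_) - 1:
                h = _relu(z)
                if rng is not None and self.dropout > 0:
                    mask = (rng.random(h.shape) >= self.dropout) / (1 - self.dropout)
                    h = h * mask
                    masks.append(mask)
                else:
                    masks.append(None)
            else:
                h = _sigmoid(z) if self.output == "sigmoid" else _softmax(z)
            acts.append(h)
        return acts, masks

    def fit(self, X, y) -> "MlpNet":
        X = np.asarray(X, dtype=float)
        y = np.asarray(y)
        if self.output == "sigmoid":
            T = y.reshape(-1, 1).astype(float)
        else:
            if y.ndim == 1:
                T = np.zeros((len(y), self.out_dim))
                T[np.arange(len(y)), y.astype(int)] = 1.0
            else:
                T = y.astype(float)
        n = len(X)
        rng = np.random.default_rng(self.seed)
        self._init_params(X.shape[1], rng)

        lr = self.learning_rate
        b1, b2, eps = 0.9, 0.999, 1e-8
        m = [np.zeros_like(W) for W in self.weights_] + [np.zeros_like(b) for b in self.biases_]
        v = [np.zeros_like(W) for W in self.weights_] + [np.zeros_like(b) for b in self.biases_]
        step = 0
        bs = self.batch_size or n
        for _ in range(self.epochs):
            order = rng.permutation(n)
            for start in range(0, n, bs):
                idx = order[start : start + bs]
                Xb, Tb = X[idx], T[idx]
                acts, masks = self._forward(Xb, rng=rng)
                # Cross-entropy + sigmoid/softmax: output delta is (p - t)/B.
                delta = (acts[-1] - Tb) / len(Xb)
                grads_W = [None] * len(self.weights_)
                grads_b = [None] * len(self.biases_)
                for i in range(len(self.weights_) - 1, -1, -1):
                    grads_W[i] = acts[i].T @ delta + self.l1 * np.sign(self.weights_[i])
                    grads_b[i] = delta.sum(axis=0)
                    if i > 0:
                        delta = delta @ self.weights_[i].T
                        if masks[i - 1] is not None:
                            delta = delta * masks[i - 1]
                        delta = delta * (acts[i] > 0)
                step += 1
                params = self.weights_ + self.biases_
                grads = grads_W + grads_b
                for j, (p, g) in enumerate(zip(params, grads)):
                    m[j] = b1 * m[j] + (1 - b1) * g
                    v[j] = b2 * v[j] + (1 - b2) * g * g
                    mhat = m[j] / (1 - b1 ** step)
                    vhat = v[j] / (1 - b2 ** step)
                    p -= lr * mhat / (np.sqrt(vhat) + eps)
        return self

    def predict_proba(self, X) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        if np.isnan(X).any():
            raise ValueError("input contains NaN; impute before scoring")
        acts, _ = self._forward(X, rng=None)
        return acts[-1]

    # -- serialization ---------------------------------------------------

    def spec_dict(self) -> dict:
        return {
            "hidden_widths": self.hidden_widths,
            "out_dim": self.out_dim,
            "output": self.output,
            "learning_rate": self.learning_rate,
            "epochs": self.epochs,
            "dropout": self.dropout,
            "l1": self.l1,
            "batch_size": self.batch_size,
            "seed": self.seed,
        }

    def weight_arrays(self, prefix: str) -> dict:
        arrays = {}
        for i, (W, b) in enumerate(zip(self.weights_, self.biases_)):
            arrays[f"{prefix}W{i}"] = W
            arrays[f"{prefix}b{i}"] = b
        return arrays

    @classmethod
    def from_arrays(cls, spec: dict, arrays, prefix: str) -> "MlpNet":
        net = cls(**spec)
        net.weights_ = []
        net.biases_ = []
        i = 0
        while f"{prefix}W{i}" in arrays:
            net.weights_.append(np.asarray(arrays[f"{prefix}W{i}"]))
            net.biases_.append(np.asarray(arrays[f"{prefix}b{i}"]))
            i += 1
        return net
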