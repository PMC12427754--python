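"""Compact feed-forward binary classifiers (shallow NN and deeper DNN).

A numpy multilayer perceptron with one or two ReLU hidden layers, inverted
dropout after each hidden layer, a sigmoid output unit, Adam optimization of
binary cross-entropy, Glorot-uniform weight initialization, and early
stopping on validation loss (patience 5, best weights restored). The
architecture and training configuration follow the tuned search space used
throughout the pipeline: hidden units {64, 128}, dropout {0.1, 0.3},
learning rate {0.001, 0.0005}, epochs {20, 30}, batch size {32, 64}.

The class exposes the scikit-learn-style ``fit`` / ``predict_proba``
surface the rest of the pipeline expects, plus input gradients used by the
integrated-gradients attribution backend.
"""

from __future__ import annotations

import numpy as np


def _glorot_uniform(rng: np.random.Generator, fan_in: int, fan_out: int) -> np.ndarray:
    limit = np.sqrt(6.0 / (fan_in + fan_out))
    return rng.uniform(-limit, limit, size=(fan_in, fan_out))


class MLPBinaryClassifier:
    """MLP with ``n_hidden_layers`` in {1, 2} ReLU layers + dropout, sigmoid output."""

    def __init__(
        self,
        n_hidden_layers: int = 1,
        hidden_units: int = 64,
        dropout: float = 0.1,
        learning_rate: float = 0.001,
        epochs: int = 20,
        batch_size: int = 32,
        patience: int = 5,
        validation_fraction: float = 0.1,
        beta1: float = 0.9,
        beta2: float = 0.999,
        eps: float = 1e-7,
        seed: int = 42,
    ) -> None:
        if n_hidden_layers not in (1, 2):
            raise ValueError("n_hidden_layers must be 1 or 2")
        self.n_hidden_layers = n_hidden_layers
        self.hidden_units = hidden_units
        self.dropout = dropout
        self.learning_rate = learning_rate
        self.epochs = epochs
        self.batch_size = batch_size
        self.patience = patience
        self.validation_fraction = validation_fraction
        self.beta1, self.beta2, self.eps = beta1, beta2, eps
        self.seed = seed
        self.weights_: list[np.ndarray] | None = None
        self.biases_: list[np.ndarray] | None = None

    # architecture introspection used by tests
    @property
    def layer_sizes(self) -> list[int]:
        if self.weights_ is None:
            raise RuntimeError("not fitted")
        return [w.shape[0] for w in self.weights_] + [1]

    def _init_params(self, n_features: int, rng: np.random.Generator) -> None:
        sizes = [n_features] + [self.hidden_units] * self.n_hidden_layers + [1]
        self.weights_ = [_glorot_uniform(rng, sizes[i], sizes[i + 1]) for i in range(len(sizes) - 1)]
        self.biases_ = [np.zeros(sizes[i + 1]) for i in range(len(sizes) - 1)]

    def _forward(
        self, X: np.ndarray, rng: np.random.Generator | None = None
    ) -> tuple[np.ndarray, list[np.ndarray], list[np.ndarray]]:
        """Returns (prob, activations per layer, dropout masks). Dropout only when rng given."""
        a = X
        activations = [a]
        masks = []
        for layer in range(self.n_hidden_layers):
            z = a @ self.weights_[layer] + self.biases_[layer]
            a = np.maximum(z, 0.0)
            if rng is not None and self.dropout > 0:
                mask = (rng.random(a.shape) >= self.dropout) / (1.0 - self.dropout)
                a = a * mask
            else:
                mask = np.ones_like(a)
            masks.append(mask)
            activations.append(a)
        z_out = a @ self.weights_[-1] + self.biases_[-1]
        p = 1.0 / (1.0 + np.exp(-np.clip(z_out, -60, 60)))
        return p.ravel(), activations, masks

    @staticmethod
    def _bce(p: np.ndarray, y: np.ndarray) -> float:
        p = np.clip(p, 1e-12, 1 - 1e-12)
        return float(-np.mean(y * np.log(p) + (1 - y) * np.log(1 - p)))

    def fit(self, X: np.ndarray, y: np.ndarray) -> "MLPBinaryClassifier":
        X = np.asarray(X, dtype=float)
        y = np.asarray(y, dtype=float).ravel()
        rng = np.random.default_rng(self.seed)
        self._init_params(X.shape[1], rng)

        n = X.shape[0]
        n_val = max(1, int(round(self.validation_fraction * n))) if n >= 10 else 0
        perm = rng.permutation(n)
        val_idx, tr_idx = perm[:n_val], perm[n_val:]
        Xtr, ytr = X[tr_idx], y[tr_idx]
        Xval, yval = X[val_idx], y[val_idx]

        m = [np.zeros_like(w) for w in self.weights_] + [np.zeros_like(b) for b in self.biases_]
        v = [np.zeros_like(w) for w in self.weights_] + [np.zeros_like(b) for b in self.biases_]
        t = 0
        best_loss = np.inf
        best_params = None
        patience_left = self.patience

        for _epoch in range(self.epochs):
            order = rng.permutation(Xtr.shape[0])
            for start in range(0, Xtr.shape[0], self.batch_size):
                batch = order[start:start + self.batch_size]
                if batch.size == 0:
                    continue
                xb, yb = Xtr[batch], ytr[batch]
                p, acts, masks = self._forward(xb, rng=rng)
                # gradient of mean BCE w.r.t. pre-sigmoid output is (p - y)/B
                delta = ((p - yb) / batch.size)[:, None]
                grads_w = [None] * len(self.weights_)
                grads_b = [None] * len(self.biases_)
                grads_w[-1] = acts[-1].T @ delta
                grads_b[-1] = delta.sum(axis=0)
                back = delta @ self.weights_[-1].T
                for layer in range(self.n_hidden_layers - 1, -1, -1):
                    back = back * masks[layer] * (acts[layer + 1] > 0)
                    grads_w[layer] = acts[layer].T @ back
                    grads_b[layer] = back.sum(axis=0)
                    if layer > 0:
                        back = back @ self.weights_[layer].T
                t += 1
                params = self.weights_ + self.biases_
                grads = grads_w + grads_b
                for i, (prm, g) in enumerate(zip(params, grads)):
                    m[i] = self.beta1 * m[i] + (1 - self.beta1) * g
                    v[i] = self.beta2 * v[i] + (1 - self.beta2) * g * g
                    mhat = m[i] / (1 - self.beta1**t)
                    vhat = v[i] / (1 - self.beta2**t)
                    prm -= self.learning_rate * mhat / (np.sqrt(vhat) + self.eps)

            if n_val:
                val_p, _, _ = self._forward(Xval)
                loss = self._bce(val_p, yval)
                if loss < best_loss - 1e-9:
                    best_loss = loss
                    best_params = (
                        [w.copy() for w in self.weights_],
                        [b.copy() for b in self.biases_],
                    )
                    patience_left = self.patience
                else:
                    patience_left -= 1
                    if patience_left <= 0:
                        break
        if best_params is not None:
            self.weights_, self.biases_ = best_params
        return self

    def predict_proba(self, X: np.ndarray) -> np.ndarray:
        p, _, _ = self._forward(np.asarray(X, dtype=float))
        return np.column_stack([1.0 - p, p])

    def predict(self, X: np.ndarray) -> np.ndarray:
        return (self.predict_proba(X)[:, 1] >= 0.5).astype(int)

    def input_gradients(self, X: np.ndarray) -> np.ndarray:
        """d p(cancer) / d x for each row (dropout off)."""
        if self.weights_ is None:
            raise RuntimeError("not fitted")
        X = np.asarray(X, dtype=float)
        p, acts, _ = self._forward(X)
        back = (p * (1.0 - p))[:, None] @ self.weights_[-1].T  # sigmoid derivative chain
        for layer in range(self.n_hidden_layers - 1, -1, -1):
            back = back * (acts[layer + 1] > 0)
            back = back @ self.weights_[layer].T
        return back
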