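"""A compact LSTM sequence classifier in plain numpy.

Single LSTM layer (32 hidden units by default) read out at the last time
step by a dense layer with a sigmoid output per class (10 classes by
default), trained with elementwise binary cross-entropy on one-hot targets
via full backpropagation-through-time and Adam.  A softmax/cross-entropy
head is available behind ``output="softmax"``.  Training is fully
deterministic given the seed (weight init and minibatch shuffling share one
generator).

The implementation is intentionally self-contained and is verified against
numerical gradients in the test suite.
"""

from __future__ import annotations

import numpy as np

__all__ = ["LSTMClassifier"]


def _sigmoid(x: np.ndarray) -> np.ndarray:
    out = np.empty_like(x)
    pos = x >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-x[pos]))
    ex = np.exp(x[~pos])
    out[~pos] = ex / (1.0 + ex)
    return out


class LSTMClassifier:
    """LSTM + dense head over fixed-length feature sequences.

    Parameters
    ----------
    n_features : per-step input dimensionality.
    n_classes : output dimensionality (dense/sigmoid head size).
    hidden_units : LSTM state size.
    epochs, learning_rate, batch_size : Adam training schedule.
    output : "sigmoid" (elementwise BCE) or "softmax" (cross-entropy).
    seed : controls weight init and shuffling; fixes every prediction.
    """

    def __init__(
        self,
        n_features: int,
        n_classes: int = 10,
        hidden_units: int = 32,
        epochs: int = 500,
        learning_rate: float = 1e-3,
        batch_size: int = 32,
        output: str = "sigmoid",
        seed: int = 0,
    ):
        if output not in ("sigmoid", "softmax"):
            raise ValueError(f"unknown output head {output!r}")
        self.n_features = n_features
        self.n_classes = n_classes
        self.hidden_units = hidden_units
        self.epochs = epochs
        self.learning_rate = learning_rate
        self.batch_size = batch_size
        self.output = output
        self.seed = seed
        self._rng = np.random.default_rng(seed)
        self._init_weights()
        self.history_: list[float] = []

    # -- parameters -------------------------------------------------------

    def _init_weights(self) -> None:
        d, h, c = self.n_features, self.hidden_units, self.n_classes
        rng = self._rng

        def glorot(fan_in, fan_out, shape):
            lim = np.sqrt(6.0 / (fan_in + fan_out))
            return rng.uniform(-lim, lim, size=shape)

        self.Wx = glorot(d, h, (d, 4 * h))
        self.Wh = glorot(h, h, (h, 4 * h))
        self.b = np.zeros(4 * h)
        self.b[h : 2 * h] = 1.0  # forget-gate bias
        self.Wy = glorot(h, c, (h, c))
        self.by = np.zeros(c)
        self._params = ["Wx", "Wh", "b", "Wy", "by"]
        self._adam_m = {p: np.zeros_like(getattr(self, p)) for p in self._params}
        self._adam_v = {p: np.zeros_like(getattr(self, p)) for p in self._params}
        self._adam_t = 0

    # -- forward / backward ----------------------------------------------

    def _forward(self, X: np.ndarray, cache: bool = False):
        """X: (B, T, d) -> logits (B, C); optionally keep per-step caches."""
        B, T, _ = X.shape
        h = self.hidden_units
        ht = np.zeros((B, h))
        ct = np.zeros((B, h))
        caches = []
        for t in range(T):
            z = X[:, t] @ self.Wx + ht @ self.Wh + self.b
            i = _sigmoid(z[:, :h])
            f = _sigmoid(z[:, h : 2 * h])
            g = np.tanh(z[:, 2 * h : 3 * h])
            o = _sigmoid(z[:, 3 * h :])
            c_prev = ct
            ct = f * c_prev + i * g
            tc = np.tanh(ct)
            if cache:
                caches.append((X[:, t], ht, c_prev, i, f, g, o, tc))
            ht = o * tc
        logits = ht @ self.Wy + self.by
        return (logits, ht, caches) if cache else logits

    def _loss_grad(self, logits: np.ndarray, y_onehot: np.ndarray):
        B, C = logits.shape
        if self.output == "sigmoid":
            p = _sigmoid(logits)
            eps = 1e-12
            loss = -np.mean(y_onehot * np.log(p + eps) + (1 - y_onehot) * np.log(1 - p + eps))
            dlogits = (p - y_onehot) / (B * C)
        else:
            m = logits - logits.max(axis=1, keepdims=True)
            e = np.exp(m)
            p = e / e.sum(axis=1, keepdims=True)
            loss = -np.mean(np.log(p[np.arange(B), y_onehot.argmax(axis=1)] + 1e-12))
            dlogits = (p - y_onehot) / B
        return float(loss), dlogits

    def _backward(self, dlogits, h_last, caches):
        h = self.hidden_units
        grads = {p: np.zeros_like(getattr(self, p)) for p in self._params}
        grads["Wy"] = h_last.T @ dlogits
        grads["by"] = dlogits.sum(axis=0)
        dh = dlogits @ self.Wy.T
        dc = np.zeros_like(h_last)
        for x_t, h_prev, c_prev, i, f, g, o, tc in reversed(caches):
            do = dh * tc
            dc = dc + dh * o * (1 - tc * tc)
            di = dc * g
            df = dc * c_prev
            dg = dc * i
            dc = dc * f
            dz = np.concatenate(
                [di * i * (1 - i), df * f * (1 - f), dg * (1 - g * g), do * o * (1 - o)],
                axis=1,
            )
            grads["Wx"] += x_t.T @ dz
            grads["Wh"] += h_prev.T @ dz
            grads["b"] += dz.sum(axis=0)
            dh = dz @ self.Wh.T
        return grads

    def _adam_step(self, grads, beta1=0.9, beta2=0.999, eps=1e-8):
        self._adam_t += 1
        lr = self.learning_rate
        t = self._adam_t
        for p in self._params:
            gm = self._adam_m[p]
            gv = self._adam_v[p]
            gm *= beta1
            gm += (1 - beta1) * grads[p]
            gv *= beta2
            gv += (1 - beta2) * grads[p] ** 2
            mhat = gm / (1 - beta1**t)
            vhat = gv / (1 - beta2**t)
            getattr(self, p).__isub__(lr * mhat / (np.sqrt(vhat) + eps))

    # -- public API -------------------------------------------------------

    def fit(self, X: np.ndarray, y: np.ndarray) -> "LSTMClassifier":
        """Train on sequences X (n, T, d) with integer class labels y (n,)."""
        X = np.asarray(X, dtype=float)
        y = np.asarray(y, dtype=int)
        if X.ndim != 3 or X.shape[2] != self.n_features:
            raise ValueError(f"expected (n, T, {self.n_features}) sequences, got {X.shape}")
        n = len(X)
        onehot = np.zeros((n, self.n_classes))
        onehot[np.arange(n), y] = 1.0
        for _ in range(self.epochs):
            order = self._rng.permutation(n)
            epoch_loss = 0.0
            for start in range(0, n, self.batch_size):
                idx = order[start : start + self.batch_size]
                logits, h_last, caches = self._forward(X[idx], cache=True)
                loss, dlogits = self._loss_grad(logits, onehot[idx])
                grads = self._backward(dlogits, h_last, caches)
                self._adam_step(grads)
                epoch_loss += loss * len(idx)
            self.history_.append(epoch_loss / n)
        return self

    def decision_scores(self, X: np.ndarray) -> np.ndarray:
        """Per-class scores in [0, 1]: sigmoid (or softmax) head outputs, (n, C)."""
        X = np.asarray(X, dtype=float)
        out = np.empty((len(X), self.n_classes))
        for start in range(0, len(X), 256):
            logits = self._forward(X[start : start + 256])
            if self.output == "sigmoid":
                out[start : start + 256] = _sigmoid(logits)
            else:
                m = logits - logits.max(axis=1, keepdims=True)
                e = np.exp(m)
                out[start : start + 256] = e / e.sum(axis=1, keepdims=True)
        return out

    def predict(self, X: np.ndarray) -> np.ndarray:
        return self.decision_scores(X).argmax(axis=1)
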