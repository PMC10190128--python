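"""A small, self-contained LSTM sequence classifier in numpy.

Implements the standard LSTM cell (input/forget/cell/output gates, forget
bias initialised to 1), a dropout + dense softmax head on the final hidden
state, cross-entropy loss, full backpropagation through time, and Adam.
Training is mini-batch with early stopping on validation accuracy.

The network is deliberately minimal — a few hundred cells of length ~10^2
per channel triple — and fully deterministic for a fixed seed, which is what
the pulse-classification experiments need.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["LSTMClassifier"]


def _sigmoid(x: np.ndarray) -> np.ndarray:
    out = np.empty_like(x)
    pos = x >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-x[pos]))
    ex = np.exp(x[~pos])
    out[~pos] = ex / (1.0 + ex)
    return out


def _softmax(z: np.ndarray) -> np.ndarray:
    z = z - z.max(axis=1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=1, keepdims=True)


@dataclass
class _Adam:
    lr: float
    beta1: float = 0.9
    beta2: float = 0.999
    eps: float = 1e-8
    t: int = 0
    m: dict = field(default_factory=dict)
    v: dict = field(default_factory=dict)

    def step(self, params: dict[str, np.ndarray],
             grads: dict[str, np.ndarray]) -> None:
        self.t += 1
        for k, g in grads.items():
            if k not in self.m:
                self.m[k] = np.zeros_like(g)
                self.v[k] = np.zeros_like(g)
            self.m[k] = self.beta1 * self.m[k] + (1 - self.beta1) * g
            self.v[k] = self.beta2 * self.v[k] + (1 - self.beta2) * g * g
            mhat = self.m[k] / (1 - self.beta1 ** self.t)
            vhat = self.v[k] / (1 - self.beta2 ** self.t)
            params[k] -= self.lr * mhat / (np.sqrt(vhat) + self.eps)


class LSTMClassifier:
    """Sequence classifier: LSTM -> dropout -> dense -> softmax.

    Parameters
    ----------
    input_dim : features per time step (e.g. 3 detector channels)
    hidden_units : LSTM state size
    n_classes : number of output classes
    learning_rate, batch_size : Adam step size and mini-batch size
    dropout : drop probability on the final hidden state during training
    max_epochs, patience : epoch cap and early-stopping patience on
        validation accuracy (best weights are restored)
    seed : seeds weight init, batch shuffling and dropout masks
    """

    def __init__(self, input_dim: int, hidden_units: int = 128,
                 n_classes: int = 2, learning_rate: float = 1e-3,
                 batch_size: int = 100, dropout: float = 0.2,
                 max_epochs: int = 50, patience: int = 5,
                 seed: int = 0) -> None:
        self.input_dim = input_dim
        self.hidden = hidden_units
        self.n_classes = n_classes
        self.lr = learning_rate
        self.batch_size = batch_size
        self.dropout = dropout
        self.max_epochs = max_epochs
        self.patience = patience
        self.seed = seed
        self.rng = np.random.default_rng(seed)
        self.params = self._init_params()
        self.history_: list[dict] = []

    def _init_params(self) -> dict[str, np.ndarray]:
        d, h, c = self.input_dim, self.hidden, self.n_classes
        rng = self.rng

        def glorot(shape: tuple[int, int]) -> np.ndarray:
            lim = np.sqrt(6.0 / sum(shape))
            return rng.uniform(-lim, lim, size=shape)

        b = np.zeros(4 * h)
        b[h:2 * h] = 1.0  # forget-gate bias
        return {
            "Wx": glorot((d, 4 * h)),
            "Wh": glorot((h, 4 * h)),
            "b": b,
            "Wy": glorot((h, c)),
            "by": np.zeros(c),
        }

    # -- forward / backward -------------------------------------------------

    def _forward(self, X: np.ndarray, train: bool = False,
                 drop_rng: np.random.Generator | None = None) -> dict:
        """X: (B, T, D). Returns cache with per-step activations."""
        p = self.params
        B, T, _ = X.shape
        h = self.hidden
        hs = np.zeros((T + 1, B, h))
        cs = np.zeros((T + 1, B, h))
        gates = np.empty((T, B, 4 * h))
        for t in range(T):
            z = X[:, t, :] @ p["Wx"] + hs[t] @ p["Wh"] + p["b"]
            i = _sigmoid(z[:, :h])
            f = _sigmoid(z[:, h:2 * h])
            g = np.tanh(z[:, 2 * h:3 * h])
            o = _sigmoid(z[:, 3 * h:])
            cs[t + 1] = f * cs[t] + i * g
            hs[t + 1] = o * np.tanh(cs[t + 1])
            gates[t] = np.concatenate([i, f, g, o], axis=1)
        h_last = hs[T]
        if train and self.dropout > 0:
            rng = drop_rng or self.rng
            mask = (rng.random(h_last.shape) >= self.dropout) / (1 - self.dropout)
        else:
            mask = np.ones_like(h_last)
        h_drop = h_last * mask
        logits = h_drop @ p["Wy"] + p["by"]
        probs = _softmax(logits)
        return {"X": X, "hs": hs, "cs": cs, "gates": gates,
                "mask": mask, "h_drop": h_drop, "probs": probs}

    def _backward(self, cache: dict, y: np.ndarray) -> dict[str, np.ndarray]:
        p = self.params
        X, hs, cs, gates = cache["X"], cache["hs"], cache["cs"], cache["gates"]
        B, T, _ = X.shape
        h = self.hidden

        dlogits = cache["probs"].copy()
        dlogits[np.arange(B), y] -= 1.0
        dlogits /= B

        grads = {
            "Wy": cache["h_drop"].T @ dlogits,
            "by": dlogits.sum(axis=0),
            "Wx": np.zeros_like(p["Wx"]),
            "Wh": np.zeros_like(p["Wh"]),
            "b": np.zeros_like(p["b"]),
        }
        dh = (dlogits @ p["Wy"].T) * cache["mask"]
        dc = np.zeros((B, h))
        for t in range(T - 1, -1, -1):
            i = gates[t][:, :h]
            f = gates[t][:, h:2 * h]
            g = gates[t][:, 2 * h:3 * h]
            o = gates[t][:, 3 * h:]
            tanh_c = np.tanh(cs[t + 1])
            do = dh * tanh_c
            dc = dc + dh * o * (1 - tanh_c ** 2)
            di = dc * g
            dg = dc * i
            df = dc * cs[t]
            dz = np.concatenate([
                di * i * (1 - i),
                df * f * (1 - f),
                dg * (1 - g ** 2),
                do * o * (1 - o),
            ], axis=1)
            grads["Wx"] += X[:, t, :].T @ dz
            grads["Wh"] += hs[t].T @ dz
            grads["b"] += dz.sum(axis=0)
            dh = dz @ p["Wh"].T
            dc = dc * f
        return grads

    def loss(self, X: np.ndarray, y: np.ndarray) -> float:
        probs = self._forward(X)["probs"]
        return float(-np.mean(np.log(probs[np.arange(len(y)), y] + 1e-300)))

    # -- training -----------------------------------------------------------

    def fit(self, X: np.ndarray, y: np.ndarray,
            X_val: np.ndarray | None = None,
            y_val: np.ndarray | None = None) -> "LSTMClassifier":
        X = np.asarray(X, dtype=float)
        y = np.asarray(y, dtype=int)
        opt = _Adam(lr=self.lr)
        shuffle_rng = np.random.default_rng(self.seed + 1)
        drop_rng = np.random.default_rng(self.seed + 2)
        best_acc, best_loss, best_params, stale = -1.0, np.inf, None, 0
        # stall guard: validation accuracy can sit at chance for many epochs
        # while the loss still falls, so an epoch counts as stale only when
        # neither the validation accuracy nor the validation loss improves
        for epoch in range(self.max_epochs):
            order = shuffle_rng.permutation(len(X))
            for s in range(0, len(X), self.batch_size):
                idx = order[s:s + self.batch_size]
                cache = self._forward(X[idx], train=True, drop_rng=drop_rng)
                if not np.all(np.isfinite(cache["probs"])):
                    raise FloatingPointError(
                        f"training diverged (non-finite loss) at epoch {epoch}"
                    )
                grads = self._backward(cache, y[idx])
                opt.step(self.params, grads)
            rec = {"epoch": epoch,
                   "train_accuracy": self.score(X, y)}
            if X_val is not None and len(X_val):
                acc = self.score(X_val, y_val)
                loss = self.loss(X_val, y_val)
                rec["val_accuracy"] = acc
                improved = acc > best_acc + 1e-12
                if improved or (acc >= best_acc - 1e-12
                                and loss < best_loss - 1e-9):
                    best_params = {k: v.copy() for k, v in self.params.items()}
                if improved or loss < best_loss - 1e-9:
                    stale = 0
                else:
                    stale += 1
                best_acc = max(best_acc, acc)
                best_loss = min(best_loss, loss)
                self.history_.append(rec)
                if stale >= self.patience:
                    break
            else:
                self.history_.append(rec)
        if best_params is not None:
            self.params = best_params
        return self

    def predict_proba(self, X: np.ndarray) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        out = []
        for s in range(0, len(X), 512):
            out.append(self._forward(X[s:s + 512])["probs"])
        return np.concatenate(out) if out else np.empty((0, self.n_classes))

    def predict(self, X: np.ndarray) -> np.ndarray:
        return self.predict_proba(X).argmax(axis=1)

    def score(self, X: np.ndarray, y: np.ndarray) -> float:
        return float(np.mean(self.predict(X) == np.asarray(y)))
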