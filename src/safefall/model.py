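"""Two-layer LSTM binary classifier, implemented in NumPy.

Architecture (defaults): LSTM(100, return sequences) -> LSTM(100) ->
dropout(0.3) -> dense(1, sigmoid). The cell uses the usual four gates
(input, forget, candidate, output); gates take logistic sigmoids, while the
candidate and cell-output nonlinearity is configurable (``relu`` by default,
``tanh`` available). Training minimizes natural-log binary cross entropy with
the Adam optimizer, full backpropagation through time, inverted dropout, and
global-norm gradient clipping (a numerical safeguard — relu cells can
otherwise blow up early in training).

Everything is seeded: weight initialization (Glorot-uniform input kernels,
orthogonal recurrent kernels, unit forget-gate bias), dropout masks, and the
optional batch shuffling. On a fixed platform a fixed seed reproduces
training bit-for-bit.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np

from .errors import ConfigurationError, DataError

_ACTIVATIONS = {"relu", "tanh"}


@dataclass(frozen=True)
class ModelConfig:
    """All architecture and training hyperparameters.

    Defaults are the reference setting: two stacked LSTM layers of 100 units,
    one dropout of 0.3 after the second layer, Adam at learning rate 0.001,
    binary cross entropy, 50 epochs with batches of 64, sigmoid output with a
    0.5 decision threshold.
    """

    lstm_units: int = 100
    num_lstm_layers: int = 2
    dropout: float = 0.3
    epochs: int = 50
    batch_size: int = 64
    learning_rate: float = 0.001
    optimizer: str = "adam"
    loss: str = "binary_crossentropy"
    hidden_activation: str = "relu"
    output_activation: str = "sigmoid"
    decision_threshold: float = 0.5
    shuffle_batches: bool = False
    grad_clip_norm: float = 5.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.dropout < 1.0:
            raise ConfigurationError(f"dropout must be in [0, 1), got {self.dropout}")
        for name in ("lstm_units", "num_lstm_layers", "epochs", "batch_size"):
            if getattr(self, name) < 1:
                raise ConfigurationError(f"{name} must be a positive integer")
        if self.learning_rate <= 0:
            raise ConfigurationError("learning_rate must be positive")
        if self.hidden_activation not in _ACTIVATIONS:
            raise ConfigurationError(
                f"hidden_activation must be one of {sorted(_ACTIVATIONS)}"
            )
        if self.optimizer != "adam":
            raise ConfigurationError("only the adam optimizer is supported")
        if self.loss not in {"binary_crossentropy", "binary cross entropy"}:
            raise ConfigurationError("only binary cross entropy loss is supported")
        if self.output_activation != "sigmoid":
            raise ConfigurationError("output activation must be sigmoid")
        if not 0.0 < self.decision_threshold < 1.0:
            raise ConfigurationError("decision_threshold must be in (0, 1)")


@dataclass
class TrainingHistory:
    train_loss: list[float] = field(default_factory=list)
    train_acc: list[float] = field(default_factory=list)
    val_loss: list[float] = field(default_factory=list)
    val_acc: list[float] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.train_loss)

    def to_csv(self, path: str | Path) -> Path:
        import pandas as pd

        df = pd.DataFrame(
            {
                "epoch": np.arange(1, len(self) + 1),
                "train_loss": self.train_loss,
                "train_acc": self.train_acc,
                "val_loss": self.val_loss,
                "val_acc": self.val_acc,
            }
        )
        path = Path(path)
        df.to_csv(path, index=False)
        return path


def _sigmoid(z: np.ndarray) -> np.ndarray:
    out = np.empty_like(z)
    pos = z >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-z[pos]))
    ez = np.exp(z[~pos])
    out[~pos] = ez / (1.0 + ez)
    return out


def _act(z: np.ndarray, kind: str) -> np.ndarray:
    return np.maximum(z, 0.0) if kind == "relu" else np.tanh(z)


def _act_grad_from_output(a: np.ndarray, kind: str) -> np.ndarray:
    # derivative expressed through the activation *output* (valid for both)
    return (a > 0).astype(a.dtype) if kind == "relu" else 1.0 - a * a


def _glorot_uniform(rng: np.random.Generator, fan_in: int, fan_out: int) -> np.ndarray:
    limit = np.sqrt(6.0 / (fan_in + fan_out))
    return rng.uniform(-limit, limit, size=(fan_in, fan_out))


def _orthogonal(rng: np.random.Generator, rows: int, cols: int) -> np.ndarray:
    a = rng.standard_normal((max(rows, cols), min(rows, cols)))
    q, r = np.linalg.qr(a)
    q *= np.sign(np.diag(r))
    return q[:rows, :cols] if q.shape[0] >= rows else q.T[:rows, :cols]


class _LSTMLayer:
    """One LSTM layer. Gate order along the 4H axis: input, forget,
    candidate, output (i, f, g, o)."""

    def __init__(self, input_dim: int, units: int, activation: str,
                 rng: np.random.Generator) -> None:
        self.input_dim = input_dim
        self.units = units
        self.activation = activation
        H = units
        self.Wx = np.hstack(
            [_glorot_uniform(rng, input_dim, H) for _ in range(4)]
        )  # (D, 4H)
        self.Wh = np.hstack([_orthogonal(rng, H, H) for _ in range(4)])  # (H, 4H)
        self.b = np.zeros(4 * H)
        self.b[H:2 * H] = 1.0  # unit forget-gate bias

    @property
    def param_count(self) -> int:
        return self.Wx.size + self.Wh.size + self.b.size

    def params(self) -> list[np.ndarray]:
        return [self.Wx, self.Wh, self.b]

    def forward(self, X: np.ndarray, cache: bool = False):
        """X: (n, T, D) -> outputs (n, T, H); optionally keep the per-step
        cache needed for backpropagation through time."""
        n, T, D = X.shape
        H = self.units
        h = np.zeros((n, H))
        c = np.zeros((n, H))
        Hs = np.empty((n, T, H))
        caches = [] if cache else None
        for t in range(T):
            x_t = X[:, t, :]
            z = x_t @ self.Wx + h @ self.Wh + self.b
            i = _sigmoid(z[:, :H])
            f = _sigmoid(z[:, H:2 * H])
            g = _act(z[:, 2 * H:3 * H], self.activation)
            o = _sigmoid(z[:, 3 * H:])
            c_prev = c
            c = f * c_prev + i * g
            ac = _act(c, self.activation)
            h = o * ac
            Hs[:, t, :] = h
            if cache:
                caches.append((x_t, i, f, g, o, c_prev, c, ac))
        if cache:
            return Hs, caches
        return Hs

    def backward(self, X: np.ndarray, caches, dHs: np.ndarray):
        """dHs: (n, T, H) gradient w.r.t. every step's output (zero rows for
        steps that feed nothing downstream). Returns (dX, [dWx, dWh, db])."""
        n, T, D = X.shape
        H = self.units
        dWx = np.zeros_like(self.Wx)
        dWh = np.zeros_like(self.Wh)
        db = np.zeros_like(self.b)
        dX = np.empty_like(X)
        dh_next = np.zeros((n, H))
        dc_next = np.zeros((n, H))
        Wh_T = self.Wh.T
        Wx_T = self.Wx.T
        for t in range(T - 1, -1, -1):
            x_t, i, f, g, o, c_prev, c, ac = caches[t]
            dh = dHs[:, t, :] + dh_next
            do = dh * ac
            dc = dc_next + dh * o * _act_grad_from_output(ac, self.activation)
            di = dc * g
            df = dc * c_prev
            dg = dc * i
            dc_next = dc * f
            dz = np.empty((n, 4 * H))
            dz[:, :H] = di * i * (1.0 - i)
            dz[:, H:2 * H] = df * f * (1.0 - f)
            dz[:, 2 * H:3 * H] = dg * _act_grad_from_output(g, self.activation)
            dz[:, 3 * H:] = do * o * (1.0 - o)
            if t == 0:
                h_prev_arr = np.zeros((n, H))
            else:
                # previous step's h = o_{t-1} * ac_{t-1}
                _, _, _, _, o_p, _, _, ac_p = caches[t - 1]
                h_prev_arr = o_p * ac_p
            dWx += x_t.T @ dz
            dWh += h_prev_arr.T @ dz
            db += dz.sum(axis=0)
            dX[:, t, :] = dz @ Wx_T
            dh_next = dz @ Wh_T
        return dX, [dWx, dWh, db]


class LSTMClassifier:
    """Stacked-LSTM binary classifier with a single sigmoid output unit."""

    def __init__(self, m: int, cfg: ModelConfig) -> None:
        if m < 1:
            raise ConfigurationError(f"feature count m must be >= 1, got {m}")
        self.m = m
        self.cfg = cfg
        rng = np.random.default_rng(cfg.seed)
        self.layers: list[_LSTMLayer] = []
        dim = m
        for _ in range(cfg.num_lstm_layers):
            self.layers.append(
                _LSTMLayer(dim, cfg.lstm_units, cfg.hidden_activation, rng)
            )
            dim = cfg.lstm_units
        self.w_out = _glorot_uniform(rng, dim, 1)[:, 0]
        self.b_out = 0.0
        self.trained = False

    # ---- parameter bookkeeping -------------------------------------------

    @property
    def param_count(self) -> int:
        """Total trainable parameter count."""
        return sum(l.param_count for l in self.layers) + self.w_out.size + 1

    def _params(self) -> list[np.ndarray]:
        out = []
        for l in self.layers:
            out.extend(l.params())
        out.append(self.w_out)
        return out

    # ---- forward ----------------------------------------------------------

    def _forward(self, X: np.ndarray, train: bool = False,
                 drop_rng: np.random.Generator | None = None):
        caches = []
        H = X
        for l in self.layers:
            H, cache = l.forward(H, cache=True)
            caches.append(cache)
        h_last = H[:, -1, :]
        if train and self.cfg.dropout > 0:
            keep = 1.0 - self.cfg.dropout
            mask = (drop_rng.random(h_last.shape) < keep) / keep
        else:
            mask = None
        h_drop = h_last if mask is None else h_last * mask
        logits = h_drop @ self.w_out + self.b_out
        scores = _sigmoid(logits)
        return scores, (caches, H, h_last, mask, h_drop)

    def predict_scores(self, X: np.ndarray) -> np.ndarray:
        X = self._check_input(X)
        scores, _ = self._forward(X, train=False)
        return scores

    def _check_input(self, X: np.ndarray) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        if X.ndim != 3 or X.shape[2] != self.m:
            raise DataError(
                f"expected input of shape (n, window_length, {self.m}), "
                f"got {X.shape}"
            )
        return X

    # ---- backward ---------------------------------------------------------

    def _backward(self, X: np.ndarray, y: np.ndarray, fwd):
        """Gradients of the mean batch BCE. Returns (grads, db_out) where
        grads aligns with :meth:`_params`."""
        caches, H_seq, h_last, mask, h_drop = fwd
        n = X.shape[0]
        logits = h_drop @ self.w_out + self.b_out
        p = _sigmoid(logits)
        dlogits = (p - y) / n  # mean BCE w.r.t. logits
        dw_out = h_drop.T @ dlogits
        db_out = dlogits.sum()
        dh_drop = np.outer(dlogits, self.w_out)
        dh_last = dh_drop if mask is None else dh_drop * mask
        grads_rev: list[np.ndarray] = []
        inputs = [X]
        # replay layer inputs: output of layer k is input of layer k+1
        for l_idx in range(len(self.layers) - 1):
            # reconstruct each step's h from the cache of that layer
            cache = caches[l_idx]
            T = len(cache)
            n_, H = cache[0][1].shape
            Hs = np.empty((n_, T, H))
            for t, (_, _, _, _, o, _, _, ac) in enumerate(cache):
                Hs[:, t, :] = o * ac
            inputs.append(Hs)
        T = X.shape[1]
        dHs = np.zeros((n, T, self.layers[-1].units))
        dHs[:, -1, :] = dh_last
        grad_pairs: list[list[np.ndarray]] = [None] * len(self.layers)
        for l_idx in range(len(self.layers) - 1, -1, -1):
            layer = self.layers[l_idx]
            dX, g = layer.backward(inputs[l_idx], caches[l_idx], dHs)
            grad_pairs[l_idx] = g
            dHs = dX
        grads: list[np.ndarray] = []
        for g in grad_pairs:
            grads.extend(g)
        grads.append(dw_out)
        return grads, db_out

    # ---- training ---------------------------------------------------------

    def fit(
        self,
        X_train: np.ndarray,
        y_train: np.ndarray,
        X_val: np.ndarray | None = None,
        y_val: np.ndarray | None = None,
    ) -> TrainingHistory:
        cfg = self.cfg
        X_train = self._check_input(X_train)
        y_train = np.asarray(y_train, dtype=float)
        if y_train.shape[0] != X_train.shape[0]:
            raise DataError("label count does not match window count")
        if X_val is not None:
            X_val = self._check_input(X_val)
            y_val = np.asarray(y_val, dtype=float)

        rng = np.random.default_rng(np.random.SeedSequence([cfg.seed, 1]))
        drop_rng = np.random.default_rng(np.random.SeedSequence([cfg.seed, 2]))
        params = self._params()
        m_adam = [np.zeros_like(p) for p in params]
        v_adam = [np.zeros_like(p) for p in params]
        mb = vb = 0.0  # Adam state for the output bias
        beta1, beta2, eps = 0.9, 0.999, 1e-7
        step = 0
        n = X_train.shape[0]
        history = TrainingHistory()
        for _epoch in range(cfg.epochs):
            order = (
                rng.permutation(n) if cfg.shuffle_batches else np.arange(n)
            )
            for start in range(0, n, cfg.batch_size):
                idx = order[start:start + cfg.batch_size]
                Xb, yb = X_train[idx], y_train[idx]
                scores, fwd = self._forward(Xb, train=True, drop_rng=drop_rng)
                grads, db_out = self._backward(Xb, yb, fwd)
                # global-norm gradient clipping
                total = np.sqrt(
                    sum(float((g * g).sum()) for g in grads) + db_out * db_out
                )
                if cfg.grad_clip_norm and total > cfg.grad_clip_norm:
                    scale = cfg.grad_clip_norm / total
                    grads = [g * scale for g in grads]
                    db_out *= scale
                step += 1
                lr_t = cfg.learning_rate * np.sqrt(1 - beta2**step) / (1 - beta1**step)
                for p, g, m_s, v_s in zip(params, grads, m_adam, v_adam):
                    m_s += (1 - beta1) * (g - m_s)
                    v_s += (1 - beta2) * (g * g - v_s)
                    p -= lr_t * m_s / (np.sqrt(v_s) + eps)
                mb += (1 - beta1) * (db_out - mb)
                vb += (1 - beta2) * (db_out * db_out - vb)
                self.b_out -= lr_t * mb / (np.sqrt(vb) + eps)
            tr_scores = self.predict_scores(X_train)
            history.train_loss.append(binary_cross_entropy(y_train, tr_scores))
            history.train_acc.append(
                float(((tr_scores >= cfg.decision_threshold) == (y_train == 1)).mean())
            )
            if X_val is not None:
                va_scores = self.predict_scores(X_val)
                history.val_loss.append(binary_cross_entropy(y_val, va_scores))
                history.val_acc.append(
                    float(
                        ((va_scores >= cfg.decision_threshold) == (y_val == 1)).mean()
                    )
                )
            else:
                history.val_loss.append(float("nan"))
                history.val_acc.append(float("nan"))
        self.trained = True
        return history

    # ---- persistence ------------------------------------------------------

    def save(self, out_dir: str | Path, feature_set: str | None = None) -> Path:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        arrays = {}
        for k, l in enumerate(self.layers):
            arrays[f"Wx{k}"] = l.Wx
            arrays[f"Wh{k}"] = l.Wh
            arrays[f"b{k}"] = l.b
        arrays["w_out"] = self.w_out
        arrays["b_out"] = np.array([self.b_out])
        np.savez(out / "weights.npz", **arrays)
        sidecar = {
            "m": self.m,
            "feature_set": feature_set,
            "trained": self.trained,
            "config": dataclasses.asdict(self.cfg),
        }
        (out / "model.json").write_text(json.dumps(sidecar, indent=2))
        return out

    @classmethod
    def load(cls, in_dir: str | Path) -> tuple["LSTMClassifier", str | None]:
        in_dir = Path(in_dir)
        sidecar = json.loads((in_dir / "model.json").read_text())
        cfg = ModelConfig(**sidecar["config"])
        model = cls(sidecar["m"], cfg)
        data = np.load(in_dir / "weights.npz")
        for k, l in enumerate(model.layers):
            l.Wx = data[f"Wx{k}"]
            l.Wh = data[f"Wh{k}"]
            l.b = data[f"b{k}"]
        model.w_out = data["w_out"]
        model.b_out = float(data["b_out"][0])
        model.trained = bool(sidecar["trained"])
        return model, sidecar.get("feature_set")


def binary_cross_entropy(
    y: np.ndarray, scores: np.ndarray, eps: float = 1e-12
) -> float:
    """Mean natural-log binary cross entropy (the training loss)."""
    s = np.clip(np.asarray(scores, dtype=float), eps, 1 - eps)
    y = np.asarray(y, dtype=float)
    return float(-(y * np.log(s) + (1 - y) * np.log(1 - s)).mean())


def lstm_param_count(m: int, units: int = 100, layers: int = 2) -> int:
    """Closed-form trainable-parameter count of the stacked architecture:
    4*(units*(in+units+1)) per LSTM layer plus (units+1) for the dense unit."""
    total = 0
    dim = m
    for _ in range(layers):
        total += 4 * (units * (dim + units + 1))
        dim = units
    return total + units + 1


def build_model(m: int, cfg: ModelConfig = ModelConfig()) -> LSTMClassifier:
    """Construct an untrained classifier for an m-feature window input."""
    return LSTMClassifier(m, cfg)


def train(
    model: LSTMClassifier,
    train_tensors: tuple[np.ndarray, np.ndarray],
    val_tensors: tuple[np.ndarray, np.ndarray] | None,
    cfg: ModelConfig | None = None,
) -> tuple[LSTMClassifier, TrainingHistory]:
    """Train in place and return (model, history)."""
    if cfg is not None and cfg != model.cfg:
        raise ConfigurationError("cfg must match the config the model was built with")
    Xv, yv = (None, None) if val_tensors is None else val_tensors
    history = model.fit(train_tensors[0], train_tensors[1], Xv, yv)
    return model, history


def predict(
    model: LSTMClassifier, inputs: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Scores in (0,1) and hard labels (1 iff score >= decision threshold)."""
    if not model.trained:
        raise DataError("model has not been trained")
    scores = model.predict_scores(inputs)
    labels = (scores >= model.cfg.decision_threshold).astype(int)
    return scores, labels
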