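"""Reduced-scale neural baselines for comparison with the linear transforms.

Two architectures mirror the structural choices of the deep-learning
reconstruction literature at desk scale:

* ``lstm`` — two stacked recurrent (LSTM) layers with tanh activations and a
  per-timestep linear head, trained with Adam/backpropagation-through-time on
  fixed-length windows.  Implemented in numpy; CPU-only and deliberately
  small.
* ``ffn`` — a committee of feed-forward networks (two tanh hidden layers and a
  linear output, i.e. three weight layers), default committee size 5; members
  are trained on identical data with different seeds and predictions are the
  unweighted mean of member outputs.  Backed by
  ``sklearn.neural_network.MLPRegressor``.

Both consume the same per-sample dataset objects as the linear pipelines and
predict in raw millivolts (inputs/outputs standardized internally with
training statistics).  These baselines are comparison scaffolding, not the
package's accuracy surface.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np

__all__ = ["DLConfig", "DLModel", "train_dl", "predict_dl", "DLPipeline"]


@dataclass(frozen=True)
class DLConfig:
    """Architecture and training hyperparameters for the neural baselines."""

    variant: str = "ffn"  # ffn | lstm
    hidden: int = 32
    n_committee: int = 5
    window: int = 500  # samples per BPTT window (lstm)
    epochs: int = 20
    batch_size: int = 256
    seed: int = 0
    learning_rate: float = 1e-3

    def __post_init__(self) -> None:
        if self.variant not in {"ffn", "lstm"}:
            raise ValueError(f"unknown DL variant {self.variant!r}")
        if self.n_committee < 1:
            raise ValueError("n_committee must be >= 1")
        if min(self.hidden, self.window, self.epochs, self.batch_size) < 1:
            raise ValueError("all sizes must be positive")


@dataclass
class _Standardizer:
    x_mean: np.ndarray
    x_scale: np.ndarray
    y_mean: np.ndarray
    y_scale: np.ndarray

    @classmethod
    def fit(cls, X: np.ndarray, Y: np.ndarray) -> "_Standardizer":
        xs = X.std(axis=0)
        ys = Y.std(axis=0)
        return cls(
            X.mean(axis=0), np.where(xs > 0, xs, 1.0),
            Y.mean(axis=0), np.where(ys > 0, ys, 1.0),
        )


@dataclass
class DLModel:
    config: DLConfig
    scaler: _Standardizer
    members: list = field(default_factory=list)  # MLPRegressor or _LSTMNet
    loss_curves: list[list[float]] = field(default_factory=list)


def _as_record_list(X, Y) -> tuple[list[np.ndarray], list[np.ndarray]]:
    if isinstance(X, np.ndarray):
        X, Y = [X], [Y]
    return [np.asarray(x, dtype=float) for x in X], [np.asarray(y, dtype=float) for y in Y]


def train_dl(X, Y, config: DLConfig = DLConfig()) -> DLModel:
    """Train one baseline on paired inputs/outputs.

    ``X`` and ``Y`` are (n_samples, n_channels) matrices or lists of them (one
    per record; the LSTM windows each record separately).  Raises
    ``FloatingPointError`` on non-finite training loss.
    """
    X_list, Y_list = _as_record_list(X, Y)
    if not X_list or any(x.size == 0 for x in X_list):
        raise ValueError("empty training dataset")
    X_all = np.vstack(X_list)
    Y_all = np.vstack(Y_list)
    scaler = _Standardizer.fit(X_all, Y_all)
    model = DLModel(config=config, scaler=scaler)
    if config.variant == "ffn":
        _train_ffn(model, X_all, Y_all)
    else:
        _train_lstm(model, X_list, Y_list)
    for curve in model.loss_curves:
        if not np.all(np.isfinite(curve)):
            raise FloatingPointError("training diverged (non-finite loss)")
    return model


def predict_dl(model: DLModel, X: np.ndarray) -> np.ndarray:
    """Per-sample predictions in mV; the committee output is the unweighted
    mean of member outputs."""
    X = np.asarray(X, dtype=float)
    if X.ndim != 2 or X.shape[1] != model.scaler.x_mean.size:
        raise ValueError(
            f"X has shape {X.shape}; model expects {model.scaler.x_mean.size} channels"
        )
    Xs = (X - model.scaler.x_mean) / model.scaler.x_scale
    if model.config.variant == "ffn":
        preds = [m.predict(Xs) for m in model.members]
    else:
        preds = [m.forward_sequence(Xs) for m in model.members]
    out = np.mean(preds, axis=0)
    if out.ndim == 1:
        out = out[:, None]
    return out * model.scaler.y_scale + model.scaler.y_mean


# ---------------------------------------------------------------------------
# FFN committee (sklearn)
# ---------------------------------------------------------------------------

def _train_ffn(model: DLModel, X_all: np.ndarray, Y_all: np.ndarray) -> None:
    from sklearn.neural_network import MLPRegressor

    cfg = model.config
    Xs = (X_all - model.scaler.x_mean) / model.scaler.x_scale
    Ys = (Y_all - model.scaler.y_mean) / model.scaler.y_scale
    for i in range(cfg.n_committee):
        member = MLPRegressor(
            hidden_layer_sizes=(cfg.hidden, cfg.hidden),
            activation="tanh",
            solver="adam",
            learning_rate_init=cfg.learning_rate,
            batch_size=min(cfg.batch_size, Xs.shape[0]),
            max_iter=cfg.epochs,
            random_state=cfg.seed + i,
            tol=0.0,
        )
        import warnings

        with warnings.catch_warnings():
            from sklearn.exceptions import ConvergenceWarning

            warnings.simplefilter("ignore", ConvergenceWarning)
            member.fit(Xs, Ys if Ys.shape[1] > 1 else Ys.ravel())
        model.members.append(member)
        model.loss_curves.append(list(member.loss_curve_))


# ---------------------------------------------------------------------------
# numpy LSTM
# ---------------------------------------------------------------------------

class _LSTMLayer:
    def __init__(self, n_in: int, n_hidden: int, rng: np.random.Generator):
        s = 1.0 / np.sqrt(n_hidden)
        self.W = rng.uniform(-s, s, (n_in, 4 * n_hidden))
        self.U = rng.uniform(-s, s, (n_hidden, 4 * n_hidden))
        self.b = np.zeros(4 * n_hidden)
        self.H = n_hidden

    def params(self):
        return [self.W, self.U, self.b]

    def forward(self, X: np.ndarray):
        """X: (T, n_in) -> hidden states (T, H) with cached gate activations."""
        T = X.shape[0]
        H = self.H
        h = np.zeros(H)
        c = np.zeros(H)
        hs = np.zeros((T, H))
        cache = []
        for t in range(T):
            z = X[t] @ self.W + h @ self.U + self.b
            i = _sigmoid(z[:H])
            f = _sigmoid(z[H : 2 * H])
            g = np.tanh(z[2 * H : 3 * H])
            o = _sigmoid(z[3 * H :])
            c_new = f * c + i * g
            h_new = o * np.tanh(c_new)
            cache.append((X[t], h, c, i, f, g, o, c_new))
            h, c = h_new, c_new
            hs[t] = h
        return hs, cache

    def backward(self, cache, d_hs: np.ndarray):
        """BPTT given upstream gradients on the hidden states."""
        T = len(cache)
        H = self.H
        dW = np.zeros_like(self.W)
        dU = np.zeros_like(self.U)
        db = np.zeros_like(self.b)
        dX = np.zeros((T, self.W.shape[0]))
        dh_next = np.zeros(H)
        dc_next = np.zeros(H)
        for t in range(T - 1, -1, -1):
            x_t, h_prev, c_prev, i, f, g, o, c_new = cache[t]
            dh = d_hs[t] + dh_next
            tanh_c = np.tanh(c_new)
            do = dh * tanh_c
            dc = dh * o * (1 - tanh_c**2) + dc_next
            di = dc * g
            df = dc * c_prev
            dg = dc * i
            dz = np.concatenate(
                [di * i * (1 - i), df * f * (1 - f), dg * (1 - g**2), do * o * (1 - o)]
            )
            dW += np.outer(x_t, dz)
            dU += np.outer(h_prev, dz)
            db += dz
            dX[t] = dz @ self.W.T
            dh_next = dz @ self.U.T
            dc_next = dc * f
        return [dW, dU, db], dX


def _sigmoid(x: np.ndarray) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-np.clip(x, -60, 60)))


class _LSTMNet:
    """Two stacked LSTM layers + per-timestep linear head."""

    def __init__(self, n_in: int, n_hidden: int, n_out: int, rng: np.random.Generator):
        self.layers = [_LSTMLayer(n_in, n_hidden, rng), _LSTMLayer(n_hidden, n_hidden, rng)]
        s = 1.0 / np.sqrt(n_hidden)
        self.W_out = rng.uniform(-s, s, (n_hidden, n_out))
        self.b_out = np.zeros(n_out)

    def params(self):
        out = []
        for layer in self.layers:
            out.extend(layer.params())
        out.extend([self.W_out, self.b_out])
        return out

    def forward_sequence(self, X: np.ndarray) -> np.ndarray:
        h = X
        for layer in self.layers:
            h, _ = layer.forward(h)
        return h @ self.W_out + self.b_out

    def loss_and_grads(self, X: np.ndarray, Y: np.ndarray):
        h1, cache1 = self.layers[0].forward(X)
        h2, cache2 = self.layers[1].forward(h1)
        pred = h2 @ self.W_out + self.b_out
        resid = pred - Y
        loss = float(np.mean(resid**2))
        d_pred = 2.0 * resid / resid.size
        dW_out = h2.T @ d_pred
        db_out = d_pred.sum(axis=0)
        d_h2 = d_pred @ self.W_out.T
        grads2, d_h1 = self.layers[1].backward(cache2, d_h2)
        grads1, _ = self.layers[0].backward(cache1, d_h1)
        return loss, grads1 + grads2 + [dW_out, db_out]


class _Adam:
    def __init__(self, params, lr: float):
        self.lr = lr
        self.m = [np.zeros_like(p) for p in params]
        self.v = [np.zeros_like(p) for p in params]
        self.t = 0

    def step(self, params, grads):
        self.t += 1
        b1, b2, eps = 0.9, 0.999, 1e-8
        for p, g, m, v in zip(params, grads, self.m, self.v):
            m *= b1
            m += (1 - b1) * g
            v *= b2
            v += (1 - b2) * g**2
            p -= self.lr * (m / (1 - b1**self.t)) / (np.sqrt(v / (1 - b2**self.t)) + eps)


def _train_lstm(model: DLModel, X_list, Y_list) -> None:
    cfg = model.config
    rng = np.random.default_rng(cfg.seed)
    n_in = X_list[0].shape[1]
    n_out = Y_list[0].shape[1]
    net = _LSTMNet(n_in, cfg.hidden, n_out, rng)
    windows = []
    for X, Y in zip(X_list, Y_list):
        Xs = (X - model.scaler.x_mean) / model.scaler.x_scale
        Ys = (Y - model.scaler.y_mean) / model.scaler.y_scale
        for start in range(0, X.shape[0], cfg.window):
            xw = Xs[start : start + cfg.window]
            if xw.shape[0] >= 2:
                windows.append((xw, Ys[start : start + cfg.window]))
    opt = _Adam(net.params(), cfg.learning_rate)
    curve = []
    for _ in range(cfg.epochs):
        order = rng.permutation(len(windows))
        epoch_loss = 0.0
        for w in order:
            loss, grads = net.loss_and_grads(*windows[w])
            opt.step(net.params(), grads)
            epoch_loss += loss
        curve.append(epoch_loss / len(windows))
    model.members.append(net)
    model.loss_curves.append(curve)


# ---------------------------------------------------------------------------
# pipeline adapter (same contract as the linear pipelines)
# ---------------------------------------------------------------------------

class DLPipeline:
    """make_pipeline adapter so neural baselines are interchangeable with the
    linear variants in cross-validation."""

    def __init__(self, config):
        from .linear import VARIANTS

        self.config = config
        self.input_names, self.output_names = VARIANTS[config.variant]
        self.dl_config = config.dl or DLConfig(variant=config.variant)
        if self.dl_config.variant != config.variant:
            self.dl_config = replace(self.dl_config, variant=config.variant)
        self.model: DLModel | None = None

    def clone(self) -> "DLPipeline":
        return DLPipeline(self.config)

    def build_input(self, item) -> np.ndarray:
        return item.record.subset(self.input_names)

    def build_target(self, item) -> np.ndarray:
        return item.record.subset(self.output_names)

    def fit(self, items: Sequence) -> "DLPipeline":
        if not items:
            raise ValueError("empty training set")
        X = [self.build_input(it) for it in items]
        Y = [self.build_target(it) for it in items]
        self.model = train_dl(X, Y, self.dl_config)
        return self

    def predict(self, item) -> np.ndarray:
        if self.model is None:
            raise RuntimeError("pipeline is not fitted")
        return predict_dl(self.model, self.build_input(item))
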