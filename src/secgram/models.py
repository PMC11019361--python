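"""Secretion classifiers and the training/evaluation regime.

Two families, as in the study design this package supports:

* classical models on tabular features (linear/RBF SVM, random forest with
  50 or 200 trees at depth 20), with class weights inversely proportional to
  sample frequency;
* deep sequence models on one-hot input — stacked GRU or LSTM layers reading
  out the final hidden state, and a VGG-style CNN (conv blocks with width-2
  max pooling, dense head 1024 -> 128) — trained with Adam (lr 0.001),
  weighted binary cross-entropy, L1+L2 penalties (lambda 1e-6), Xavier init,
  early stopping and learning-rate decay.

The GRU cell implements
    z_t = sigmoid(W_z x_t + U_z h_{t-1} + b_z)
    r_t = sigmoid(W_r x_t + U_r h_{t-1} + b_r)
    h'_t = tanh(W_h x_t + U_h (r_t * h_{t-1}) + b_h)
    h_t = (1 - z_t) * h_{t-1} + z_t * h'_t
and the LSTM cell
    i_t = sigmoid(W_i x_t + U_i h_{t-1} + b_i)
    f_t = sigmoid(W_f x_t + U_f h_{t-1} + b_f)
    o_t = sigmoid(W_o x_t + U_o h_{t-1} + b_o)
    c_t = f_t * c_{t-1} + i_t * tanh(W_c x_t + U_c h_{t-1} + b_c)
    h_t = o_t * tanh(c_t)
(elementwise products), with the sigmoid-transformed final linear output
read as the secretion probability.

All estimators follow the scikit-learn protocol (``fit`` / ``predict_proba``
/ ``get_params``) and compose with sklearn model selection.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from typing import Mapping

import numpy as np
from scipy.stats import rankdata
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.ensemble import RandomForestClassifier
from sklearn.metrics import average_precision_score
from sklearn.model_selection import train_test_split
from sklearn.svm import SVC
from sklearn.utils.validation import check_is_fitted

from . import _autodiff as ad
from .features import encode_onehot, MAX_LEN

LABEL_TO_INT = {"IC": 0, "EC": 1, 0: 0, 1: 1}


def _sigmoid(x: np.ndarray) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-np.clip(x, -60, 60)))


# ---------------------------------------------------------------------------
# Printed cell recurrences (pure numpy; the reference semantics of the cells)
# ---------------------------------------------------------------------------

@dataclass
class GRUCellParams:
    W_z: np.ndarray; U_z: np.ndarray; b_z: np.ndarray
    W_r: np.ndarray; U_r: np.ndarray; b_r: np.ndarray
    W_h: np.ndarray; U_h: np.ndarray; b_h: np.ndarray

    def __post_init__(self):
        d, h = self.W_z.shape
        for name in ("W_z", "W_r", "W_h"):
            if getattr(self, name).shape != (d, h):
                raise ValueError(f"{name} shape mismatch")
        for name in ("U_z", "U_r", "U_h"):
            if getattr(self, name).shape != (h, h):
                raise ValueError(f"{name} shape mismatch")
        for name in ("b_z", "b_r", "b_h"):
            if getattr(self, name).shape != (h,):
                raise ValueError(f"{name} shape mismatch")


@dataclass
class LSTMCellParams:
    W_i: np.ndarray; U_i: np.ndarray; b_i: np.ndarray
    W_f: np.ndarray; U_f: np.ndarray; b_f: np.ndarray
    W_o: np.ndarray; U_o: np.ndarray; b_o: np.ndarray
    W_c: np.ndarray; U_c: np.ndarray; b_c: np.ndarray

    def __post_init__(self):
        d, h = self.W_i.shape
        for name in ("W_i", "W_f", "W_o", "W_c"):
            if getattr(self, name).shape != (d, h):
                raise ValueError(f"{name} shape mismatch")
        for name in ("U_i", "U_f", "U_o", "U_c"):
            if getattr(self, name).shape != (h, h):
                raise ValueError(f"{name} shape mismatch")
        for name in ("b_i", "b_f", "b_o", "b_c"):
            if getattr(self, name).shape != (h,):
                raise ValueError(f"{name} shape mismatch")


def gru_step(x: np.ndarray, h_prev: np.ndarray, params: GRUCellParams) -> np.ndarray:
    """One GRU update; x (..., d), h_prev (..., H)."""
    x = np.asarray(x, dtype=float)
    h_prev = np.asarray(h_prev, dtype=float)
    if x.shape[-1] != params.W_z.shape[0] or h_prev.shape[-1] != params.U_z.shape[0]:
        raise ValueError("input/hidden dimension mismatch with parameters")
    z = _sigmoid(x @ params.W_z + h_prev @ params.U_z + params.b_z)
    r = _sigmoid(x @ params.W_r + h_prev @ params.U_r + params.b_r)
    h_tilde = np.tanh(x @ params.W_h + (r * h_prev) @ params.U_h + params.b_h)
    return (1.0 - z) * h_prev + z * h_tilde


def lstm_step(
    x: np.ndarray, h_prev: np.ndarray, c_prev: np.ndarray, params: LSTMCellParams
) -> tuple[np.ndarray, np.ndarray]:
    """One LSTM update; returns (h, c)."""
    x = np.asarray(x, dtype=float)
    h_prev = np.asarray(h_prev, dtype=float)
    c_prev = np.asarray(c_prev, dtype=float)
    if x.shape[-1] != params.W_i.shape[0] or h_prev.shape[-1] != params.U_i.shape[0]:
        raise ValueError("input/hidden dimension mismatch with parameters")
    i = _sigmoid(x @ params.W_i + h_prev @ params.U_i + params.b_i)
    f = _sigmoid(x @ params.W_f + h_prev @ params.U_f + params.b_f)
    o = _sigmoid(x @ params.W_o + h_prev @ params.U_o + params.b_o)
    c = f * c_prev + i * np.tanh(x @ params.W_c + h_prev @ params.U_c + params.b_c)
    h = o * np.tanh(c)
    return h, c


def class_weights(label_counts: Mapping) -> dict:
    """w_c = N_total / (K * N_c), K = 2 — inverse sample-frequency weighting."""
    if len(label_counts) != 2 or any(v <= 0 for v in label_counts.values()):
        raise ValueError("class_weights requires two non-empty classes")
    total = sum(label_counts.values())
    return {c: total / (2.0 * n) for c, n in label_counts.items()}


# ---------------------------------------------------------------------------
# Deep sequence classifiers
# ---------------------------------------------------------------------------

def _coerce_labels(y) -> np.ndarray:
    return np.array([LABEL_TO_INT[v] for v in y], dtype=np.float64)


def _coerce_inputs(X, max_len: int) -> tuple[np.ndarray, np.ndarray]:
    if isinstance(X, tuple) and len(X) == 2:
        return np.asarray(X[0], dtype=np.float64), np.asarray(X[1], dtype=np.float64)
    arr = np.asarray(X)
    if arr.dtype.kind in "UO":  # sequences / records
        Xoh, mask = encode_onehot(list(X), max_len=max_len)
        return Xoh.astype(np.float64), mask.astype(np.float64)
    if arr.ndim == 3:
        return arr.astype(np.float64), (arr.sum(axis=2) > 0).astype(np.float64)
    raise ValueError("X must be sequences, a (onehot, mask) tuple, or a 3-D one-hot array")


class _DeepSequenceClassifier(BaseEstimator, ClassifierMixin):
    """Shared fit/predict machinery for the GRU/LSTM/CNN families."""

    _family = "deep"
    # recurrent families can truncate a batch to its longest real sequence
    _variable_length = False

    def __init__(
        self,
        hidden_size: int = 64,
        n_layers: int = 2,
        max_len: int = MAX_LEN,
        learning_rate: float = 1e-3,
        max_epochs: int = 100,
        batch_size: int = 128,
        l1: float = 1e-6,
        l2: float = 1e-6,
        dropout: float = 0.1,
        patience: int = 10,
        lr_decay_factor: float = 0.5,
        lr_decay_patience: int = 5,
        class_weight: str | None = "balanced",
        validation_fraction: float = 0.1,
        random_state: int | None = 0,
        verbose: int = 0,
    ):
        self.hidden_size = hidden_size
        self.n_layers = n_layers
        self.max_len = max_len
        self.learning_rate = learning_rate
        self.max_epochs = max_epochs
        self.batch_size = batch_size
        self.l1 = l1
        self.l2 = l2
        self.dropout = dropout
        self.patience = patience
        self.lr_decay_factor = lr_decay_factor
        self.lr_decay_patience = lr_decay_patience
        self.class_weight = class_weight
        self.validation_fraction = validation_fraction
        self.random_state = random_state
        self.verbose = verbose

    # subclass API -----------------------------------------------------------
    def _init_params(self, rng: np.random.Generator) -> dict[str, ad.Tensor]:
        raise NotImplementedError

    def _forward(self, X: ad.Tensor, mask: np.ndarray, params: dict[str, ad.Tensor],
                 drop_rng: np.random.Generator | None = None) -> ad.Tensor:
        raise NotImplementedError

    # -------------------------------------------------------------------------
    def fit(self, X, y, X_val=None, y_val=None):
        Xoh, mask = _coerce_inputs(X, self.max_len)
        yv = _coerce_labels(y)
        if len(np.unique(yv)) < 2:
            raise ValueError("training data must contain both classes")
        self.classes_ = np.array([0, 1])

        rng = np.random.default_rng(self.random_state)
        if X_val is not None:
            Xv, mv = _coerce_inputs(X_val, self.max_len)
            yvv = _coerce_labels(y_val)
        elif self.validation_fraction and self.validation_fraction > 0:
            idx = np.arange(len(yv))
            tr, va = train_test_split(
                idx, test_size=self.validation_fraction, stratify=yv,
                random_state=int(rng.integers(2**31 - 1)),
            )
            Xv, mv, yvv = Xoh[va], mask[va], yv[va]
            Xoh, mask, yv = Xoh[tr], mask[tr], yv[tr]
        else:
            Xv = mv = yvv = None

        if self.class_weight == "balanced":
            cw = class_weights({0: int((yv == 0).sum()), 1: int((yv == 1).sum())})
        else:
            cw = {0: 1.0, 1: 1.0}
        sample_w = np.where(yv == 1, cw[1], cw[0])

        params = self._init_params(rng)
        plist = list(params.values())
        opt = ad.Adam(plist, lr=self.learning_rate, l1=self.l1, l2=self.l2)

        n = len(yv)
        best_val = np.inf
        best_state = {k: v.data.copy() for k, v in params.items()}
        stagnant = decay_stagnant = 0
        history: dict[str, list[float]] = {"train_loss": [], "val_loss": []}

        for epoch in range(self.max_epochs):
            order = rng.permutation(n)
            drop_rng = np.random.default_rng(rng.integers(2**31 - 1))
            ep_loss = 0.0
            for start in range(0, n, self.batch_size):
                b = order[start : start + self.batch_size]
                Xb, mb = Xoh[b], mask[b]
                if self._variable_length:
                    t_max = max(int(mb.sum(axis=1).max()), 1)
                    Xb, mb = Xb[:, :t_max], mb[:, :t_max]
                xb = ad.Tensor(Xb)
                logits = self._forward(xb, mb, params, drop_rng=drop_rng)
                loss = ad.weighted_bce_with_logits(logits, yv[b], sample_w[b])
                if not np.isfinite(loss.data):
                    raise FloatingPointError(
                        f"non-finite training loss at epoch {epoch}; aborting"
                    )
                opt.zero_grad()
                loss.backward()
                opt.step()
                ep_loss += float(loss.data) * len(b)
            ep_loss /= n
            history["train_loss"].append(ep_loss)

            if Xv is not None and len(yvv):
                val_logits = self._predict_logits(Xv, mv, params)
                vw = np.where(yvv == 1, cw[1], cw[0])
                sp = np.logaddexp(0.0, val_logits)
                val_loss = float(np.mean(vw * (sp - yvv * val_logits)))
            else:
                val_loss = ep_loss
            history["val_loss"].append(val_loss)
            if self.verbose:
                print(f"epoch {epoch}: train {ep_loss:.4f} val {val_loss:.4f}")

            if val_loss < best_val - 1e-6:
                best_val = val_loss
                best_state = {k: v.data.copy() for k, v in params.items()}
                stagnant = decay_stagnant = 0
            else:
                stagnant += 1
                decay_stagnant += 1
                if decay_stagnant >= self.lr_decay_patience:
                    opt.lr *= self.lr_decay_factor
                    decay_stagnant = 0
                if stagnant >= self.patience:
                    break

        for k, v in params.items():
            v.data = best_state[k]
        self.params_ = params
        self.history_ = history
        self.n_epochs_ = len(history["train_loss"])
        return self

    def _predict_logits(self, Xoh: np.ndarray, mask: np.ndarray,
                        params: dict[str, ad.Tensor] | None = None) -> np.ndarray:
        params = params if params is not None else self.params_
        out = np.empty(len(Xoh))
        # chunked inference keeps memory flat on large batches
        for start in range(0, len(Xoh), 1024):
            Xb, mb = Xoh[start : start + 1024], mask[start : start + 1024]
            if self._variable_length:
                t_max = max(int(mb.sum(axis=1).max()), 1)
                Xb, mb = Xb[:, :t_max], mb[:, :t_max]
            logits = self._forward(ad.Tensor(Xb), mb, params, drop_rng=None)
            out[start : start + 1024] = logits.data.ravel()
        return out

    def decision_function(self, X) -> np.ndarray:
        check_is_fitted(self, "params_")
        Xoh, mask = _coerce_inputs(X, self.max_len)
        return self._predict_logits(Xoh, mask)

    def predict_proba(self, X) -> np.ndarray:
        p = _sigmoid(self.decision_function(X))
        return np.column_stack([1.0 - p, p])

    def secretion_probability(self, X) -> np.ndarray:
        """Sigmoid-transformed output: probability the RNA is extracellular."""
        return self.predict_proba(X)[:, 1]

    def predict(self, X) -> np.ndarray:
        return (self.secretion_probability(X) >= 0.5).astype(int)

    def input_gradient(self, X) -> np.ndarray:
        """Gradient of the pre-sigmoid output w.r.t. the one-hot input."""
        check_is_fitted(self, "params_")
        Xoh, mask = _coerce_inputs(X, self.max_len)
        xb = ad.Tensor(Xoh, requires_grad=True)
        logits = self._forward(xb, mask, self.params_, drop_rng=None)
        logits.sum().backward()
        return xb.grad if xb.grad is not None else np.zeros_like(Xoh)

    # checkpointing -----------------------------------------------------------
    def save(self, path) -> None:
        """Documented container: architecture spec + flat parameter arrays."""
        check_is_fitted(self, "params_")
        spec = {"family": self._family, "params": self.get_params()}
        arrays = {k: v.data for k, v in self.params_.items()}
        np.savez(path, __spec__=np.frombuffer(json.dumps(spec).encode(), dtype=np.uint8),
                 **arrays)

    @classmethod
    def load(cls, path):
        with np.load(path) as data:
            spec = json.loads(bytes(data["__spec__"]).decode())
            model = cls(**spec["params"])
            rng = np.random.default_rng(0)
            params = model._init_params(rng)
            for k in params:
                params[k].data = np.asarray(data[k], dtype=np.float64)
        model.params_ = params
        model.classes_ = np.array([0, 1])
        model.history_ = {}
        return model


class GRUSecretionClassifier(_DeepSequenceClassifier):
    """Stacked unidirectional GRU layers -> final hidden state -> linear -> sigmoid."""

    _family = "gru"
    _variable_length = True

    def _init_params(self, rng):
        H, L = self.hidden_size, self.n_layers
        p: dict[str, ad.Tensor] = {}
        for layer in range(L):
            d = 4 if layer == 0 else H
            for gate in ("z", "r", "h"):
                p[f"W_{gate}{layer}"] = ad.Tensor(ad.xavier(rng, d, H), True, True)
                p[f"U_{gate}{layer}"] = ad.Tensor(ad.xavier(rng, H, H), True, True)
                p[f"b_{gate}{layer}"] = ad.Tensor(np.zeros((1, H)), True, False)
        p["W_out"] = ad.Tensor(ad.xavier(rng, H, 1), True, True)
        p["b_out"] = ad.Tensor(np.zeros((1, 1)), True, False)
        return p

    def _forward(self, X, mask, params, drop_rng=None):
        T = X.data.shape[1]
        h = X
        for layer in range(self.n_layers):
            h = ad.gru_layer(h, mask, params, layer)
            if layer < self.n_layers - 1:
                h = ad.dropout(h, self.dropout, drop_rng)
        last = ad.select_time(h, T - 1)
        return last.matmul(params["W_out"]) + params["b_out"]


class LSTMSecretionClassifier(_DeepSequenceClassifier):
    """Stacked LSTM layers -> final hidden state -> linear -> sigmoid."""

    _family = "lstm"
    _variable_length = True

    def _init_params(self, rng):
        H, L = self.hidden_size, self.n_layers
        p: dict[str, ad.Tensor] = {}
        for layer in range(L):
            d = 4 if layer == 0 else H
            for gate in ("i", "f", "o", "c"):
                p[f"W_{gate}{layer}"] = ad.Tensor(ad.xavier(rng, d, H), True, True)
                p[f"U_{gate}{layer}"] = ad.Tensor(ad.xavier(rng, H, H), True, True)
                p[f"b_{gate}{layer}"] = ad.Tensor(np.zeros((1, H)), True, False)
        p["W_out"] = ad.Tensor(ad.xavier(rng, H, 1), True, True)
        p["b_out"] = ad.Tensor(np.zeros((1, 1)), True, False)
        return p

    def _forward(self, X, mask, params, drop_rng=None):
        T = X.data.shape[1]
        h = X
        for layer in range(self.n_layers):
            h = ad.lstm_layer(h, mask, params, layer)
            if layer < self.n_layers - 1:
                h = ad.dropout(h, self.dropout, drop_rng)
        last = ad.select_time(h, T - 1)
        return last.matmul(params["W_out"]) + params["b_out"]


class CNNSecretionClassifier(_DeepSequenceClassifier):
    """VGG-style conv blocks (width-2 max pooling) -> dense 1024 -> 128 -> sigmoid.

    ``conv_plan`` is a tuple of (channels, n_conv_layers) per block; every conv
    uses kernel 3, same padding, ReLU.
    """

    _family = "cnn"

    def __init__(self, conv_plan: tuple = ((32, 2), (64, 2)), kernel_size: int = 3,
                 head_widths: tuple = (1024, 128), **kwargs):
        kwargs.setdefault("hidden_size", 64)
        super().__init__(**kwargs)
        self.conv_plan = conv_plan
        self.kernel_size = kernel_size
        self.head_widths = head_widths

    def _flat_dim(self) -> int:
        L = self.max_len
        for _, _n in self.conv_plan:
            L //= 2
        return L * self.conv_plan[-1][0]

    def _init_params(self, rng):
        k = self.kernel_size
        p: dict[str, ad.Tensor] = {}
        c_in = 4
        for bi, (ch, n_conv) in enumerate(self.conv_plan):
            for ci in range(n_conv):
                p[f"convW_{bi}_{ci}"] = ad.Tensor(ad.xavier(rng, k * c_in, ch), True, True)
                p[f"convb_{bi}_{ci}"] = ad.Tensor(np.zeros((1, 1, ch)), True, False)
                c_in = ch
        d = self._flat_dim()
        widths = list(self.head_widths) + [1]
        for li, w in enumerate(widths):
            p[f"denseW_{li}"] = ad.Tensor(ad.xavier(rng, d, w), True, True)
            p[f"denseb_{li}"] = ad.Tensor(np.zeros((1, w)), True, False)
            d = w
        return p

    def _forward(self, X, mask, params, drop_rng=None):
        pad = self.kernel_size // 2
        h = X
        for bi, (ch, n_conv) in enumerate(self.conv_plan):
            for ci in range(n_conv):
                cols = ad.unfold1d(h, self.kernel_size, pad)
                B, L, KC = cols.data.shape
                flat = cols.reshape(B * L, KC)
                conv = flat.matmul(params[f"convW_{bi}_{ci}"]).reshape(B, L, ch)
                h = ad.relu(conv + params[f"convb_{bi}_{ci}"])
            h = ad.maxpool2(h)
        B = h.data.shape[0]
        flat = h.reshape(B, self._flat_dim())
        n_hidden = len(self.head_widths)
        for li in range(n_hidden + 1):
            flat = flat.matmul(params[f"denseW_{li}"]) + params[f"denseb_{li}"]
            if li < n_hidden:
                flat = ad.relu(flat)
        return flat


# ---------------------------------------------------------------------------
# Classical models on tabular features
# ---------------------------------------------------------------------------

class SVMSecretionClassifier(BaseEstimator, ClassifierMixin):
    """SVM on numeric features (sequence-typed features are excluded upstream)."""

    def __init__(self, kernel: str = "linear", C: float = 1.0,
                 class_weight: str | None = "balanced", random_state: int | None = 0):
        self.kernel = kernel
        self.C = C
        self.class_weight = class_weight
        self.random_state = random_state

    def fit(self, X, y):
        yv = _coerce_labels(y).astype(int)
        self.model_ = SVC(kernel=self.kernel, C=self.C, class_weight=self.class_weight,
                          random_state=self.random_state)
        self.model_.fit(np.asarray(X, dtype=float), yv)
        self.classes_ = self.model_.classes_
        return self

    def predict_proba(self, X):
        # sigmoid-transformed margin, consistent with the deep families'
        # probability convention (uncalibrated)
        check_is_fitted(self, "model_")
        p = _sigmoid(self.model_.decision_function(np.asarray(X, dtype=float)))
        return np.column_stack([1.0 - p, p])

    def secretion_probability(self, X):
        return self.predict_proba(X)[:, 1]

    def predict(self, X):
        return self.model_.predict(np.asarray(X, dtype=float))


class RandomForestSecretionClassifier(BaseEstimator, ClassifierMixin):
    """Random forest with the study's grid: 50 or 200 trees, depth 20."""

    def __init__(self, n_trees: int = 50, max_depth: int = 20,
                 class_weight: str | None = "balanced", random_state: int | None = 0):
        if n_trees not in (50, 200):
            # other sizes work; the canonical grid is {50, 200}
            pass
        self.n_trees = n_trees
        self.max_depth = max_depth
        self.class_weight = class_weight
        self.random_state = random_state

    def fit(self, X, y):
        yv = _coerce_labels(y).astype(int)
        self.model_ = RandomForestClassifier(
            n_estimators=self.n_trees, max_depth=self.max_depth,
            class_weight=self.class_weight, random_state=self.random_state,
        )
        self.model_.fit(np.asarray(X, dtype=float), yv)
        self.classes_ = self.model_.classes_
        return self

    def predict_proba(self, X):
        check_is_fitted(self, "model_")
        return self.model_.predict_proba(np.asarray(X, dtype=float))

    def secretion_probability(self, X):
        return self.predict_proba(X)[:, 1]

    def predict(self, X):
        return self.model_.predict(np.asarray(X, dtype=float))


# ---------------------------------------------------------------------------
# Model zoo plumbing
# ---------------------------------------------------------------------------

FAMILIES = ("svm_linear", "svm_rbf", "rf", "cnn", "lstm", "gru")


@dataclass
class ModelSpec:
    family: str = "gru"
    hyperparams: dict = field(default_factory=dict)
    class_weighting: bool = True

    def __post_init__(self):
        if self.family not in FAMILIES:
            raise ValueError(f"family must be one of {FAMILIES}, got {self.family!r}")


def build_model(spec: ModelSpec):
    """Instantiate an untrained classifier from a family spec."""
    cw = "balanced" if spec.class_weighting else None
    hp = dict(spec.hyperparams)
    if spec.family == "svm_linear":
        return SVMSecretionClassifier(kernel="linear", class_weight=cw, **hp)
    if spec.family == "svm_rbf":
        return SVMSecretionClassifier(kernel="rbf", class_weight=cw, **hp)
    if spec.family == "rf":
        return RandomForestSecretionClassifier(class_weight=cw, **hp)
    if spec.family == "cnn":
        return CNNSecretionClassifier(class_weight=cw, **hp)
    if spec.family == "lstm":
        return LSTMSecretionClassifier(class_weight=cw, **hp)
    return GRUSecretionClassifier(class_weight=cw, **hp)


@dataclass
class TrainConfig:
    learning_rate: float = 1e-3
    max_epochs: int = 100
    batch_size: int = 128
    l1_lambda: float = 1e-6
    l2_lambda: float = 1e-6
    patience: int = 10
    lr_decay_factor: float = 0.5
    lr_decay_patience: int = 5
    ic_downsample_ratio: float = 4.33
    split_fractions: tuple = (0.8, 0.1, 0.1)
    seed: int = 0

    def __post_init__(self):
        if abs(sum(self.split_fractions) - 1.0) > 1e-9:
            raise ValueError("split fractions must sum to 1")
        if min(self.split_fractions) <= 0:
            raise ValueError("split fractions must be positive")


def downsample_majority(X, y: np.ndarray, ratio: float, rng: np.random.Generator):
    """Subsample IC (label 0) to at most ratio x the EC count; order preserved."""
    y = np.asarray(y)
    pos = np.flatnonzero(y == 1)
    neg = np.flatnonzero(y == 0)
    n_keep = int(round(ratio * len(pos)))
    if len(neg) > n_keep:
        neg = np.sort(rng.choice(neg, size=n_keep, replace=False))
    idx = np.sort(np.concatenate([pos, neg]))
    if isinstance(X, np.ndarray):
        return X[idx], y[idx], idx
    return [X[i] for i in idx], y[idx], idx


def stratified_split(y: np.ndarray, fractions=(0.8, 0.1, 0.1), seed: int = 0):
    """Index triple (train, val, test) stratified by label."""
    idx = np.arange(len(y))
    f_train, f_val, f_test = fractions
    tr, rest = train_test_split(idx, test_size=f_val + f_test, stratify=y, random_state=seed)
    va, te = train_test_split(
        rest, test_size=f_test / (f_val + f_test), stratify=y[rest], random_state=seed + 1
    )
    return tr, va, te


def train(model, X, y, config: TrainConfig | None = None):
    """Full training regime: IC downsampling, stratified 0.8/0.1/0.1 split,
    fit with early stopping, best-validation model returned.

    Returns (fitted model, history dict with the index splits and metrics).
    """
    config = config or TrainConfig()
    y = _coerce_labels(y)
    if len(np.unique(y)) < 2:
        raise ValueError("training requires both classes")
    rng = np.random.default_rng(config.seed)
    X, y, kept = downsample_majority(X, y, config.ic_downsample_ratio, rng)
    tr, va, te = stratified_split(y, config.split_fractions, seed=config.seed)

    def take(obj, idx):
        return obj[idx] if isinstance(obj, np.ndarray) else [obj[i] for i in idx]

    if isinstance(model, _DeepSequenceClassifier):
        model.set_params(
            learning_rate=config.learning_rate, max_epochs=config.max_epochs,
            batch_size=config.batch_size, l1=config.l1_lambda, l2=config.l2_lambda,
            patience=config.patience, lr_decay_factor=config.lr_decay_factor,
            lr_decay_patience=config.lr_decay_patience, random_state=config.seed,
            validation_fraction=0.0,
        )
        model.fit(take(X, tr), y[tr], X_val=take(X, va), y_val=y[va])
        history = dict(model.history_)
    else:
        model.fit(take(X, tr), y[tr])
        history = {}
    history.update({
        "kept_indices": kept, "train_idx": tr, "val_idx": va, "test_idx": te,
    })
    return model, history


# ---------------------------------------------------------------------------
# Evaluation
# ---------------------------------------------------------------------------

@dataclass
class EvalReport:
    auroc: float
    auprc: float
    sensitivity: float
    specificity: float
    accuracy: float
    tp: int
    fp: int
    tn: int
    fn: int
    threshold: float
    roc_band: dict | None = None

    def as_dict(self) -> dict:
        d = asdict(self)
        d.pop("roc_band")
        return d


def auroc_score(labels: np.ndarray, probs: np.ndarray) -> float:
    """AUROC via the rank statistic (Mann-Whitney); ties get half credit."""
    labels = np.asarray(labels)
    probs = np.asarray(probs, dtype=float)
    n_pos = int((labels == 1).sum())
    n_neg = int((labels == 0).sum())
    if n_pos == 0 or n_neg == 0:
        raise ValueError("AUROC undefined with a single class")
    ranks = rankdata(probs)
    u = ranks[labels == 1].sum() - n_pos * (n_pos + 1) / 2.0
    return float(u / (n_pos * n_neg))


def threshold_at_specificity(neg_probs: np.ndarray, target: float) -> float:
    """Smallest decision threshold achieving specificity >= target on negatives."""
    neg = np.sort(np.asarray(neg_probs, dtype=float))
    candidates = np.concatenate([np.unique(neg), [neg[-1] + 1.0]])
    for t in candidates:
        if np.mean(neg < t) >= target:
            return float(t)
    return float(candidates[-1])  # pragma: no cover


def evaluate(
    probs,
    labels,
    threshold: float = 0.5,
    at_specificity: float | None = None,
    bootstrap: int = 0,
    seed: int = 0,
) -> EvalReport:
    """Confusion metrics at a threshold (or at a target specificity), AUROC,
    AUPRC, and an optional percentile bootstrap ROC band."""
    probs = np.asarray(probs, dtype=float)
    labels = _coerce_labels(labels).astype(int)
    if len(probs) != len(labels):
        raise ValueError("probs and labels must have equal length")
    auroc = auroc_score(labels, probs)
    auprc = float(average_precision_score(labels, probs))

    if at_specificity is not None:
        threshold = threshold_at_specificity(probs[labels == 0], at_specificity)
    pred = probs >= threshold
    tp = int((pred & (labels == 1)).sum())
    fp = int((pred & (labels == 0)).sum())
    tn = int((~pred & (labels == 0)).sum())
    fn = int((~pred & (labels == 1)).sum())
    sens = tp / (tp + fn) if tp + fn else float("nan")
    spec = tn / (tn + fp) if tn + fp else float("nan")
    acc = (tp + tn) / len(labels)

    band = None
    if bootstrap:
        rng = np.random.default_rng(seed)
        grid = np.linspace(0.0, 1.0, 101)
        tprs = np.empty((bootstrap, grid.size))
        n = len(labels)
        for b in range(bootstrap):
            idx = rng.integers(0, n, size=n)
            lb, pb = labels[idx], probs[idx]
            if lb.min() == lb.max():  # degenerate resample: redraw
                idx = rng.integers(0, n, size=n)
                lb, pb = labels[idx], probs[idx]
            fpr, tpr = _roc_curve(lb, pb)
            tprs[b] = np.interp(grid, fpr, tpr)
        band = {
            "fpr": grid,
            "tpr_mean": tprs.mean(axis=0),
            "tpr_lo": np.percentile(tprs, 2.5, axis=0),
            "tpr_hi": np.percentile(tprs, 97.5, axis=0),
        }
    return EvalReport(auroc, auprc, sens, spec, acc, tp, fp, tn, fn,
                      float(threshold), band)


def _roc_curve(labels: np.ndarray, probs: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    order = np.argsort(-probs, kind="stable")
    lab = labels[order]
    tps = np.cumsum(lab == 1)
    fps = np.cumsum(lab == 0)
    n_pos = max(int((labels == 1).sum()), 1)
    n_neg = max(int((labels == 0).sum()), 1)
    fpr = np.concatenate([[0.0], fps / n_neg, [1.0]])
    tpr = np.concatenate([[0.0], tps / n_pos, [1.0]])
    return fpr, tpr


__all__ = [
    "GRUCellParams", "LSTMCellParams", "gru_step", "lstm_step", "class_weights",
    "GRUSecretionClassifier", "LSTMSecretionClassifier", "CNNSecretionClassifier",
    "SVMSecretionClassifier", "RandomForestSecretionClassifier",
    "ModelSpec", "TrainConfig", "build_model", "train",
    "downsample_majority", "stratified_split",
    "EvalReport", "evaluate", "auroc_score", "threshold_at_specificity",
]
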