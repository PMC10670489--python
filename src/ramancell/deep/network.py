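"""The windowed CNN-LSTM classifier with a selective (reject) branch.

Each spectrum is cut into ``k_s`` slices; every slice is reshaped into a
small 2-D patch and passed through a shared (time-distributed)
convolutional stack with a 6x4 kernel; the per-slice feature vectors form
a length-``k_s`` sequence consumed by a 100-unit LSTM whose final state
feeds three heads: the main softmax classifier, a SelectiveNet-style
confidence branch, and an auxiliary classifier used only as a training
signal for the shared representation.

Two architectures are provided, named by their total layer count (every
named layer — input, wrapper, conv, activation, pooling, dropout, dense,
output, selective and auxiliary layers — is counted, see
:func:`layer_manifest`): a 25-layer network with one convolution per stage
and a 56-layer network with four stages of four convolutions each.
"""

from __future__ import annotations

import dataclasses

import numpy as np

from ..spectra import LABELS
from .layers import (
    LSTM, Adam, Conv2D, Dense, Dropout, Flatten, MaxPool2D, ReLU,
    sigmoid, softmax,
)

AUGMENTATION_MODES = ("none", "frequency", "value", "both")


@dataclasses.dataclass
class NetConfig:
    """Architecture and training hyper-parameters of the CNN-LSTM."""

    n_layers: int = 25                       # 25 or 56
    learning_rate: float = 0.001
    dropout: float = 0.15                    # tuned dropout inside the head
    conv_filters: tuple[int, ...] = (64, 128, 256)
    kernel_height: int = 6
    kernel_width: int = 4
    lstm_units: int = 100
    head_dropout: float = 0.5                # fixed dropout after the LSTM
    dense_hidden: int = 64
    reject_threshold: float | None = None    # typically 0.2 or 0.8; None = off
    augmentation: str = "none"
    epochs: int = 100
    batch_size: int = 32
    seed: int = 0
    k_s: int = 3
    n_points: int = 601                      # points per preprocessed spectrum
    reshape_rows: int = 8                    # rows of the 2-D slice patch
    selective_lambda: float = 32.0
    target_coverage: float = 0.9
    augment_pct: float = 10.0
    patience: int = 15                       # early-stopping patience (epochs)

    def __post_init__(self) -> None:
        if self.n_layers not in (25, 56):
            raise ValueError("n_layers must be 25 or 56")
        if self.learning_rate <= 0:
            raise ValueError("learning_rate must be positive")
        if not 0 <= self.dropout < 1 or not 0 <= self.head_dropout < 1:
            raise ValueError("dropout rates must be in [0, 1)")
        if self.augmentation not in AUGMENTATION_MODES:
            raise ValueError(f"augmentation must be one of {AUGMENTATION_MODES}")
        if self.reject_threshold is not None and not 0 <= self.reject_threshold <= 1:
            raise ValueError("reject_threshold must be in [0, 1]")
        if self.k_s < 1 or self.reshape_rows < 1:
            raise ValueError("k_s and reshape_rows must be >= 1")

    @property
    def selective(self) -> bool:
        return self.reject_threshold is not None

    def stage_plan(self) -> tuple[tuple[int, int], ...]:
        """(filters, convs per stage) for each conv stage of the architecture."""
        f = self.conv_filters
        if self.n_layers == 25:
            return ((f[0], 1), (f[1], 1), (f[2], 1))
        return ((f[0], 4), (f[1], 4), (f[2], 4), (f[-1], 4))


def layer_manifest(cfg: NetConfig) -> list[str]:
    """Named-layer manifest of the architecture; its length equals
    ``cfg.n_layers``."""
    names = ["input", "window-split"]
    for si, (filters, n_convs) in enumerate(cfg.stage_plan()):
        for ci in range(n_convs):
            names += [f"conv{si+1}.{ci+1}({filters})", f"relu{si+1}.{ci+1}"]
        if cfg.n_layers == 56:
            names.append(f"stage-dropout{si+1}")
        names.append(f"maxpool{si+1}")
    names += [
        "flatten", "sequence-stack", "lstm", "lstm-dropout",
        "dense", "dense-relu", "head-dropout", "dense-logits", "softmax",
        "sel-dense", "sel-relu", "sel-logit", "sel-sigmoid", "aux-dense",
    ]
    assert len(names) == cfg.n_layers, (len(names), cfg.n_layers)
    return names


class CNNLSTM:
    """The classifier: build with :func:`build_model`, train with the
    routines in :mod:`ramancell.deep.training`."""

    def __init__(self, cfg: NetConfig):
        self.cfg = cfg
        self.classes = np.array(LABELS)  # (Non-Tumor, Tumor)
        self.name = f"CNN-LSTM-{cfg.n_layers}"
        self.preprocess_hash: str | None = None
        self._build()

    # ------------------------------------------------------------------ build
    def _build(self) -> None:
        cfg = self.cfg
        rng = np.random.default_rng(cfg.seed)
        self.rng = rng
        L = cfg.n_points // cfg.k_s
        rows = cfg.reshape_rows
        cols = L // rows
        if cols < 1:
            raise ValueError("slice too short for the requested patch rows")
        self.patch = (rows, cols)
        self.conv_stack: list = []
        in_ch, h, w = 1, rows, cols
        for filters, n_convs in cfg.stage_plan():
            for _ in range(n_convs):
                self.conv_stack.append(
                    Conv2D(in_ch, filters, cfg.kernel_height, cfg.kernel_width, rng)
                )
                self.conv_stack.append(ReLU())
                in_ch = filters
            if cfg.n_layers == 56:
                self.conv_stack.append(Dropout(cfg.dropout, rng))
            self.conv_stack.append(MaxPool2D())
            h = max(h // 2, 1) if h >= 2 else h
            w = max(w // 2, 1) if w >= 2 else w
        self.flat_dim = in_ch * h * w
        self.flatten = Flatten()
        self.lstm = LSTM(self.flat_dim, cfg.lstm_units, rng)
        self.head_drop1 = Dropout(cfg.head_dropout, rng)
        self.head_dense = Dense(cfg.lstm_units, cfg.dense_hidden, rng)
        self.head_relu = ReLU()
        self.head_drop2 = Dropout(cfg.dropout, rng)
        self.head_logits = Dense(cfg.dense_hidden, 2, rng)
        self.sel_dense = Dense(cfg.lstm_units, 32, rng)
        self.sel_relu = ReLU()
        self.sel_logit = Dense(32, 1, rng)
        self.aux_dense = Dense(cfg.lstm_units, 2, rng)

        self._layers = self.conv_stack + [
            self.lstm, self.head_drop1, self.head_dense, self.head_relu,
            self.head_drop2, self.head_logits,
            self.sel_dense, self.sel_relu, self.sel_logit, self.aux_dense,
        ]

    @property
    def params(self) -> list[np.ndarray]:
        return [p for layer in self._layers for p in layer.params]

    @property
    def grads(self) -> list[np.ndarray]:
        return [g for layer in self._layers for g in layer.grads]

    def n_parameters(self) -> int:
        return int(sum(p.size for p in self.params))

    def make_optimizer(self) -> Adam:
        return Adam(self.params, lr=self.cfg.learning_rate)

    # ---------------------------------------------------------------- forward
    def _patches(self, Xw: np.ndarray) -> np.ndarray:
        """(N, k_s, L) windows -> (N*k_s, 1, rows, cols) patches."""
        N, T, L = Xw.shape
        rows, cols = self.patch
        return Xw[:, :, : rows * cols].reshape(N * T, 1, rows, cols)

    def forward(self, Xw: np.ndarray, train: bool = False) -> dict:
        N, T, _ = Xw.shape
        z = self._patches(Xw)
        for layer in self.conv_stack:
            z = layer.forward(z, train)
        z = self.flatten.forward(z, train)            # (N*T, D)
        seq = z.reshape(N, T, self.flat_dim)
        h = self.lstm.forward(seq, train)             # (N, H)
        d1 = self.head_drop1.forward(h, train)
        a1 = self.head_relu.forward(self.head_dense.forward(d1, train), train)
        d2 = self.head_drop2.forward(a1, train)
        logits = self.head_logits.forward(d2, train)
        probs = softmax(logits)
        s1 = self.sel_relu.forward(self.sel_dense.forward(h, train), train)
        g_logit = self.sel_logit.forward(s1, train)
        g = sigmoid(g_logit[:, 0])
        aux_logits = self.aux_dense.forward(h, train)
        return {
            "probs": probs, "logits": logits, "g": g,
            "aux_probs": softmax(aux_logits), "h": h, "N": N, "T": T,
        }

    # ------------------------------------------------------------------- loss
    def loss_and_backward(self, Xw: np.ndarray, y_idx: np.ndarray,
                          train: bool = True) -> float:
        """Compute the training loss and populate all parameter gradients.

        With the selective branch enabled the loss is the SelectiveNet
        objective: confidence-weighted selective risk plus a quadratic
        coverage penalty, averaged 1:1 with the auxiliary-head
        cross-entropy.  Otherwise it is plain cross-entropy.
        """
        cfg = self.cfg
        out = self.forward(Xw, train=train)
        N = out["N"]
        probs, g, aux_probs = out["probs"], out["g"], out["aux_probs"]
        onehot = np.zeros((N, 2))
        onehot[np.arange(N), y_idx] = 1.0
        eps = 1e-12
        ce = -np.log(probs[np.arange(N), y_idx] + eps)

        if cfg.selective:
            G = g.sum() + eps
            risk = float((g * ce).sum() / G)
            shortfall = max(0.0, cfg.target_coverage - float(g.mean()))
            penalty = cfg.selective_lambda * shortfall**2
            aux_ce = float(-np.log(aux_probs[np.arange(N), y_idx] + eps).mean())
            loss = 0.5 * (risk + penalty) + 0.5 * aux_ce
            w = 0.5 * g / G
            dlogits = (probs - onehot) * w[:, None]
            dg = 0.5 * ((ce * G - (g * ce).sum()) / G**2
                        - 2.0 * cfg.selective_lambda * shortfall / N)
            daux = 0.5 * (aux_probs - onehot) / N
        else:
            loss = float(ce.mean())
            dlogits = (probs - onehot) / N
            dg = np.zeros(N)
            daux = np.zeros((N, 2))

        # ------------------------------------------------ backward pass
        dh = self.head_drop1.backward(
            self.head_dense.backward(
                self.head_relu.backward(
                    self.head_drop2.backward(self.head_logits.backward(dlogits))
                )
            )
        )
        dg_logit = (dg * g * (1.0 - g))[:, None]
        dh += self.sel_dense.backward(
            self.sel_relu.backward(self.sel_logit.backward(dg_logit))
        )
        dh += self.aux_dense.backward(daux)
        dseq = self.lstm.backward(dh)
        dz = self.flatten.backward(dseq.reshape(-1, self.flat_dim))
        for layer in reversed(self.conv_stack):
            dz = layer.backward(dz)
        return float(loss)

    # ---------------------------------------------------------------- predict
    def predict_proba(self, Xw: np.ndarray) -> np.ndarray:
        return self.forward(Xw, train=False)["probs"]

    def predict_windowed(self, Xw: np.ndarray) -> np.ndarray:
        probs = self.predict_proba(Xw)
        return self.classes[probs.argmax(axis=1)]

    def confidence_windowed(self, Xw: np.ndarray) -> np.ndarray:
        out = self.forward(Xw, train=False)
        if self.cfg.selective:
            return out["g"]
        return out["probs"].max(axis=1)

    def _window(self, X: np.ndarray) -> np.ndarray:
        from .windows import window_matrix

        return window_matrix(np.asarray(X, dtype=float), self.cfg.k_s)

    def predict(self, X: np.ndarray) -> np.ndarray:
        """Spectrum-matrix interface shared with the linear models."""
        return self.predict_windowed(self._window(X))

    def confidence(self, X: np.ndarray) -> np.ndarray:
        return self.confidence_windowed(self._window(X))


def build_model(cfg: NetConfig) -> CNNLSTM:
    """Construct the (deterministically initialized) CNN-LSTM for ``cfg``."""
    return CNNLSTM(cfg)


@dataclasses.dataclass
class SelectivePrediction:
    label: str          # class label or "REJECT"
    confidence: float
    threshold_used: float


REJECT = "REJECT"


def selective_predict(model: CNNLSTM, Xw_or_X: np.ndarray,
                      threshold: float) -> list[SelectivePrediction]:
    """Classify each spectrum, abstaining whenever confidence < threshold."""
    if not 0 <= threshold <= 1:
        raise ValueError("threshold must be in [0, 1]")
    X = np.asarray(Xw_or_X, dtype=float)
    Xw = X if X.ndim == 3 else model._window(X)
    labels = model.predict_windowed(Xw)
    conf = model.confidence_windowed(Xw)
    return [
        SelectivePrediction(
            label=(REJECT if c < threshold else l),
            confidence=float(c),
            threshold_used=threshold,
        )
        for l, c in zip(labels, conf)
    ]
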