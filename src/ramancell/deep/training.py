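"""Training of the CNN-LSTM: k-fold cross-validation, window-level
augmentation of the training folds only, early stopping, and the ablation
grid over architecture x reject threshold x augmentation mode."""

from __future__ import annotations

import dataclasses

import numpy as np
import pandas as pd
from sklearn.model_selection import StratifiedKFold

from ..chemometrics import compute_metrics, harmonic_f1
from ..spectra import TUMOR
from .network import AUGMENTATION_MODES, CNNLSTM, NetConfig, build_model
from .windows import augment_frequency, augment_value, window_matrix

__all__ = ["FoldResult", "CVResult", "augment_windows", "fit", "train_cv",
           "ablation_grid"]


@dataclasses.dataclass
class FoldResult:
    fold: int
    precision: float
    recall: float
    f1: float
    n_val: int
    n_rejected: int
    loss_curve: list[float]


@dataclasses.dataclass
class CVResult:
    folds: list[FoldResult]
    cfg: NetConfig
    #: instrumentation: per fold, the sets of sample indices that received
    #: augmentation and that formed the validation fold (always disjoint)
    augmented_ids: list[set]
    val_ids: list[set]

    @property
    def mean_f1(self) -> float:
        vals = [f.f1 for f in self.folds if np.isfinite(f.f1)]
        return float(np.mean(vals)) if vals else float("nan")

    @property
    def mean_precision(self) -> float:
        vals = [f.precision for f in self.folds if np.isfinite(f.precision)]
        return float(np.mean(vals)) if vals else float("nan")

    @property
    def mean_recall(self) -> float:
        vals = [f.recall for f in self.folds if np.isfinite(f.recall)]
        return float(np.mean(vals)) if vals else float("nan")

    def table(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "fold": f.fold, "precision": f.precision,
                    "recall": f.recall, "f1": f.f1,
                    "n_val": f.n_val, "n_rejected": f.n_rejected,
                }
                for f in self.folds
            ]
        )


def augment_windows(Xw: np.ndarray, mode: str, pct: float,
                    rng: np.random.Generator) -> np.ndarray:
    """One augmented copy of every windowed spectrum (training data only)."""
    if mode not in AUGMENTATION_MODES:
        raise ValueError(f"unknown augmentation mode {mode!r}")
    if mode == "none":
        return Xw[:0]
    out = np.empty_like(Xw)
    for i in range(Xw.shape[0]):
        for j in range(Xw.shape[1]):
            w = Xw[i, j]
            if mode in ("value", "both"):
                w = augment_value(w, pct, rng)
            if mode in ("frequency", "both"):
                w = augment_frequency(w, pct, rng)
            out[i, j] = w
    return out


def _epoch(model: CNNLSTM, opt, Xw, y_idx, rng) -> float:
    order = rng.permutation(Xw.shape[0])
    bs = model.cfg.batch_size
    losses = []
    for start in range(0, order.size, bs):
        batch = order[start : start + bs]
        loss = model.loss_and_backward(Xw[batch], y_idx[batch], train=True)
        opt.step(model.grads)
        losses.append(loss)
    return float(np.mean(losses))


def _val_loss(model: CNNLSTM, Xw, y_idx) -> float:
    probs = model.predict_proba(Xw)
    return float(-np.log(probs[np.arange(len(y_idx)), y_idx] + 1e-12).mean())


def _encode(model: CNNLSTM, y) -> np.ndarray:
    lookup = {c: i for i, c in enumerate(model.classes)}
    return np.array([lookup[v] for v in y])


def fit(cfg: NetConfig, X: np.ndarray, y, Xw_val=None, y_val=None,
        log: list | None = None) -> CNNLSTM:
    """Train one CNN-LSTM on (X, y) with the configured augmentation.

    If a validation set is supplied, early stopping monitors its loss with
    ``cfg.patience``; validation data are never augmented.
    """
    model = build_model(cfg)
    rng = np.random.default_rng(cfg.seed + 1)
    Xw = window_matrix(np.asarray(X, dtype=float), cfg.k_s)
    y_idx = _encode(model, np.asarray(y))
    aug = augment_windows(Xw, cfg.augmentation, cfg.augment_pct, rng)
    Xw_train = np.concatenate([Xw, aug]) if aug.size else Xw
    y_train = np.concatenate([y_idx, y_idx[: aug.shape[0]]]) if aug.size else y_idx

    opt = model.make_optimizer()
    best_val = np.inf
    best_params = None
    stale = 0
    yv = _encode(model, np.asarray(y_val)) if y_val is not None else None
    for epoch in range(cfg.epochs):
        train_loss = _epoch(model, opt, Xw_train, y_train, rng)
        entry = {"epoch": epoch, "train_loss": train_loss}
        if Xw_val is not None:
            vloss = _val_loss(model, Xw_val, yv)
            entry["val_loss"] = vloss
            if vloss < best_val - 1e-6:
                best_val = vloss
                best_params = [p.copy() for p in model.params]
                stale = 0
            else:
                stale += 1
                if stale >= cfg.patience:
                    if log is not None:
                        log.append(entry)
                    break
        if log is not None:
            log.append(entry)
    if best_params is not None:
        for p, bp in zip(model.params, best_params):
            p[...] = bp
    return model


def _fold_metrics(model: CNNLSTM, Xw_val, y_val, fold, losses) -> FoldResult:
    labels = model.predict_windowed(Xw_val)
    conf = model.confidence_windowed(Xw_val)
    threshold = model.cfg.reject_threshold
    if threshold is not None:
        accept = conf >= threshold
    else:
        accept = np.ones(len(labels), dtype=bool)
    n_rej = int((~accept).sum())
    if accept.sum() == 0:
        prec = rec = f1 = float("nan")
    else:
        m = compute_metrics(np.asarray(y_val)[accept], labels[accept],
                            positive_class=TUMOR)
        prec, rec, f1 = m.precision, m.sensitivity, m.f1
    return FoldResult(fold=fold, precision=prec, recall=rec, f1=f1,
                      n_val=len(y_val), n_rejected=n_rej, loss_curve=losses)


def train_cv(cfg: NetConfig, X: np.ndarray, y, k: int = 5) -> CVResult:
    """Stratified k-fold cross-validation of the CNN-LSTM.

    Augmentation is applied to the training folds only; validation folds
    are scored as-is.  Rejected spectra (confidence below the configured
    threshold) are excluded from the fold precision/recall/F1.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=cfg.seed)
    folds: list[FoldResult] = []
    augmented_ids: list[set] = []
    val_ids: list[set] = []
    Xw_all = window_matrix(X, cfg.k_s)
    for fold, (train_idx, val_idx) in enumerate(skf.split(X, y)):
        fold_cfg = dataclasses.replace(cfg, seed=cfg.seed + fold)
        log: list = []
        model = fit(fold_cfg, X[train_idx], y[train_idx],
                    Xw_val=Xw_all[val_idx], y_val=y[val_idx], log=log)
        losses = [e["train_loss"] for e in log]
        folds.append(_fold_metrics(model, Xw_all[val_idx], y[val_idx],
                                   fold, losses))
        augmented_ids.append(
            set(train_idx.tolist()) if cfg.augmentation != "none" else set()
        )
        val_ids.append(set(val_idx.tolist()))
    return CVResult(folds=folds, cfg=cfg,
                    augmented_ids=augmented_ids, val_ids=val_ids)


# ------------------------------------------------------------------ ablation
#: (n_layers, learning rate, tuned dropout) of the two reference networks
ABLATION_ARCHS = ((25, 0.001, 0.15), (56, 0.01, 0.2))
ABLATION_REJECTS = (0.2, 0.8)


def ablation_grid(X, y, evaluator=None, base_cfg: NetConfig | None = None,
                  k: int = 5) -> pd.DataFrame:
    """16-row ablation: 2 architectures x 2 reject thresholds x 4
    augmentation modes, each scored by CV precision/recall/F1.

    ``evaluator(cfg) -> (precision, recall)`` may replace the (expensive)
    default of a full cross-validated training run.
    """
    base = base_cfg or NetConfig()

    def default_evaluator(cfg: NetConfig):
        res = train_cv(cfg, X, y, k=k)
        return res.mean_precision, res.mean_recall

    evaluator = evaluator or default_evaluator
    rows = []
    for n_layers, lr, dropout in ABLATION_ARCHS:
        for reject in ABLATION_REJECTS:
            for mode in AUGMENTATION_MODES:
                cfg = dataclasses.replace(
                    base, n_layers=n_layers, learning_rate=lr,
                    dropout=dropout, reject_threshold=reject,
                    augmentation=mode,
                )
                prec, rec = evaluator(cfg)
                f1 = harmonic_f1(prec, rec)
                rows.append(
                    {
                        "n_layers": n_layers, "lr": lr, "dropout": dropout,
                        "reject": reject, "augmentation": mode,
                        "precision": prec, "recall": rec, "f1": f1,
                    }
                )
    return pd.DataFrame(rows)
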