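"""Chemometric classifiers: PCA, LDA, grid-tuned LDA and PCA-LDA.

PCA is computed explicitly from the covariance matrix of the mean-centered
intensity matrix.  LDA and its tuned variants wrap
:class:`sklearn.discriminant_analysis.LinearDiscriminantAnalysis` behind a
uniform predict/confidence contract shared with the neural classifier, so
that every model can drive the blind-mixture evaluation the same way.
"""

from __future__ import annotations

import dataclasses
from typing import Callable, Iterable, Sequence

import numpy as np
from sklearn.discriminant_analysis import LinearDiscriminantAnalysis
from sklearn.model_selection import (
    GroupShuffleSplit,
    StratifiedKFold,
    train_test_split,
)

from .spectra import NON_TUMOR, TUMOR

__all__ = [
    "PCAModel",
    "Metrics",
    "CVConfig",
    "LinearModel",
    "pca_fit",
    "lda_fit",
    "lda_predict",
    "default_lda_grid",
    "tune_lda_grid",
    "pca_lda_loocv",
    "learning_curve",
    "compute_metrics",
    "harmonic_f1",
    "stratified_split",
    "cell_split",
]


# --------------------------------------------------------------------------- PCA
@dataclasses.dataclass
class PCAModel:
    mean_spectrum: np.ndarray
    components: np.ndarray            # (n_components, p), orthonormal rows
    explained_variance: np.ndarray    # eigenvalues, decreasing
    explained_variance_pct: np.ndarray

    def transform(self, X: np.ndarray, n_components: int | None = None) -> np.ndarray:
        W = self.components if n_components is None else self.components[:n_components]
        return (np.asarray(X) - self.mean_spectrum) @ W.T

    def inverse_transform(self, scores: np.ndarray, n_components: int | None = None):
        W = self.components if n_components is None else self.components[:n_components]
        return scores @ W + self.mean_spectrum

    def cumulative_variance_pct(self, n_components: int) -> float:
        return float(self.explained_variance_pct[:n_components].sum())


def pca_fit(X: np.ndarray) -> PCAModel:
    """Principal components from the eigendecomposition of the covariance
    matrix of the mean-centered data, sorted by decreasing variance."""
    X = np.asarray(X, dtype=float)
    if X.ndim != 2 or X.shape[0] < 2:
        raise ValueError("need at least two spectra")
    mean = X.mean(axis=0)
    C = np.cov(X - mean, rowvar=False, ddof=1)
    eigvals, eigvecs = np.linalg.eigh(np.atleast_2d(C))
    order = np.argsort(eigvals)[::-1]
    eigvals = np.clip(eigvals[order], 0.0, None)
    eigvecs = eigvecs[:, order]
    total = eigvals.sum()
    pct = 100.0 * eigvals / total if total > 0 else np.zeros_like(eigvals)
    return PCAModel(
        mean_spectrum=mean,
        components=eigvecs.T,
        explained_variance=eigvals,
        explained_variance_pct=pct,
    )


# --------------------------------------------------------------- metrics & CV
@dataclasses.dataclass
class Metrics:
    """Binary confusion counts and derived rates (positive class = Tumor)."""

    tn: int
    fp: int
    fn: int
    tp: int

    @property
    def n(self) -> int:
        return self.tn + self.fp + self.fn + self.tp

    @property
    def accuracy(self) -> float:
        return (self.tp + self.tn) / self.n

    @property
    def sensitivity(self) -> float:
        return self.tp / (self.tp + self.fn) if self.tp + self.fn else float("nan")

    @property
    def specificity(self) -> float:
        return self.tn / (self.tn + self.fp) if self.tn + self.fp else float("nan")

    @property
    def precision(self) -> float:
        return self.tp / (self.tp + self.fp) if self.tp + self.fp else float("nan")

    @property
    def f1(self) -> float:
        p, r = self.precision, self.sensitivity
        if not np.isfinite(p) or not np.isfinite(r) or p + r == 0:
            return float("nan")
        return 2.0 * p * r / (p + r)

    @property
    def confusion(self) -> np.ndarray:
        """2x2 counts, rows = true (Non-Tumor, Tumor), cols = predicted."""
        return np.array([[self.tn, self.fp], [self.fn, self.tp]])

    def as_percent(self, value: float) -> float:
        """Rate as a percentage rounded to 2 decimals (reporting convention)."""
        return round(100.0 * value, 2)


def harmonic_f1(precision: float, recall: float) -> float:
    """F1 as the harmonic mean of precision and recall."""
    if precision + recall == 0:
        return float("nan")
    return 2.0 * precision * recall / (precision + recall)


def compute_metrics(
    y_true: Sequence[str], y_pred: Sequence[str], positive_class: str = TUMOR
) -> Metrics:
    """Confusion counts and rates; sensitivity = recall on the Tumor class."""
    y_true = list(y_true)
    y_pred = list(y_pred)
    if len(y_true) == 0:
        raise ValueError("empty input")
    if len(y_true) != len(y_pred):
        raise ValueError("label vectors must have equal length")
    tp = fp = tn = fn = 0
    for t, p in zip(y_true, y_pred):
        if t == positive_class:
            if p == positive_class:
                tp += 1
            else:
                fn += 1
        else:
            if p == positive_class:
                fp += 1
            else:
                tn += 1
    return Metrics(tn=tn, fp=fp, fn=fn, tp=tp)


@dataclasses.dataclass
class CVConfig:
    k: int = 5
    split_mode: str = "spectrum"  # or "cell"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.k < 2:
            raise ValueError("k must be >= 2")
        if self.split_mode not in ("spectrum", "cell"):
            raise ValueError("split_mode must be 'spectrum' or 'cell'")


def stratified_split(X, y, test_size: float = 0.2, seed: int = 0):
    """Stratified random 80/20 (by default) spectrum-level split."""
    return train_test_split(
        X, np.asarray(y), test_size=test_size, random_state=seed, stratify=y
    )


def cell_split(X, y, groups, test_size: float = 0.2, seed: int = 0):
    """Cell-grouped split: no cell contributes spectra to both sides."""
    splitter = GroupShuffleSplit(n_splits=1, test_size=test_size, random_state=seed)
    (train_idx, test_idx), = splitter.split(X, y, groups=np.asarray(groups))
    y = np.asarray(y)
    return X[train_idx], X[test_idx], y[train_idx], y[test_idx]


# ----------------------------------------------------------------- classifiers
class LinearModel:
    """Uniform predict/confidence wrapper around a fitted linear discriminant
    (optionally preceded by a PCA projection)."""

    def __init__(self, estimator, name: str = "LDA", pca: PCAModel | None = None,
                 n_pc: int | None = None):
        self.estimator = estimator
        self.name = name
        self.pca = pca
        self.n_pc = n_pc
        self.preprocess_hash: str | None = None

    def _features(self, X):
        X = np.asarray(X, dtype=float)
        if self.pca is not None:
            return self.pca.transform(X, self.n_pc)
        return X

    def predict(self, X) -> np.ndarray:
        return self.estimator.predict(self._features(X))

    def confidence(self, X) -> np.ndarray:
        proba = self.estimator.predict_proba(self._features(X))
        return proba.max(axis=1)


def lda_fit(X, y, name: str = "LDA", **lda_kwargs) -> LinearModel:
    """Plain linear discriminant with empirical class priors."""
    y = np.asarray(y)
    if np.unique(y).size < 2:
        raise ValueError("LDA needs two classes")
    est = LinearDiscriminantAnalysis(**lda_kwargs)
    est.fit(np.asarray(X, dtype=float), y)
    return LinearModel(est, name=name)


def lda_predict(model: LinearModel, X) -> np.ndarray:
    return model.predict(X)


def default_lda_grid() -> list[dict]:
    """The standard tunable surface of LDA: solver x shrinkage x priors."""
    grid: list[dict] = []
    priors_options = (None, [0.5, 0.5])
    for priors in priors_options:
        grid.append({"solver": "svd", "priors": priors})
        for solver in ("lsqr", "eigen"):
            for shrinkage in (None, "auto", 0.1, 0.3, 0.5, 0.7, 0.9):
                grid.append({"solver": solver, "shrinkage": shrinkage, "priors": priors})
    return grid


def _cv_accuracy(params: dict, X, y, cv: CVConfig, groups=None) -> float:
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    skf = StratifiedKFold(n_splits=cv.k, shuffle=True, random_state=cv.seed)
    accs = []
    for train_idx, val_idx in skf.split(X, y):
        est = LinearDiscriminantAnalysis(**params)
        try:
            est.fit(X[train_idx], y[train_idx])
        except np.linalg.LinAlgError:
            # e.g. the eigen solver without shrinkage on singular
            # within-class scatter (p > n): infeasible configuration
            return -np.inf
        accs.append(float(np.mean(est.predict(X[val_idx]) == y[val_idx])))
    return float(np.mean(accs))


def tune_lda_grid(
    X, y, grid: list[dict] | None = None, cv: CVConfig | None = None
) -> tuple[LinearModel, list[tuple[dict, float]]]:
    """Exhaustive grid search over LDA hyper-parameters by k-fold CV accuracy.

    The best configuration (ties broken by first-in-grid order) is refitted
    on the full data.  Returns the model and the (params, cv_accuracy)
    history.
    """
    grid = default_lda_grid() if grid is None else list(grid)
    if not grid:
        raise ValueError("grid must be non-empty")
    cv = cv or CVConfig()
    history = [(params, _cv_accuracy(params, X, y, cv)) for params in grid]
    best_idx = int(np.argmax([acc for _, acc in history]))
    best_params = history[best_idx][0]
    est = LinearDiscriminantAnalysis(**best_params)
    est.fit(np.asarray(X, dtype=float), np.asarray(y))
    model = LinearModel(est, name="Hyper-parameter-tuned LDA")
    model.grid_history = history
    model.best_params = best_params
    return model, history


def pca_lda_loocv(
    X, y, pc_range: Iterable[int] = range(5, 61)
) -> tuple[int, LinearModel, dict]:
    """Select the number of leading principal components for LDA by
    leave-one-out cross-validation.

    For each candidate count the LOOCV misclassification error of LDA on
    the leading-PC scores is computed; the count minimizing the error wins
    (smallest count on ties).  Returns the selected count, the final
    PCA+LDA model fitted on all data, and a detail dict with the error
    curve and the cumulative explained variance of the selection.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    n = X.shape[0]
    pca = pca_fit(X)
    max_pc = pca.components.shape[0]
    candidates = [c for c in pc_range if 1 <= c <= min(max_pc, n - 2)]
    if not candidates:
        raise ValueError("pc_range contains no feasible candidate")
    scores_full = pca.transform(X, max(candidates))
    errors = {}
    for n_pc in candidates:
        S = scores_full[:, :n_pc]
        wrong = 0
        for i in range(n):
            mask = np.ones(n, dtype=bool)
            mask[i] = False
            est = LinearDiscriminantAnalysis()
            est.fit(S[mask], y[mask])
            wrong += int(est.predict(S[i : i + 1])[0] != y[i])
        errors[n_pc] = wrong / n
    best = min(candidates, key=lambda c: (errors[c], c))
    est = LinearDiscriminantAnalysis()
    est.fit(scores_full[:, :best], y)
    model = LinearModel(est, name="PCA-LDA", pca=pca, n_pc=best)
    detail = {
        "loocv_error": errors,
        "cumulative_variance_pct": pca.cumulative_variance_pct(best),
    }
    return best, model, detail


def learning_curve(
    model_builder: Callable[[], object],
    X,
    y,
    cv: CVConfig | None = None,
    train_sizes: Sequence[int] | None = None,
) -> list[tuple[int, float, float]]:
    """Train/CV accuracy as a function of training-set size.

    For each size, each of the k folds is held out once while a random
    stratified subsample of the remaining data of that size is used for
    training.  Returns (n_train, mean train accuracy, mean CV accuracy)
    per grid point.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    cv = cv or CVConfig()
    n = X.shape[0]
    max_train = n - n // cv.k
    if train_sizes is None:
        train_sizes = np.unique(
            np.linspace(max(10, 2 * cv.k), max_train, 8, dtype=int)
        )
    rng = np.random.default_rng(cv.seed)
    skf = StratifiedKFold(n_splits=cv.k, shuffle=True, random_state=cv.seed)
    folds = list(skf.split(X, y))
    curve = []
    for size in train_sizes:
        if size > max_train:
            raise ValueError(f"train size {size} exceeds available data ({max_train})")
        train_accs, val_accs = [], []
        for train_idx, val_idx in folds:
            sub = rng.choice(train_idx, size=size, replace=False)
            if np.unique(y[sub]).size < 2:  # force both classes into tiny draws
                sub = np.concatenate(
                    [
                        rng.choice(train_idx[y[train_idx] == c], size=size // 2,
                                   replace=False)
                        for c in np.unique(y)
                    ]
                )
            est = model_builder()
            est.fit(X[sub], y[sub])
            train_accs.append(float(np.mean(est.predict(X[sub]) == y[sub])))
            val_accs.append(float(np.mean(est.predict(X[val_idx]) == y[val_idx])))
        curve.append((int(size), float(np.mean(train_accs)), float(np.mean(val_accs))))
    return curve
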