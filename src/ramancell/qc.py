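"""PLS-based outlier screening with Q-residual and Hotelling T2 statistics.

A PLS1-DA decomposition (class indicator as the response) is fitted to the
preprocessed spectra.  For each spectrum the squared norm of its X-residual
(Q, also called SPE) and its Mahalanobis distance in score space (T2) are
computed.  Spectra exceeding the 95% confidence limits — Q via the
Jackson-Mudholkar approximation from the residual eigenvalues, T2 via the
F-distribution — are flagged as outliers.
"""

from __future__ import annotations

import dataclasses

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.cross_decomposition import PLSRegression

from .spectra import TUMOR, SpectrumSet

__all__ = ["OutlierModel", "OutlierReport", "fit_outlier_model", "flag_outliers"]


@dataclasses.dataclass
class OutlierModel:
    n_components: int
    scores: np.ndarray       # (n, A) latent coordinates
    q_stats: np.ndarray      # (n,) squared reconstruction residuals
    t2_stats: np.ndarray     # (n,) Mahalanobis distances in score space
    q_limit: float
    t2_limit: float
    confidence: float = 0.95


@dataclasses.dataclass
class OutlierReport:
    table: pd.DataFrame          # spectrum id, Q, T2, per-rule flags
    removed_per_class: dict      # class label -> flagged count
    rule: str

    def to_tsv(self, path) -> None:
        self.table.to_csv(path, sep="\t", index=False)


def _jackson_mudholkar_limit(residual_eigvals: np.ndarray, alpha: float) -> float:
    """95% (1-alpha) confidence limit of the Q statistic from the eigenvalues
    of the residual covariance."""
    lam = residual_eigvals[residual_eigvals > 1e-12 * residual_eigvals.max()] \
        if residual_eigvals.size and residual_eigvals.max() > 0 else residual_eigvals
    theta1 = lam.sum()
    theta2 = (lam**2).sum()
    theta3 = (lam**3).sum()
    if theta1 <= 0 or theta2 <= 0:
        return float(np.finfo(float).tiny)
    h0 = 1.0 - 2.0 * theta1 * theta3 / (3.0 * theta2**2)
    if h0 <= 0:  # heavy-tailed eigenvalue spectrum: fall back to h0 -> small
        h0 = 1e-3
    z = stats.norm.ppf(1.0 - alpha)
    inner = (
        z * np.sqrt(2.0 * theta2 * h0**2) / theta1
        + 1.0
        + theta2 * h0 * (h0 - 1.0) / theta1**2
    )
    if inner <= 0:
        return float(theta1)
    return float(theta1 * inner ** (1.0 / h0))


def fit_outlier_model(
    spectrum_set: SpectrumSet, n_components: int = 5, confidence: float = 0.95
) -> OutlierModel:
    """Fit the PLS outlier model on a labeled, preprocessed set.

    The response is the class indicator (Non-Tumor = 0, Tumor = 1).
    """
    X = spectrum_set.to_matrix()
    labels = spectrum_set.labels()
    if any(l is None for l in labels):
        raise ValueError("outlier screening needs labeled spectra")
    y = np.array([1.0 if l == TUMOR else 0.0 for l in labels])
    n, p = X.shape
    if n_components >= n:
        raise ValueError("n_components must be < number of spectra")
    if np.allclose(X.std(axis=0), 0):
        raise ValueError("degenerate (constant) data")

    pls = PLSRegression(n_components=n_components, scale=False)
    pls.fit(X, y)
    T = pls.x_scores_                       # (n, A)
    P = pls.x_loadings_                     # (p, A)
    Xc = X - X.mean(axis=0)
    E = Xc - T @ P.T                        # X-residuals
    q = np.einsum("ij,ij->i", E, E)

    score_var = T.var(axis=0, ddof=1)
    score_var = np.where(score_var > 0, score_var, np.inf)
    t2 = ((T**2) / score_var).sum(axis=1)

    alpha = 1.0 - confidence
    # residual eigenvalues via SVD of E
    sv = np.linalg.svd(E, compute_uv=False)
    residual_eig = sv**2 / max(n - 1, 1)
    q_limit = _jackson_mudholkar_limit(residual_eig, alpha)
    A = n_components
    t2_limit = float(
        A * (n - 1) / (n - A) * stats.f.ppf(confidence, A, n - A)
    )
    return OutlierModel(
        n_components=n_components,
        scores=T,
        q_stats=q,
        t2_stats=t2,
        q_limit=q_limit,
        t2_limit=t2_limit,
        confidence=confidence,
    )


def flag_outliers(
    spectrum_set: SpectrumSet,
    model: OutlierModel,
    rule: str = "either",
) -> tuple[SpectrumSet, OutlierReport]:
    """Set ``outlier_flag`` on spectra exceeding the confidence limits.

    rule="either" flags Q > q_limit OR T2 > t2_limit (conservative
    screening); rule="both" requires both statistics to exceed their limit.
    Returns a new set (flags set, spectra retained) and a report.
    """
    if rule not in ("either", "both"):
        raise ValueError("rule must be 'either' or 'both'")
    if len(spectrum_set) != model.q_stats.size:
        raise ValueError("model was not fitted on this set")
    q_flag = model.q_stats > model.q_limit
    t2_flag = model.t2_stats > model.t2_limit
    combined = (q_flag | t2_flag) if rule == "either" else (q_flag & t2_flag)

    flagged = [s.copy(outlier_flag=bool(f)) for s, f in zip(spectrum_set, combined)]
    removed: dict[str, int] = {}
    for s, f in zip(spectrum_set, combined):
        if f:
            key = s.label if s.label is not None else "unknown"
            removed[key] = removed.get(key, 0) + 1
    table = pd.DataFrame(
        {
            "spectrum": np.arange(len(spectrum_set)),
            "cell_id": spectrum_set.cell_ids(),
            "label": [s.label for s in spectrum_set],
            "Q": model.q_stats,
            "T2": model.t2_stats,
            "q_flag": q_flag,
            "t2_flag": t2_flag,
            "outlier": combined,
        }
    )
    out = SpectrumSet(flagged, meta=dict(spectrum_set.meta))
    return out, OutlierReport(table=table, removed_per_class=removed, rule=rule)
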