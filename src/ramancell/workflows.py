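"""End-to-end study workflows on the synthetic two-class task.

``run_synthetic_study`` reproduces the full analysis campaign on simulated
data: generate the campaign-scale dataset (40 cells per class, 5 spectra per
cell, 10% corrupted acquisitions), preprocess, screen outliers, train the
tuned-LDA and PCA-LDA classifiers on an 80/20 stratified split,
cross-validate the CNN-LSTM, and estimate the tumor fraction of blind
4:1 and 3:2 cell mixtures.  Problem sizes (2 cm^-1 axis step, reduced
CNN filter counts, 5-step PC scan) are chosen so the whole study runs in
minutes on one CPU core; see docs/methods.md.
"""

from __future__ import annotations

import dataclasses

import numpy as np

from . import chemometrics, deep, evaluate, preprocess, qc, synth
from .spectra import NON_TUMOR, TUMOR

__all__ = ["run_synthetic_study", "null_t2_flag_rate"]


def null_t2_flag_rate(n: int = 2000, p: int = 20, n_components: int = 5,
                      seed: int = 0) -> float:
    """Fraction of multivariate-normal null samples flagged by the
    Hotelling-T2 rule alone; calibrated limits should flag ~5%."""
    rng = np.random.default_rng(seed)
    X = rng.normal(size=(n, p))
    y = rng.integers(0, 2, size=n)
    from sklearn.cross_decomposition import PLSRegression
    from scipy import stats as sps

    pls = PLSRegression(n_components=n_components, scale=False)
    pls.fit(X, y.astype(float))
    T = pls.x_scores_
    var = T.var(axis=0, ddof=1)
    t2 = ((T**2) / var).sum(axis=1)
    A = n_components
    limit = A * (n - 1) / (n - A) * sps.f.ppf(0.95, A, n - A)
    return float(np.mean(t2 > limit))


def run_synthetic_study(
    seed: int = 0,
    n_cells_per_class: int = 40,
    spectra_per_cell: int = 5,
    outlier_fraction: float = 0.1,
    axis_step: float = 2.0,
    cnn_epochs: int = 80,
    cnn_filters: tuple[int, ...] = (8, 16, 32),
    run_cnn: bool = True,
) -> dict:
    """Run the complete synthetic study; returns a flat dict of results."""
    seed = int(seed) % (2**31 - 1)
    axis = np.arange(600.0, 1800.0 + axis_step, axis_step)
    cfg = synth.SimConfig(
        n_cells_per_class=n_cells_per_class,
        spectra_per_cell=spectra_per_cell,
        axis=axis,
        outlier_fraction=outlier_fraction,
        seed=seed,
    )
    bands = synth.default_band_table()
    raw = synth.generate_dataset(cfg, bands)

    pre_cfg = preprocess.PreprocessConfig()
    data = preprocess.run_pipeline(raw, cfg=pre_cfg)

    # ------------------------------------------------------------- QC stage
    model_qc = qc.fit_outlier_model(data, n_components=5)
    flagged, report = qc.flag_outliers(data, model_qc, rule="either")
    truth = np.array([bool(s.meta.get("corrupted", False)) for s in raw])
    detected = np.array([s.outlier_flag for s in flagged])
    n_corrupt = int(truth.sum())
    detection_rate = float(detected[truth].mean()) if n_corrupt else float("nan")
    false_rate = float(detected[~truth].mean())
    clean = flagged.without_outliers()
    counts = clean.class_counts()

    results = {
        "n_spectra_raw": len(raw),
        "n_corrupted": n_corrupt,
        "outlier_detection_rate": detection_rate,
        "outlier_false_flag_rate": false_rate,
        "retained_tumor": counts.get(TUMOR, 0),
        "retained_nontumor": counts.get(NON_TUMOR, 0),
        "null_t2_flag_rate": null_t2_flag_rate(seed=seed),
    }

    # ------------------------------------------------- chemometric classifiers
    X = clean.to_matrix()
    y = np.array([s.label for s in clean])
    X_tr, X_te, y_tr, y_te = chemometrics.stratified_split(X, y, seed=seed)

    cv = chemometrics.CVConfig(k=5, seed=seed)
    tuned, _ = chemometrics.tune_lda_grid(X_tr, y_tr, cv=cv)
    tuned.preprocess_hash = data.meta["preprocess_hash"]
    m_tuned = chemometrics.compute_metrics(y_te, tuned.predict(X_te))
    results["tuned_lda_test_accuracy"] = m_tuned.accuracy
    results["tuned_lda_test_sensitivity"] = m_tuned.sensitivity
    results["tuned_lda_test_specificity"] = m_tuned.specificity

    n_pc, pca_lda, detail = chemometrics.pca_lda_loocv(
        X_tr, y_tr, pc_range=range(5, 61, 5)
    )
    pca_lda.preprocess_hash = data.meta["preprocess_hash"]
    m_pca = chemometrics.compute_metrics(y_te, pca_lda.predict(X_te))
    results["pca_lda_test_accuracy"] = m_pca.accuracy
    results["pca_lda_n_components"] = n_pc
    results["pca_lda_cumulative_variance_pct"] = detail["cumulative_variance_pct"]

    # ----------------------------------------------------------- CNN-LSTM CV
    if run_cnn:
        net_cfg = deep.NetConfig(
            n_layers=25,
            conv_filters=cnn_filters,
            epochs=cnn_epochs,
            patience=10,
            n_points=X.shape[1],
            seed=seed,
        )
        cv_res = deep.train_cv(net_cfg, X, y, k=5)
        results["cnn_cv_f1"] = cv_res.mean_f1
        results["cnn_cv_precision"] = cv_res.mean_precision
        results["cnn_cv_recall"] = cv_res.mean_recall

    # --------------------------------------------------------- blind mixtures
    mixtures = {}
    for name, (n_t, n_nt) in {"mix_80": (16, 4), "mix_60": (12, 8)}.items():
        mix_cfg = dataclasses.replace(cfg, seed=seed + 1000 + n_t)
        blind_raw, nominal = synth.generate_mixture(n_t, n_nt, mix_cfg, bands)
        blind = preprocess.run_pipeline(blind_raw, cfg=pre_cfg)
        rep_tuned = evaluate.blind_predict(tuned, blind)
        rep_pca = evaluate.blind_predict(pca_lda, blind)
        mixtures[name] = {
            "nominal_pct": nominal,
            "tuned_lda_pct": rep_tuned.percent_tumor,
            "pca_lda_pct": rep_pca.percent_tumor,
            "n_spectra": rep_tuned.n_spectra,
        }
    results["mixtures"] = mixtures
    return results
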