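"""Estimate the tumor fraction of blind cell mixtures by vote counting.

Cells are mixed at known 4:1 and 3:2 Tumor/Non-Tumor ratios, their labels
hidden, and the spectra pushed through the same preprocessing as the
training data; each spectrum's class vote contributes to the estimated
tumor percentage.
"""

import warnings

import numpy as np

from ramancell import chemometrics as cm
from ramancell import evaluate, preprocess, qc, synth

warnings.simplefilter("ignore", RuntimeWarning)

cfg = synth.SimConfig(
    n_cells_per_class=40, axis=np.arange(600.0, 1802.0, 2.0),
    outlier_fraction=0.1, seed=1,
)
data = preprocess.run_pipeline(synth.generate_dataset(cfg))
clean = qc.flag_outliers(data, qc.fit_outlier_model(data, 5))[0].without_outliers()
X = clean.to_matrix()
y = np.array([s.label for s in clean])

tuned, _ = cm.tune_lda_grid(X, y, cv=cm.CVConfig(k=5, seed=1))
tuned.preprocess_hash = data.meta["preprocess_hash"]

reports = {"Hyper-parameter tuned LDA": []}
names = []
for name, (n_t, n_nt) in {"MIX1 (80%)": (16, 4), "MIX2 (60%)": (12, 8)}.items():
    mix_cfg = synth.SimConfig(
        n_cells_per_class=40, axis=cfg.axis, outlier_fraction=0.0,
        seed=100 + n_t,
    )
    blind_raw, nominal = synth.generate_mixture(n_t, n_nt, mix_cfg)
    blind = preprocess.run_pipeline(blind_raw)
    reports["Hyper-parameter tuned LDA"].append(
        evaluate.blind_predict(tuned, blind)
    )
    names.append(name)

table, text = evaluate.compare_models(reports, set_names=names)
print(text)
# Each column is one blind set; the model's estimated tumor percentage
# should track the nominal row to within a few points.
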