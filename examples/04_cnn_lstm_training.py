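"""Cross-validate the windowed CNN-LSTM classifier.

Each spectrum is cut into 3 slices feeding a shared convolutional stack; a
100-unit LSTM reads the slice sequence and a softmax head classifies.  A
compact filter configuration keeps the run to a couple of minutes on one
CPU core while preserving the architecture.
"""

import warnings

import numpy as np

from ramancell import deep, preprocess, qc, synth

warnings.simplefilter("ignore", RuntimeWarning)

cfg = synth.SimConfig(
    n_cells_per_class=40, axis=np.arange(600.0, 1802.0, 2.0),
    outlier_fraction=0.1, seed=1,
)
data = preprocess.run_pipeline(synth.generate_dataset(cfg))
clean = qc.flag_outliers(data, qc.fit_outlier_model(data, 5))[0].without_outliers()
X = clean.to_matrix()
y = np.array([s.label for s in clean])

net_cfg = deep.NetConfig(
    n_layers=25, conv_filters=(8, 16, 32), n_points=X.shape[1],
    epochs=80, patience=10, seed=1,
)
print("architecture:", " -> ".join(deep.layer_manifest(net_cfg)[:8]), "...")
result = deep.train_cv(net_cfg, X, y, k=5)
print(result.table().to_string(index=False))
print(f"mean CV F1: {result.mean_f1:.3f}")
# Per-fold precision/recall/F1 on held-out folds; augmentation (if
# enabled) is applied to training folds only.
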