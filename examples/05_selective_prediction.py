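"""Selective prediction: let the network abstain when it is uncertain.

A CNN-LSTM trained with the SelectiveNet-style confidence branch emits a
confidence score per spectrum; predictions below the threshold are
rejected.  Sweeping the threshold trades coverage for precision.
"""

import numpy as np

from ramancell import deep
from ramancell.spectra import NON_TUMOR, TUMOR

rng = np.random.default_rng(0)
n, p = 120, 96
X = rng.normal(0.0, 0.3, size=(n, p))
y = np.array([NON_TUMOR, TUMOR] * (n // 2))
bump = np.exp(-0.5 * ((np.arange(p) - p / 3) / 4.0) ** 2)
X[y == TUMOR] += 2.5 * bump
# an ambiguous subpopulation: weak signal, labels uninformative there
ambiguous = rng.random(n) < 0.3
X[ambiguous & (y == TUMOR)] -= 2.3 * bump

cfg = deep.NetConfig(
    n_layers=25, conv_filters=(2, 3, 4), n_points=p, lstm_units=8,
    dense_hidden=6, reject_threshold=0.8, learning_rate=0.005,
    target_coverage=0.7,  # ~30% of the inputs are genuinely ambiguous
    epochs=60, seed=0,
)
model = deep.fit(cfg, X, y)

for threshold in (0.0, 0.5, 0.8, 0.95):
    preds = deep.selective_predict(model, X, threshold)
    kept = [(p_.label, t) for p_, t in zip(preds, y) if p_.label != deep.REJECT]
    coverage = len(kept) / n
    acc = np.mean([l == t for l, t in kept]) if kept else float("nan")
    print(f"threshold {threshold:4.2f}: coverage {coverage:5.1%}, "
          f"accuracy on accepted {acc:6.1%}")
# Raising the threshold rejects more spectra (lower coverage) and should
# keep the accepted predictions at least as accurate.
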