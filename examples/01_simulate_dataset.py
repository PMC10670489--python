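"""Simulate a two-class single-cell Raman dataset and write it to disk.

Generates the study-design layout — 40 Tumor and 40 Non-Tumor cells, five
nucleus-focused acquisitions per cell on the 600-1800 cm^-1 fingerprint
grid — with 10% of the spectra corrupted by cosmic-ray spikes or
fluorescence bursts, then saves one CSV per spectrum plus a manifest.
"""

import numpy as np

from ramancell import synth

cfg = synth.SimConfig(
    n_cells_per_class=40,
    spectra_per_cell=5,
    axis=np.arange(600.0, 1802.0, 2.0),
    outlier_fraction=0.1,
    seed=1,
)
dataset = synth.generate_dataset(cfg)

counts = dataset.class_counts()
n_corrupted = sum(bool(s.meta.get("corrupted", False)) for s in dataset)
manifest = dataset.write("scratch/simulated_dataset")

print(f"spectra per class: {counts}")
print(f"corrupted (ground-truth outliers): {n_corrupted}")
print(f"manifest written to: {manifest}")
# 200 spectra per class mirror the acquisition campaign; the corrupted
# fraction is what the QC stage is expected to find and remove.
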