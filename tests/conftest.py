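import warnings

import numpy as np
import pytest

from ramancell import preprocess, synth, workflows


@pytest.fixture(scope="session")
def bands():
    return synth.default_band_table()


@pytest.fixture(scope="session")
def small_dataset(bands):
    """Compact two-class dataset: 6 cells per class, step-2 axis, no
    corruption — fast input for preprocessing/classifier unit tests."""
    cfg = synth.SimConfig(
        n_cells_per_class=6,
        axis=np.arange(600.0, 1802.0, 2.0),
        outlier_fraction=0.0,
        seed=7,
    )
    return cfg, synth.generate_dataset(cfg, bands)


@pytest.fixture(scope="session")
def small_preprocessed(small_dataset):
    _, raw = small_dataset
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        return preprocess.run_pipeline(raw)


@pytest.fixture(scope="session")
def campaign_study():
    """The full synthetic study at campaign-scale conditions (40 cells per
    class, 5 spectra per cell, 10% corrupted), including the CNN-LSTM
    cross-validation.  Computed once per session."""
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        return workflows.run_synthetic_study(seed=1)
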