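"""Fixed-size windowing of spectra and window-level augmentation.

Each preprocessed spectrum is cut into ``k_s`` contiguous, non-overlapping,
equal-length slices (trailing points beyond a multiple of ``k_s`` are
dropped); each slice feeds one channel of the CNN ensemble.  Two
augmentations operate at the window level: a multiplicative intensity
perturbation and a random shift of the frequency axis, both bounded by a
small percentage (10% by default).
"""

from __future__ import annotations

import dataclasses

import numpy as np

from ..spectra import Spectrum

__all__ = [
    "WindowedSpectrum",
    "window_spectrum",
    "window_matrix",
    "augment_value",
    "augment_frequency",
    "frequency_shift",
]


@dataclasses.dataclass
class WindowedSpectrum:
    slices: list[np.ndarray]
    source_id: str = ""

    @property
    def k_s(self) -> int:
        return len(self.slices)

    def concatenated(self) -> np.ndarray:
        return np.concatenate(self.slices)


def window_spectrum(s: Spectrum | np.ndarray, k_s: int = 3) -> WindowedSpectrum:
    """Cut a spectrum into ``k_s`` equal, contiguous, non-overlapping slices."""
    if k_s < 1:
        raise ValueError("k_s must be >= 1")
    if isinstance(s, Spectrum):
        values, source_id = s.intensities, s.cell_id
    else:
        values, source_id = np.asarray(s, dtype=float), ""
    if values.size < k_s:
        raise ValueError("spectrum shorter than the number of slices")
    length = values.size // k_s
    slices = [values[i * length : (i + 1) * length].copy() for i in range(k_s)]
    return WindowedSpectrum(slices=slices, source_id=source_id)


def window_matrix(X: np.ndarray, k_s: int = 3) -> np.ndarray:
    """Window every row of an (n, p) matrix: returns (n, k_s, p // k_s)."""
    X = np.asarray(X, dtype=float)
    if k_s < 1:
        raise ValueError("k_s must be >= 1")
    length = X.shape[1] // k_s
    return X[:, : k_s * length].reshape(X.shape[0], k_s, length)


def augment_value(
    window: np.ndarray, pct: float = 10.0, rng: np.random.Generator | None = None
) -> np.ndarray:
    """Scale the whole window by a factor drawn uniformly in [1-pct%, 1+pct%]."""
    if pct < 0:
        raise ValueError("pct must be >= 0")
    rng = np.random.default_rng() if rng is None else rng
    factor = 1.0 + rng.uniform(-pct / 100.0, pct / 100.0)
    return np.asarray(window, dtype=float) * factor


def frequency_shift(window: np.ndarray, shift: float) -> np.ndarray:
    """Resample the window after translating its index axis by ``shift``
    points; edges are padded with the boundary value.  Length is unchanged."""
    window = np.asarray(window, dtype=float)
    idx = np.arange(window.size, dtype=float)
    return np.interp(idx - shift, idx, window)


def augment_frequency(
    window: np.ndarray, pct: float = 10.0, rng: np.random.Generator | None = None
) -> np.ndarray:
    """Shift the frequency axis of the window by a random amount of
    magnitude <= pct% of the window span."""
    if pct < 0:
        raise ValueError("pct must be >= 0")
    rng = np.random.default_rng() if rng is None else rng
    window = np.asarray(window, dtype=float)
    shift = rng.uniform(-1.0, 1.0) * pct / 100.0 * window.size
    return frequency_shift(window, shift)
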