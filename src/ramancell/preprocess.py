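"""Spectral preprocessing chain.

Order is fixed: axis calibration against the 520.7 cm^-1 silicon line,
substrate background subtraction, cropping to the 600-1800 cm^-1
fingerprint region, iterative polynomial (order 3) baseline correction and
unit-L2 vector normalization.  Every preprocessed spectrum leaves the
pipeline with unit Euclidean norm and no points outside the fingerprint
interval.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import warnings

import numpy as np

from .spectra import FINGERPRINT, Spectrum, SpectrumSet

SILICON_LINE = 520.7  # cm^-1, crystalline Si reference

PIPELINE_ORDER = (
    "calibrate_axis",
    "subtract_background",
    "crop",
    "baseline_correct",
    "vector_normalize",
)


@dataclasses.dataclass
class PreprocessConfig:
    baseline_order: int = 3
    baseline_max_iter: int = 100
    baseline_tol: float = 1e-4
    reference_si_line: float = SILICON_LINE
    crop_range: tuple[float, float] = FINGERPRINT
    normalize: bool = True

    def __post_init__(self) -> None:
        if self.baseline_order < 0:
            raise ValueError("baseline_order must be >= 0")
        if self.baseline_tol <= 0:
            raise ValueError("baseline_tol must be positive")

    def hash(self) -> str:
        """Stable digest of the configuration + pipeline order, used to
        verify that blind sets were preprocessed like the training data."""
        payload = json.dumps(
            {**dataclasses.asdict(self), "order": PIPELINE_ORDER}, sort_keys=True
        )
        return hashlib.sha1(payload.encode()).hexdigest()


def spot_diameter(wavelength: float, numerical_aperture: float) -> float:
    """Diffraction-limited laser spot diameter 1.22*lambda/NA (nm in, nm out)."""
    if wavelength <= 0:
        raise ValueError("wavelength must be positive")
    if not 0 < numerical_aperture <= 1.5:
        raise ValueError("numerical aperture must be in (0, 1.5]")
    return 1.22 * wavelength / numerical_aperture


def calibrate_axis(
    s: Spectrum, measured_si_line: float, reference: float = SILICON_LINE
) -> Spectrum:
    """Rigid axis translation aligning the measured Si line to the reference."""
    offset = reference - measured_si_line
    if abs(offset) > 10.0:
        raise ValueError(
            f"measured Si line off by {-offset:.1f} cm^-1 (> 10): instrument fault?"
        )
    return s.copy(shifts=s.shifts + offset)


def subtract_background(s: Spectrum, bg: Spectrum) -> Spectrum:
    """Subtract the substrate background, linearly interpolated onto the
    sample grid if the two grids differ."""
    if bg.shifts[0] > s.shifts[0] or bg.shifts[-1] < s.shifts[-1]:
        raise ValueError("background grid does not cover the sample grid")
    bg_interp = np.interp(s.shifts, bg.shifts, bg.intensities)
    return s.copy(intensities=s.intensities - bg_interp)


def crop(s: Spectrum, lo: float = FINGERPRINT[0], hi: float = FINGERPRINT[1]) -> Spectrum:
    """Restrict to the closed interval [lo, hi] cm^-1."""
    mask = (s.shifts >= lo) & (s.shifts <= hi)
    if not mask.any():
        raise ValueError("crop interval contains no points")
    return s.copy(shifts=s.shifts[mask], intensities=s.intensities[mask])


def baseline_correct(
    s: Spectrum, cfg: PreprocessConfig | None = None
) -> tuple[Spectrum, np.ndarray]:
    """Remove the smooth fluorescence background by iterative polynomial
    fitting (modified polyfit).

    A polynomial of ``baseline_order`` is fitted, the working signal is
    clipped to the fitted curve (peaks are progressively excluded), and the
    fit repeats until the relative change of the baseline drops below
    ``baseline_tol`` or ``baseline_max_iter`` is reached.  On a peak-free
    polynomial input of degree <= order the first fit is already exact.

    Returns the corrected spectrum and the estimated baseline.
    """
    cfg = cfg or PreprocessConfig()
    if len(s) <= cfg.baseline_order + 1:
        raise ValueError("spectrum too short for the requested baseline order")
    x, y = s.shifts, s.intensities
    work = y.copy()
    prev = None
    fit = np.zeros_like(y)
    for _ in range(cfg.baseline_max_iter):
        poly = np.polynomial.Polynomial.fit(x, work, deg=cfg.baseline_order)
        fit = poly(x)
        work = np.minimum(work, fit)
        if prev is not None:
            denom = np.linalg.norm(prev)
            if denom == 0 or np.linalg.norm(fit - prev) / denom < cfg.baseline_tol:
                break
        prev = fit
    else:
        warnings.warn("baseline correction did not converge", RuntimeWarning)
    return s.copy(intensities=y - fit), fit


def vector_normalize(s: Spectrum) -> Spectrum:
    """Scale intensities to unit Euclidean norm."""
    norm = np.linalg.norm(s.intensities)
    if norm == 0:
        raise ValueError("cannot normalize an all-zero spectrum")
    return s.copy(intensities=s.intensities / norm)


def run_pipeline(
    spectrum_set: SpectrumSet,
    bg: Spectrum | None = None,
    cfg: PreprocessConfig | None = None,
    measured_si_line: float | None = None,
) -> SpectrumSet:
    """Apply the full chain to every raw spectrum of the set.

    ``measured_si_line=None`` skips the (identity) calibration step;
    ``bg=None`` skips background subtraction.  The output carries the
    configuration hash in ``meta['preprocess_hash']``.
    """
    cfg = cfg or PreprocessConfig()
    out = []
    for s in spectrum_set:
        if s.stage != "raw":
            raise ValueError("run_pipeline expects raw spectra")
        if measured_si_line is not None:
            s = calibrate_axis(s, measured_si_line, cfg.reference_si_line)
        if bg is not None:
            s = subtract_background(s, bg)
        s = crop(s, *cfg.crop_range)
        s, _ = baseline_correct(s, cfg)
        if cfg.normalize:
            s = vector_normalize(s)
        s.stage = "preprocessed"
        out.append(s)
    meta = dict(spectrum_set.meta)
    meta["preprocess_hash"] = cfg.hash()
    return SpectrumSet(out, meta=meta)
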