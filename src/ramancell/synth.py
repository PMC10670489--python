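"""Synthetic two-class Raman datasets for single liver cells.

The generator emulates the statistical structure of a nucleus-focused
Raman study of primary hepatocellular-carcinoma (HCC) cells versus cells
from the adjacent non-tumor tissue: ~40 cells per class with 5 spectra per
cell on the 600-1800 cm^-1 fingerprint grid, pseudo-Voigt peaks at the
canonical biomolecular band positions, a smooth cubic fluorescence
baseline, additive Gaussian noise, per-cell heterogeneity of the
nucleic-acid signal and a small fraction of corrupted (outlier)
acquisitions.

The class contrast is concentrated where DNA/RNA bands sit: Tumor cells
carry more nucleic acid (782-785, 1094, 1335, 1370, 1578 cm^-1 elevated),
while the Amide III band near 1240 cm^-1 and the CH2/CH3 deformation band
at 1438 cm^-1 are stronger in Non-Tumor cells.
"""

from __future__ import annotations

import dataclasses

import numpy as np

from .spectra import FINGERPRINT, NON_TUMOR, TUMOR, Spectrum, SpectrumSet

__all__ = [
    "BandSpec",
    "SimConfig",
    "default_band_table",
    "generate_spectrum",
    "generate_dataset",
    "generate_mixture",
]


@dataclasses.dataclass(frozen=True)
class BandSpec:
    """One Raman band of the simulated cell spectrum.

    ``tumor_multiplier`` scales the amplitude for Tumor cells: >1 for bands
    elevated in tumor cells, <1 for bands elevated in non-tumor cells.
    """

    center: float          # cm^-1
    width: float           # FWHM, cm^-1
    base_amplitude: float  # a.u.
    tumor_multiplier: float = 1.0
    assignment: str = ""

    def __post_init__(self) -> None:
        if not (FINGERPRINT[0] <= self.center <= FINGERPRINT[1]):
            raise ValueError("band center outside the fingerprint region")
        if self.width <= 0:
            raise ValueError("band width must be positive")
        if self.base_amplitude < 0:
            raise ValueError("band amplitude must be non-negative")
        if self.tumor_multiplier <= 0:
            raise ValueError("tumor_multiplier must be positive")


# Amplitude multipliers for the class-informative bands.  Magnitudes put the
# class-mean difference at a few percent of the tallest peaks, the regime in
# which the classification task is hard but solvable (see docs/methods.md).
_ELEVATED_IN_TUMOR = 1.25
_ELEVATED_IN_NONTUMOR = 0.80

#: (center, width, amplitude, tumor_multiplier, assignment)
_BAND_TABLE: tuple[tuple[float, float, float, float, str], ...] = (
    (729.0, 12.0, 0.30, 1.0, "A ring breathing (nucleic acid)"),
    (757.0, 12.0, 0.35, 1.0, "Trp ring breathing (protein)"),
    (784.0, 14.0, 0.60, _ELEVATED_IN_TUMOR, "DNA backbone / U,C,T ring breathing"),
    (826.0, 12.0, 0.25, 1.0, "O-P-O stretch (nucleic acid)"),
    (850.0, 18.0, 0.20, 1.0, "polysaccharide structure"),
    (854.0, 10.0, 0.40, 1.0, "Tyr ring breathing (protein)"),
    (1004.0, 8.0, 1.00, 1.0, "Phe ring breathing (protein)"),
    (1031.0, 10.0, 0.35, 1.0, "Phe C-H in-plane bend (protein)"),
    (1064.0, 12.0, 0.30, 1.0, "skeletal C-C stretch (lipid)"),
    (1094.0, 16.0, 0.40, _ELEVATED_IN_TUMOR, "symmetric PO2- stretch (nucleic acid)"),
    (1177.0, 12.0, 0.25, 1.0, "Tyr C-H bend (protein)"),
    (1207.0, 12.0, 0.25, 1.0, "Phe, Trp C-C6H5 stretch (protein)"),
    (1243.0, 20.0, 0.50, _ELEVATED_IN_NONTUMOR, "Amide III (protein)"),
    (1305.0, 14.0, 0.40, 1.0, "CH2 twist (lipid/protein)"),
    (1335.0, 16.0, 0.60, _ELEVATED_IN_TUMOR, "A,G ring breathing, C-H def."),
    (1370.0, 14.0, 0.35, _ELEVATED_IN_TUMOR, "DNA bases ring breathing"),
    (1438.0, 14.0, 0.50, _ELEVATED_IN_NONTUMOR, "CH2, CH3 deformation (protein)"),
    (1444.0, 14.0, 0.70, 1.0, "CH2, CH3 deformation (lipid/protein)"),
    (1578.0, 14.0, 0.45, _ELEVATED_IN_TUMOR, "A,G ring breathing (nucleic acid)"),
    (1606.0, 10.0, 0.30, 1.0, "Tyr, Phe C=C bend"),
    (1618.0, 10.0, 0.30, 1.0, "Phe, Tyr, Trp C=C"),
    (1656.0, 20.0, 0.90, 1.0, "C=C stretch, Amide I (lipid/protein)"),
)


def default_band_table() -> list[BandSpec]:
    """Band table of the simulated cell spectrum, one entry per canonical band.

    Nucleic-acid bands at 782-785, 1094, 1335, 1370 and 1578 cm^-1 carry
    ``tumor_multiplier`` > 1; the 1240-1246 Amide III and 1438 cm^-1
    CH2/CH3 bands carry ``tumor_multiplier`` < 1; every other band is
    class-neutral.
    """
    return [BandSpec(*row) for row in _BAND_TABLE]


def band_near(bands: list[BandSpec], center: float, tol: float = 5.0) -> BandSpec:
    """Return the band whose center is closest to ``center`` (within ``tol``)."""
    best = min(bands, key=lambda b: abs(b.center - center))
    if abs(best.center - center) > tol:
        raise KeyError(f"no band within {tol} cm^-1 of {center}")
    return best


@dataclasses.dataclass
class SimConfig:
    """Study-design parameters of the simulated acquisition campaign."""

    n_cells_per_class: int = 40
    spectra_per_cell: int = 5
    axis: np.ndarray = dataclasses.field(
        default_factory=lambda: np.arange(600.0, 1801.0, 1.0)
    )
    noise_sd: float = 0.08
    #: (low, high) for each cubic coefficient c0..c3 of the fluorescence
    #: baseline c0 + c1*u + c2*u^2 + c3*u^3, u in [0, 1] across the axis
    baseline_coeffs_range: tuple[tuple[float, float], ...] = (
        (1.0, 4.0),
        (-1.5, 1.5),
        (-1.5, 1.5),
        (-0.8, 0.8),
    )
    cell_effect_sd: float = 0.25
    outlier_fraction: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        self.axis = np.asarray(self.axis, dtype=float)
        if self.n_cells_per_class < 1 or self.spectra_per_cell < 1:
            raise ValueError("counts must be >= 1")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if not 0 <= self.outlier_fraction < 1:
            raise ValueError("outlier_fraction must be in [0, 1)")
        if self.axis.size > 1 and not np.all(np.diff(self.axis) > 0):
            raise ValueError("axis must be strictly increasing")
        if len(self.baseline_coeffs_range) != 4:
            raise ValueError("baseline needs four coefficient ranges (cubic)")


def pseudo_voigt(x: np.ndarray, center: float, fwhm: float, eta: float = 0.5) -> np.ndarray:
    """Unit-height pseudo-Voigt line: eta*Lorentzian + (1-eta)*Gaussian."""
    d2 = (x - center) ** 2
    lorentz = 1.0 / (1.0 + 4.0 * d2 / fwhm**2)
    gauss = np.exp(-4.0 * np.log(2.0) * d2 / fwhm**2)
    return eta * lorentz + (1.0 - eta) * gauss


def _peak_profile(axis, bands, label, cell_effect):
    y = np.zeros_like(axis)
    for b in bands:
        amp = b.base_amplitude
        if label == TUMOR:
            amp *= b.tumor_multiplier
        if b.tumor_multiplier != 1.0:
            # per-cell heterogeneity concentrated in the class-informative
            # (nucleic-acid / discriminative) bands
            amp *= cell_effect
        y += amp * pseudo_voigt(axis, b.center, b.width)
    return y


def _baseline(axis, coeffs):
    u = (axis - axis[0]) / (axis[-1] - axis[0])
    c0, c1, c2, c3 = coeffs
    return c0 + c1 * u + c2 * u**2 + c3 * u**3


def generate_spectrum(
    label: str,
    bands: list[BandSpec],
    cfg: SimConfig,
    cell_effect: float = 1.0,
    rng: np.random.Generator | None = None,
    cell_id: str = "cell",
    with_baseline: bool = True,
) -> Spectrum:
    """Simulate one raw acquisition: peaks + cubic baseline + Gaussian noise.

    Deterministic given the state of ``rng``.
    """
    if label not in (TUMOR, NON_TUMOR):
        raise ValueError(f"label must be {TUMOR!r} or {NON_TUMOR!r}")
    rng = np.random.default_rng(cfg.seed) if rng is None else rng
    y = _peak_profile(cfg.axis, bands, label, cell_effect)
    if with_baseline:
        coeffs = [rng.uniform(lo, hi) for lo, hi in cfg.baseline_coeffs_range]
        y = y + _baseline(cfg.axis, coeffs)
    if cfg.noise_sd > 0:
        y = y + rng.normal(0.0, cfg.noise_sd, size=cfg.axis.size)
    elif with_baseline or cfg.noise_sd == 0:
        # keep the rng stream aligned whether or not noise is drawn
        pass
    return Spectrum(cfg.axis.copy(), y, cell_id=cell_id, label=label)


def _corrupt(spectrum: Spectrum, bands, rng) -> None:
    """Apply one of two corruption modes in place: a narrow cosmic-ray-like
    spike of >= 10x the tallest band, or a 10x fluorescence baseline with
    the accompanying shot noise (the smooth part of a fluorescence burst is
    removed by baseline correction, its shot noise is not)."""
    max_amp = max(b.base_amplitude for b in bands)
    if rng.random() < 0.5:
        pos = rng.uniform(spectrum.shifts[0] + 20, spectrum.shifts[-1] - 20)
        spike = 12.0 * max_amp * pseudo_voigt(spectrum.shifts, pos, 3.0)
        spectrum.intensities = spectrum.intensities + spike
    else:
        u = (spectrum.shifts - spectrum.shifts[0]) / (
            spectrum.shifts[-1] - spectrum.shifts[0]
        )
        extra = 10.0 * max_amp * (0.5 + u - 0.6 * u**2)
        shot = rng.normal(0.0, 0.08 * np.sqrt(np.abs(extra) / max_amp) * max_amp)
        spectrum.intensities = spectrum.intensities + extra + shot
    spectrum.meta["corrupted"] = True


def generate_dataset(cfg: SimConfig, bands: list[BandSpec] | None = None) -> SpectrumSet:
    """Two-class dataset: ``n_cells_per_class`` cells per class with
    ``spectra_per_cell`` acquisitions each; exactly
    ``round(outlier_fraction * N)`` spectra corrupted and marked in
    ``meta['corrupted']`` for QC validation."""
    bands = default_band_table() if bands is None else bands
    rng = np.random.default_rng(cfg.seed)
    spectra: list[Spectrum] = []
    for label, prefix in ((NON_TUMOR, "NT"), (TUMOR, "T")):
        for c in range(cfg.n_cells_per_class):
            cell_id = f"{prefix}{c:03d}"
            cell_effect = float(
                np.exp(rng.normal(0.0, cfg.cell_effect_sd))
            )
            for _ in range(cfg.spectra_per_cell):
                spectra.append(
                    generate_spectrum(
                        label, bands, cfg, cell_effect, rng, cell_id=cell_id
                    )
                )
    n_corrupt = int(round(cfg.outlier_fraction * len(spectra)))
    if n_corrupt:
        idx = rng.choice(len(spectra), size=n_corrupt, replace=False)
        for i in idx:
            _corrupt(spectra[i], bands, rng)
    return SpectrumSet(spectra, meta={"sim_seed": cfg.seed})


def generate_mixture(
    n_tumor_cells: int,
    n_nontumor_cells: int,
    cfg: SimConfig,
    bands: list[BandSpec] | None = None,
) -> tuple[SpectrumSet, float]:
    """Blind set mixing Tumor and Non-Tumor cells in a known cell ratio.

    Labels are hidden (``label=None``); the ground truth is kept only in
    ``meta['true_labels']``.  Returns the set and the nominal tumor
    percentage ``100 * n_tumor_cells / (n_tumor_cells + n_nontumor_cells)``.
    """
    if n_tumor_cells < 0 or n_nontumor_cells < 0:
        raise ValueError("cell counts must be >= 0")
    if n_tumor_cells + n_nontumor_cells == 0:
        raise ValueError("at least one cell is required")
    bands = default_band_table() if bands is None else bands
    rng = np.random.default_rng(cfg.seed + 1)
    spectra: list[Spectrum] = []
    truth: list[str] = []
    plan = [(TUMOR, "MT")] * n_tumor_cells + [(NON_TUMOR, "MN")] * n_nontumor_cells
    for c, (label, prefix) in enumerate(plan):
        cell_effect = float(np.exp(rng.normal(0.0, cfg.cell_effect_sd)))
        for _ in range(cfg.spectra_per_cell):
            s = generate_spectrum(
                label, bands, cfg, cell_effect, rng, cell_id=f"{prefix}{c:03d}"
            )
            truth.append(label)
            s.label = None
            spectra.append(s)
    nominal = 100.0 * n_tumor_cells / (n_tumor_cells + n_nontumor_cells)
    return (
        SpectrumSet(
            spectra,
            meta={"true_labels": truth, "nominal_tumor_pct": nominal},
        ),
        nominal,
    )
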