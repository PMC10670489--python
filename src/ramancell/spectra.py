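"""Core containers for single-cell Raman spectra.

A :class:`Spectrum` is one acquisition: a strictly increasing Raman-shift
axis (cm^-1), an intensity vector (a.u.), the id of the cell it was taken
from and an optional class label.  A :class:`SpectrumSet` is an ordered
collection with per-cell grouping, set-level metadata (e.g. the hash of the
preprocessing configuration that produced it) and plain-text I/O: one
two-column CSV per spectrum plus a tab-separated manifest.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path
from typing import Iterator, Sequence

import numpy as np
import pandas as pd

TUMOR = "Tumor"
NON_TUMOR = "Non-Tumor"
LABELS = (NON_TUMOR, TUMOR)

#: fingerprint region analysed throughout (closed interval, cm^-1)
FINGERPRINT = (600.0, 1800.0)


@dataclasses.dataclass
class Spectrum:
    """One Raman acquisition on a single cell.

    Parameters
    ----------
    shifts
        Raman-shift axis in cm^-1, strictly increasing.
    intensities
        Intensities in arbitrary units, same length as ``shifts``.
    cell_id
        Identifier of the cell the spectrum was acquired on.
    label
        ``"Tumor"``, ``"Non-Tumor"`` or ``None`` when unknown (blind sets).
    stage
        ``"raw"`` or ``"preprocessed"``.
    outlier_flag
        Set by the QC module when the spectrum is screened out.
    """

    shifts: np.ndarray
    intensities: np.ndarray
    cell_id: str
    label: str | None = None
    stage: str = "raw"
    outlier_flag: bool = False
    meta: dict = dataclasses.field(default_factory=dict)

    def __post_init__(self) -> None:
        self.shifts = np.asarray(self.shifts, dtype=float)
        self.intensities = np.asarray(self.intensities, dtype=float)
        if self.shifts.shape != self.intensities.shape:
            raise ValueError("shifts and intensities must have the same length")
        if self.shifts.ndim != 1:
            raise ValueError("spectra are one-dimensional")
        if self.shifts.size > 1 and not np.all(np.diff(self.shifts) > 0):
            raise ValueError("Raman-shift axis must be strictly increasing")
        if self.label is not None and self.label not in LABELS:
            raise ValueError(f"label must be one of {LABELS} or None")

    def copy(self, **updates) -> "Spectrum":
        fields = {
            "shifts": self.shifts.copy(),
            "intensities": self.intensities.copy(),
            "cell_id": self.cell_id,
            "label": self.label,
            "stage": self.stage,
            "outlier_flag": self.outlier_flag,
            "meta": dict(self.meta),
        }
        fields.update(updates)
        return Spectrum(**fields)

    def __len__(self) -> int:
        return self.shifts.size


class SpectrumSet:
    """Ordered collection of spectra with set-level metadata."""

    def __init__(self, spectra: Sequence[Spectrum], meta: dict | None = None):
        self.spectra: list[Spectrum] = list(spectra)
        self.meta: dict = dict(meta or {})

    def __len__(self) -> int:
        return len(self.spectra)

    def __iter__(self) -> Iterator[Spectrum]:
        return iter(self.spectra)

    def __getitem__(self, i):
        if isinstance(i, slice):
            return SpectrumSet(self.spectra[i], meta=dict(self.meta))
        return self.spectra[i]

    # ------------------------------------------------------------------ views
    def labels(self) -> list[str | None]:
        return [s.label for s in self.spectra]

    def cell_ids(self) -> list[str]:
        return [s.cell_id for s in self.spectra]

    def by_cell(self) -> dict[str, list[Spectrum]]:
        groups: dict[str, list[Spectrum]] = {}
        for s in self.spectra:
            groups.setdefault(s.cell_id, []).append(s)
        return groups

    def class_counts(self) -> dict[str, int]:
        counts: dict[str, int] = {}
        for s in self.spectra:
            key = s.label if s.label is not None else "unknown"
            counts[key] = counts.get(key, 0) + 1
        return counts

    def subset(self, mask) -> "SpectrumSet":
        mask = np.asarray(mask, dtype=bool)
        if mask.size != len(self):
            raise ValueError("mask length mismatch")
        kept = [s for s, m in zip(self.spectra, mask) if m]
        return SpectrumSet(kept, meta=dict(self.meta))

    def without_outliers(self) -> "SpectrumSet":
        return self.subset([not s.outlier_flag for s in self.spectra])

    def common_axis(self) -> np.ndarray:
        """Shared Raman-shift grid; raises if spectra differ."""
        if not self.spectra:
            raise ValueError("empty set has no axis")
        axis = self.spectra[0].shifts
        for s in self.spectra[1:]:
            if s.shifts.shape != axis.shape or not np.allclose(s.shifts, axis):
                raise ValueError("spectra are not on a common grid")
        return axis

    def to_matrix(self) -> np.ndarray:
        """(n_spectra, n_points) intensity matrix on the common grid."""
        self.common_axis()
        return np.vstack([s.intensities for s in self.spectra])

    # --------------------------------------------------------------------- IO
    def write(self, directory: str | Path) -> Path:
        """Write one `shift_cm-1,intensity` CSV per spectrum plus a manifest TSV."""
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        rows = []
        for i, s in enumerate(self.spectra):
            name = f"spectrum_{i:04d}.csv"
            pd.DataFrame(
                {"shift_cm-1": s.shifts, "intensity": s.intensities}
            ).to_csv(directory / name, index=False)
            rows.append(
                {
                    "spectrum_path": name,
                    "cell_id": s.cell_id,
                    "label": s.label if s.label is not None else "unknown",
                    "is_outlier_truth": bool(s.meta.get("corrupted", False)),
                }
            )
        manifest = directory / "manifest.tsv"
        pd.DataFrame(rows).to_csv(manifest, sep="\t", index=False)
        return manifest

    @classmethod
    def read(cls, directory: str | Path) -> "SpectrumSet":
        directory = Path(directory)
        manifest = pd.read_csv(directory / "manifest.tsv", sep="\t")
        spectra = []
        for row in manifest.itertuples(index=False):
            table = pd.read_csv(directory / row.spectrum_path)
            label = None if row.label == "unknown" else row.label
            s = Spectrum(
                shifts=table["shift_cm-1"].to_numpy(),
                intensities=table["intensity"].to_numpy(),
                cell_id=str(row.cell_id),
                label=label,
            )
            if bool(row.is_outlier_truth):
                s.meta["corrupted"] = True
            spectra.append(s)
        return cls(spectra)
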