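"""Core in-memory containers for single-specimen MALDI-TOF fingerprints.

A measurement is a profile-mode mass spectrum: an ascending mass axis in
Daltons (singly charged ions, so m/z is effectively molecular mass) with
non-negative, arbitrary-unit intensities, tagged with the specimen it came
from, the technical replicate number and (for reference specimens) the
taxonomic label used for supervised identification.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

__all__ = ["TaxonLabel", "RawSpectrum", "PeakList"]


@dataclass(frozen=True)
class TaxonLabel:
    """Taxonomic assignment of a specimen.

    Reference-library specimens carry at least a species name; query
    spectra may leave every field empty. ``class_`` carries the trailing
    underscore to avoid the Python keyword.
    """

    species: str = ""
    genus: str = ""
    class_: str = ""
    phylum: str = ""
    sex: str = ""

    def level(self, level: str) -> str:
        """Return the label at ``level`` ('species', 'genus', 'class', 'phylum')."""
        key = {"species": "species", "genus": "genus", "class": "class_",
               "class_": "class_", "phylum": "phylum", "sex": "sex"}[level]
        return getattr(self, key)


def _as_float_array(x, name: str) -> np.ndarray:
    arr = np.asarray(x, dtype=float)
    if arr.ndim != 1:
        raise ValueError(f"{name} must be one-dimensional, got shape {arr.shape}")
    if not np.all(np.isfinite(arr)):
        raise ValueError(f"{name} contains non-finite values")
    return arr


@dataclass
class RawSpectrum:
    """One measured spectrum: ascending masses (Da) and non-negative intensities."""

    masses: np.ndarray
    intensities: np.ndarray
    specimen_id: str = ""
    replicate_id: str = ""
    taxon: TaxonLabel | None = None

    def __post_init__(self) -> None:
        self.masses = _as_float_array(self.masses, "masses")
        self.intensities = _as_float_array(self.intensities, "intensities")
        if len(self.masses) != len(self.intensities):
            raise ValueError(
                f"masses ({len(self.masses)}) and intensities "
                f"({len(self.intensities)}) differ in length"
            )
        if len(self.masses) < 1:
            raise ValueError("a spectrum needs at least one point")
        if np.any(np.diff(self.masses) <= 0):
            raise ValueError("masses must be strictly increasing")
        if np.any(self.intensities < 0):
            raise ValueError("intensities must be non-negative")

    def __len__(self) -> int:
        return len(self.masses)

    def with_intensities(self, intensities: np.ndarray) -> "RawSpectrum":
        """Copy of this spectrum with new intensities on the same mass axis."""
        return replace(self, intensities=np.asarray(intensities, dtype=float))

    def tic(self) -> float:
        """Total ion current (sum of intensities)."""
        return float(self.intensities.sum())


@dataclass
class PeakList:
    """Detected peaks of one spectrum: masses, intensities and SNR values."""

    masses: np.ndarray
    intensities: np.ndarray
    snr_values: np.ndarray
    specimen_id: str = ""
    replicate_id: str = ""
    taxon: TaxonLabel | None = None

    def __post_init__(self) -> None:
        self.masses = np.asarray(self.masses, dtype=float)
        self.intensities = np.asarray(self.intensities, dtype=float)
        self.snr_values = np.asarray(self.snr_values, dtype=float)
        n = len(self.masses)
        if not (len(self.intensities) == len(self.snr_values) == n):
            raise ValueError("peak arrays differ in length")
        if n > 1 and np.any(np.diff(self.masses) <= 0):
            raise ValueError("peak masses must be strictly increasing")

    def __len__(self) -> int:
        return len(self.masses)
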