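"""Core in-memory containers: a single spectrum and an aligned spectra matrix.

A :class:`Spectrum` is the atomic observation — one wavenumber axis with one
intensity vector and per-cell metadata.  A :class:`SpectraSet` is the
pipeline's working object: an ``(n_spectra, n_channels)`` intensity matrix on
a single shared axis plus a row-aligned metadata table.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

#: metadata columns every SpectraSet carries (extra columns are preserved)
META_COLUMNS = ("spectrum_id", "cell_id", "label", "batch", "location")

LOCATIONS = ("center", "periphery", "unknown")


def _as_float_array(x, name: str) -> np.ndarray:
    arr = np.asarray(x, dtype=float)
    if arr.ndim != 1:
        raise ValueError(f"{name} must be one-dimensional, got shape {arr.shape}")
    return arr


@dataclass
class Spectrum:
    """One Raman spectrum: intensity vs wavenumber shift (cm^-1)."""

    wavenumbers: np.ndarray
    intensities: np.ndarray
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.wavenumbers = _as_float_array(self.wavenumbers, "wavenumbers")
        self.intensities = _as_float_array(self.intensities, "intensities")
        if self.wavenumbers.size != self.intensities.size:
            raise ValueError(
                f"axis length {self.wavenumbers.size} != intensity length "
                f"{self.intensities.size}"
            )
        if self.wavenumbers.size and np.any(np.diff(self.wavenumbers) <= 0):
            raise ValueError("wavenumbers must be strictly ascending")
        if not np.all(np.isfinite(self.wavenumbers)):
            raise ValueError("non-finite wavenumber values")
        if not np.all(np.isfinite(self.intensities)):
            raise ValueError("non-finite intensity values")

    def __len__(self) -> int:
        return self.wavenumbers.size

    def with_intensities(self, intensities: np.ndarray) -> "Spectrum":
        """Copy of this spectrum with new intensities, metadata preserved."""
        return Spectrum(self.wavenumbers.copy(), np.asarray(intensities, float), dict(self.meta))


@dataclass
class SpectraSet:
    """Aligned collection of spectra on a common wavenumber grid.

    ``meta`` must contain a unique ``spectrum_id`` column; ``label`` may be
    null for prediction-only use.
    """

    wavenumbers: np.ndarray
    intensities: np.ndarray
    meta: pd.DataFrame

    def __post_init__(self) -> None:
        self.wavenumbers = _as_float_array(self.wavenumbers, "wavenumbers")
        self.intensities = np.asarray(self.intensities, dtype=float)
        if self.intensities.ndim != 2:
            raise ValueError("intensities must be a 2-D (spectra x channels) matrix")
        if self.intensities.shape[1] != self.wavenumbers.size:
            raise ValueError(
                f"matrix has {self.intensities.shape[1]} channels but the axis has "
                f"{self.wavenumbers.size}"
            )
        if np.any(np.diff(self.wavenumbers) <= 0):
            raise ValueError("wavenumbers must be strictly ascending")
        if not isinstance(self.meta, pd.DataFrame):
            self.meta = pd.DataFrame(self.meta)
        if len(self.meta) != self.intensities.shape[0]:
            raise ValueError(
                f"metadata rows ({len(self.meta)}) != spectra ({self.intensities.shape[0]})"
            )
        if "spectrum_id" not in self.meta.columns:
            raise ValueError("metadata must contain a 'spectrum_id' column")
        ids = self.meta["spectrum_id"].astype(str)
        if ids.duplicated().any():
            dupes = sorted(ids[ids.duplicated()].unique())
            raise ValueError(f"duplicated spectrum ids: {dupes}")
        self.meta = self.meta.reset_index(drop=True)
        if not np.all(np.isfinite(self.intensities)):
            raise ValueError("non-finite intensity values")

    def __len__(self) -> int:
        return self.intensities.shape[0]

    @property
    def n_channels(self) -> int:
        return self.wavenumbers.size

    @property
    def spectrum_ids(self) -> np.ndarray:
        return self.meta["spectrum_id"].astype(str).to_numpy()

    @property
    def labels(self) -> np.ndarray:
        """Label per spectrum (object array; None/NaN where unlabelled)."""
        if "label" not in self.meta.columns:
            return np.array([None] * len(self), dtype=object)
        return self.meta["label"].to_numpy(dtype=object)

    def spectrum(self, i: int) -> Spectrum:
        """Row ``i`` as a standalone :class:`Spectrum`."""
        return Spectrum(
            self.wavenumbers.copy(),
            self.intensities[i].copy(),
            self.meta.iloc[i].to_dict(),
        )

    def subset(self, index) -> "SpectraSet":
        """New set from a boolean mask or integer row index (order preserved)."""
        index = np.asarray(index)
        if index.dtype == bool:
            index = np.flatnonzero(index)
        return SpectraSet(
            self.wavenumbers.copy(),
            self.intensities[index].copy(),
            self.meta.iloc[index].reset_index(drop=True),
        )

    @classmethod
    def from_spectra(cls, spectra: list[Spectrum]) -> "SpectraSet":
        """Stack spectra that share an identical axis."""
        if not spectra:
            raise ValueError("cannot build a SpectraSet from zero spectra")
        axis = spectra[0].wavenumbers
        for s in spectra[1:]:
            if s.wavenumbers.size != axis.size or not np.array_equal(s.wavenumbers, axis):
                raise ValueError("all spectra must share one wavenumber axis")
        meta = pd.DataFrame([s.meta for s in spectra])
        if "spectrum_id" not in meta.columns:
            meta["spectrum_id"] = [f"s{i:05d}" for i in range(len(spectra))]
        return cls(axis.copy(), np.vstack([s.intensities for s in spectra]), meta)
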