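"""The labeled spectra container used throughout the pipeline.

A :class:`SpectrumSet` is the universal currency of the package: a
``(n_samples, n_bands)`` reflectance matrix, its wavelength grid in
nanometres, one class label per row and a unique sample identifier per row.
Every pretreatment maps a SpectrumSet to a SpectrumSet of identical shape;
selectors and classifiers consume its matrix and labels.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .exceptions import InvalidArgumentError

__all__ = ["SpectrumSet"]


@dataclass
class SpectrumSet:
    """Sample x band reflectance matrix with wavelengths, labels and ids.

    Parameters
    ----------
    reflectance : ndarray of shape (n_samples, n_bands)
        Unitless reflectance values. Must be finite.
    wavelengths : ndarray of shape (n_bands,)
        Band centres in nanometres, strictly ascending.
    labels : ndarray of shape (n_samples,)
        Class identifier per sample (any hashable; stored as object array).
    sample_ids : ndarray of shape (n_samples,)
        Unique string identifier per sample.
    """

    reflectance: np.ndarray
    wavelengths: np.ndarray
    labels: np.ndarray
    sample_ids: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.reflectance = np.asarray(self.reflectance, dtype=float)
        self.wavelengths = np.asarray(self.wavelengths, dtype=float)
        self.labels = np.asarray(self.labels)
        if self.reflectance.ndim != 2:
            raise InvalidArgumentError(
                f"reflectance must be 2-D, got shape {self.reflectance.shape}"
            )
        n, p = self.reflectance.shape
        if self.sample_ids is None:
            self.sample_ids = np.array([f"s{i:05d}" for i in range(n)])
        else:
            self.sample_ids = np.asarray(self.sample_ids, dtype=object)
        if self.labels.shape != (n,):
            raise InvalidArgumentError(
                f"labels length {self.labels.shape} does not match {n} samples"
            )
        if self.sample_ids.shape != (n,):
            raise InvalidArgumentError(
                f"sample_ids length {self.sample_ids.shape} does not match {n} samples"
            )
        if self.wavelengths.shape != (p,):
            raise InvalidArgumentError(
                f"wavelength count {self.wavelengths.shape} does not match {p} bands"
            )
        if p > 1 and not np.all(np.diff(self.wavelengths) > 0):
            raise InvalidArgumentError("wavelengths must be strictly increasing")
        if not np.all(np.isfinite(self.reflectance)):
            raise InvalidArgumentError("reflectance contains NaN or Inf")
        if len(set(self.sample_ids.tolist())) != n:
            raise InvalidArgumentError("sample_ids must be unique")

    # -- basic queries -------------------------------------------------
    @property
    def n_samples(self) -> int:
        return self.reflectance.shape[0]

    @property
    def n_bands(self) -> int:
        return self.reflectance.shape[1]

    @property
    def classes(self) -> np.ndarray:
        """Sorted unique class labels."""
        return np.unique(self.labels)

    def __len__(self) -> int:
        return self.n_samples

    # -- derivation helpers --------------------------------------------
    def with_reflectance(self, reflectance: np.ndarray) -> "SpectrumSet":
        """Return a copy sharing metadata but with a new reflectance matrix."""
        return SpectrumSet(
            reflectance=np.asarray(reflectance, dtype=float),
            wavelengths=self.wavelengths.copy(),
            labels=self.labels.copy(),
            sample_ids=self.sample_ids.copy(),
        )

    def subset(self, index: np.ndarray) -> "SpectrumSet":
        """Row-subset by integer or boolean index."""
        index = np.asarray(index)
        return SpectrumSet(
            reflectance=self.reflectance[index],
            wavelengths=self.wavelengths.copy(),
            labels=self.labels[index],
            sample_ids=self.sample_ids[index],
        )

    def select_bands(self, band_index: np.ndarray) -> "SpectrumSet":
        """Column-subset to the given band indices (ascending order kept)."""
        band_index = np.asarray(band_index)
        return SpectrumSet(
            reflectance=self.reflectance[:, band_index],
            wavelengths=self.wavelengths[band_index],
            labels=self.labels.copy(),
            sample_ids=self.sample_ids.copy(),
        )

    def to_dataframe(self) -> pd.DataFrame:
        """Tidy frame: sample_id, label, then one column per wavelength."""
        cols = {
            "sample_id": self.sample_ids,
            "label": self.labels,
        }
        frame = pd.DataFrame(cols)
        band_cols = pd.DataFrame(
            self.reflectance, columns=[f"{wl:.10f}" for wl in self.wavelengths]
        )
        return pd.concat([frame, band_cols], axis=1)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, SpectrumSet):
            return NotImplemented
        return (
            self.reflectance.shape == other.reflectance.shape
            and np.array_equal(self.reflectance, other.reflectance)
            and np.array_equal(self.wavelengths, other.wavelengths)
            and np.array_equal(self.labels.astype(str), other.labels.astype(str))
            and np.array_equal(
                self.sample_ids.astype(str), other.sample_ids.astype(str)
            )
        )
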