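"""Containers for point spectra and labelled spectra sets."""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Any

import numpy as np
import pandas as pd

from .axes import WavenumberAxis

__all__ = ["Spectrum", "ReferenceSpectrum", "SpectraSet"]


@dataclass
class Spectrum:
    """One intensity-vs-wavenumber trace with acquisition metadata.

    ``meta`` may carry position, treatment label, and the AFM detection
    (f1) / drive (f2) frequencies; the QCL pulse (modulation) frequency is
    their difference f_m = f2 - f1.
    """

    axis: WavenumberAxis
    intensity: np.ndarray
    meta: dict[str, Any] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.intensity = np.asarray(self.intensity, dtype=float)
        if self.intensity.shape != (self.axis.n_bins,):
            raise ValueError(
                f"intensity length {self.intensity.shape} does not match axis "
                f"bin count {self.axis.n_bins}"
            )
        if not np.all(np.isfinite(self.intensity)):
            raise ValueError("intensity contains non-finite values")

    def with_intensity(self, values: np.ndarray, axis: WavenumberAxis | None = None) -> "Spectrum":
        return Spectrum(axis or self.axis, np.asarray(values, dtype=float), dict(self.meta))


@dataclass
class ReferenceSpectrum:
    """Nonnegative reference trace: QCL power spectrum or CaF2 substrate response."""

    axis: WavenumberAxis
    intensity: np.ndarray
    source: str = "power_spectrum"

    def __post_init__(self) -> None:
        self.intensity = np.asarray(self.intensity, dtype=float)
        if self.intensity.shape != (self.axis.n_bins,):
            raise ValueError("reference length does not match axis bin count")
        if np.any(self.intensity < 0):
            raise ValueError("reference intensities must be nonnegative")


@dataclass
class SpectraSet:
    """A stack of spectra on a shared axis with per-spectrum labels.

    ``labels`` is a DataFrame with one row per spectrum; the generator
    fills columns ``group`` (treated/control), ``stratum``, ``row``/``col``
    (pixel position), ``dominant`` (dominant component) and ``bound``.
    """

    axis: WavenumberAxis
    intensities: np.ndarray  # (n_spectra, n_bins)
    labels: pd.DataFrame
    reference: ReferenceSpectrum | None = None
    meta: dict[str, Any] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.intensities = np.asarray(self.intensities, dtype=float)
        if self.intensities.ndim != 2 or self.intensities.shape[1] != self.axis.n_bins:
            raise ValueError("intensities must be (n_spectra, n_bins) on the axis")
        if len(self.labels) != self.intensities.shape[0]:
            raise ValueError("labels must have one row per spectrum")

    def __len__(self) -> int:
        return self.intensities.shape[0]

    def spectrum(self, i: int) -> Spectrum:
        return Spectrum(self.axis, self.intensities[i], dict(self.labels.iloc[i]))

    def select(self, mask) -> "SpectraSet":
        mask = np.asarray(mask)
        return SpectraSet(
            self.axis,
            self.intensities[mask],
            self.labels.iloc[mask].reset_index(drop=True),
            self.reference,
            dict(self.meta),
        )

    def group(self, name: str) -> "SpectraSet":
        return self.select((self.labels["group"] == name).to_numpy())

    def mean_spectrum(self, mask=None) -> Spectrum:
        data = self.intensities if mask is None else self.intensities[np.asarray(mask)]
        if data.shape[0] == 0:
            raise ValueError("cannot average an empty selection")
        return Spectrum(self.axis, data.mean(axis=0))

    def with_intensities(self, values: np.ndarray, axis: WavenumberAxis | None = None) -> "SpectraSet":
        return SpectraSet(axis or self.axis, values, self.labels.copy(), self.reference, dict(self.meta))
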