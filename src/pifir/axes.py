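"""Wavenumber axis handling.

All spectral data in this package live on a uniformly sampled, ascending
wavenumber axis in cm^-1.  The QCL sources used for photoinduced-force
infrared (PiF-IR) spectroscopy are tunable at ~1 cm^-1 spectral bandwidth,
so the default bin width is 1 cm^-1.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["WavenumberAxis"]


@dataclass(frozen=True)
class WavenumberAxis:
    """Uniform ascending wavenumber grid.

    Parameters
    ----------
    start, stop : float
        First and last wavenumber in cm^-1, ``start < stop``.
    step : float, default 1.0
        Bin width in cm^-1.

    The number of bins is ``round((stop - start) / step) + 1`` and both
    endpoints are included.
    """

    start: float
    stop: float
    step: float = 1.0

    def __post_init__(self) -> None:
        if not self.start < self.stop:
            raise ValueError(f"start ({self.start}) must be < stop ({self.stop})")
        if not self.step > 0:
            raise ValueError(f"step must be positive, got {self.step}")

    @property
    def n_bins(self) -> int:
        return int(round((self.stop - self.start) / self.step)) + 1

    @property
    def values(self) -> np.ndarray:
        return self.start + self.step * np.arange(self.n_bins)

    def __len__(self) -> int:
        return self.n_bins

    def index_of(self, wavenumber: float) -> int:
        """Index of the bin nearest to ``wavenumber`` (must lie on the axis)."""
        idx = int(round((wavenumber - self.start) / self.step))
        if idx < 0 or idx >= self.n_bins:
            raise ValueError(
                f"wavenumber {wavenumber} cm^-1 outside axis "
                f"[{self.start}, {self.stop}]"
            )
        return idx

    def contains(self, wavenumber: float) -> bool:
        return self.start <= wavenumber <= self.stop

    def window(self, lo: float, hi: float) -> np.ndarray:
        """Boolean mask of bins with ``lo <= nu <= hi``."""
        v = self.values
        return (v >= lo) & (v <= hi)

    def slice(self, i0: int, i1: int) -> "WavenumberAxis":
        """Sub-axis covering bins ``i0 .. i1-1`` (contiguous)."""
        if not (0 <= i0 < i1 <= self.n_bins):
            raise ValueError(f"invalid bin range [{i0}, {i1})")
        v = self.values
        return WavenumberAxis(float(v[i0]), float(v[i1 - 1]), self.step)

    def intersect(self, other: "WavenumberAxis") -> "WavenumberAxis":
        """Largest common sub-axis of two axes with equal step."""
        if not np.isclose(self.step, other.step):
            raise ValueError("axes have different steps")
        lo, hi = max(self.start, other.start), min(self.stop, other.stop)
        if lo >= hi:
            raise ValueError("axes do not overlap")
        return WavenumberAxis(lo, hi, self.step)
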