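"""Containers for scan maps and hyperspectral cubes."""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Any

import numpy as np

from .axes import WavenumberAxis

__all__ = ["ScanImage", "HyperspectralCube"]

_CHANNELS = ("height", "pif", "phase")


@dataclass
class ScanImage:
    """A 2D single-channel scan map.

    ``channel`` is one of height (nm), pif (photoinduced-force intensity at
    one illumination wavenumber) or phase.  Rows are the slow-scan axis,
    columns the fast-scan axis; origin is the top-left pixel.
    """

    data: np.ndarray
    channel: str = "pif"
    wavenumber: float | None = None  # cm^-1, pif channel only
    pixel_size_nm: float = 20.0
    meta: dict[str, Any] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 2:
            raise ValueError("scan data must be 2D")
        if not np.all(np.isfinite(self.data)):
            raise ValueError("scan data contains non-finite values")
        if self.channel not in _CHANNELS:
            raise ValueError(f"channel must be one of {_CHANNELS}")
        if self.pixel_size_nm <= 0:
            raise ValueError("pixel_size_nm must be positive")

    @property
    def shape(self) -> tuple[int, int]:
        return self.data.shape

    def with_data(self, data: np.ndarray) -> "ScanImage":
        return ScanImage(data, self.channel, self.wavenumber, self.pixel_size_nm, dict(self.meta))


@dataclass
class HyperspectralCube:
    """(rows, cols, wavenumber) PiF intensities with shared axis metadata."""

    data: np.ndarray
    axis: WavenumberAxis
    pixel_size_nm: float = 13.0
    meta: dict[str, Any] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 3:
            raise ValueError("cube data must be (rows, cols, bins)")
        if self.data.shape[2] != self.axis.n_bins:
            raise ValueError(
                f"cube spectral dimension {self.data.shape[2]} does not match "
                f"axis bin count {self.axis.n_bins}"
            )
        if self.pixel_size_nm <= 0:
            raise ValueError("pixel_size_nm must be positive")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape

    @property
    def grid(self) -> tuple[int, int]:
        return self.data.shape[:2]

    def slice_at(self, wavenumber: float) -> ScanImage:
        """Single-wavenumber image (nearest axis bin)."""
        idx = self.axis.index_of(wavenumber)
        return ScanImage(
            self.data[:, :, idx],
            channel="pif",
            wavenumber=float(self.axis.values[idx]),
            pixel_size_nm=self.pixel_size_nm,
            meta=dict(self.meta),
        )

    def flatten_pixels(self) -> np.ndarray:
        """Row-major (n_pixels, n_bins) view of the cube."""
        r, c, b = self.data.shape
        return self.data.reshape(r * c, b)
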