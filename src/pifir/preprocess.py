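"""Spectral and scan-level preprocessing.

The standard chain applied to PiF-IR point spectra before chemometrics:

1. calibration against a reference (QCL power spectrum / CaF2 substrate
   response), with bins below a clip fraction of the reference peak
   discarded and the axis trimmed to the largest contiguous valid range;
2. removal of the constant background (mean of the lowest-decile
   intensities);
3. Savitzky-Golay smoothing, by default order 2, window 11, two passes
   (the "2-11-11" convention; a single-pass reading is one config key
   away);
4. L2 vector normalization.

Scan maps get a line-by-line multiplicative drift correction in the
slow-scan direction based on row medians.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.signal import savgol_filter

from .axes import WavenumberAxis
from .images import ScanImage
from .spectra import ReferenceSpectrum, SpectraSet, Spectrum

__all__ = [
    "SpectralMask",
    "PreprocessConfig",
    "power_clip_mask",
    "calibrate_spectrum",
    "remove_constant_background",
    "l2_normalize",
    "savgol_smooth",
    "correct_line_drift",
    "preprocess_spectra",
]


@dataclass(frozen=True)
class SpectralMask:
    """Per-bin validity flags derived from a reference spectrum."""

    valid: np.ndarray
    fraction_threshold: float

    def __post_init__(self) -> None:
        object.__setattr__(self, "valid", np.asarray(self.valid, dtype=bool))
        if not self.valid.any():
            raise ValueError("mask has no valid bins")
        if not 0.0 < self.fraction_threshold < 1.0:
            raise ValueError("fraction threshold must be in (0, 1)")

    def largest_contiguous(self) -> tuple[int, int]:
        """Start (inclusive) and stop (exclusive) of the longest valid run."""
        best = (0, 0)
        start = None
        padded = np.concatenate([self.valid, [False]])
        for i, v in enumerate(padded):
            if v and start is None:
                start = i
            elif not v and start is not None:
                if i - start > best[1] - best[0]:
                    best = (start, i)
                start = None
        return best


@dataclass(frozen=True)
class PreprocessConfig:
    """Defaults of the standard chain; all exposed for override."""

    clip_fraction: float = 0.05
    sg_order: int = 2
    sg_window: int = 11
    sg_passes: int = 2
    background_quantile: float = 0.1
    normalize: bool = True
    smooth_before_normalize: bool = True

    def __post_init__(self) -> None:
        if not 0.0 < self.clip_fraction < 1.0:
            raise ValueError("clip_fraction must be in (0, 1)")
        if self.sg_window % 2 == 0 or self.sg_window <= self.sg_order:
            raise ValueError("sg_window must be odd and greater than sg_order")


def power_clip_mask(reference: ReferenceSpectrum, fraction: float = 0.05) -> SpectralMask:
    """Bins where the reference reaches ``fraction`` of its peak intensity."""
    peak = reference.intensity.max()
    if peak <= 0:
        raise ValueError("reference spectrum has no positive maximum")
    return SpectralMask(reference.intensity >= fraction * peak, fraction)


def calibrate_spectrum(
    raw: Spectrum | SpectraSet, reference: ReferenceSpectrum, mask: SpectralMask | None = None
):
    """Divide by the reference on valid bins; trim to the longest valid run.

    Clipped bins are dropped rather than interpolated, mirroring the
    restriction of hyperspectra to the range one QCL chip covers.
    """
    axis = raw.axis
    if (axis.start, axis.stop, axis.step) != (
        reference.axis.start,
        reference.axis.stop,
        reference.axis.step,
    ):
        raise ValueError("sample and reference axes differ")
    if mask is None:
        mask = power_clip_mask(reference)
    i0, i1 = mask.largest_contiguous()
    if i1 - i0 < 2:
        raise ValueError("no usable contiguous valid range in the reference")
    sub_axis = axis.slice(i0, i1)
    ref = reference.intensity[i0:i1]
    if isinstance(raw, SpectraSet):
        return raw.with_intensities(raw.intensities[:, i0:i1] / ref, axis=sub_axis)
    return raw.with_intensity(raw.intensity[i0:i1] / ref, axis=sub_axis)


def _background(values: np.ndarray, quantile: float) -> float:
    n = max(1, int(round(quantile * values.size)))
    return float(np.sort(values)[:n].mean())


def remove_constant_background(spec: Spectrum | SpectraSet, quantile: float = 0.1):
    """Subtract the mean of the lowest-``quantile`` intensities per spectrum."""
    if isinstance(spec, SpectraSet):
        out = spec.intensities.copy()
        for i in range(out.shape[0]):
            out[i] -= _background(out[i], quantile)
        return spec.with_intensities(out)
    return spec.with_intensity(spec.intensity - _background(spec.intensity, quantile))


def l2_normalize(spec: Spectrum | SpectraSet):
    """Scale each spectrum to unit Euclidean norm."""
    if isinstance(spec, SpectraSet):
        norms = np.linalg.norm(spec.intensities, axis=1, keepdims=True)
        if np.any(norms == 0):
            raise ValueError("cannot normalize an all-zero spectrum")
        return spec.with_intensities(spec.intensities / norms)
    norm = np.linalg.norm(spec.intensity)
    if norm == 0:
        raise ValueError("cannot normalize an all-zero spectrum")
    return spec.with_intensity(spec.intensity / norm)


def savgol_smooth(
    spec: Spectrum | SpectraSet, order: int = 2, window: int = 11, passes: int = 2
):
    """Savitzky-Golay smoothing, applied ``passes`` times.

    Endpoints are handled by the polynomial fit on the edge window, so the
    spectrum keeps its length.  A polynomial of degree <= ``order`` is a
    fixed point of the filter.
    """
    if window % 2 == 0 or window <= order:
        raise ValueError("window must be odd and greater than order")
    n_bins = spec.axis.n_bins
    if n_bins < window:
        raise ValueError("spectrum shorter than the smoothing window")

    def smooth(v: np.ndarray) -> np.ndarray:
        for _ in range(passes):
            v = savgol_filter(v, window, order, mode="interp", axis=-1)
        return v

    if isinstance(spec, SpectraSet):
        return spec.with_intensities(smooth(spec.intensities))
    return spec.with_intensity(smooth(spec.intensity))


def correct_line_drift(
    scan: ScanImage, reference_region: slice | np.ndarray | None = None
) -> ScanImage:
    """Equalize row medians against the global median (slow-scan drift).

    Medians are taken over ``reference_region`` columns when given.  Rows
    whose median is <= 0 are left unchanged and flagged in
    ``meta['drift_skipped_rows']``.  Within-row structure is preserved
    exactly (each row is scaled by one factor).
    """
    data = scan.data
    if data.shape[0] < 2:
        raise ValueError("drift correction needs at least 2 rows")
    region = data if reference_region is None else data[:, reference_region]
    row_medians = np.median(region, axis=1)
    usable = row_medians > 0
    if not usable.any():
        out = scan.with_data(data.copy())
        out.meta["drift_skipped_rows"] = list(range(data.shape[0]))
        return out
    global_median = float(np.median(region[usable]))
    factors = np.ones_like(row_medians)
    factors[usable] = global_median / row_medians[usable]
    out = scan.with_data(data * factors[:, None])
    out.meta["drift_skipped_rows"] = list(np.flatnonzero(~usable))
    return out


def preprocess_spectra(
    spectra: SpectraSet,
    config: PreprocessConfig = PreprocessConfig(),
    reference: ReferenceSpectrum | None = None,
) -> SpectraSet:
    """Standard chain: calibrate -> background -> smooth -> normalize.

    The reference defaults to the one attached to the set; without any,
    calibration is skipped.  The smooth/normalize order follows
    ``config.smooth_before_normalize``.
    """
    out = spectra
    ref = reference if reference is not None else spectra.reference
    if ref is not None:
        out = calibrate_spectrum(out, ref, power_clip_mask(ref, config.clip_fraction))
    out = remove_constant_background(out, config.background_quantile)
    steps = [
        lambda s: savgol_smooth(s, config.sg_order, config.sg_window, config.sg_passes),
        l2_normalize if config.normalize else (lambda s: s),
    ]
    if not config.smooth_before_normalize:
        steps.reverse()
    for step in steps:
        out = step(out)
    out.meta["preprocessed"] = True
    out.meta["preprocess_config"] = config
    return out
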