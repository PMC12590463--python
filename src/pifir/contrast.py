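"""Multi-frequency contrast imaging.

The illumination anisotropy on a curved cell surface modulates the PiF
intensity identically at every wavenumber.  Merging two single-frequency
scans into one false-color image therefore cancels it: the glycan-band
scan (1060 cm^-1) feeds the red+blue channels (pink) and the amide-band
scan (1520 cm^-1) the green channel, so hue encodes relative absorption
while the common anisotropic gain only affects brightness.  From
hyperspectral cubes, narrow band-mean channel maps provide the same logic
spectrally resolved; the three-band composite (1655 -> blue, 1624 -> red,
1540 -> green) renders hydrogen-bonded amide regions reddish.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Any

import numpy as np

from .images import HyperspectralCube, ScanImage

__all__ = [
    "Offset",
    "RGBContrast",
    "ChannelMap",
    "register_scans",
    "crop_to_overlap",
    "scale_channel",
    "merge_two_frequency",
    "band_channel_map",
    "three_band_rgb",
    "THREE_BAND_DEFAULTS",
]

#: (center, channel) triplet of the default hydrogen-bond composite
THREE_BAND_DEFAULTS = ((1655.0, "b"), (1624.0, "r"), (1540.0, "g"))


@dataclass(frozen=True)
class Offset:
    """Integer-pixel translation between two scans of the same position."""

    drow: int
    dcol: int
    peak_correlation: float


@dataclass
class RGBContrast:
    """Three display channels in [0, 1] plus the band bookkeeping."""

    r: np.ndarray
    g: np.ndarray
    b: np.ndarray
    band_map: dict[str, Any] = field(default_factory=dict)
    scaling: tuple[float, float] = (1.0, 99.0)

    def __post_init__(self) -> None:
        if not (self.r.shape == self.g.shape == self.b.shape):
            raise ValueError("RGB channels must share one shape")
        for ch in (self.r, self.g, self.b):
            if ch.min() < -1e-12 or ch.max() > 1 + 1e-12:
                raise ValueError("channels must be scaled to [0, 1]")

    def stack(self) -> np.ndarray:
        return np.dstack([self.r, self.g, self.b])


@dataclass(frozen=True)
class ChannelMap:
    """Mean intensity over a narrow band |nu - center| <= halfwidth."""

    data: np.ndarray
    center: float
    halfwidth: float
    n_bins: int


def register_scans(
    reference_height: ScanImage,
    moving_height: ScanImage,
    max_shift: int | None = None,
    min_correlation: float = 0.2,
) -> Offset:
    """Integer-pixel translation maximizing normalized cross-correlation.

    The search is exhaustive over shifts up to ``max_shift`` (default a
    quarter of the smaller image side) on mean-subtracted height maps; the
    Pearson correlation of the overlapping region is reported, and a peak
    below ``min_correlation`` raises a registration failure.

    The returned offset satisfies ``moving[r, c] ~= reference[r - drow,
    c - dcol]`` on the overlap.
    """
    if reference_height.pixel_size_nm != moving_height.pixel_size_nm:
        raise ValueError("scans must share one pixel size")
    a = reference_height.data - reference_height.data.mean()
    b = moving_height.data - moving_height.data.mean()
    rows = min(a.shape[0], b.shape[0])
    cols = min(a.shape[1], b.shape[1])
    if max_shift is None:
        max_shift = min(rows, cols) // 4
    best = (0.0, 0, 0)
    found = False
    for dr in range(-max_shift, max_shift + 1):
        for dc in range(-max_shift, max_shift + 1):
            ra0, ra1 = max(0, -dr), min(a.shape[0], b.shape[0] - dr)
            ca0, ca1 = max(0, -dc), min(a.shape[1], b.shape[1] - dc)
            if ra1 - ra0 < 4 or ca1 - ca0 < 4:
                continue
            pa = a[ra0:ra1, ca0:ca1]
            pb = b[ra0 + dr : ra1 + dr, ca0 + dc : ca1 + dc]
            pa = pa - pa.mean()
            pb = pb - pb.mean()
            denom = np.linalg.norm(pa) * np.linalg.norm(pb)
            if denom == 0:
                continue
            corr = float((pa * pb).sum() / denom)
            if not found or corr > best[0]:
                best = (corr, dr, dc)
                found = True
    if not found or best[0] < min_correlation:
        raise ValueError(
            f"registration failed: peak correlation {best[0]:.3f} below {min_correlation}"
        )
    return Offset(drow=best[1], dcol=best[2], peak_correlation=best[0])


def crop_to_overlap(
    scan_a: ScanImage, scan_b: ScanImage, offset: Offset
) -> tuple[ScanImage, ScanImage]:
    """Crop both scans to the common field of view implied by ``offset``."""
    dr, dc = offset.drow, offset.dcol
    ra0, ra1 = max(0, -dr), min(scan_a.shape[0], scan_b.shape[0] - dr)
    ca0, ca1 = max(0, -dc), min(scan_a.shape[1], scan_b.shape[1] - dc)
    if ra1 <= ra0 or ca1 <= ca0:
        raise ValueError("scans have no overlap at this offset")
    out_a = scan_a.with_data(scan_a.data[ra0:ra1, ca0:ca1])
    out_b = scan_b.with_data(scan_b.data[ra0 + dr : ra1 + dr, ca0 + dc : ca1 + dc])
    return out_a, out_b


def scale_channel(
    data: np.ndarray, low_pct: float = 1.0, high_pct: float = 99.0
) -> np.ndarray:
    """Percentile-clipped linear rescale to [0, 1]; constant maps become 0.5."""
    if low_pct >= high_pct:
        raise ValueError("low percentile must be below high percentile")
    data = np.asarray(data, dtype=float)
    if not np.all(np.isfinite(data)):
        raise ValueError("channel data must be finite")
    lo, hi = np.percentile(data, [low_pct, high_pct])
    if hi <= lo:
        return np.full(data.shape, 0.5)
    return np.clip((data - lo) / (hi - lo), 0.0, 1.0)


def merge_two_frequency(
    amide_scan: ScanImage,
    glycan_scan: ScanImage,
    percentiles: tuple[float, float] = (1.0, 99.0),
) -> RGBContrast:
    """Anisotropy-cancelling two-frequency merge.

    G = scaled amide-band scan; R = B = scaled glycan-band scan, so
    glycan-dominated pixels render pink and amide-dominated pixels green.
    Each channel is scaled independently, which absorbs any global gain
    (and, because the anisotropy factor is frequency independent, makes
    the hue insensitive to it).
    """
    if amide_scan.shape != glycan_scan.shape:
        raise ValueError("scans must be co-registered to equal shapes")
    g = scale_channel(amide_scan.data, *percentiles)
    rb = scale_channel(glycan_scan.data, *percentiles)
    return RGBContrast(
        r=rb,
        g=g,
        b=rb,
        band_map={
            "g": amide_scan.wavenumber,
            "r+b": glycan_scan.wavenumber,
        },
        scaling=percentiles,
    )


def band_channel_map(
    cube: HyperspectralCube, center: float, halfwidth: float = 2.0
) -> ChannelMap:
    """Per-pixel mean over the bins with |nu - center| <= halfwidth."""
    nus = cube.axis.values
    sel = np.abs(nus - center) <= halfwidth
    if not sel.any() or not (cube.axis.start <= center <= cube.axis.stop):
        raise ValueError(f"band {center} +- {halfwidth} cm^-1 outside the cube axis")
    return ChannelMap(
        data=cube.data[:, :, sel].mean(axis=2),
        center=center,
        halfwidth=halfwidth,
        n_bins=int(sel.sum()),
    )


def three_band_rgb(
    cube: HyperspectralCube,
    bands: tuple[tuple[float, str], ...] = THREE_BAND_DEFAULTS,
    halfwidth: float = 2.0,
    percentiles: tuple[float, float] = (1.0, 99.0),
) -> RGBContrast:
    """Three-band composite localizing hydrogen-bonded amide.

    Defaults: 1655 cm^-1 (unbound amide I) -> blue, 1624 cm^-1 (bound
    amide I) -> red, 1540 cm^-1 (unbound amide II) -> green; bound regions
    appear reddish.  Channels are scaled independently.
    """
    channels: dict[str, np.ndarray] = {}
    band_map: dict[str, float] = {}
    for center, ch in bands:
        if ch not in ("r", "g", "b") or ch in channels:
            raise ValueError("bands must map to distinct channels r, g, b")
        channels[ch] = scale_channel(band_channel_map(cube, center, halfwidth).data, *percentiles)
        band_map[ch] = center
    if set(channels) != {"r", "g", "b"}:
        raise ValueError("need exactly three bands for r, g and b")
    return RGBContrast(
        r=channels["r"], g=channels["g"], b=channels["b"], band_map=band_map, scaling=percentiles
    )
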