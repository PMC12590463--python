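"""Synthetic PiF-IR scenes of bacterial cell surfaces.

This module generates labelled synthetic data with the statistical and
physical structure that nanoscale photothermal imaging of vancomycin-treated
B. subtilis exhibits: a capsule-shaped cell on a flat (non-absorbing)
substrate, per-pixel surface composition expressed through component
fractions, an illumination-direction anisotropy that modulates intensity
independently of wavenumber, and the characteristic scan artifacts
(slow-scan line drift, equidistant contamination streaks, edge overshoot,
topography-correlated detection-frequency modulation).

Composition model
-----------------
Each on-cell pixel carries a protein fraction ``p`` and a bound fraction
``beta`` (the fraction of that protein hydrogen-bonded to vancomycin):

    f_amide_unbound = p * (1 - beta)
    f_amide_bound   = p * beta
    f_glycan        = 0.85 - p
    f_lipid         = 0.05

Treated scenes contain three region types: intact surface (glycan-rich,
p ~ 0.18), damage patches (exposed protein, p ~ 0.62, partially bound),
and bound regions at the septum piecrust (beta ~ 0.88).  Control scenes
are entirely intact surface.  The defaults were chosen so that the
ensemble reproduces the qualitative chemometric structure reported for
the real system: PC1 separating glycan- from amide-dominated spectra with
all controls on the glycan side, PC2 carrying the hydrogen-bond
substitution signature, and a treated-minus-control difference spectrum
dominated by the bound amide I band at 1624 cm^-1.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Any

import numpy as np
import pandas as pd

from .axes import WavenumberAxis
from .components import ComponentSpectrum, default_components
from .images import HyperspectralCube, ScanImage
from .spectra import ReferenceSpectrum, SpectraSet

__all__ = [
    "CellGeometry",
    "IlluminationSpec",
    "ArtifactConfig",
    "Scene",
    "GroundTruth",
    "render_topography",
    "compute_anisotropy",
    "render_scan",
    "render_hyperspectrum",
    "apply_artifacts",
    "sample_point_spectra",
    "make_power_reference",
    "make_cell_scene",
    "make_hyperspectral_scene",
    "DEFAULT_STRATA",
]

#: per-stratum (p_mean, p_sigma, beta_mean, beta_sigma) and sampling counts
#: mirroring the 51 treated / 13 control point-spectra experiment
DEFAULT_STRATA: dict[str, dict[str, float]] = {
    "intact": dict(p=0.18, p_sigma=0.04, beta=0.12, beta_sigma=0.04, n=16),
    "damage": dict(p=0.62, p_sigma=0.08, beta=0.35, beta_sigma=0.06, n=15),
    "bound": dict(p=0.48, p_sigma=0.08, beta=0.88, beta_sigma=0.05, n=20),
    "control": dict(p=0.18, p_sigma=0.04, beta=0.0, beta_sigma=0.0, n=13),
}

_LIPID_FRACTION = 0.05
_TOTAL_ABSORBING = 0.90  # remainder is non-absorbing substrate contribution


@dataclass(frozen=True)
class CellGeometry:
    """Capsule-cell geometry in a pixel grid.

    ``semi_axes`` are (along-columns, along-rows) in nm; the long axis of
    the cell lies along the fast-scan (column) direction.  ``septum`` is an
    optional dict with keys ``position`` (column, px), ``width``, ``depth``
    and ``piecrust_width`` (nm); ``damage_patches`` is a list of dicts with
    ``center`` ((row, col) px), ``radius`` and optional ``depth`` (nm).
    """

    center: tuple[float, float]  # (row, col) px
    semi_axes: tuple[float, float]  # (along cols, along rows) nm
    height_max: float  # nm
    fibril_width: float = 7.5  # nm, peptidoglycan filaments are 6-9 nm
    fibril_contrast: float = 0.0
    septum: dict[str, float] | None = None
    damage_patches: tuple[dict[str, Any], ...] = ()

    def __post_init__(self) -> None:
        if self.height_max < 0:
            raise ValueError("height_max must be >= 0")
        if not 4.0 <= self.fibril_width <= 20.0:
            raise ValueError("fibril_width must be within [4, 20] nm")
        if self.septum is not None and self.septum["width"] >= 2 * self.semi_axes[0]:
            raise ValueError("septum wider than the cell")


@dataclass(frozen=True)
class IlluminationSpec:
    """Direction and strength of the frequency-independent anisotropy.

    ``azimuth_deg`` is the in-plane propagation direction of the
    illumination, measured counterclockwise from the fast-scan (+column)
    axis.  ``strength`` scales the linear directional-gradient model;
    ``clamp`` bounds the resulting factor.
    """

    azimuth_deg: float = 30.0
    strength: float = 0.5
    clamp: tuple[float, float] = (0.2, 1.8)

    def __post_init__(self) -> None:
        if self.strength < 0:
            raise ValueError("anisotropy strength must be >= 0")
        lo, hi = self.clamp
        if not (0 < lo <= 1 <= hi):
            raise ValueError("clamp must satisfy 0 < min <= 1 <= max")


@dataclass(frozen=True)
class ArtifactConfig:
    """Scan-artifact toggles and amplitudes (all toggles default off)."""

    line_drift: bool = False
    line_drift_sigma: float = 0.05
    streaks: bool = False
    streak_period: int = 8
    streak_amplitude: float = 0.3
    streak_component: str = "contaminant"
    overshoot: bool = False
    overshoot_gain: float = 0.3
    fixed_f1: bool = False
    fixed_f1_gain: float = 0.2

    def __post_init__(self) -> None:
        for name in ("line_drift_sigma", "streak_amplitude", "overshoot_gain", "fixed_f1_gain"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.streaks and self.streak_period < 2:
            raise ValueError("streak_period must be >= 2 when streaks are on")

    @classmethod
    def all_on(cls, **kwargs) -> "ArtifactConfig":
        return cls(line_drift=True, streaks=True, overshoot=True, fixed_f1=True, **kwargs)

    @property
    def any_on(self) -> bool:
        return self.line_drift or self.streaks or self.overshoot or self.fixed_f1


@dataclass
class GroundTruth:
    """Per-pixel truth maps of a scene plus optional per-spectrum labels."""

    height: np.ndarray
    anisotropy: np.ndarray
    fractions: dict[str, np.ndarray]
    bound_threshold: float = 0.3
    labels: pd.DataFrame | None = None

    @property
    def bound_mask(self) -> np.ndarray:
        return self.fractions["amide_bound"] >= self.bound_threshold


@dataclass
class Scene:
    """A fully specified synthetic scene: geometry, composition, optics."""

    shape: tuple[int, int]
    pixel_size_nm: float
    axis: WavenumberAxis
    geometry: CellGeometry | None
    fractions: dict[str, np.ndarray]
    illumination: IlluminationSpec
    components: dict[str, ComponentSpectrum]
    noise: dict[str, float] = field(default_factory=lambda: dict(mult_sigma=0.05, add_sigma=0.02))
    power_envelope: np.ndarray | None = None
    seed: int = 0
    masks: dict[str, np.ndarray] = field(default_factory=dict)
    bound_threshold: float = 0.3

    def __post_init__(self) -> None:
        total = np.zeros(self.shape)
        for name, f in self.fractions.items():
            f = np.asarray(f, dtype=float)
            if f.shape != self.shape:
                raise ValueError(f"fraction map {name} has shape {f.shape}, expected {self.shape}")
            if np.any(f < -1e-12) or np.any(f > 1 + 1e-12):
                raise ValueError(f"fraction map {name} outside [0, 1]")
            self.fractions[name] = np.clip(f, 0.0, 1.0)
            total += f
        if np.any(total > 1 + 1e-9):
            raise ValueError("per-pixel fraction sum exceeds 1")
        self._height: np.ndarray | None = None
        self._anisotropy: np.ndarray | None = None

    @property
    def height(self) -> np.ndarray:
        if self._height is None:
            if self.geometry is None:
                self._height = np.zeros(self.shape)
            else:
                self._height = render_topography(self.geometry, self.shape, self.pixel_size_nm)
        return self._height

    @property
    def anisotropy(self) -> np.ndarray:
        if self._anisotropy is None:
            self._anisotropy = compute_anisotropy(self.height, self.illumination)
        return self._anisotropy

    def component_value(self, name: str, wavenumber: float) -> float:
        return self.components[name].value_at(wavenumber)

    def signal_map(self, wavenumber: float) -> np.ndarray:
        """Noise- and artifact-free PiF map: A * sum_c f_c * S_c(nu)."""
        if not self.axis.contains(wavenumber):
            raise ValueError(
                f"wavenumber {wavenumber} cm^-1 outside the component axis "
                f"[{self.axis.start}, {self.axis.stop}]"
            )
        mix = np.zeros(self.shape)
        for name, f in self.fractions.items():
            mix += f * self.components[name].value_at(wavenumber)
        return self.anisotropy * mix

    def ground_truth(self) -> GroundTruth:
        return GroundTruth(
            height=self.height.copy(),
            anisotropy=self.anisotropy.copy(),
            fractions={k: v.copy() for k, v in self.fractions.items()},
            bound_threshold=self.bound_threshold,
        )


# ---------------------------------------------------------------------------
# topography and optics


def render_topography(
    geometry: CellGeometry,
    shape: tuple[int, int],
    pixel_size_nm: float,
    return_masks: bool = False,
):
    """Height map of a capsule cell with optional texture, septum, damage.

    The capsule is an ellipsoidal cap; fibril ridges (circumferential
    glycan strands) modulate it multiplicatively along the long axis; the
    septum is a transverse depression with raised piecrust rims; damage
    patches are Gaussian depressions.  The result is clipped at 0.
    """
    rows, cols = shape
    rr, cc = np.mgrid[0:rows, 0:cols].astype(float)
    r0, c0 = geometry.center
    a, b = geometry.semi_axes
    u_nm = (cc - c0) * pixel_size_nm  # along long axis
    v_nm = (rr - r0) * pixel_size_nm
    q2 = (u_nm / a) ** 2 + (v_nm / b) ** 2
    h = geometry.height_max * np.sqrt(np.clip(1.0 - q2, 0.0, None))
    cell = h > 0

    if geometry.fibril_contrast > 0:
        period = 2.0 * geometry.fibril_width
        ripple = 1.0 + 0.5 * geometry.fibril_contrast * np.cos(2 * np.pi * u_nm / period)
        h = h * np.where(cell, ripple, 1.0)

    septum_mask = np.zeros(shape, dtype=bool)
    piecrust_mask = np.zeros(shape, dtype=bool)
    if geometry.septum is not None:
        s = geometry.septum
        halfw = s["width"] / 2.0
        pcw = s.get("piecrust_width", 0.0)
        d_nm = (cc - s["position"]) * pixel_size_nm
        inside = np.abs(d_nm) <= halfw
        profile = np.where(inside, np.cos(np.pi * d_nm / (2 * halfw)) ** 2, 0.0)
        h = h - s["depth"] * profile * cell
        septum_mask = inside & cell
        if pcw > 0:
            rim_d = np.abs(d_nm) - halfw
            rim = (rim_d > 0) & (rim_d <= pcw) & cell
            h = h + 0.25 * s["depth"] * np.sin(np.pi * rim_d / pcw) ** 2 * rim
            piecrust_mask = rim

    damage_mask = np.zeros(shape, dtype=bool)
    for patch in geometry.damage_patches:
        pr, pc = patch["center"]
        radius = patch["radius"]
        depth = patch.get("depth", 0.25 * geometry.height_max)
        d2 = ((rr - pr) ** 2 + (cc - pc) ** 2) * pixel_size_nm**2
        h = h - depth * np.exp(-d2 / radius**2) * cell
        damage_mask |= (d2 <= radius**2) & cell

    h = np.clip(h, 0.0, None)
    if return_masks:
        return h, dict(cell=cell, septum=septum_mask, piecrust=piecrust_mask, damage=damage_mask)
    return h


def compute_anisotropy(height: np.ndarray, illum: IlluminationSpec) -> np.ndarray:
    """Illumination anisotropy factor map A(x, y).

    A = clamp(1 - a * g_hat), with g_hat the directional derivative of the
    height along the propagation azimuth normalized by its maximum absolute
    value.  Slopes facing the source (height increasing along propagation)
    get A < 1; the factor carries no wavenumber dependence.
    """
    height = np.asarray(height, dtype=float)
    if not np.all(np.isfinite(height)):
        raise ValueError("height map must be finite")
    lo, hi = illum.clamp
    if illum.strength == 0:
        return np.ones_like(height)
    grad_row, grad_col = np.gradient(height)
    theta = math.radians(illum.azimuth_deg)
    # azimuth measured CCW from +columns; +rows point down the image
    g = math.cos(theta) * grad_col - math.sin(theta) * grad_row
    gmax = np.max(np.abs(g))
    if gmax == 0:
        return np.ones_like(height)
    return np.clip(1.0 - illum.strength * g / gmax, lo, hi)


# ---------------------------------------------------------------------------
# rendering


def _seed_pair(seed: int | None, n: int):
    ss = np.random.SeedSequence(0 if seed is None else seed)
    return [np.random.default_rng(c) for c in ss.spawn(n)]


def render_scan(
    scene: Scene,
    wavenumber: float,
    artifacts: ArtifactConfig | None = None,
    seed: int | None = None,
    with_noise: bool = True,
) -> tuple[ScanImage, ScanImage]:
    """Single-illumination-frequency PiF scan plus the paired height scan.

    The deterministic signal is A * sum_c f_c * S_c(nu); multiplicative
    (lognormal) and additive (Gaussian, scaled by the scene mean signal)
    detector noise are applied, then scan artifacts in their fixed order,
    and the result is clipped at zero.
    """
    sig = scene.signal_map(wavenumber)
    rng_noise, rng_art = _seed_pair(seed, 2)
    if with_noise:
        ms = scene.noise.get("mult_sigma", 0.0)
        ads = scene.noise.get("add_sigma", 0.0)
        if ms > 0:
            sig = sig * np.exp(rng_noise.normal(0.0, ms, sig.shape))
        if ads > 0 and sig.mean() > 0:
            sig = sig + rng_noise.normal(0.0, ads * sig.mean(), sig.shape)
    pif = ScanImage(
        sig, channel="pif", wavenumber=wavenumber, pixel_size_nm=scene.pixel_size_nm
    )
    height = ScanImage(scene.height, channel="height", pixel_size_nm=scene.pixel_size_nm)
    if artifacts is not None and artifacts.any_on:
        contaminant = scene.component_value(artifacts.streak_component, wavenumber)
        pif = apply_artifacts(
            pif, artifacts, rng=rng_art, height=scene.height, contaminant_value=contaminant
        )
    pif = pif.with_data(np.clip(pif.data, 0.0, None))
    return pif, height


def render_hyperspectrum(
    scene: Scene,
    axis: WavenumberAxis | None = None,
    artifacts: ArtifactConfig | None = None,
    seed: int | None = None,
    with_noise: bool = True,
) -> HyperspectralCube:
    """Hyperspectral cube consistent with :func:`render_scan` slice by slice.

    With noise off a cube slice is bit-identical to the corresponding
    single-frequency scan; with noise on, slices carry independent noise
    realizations derived from the one seed.
    """
    axis = axis or WavenumberAxis(1400.0, 1660.0, scene.axis.step)
    if not math.isclose(axis.step, scene.axis.step):
        raise ValueError("hyperspectrum axis step must match the component axis step")
    if axis.start < scene.axis.start or axis.stop > scene.axis.stop:
        raise ValueError("hyperspectrum axis outside the configured component range")
    nus = axis.values
    ss = np.random.SeedSequence(0 if seed is None else seed)
    child_seeds = ss.spawn(len(nus))
    cube = np.empty(scene.shape + (len(nus),))
    for i, nu in enumerate(nus):
        pif, _ = render_scan(
            scene,
            float(nu),
            artifacts=artifacts,
            seed=None,
            with_noise=False,
        )
        data = pif.data
        if with_noise:
            rng = np.random.default_rng(child_seeds[i])
            ms = scene.noise.get("mult_sigma", 0.0)
            ads = scene.noise.get("add_sigma", 0.0)
            if ms > 0:
                data = data * np.exp(rng.normal(0.0, ms, data.shape))
            if ads > 0 and data.mean() > 0:
                data = data + rng.normal(0.0, ads * data.mean(), data.shape)
            data = np.clip(data, 0.0, None)
        cube[:, :, i] = data
    return HyperspectralCube(cube, axis, pixel_size_nm=scene.pixel_size_nm)


def apply_artifacts(
    scan: ScanImage,
    config: ArtifactConfig,
    seed: int | None = None,
    rng: np.random.Generator | None = None,
    height: np.ndarray | None = None,
    contaminant_value: float | None = None,
) -> ScanImage:
    """Apply scan artifacts in order drift -> streaks -> overshoot -> fixed-f1.

    * line drift: per-row multiplicative gain exp(N(0, sigma))
    * streaks: every ``streak_period``-th row gains
      ``streak_amplitude * S_contaminant(nu)``
    * overshoot: additive spike proportional to the positive fast-scan
      height derivative (scaled to the scan maximum)
    * fixed-f1: multiplicative ``1 + gain * h / h_max`` emulating the
      topography-correlated detection-frequency modulation when the
      mechanical detection frequency is not re-adjusted

    With all toggles off the scan is returned unchanged.
    """
    if not config.any_on:
        return scan
    rng = rng if rng is not None else np.random.default_rng(seed)
    data = scan.data.copy()
    rows = data.shape[0]
    if config.line_drift:
        gains = np.exp(rng.normal(0.0, config.line_drift_sigma, rows))
        data *= gains[:, None]
    if config.streaks:
        if contaminant_value is None:
            raise ValueError("streak artifact needs the contaminant intensity at this wavenumber")
        data[:: config.streak_period, :] += config.streak_amplitude * contaminant_value
    if config.overshoot:
        if height is None:
            raise ValueError("overshoot artifact needs the height map")
        dcol = np.gradient(np.asarray(height, dtype=float), axis=1)
        pos = np.clip(dcol, 0.0, None)
        if pos.max() > 0:
            data += config.overshoot_gain * (pos / pos.max()) * data.max()
    if config.fixed_f1:
        if height is None:
            raise ValueError("fixed-f1 artifact needs the height map")
        hmax = np.asarray(height).max()
        if hmax > 0:
            data *= 1.0 + config.fixed_f1_gain * np.asarray(height) / hmax
    out = scan.with_data(data)
    out.meta["artifacts"] = config
    return out


# ---------------------------------------------------------------------------
# point spectra


def make_power_reference(axis: WavenumberAxis) -> ReferenceSpectrum:
    """Smooth synthetic QCL power envelope used as calibration reference."""
    nu = axis.values
    env = 0.25 + 0.75 * np.exp(-0.5 * ((nu - 1350.0) / 320.0) ** 2)
    return ReferenceSpectrum(axis, env, source="power_spectrum")


def sample_point_spectra(
    scene_treated: Scene,
    scene_control: Scene,
    n_treated: int = 51,
    n_control: int = 13,
    seed: int = 0,
    with_noise: bool = True,
) -> tuple[SpectraSet, GroundTruth]:
    """Draw labelled point spectra from a treated and a control scene.

    Positions are restricted to on-cell pixels (fraction sum > 0.5).  The
    treated draw is stratified over the scene's bound, damage and intact
    regions in the proportions of the default experiment (20:15:16 of 51),
    so the set contains hydrogen-bonded, protein-exposed and intact-glycan
    surface spectra.  Every spectrum carries its position, stratum and
    ground-truth labels; the returned ground truth holds the treated
    scene's maps plus the label table.
    """
    if n_treated < 1 or n_control < 1:
        raise ValueError("need at least one treated and one control spectrum")
    if (scene_treated.axis.start, scene_treated.axis.stop, scene_treated.axis.step) != (
        scene_control.axis.start,
        scene_control.axis.stop,
        scene_control.axis.step,
    ):
        raise ValueError("treated and control scenes must share the wavenumber axis")
    rng = np.random.default_rng(np.random.SeedSequence(seed))

    def on_cell(scene: Scene) -> np.ndarray:
        total = sum(scene.fractions.values())
        return total > 0.5

    def stratified_positions(scene: Scene, n: int) -> list[tuple[int, int, str]]:
        cell = on_cell(scene)
        if not cell.any():
            raise ValueError("scene has no on-cell pixels")
        strata_masks = {}
        for name in ("bound", "damage"):
            m = scene.masks.get(name)
            if m is not None and (m & cell).any():
                strata_masks[name] = m & cell
        used = np.zeros(scene.shape, dtype=bool)
        for m in strata_masks.values():
            used |= m
        strata_masks["intact"] = cell & ~used
        # proportions of the default experiment, scaled to n
        weights = {"bound": 20 / 51, "damage": 15 / 51, "intact": 16 / 51}
        names = [s for s in ("bound", "damage", "intact") if s in strata_masks and strata_masks[s].any()]
        counts = {s: int(round(n * weights[s])) for s in names}
        counts[names[-1]] += n - sum(counts.values())
        out: list[tuple[int, int, str]] = []
        for s in names:
            idx = np.flatnonzero(strata_masks[s])
            take = min(counts[s], idx.size)
            chosen = rng.choice(idx, size=take, replace=counts[s] > idx.size)
            for flat in np.atleast_1d(chosen):
                r, c = np.unravel_index(int(flat), scene.shape)
                out.append((int(r), int(c), s))
        while len(out) < n:  # top up from anywhere on the cell
            idx = np.flatnonzero(cell)
            r, c = np.unravel_index(int(rng.choice(idx)), scene.shape)
            out.append((int(r), int(c), "intact"))
        return out[:n]

    def render_at(scene: Scene, r: int, c: int) -> np.ndarray:
        base = np.zeros(scene.axis.n_bins)
        for name, f in scene.fractions.items():
            base += f[r, c] * scene.components[name].rendered
        base = scene.anisotropy[r, c] * base
        if scene.power_envelope is not None:
            base = base * scene.power_envelope
        if with_noise:
            ms = scene.noise.get("mult_sigma", 0.0)
            ads = scene.noise.get("add_sigma", 0.0)
            if ms > 0:
                base = base * np.exp(rng.normal(0.0, ms, base.shape))
            if ads > 0 and base.mean() > 0:
                base = base + rng.normal(0.0, ads * base.mean(), base.shape)
        return base

    records = []
    rows = []
    for scene, group, positions in (
        (scene_treated, "treated", stratified_positions(scene_treated, n_treated)),
        (
            scene_control,
            "control",
            [(r, c, "control") for r, c, _ in stratified_positions(scene_control, n_control)],
        ),
    ):
        for r, c, stratum in positions:
            rows.append(render_at(scene, r, c))
            fracs = {name: float(f[r, c]) for name, f in scene.fractions.items()}
            dominant = max(fracs, key=fracs.get)
            records.append(
                dict(
                    group=group,
                    stratum=stratum,
                    row=r,
                    col=c,
                    dominant=dominant,
                    bound=fracs.get("amide_bound", 0.0) >= scene.bound_threshold,
                )
            )
    labels = pd.DataFrame.from_records(records)
    reference = None
    if scene_treated.power_envelope is not None:
        reference = ReferenceSpectrum(
            scene_treated.axis, scene_treated.power_envelope, source="power_spectrum"
        )
    spectra = SpectraSet(scene_treated.axis, np.array(rows), labels, reference=reference)
    truth = scene_treated.ground_truth()
    truth.labels = labels
    return spectra, truth


# ---------------------------------------------------------------------------
# scene builders


def _paint(
    rng: np.random.Generator,
    shape: tuple[int, int],
    region_masks: dict[str, np.ndarray],
    coverage: np.ndarray,
    strata: dict[str, dict[str, float]],
    order: tuple[str, ...],
) -> dict[str, np.ndarray]:
    """Per-pixel composition maps from stratum statistics."""
    p = np.zeros(shape)
    beta = np.zeros(shape)
    assigned = np.zeros(shape, dtype=bool)
    for name in order:
        mask = region_masks[name] & ~assigned
        st = strata[name]
        p[mask] = np.clip(rng.normal(st["p"], st["p_sigma"], int(mask.sum())), 0.08, 0.75)
        if st["beta_sigma"] > 0:
            beta[mask] = np.clip(
                rng.normal(st["beta"], st["beta_sigma"], int(mask.sum())), 0.0, 1.0
            )
        else:
            beta[mask] = st["beta"]
        assigned |= mask
    fractions = {
        "glycan": (_TOTAL_ABSORBING - _LIPID_FRACTION - p) * coverage,
        "amide_unbound": p * (1.0 - beta) * coverage,
        "amide_bound": p * beta * coverage,
        "membrane_lipid": np.full(shape, _LIPID_FRACTION) * coverage,
    }
    return {k: np.clip(v, 0.0, 1.0) for k, v in fractions.items()}


def make_cell_scene(
    kind: str = "treated",
    shape: tuple[int, int] = (64, 64),
    pixel_size_nm: float = 20.0,
    axis: WavenumberAxis | None = None,
    seed: int = 0,
    amideI_shift: float | None = None,
    amideII_shift: float | None = None,
    illumination: IlluminationSpec | None = None,
    noise: dict[str, float] | None = None,
    power_envelope: bool = True,
    fibril_contrast: float = 0.0,
) -> Scene:
    """Overview scene of a single cell (default 64x64 px at 20 nm/pixel).

    ``kind`` selects the composition: ``treated`` (intact + damage patches
    + bound septum piecrust), ``control`` (intact surface only) or
    ``bound`` (the whole cell fully hydrogen-bonded; used for the
    shift-recovery experiments).
    """
    if kind not in ("treated", "control", "bound"):
        raise ValueError("kind must be treated, control or bound")
    axis = axis or WavenumberAxis(900.0, 1800.0, 1.0)
    rng = np.random.default_rng(np.random.SeedSequence(seed))
    rows, cols = shape
    field_c = cols * pixel_size_nm
    field_r = rows * pixel_size_nm
    septum = None
    patches: tuple[dict[str, Any], ...] = ()
    if kind == "treated":
        septum = dict(
            position=cols / 2.0,
            width=0.07 * field_c,
            depth=0.25 * 300.0,
            piecrust_width=0.05 * field_c,
        )
        patches = (
            dict(center=(rows * 0.38, cols * 0.24), radius=0.09 * field_c),
            dict(center=(rows * 0.60, cols * 0.74), radius=0.08 * field_c),
        )
    geometry = CellGeometry(
        center=(rows / 2.0, cols / 2.0),
        semi_axes=(0.42 * field_c, 0.30 * field_r),
        height_max=300.0,
        fibril_contrast=fibril_contrast,
        septum=septum,
        damage_patches=patches,
    )
    height, masks = render_topography(geometry, shape, pixel_size_nm, return_masks=True)
    coverage = np.clip(height / (0.15 * geometry.height_max), 0.0, 1.0)

    strata = {k: dict(v) for k, v in DEFAULT_STRATA.items()}
    if kind == "treated":
        region = dict(bound=masks["piecrust"], damage=masks["damage"], intact=masks["cell"])
        order = ("bound", "damage", "intact")
    elif kind == "control":
        region = dict(intact=masks["cell"])
        strata["intact"] = strata["control"] | {"n": strata["intact"]["n"]}
        order = ("intact",)
    else:  # fully bound
        region = dict(bound=masks["cell"])
        strata["bound"] = dict(p=0.48, p_sigma=0.08, beta=1.0, beta_sigma=0.0, n=0)
        order = ("bound",)
    fractions = _paint(rng, shape, region, coverage, strata, order)
    masks["bound"] = masks.get("piecrust", np.zeros(shape, bool)) if kind == "treated" else (
        masks["cell"] if kind == "bound" else np.zeros(shape, bool)
    )

    components = default_components(axis, amideI_shift=amideI_shift, amideII_shift=amideII_shift)
    scene = Scene(
        shape=shape,
        pixel_size_nm=pixel_size_nm,
        axis=axis,
        geometry=geometry,
        fractions=fractions,
        illumination=illumination or IlluminationSpec(),
        components=components,
        noise=noise or dict(mult_sigma=0.05, add_sigma=0.02),
        power_envelope=make_power_reference(axis).intensity if power_envelope else None,
        seed=seed,
        masks=masks,
    )
    return scene


def make_hyperspectral_scene(
    shape: tuple[int, int] = (32, 32),
    pixel_size_nm: float = 13.0,
    axis: WavenumberAxis | None = None,
    seed: int = 0,
    illumination: IlluminationSpec | None = None,
    noise: dict[str, float] | None = None,
) -> Scene:
    """Zoomed scene of a dividing-cell region for hyperspectral scans.

    Default 32x32 pixels at 13 nm/pixel with components rendered over the
    1400-1660 cm^-1 chip range; the septum piecrust carries the bound
    component and one damage patch exposes unbound protein, so three-band
    composites and interaction-score maps have structure to find.
    """
    axis = axis or WavenumberAxis(1400.0, 1660.0, 1.0)
    rng = np.random.default_rng(np.random.SeedSequence(seed))
    rows, cols = shape
    field_c = cols * pixel_size_nm
    field_r = rows * pixel_size_nm
    geometry = CellGeometry(
        center=(rows / 2.0, cols / 2.0),
        semi_axes=(0.46 * field_c, 0.34 * field_r),
        height_max=250.0,
        septum=dict(
            position=cols / 2.0,
            width=0.13 * field_c,
            depth=80.0,
            piecrust_width=0.10 * field_c,
        ),
        damage_patches=(dict(center=(rows * 0.30, cols * 0.22), radius=0.12 * field_c),),
    )
    height, masks = render_topography(geometry, shape, pixel_size_nm, return_masks=True)
    coverage = np.clip(height / (0.15 * geometry.height_max), 0.0, 1.0)
    region = dict(bound=masks["piecrust"], damage=masks["damage"], intact=masks["cell"])
    fractions = _paint(
        rng, shape, region, coverage, DEFAULT_STRATA, ("bound", "damage", "intact")
    )
    masks["bound"] = masks["piecrust"]
    return Scene(
        shape=shape,
        pixel_size_nm=pixel_size_nm,
        axis=axis,
        geometry=geometry,
        fractions=fractions,
        illumination=illumination or IlluminationSpec(),
        components=default_components(axis),
        noise=noise or dict(mult_sigma=0.05, add_sigma=0.02),
        power_envelope=None,
        seed=seed,
        masks=masks,
    )
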