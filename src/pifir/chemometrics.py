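"""PCA chemometrics of spectra sets and hyperspectral cubes.

PCA is fit on mean-centered (not variance-scaled) spectra; the spectra
are expected to be L2-normalized by preprocessing, so variance scaling
would only inflate noise bins.  Loading signs are fixed by orienting each
loading to have nonnegative inner product with the treated-minus-control
difference spectrum (or, without labels, a positive largest-magnitude
element); the convention puts glycan-rich control spectra at negative PC1
scores.  Treated spectra are split into an "amide" subgroup (positive PC1
score) and a "glycan" subgroup (non-positive), and mean difference
spectra between arbitrary row sets expose the band signatures.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from sklearn.decomposition import PCA

from .axes import WavenumberAxis
from .images import HyperspectralCube
from .preprocess import savgol_smooth
from .spectra import SpectraSet, Spectrum

__all__ = [
    "SpectraMatrix",
    "PCAModel",
    "SubgroupAssignment",
    "DifferenceSpectrum",
    "assemble_matrix",
    "fit_pca",
    "orient_loadings",
    "split_by_pc1",
    "difference_spectrum",
    "score_maps",
    "smooth_components",
]


@dataclass
class SpectraMatrix:
    """Rows = spectra or cube pixels; columns = wavenumber bins."""

    values: np.ndarray
    axis: WavenumberAxis
    labels: pd.DataFrame  # columns: group, cube_id, row, col (as applicable)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2 or self.values.shape[1] != self.axis.n_bins:
            raise ValueError("matrix must be (rows, axis bins)")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("matrix contains missing or non-finite values")
        if len(self.labels) != self.values.shape[0]:
            raise ValueError("labels must have one row per matrix row")

    @property
    def n_rows(self) -> int:
        return self.values.shape[0]


@dataclass
class PCAModel:
    """Mean spectrum, oriented loadings, scores, explained variance."""

    mean_spectrum: np.ndarray
    loadings: np.ndarray  # (k, bins)
    scores: np.ndarray  # (rows, k)
    explained_variance_fraction: np.ndarray
    axis: WavenumberAxis
    labels: pd.DataFrame
    oriented: bool = False
    loadings_orthonormal: bool = True

    def loading(self, component: int) -> np.ndarray:
        """1-based component accessor (PC1 is ``loading(1)``)."""
        return self.loadings[component - 1]

    def score(self, component: int) -> np.ndarray:
        return self.scores[:, component - 1]


@dataclass(frozen=True)
class SubgroupAssignment:
    """Per-row class: amide / glycan (treated, by PC1 sign) or control."""

    classes: pd.Series

    def counts(self) -> dict[str, int]:
        return self.classes.value_counts().to_dict()


@dataclass(frozen=True)
class DifferenceSpectrum:
    """mean(set A) - mean(set B) on a shared axis."""

    axis: WavenumberAxis
    values: np.ndarray
    description: str = ""

    def as_spectrum(self) -> Spectrum:
        return Spectrum(self.axis, self.values, {"description": self.description})


def assemble_matrix(
    spectra: SpectraSet | None = None,
    cubes: list[HyperspectralCube] | None = None,
) -> SpectraMatrix:
    """Stack point spectra and/or flattened cubes into one matrix.

    Cube pixels become rows in row-major order; labels carry the cube id
    and pixel coordinates so score maps can be reshaped later.  Cubes with
    different (equal-step) axes are trimmed to the common range.
    """
    if spectra is None and not cubes:
        raise ValueError("need at least one input")
    blocks: list[np.ndarray] = []
    frames: list[pd.DataFrame] = []
    axis: WavenumberAxis | None = None
    if spectra is not None:
        axis = spectra.axis
        blocks.append(spectra.intensities)
        lab = spectra.labels.copy()
        lab["cube_id"] = -1
        frames.append(lab)
    if cubes:
        for cube in cubes:
            axis = cube.axis if axis is None else axis.intersect(cube.axis)
    if axis is None:
        raise ValueError("no axis could be determined")
    # trim every block to the common axis
    def trim(values: np.ndarray, src: WavenumberAxis) -> np.ndarray:
        i0 = src.index_of(axis.start)
        return values[:, i0 : i0 + axis.n_bins]

    if spectra is not None:
        blocks[0] = trim(blocks[0], spectra.axis)
    for cube_id, cube in enumerate(cubes or []):
        r, c, _ = cube.shape
        blocks.append(trim(cube.flatten_pixels(), cube.axis))
        rr, cc = np.meshgrid(np.arange(r), np.arange(c), indexing="ij")
        frames.append(
            pd.DataFrame(
                dict(
                    group="cube",
                    cube_id=cube_id,
                    row=rr.ravel(),
                    col=cc.ravel(),
                )
            )
        )
    labels = pd.concat(frames, ignore_index=True)
    return SpectraMatrix(np.vstack(blocks), axis, labels)


def fit_pca(matrix: SpectraMatrix, k: int = 5) -> PCAModel:
    """Mean-centered PCA via singular value decomposition.

    No variance scaling is applied.  Loadings are returned unoriented;
    call :func:`orient_loadings` to fix signs.
    """
    n = matrix.n_rows
    if n < k + 1:
        raise ValueError(f"need at least {k + 1} rows for {k} components")
    rank = int(np.linalg.matrix_rank(matrix.values - matrix.values.mean(axis=0)))
    if k > rank:
        raise ValueError(f"k={k} exceeds the matrix rank {rank}")
    pca = PCA(n_components=k, svd_solver="full")
    scores = pca.fit_transform(matrix.values)
    return PCAModel(
        mean_spectrum=pca.mean_,
        loadings=pca.components_.copy(),
        scores=scores,
        explained_variance_fraction=pca.explained_variance_ratio_.copy(),
        axis=matrix.axis,
        labels=matrix.labels.copy(),
    )


def orient_loadings(
    model: PCAModel, difference: DifferenceSpectrum | np.ndarray | None = None
) -> PCAModel:
    """Fix loading signs (idempotent); scores are flipped consistently.

    With a difference spectrum, each loading is flipped so its inner
    product with it is >= 0; otherwise so its largest-magnitude element is
    positive.
    """
    loadings = model.loadings.copy()
    scores = model.scores.copy()
    ref = None
    if difference is not None:
        ref = difference.values if isinstance(difference, DifferenceSpectrum) else np.asarray(difference)
        if ref.shape != (model.axis.n_bins,):
            raise ValueError("difference spectrum does not match the model axis")
    for i in range(loadings.shape[0]):
        if ref is not None:
            flip = float(loadings[i] @ ref) < 0
        else:
            flip = loadings[i][np.argmax(np.abs(loadings[i]))] < 0
        if flip:
            loadings[i] = -loadings[i]
            scores[:, i] = -scores[:, i]
    return replace(model, loadings=loadings, scores=scores, oriented=True)


def split_by_pc1(model: PCAModel) -> SubgroupAssignment:
    """Class treated rows by PC1-score sign: positive -> amide, else glycan.

    Control rows keep the ``control`` class.  Requires an oriented model
    (PCA signs are otherwise arbitrary) and a ``group`` label column.
    """
    if not model.oriented:
        raise ValueError("orient the loadings before splitting by PC1 sign")
    if "group" not in model.labels.columns:
        raise ValueError("labels must carry a 'group' column")
    pc1 = model.score(1)
    classes = []
    for i, group in enumerate(model.labels["group"]):
        if group == "control":
            classes.append("control")
        else:
            classes.append("amide" if pc1[i] > 0 else "glycan")
    return SubgroupAssignment(pd.Series(classes, name="subgroup"))


def difference_spectrum(
    matrix: SpectraMatrix | SpectraSet,
    mask_a: np.ndarray,
    mask_b: np.ndarray,
    description: str = "",
) -> DifferenceSpectrum:
    """mean(rows in A) - mean(rows in B); antisymmetric under swap."""
    values = matrix.values if isinstance(matrix, SpectraMatrix) else matrix.intensities
    mask_a = np.asarray(mask_a, dtype=bool)
    mask_b = np.asarray(mask_b, dtype=bool)
    if mask_a.sum() == 0 or mask_b.sum() == 0:
        raise ValueError("both sets must be non-empty")
    return DifferenceSpectrum(
        matrix.axis, values[mask_a].mean(axis=0) - values[mask_b].mean(axis=0), description
    )


def treated_minus_control(matrix: SpectraMatrix | SpectraSet) -> DifferenceSpectrum:
    """Convenience: difference of the treated and control group means."""
    labels = matrix.labels
    groups = labels["group"].to_numpy()
    return difference_spectrum(
        matrix, groups == "treated", groups == "control", "treated - control"
    )


def score_maps(model: PCAModel, cube_id: int = 0, components: int | None = None) -> list[np.ndarray]:
    """Reshape the scores of one cube back to its pixel grid."""
    labels = model.labels
    if "cube_id" not in labels.columns:
        raise ValueError("model rows carry no cube ids")
    sel = (labels["cube_id"] == cube_id).to_numpy()
    if not sel.any():
        raise ValueError(f"no rows for cube {cube_id}")
    sub = labels.loc[sel]
    if sub[["row", "col"]].isna().any().any():
        raise ValueError("cube rows lack pixel coordinates")
    rows = int(sub["row"].max()) + 1
    cols = int(sub["col"].max()) + 1
    k = model.loadings.shape[0] if components is None else components
    maps = []
    for comp in range(k):
        img = np.full((rows, cols), np.nan)
        img[sub["row"].to_numpy(int), sub["col"].to_numpy(int)] = model.scores[sel, comp]
        maps.append(img)
    return maps


def smooth_components(model: PCAModel, order: int = 2, window: int = 11, passes: int = 2) -> PCAModel:
    """Savitzky-Golay smooth the loadings (scores unchanged).

    Smoothing breaks exact orthonormality; the model is flagged
    accordingly.
    """
    smoothed = np.vstack(
        [
            savgol_smooth(Spectrum(model.axis, ld), order, window, passes).intensity
            for ld in model.loadings
        ]
    )
    return replace(model, loadings=smoothed, loadings_orthonormal=False)
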