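"""PCA chemometrics: fitting, orientation, subgrouping, difference spectra."""

import numpy as np
import pandas as pd
import pytest

from pifir.axes import WavenumberAxis
from pifir.chemometrics import (
    DifferenceSpectrum,
    SpectraMatrix,
    assemble_matrix,
    difference_spectrum,
    fit_pca,
    orient_loadings,
    score_maps,
    smooth_components,
    split_by_pc1,
    treated_minus_control,
)
from pifir.images import HyperspectralCube
from pifir.preprocess import preprocess_spectra


def _matrix(values, axis=None, groups=None):
    values = np.asarray(values, dtype=float)
    axis = axis or WavenumberAxis(1000, 1000 + values.shape[1] - 1, 1.0)
    labels = pd.DataFrame({"group": groups or ["treated"] * values.shape[0]})
    return SpectraMatrix(values, axis, labels)


@pytest.fixture(scope="module")
def processed_set(labeled_set):
    spectra, truth = labeled_set
    return preprocess_spectra(spectra), truth


@pytest.fixture(scope="module")
def oriented_model(processed_set):
    processed, _ = processed_set
    matrix = assemble_matrix(spectra=processed)
    diff = treated_minus_control(matrix)
    return matrix, diff, orient_loadings(fit_pca(matrix, 5), diff)


class TestAssembleMatrix:
    def test_cube_flattening_row_counts(self, hyper_cube):
        m1 = assemble_matrix(cubes=[hyper_cube])
        assert m1.values.shape == (1024, 261)
        m2 = assemble_matrix(cubes=[hyper_cube, hyper_cube])
        assert m2.values.shape == (2048, 261)
        assert set(m2.labels["cube_id"]) == {0, 1}

    def test_point_spectra_row_count(self, processed_set):
        processed, _ = processed_set
        m = assemble_matrix(spectra=processed)
        assert m.n_rows == 64

    def test_pixel_coordinates_roundtrip(self, hyper_cube):
        m = assemble_matrix(cubes=[hyper_cube])
        i = 5 * 32 + 7  # row-major flattening
        assert (m.labels.loc[i, "row"], m.labels.loc[i, "col"]) == (5, 7)
        np.testing.assert_array_equal(m.values[i], hyper_cube.data[5, 7, :])


class TestFitPCA:
    def test_rank_one_pair(self):
        v = np.array([1.0, 2.0, 3.0, 4.0])
        model = fit_pca(_matrix([v, -v]), k=1)
        cos = abs(model.loadings[0] @ (v / np.linalg.norm(v)))
        assert cos == pytest.approx(1.0, abs=1e-12)
        assert model.explained_variance_fraction[0] == pytest.approx(1.0, abs=1e-12)

    def test_two_component_mixture_pc1_direction(self, components, axis):
        """On noiseless two-component mixtures PC1 is the component
        difference direction (the generator components are the oracle)."""
        g = components["glycan"].rendered
        a = components["amide_unbound"].rendered
        fracs = np.linspace(0.1, 0.9, 12)
        rows = np.array([f * a + (1 - f) * g for f in fracs])
        model = fit_pca(_matrix(rows, axis=axis), k=1)
        direction = (a - g) / np.linalg.norm(a - g)
        angle = np.degrees(np.arccos(min(1.0, abs(model.loadings[0] @ direction))))
        assert angle < 5.0

    def test_brute_force_eigendecomposition_oracle(self):
        """Loadings/eigenvalues match an explicit covariance eigensolve."""
        rng = np.random.default_rng(0)
        X = rng.random((8, 6))
        model = fit_pca(_matrix(X), k=5)
        Xc = X - X.mean(axis=0)
        evals, evecs = np.linalg.eigh(Xc.T @ Xc / (X.shape[0] - 1))
        order = np.argsort(evals)[::-1]
        evals, evecs = evals[order], evecs[:, order]
        total = np.trace(Xc.T @ Xc / (X.shape[0] - 1))
        for i in range(5):
            cos = abs(model.loadings[i] @ evecs[:, i])
            assert cos == pytest.approx(1.0, abs=1e-8)
            assert model.explained_variance_fraction[i] == pytest.approx(
                evals[i] / total, abs=1e-8
            )

    def test_row_permutation_invariance(self):
        rng = np.random.default_rng(1)
        X = rng.random((12, 7))
        perm = rng.permutation(12)
        m1 = fit_pca(_matrix(X), k=3)
        m2 = fit_pca(_matrix(X[perm]), k=3)
        for i in range(3):
            sign = np.sign(m1.loadings[i] @ m2.loadings[i])
            np.testing.assert_allclose(m1.loadings[i], sign * m2.loadings[i], atol=1e-9)
            np.testing.assert_allclose(m1.scores[perm, i], sign * m2.scores[:, i], atol=1e-9)

    def test_reconstruction_error_decreases_with_k(self):
        rng = np.random.default_rng(2)
        X = rng.random((10, 9))
        Xc = X - X.mean(axis=0)
        errors = []
        for k in (1, 3, 5, 9):
            model = fit_pca(_matrix(X), k=k)
            recon = model.scores @ model.loadings
            errors.append(np.linalg.norm(Xc - recon))
        assert all(a >= b - 1e-12 for a, b in zip(errors, errors[1:]))
        assert errors[-1] < 1e-8  # full-rank reconstruction

    def test_model_invariants(self, oriented_model):
        _, _, model = oriented_model
        gram = model.loadings @ model.loadings.T
        np.testing.assert_allclose(gram, np.eye(gram.shape[0]), atol=1e-8)
        np.testing.assert_allclose(model.scores.mean(axis=0), 0.0, atol=1e-8)
        evf = model.explained_variance_fraction
        assert np.all(np.diff(evf) <= 1e-12) and np.all((evf >= 0) & (evf <= 1))

    def test_k_exceeding_rank_rejected(self):
        v = np.array([1.0, 2.0, 3.0])
        with pytest.raises(ValueError):
            fit_pca(_matrix([v, 2 * v, 3 * v, 4 * v]), k=3)


class TestOrientation:
    def test_flip_and_idempotence(self):
        rng = np.random.default_rng(3)
        X = rng.random((10, 6))
        model = fit_pca(_matrix(X), k=3)
        ref = -model.loadings[0] + 0.01 * rng.random(6)
        oriented = orient_loadings(model, DifferenceSpectrum(model.axis, ref))
        assert oriented.loadings[0] @ ref >= 0
        again = orient_loadings(oriented, DifferenceSpectrum(model.axis, ref))
        np.testing.assert_array_equal(again.loadings, oriented.loadings)
        # scores flipped consistently: reconstruction unchanged
        np.testing.assert_allclose(
            oriented.scores @ oriented.loadings, model.scores @ model.loadings, atol=1e-12
        )

    def test_oriented_pc1_amide_positive_glycan_negative(self, oriented_model):
        """PC1 shows the anticorrelated amide-vs-glycan variation with the
        amide side positive under the difference-spectrum convention."""
        matrix, _, model = oriented_model
        pc1 = model.loadings[0]
        amideII = matrix.axis.window(1535, 1545)
        glycan = matrix.axis.window(1030, 1090)
        assert pc1[amideII].mean() > 0 > pc1[glycan].mean()

    def test_default_largest_element_rule(self):
        rng = np.random.default_rng(4)
        X = rng.random((10, 6))
        model = orient_loadings(fit_pca(_matrix(X), k=3))
        for ld in model.loadings:
            assert ld[np.argmax(np.abs(ld))] > 0


class TestSubgroupSplit:
    def test_sign_rule_with_tie(self):
        axis = WavenumberAxis(1000, 1002, 1.0)
        labels = pd.DataFrame({"group": ["treated"] * 3 + ["control"]})
        from pifir.chemometrics import PCAModel

        model = PCAModel(
            mean_spectrum=np.zeros(3),
            loadings=np.eye(1, 3),
            scores=np.array([[1.0], [-1.0], [0.0], [5.0]]),
            explained_variance_fraction=np.array([1.0]),
            axis=axis,
            labels=labels,
            oriented=True,
        )
        classes = split_by_pc1(model).classes.tolist()
        assert classes == ["amide", "glycan", "glycan", "control"]

    def test_unoriented_model_refused(self, oriented_model):
        matrix, _, _ = oriented_model
        with pytest.raises(ValueError, match="orient"):
            split_by_pc1(fit_pca(matrix, 2))

    def test_controls_all_negative_and_kept_as_control(self, oriented_model):
        matrix, _, model = oriented_model
        controls = (matrix.labels["group"] == "control").to_numpy()
        assert (model.score(1)[controls] < 0).all()
        assert (split_by_pc1(model).classes[controls] == "control").all()

    def test_bound_and_damage_positions_mostly_amide_class(self, oriented_model):
        matrix, _, model = oriented_model
        classes = split_by_pc1(model).classes
        bd = matrix.labels["stratum"].isin(["bound", "damage"]).to_numpy()
        assert (classes[bd] == "amide").mean() > 0.8


class TestDifferenceSpectrum:
    def test_identical_sets_give_zero(self):
        m = _matrix(np.random.default_rng(5).random((6, 5)))
        mask = np.array([True, True, True, False, False, False])
        d = difference_spectrum(m, mask, mask)
        np.testing.assert_allclose(d.values, 0.0, atol=1e-15)

    def test_antisymmetric_under_swap(self):
        m = _matrix(np.random.default_rng(6).random((6, 5)))
        a = np.array([True] * 3 + [False] * 3)
        np.testing.assert_allclose(
            difference_spectrum(m, a, ~a).values, -difference_spectrum(m, ~a, a).values,
            atol=1e-15,
        )

    def test_treated_minus_control_band_signs(self, oriented_model):
        """Treated spectra gain amide intensity and lose glycan intensity."""
        matrix, diff, _ = oriented_model
        amideI = matrix.axis.window(1610, 1660)
        amideII = matrix.axis.window(1530, 1570)
        glycan = matrix.axis.window(1030, 1090)
        assert diff.values[amideI].mean() > 0
        assert diff.values[amideII].mean() > 0
        assert diff.values[glycan].mean() < 0

    def test_empty_set_rejected(self):
        m = _matrix(np.ones((4, 5)))
        with pytest.raises(ValueError):
            difference_spectrum(m, np.zeros(4, bool), np.ones(4, bool))


class TestScoreMaps:
    def test_constant_cube_scores_are_zero(self):
        axis = WavenumberAxis(1400, 1410, 1.0)
        cube = HyperspectralCube(np.ones((4, 4, axis.n_bins)), axis)
        rng = np.random.default_rng(7)
        noisy = HyperspectralCube(
            cube.data + 1e-9 * rng.random(cube.data.shape), axis
        )  # tiny jitter keeps the rank positive
        model = fit_pca(assemble_matrix(cubes=[noisy]), k=1)
        maps = score_maps(model, cube_id=0)
        np.testing.assert_allclose(maps[0], 0.0, atol=1e-6)

    def test_bound_stripe_elevates_scores(self, hyper_cube, hyper_scene):
        model = orient_loadings(fit_pca(assemble_matrix(cubes=[hyper_cube]), k=3))
        bound = hyper_scene.ground_truth().bound_mask
        best = max(
            range(1, 4),
            key=lambda k: np.abs(score_maps(model, 0)[k - 1])[bound].mean(),
        )
        smap = np.abs(score_maps(model, 0)[best - 1])
        assert smap[bound].mean() > 2 * smap[~bound].mean()

    def test_combined_fit_gives_per_cube_maps(self, hyper_cube):
        model = fit_pca(assemble_matrix(cubes=[hyper_cube, hyper_cube]), k=2)
        maps0 = score_maps(model, cube_id=0)
        maps1 = score_maps(model, cube_id=1)
        assert maps0[0].shape == maps1[0].shape == (32, 32)
        np.testing.assert_allclose(maps0[0], maps1[0], atol=1e-9)  # identical cubes

    def test_missing_coordinates_rejected(self, oriented_model):
        _, _, model = oriented_model
        with pytest.raises(ValueError):
            score_maps(model, cube_id=0)


class TestSmoothComponents:
    def test_polynomial_loadings_unchanged(self):
        axis = WavenumberAxis(1000, 1100, 1.0)
        x = np.linspace(-1, 1, axis.n_bins)
        rows = np.array([(0.5 + 0.1 * i) * (x**2) + (i % 3) * x for i in range(6)])
        model = fit_pca(_matrix(rows, axis=axis), k=2)
        smoothed = smooth_components(model)
        np.testing.assert_allclose(smoothed.loadings, model.loadings, atol=1e-9)
        assert not smoothed.loadings_orthonormal

    def test_noisy_loading_variance_reduced(self, oriented_model):
        _, _, model = oriented_model
        rng = np.random.default_rng(8)
        noisy = model.loadings + rng.normal(0, 0.05, model.loadings.shape)
        from dataclasses import replace

        noisy_model = replace(model, loadings=noisy)
        smoothed = smooth_components(noisy_model)
        resid_before = np.var(noisy - model.loadings)
        resid_after = np.var(smoothed.loadings - model.loadings)
        assert resid_after < 0.5 * resid_before
        np.testing.assert_array_equal(smoothed.scores, model.scores)
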