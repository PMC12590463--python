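"""Synthetic scene generator: topography, anisotropy, rendering, sampling."""

import numpy as np
import pytest

from pifir.axes import WavenumberAxis
from pifir.scene import (
    ArtifactConfig,
    CellGeometry,
    IlluminationSpec,
    apply_artifacts,
    compute_anisotropy,
    make_cell_scene,
    make_hyperspectral_scene,
    render_hyperspectrum,
    render_scan,
    render_topography,
    sample_point_spectra,
)
from pifir.images import ScanImage
from pifir.preprocess import correct_line_drift


class TestTopography:
    def test_zero_height_max_gives_flat_map(self):
        geo = CellGeometry((16, 16), (300, 200), height_max=0.0)
        assert np.all(render_topography(geo, (32, 32), 20.0) == 0)

    def test_plain_capsule_peaks_at_center(self):
        geo = CellGeometry((16, 16), (300, 200), height_max=300.0)
        h = render_topography(geo, (33, 33), 20.0)
        assert np.unravel_index(np.argmax(h), h.shape) == (16, 16)
        assert h.min() >= 0

    def test_septum_depth_along_long_axis_centerline(self):
        """The septum floor sits `depth` below the capsule ridge."""
        geo = CellGeometry(
            (16, 16),
            (300, 200),
            height_max=300.0,
            septum=dict(position=16, width=100, depth=50.0, piecrust_width=0),
        )
        h = render_topography(geo, (33, 33), 20.0)
        ridge = h[16, :]
        cols_nm = (np.arange(33) - 16) * 20.0
        in_septum = np.abs(cols_nm) <= 50.0
        assert ridge[in_septum].min() == pytest.approx(300.0 - 50.0, abs=1.0)
        assert h[16, 16] == pytest.approx(250.0, abs=1e-9)

    def test_septum_wider_than_cell_rejected(self):
        with pytest.raises(ValueError, match="septum"):
            CellGeometry(
                (16, 16), (300, 200), 300.0, septum=dict(position=16, width=700, depth=50)
            )

    def test_region_masks_are_disjoint_parts_of_the_cell(self):
        geo = CellGeometry(
            (16, 16),
            (300, 200),
            height_max=300.0,
            septum=dict(position=16, width=80, depth=50.0, piecrust_width=60.0),
            damage_patches=(dict(center=(10, 8), radius=60.0),),
        )
        _, masks = render_topography(geo, (33, 33), 20.0, return_masks=True)
        for name in ("septum", "piecrust", "damage"):
            assert masks[name].any()
            assert not (masks[name] & ~masks["cell"]).any()


class TestAnisotropy:
    def test_zero_strength_gives_unity(self):
        h = np.random.default_rng(0).random((16, 16))
        A = compute_anisotropy(h, IlluminationSpec(strength=0.0))
        assert np.all(A == 1.0)

    def test_flat_scene_gives_unity_without_division_error(self):
        A = compute_anisotropy(np.ones((16, 16)), IlluminationSpec(strength=0.8))
        assert np.all(A == 1.0)

    def test_bump_front_darker_than_back(self):
        """Slopes facing the illumination get A < 1, the far side A > 1."""
        rr, cc = np.mgrid[0:33, 0:33]
        h = 100 * np.exp(-(((rr - 16) / 6.0) ** 2 + ((cc - 16) / 6.0) ** 2))
        A = compute_anisotropy(h, IlluminationSpec(azimuth_deg=0.0, strength=0.5))
        front = A[:, :16][h[:, :16] > 5]
        back = A[:, 17:][h[:, 17:] > 5]
        assert front.mean() < 1.0 < back.mean()

    def test_clamp_bounds_respected(self):
        rr, cc = np.mgrid[0:17, 0:17]
        h = 50.0 * cc
        A = compute_anisotropy(h, IlluminationSpec(azimuth_deg=0, strength=5.0, clamp=(0.3, 1.6)))
        assert A.min() >= 0.3 and A.max() <= 1.6


class TestRenderScan:
    def test_mixture_identity_on_pure_pixel(self, quiet_scene):
        """Noise/anisotropy off: a pixel's PiF equals sum_c f_c * S_c(nu)."""
        pif, _ = render_scan(quiet_scene, 1520.0, with_noise=False)
        r, c = 20, 32
        expected = sum(
            quiet_scene.fractions[name][r, c] * comp.value_at(1520.0)
            for name, comp in quiet_scene.components.items()
            if name in quiet_scene.fractions
        )
        assert pif.data[r, c] == pytest.approx(expected, abs=1e-12)

    def test_mixture_oracle_full_scene(self, quiet_scene):
        """Naive double-loop mixture oracle matches the vectorized renderer."""
        nu = 1520.0
        pif, _ = render_scan(quiet_scene, nu, with_noise=False)
        rows, cols = quiet_scene.shape
        expected = np.zeros((rows, cols))
        for r in range(rows):
            for c in range(cols):
                acc = 0.0
                for name, f in quiet_scene.fractions.items():
                    acc += f[r, c] * quiet_scene.components[name].value_at(nu)
                expected[r, c] = acc
        np.testing.assert_allclose(pif.data, expected, atol=1e-10)

    def test_two_frequency_ratio_free_of_gradient_term(self, treated_scene):
        """The anisotropy factor cancels exactly in per-pixel ratios."""
        a, _ = render_scan(treated_scene, 1520.0, with_noise=False)
        b, _ = render_scan(treated_scene, 1060.0, with_noise=False)
        on = (a.data > 1e-6) & (b.data > 1e-6)
        ratio = a.data[on] / b.data[on]
        A = treated_scene.anisotropy[on]
        corr = np.corrcoef(ratio, A)[0, 1]
        assert abs(corr) < 0.05

    def test_amide_pixel_brighter_than_glycan_pixel_at_1520(self, components):
        assert components["amide_unbound"].value_at(1520.0) > components["glycan"].value_at(1520.0)

    def test_wavenumber_outside_axis_rejected(self, treated_scene):
        with pytest.raises(ValueError, match="outside"):
            render_scan(treated_scene, 2500.0)

    def test_reproducible_under_seed(self, treated_scene):
        a, _ = render_scan(treated_scene, 1520.0, seed=5)
        b, _ = render_scan(treated_scene, 1520.0, seed=5)
        np.testing.assert_array_equal(a.data, b.data)


class TestHyperspectrum:
    def test_default_cube_shape(self, hyper_cube):
        assert hyper_cube.shape == (32, 32, 261)

    def test_noise_off_slice_equals_scan(self, quiet_scene):
        axis = WavenumberAxis(1500.0, 1530.0)
        cube = render_hyperspectrum(quiet_scene, axis, with_noise=False)
        pif, _ = render_scan(quiet_scene, 1510.0, with_noise=False)
        np.testing.assert_array_equal(cube.slice_at(1510.0).data, pif.data)

    def test_substrate_pixel_spectrum_is_zero(self, hyper_scene):
        cube = render_hyperspectrum(hyper_scene, with_noise=False)
        total = sum(hyper_scene.fractions.values())
        r, c = np.unravel_index(np.argmin(total), total.shape)
        assert total[r, c] == 0
        assert np.all(cube.data[r, c, :] == 0)

    def test_axis_step_mismatch_rejected(self, hyper_scene):
        with pytest.raises(ValueError, match="step"):
            render_hyperspectrum(hyper_scene, WavenumberAxis(1400, 1660, 2.0))


class TestArtifacts:
    def _flat_scan(self, rows=32, cols=32, value=2.0):
        return ScanImage(np.full((rows, cols), value), channel="pif", wavenumber=1060.0)

    def test_all_toggles_off_is_identity(self):
        scan = self._flat_scan()
        out = apply_artifacts(scan, ArtifactConfig(), seed=0)
        np.testing.assert_array_equal(out.data, scan.data)

    def test_streaks_hit_every_period_th_row(self):
        scan = self._flat_scan()
        cfg = ArtifactConfig(streaks=True, streak_period=8, streak_amplitude=0.5)
        out = apply_artifacts(scan, cfg, seed=0, contaminant_value=1.0)
        affected = np.flatnonzero(np.abs(out.data[:, 0] - 2.0) > 1e-12)
        assert list(affected) == [0, 8, 16, 24]

    def test_line_drift_roundtrip_with_correction(self):
        base = np.outer(np.ones(32), np.linspace(1, 2, 32))
        scan = ScanImage(base, channel="pif", wavenumber=1060.0)
        cfg = ArtifactConfig(line_drift=True, line_drift_sigma=0.2)
        drifted = apply_artifacts(scan, cfg, seed=3)
        corrected = correct_line_drift(drifted)
        row_medians = np.median(corrected.data, axis=1)
        assert np.ptp(row_medians) / np.median(row_medians) < 0.01

    def test_overshoot_adds_spikes_at_rising_edges(self, treated_scene):
        pif, height = render_scan(treated_scene, 1060.0, with_noise=False)
        cfg = ArtifactConfig(overshoot=True, overshoot_gain=0.5)
        out = apply_artifacts(pif, cfg, height=treated_scene.height)
        dcol = np.gradient(treated_scene.height, axis=1)
        assert np.all(out.data[dcol > 0] >= pif.data[dcol > 0])
        np.testing.assert_allclose(out.data[dcol <= 0], pif.data[dcol <= 0])


class TestPointSpectra:
    def test_default_set_sizes_and_labels(self, labeled_set):
        spectra, truth = labeled_set
        assert len(spectra) == 64
        counts = spectra.labels["group"].value_counts()
        assert counts["treated"] == 51 and counts["control"] == 13
        assert {"row", "col", "stratum", "bound"} <= set(spectra.labels.columns)

    def test_no_controls_rejected(self, treated_scene, control_scene):
        with pytest.raises(ValueError):
            sample_point_spectra(treated_scene, control_scene, n_treated=5, n_control=0)

    def test_noiseless_bound_pixel_matches_component_spectrum(self):
        scene = make_cell_scene(
            "bound",
            seed=7,
            noise=dict(mult_sigma=0.0, add_sigma=0.0),
            power_envelope=False,
        )
        spectra, _ = sample_point_spectra(scene, make_cell_scene("control", seed=8), seed=9)
        i = int(np.argmax(spectra.labels["group"] == "treated"))
        r, c = spectra.labels.loc[i, ["row", "col"]]
        expected = np.zeros(scene.axis.n_bins)
        for name, f in scene.fractions.items():
            expected += f[r, c] * scene.components[name].rendered
        expected *= scene.anisotropy[r, c]
        np.testing.assert_allclose(spectra.intensities[i], expected, atol=1e-12)

    def test_bound_labels_consistent_with_fractions(self, labeled_set, treated_scene):
        spectra, truth = labeled_set
        treated = spectra.labels[spectra.labels["group"] == "treated"]
        for _, row in treated.iterrows():
            f_bound = treated_scene.fractions["amide_bound"][row["row"], row["col"]]
            assert row["bound"] == (f_bound >= treated_scene.bound_threshold)

    def test_reproducible_under_seed(self, treated_scene, control_scene):
        a, _ = sample_point_spectra(treated_scene, control_scene, seed=42)
        b, _ = sample_point_spectra(treated_scene, control_scene, seed=42)
        np.testing.assert_array_equal(a.intensities, b.intensities)
        assert a.labels.equals(b.labels)

    def test_fraction_sums_bounded(self, treated_scene, hyper_scene):
        for scene in (treated_scene, hyper_scene):
            total = sum(scene.fractions.values())
            assert total.max() <= 1 + 1e-9 and total.min() >= 0
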