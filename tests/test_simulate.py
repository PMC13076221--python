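import numpy as np
import pytest

from lipidspec.core import Spectrum
from lipidspec.simulate import (
    EndmemberSpec,
    ScenarioConfig,
    available_species,
    generate_cell_series,
    generate_disk_micrograph,
    generate_guv_spectra,
    generate_phantom_cube,
    load_endmember_spec,
    lorentzian,
    synthesize_endmember,
)
from lipidspec.stats import band_auc

from conftest import small_phantom_config


def _has_local_peak(s: Spectrum, center: float, shoulder: float = 20.0) -> bool:
    """True if the spectrum peaks near `center` (grid may not hit it exactly)."""
    nu = s.grid.values
    near = np.abs(nu - center) <= 3.0
    away = (np.abs(nu - center) > shoulder) & (np.abs(nu - center) < 2 * shoulder)
    return s.intensity[near].max() > s.intensity[away].max()


class TestEndmembers:
    def test_zero_bands_gives_zero_spectrum(self, fingerprint_grid):
        spec = EndmemberSpec("empty", bands=())
        s = synthesize_endmember(spec, fingerprint_grid)
        assert np.all(s.intensity == 0)

    def test_lorentzian_unit_peak(self):
        assert lorentzian(np.array([1056.0]), 1056.0, 12.0)[0] == 1.0
        # half maximum at +/- FWHM/2
        assert lorentzian(np.array([1050.0, 1062.0]), 1056.0, 12.0) == pytest.approx(
            [0.5, 0.5]
        )

    def test_chol_peaks_at_sterol_ring(self, fingerprint_grid):
        s = synthesize_endmember(load_endmember_spec("Chol"), fingerprint_grid)
        assert _has_local_peak(s, 1056.0, shoulder=10.0)

    def test_sm_amide_and_acyl_peaks(self, fingerprint_grid):
        s = synthesize_endmember(load_endmember_spec("SM"), fingerprint_grid)
        for center in (1645.0, 1555.0, 1464.0):
            assert _has_local_peak(s, center)

    def test_carbon_tape_is_flat(self, fingerprint_grid):
        s = synthesize_endmember(load_endmember_spec("carbon_tape"), fingerprint_grid)
        assert np.all(s.intensity == s.intensity[0])
        assert s.intensity[0] > 0

    def test_complex_band_shifted_8_from_sterol(self):
        chol = dict((c, (a, w)) for c, a, w in load_endmember_spec("Chol").bands)
        complexed = dict(
            (c, (a, w)) for c, a, w in load_endmember_spec("MbCD_Chol_complex").bands
        )
        assert 1056.0 in chol and 1048.0 in complexed
        assert 1056.0 - 1048.0 == 8.0

    def test_unknown_species(self):
        with pytest.raises(KeyError, match="unknown endmember"):
            load_endmember_spec("POPC")

    def test_index_lists_all_species(self):
        assert {"Chol", "DOPC", "SM", "water", "carbon_tape", "sucrose"} <= set(
            available_species()
        )

    def test_negative_amplitude_rejected(self):
        with pytest.raises(ValueError, match="amplitude"):
            EndmemberSpec("bad", bands=((1000.0, -1.0, 12.0),))


class TestPhantom:
    def test_noiseless_well_pixel_equals_endmember(self, clean_phantom):
        truth = clean_phantom.truth
        r, c = [int(v.mean()) for v in np.nonzero(truth.mask("SM"))]
        expected = synthesize_endmember(
            load_endmember_spec("SM"), clean_phantom.grid
        ).intensity
        np.testing.assert_array_equal(clean_phantom.data[r, c], expected)

    def test_seeded_determinism(self):
        a = generate_phantom_cube(small_phantom_config())
        b = generate_phantom_cube(small_phantom_config())
        np.testing.assert_array_equal(a.data, b.data)
        np.testing.assert_array_equal(a.truth.gain, b.truth.gain)

    def test_noise_sd_matches_direct_sample_sd(self, clean_phantom):
        # oracle: sample s.d. of (noisy - clean) over >= 1e4 voxels
        noisy = generate_phantom_cube(
            small_phantom_config(noise_sigma=0.02, drift_range=(1.0, 1.0))
        )
        residual = noisy.data - clean_phantom.data
        assert residual.size >= 10_000
        expected = 0.02 * clean_phantom.data.max()
        assert residual.std() == pytest.approx(expected, rel=0.05)

    def test_drift_gains_within_bounds(self, small_phantom):
        lo, hi = 0.7, 1.3
        assert np.all(small_phantom.truth.gain >= lo)
        assert np.all(small_phantom.truth.gain <= hi)

    def test_wells_do_not_fit(self):
        with pytest.raises(ValueError, match="radius"):
            generate_phantom_cube(
                small_phantom_config(image_size=40, well_radius=20)
            )

    def test_four_disjoint_wells(self, small_phantom):
        labels = small_phantom.truth.labels
        assert set(np.unique(labels)) == {0, 1, 2, 3, 4}
        assert small_phantom.truth.names == [
            "carbon_tape", "Chol", "DOPC", "SM", "water",
        ]

    def test_pe_s1p_scenario_wells(self):
        cube = generate_phantom_cube(
            small_phantom_config(scenario="phantom2d_pe_s1p")
        )
        assert cube.truth.names[1:] == ["DOPC", "DOPE", "S1P", "water"]

    def test_grid_is_catalog(self, small_phantom):
        assert len(small_phantom.grid) == 22

    def test_noise_scaling_doubles(self):
        clean = generate_phantom_cube(
            small_phantom_config(noise_sigma=0.0)
        )
        sds = []
        for sigma in (0.02, 0.04):
            noisy = generate_phantom_cube(small_phantom_config(noise_sigma=sigma))
            sds.append((noisy.data - clean.data).std())
        assert sds[1] / sds[0] == pytest.approx(2.0, rel=0.05)


class TestGUV:
    def test_pure_dopc_is_endmember_plus_sucrose(self):
        config = ScenarioConfig.defaults(
            "guv", composition={"DOPC": 1.0}, n_samples=1,
        )
        config.composition_jitter = 0.0
        config.noise_sigma = 0.0
        (spectrum, truth), = generate_guv_spectra(config)
        grid = spectrum.grid
        dopc = synthesize_endmember(load_endmember_spec("DOPC"), grid).intensity
        sucrose = synthesize_endmember(load_endmember_spec("sucrose"), grid).intensity
        expected = dopc / np.abs(dopc).sum() + 0.2 * sucrose / np.abs(sucrose).sum()
        np.testing.assert_allclose(spectrum.intensity, expected, rtol=1e-12)
        assert truth == {"DOPC": 1.0, "SM": 0.0, "Chol": 0.0}

    def test_one_to_one_mix_is_exact_linear_combination(self):
        config = ScenarioConfig.defaults(
            "guv", composition={"SM": 0.5, "Chol": 0.5}, n_samples=1,
            composition_jitter=0.0, noise_sigma=0.0, sucrose_level=0.0,
        )
        (spectrum, truth), = generate_guv_spectra(config)
        grid = spectrum.grid
        parts = []
        for sp in ("SM", "Chol"):
            y = synthesize_endmember(load_endmember_spec(sp), grid).intensity
            parts.append(y / np.abs(y).sum())
        np.testing.assert_allclose(
            spectrum.intensity, 0.5 * parts[0] + 0.5 * parts[1], rtol=1e-12
        )
        assert truth["SM"] == truth["Chol"] == 0.5

    def test_jitter_matches_recorded_truth_spread(self):
        # oracle: sample s.d. of the recorded true fractions
        config = ScenarioConfig.defaults("guv", seed=5, n_samples=400)
        samples = generate_guv_spectra(config)
        fracs = np.array([[t["DOPC"], t["SM"], t["Chol"]] for _, t in samples])
        rel_sd = fracs.std(axis=0) / fracs.mean(axis=0)
        # renormalization shrinks the per-component spread below the raw 0.15
        assert np.all(rel_sd > 0.05) and np.all(rel_sd < 0.25)

    def test_determinism(self):
        config = ScenarioConfig.defaults("guv", seed=3, n_samples=4)
        a = generate_guv_spectra(config)
        b = generate_guv_spectra(ScenarioConfig.defaults("guv", seed=3, n_samples=4))
        for (sa, ta), (sb, tb) in zip(a, b):
            np.testing.assert_array_equal(sa.intensity, sb.intensity)
            assert ta == tb

    def test_empty_composition_rejected(self):
        with pytest.raises(ValueError, match="empty|zero"):
            generate_guv_spectra(ScenarioConfig("guv", composition={}))

    def test_non_lipid_key_rejected(self):
        with pytest.raises(ValueError, match="lipids"):
            generate_guv_spectra(
                ScenarioConfig("guv", composition={"water": 1.0})
            )


class TestCellSeries:
    def test_zero_effect_keeps_timepoints_identical(self):
        config = ScenarioConfig.defaults(
            "cells_sm", effect_percent=0.0, noise_sigma=0.0, n_samples=3
        )
        series = generate_cell_series(config)
        t0 = series["T0"]
        for label in ("T48", "T72"):
            for a, b in zip(t0, series[label]):
                np.testing.assert_array_equal(a.intensity, b.intensity)

    def test_clean_auc_ratio_is_exactly_the_effect(self):
        from lipidspec.preprocess import preprocess_cell_spectrum

        config = ScenarioConfig.defaults(
            "cells_sm", noise_sigma=0.0, heterogeneity=0.0, n_samples=1
        )
        series = generate_cell_series(config)
        aucs = {}
        for label in ("T0", "T72"):
            s = series[label][0]
            pre = preprocess_cell_spectrum(s, series.medium, s.grid)
            aucs[label] = band_auc(pre.spectrum, series.truth["window"])
        assert aucs["T72"] / aucs["T0"] == pytest.approx(2.17, abs=1e-9)

    def test_chol_marker_at_1048_not_1056(self):
        config = ScenarioConfig.defaults(
            "cells_chol", noise_sigma=0.0, heterogeneity=0.0, n_samples=1
        )
        series = generate_cell_series(config)
        diff = series["T16"][0].intensity - series["T0"][0].intensity
        assert series["T16"][0].grid.values[np.argmax(diff)] == 1048.0

    def test_marker_band_locality(self):
        config = ScenarioConfig.defaults(
            "cells_sm", noise_sigma=0.0, heterogeneity=0.0, n_samples=1
        )
        series = generate_cell_series(config)
        grid = series["T0"][0].grid.values
        diff = np.abs(series["T72"][0].intensity - series["T0"][0].intensity)
        peak = diff.max()
        outside = np.abs(grid - 1464.0) > 60.0  # Lorentzian support at 1% of peak
        assert np.all(diff[outside] < 0.01 * peak)

    def test_medium_returned_on_same_grid(self):
        series = generate_cell_series(
            ScenarioConfig.defaults("cells_chol", n_samples=2)
        )
        assert series.medium.grid == series["T0"][0].grid

    def test_determinism(self):
        config = ScenarioConfig.defaults("cells_control", seed=11, n_samples=4)
        a = generate_cell_series(config)
        b = generate_cell_series(
            ScenarioConfig.defaults("cells_control", seed=11, n_samples=4)
        )
        for label in a.timepoints:
            for sa, sb in zip(a[label], b[label]):
                np.testing.assert_array_equal(sa.intensity, sb.intensity)

    def test_unknown_scenario(self):
        with pytest.raises(ValueError):
            ScenarioConfig("cells_unknown")

    def test_non_cell_scenario_rejected(self):
        with pytest.raises(ValueError, match="cell scenario"):
            generate_cell_series(ScenarioConfig("phantom2d"))

    def test_paired_heterogeneity_constant_across_time(self):
        config = ScenarioConfig.defaults(
            "cells_sm", noise_sigma=0.0, n_samples=5, effect_percent=0.0
        )
        series = generate_cell_series(config)
        scales = np.array(series.truth["cell_scale"])
        assert len(np.unique(scales)) == 5  # heterogeneity drawn per cell
        ratio = series["T72"][2].intensity / series["T0"][2].intensity
        np.testing.assert_allclose(ratio, 1.0)


class TestDiskMicrograph:
    def test_truth_geometry(self):
        image, mask = generate_disk_micrograph(
            shape=(64, 64), radius=8, intensity=2.0, background=0.5,
            noise_sigma=0.0,
        )
        assert image[mask].min() == 2.0
        assert image[~mask].max() == 0.5

    def test_determinism(self):
        a, _ = generate_disk_micrograph(seed=9)
        b, _ = generate_disk_micrograph(seed=9)
        np.testing.assert_array_equal(a, b)
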