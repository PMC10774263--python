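"""Phantom generators: determinism, self-consistency, cell-silent property."""

import numpy as np
import pytest

from optirlipid import (
    CellPhantomSpec,
    ComponentLibrary,
    detect_peaks,
    fit_spectrum,
    make_cell_image,
    make_dilution_series,
    make_organoid_phantom,
    make_power_spectrum,
    make_spectrum,
    mask_silent_gap,
    two_sample_test,
)
from optirlipid.metrics import cell_metrics
from optirlipid.phantoms import DEFAULT_AXIS


class TestComponentLibrary:
    def test_default_axis_matches_scan_range(self):
        assert DEFAULT_AXIS[0] == 980.0
        assert DEFAULT_AXIS[-1] == 2300.0
        assert DEFAULT_AXIS.size == 661  # 2 cm^-1 spacing

    def test_components_unit_maximum(self, library):
        for name, comp in library.components.items():
            assert comp.max() == pytest.approx(1.0)
            assert comp.min() >= 0.0

    def test_cell_silent_region_free_of_endogenous_signal(self, library):
        sel = (library.axis >= 2000.0) & (library.axis <= 2320.0)
        for name, comp in library.components.items():
            if name == "azide":
                continue
            assert comp[sel].max() < 1e-6


class TestMakeSpectrum:
    def test_azide_only_peak_in_silent_region(self, library):
        s, _ = make_spectrum({"azide": 1.0}, library=library)
        cands = detect_peaks(s)
        silent = [c for c in cands if 2000.0 <= c <= 2320.0]
        assert silent and abs(silent[0] - 2096.0) <= 2.0

    def test_zero_weights_fit_to_statistically_zero_areas(self, library):
        s, _ = make_spectrum({}, noise_sd=0.005, seed=0, library=library)
        s = mask_silent_gap(s)
        fit = fit_spectrum(s, [1654.0, 1744.0, 2096.0])
        for area in fit.areas.values():
            assert abs(area) < 0.5  # pure noise: no real band area

    def test_doubling_weights_doubles_true_areas(self, library):
        _, t1 = make_spectrum({"protein": 1.0, "azide": 0.5}, library=library)
        _, t2 = make_spectrum({"protein": 2.0, "azide": 1.0}, library=library)
        for band, area in t1["band_areas"].items():
            assert t2["band_areas"][band] == pytest.approx(2.0 * area, rel=1e-12)

    def test_negative_noise_rejected(self):
        with pytest.raises(ValueError):
            make_spectrum({"protein": 1.0}, noise_sd=-0.1)

    def test_seed_determinism(self, library):
        s1, _ = make_spectrum({"protein": 1.0}, noise_sd=0.01, seed=5, library=library)
        s2, _ = make_spectrum({"protein": 1.0}, noise_sd=0.01, seed=5, library=library)
        np.testing.assert_array_equal(s1.intensity, s2.intensity)

    def test_true_areas_recovered_by_fit(self, library):
        weights = {"protein": 1.0, "total_lipid": 0.5, "azide": 0.25}
        s, truth = make_spectrum(weights, library=library)
        s = mask_silent_gap(s)
        fit = fit_spectrum(s, detect_peaks(s))
        for band in ("amide_I", "lipid_carbonyl", "azide"):
            assert fit.areas[band] == pytest.approx(truth["band_areas"][band],
                                                    rel=1e-3)


class TestMakeCellImage:
    def test_seed_determinism_bit_identical(self):
        spec = CellPhantomSpec(fov_um=25.0, n_cells=1, cell_radius_um=6.0)
        a, ta = make_cell_image(spec, seed=3, noise_snr=50.0)
        b, tb = make_cell_image(spec, seed=3, noise_snr=50.0)
        for band in a:
            np.testing.assert_array_equal(a[band].pixels, b[band].pixels)
        np.testing.assert_array_equal(ta.cell_mask.labels, tb.cell_mask.labels)

    def test_truths_recomputable_from_weight_maps(self):
        spec = CellPhantomSpec(fov_um=25.0, n_cells=1, cell_radius_um=6.0)
        _, truth = make_cell_image(spec, seed=4)
        again = truth.recompute_cell_truths()
        for k, v in truth.cell_truths.items():
            assert again[k]["new_lipid_fraction"] == pytest.approx(
                v["new_lipid_fraction"]
            )

    def test_no_psf_no_noise_ratio_is_exact_weight_ratio(self):
        spec = CellPhantomSpec(fov_um=25.0, n_cells=1, cell_radius_um=6.0,
                               droplets_per_cell=2, droplet_radius_um=1.0,
                               new_lipid_fraction=0.37)
        imgs, truth = make_cell_image(spec, seed=5, apply_psf=False,
                                      noise_snr=None)
        lipid = truth.weight_maps["total_lipid"]
        sel = lipid > 1e-9
        ratio = imgs["azide"].pixels[sel] / imgs["lipid_carbonyl"].pixels[sel]
        np.testing.assert_allclose(ratio, 0.37, rtol=1e-9)

    def test_subresolution_droplet_profile_fwhm_matches_psf(self):
        from optirlipid import droplet_line_profile, fwhm_line_profile
        from optirlipid.phantoms import make_resolution_phantom

        fwhms = []
        for seed in range(3):
            img, center = make_resolution_phantom(seed=seed, noise_snr=None)
            pos, vals = droplet_line_profile(img, center)
            fwhms.append(fwhm_line_profile(pos, vals))
        assert np.mean(fwhms) == pytest.approx(0.5, rel=0.05)

    def test_effect_recovery_two_conditions(self, bands):
        # true fractions 0.3 vs 0.6, n cells per group via point spectra:
        # the full spectral pipeline detects the difference in the right
        # direction (scaled-down analogue of a two-condition experiment)
        rng = np.random.default_rng(12)
        groups = {}
        for name, frac in (("control", 0.3), ("treated", 0.6)):
            vals = []
            for _ in range(8):
                lipid = 0.5 * rng.lognormal(0.0, 0.15)
                s, _ = make_spectrum(
                    {"protein": 1.0, "total_lipid": lipid, "azide": lipid * frac},
                    noise_sd=0.01, seed=int(rng.integers(0, 2**31 - 1)),
                )
                s = mask_silent_gap(s)
                fit = fit_spectrum(s, detect_peaks(s), bands)
                vals.append(cell_metrics(fit, bands=bands).new_lipid_fraction)
            groups[name] = vals
        res = two_sample_test(groups["control"], groups["treated"])
        assert np.mean(groups["treated"]) > np.mean(groups["control"])
        assert res.p_value < 0.05

    def test_droplet_radius_below_minimum_rejected(self):
        from optirlipid.exceptions import GeometryError

        spec = CellPhantomSpec(droplet_radius_um=0.01)
        with pytest.raises(GeometryError):
            make_cell_image(spec)


class TestOrganoidPhantom:
    def test_flat_profile_in_infinite_decay_limit(self):
        ph = make_organoid_phantom(radius_um=300.0, decay_length_um=float("inf"),
                                   seed=0, pixel_size_um=5.0,
                                   n_locations=3, spectra_per_location=3,
                                   noise_sd=0.0)
        areas = ph.truth["true_azide_areas"]
        np.testing.assert_allclose(areas, areas[0], rtol=1e-9)

    def test_surface_to_depth_area_ratio_closed_form(self):
        L = 250.0
        ph = make_organoid_phantom(radius_um=1000.0, decay_length_um=L, seed=1,
                                   pixel_size_um=10.0, n_locations=5,
                                   spectra_per_location=3, noise_sd=0.0)
        depths = ph.truth["depths_um"]
        areas = ph.truth["true_azide_areas"]
        for d, a in zip(depths, areas):
            assert a / areas[0] == pytest.approx(np.exp(-d / L), rel=1e-9)

    def test_decay_length_recovery_over_seeds(self):
        # fitted exponential decay length within 10% of truth (mean of seeds)
        from scipy.optimize import curve_fit

        from optirlipid.metrics import depth_profile

        recovered = []
        for seed in range(10):
            ph = make_organoid_phantom(radius_um=400.0, decay_length_um=150.0,
                                       seed=seed, pixel_size_um=5.0,
                                       n_locations=5, spectra_per_location=3,
                                       noise_sd=0.003)
            prof = depth_profile(ph.spectra, ph.tissue_mask, use_fit=False)
            popt, _ = curve_fit(lambda d, a, L: a * np.exp(-d / L),
                                prof.distances_um, prof.mean_areas,
                                p0=[prof.mean_areas[0], 100.0])
            recovered.append(popt[1])
        assert np.mean(recovered) == pytest.approx(150.0, rel=0.10)

    def test_seed_determinism(self):
        a = make_organoid_phantom(radius_um=300.0, seed=6, pixel_size_um=10.0,
                                  n_locations=3, spectra_per_location=3)
        b = make_organoid_phantom(radius_um=300.0, seed=6, pixel_size_um=10.0,
                                  n_locations=3, spectra_per_location=3)
        np.testing.assert_array_equal(a.azide_image.pixels, b.azide_image.pixels)
        for sa, sb in zip(a.spectra, b.spectra):
            np.testing.assert_array_equal(sa.intensity, sb.intensity)


class TestDilutionSeries:
    def test_zero_noise_is_perfectly_linear(self):
        series, _ = make_dilution_series(noise_sd=0.0, seed=0)
        slopes = series.areas / series.concentrations
        np.testing.assert_allclose(slopes, slopes[0], rtol=1e-12)

    def test_halving_slope_doubles_analytic_lod(self):
        _, t1 = make_dilution_series(slope=1e-3, noise_sd=0.02, seed=0)
        _, t2 = make_dilution_series(slope=5e-4, noise_sd=0.02, seed=0)
        assert t2["analytic_lod_um"] == pytest.approx(2.0 * t1["analytic_lod_um"])

    def test_default_analytic_lod_is_100_um(self):
        _, truth = make_dilution_series(seed=0)
        assert truth["analytic_lod_um"] == pytest.approx(100.0)


class TestPowerSpectrumModel:
    def test_pinned_at_reference_wavenumber(self):
        p = make_power_spectrum(power_at_ref_mw=5.0)
        assert p.at(2096.0) == pytest.approx(5.0, rel=1e-6)

    def test_strictly_positive_everywhere(self):
        p = make_power_spectrum()
        assert (p.power_mw > 0).all()
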