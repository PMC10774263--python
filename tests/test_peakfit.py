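"""Peak detection, whole-spectrum fitting and FWHM estimation oracles."""

import math

import numpy as np
import pytest

from optirlipid import (
    FitConfig,
    Spectrum,
    band_area,
    detect_peaks,
    fit_spectrum,
    fwhm_line_profile,
    make_spectrum,
    mask_silent_gap,
)
from optirlipid.exceptions import EstimationError, FitError, FormatError
from optirlipid.peakfit import GAUSS_AREA_FACTOR, PeakComponent

AXIS = np.arange(980.0, 2300.0 + 1e-9, 2.0)


def gauss_sum(centers, fwhms, amps, baseline=0.0):
    y = np.full(AXIS.size, float(baseline))
    for c, f, a in zip(centers, fwhms, amps):
        y = y + a * np.exp(-4 * math.log(2) * ((AXIS - c) / f) ** 2)
    return Spectrum(AXIS, y, power_normalized=True)


class TestDetectPeaks:
    def test_single_gaussian_found_at_center(self):
        s = gauss_sum([1654.0], [30.0], [1.0])
        cands = detect_peaks(s)
        assert len(cands) == 1
        assert abs(cands[0] - 1654.0) <= 2.0  # one grid step

    def test_azide_library_spectrum_yields_silent_region_peak(self, library):
        s, _ = make_spectrum({"azide": 1.0}, library=library)
        cands = detect_peaks(s)
        silent = [c for c in cands if 2000.0 <= c <= 2320.0]
        assert len(silent) == 1
        assert abs(silent[0] - 2096.0) <= 2.0

    def test_two_gaussians_at_1p2_fwhm_separation(self):
        # analytic second-derivative minima of this pair (brute-force search
        # of the closed-form second derivative on a 0.001 cm^-1 grid):
        # 1599.006 and 1636.994
        s = gauss_sum([1600.0, 1636.0], [30.0, 30.0], [1.0, 1.0])
        cands = detect_peaks(s)
        near = [c for c in cands if 1580.0 <= c <= 1660.0]
        assert len(near) == 2
        assert abs(near[0] - 1599.006) <= 2.0
        assert abs(near[1] - 1636.994) <= 2.0

    def test_masked_gap_excluded_from_candidates(self):
        s = gauss_sum([1900.0, 1654.0], [30.0, 30.0], [5.0, 1.0])
        cands = detect_peaks(mask_silent_gap(s))
        assert all(not (1780.0 <= c <= 2030.0) for c in cands)

    def test_window_larger_than_spectrum_rejected(self):
        axis = np.arange(1600.0, 1614.0, 2.0)
        s = Spectrum(axis, np.ones(axis.size), power_normalized=True)
        with pytest.raises(FormatError):
            detect_peaks(s, smooth_window=11)


class TestFitSpectrum:
    def test_noiseless_single_gaussian_recovered_exactly(self):
        s = gauss_sum([1740.0], [30.0], [2.0])
        fit = fit_spectrum(s, [1741.0])
        assert fit.converged
        comp = fit.band_components["lipid_carbonyl"]
        assert comp.center == pytest.approx(1740.0, abs=1e-4)
        assert comp.fwhm == pytest.approx(30.0, rel=1e-6)
        assert comp.amplitude == pytest.approx(2.0, rel=1e-6)
        assert fit.areas["lipid_carbonyl"] == pytest.approx(
            2.0 * 30.0 * GAUSS_AREA_FACTOR, rel=1e-6
        )

    def test_noiseless_triple_gaussian_areas_closed_form(self):
        amps, fwhms = [1.0, 0.5, 0.25], [28.0, 24.0, 20.0]
        centers = [1654.0, 1740.0, 2096.0]
        s = gauss_sum(centers, fwhms, amps, baseline=0.1)
        fit = fit_spectrum(s, centers)
        assert fit.converged
        for name, a, f in zip(["amide_I", "lipid_carbonyl", "azide"], amps, fwhms):
            assert fit.areas[name] == pytest.approx(a * f * GAUSS_AREA_FACTOR, rel=1e-4)

    def test_noisy_median_area_error_below_two_percent(self):
        # 1% noise, 50 seeded replicates; oracle = closed-form true areas
        rng = np.random.default_rng(42)
        true = {"amide_I": 1.0 * 28.0, "lipid_carbonyl": 0.5 * 24.0, "azide": 0.25 * 20.0}
        errors = []
        for _ in range(50):
            s = gauss_sum([1654.0, 1740.0, 2096.0], [28.0, 24.0, 20.0],
                          [1.0, 0.5, 0.25])
            noisy = Spectrum(AXIS, s.intensity + rng.normal(0, 0.01, AXIS.size),
                             power_normalized=True)
            fit = fit_spectrum(noisy, [1654.0, 1740.0, 2096.0])
            for name, af in true.items():
                errors.append(abs(fit.areas[name] - af * GAUSS_AREA_FACTOR)
                              / (af * GAUSS_AREA_FACTOR))
        assert np.median(errors) < 0.02

    def test_fitted_area_matches_dense_numerical_integration(self):
        s = gauss_sum([1654.0, 1740.0, 2096.0], [28.0, 24.0, 20.0], [1.0, 0.5, 0.25])
        fit = fit_spectrum(s, [1654.0, 1740.0, 2096.0])
        for comp in fit.components:
            x = np.linspace(comp.center - 8 * comp.fwhm, comp.center + 8 * comp.fwhm,
                            20001)
            numeric = np.trapezoid(comp.profile(x), x)
            assert numeric == pytest.approx(comp.area, rel=1e-3)

    def test_masked_gap_spike_does_not_perturb_fit(self):
        s = gauss_sum([1654.0, 2096.0], [28.0, 20.0], [1.0, 0.25])
        clean_fit = fit_spectrum(mask_silent_gap(s), [1654.0, 2096.0])
        spiked = s.intensity.copy()
        spiked[(AXIS >= 1890.0) & (AXIS <= 1910.0)] += 5.0  # inside the gap
        s2 = mask_silent_gap(Spectrum(AXIS, spiked, power_normalized=True))
        spiked_fit = fit_spectrum(s2, [1654.0, 2096.0])
        assert spiked_fit.areas["azide"] == pytest.approx(
            clean_fit.areas["azide"], rel=1e-6
        )

    def test_duplicate_seeds_deduplicated_with_warning(self):
        s = gauss_sum([1654.0], [30.0], [1.0])
        with pytest.warns(UserWarning, match="dedup"):
            fit = fit_spectrum(s, [1654.0, 1654.2])
        assert len(fit.components) == 1

    def test_amplitude_scaling_is_monotone_and_local(self):
        base = fit_spectrum(
            gauss_sum([1654.0, 1740.0], [28.0, 24.0], [1.0, 0.5]), [1654.0, 1740.0]
        )
        scaled = fit_spectrum(
            gauss_sum([1654.0, 1740.0], [28.0, 24.0], [1.0, 1.5]), [1654.0, 1740.0]
        )
        assert scaled.areas["lipid_carbonyl"] == pytest.approx(
            3.0 * base.areas["lipid_carbonyl"], rel=1e-4
        )
        assert scaled.areas["amide_I"] == pytest.approx(base.areas["amide_I"], rel=1e-4)

    def test_pseudo_voigt_area_closed_form(self):
        cfg = FitConfig(shape="pseudo_voigt", eta=0.3)
        comp = PeakComponent(1740.0, 30.0, 2.0, shape="pseudo_voigt", eta=0.3)
        gauss = 2.0 * 30.0 * GAUSS_AREA_FACTOR
        lor = 2.0 * 30.0 * math.pi / 2.0
        assert comp.area == pytest.approx(0.3 * lor + 0.7 * gauss, rel=1e-12)
        # self-fit of the pseudo-Voigt model recovers its own parameters
        y = comp.profile(AXIS)
        s = Spectrum(AXIS, y, power_normalized=True)
        fit = fit_spectrum(s, [1740.0], config=cfg)
        assert fit.areas["lipid_carbonyl"] == pytest.approx(comp.area, rel=1e-4)


class TestBandArea:
    def test_pa_only_spectrum_reports_azide_absent(self, library):
        # palmitic-acid control: no azide component anywhere in the window
        s, _ = make_spectrum({"protein": 1.0, "total_lipid": 0.5}, library=library)
        s = mask_silent_gap(s)
        fit = fit_spectrum(s, detect_peaks(s))
        assert band_area(fit, "azide") is None  # absent, not 0

    def test_zero_amplitude_component_gives_zero_area(self):
        s = gauss_sum([1654.0], [30.0], [1.0])
        fit = fit_spectrum(s, [1654.0, 2096.0])
        azide = band_area(fit, "azide")
        assert azide is not None
        assert azide == pytest.approx(0.0, abs=1e-6)

    def test_component_at_2080_assigned_to_azide_band(self):
        s = gauss_sum([1654.0, 2080.0], [28.0, 20.0], [1.0, 0.3])
        fit = fit_spectrum(s, [1654.0, 2080.0])
        assert band_area(fit, "azide") == pytest.approx(
            0.3 * 20.0 * GAUSS_AREA_FACTOR, rel=1e-4
        )

    def test_unknown_band_name_raises_key_error(self):
        s = gauss_sum([1654.0], [30.0], [1.0])
        fit = fit_spectrum(s, [1654.0])
        with pytest.raises(KeyError):
            band_area(fit, "no_such_band")

    def test_unconverged_fit_rejected(self):
        s = gauss_sum([1654.0], [30.0], [1.0])
        fit = fit_spectrum(s, [1654.0])
        fit.converged = False
        with pytest.raises(FitError):
            band_area(fit, "amide_I")


class TestFwhmLineProfile:
    SIGMA = 0.21233045007200477  # gives exactly 0.5 um FWHM

    def _profile(self, offset=0.0, reverse=False):
        x = np.linspace(-1.5, 1.5, 31)
        y = 2.0 * np.exp(-(x**2) / (2 * self.SIGMA**2)) + offset
        if reverse:
            x, y = -x[::-1], y[::-1]
        return x, y

    def test_exact_gaussian_gives_500nm(self):
        x, y = self._profile()
        assert fwhm_line_profile(x, y) == pytest.approx(0.500, abs=1e-6)

    def test_offset_invariance(self):
        x, y0 = self._profile()
        _, y10 = self._profile(offset=10.0)
        assert fwhm_line_profile(x, y10) == pytest.approx(
            fwhm_line_profile(x, y0), rel=1e-9
        )

    def test_axis_reversal_invariance(self):
        x, y = self._profile()
        xr, yr = self._profile(reverse=True)
        assert fwhm_line_profile(xr, yr) == pytest.approx(
            fwhm_line_profile(x, y), rel=1e-9
        )

    def test_too_few_samples_rejected(self):
        with pytest.raises(EstimationError):
            fwhm_line_profile(np.linspace(0, 1, 5), np.ones(5))

    def test_width_spanning_profile_rejected(self):
        x = np.linspace(-0.2, 0.2, 21)
        y = 1.0 + 0.001 * x  # essentially flat: fitted sigma unbounded
        with pytest.raises(EstimationError):
            fwhm_line_profile(x, y)
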