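"""Normalization order, idempotence and scale invariance."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as hst

from optirlipid import (
    ChannelImage,
    PowerSpectrum,
    Spectrum,
    amide_normalize,
    average_cell_spectrum,
    mask_silent_gap,
    power_normalize_image,
    power_normalize_spectrum,
)
from optirlipid.exceptions import (
    AxisMismatchError,
    CoverageError,
    FormatError,
    NormalizationError,
)

AXIS = np.arange(980.0, 2300.0 + 1e-9, 2.0)


def spec(intensity, **kw):
    kw.setdefault("power_normalized", True)
    return Spectrum(AXIS, np.asarray(intensity, dtype=float), **kw)


def cell_like(scale=1.0):
    y = scale * (
        1.0 * np.exp(-4 * np.log(2) * ((AXIS - 1654.0) / 25.0) ** 2)
        + 0.5 * np.exp(-4 * np.log(2) * ((AXIS - 1744.0) / 25.0) ** 2)
        + 0.25 * np.exp(-4 * np.log(2) * ((AXIS - 2096.0) / 25.0) ** 2)
        + 0.05
    )
    return spec(y)


class TestPowerNormalizeSpectrum:
    def test_constant_power_halves_intensity(self):
        s = spec(np.full(AXIS.size, 3.0))
        s.power_normalized = False
        p = PowerSpectrum(AXIS, np.full(AXIS.size, 2.0))
        out = power_normalize_spectrum(s, p)
        np.testing.assert_allclose(out.intensity, 1.5)
        assert out.power_normalized

    def test_power_equal_to_intensity_gives_flat_unity(self):
        y = 1.0 + np.linspace(0.0, 4.0, AXIS.size)
        s = Spectrum(AXIS, y, power_normalized=False)
        out = power_normalize_spectrum(s, PowerSpectrum(AXIS, y))
        np.testing.assert_allclose(out.intensity, 1.0)

    def test_linear_power_ramp_pointwise_division(self):
        axis = np.array([1000.0, 1500.0, 2000.0])
        s = Spectrum(axis, np.array([2.0, 6.0, 8.0]), power_normalized=False)
        p = PowerSpectrum(axis, np.array([1.0, 2.0, 4.0]))
        out = power_normalize_spectrum(s, p)
        np.testing.assert_allclose(out.intensity, [2.0, 3.0, 2.0])

    def test_power_interpolated_onto_spectrum_axis(self):
        s = Spectrum(np.array([1500.0, 1600.0]), np.array([3.0, 3.0]),
                     power_normalized=False)
        p = PowerSpectrum(np.array([1000.0, 2000.0]), np.array([1.0, 3.0]))
        out = power_normalize_spectrum(s, p)
        np.testing.assert_allclose(out.intensity, [3.0 / 2.0, 3.0 / 2.2])

    def test_incomplete_coverage_raises(self):
        s = spec(np.ones(AXIS.size))
        s.power_normalized = False
        p = PowerSpectrum(np.array([1000.0, 2000.0]), np.array([5.0, 5.0]))
        with pytest.raises(CoverageError):
            power_normalize_spectrum(s, p)

    def test_double_normalization_refused(self):
        s = cell_like()  # already power_normalized
        p = PowerSpectrum(AXIS, np.full(AXIS.size, 2.0))
        with pytest.raises(NormalizationError):
            power_normalize_spectrum(s, p)


class TestAmideNormalize:
    def test_anchor_value_becomes_one(self):
        s = cell_like(scale=4.0)
        out = amide_normalize(s)
        assert out.value_at(1654.0) == pytest.approx(1.0, abs=1e-12)
        assert out.amide_normalized

    def test_idempotent(self):
        once = amide_normalize(cell_like())
        twice = amide_normalize(once)
        np.testing.assert_array_equal(once.intensity, twice.intensity)

    def test_anchor_interpolated_between_grid_points(self):
        axis = np.array([1652.0, 1656.0])
        s = Spectrum(axis, np.array([2.0, 4.0]), power_normalized=True)
        out = amide_normalize(s)
        # anchor value is 3.0 by linear interpolation; everything divided by 3
        np.testing.assert_allclose(out.intensity, [2.0 / 3.0, 4.0 / 3.0])

    def test_nonpositive_anchor_flagged_not_divided(self):
        s = spec(np.zeros(AXIS.size))
        with pytest.raises(NormalizationError):
            amide_normalize(s)

    def test_requires_power_normalization_first(self):
        s = cell_like()
        s.power_normalized = False
        with pytest.raises(NormalizationError):
            amide_normalize(s)

    @given(scale=hst.floats(min_value=1e-3, max_value=1e3))
    @settings(max_examples=25, deadline=None)
    def test_scale_invariance(self, scale):
        base = amide_normalize(cell_like())
        scaled = amide_normalize(cell_like(scale=scale))
        np.testing.assert_allclose(scaled.intensity, base.intensity, rtol=1e-9)


class TestMaskSilentGap:
    def test_no_points_in_gap_unchanged(self):
        axis = np.array([1600.0, 1700.0, 2100.0])
        s = Spectrum(axis, np.ones(3), power_normalized=True)
        out = mask_silent_gap(s)
        assert not out.excluded.any()

    def test_default_axis_excludes_126_points(self):
        s = cell_like()
        out = mask_silent_gap(s)
        # gridpoints of 980:2:2300 inside [1780, 2030]: (2030-1780)/2 + 1
        assert int(out.excluded.sum()) == 126

    def test_data_retained_not_deleted(self):
        s = cell_like()
        out = mask_silent_gap(s)
        assert out.intensity.size == s.intensity.size
        np.testing.assert_array_equal(out.intensity, s.intensity)


class TestAverageCellSpectrum:
    def _normalized(self, scale=1.0, n=3):
        return [amide_normalize(cell_like(scale=scale)) for _ in range(n)]

    def test_three_identical_spectra_average_to_same(self):
        spectra = self._normalized()
        out = average_cell_spectrum(spectra)
        np.testing.assert_allclose(out.intensity, spectra[0].intensity)
        assert out.meta["n_averaged"] == 3

    def test_fewer_than_min_raises_with_count(self):
        with pytest.raises(FormatError, match="got 2"):
            average_cell_spectrum(self._normalized(n=2))

    def test_pointwise_arithmetic_mean(self):
        axis = np.array([1652.0, 1654.0, 1656.0])
        sp = [
            Spectrum(axis, np.array([v, 1.0, v]), power_normalized=True,
                     amide_normalized=True)
            for v in (1.0, 2.0, 3.0)
        ]
        out = average_cell_spectrum(sp)
        np.testing.assert_allclose(out.intensity, [2.0, 1.0, 2.0])

    def test_axis_mismatch_rejected(self):
        a = amide_normalize(cell_like())
        axis = np.array([1652.0, 1654.0, 1656.0])
        b = Spectrum(axis, np.array([1.0, 1.0, 1.0]), power_normalized=True,
                     amide_normalized=True)
        with pytest.raises(AxisMismatchError):
            average_cell_spectrum([a, b, a])

    def test_normalize_then_average_is_pipeline_order(self):
        # averaging raw spectra of different shape and scale then normalizing
        # differs from the pipeline's normalize-then-average; pin the order.
        def point_spectrum(scale, lipid):
            y = scale * (
                np.exp(-4 * np.log(2) * ((AXIS - 1654.0) / 25.0) ** 2)
                + lipid * np.exp(-4 * np.log(2) * ((AXIS - 1744.0) / 25.0) ** 2)
                + 0.05
            )
            return spec(y)

        raw = [point_spectrum(c, lipid) for c, lipid in
               ((1.0, 0.2), (2.0, 0.8), (4.0, 0.5))]
        norm_then_avg = average_cell_spectrum([amide_normalize(s) for s in raw])
        pooled = Spectrum(AXIS, np.mean([s.intensity for s in raw], axis=0),
                          power_normalized=True)
        avg_then_norm = amide_normalize(pooled)
        assert not np.allclose(norm_then_avg.intensity, avg_then_norm.intensity)
        # and the pipeline result has anchor exactly 1
        assert norm_then_avg.value_at(1654.0) == pytest.approx(1.0, abs=1e-12)


class TestPowerNormalizeImage:
    def test_divides_by_power_at_wavenumber(self):
        img = ChannelImage(np.full((4, 4), 10.0), 0.5, 2096.0)
        p = PowerSpectrum(AXIS, np.full(AXIS.size, 5.0))
        out = power_normalize_image(img, p)
        np.testing.assert_allclose(out.pixels, 2.0)
        assert out.power_normalized

    def test_unit_power_is_identity(self):
        img = ChannelImage(np.random.default_rng(0).random((4, 4)), 0.5, 1744.0)
        p = PowerSpectrum(AXIS, np.ones(AXIS.size))
        out = power_normalize_image(img, p)
        np.testing.assert_array_equal(out.pixels, img.pixels)

    def test_ramped_power_ratio_matches_hand_value(self):
        # power 2 mW at 1744, 4 mW at 2096; equal raw constants
        p = PowerSpectrum(np.array([1744.0, 2096.0]), np.array([2.0, 4.0]))
        a = power_normalize_image(ChannelImage(np.full((2, 2), 8.0), 0.5, 1744.0), p)
        b = power_normalize_image(ChannelImage(np.full((2, 2), 8.0), 0.5, 2096.0), p)
        assert (a.pixels[0, 0] / b.pixels[0, 0]) == pytest.approx(2.0)

    def test_wavenumber_outside_power_axis_raises(self):
        img = ChannelImage(np.ones((2, 2)), 0.5, 2200.0)
        p = PowerSpectrum(np.array([1000.0, 2100.0]), np.array([5.0, 5.0]))
        with pytest.raises(CoverageError):
            power_normalize_image(img, p)


@given(scale=hst.floats(min_value=1e-2, max_value=1e2))
@settings(max_examples=20, deadline=None)
def test_quantification_ratios_invariant_to_global_rescale(scale):
    """2096/1740 and 1740/1650 are unchanged by any positive global rescale."""
    from optirlipid import detect_peaks, fit_spectrum

    def ratios(s):
        s = mask_silent_gap(amide_normalize(s))
        fit = fit_spectrum(s, detect_peaks(s))
        return (
            fit.areas["lipid_carbonyl"] / fit.areas["amide_I"],
            fit.areas["azide"] / fit.areas["lipid_carbonyl"],
        )

    r1 = ratios(cell_like(1.0))
    r2 = ratios(cell_like(scale))
    np.testing.assert_allclose(r2, r1, rtol=1e-6)
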