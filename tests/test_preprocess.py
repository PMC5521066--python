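import numpy as np
import pytest

from amidefit import (
    DerivativeSettings,
    Spectrum,
    find_band_positions,
    second_derivative,
    subtract_flat_baseline,
)
from amidefit.bands import gaussian_profile

from conftest import gaussian


def _spec(nu, ab):
    return Spectrum(np.asarray(nu, float), np.asarray(ab, float))


class TestDerivativeSettings:
    @pytest.mark.parametrize(
        "window, order",
        [(8, 3), (5, 1), (5, 5), (3, 3)],
    )
    def test_invalid_combinations_rejected(self, window, order):
        with pytest.raises(ValueError):
            DerivativeSettings(window_points=window, poly_order=order)


class TestFlatBaseline:
    def test_constant_offset_removed(self):
        nu = np.arange(1300.0, 2051.0, 2.0)
        ab = gaussian(nu, 1650.0, 30.0, 0.5)
        shifted = _spec(nu, ab + 0.3)
        corrected = subtract_flat_baseline(shifted)
        assert np.allclose(corrected.absorbance, ab, atol=1e-12)

    def test_already_flat_region_unchanged(self):
        nu = np.arange(1300.0, 2051.0, 2.0)
        ab = gaussian(nu, 1650.0, 30.0, 0.5)  # zero in 1800–2000 to 1e-30
        corrected = subtract_flat_baseline(_spec(nu, ab))
        assert np.allclose(corrected.absorbance, ab, atol=1e-12)

    def test_peak_preserved_and_tails_zeroed(self):
        nu = np.arange(1300.0, 2051.0, 2.0)
        ab = gaussian(nu, 1650.0, 30.0, 0.5) + 0.05
        corrected = subtract_flat_baseline(_spec(nu, ab))
        i_peak = np.argmin(np.abs(nu - 1650.0))
        i_tail = np.argmin(np.abs(nu - 1900.0))
        assert corrected.absorbance[i_peak] == pytest.approx(0.5, abs=1e-9)
        assert corrected.absorbance[i_tail] == pytest.approx(0.0, abs=1e-9)

    def test_flat_window_mean_is_zero_afterwards(self):
        nu = np.arange(1300.0, 2051.0, 2.0)
        rng = np.random.default_rng(3)
        corrected = subtract_flat_baseline(_spec(nu, rng.normal(0.2, 0.01, nu.size)))
        flat = corrected.select(1800.0, 2000.0)
        assert abs(corrected.absorbance[flat].mean()) < 1e-12

    def test_missing_flat_window_raises(self):
        nu = np.arange(1300.0, 1701.0, 2.0)
        with pytest.raises(ValueError, match="flat window"):
            subtract_flat_baseline(_spec(nu, np.zeros_like(nu)))


class TestSecondDerivative:
    def test_quadratic_is_exact(self):
        nu = np.arange(1500.0, 1701.0, 2.0)
        a = 3.7e-4
        d2 = second_derivative(_spec(nu, a * nu**2))
        interior = slice(5, -5)
        assert np.allclose(d2.absorbance[interior], 2 * a, rtol=1e-8)

    def test_single_gaussian_minimum_at_center(self):
        nu = np.arange(1500.0, 1801.0, 2.0)
        d2 = second_derivative(_spec(nu, gaussian(nu, 1650.0, 30.0, 1.0)))
        assert abs(nu[np.argmin(d2.absorbance)] - 1650.0) <= 2.0

    def test_matches_closed_form_gaussian_second_derivative(self):
        nu = np.arange(1500.0, 1801.0, 2.0)
        fwhm, amp, c = 30.0, 1.0, 1650.0
        d2 = second_derivative(_spec(nu, gaussian(nu, c, fwhm, amp)))
        k = 4.0 * np.log(2.0) / fwhm**2
        u = nu - c
        exact = amp * np.exp(-k * u**2) * (4.0 * k**2 * u**2 - 2.0 * k)
        interior = slice(6, -6)
        assert np.max(np.abs(d2.absorbance[interior] - exact[interior])) < 1e-3

    def test_linearity(self):
        nu = np.arange(1500.0, 1801.0, 2.0)
        s1 = gaussian(nu, 1640.0, 25.0, 0.7)
        s2 = gaussian(nu, 1670.0, 35.0, 0.4)
        a, b = 2.5, -0.8
        d_combo = second_derivative(_spec(nu, a * s1 + b * s2)).absorbance
        d_parts = a * second_derivative(_spec(nu, s1)).absorbance + b * second_derivative(
            _spec(nu, s2)
        ).absorbance
        assert np.allclose(d_combo, d_parts, atol=1e-10)

    def test_window_larger_than_grid_raises(self):
        nu = np.arange(1600.0, 1611.0, 2.0)
        with pytest.raises(ValueError, match="window"):
            second_derivative(_spec(nu, np.zeros_like(nu)), DerivativeSettings(13, 3))

    def test_non_uniform_grid_resampled_with_warning(self):
        nu = np.sort(np.concatenate([np.arange(1500.0, 1700.0, 2.0), [1650.7]]))
        with pytest.warns(UserWarning, match="resampling"):
            d2 = second_derivative(_spec(nu, gaussian(nu, 1600.0, 30.0, 1.0)))
        assert d2.is_uniform()


class TestBandPositionDetection:
    def test_two_separated_gaussians_found(self):
        nu = np.arange(1560.0, 1741.0, 2.0)
        # equal areas: amplitude ∝ 1/fwhm
        ab = gaussian(nu, 1634.0, 32.0, 1.0 / 32.0) + gaussian(nu, 1675.0, 23.0, 1.0 / 23.0)
        d2 = second_derivative(_spec(nu, ab))
        found = find_band_positions(d2, 1700.0, 1595.0, min_depth_fraction=0.05)
        assert len(found) == 2
        assert abs(found[0].center - 1634.0) <= 2.0
        assert abs(found[1].center - 1675.0) <= 2.0

    def test_single_gaussian_found_at_center(self):
        nu = np.arange(1560.0, 1741.0, 2.0)
        d2 = second_derivative(_spec(nu, gaussian(nu, 1650.0, 28.0, 0.4)))
        found = find_band_positions(d2, 1700.0, 1595.0)
        assert len(found) == 1
        assert abs(found[0].center - 1650.0) <= 2.0

    def test_flat_spectrum_yields_nothing(self):
        nu = np.arange(1560.0, 1741.0, 2.0)
        d2 = second_derivative(_spec(nu, np.zeros_like(nu)))
        assert find_band_positions(d2, 1700.0, 1595.0) == []

    def test_region_outside_grid_raises(self):
        nu = np.arange(1560.0, 1741.0, 2.0)
        d2 = second_derivative(_spec(nu, gaussian(nu, 1650.0, 28.0, 0.4)))
        with pytest.raises(ValueError, match="outside"):
            find_band_positions(d2, 980.0, 900.0)

    def test_raising_threshold_never_adds_positions(self):
        nu = np.arange(1560.0, 1741.0, 2.0)
        ab = gaussian(nu, 1620.0, 25.0, 1.0) + gaussian(nu, 1670.0, 25.0, 0.2)
        d2 = second_derivative(_spec(nu, ab))
        counts = [
            len(find_band_positions(d2, 1700.0, 1595.0, min_depth_fraction=f))
            for f in (0.0, 0.05, 0.2, 0.5, 0.9)
        ]
        assert counts == sorted(counts, reverse=True)

    def test_free_state_component_minima_all_detected(self, free_preset):
        """The four free-state amide I components each leave a d² minimum
        within ±3 cm⁻¹ of the published positions."""
        from amidefit import make_spectrum

        s = make_spectrum(free_preset)
        d2 = second_derivative(s)
        found = find_band_positions(d2, 1700.0, 1595.0, min_depth_fraction=0.0)
        centers = np.array([b.center for b in found])
        for expected in (1606.0, 1634.0, 1655.0, 1675.0):
            assert np.min(np.abs(centers - expected)) <= 3.0
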