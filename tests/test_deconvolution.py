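import numpy as np
import pytest

from amidefit import (
    BandSet,
    GaussianBand,
    Spectrum,
    compare_compositions,
    composition,
    deconvolve,
    fit_bands,
    make_spectrum,
    model_spectrum,
)
from amidefit.bands import GAUSS_AREA_FACTOR
from amidefit.deconvolution import FitResult

from conftest import ADSORBED_COMPOSITION, FREE_COMPOSITION, gaussian


def _areas_percent(fit, lo=1595.0, hi=1700.0):
    inside = [b for b in fit.bandset if lo <= b.center <= hi]
    total = sum(b.area for b in inside)
    return {round(b.center): 100.0 * b.area / total for b in inside}


class TestFitBands:
    def test_single_gaussian_recovered_exactly(self):
        nu = np.arange(1560.0, 1741.0, 2.0)
        s = Spectrum(nu, gaussian(nu, 1650.0, 30.0, 0.5))
        fit = fit_bands(s, [1650.0])
        band = fit.bandset.bands[0]
        assert band.amplitude == pytest.approx(0.5, abs=1e-6)
        assert band.fwhm == pytest.approx(30.0, abs=1e-6)
        assert fit.chi_square < 1e-12

    def test_free_state_areas_at_known_positions(self, free_preset):
        s = make_spectrum(free_preset)
        fit = fit_bands(s, [1606.0, 1634.0, 1655.0, 1675.0])
        areas = _areas_percent(fit)
        for center, expected in [(1606, 7), (1634, 58), (1655, 25), (1675, 10)]:
            assert areas[center] == pytest.approx(expected, abs=1.0)

    def test_free_state_areas_with_noise(self, noisy_free_spectrum):
        fit = fit_bands(noisy_free_spectrum, [1606.0, 1634.0, 1655.0, 1675.0])
        areas = _areas_percent(fit)
        for center, expected in [(1606, 7), (1634, 58), (1655, 25), (1675, 10)]:
            assert areas[center] == pytest.approx(expected, abs=3.0)

    def test_positions_never_move(self, free_preset):
        s = make_spectrum(free_preset)
        given = [1608.0, 1632.0, 1657.0]  # deliberately off the true centers
        fit = fit_bands(s, given)
        assert np.allclose(sorted(b.center for b in fit.bandset), sorted(given), atol=1e-9)

    def test_amplitudes_non_negative(self):
        nu = np.arange(1560.0, 1741.0, 2.0)
        # a dip the model cannot follow with positive bands
        s = Spectrum(nu, gaussian(nu, 1650.0, 30.0, 0.5) - gaussian(nu, 1620.0, 20.0, 0.2))
        fit = fit_bands(s, [1620.0, 1650.0])
        assert all(b.amplitude >= 0 for b in fit.bandset)

    def test_overparameterized_fit_rejected(self):
        nu = np.arange(1640.0, 1661.0, 2.0)
        s = Spectrum(nu, gaussian(nu, 1650.0, 30.0, 0.5))
        with pytest.raises(ValueError, match="resolved"):
            fit_bands(s, list(np.linspace(1642.0, 1658.0, 5)), region_hi=1660, region_lo=1640)

    def test_positions_outside_region_rejected(self):
        nu = np.arange(1560.0, 1741.0, 2.0)
        s = Spectrum(nu, gaussian(nu, 1650.0, 30.0, 0.5))
        with pytest.raises(ValueError, match="inside"):
            fit_bands(s, [1450.0])

    def test_chi_square_never_worse_than_initial_guess(self, free_preset):
        """Monotone residual: the optimiser at least matches its start."""
        s = make_spectrum(free_preset)
        mask = s.select(1480.0, 1700.0)
        grid, data = s.wavenumbers[mask], s.absorbance[mask]
        positions = [1610.0, 1640.0, 1660.0]
        init_fwhm = 25.0
        a0 = np.clip(np.interp(positions, grid, data), 0.0, None)
        model0 = sum(
            gaussian(grid, c, init_fwhm, a) for c, a in zip(positions, a0)
        )
        chi_init = float(np.sum((model0 - data) ** 2))
        fit = fit_bands(s, positions, init_fwhm=init_fwhm)
        assert fit.chi_square <= chi_init


class TestGridSearchOracle:
    """fit_bands against an exhaustive amplitude grid search on tiny problems."""

    @pytest.mark.parametrize(
        "bands",
        [
            [(1650.0, 30.0, 0.5)],
            [(1630.0, 28.0, 0.6), (1668.0, 24.0, 0.3)],
        ],
    )
    def test_amplitude_fit_matches_grid_search(self, bands):
        nu = np.arange(1600.0, 1699.0, 2.0)  # 50 points
        data = sum(gaussian(nu, c, f, a) for c, f, a in bands)
        s = Spectrum(nu, data)
        centers = [c for c, _, _ in bands]
        fwhms = [f for _, f, _ in bands]
        fit = fit_bands(s, centers, init_fwhm=fwhms, fit_widths=False,
                        region_hi=1700.0, region_lo=1595.0)

        profiles = np.array([gaussian(nu, c, f, 1.0) for c, f, _ in bands])
        amp_grid = np.arange(0.0, 2.0 * data.max() + 1e-9, 1e-3)
        # χ²(a) = yᵀy − 2 aᵀb + aᵀM a evaluated on the full grid
        b = profiles @ data
        m = profiles @ profiles.T
        yy = float(data @ data)
        if len(bands) == 1:
            chis = yy - 2 * amp_grid * b[0] + amp_grid**2 * m[0, 0]
            chi_oracle = float(np.min(chis))
        else:
            a1 = amp_grid[:, None]
            a2 = amp_grid[None, :]
            chis = (
                yy
                - 2 * (a1 * b[0] + a2 * b[1])
                + a1**2 * m[0, 0]
                + 2 * a1 * a2 * m[0, 1]
                + a2**2 * m[1, 1]
            )
            chi_oracle = float(np.min(chis))
        assert abs(fit.chi_square - chi_oracle) < 1e-4


class TestParameterRecovery:
    @staticmethod
    def _random_bandset(seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(3, 7))
        while True:
            centers = np.sort(rng.uniform(1600.0, 1695.0, n))
            if np.diff(centers).min() >= 15.0:
                break
        fwhms = rng.uniform(20.0, 35.0, n)
        fractions = rng.dirichlet(np.full(n, 2.0))
        bands = [
            GaussianBand(c, f, frac / (f * GAUSS_AREA_FACTOR))
            for c, f, frac in zip(centers, fwhms, fractions)
        ]
        return BandSet(bands).scaled_to_area(10.0), 100.0 * fractions

    @pytest.mark.parametrize("seed", range(10))
    def test_area_fractions_recovered_within_two_points(self, seed):
        """Well-separated random band sets, noise 0.5 % of peak: fitting
        amplitudes at the known positions and widths recovers every area
        fraction to ≤ 2 percentage points."""
        bandset, truth = self._random_bandset(seed)
        grid = np.arange(1560.0, 1741.0, 2.0)
        clean = model_spectrum(bandset, grid)
        noise = np.random.default_rng(seed + 1000).normal(
            0.0, 0.005 * float(clean.absorbance.max()), grid.size
        )
        s = Spectrum(grid, clean.absorbance + noise)
        fit = fit_bands(
            s, bandset.centers, init_fwhm=bandset.fwhms, fit_widths=False,
            region_hi=1700.0, region_lo=1595.0,
        )
        areas = np.array([b.area for b in fit.bandset])
        recovered = 100.0 * areas / areas.sum()
        assert np.max(np.abs(recovered - truth)) <= 2.0

    @pytest.mark.parametrize("seed", range(5))
    def test_width_fitting_stays_close(self, seed):
        """With widths also free the overlap makes fractions less
        identifiable; they still stay within 5 points."""
        bandset, truth = self._random_bandset(seed)
        grid = np.arange(1560.0, 1741.0, 2.0)
        clean = model_spectrum(bandset, grid)
        noise = np.random.default_rng(seed + 1000).normal(
            0.0, 0.005 * float(clean.absorbance.max()), grid.size
        )
        s = Spectrum(grid, clean.absorbance + noise)
        fit = fit_bands(
            s, bandset.centers, init_fwhm=bandset.fwhms, fit_widths=True,
            region_hi=1700.0, region_lo=1595.0,
        )
        areas = np.array([b.area for b in fit.bandset])
        recovered = 100.0 * areas / areas.sum()
        assert np.max(np.abs(recovered - truth)) <= 5.0


class TestDeconvolve:
    def test_noiseless_free_spectrum_exact(self, free_spectrum):
        fit = deconvolve(free_spectrum)
        comp = composition(fit)
        for cls, expected in FREE_COMPOSITION.items():
            assert comp[cls] == pytest.approx(expected, abs=0.1)

    def test_noiseless_adsorbed_spectrum_exact(self, adsorbed_spectrum):
        """The 1641 cm⁻¹ random component leaves no separate derivative
        minimum, yet residual-driven band addition recovers it."""
        fit = deconvolve(adsorbed_spectrum)
        comp = composition(fit)
        for cls, expected in ADSORBED_COMPOSITION.items():
            assert comp[cls] == pytest.approx(expected, abs=0.1)

    def test_zero_spectrum_rejected(self):
        nu = np.arange(1450.0, 1751.0, 2.0)
        with pytest.raises(ValueError, match="zero"):
            deconvolve(Spectrum(nu, np.zeros_like(nu)))


class TestComposition:
    def _identity_fit(self, bandset):
        grid = np.arange(1560.0, 1741.0, 2.0)
        return FitResult(
            bandset=bandset,
            chi_square=0.0,
            n_iterations=0,
            converged=True,
            residuals=Spectrum(grid, np.zeros_like(grid)),
        )

    def test_free_preset_composition(self, free_preset):
        comp = composition(self._identity_fit(free_preset))
        assert comp.percent_area == pytest.approx(FREE_COMPOSITION)

    def test_adsorbed_preset_composition(self, adsorbed_preset):
        comp = composition(self._identity_fit(adsorbed_preset))
        assert comp.percent_area == pytest.approx(ADSORBED_COMPOSITION)

    def test_single_band_is_everything(self):
        bs = BandSet([GaussianBand(1650.0, 25.0, 0.4, "alpha-helix")])
        comp = composition(self._identity_fit(bs))
        assert comp["alpha-helix"] == pytest.approx(100.0)

    def test_amide2_band_excluded(self, free_preset):
        with_amide2 = BandSet(
            list(free_preset.bands) + [GaussianBand(1545.0, 40.0, 0.2, "amide-II")]
        )
        comp = composition(self._identity_fit(with_amide2))
        assert comp["amide-II"] == 0.0
        assert sum(comp.percent_area.values()) == pytest.approx(100.0, abs=0.1)

    def test_percentages_sum_to_hundred(self, adsorbed_preset):
        comp = composition(self._identity_fit(adsorbed_preset))
        assert sum(comp.percent_area.values()) == pytest.approx(100.0, abs=0.1)


class TestCompareCompositions:
    def test_identical_compositions_no_change(self, free_preset):
        grid = np.arange(1560.0, 1741.0, 2.0)
        fit = FitResult(free_preset, 0.0, 0, True, Spectrum(grid, np.zeros_like(grid)))
        comp = composition(fit)
        change = compare_compositions(comp, comp)
        assert all(abs(d) < 1e-12 for d in change.delta_points.values())

    def test_beta_sheet_reduction_arithmetic(self):
        from amidefit.deconvolution import StructureComposition

        ref = StructureComposition({"beta-sheet": 58.0, "alpha-helix": 42.0})
        treated = StructureComposition({"beta-sheet": 42.0, "alpha-helix": 58.0})
        change = compare_compositions(ref, treated)
        assert change.delta_points["beta-sheet"] == pytest.approx(-16.0)
        assert change.relative_change["beta-sheet"] == pytest.approx(-16.0 / 58.0)

    def test_emerging_class_has_undefined_relative_change(self):
        from amidefit.deconvolution import StructureComposition

        ref = StructureComposition({"beta-sheet": 100.0})
        treated = StructureComposition({"beta-sheet": 83.0, "random": 17.0})
        change = compare_compositions(ref, treated)
        assert change.delta_points["random"] == pytest.approx(17.0)
        assert change.relative_change["random"] is None
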