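"""Band-resolution pipeline: second derivative, FSD, constrained fitting."""

import numpy as np
import pytest

from helixorder import spectra as sp
from helixorder import synthetic as syn
from helixorder.deconvolution import (
    AmideBandModel,
    BandComponent,
    FitConstraints,
    assign_center,
    estimate_fwhm,
    fit_bands,
    find_band_seeds,
    fourier_self_deconvolution,
    second_derivative,
    structure_fractions,
)
from helixorder.exceptions import ParameterError, SeedingError
from helixorder.spectra import Spectrum


def _fwhm_of(spectrum):
    ab, nu = spectrum.absorbance, spectrum.wavenumbers
    above = nu[ab > ab.max() / 2]
    return above.max() - above.min()


class TestSecondDerivative:
    def test_minimum_at_lorentzian_center(self):
        s, _ = syn.gen_spectrum([BandComponent(1653.0, 20.0, 1.0)], grid=(1580, 1780, 0.5))
        d2 = second_derivative(s)
        assert abs(d2.wavenumbers[np.argmin(d2.absorbance)] - 1653.0) <= 0.5

    def test_two_band_minima_within_one_wavenumber(self):
        s, _ = syn.gen_spectrum(
            [BandComponent(1653.0, 20.0, 1.0), BandComponent(1623.0, 20.0, 1.0)],
            grid=(1580, 1780, 0.25),
        )
        d2 = second_derivative(s)
        from scipy.signal import find_peaks

        idx, _ = find_peaks(-d2.absorbance, prominence=0.1 * np.ptp(d2.absorbance))
        found = sorted(d2.wavenumbers[idx])
        assert len(found) == 2
        assert abs(found[0] - 1623.0) < 1.0 and abs(found[1] - 1653.0) < 1.0

    def test_constant_spectrum_gives_zero(self):
        nu = np.linspace(1580, 1780, 101)
        d2 = second_derivative(Spectrum(nu, np.full_like(nu, 0.4)))
        np.testing.assert_allclose(d2.absorbance, 0.0, atol=1e-12)

    @pytest.mark.parametrize("window", [8, 501])
    def test_bad_window_raises(self, window):
        nu = np.linspace(1580, 1780, 101)
        with pytest.raises(ParameterError):
            second_derivative(Spectrum(nu, nu * 0.0), smooth_window=window)


class TestFSD:
    def test_narrows_lorentzian_by_factor_two(self, lorentzian_spectrum):
        s, _ = lorentzian_spectrum
        out = fourier_self_deconvolution(s, band_fwhm=20.0, narrowing_factor=2.0)
        assert _fwhm_of(out) == pytest.approx(10.0, abs=0.5)

    def test_identity_at_factor_one(self, lorentzian_spectrum):
        s, _ = lorentzian_spectrum
        out = fourier_self_deconvolution(s, narrowing_factor=1.0)
        np.testing.assert_allclose(out.absorbance, s.absorbance, atol=1e-6)

    def test_area_conserved_within_two_percent(self, lorentzian_spectrum):
        s, _ = lorentzian_spectrum
        out = fourier_self_deconvolution(s, 20.0, 2.0)
        a0 = np.trapezoid(s.absorbance, s.wavenumbers)
        a1 = np.trapezoid(out.absorbance, out.wavenumbers)
        assert a1 == pytest.approx(a0, rel=0.02)

    def test_resolves_bands_fourteen_apart(self):
        s, _ = syn.gen_spectrum(
            [BandComponent(1646.0, 20.0, 1.0), BandComponent(1660.0, 20.0, 1.0)],
            grid=(1580, 1780, 0.25),
        )
        out = fourier_self_deconvolution(s, 20.0, 2.0)
        from scipy.signal import find_peaks

        idx, _ = find_peaks(out.absorbance, prominence=0.05 * np.ptp(out.absorbance))
        centers = out.wavenumbers[idx]
        near = [c for c in centers if 1640 < c < 1666]
        assert len(near) == 2

    def test_nonuniform_grid_rejected(self):
        nu = np.concatenate([np.linspace(1580, 1700, 100), np.linspace(1701, 1780, 200)])
        with pytest.raises(ParameterError, match="uniform"):
            fourier_self_deconvolution(Spectrum(nu, np.zeros_like(nu)))

    def test_aggressive_narrowing_sets_noise_flag(self, lorentzian_spectrum):
        s, _ = lorentzian_spectrum
        out = fourier_self_deconvolution(s, 20.0, 6.0, max_noise_amplification=1e3)
        assert out.meta.get("fsd_noise_warning") is True


class TestFitBands:
    def test_recovers_three_planted_lorentzians(self):
        truth = [
            BandComponent(1620.0, 15.0, 0.3),
            BandComponent(1655.0, 25.0, 0.6),
            BandComponent(1700.0, 18.0, 0.2),
        ]
        s, _ = syn.gen_spectrum(truth, grid=(1580, 1780, 0.5))
        work = sp.subtract_baseline(s)
        result = fit_bands(work, truth)
        for got, want in zip(result.components, truth):
            assert got.center == pytest.approx(want.center, abs=0.1)
            assert got.area == pytest.approx(want.area, rel=0.01)

    def test_close_seeds_rejected(self):
        nu = np.linspace(1580, 1780, 101)
        s = Spectrum(nu, np.exp(-((nu - 1650) ** 2) / 500))
        seeds = [BandComponent(1650.0, 20.0, 1.0), BandComponent(1652.0, 20.0, 1.0)]
        with pytest.raises(SeedingError, match="closer"):
            fit_bands(s, seeds)

    def test_seed_outside_window_rejected(self):
        nu = np.linspace(1580, 1780, 101)
        s = Spectrum(nu, np.exp(-((nu - 1650) ** 2) / 500))
        with pytest.raises(SeedingError, match="outside"):
            fit_bands(s, [BandComponent(1800.0, 20.0, 1.0)])

    def test_shape_mismatch_leaves_residual(self):
        # pure Gaussian data fitted with a single Lorentzian converges but
        # cannot reach zero residual
        gauss = [BandComponent(1660.0, 25.0, 1.0, shape="gaussian")]
        s, _ = syn.gen_spectrum(gauss, grid=(1580, 1780, 0.5))
        seed = [BandComponent(1660.0, 25.0, 1.0, shape="lorentzian")]
        result = fit_bands(sp.subtract_baseline(s), seed)
        assert result.residual_rms > 1e-4

    def test_noise_shifts_centers_less_than_one_wavenumber(self):
        truth = syn.solution_phase_bands()
        peak_height = truth[2].height
        shifts = []
        for rep in range(20):
            s, _ = syn.gen_spectrum(
                truth, noise_sd=0.01 * peak_height, grid=(1580, 1780, 0.5), seed=100 + rep
            )
            r = AmideBandModel(s, seeds=truth).fit()
            shifts.append(abs(r.component("alpha_helix").center - 1653.0))
        assert np.mean(shifts) < 1.0


class TestStructureFractions:
    def test_equal_areas_split_half_half(self):
        comps = [
            BandComponent(1653.0, 30.0, 1.0, assignment="alpha_helix"),
            BandComponent(1670.0, 20.0, 1.0, assignment="turn"),
        ]
        f = structure_fractions(comps)
        assert f["alpha_helix"] == pytest.approx(0.5)
        assert f["turn"] == pytest.approx(0.5)

    def test_planted_five_band_alpha_fraction(self, solution_spectrum):
        s, _ = solution_spectrum
        r = AmideBandModel(s).fit()
        assert r.structure_fractions["alpha_helix"] == pytest.approx(0.50, abs=0.02)

    def test_single_class_gives_unity(self):
        comps = [BandComponent(1650.0, 30.0, 2.0, assignment="alpha_helix")]
        assert structure_fractions(comps)["alpha_helix"] == pytest.approx(1.0)

    def test_invariant_under_rescaling(self, solution_spectrum):
        s, _ = solution_spectrum
        r1 = AmideBandModel(s).fit()
        r2 = AmideBandModel(s.with_absorbance(s.absorbance * 7.3)).fit()
        for cls, frac in r1.structure_fractions.items():
            assert r2.structure_fractions[cls] == pytest.approx(frac, abs=1e-6)

    def test_fractions_sum_to_one(self, solution_spectrum):
        s, _ = solution_spectrum
        r = AmideBandModel(s).fit()
        assert sum(r.structure_fractions.values()) == pytest.approx(1.0, abs=1e-9)


class TestEstimateFwhm:
    def test_solution_phase_width(self, solution_spectrum):
        s, _ = solution_spectrum
        r = AmideBandModel(s).fit()
        assert estimate_fwhm(r, "alpha_helix") == pytest.approx(34.0, abs=0.2)

    def test_membrane_phase_width(self):
        s, _ = syn.gen_spectrum(syn.membrane_phase_bands(), grid=(1580, 1780, 0.5))
        r = AmideBandModel(s).fit()
        assert r.component("alpha_helix").center == pytest.approx(1650.0, abs=1.0)
        assert estimate_fwhm(r, "alpha_helix") == pytest.approx(30.6, abs=0.2)

    def test_absent_class_raises_lookup(self, solution_spectrum):
        s, _ = solution_spectrum
        r = AmideBandModel(s).fit()
        with pytest.raises(LookupError):
            estimate_fwhm(r, "aggregated_beta")

    def test_multiplicity_warns_and_weights(self):
        comps = [
            BandComponent(1650.0, 30.0, 3.0, assignment="alpha_helix"),
            BandComponent(1655.0, 40.0, 1.0, assignment="alpha_helix"),
        ]
        from helixorder.deconvolution import DeconvolutionResult

        r = DeconvolutionResult(comps, 0.0, structure_fractions(comps))
        with pytest.warns(UserWarning, match="area-weighted"):
            val = estimate_fwhm(r, "alpha_helix")
        assert val == pytest.approx((3 * 30 + 1 * 40) / 4)


class TestSeeding:
    def test_aggregation_band_detected_and_assigned(self):
        s, _ = syn.gen_spectrum(
            syn.membrane_phase_bands(aggregated=True), grid=(1580, 1780, 0.5)
        )
        seeds = find_band_seeds(s)
        assert any(abs(c.center - 1614.0) < 4 for c in seeds)
        assert assign_center(1614.0) == "aggregated_beta"

    def test_merge_keeps_deeper_minimum(self):
        # two candidates within 8 cm^-1 collapse to one seed
        s, _ = syn.gen_spectrum(
            [BandComponent(1650.0, 20.0, 1.0), BandComponent(1655.0, 20.0, 0.2)],
            grid=(1580, 1780, 0.25),
        )
        seeds = find_band_seeds(s, merge_distance=8.0)
        near = [c for c in seeds if 1640 < c.center < 1665]
        assert len(near) == 1
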