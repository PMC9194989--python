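"""Spectrum model, beam quality descriptors, dose-to-tissue conversion."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from tldose.coefficients import TissueCoefficientTable
from tldose.spectrum import (
    SpectrumModel,
    check_spectrum_match,
    effective_energy,
    generate_spectrum,
    half_value_layer,
    load_spectrum_csv,
    mean_energy,
    save_spectrum_csv,
    tissue_conversion_factor,
)


def monoenergetic(energy: float) -> SpectrumModel:
    return SpectrumModel([energy - 1.0, energy, energy + 1.0], [0.0, 1.0, 0.0])


class TestGenerateSpectrum:
    def test_endpoint_fluence_is_zero(self, coeffs):
        spec = generate_spectrum(80.0, [], coeffs=coeffs)
        assert spec.energies[-1] < 80.0
        # bremsstrahlung intensity vanishes toward the tube potential
        assert spec.fluence[-1] < spec.fluence[len(spec.fluence) // 2]

    def test_filtration_attenuates_every_bin(self, coeffs):
        bare = generate_spectrum(80.0, [], coeffs=coeffs)
        filt = generate_spectrum(80.0, [("Al", 2.0)], coeffs=coeffs)
        # compare unnormalised shapes: refilter the bare spectrum by hand
        mu = coeffs.attenuation["Al"].mu_linear(bare.energies)
        attenuated = bare.fluence * np.exp(-mu * 2.0)
        assert np.all(attenuated < bare.fluence)
        np.testing.assert_allclose(
            filt.fluence, attenuated / attenuated.sum(), rtol=1e-12
        )

    def test_beam_hardening_raises_mean_energy(self, coeffs):
        light = generate_spectrum(80.0, [("Al", 2.0)], coeffs=coeffs)
        heavy = generate_spectrum(80.0, [("Al", 6.0)], coeffs=coeffs)
        assert mean_energy(heavy) > mean_energy(light)

    def test_unknown_filter_material_errors(self, coeffs):
        with pytest.raises(Exception, match="unknown filter"):
            generate_spectrum(80.0, [("Unobtainium", 1.0)], coeffs=coeffs)

    def test_kvp_range_enforced(self, coeffs):
        with pytest.raises(ValueError):
            generate_spectrum(30.0, [], coeffs=coeffs)


class TestBeamQuality:
    def test_monoenergetic_hvl_closed_form(self, coeffs):
        spec = monoenergetic(50.0)
        mu = coeffs.attenuation["Al"].mu_linear(50.0)  # 1/mm
        assert half_value_layer(spec, "Al", coeffs) == pytest.approx(
            np.log(2) / mu, abs=1e-3
        )

    def test_hvl_at_least_softest_bin(self, coeffs):
        spec = generate_spectrum(80.0, [("Al", 2.0)], coeffs=coeffs)
        hvl = half_value_layer(spec, "Al", coeffs)
        mu_low = coeffs.attenuation["Al"].mu_linear(float(spec.energies[0]))
        assert hvl >= np.log(2) / mu_low

    def test_monoenergetic_effective_energy_fixed_point(self, coeffs):
        assert effective_energy(monoenergetic(50.0), coeffs=coeffs) == pytest.approx(
            50.0, rel=1e-3
        )

    def test_effective_energy_increases_with_filtration(self, coeffs):
        light = generate_spectrum(80.0, [("Al", 2.0)], coeffs=coeffs)
        heavy = generate_spectrum(80.0, [("Al", 6.0)], coeffs=coeffs)
        assert effective_energy(heavy, coeffs=coeffs) > effective_energy(
            light, coeffs=coeffs
        )

    def test_equal_hvl_means_equal_effective_energy(self, coeffs):
        a = monoenergetic(40.0)
        b = SpectrumModel([39.0, 40.0, 41.0], [0.0, 2.5, 0.0])  # same line, rescaled
        assert effective_energy(a, coeffs=coeffs) == pytest.approx(
            effective_energy(b, coeffs=coeffs), rel=1e-9
        )


class TestSpectrumMatch:
    def test_identical_spectra_pass(self, coeffs, spectrum_80kvp):
        report = check_spectrum_match(spectrum_80kvp, spectrum_80kvp, coeffs=coeffs)
        assert report.passed and report.difference_kev == 0.0

    def test_boundary_is_inclusive(self):
        from tldose.spectrum import SpectrumMatchReport

        report = SpectrumMatchReport(45.0, 40.0, 5.0, abs(45.0 - 40.0) <= 5.0)
        assert report.passed

    def test_seven_kev_difference_fails(self, coeffs):
        report = check_spectrum_match(
            monoenergetic(47.0), monoenergetic(40.0), tol=5.0, coeffs=coeffs
        )
        assert not report.passed
        assert report.difference_kev == pytest.approx(7.0, abs=0.2)


class TestTissueConversion:
    def test_water_against_itself_is_unity(self, coeffs, spectrum_80kvp):
        water = coeffs.tissues["water"]
        assert tissue_conversion_factor(spectrum_80kvp, water, water) == 1.0

    def test_monoenergetic_reduces_to_pointwise_ratio(self, coeffs):
        spec = monoenergetic(50.0)
        tissue = coeffs.tissues["soft_tissue"]
        water = coeffs.tissues["water"]
        assert tissue_conversion_factor(spec, tissue, water) == pytest.approx(
            tissue(50.0) / water(50.0), rel=1e-12
        )

    def test_two_bin_hand_computed_ratio(self):
        spec = SpectrumModel([20.0, 40.0], [3.0, 1.0])
        tissue = TissueCoefficientTable("t", [20.0, 40.0], [0.5, 0.07])
        water = TissueCoefficientTable("water", [20.0, 40.0], [0.55, 0.069])
        # energy-fluence weights: 3*20=60 and 1*40=40
        expected = (60 * 0.5 + 40 * 0.07) / (60 * 0.55 + 40 * 0.069)
        assert tissue_conversion_factor(spec, tissue, water) == pytest.approx(
            expected, rel=1e-12
        )

    @settings(derandomize=True, max_examples=25)
    @given(scale=st.floats(min_value=1e-3, max_value=1e3))
    def test_invariant_to_fluence_rescaling(self, coeffs, spectrum_80kvp, scale):
        tissue = coeffs.tissues["soft_tissue"]
        water = coeffs.tissues["water"]
        scaled = SpectrumModel(spectrum_80kvp.energies, spectrum_80kvp.fluence * scale)
        assert tissue_conversion_factor(scaled, tissue, water) == pytest.approx(
            tissue_conversion_factor(spectrum_80kvp, tissue, water), rel=1e-12
        )

    def test_constant_tables_give_constant_ratio(self, spectrum_80kvp):
        tissue = TissueCoefficientTable("t", [10.0, 150.0], [1.2, 1.2])
        water = TissueCoefficientTable("water", [10.0, 150.0], [0.8, 0.8])
        assert tissue_conversion_factor(spectrum_80kvp, tissue, water) == pytest.approx(
            1.5, rel=1e-12
        )

    def test_binned_sum_matches_trapezoid_oracle(self, coeffs):
        """At <=1 keV bins the discrete sum tracks continuous integration."""
        spec = generate_spectrum(80.0, [("Al", 5.0)], bin_width=1.0, coeffs=coeffs)
        tissue = coeffs.tissues["soft_tissue"]
        water = coeffs.tissues["water"]
        binned = tissue_conversion_factor(spec, tissue, water)
        e = spec.energies
        w = spec.fluence * e
        oracle = np.trapezoid(w * tissue(e), e) / np.trapezoid(w * water(e), e)
        assert binned == pytest.approx(oracle, rel=0.005)


class TestSpectrumIo:
    def test_csv_round_trip(self, tmp_path, spectrum_80kvp):
        path = tmp_path / "spec.csv"
        save_spectrum_csv(spectrum_80kvp, path)
        loaded = load_spectrum_csv(path)
        np.testing.assert_allclose(loaded.energies, spectrum_80kvp.energies)
        np.testing.assert_allclose(loaded.fluence, spectrum_80kvp.fluence)

    def test_negative_fluence_rejected(self):
        with pytest.raises(ValueError):
            SpectrumModel([10.0, 20.0], [1.0, -0.1])

    def test_fluence_above_kvp_rejected(self):
        with pytest.raises(ValueError):
            SpectrumModel([10.0, 90.0], [1.0, 1.0], kvp=80.0)
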