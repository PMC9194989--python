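"""Marrow dose model: site doses, mass weighting, cellularity mixing."""

import numpy as np
import pytest

from tldose.coefficients import (
    CoefficientError,
    SkeletalSite,
    TissueCoefficientTable,
)
from tldose.skeletal_dosimetry import (
    marrow_dose_results,
    shallow_marrow_conversion,
    site_marrow_dose,
    total_marrow_dose,
)
from tldose.spectrum import SpectrumModel


def make_site(name, rbm=10.0, shallow=5.0, cellularity=1.0, d_rbm=0.0, d_sh=0.0):
    return SkeletalSite(name, rbm, shallow, cellularity, d_rbm, d_sh)


class TestSiteMarrowDose:
    def test_no_enhancement_limit(self):
        assert site_marrow_dose(2.0, 1.0, 0.0) == pytest.approx(2.0)

    def test_direct_arithmetic(self):
        assert site_marrow_dose(2.0, 1.0, 0.5) == pytest.approx(3.0)

    def test_conversion_and_enhancement_compound(self):
        assert site_marrow_dose(1.0, 1.05, 0.1) == pytest.approx(1.155)

    def test_negative_def_rejected(self):
        with pytest.raises(ValueError):
            site_marrow_dose(1.0, 1.0, -0.1)


class TestTotalMarrowDose:
    def test_uniform_site_dose_is_preserved(self):
        sites = {n: make_site(n, rbm=m) for n, m in [("a", 1.0), ("b", 3.0), ("c", 6.0)]}
        dose, sd = total_marrow_dose({n: (2.0, 0.0) for n in sites}, sites, "rbm")
        assert dose == pytest.approx(2.0)

    def test_two_site_mass_weighting(self):
        sites = {"a": make_site("a", rbm=1.0), "b": make_site("b", rbm=3.0)}
        dose, _ = total_marrow_dose({"a": (4.0, 0.0), "b": (0.0, 0.0)}, sites, "rbm")
        assert dose == pytest.approx(1.0)

    def test_partial_skeleton_requires_flag(self):
        sites = {"a": make_site("a", rbm=1.0), "b": make_site("b", rbm=3.0)}
        with pytest.raises(CoefficientError, match="renormalize_partial"):
            total_marrow_dose({"a": (4.0, 0.0)}, sites, "rbm")
        dose, _ = total_marrow_dose(
            {"a": (4.0, 0.0)}, sites, "rbm", renormalize_partial=True
        )
        assert dose == pytest.approx(4.0)

    def test_five_site_brute_force_oracle(self):
        """Full model vs an independent term-by-term evaluation."""
        masses = {"legs": 30.0, "pelvis": 22.0, "rib": 12.0, "spine": 42.0, "skull": 44.0}
        defs = {"legs": 0.14, "pelvis": 0.17, "rib": 0.21, "spine": 0.19, "skull": 0.25}
        water_doses = {"legs": 18.0, "pelvis": 19.5, "rib": 21.0, "spine": 17.0, "skull": 15.5}
        conv = 0.97
        sites = {n: make_site(n, rbm=m, d_rbm=defs[n]) for n, m in masses.items()}

        site_doses = {
            n: (site_marrow_dose(water_doses[n], conv, defs[n]), 0.0) for n in sites
        }
        dose, _ = total_marrow_dose(site_doses, sites, "rbm")

        m_total = sum(masses.values())
        oracle = sum(
            water_doses[n] * conv * (1.0 + defs[n]) * masses[n] / m_total
            for n in masses
        )
        assert dose == pytest.approx(oracle, rel=1e-12)

    def test_monotone_in_def_and_site_dose(self):
        sites = {"a": make_site("a", rbm=1.0, d_rbm=0.1), "b": make_site("b", rbm=1.0)}
        base = {"a": (site_marrow_dose(2.0, 1.0, 0.1), 0.0), "b": (2.0, 0.0)}
        more_def = {"a": (site_marrow_dose(2.0, 1.0, 0.3), 0.0), "b": (2.0, 0.0)}
        more_dose = {"a": (site_marrow_dose(2.5, 1.0, 0.1), 0.0), "b": (2.0, 0.0)}
        d0, _ = total_marrow_dose(base, sites, "rbm")
        assert total_marrow_dose(more_def, sites, "rbm")[0] > d0
        assert total_marrow_dose(more_dose, sites, "rbm")[0] > d0

    def test_compartment_inputs_fully_determine_output(self):
        """Swapping (mass, DEF, conversion) input sets swaps the outputs."""
        rbm_masses = {"a": 1.0, "b": 3.0}
        sh_masses = {"a": 2.0, "b": 2.0}
        sites = {
            n: SkeletalSite(n, rbm_masses[n], sh_masses[n], 1.0, 0.1, 0.4)
            for n in ("a", "b")
        }
        water = {"a": (2.0, 0.0), "b": (3.0, 0.0)}
        rbm_in = {n: (site_marrow_dose(d, 1.0, sites[n].def_rbm), s) for n, (d, s) in water.items()}
        sh_in = {n: (site_marrow_dose(d, 1.0, sites[n].def_shallow), s) for n, (d, s) in water.items()}
        d_rbm, _ = total_marrow_dose(rbm_in, sites, "rbm")
        d_sh, _ = total_marrow_dose(sh_in, sites, "shallow")
        # recompute with the roles swapped: shallow inputs under rbm masses
        swapped = {
            n: SkeletalSite(n, sh_masses[n], rbm_masses[n], 1.0, 0.4, 0.1)
            for n in ("a", "b")
        }
        d_swap, _ = total_marrow_dose(sh_in, swapped, "rbm")
        sh_under_sh = total_marrow_dose(sh_in, sites, "shallow")[0]
        assert d_swap == pytest.approx(sh_under_sh)
        assert d_rbm != pytest.approx(d_sh)


class TestShallowMarrowConversion:
    flat = SpectrumModel([20.0, 40.0, 60.0], [1.0, 1.0, 1.0])

    @staticmethod
    def constant_coeffs(red=1.2, yellow=0.8, water=1.0):
        """Minimal coefficient-set stand-in with constant tables."""

        class FakeSet:
            tissues = {
                "red_marrow": TissueCoefficientTable("red_marrow", [10.0, 150.0], [red, red]),
                "yellow_marrow": TissueCoefficientTable(
                    "yellow_marrow", [10.0, 150.0], [yellow, yellow]
                ),
                "water": TissueCoefficientTable("water", [10.0, 150.0], [water, water]),
            }

        return FakeSet()

    def test_full_cellularity_is_pure_red(self, coeffs, spectrum_80kvp):
        from tldose.spectrum import tissue_conversion_factor

        site = make_site("spine", cellularity=1.0)
        conv = shallow_marrow_conversion(site, coeffs, spectrum_80kvp)
        pure_red = tissue_conversion_factor(
            spectrum_80kvp, coeffs.tissues["red_marrow"], coeffs.tissues["water"]
        )
        assert conv == pytest.approx(pure_red, rel=1e-12)

    def test_zero_cellularity_is_pure_yellow(self, coeffs, spectrum_80kvp):
        from tldose.spectrum import tissue_conversion_factor

        site = make_site("legs", cellularity=0.0)
        conv = shallow_marrow_conversion(site, coeffs, spectrum_80kvp)
        pure_yellow = tissue_conversion_factor(
            spectrum_80kvp, coeffs.tissues["yellow_marrow"], coeffs.tissues["water"]
        )
        assert conv == pytest.approx(pure_yellow, rel=1e-12)

    def test_half_cellularity_with_constant_tables(self):
        # 0.5 * 1.2 + 0.5 * 0.8 = 1.0 against water = 1.0
        site = make_site("rib", cellularity=0.5)
        conv = shallow_marrow_conversion(site, self.constant_coeffs(), self.flat)
        assert conv == pytest.approx(1.0, rel=1e-12)


class TestMarrowDoseResults:
    def test_degenerate_limit_is_plain_weighted_mean(self, coeffs):
        """DEF=0, cellularity=1, marrow coefficients = water => mass-weighted mean."""
        water = coeffs.tissues["water"]
        neutral = type(coeffs)(
            tissues={
                "water": water,
                "red_marrow": TissueCoefficientTable(
                    "red_marrow", water.energies, water.mu_en_over_rho
                ),
                "yellow_marrow": TissueCoefficientTable(
                    "yellow_marrow", water.energies, water.mu_en_over_rho
                ),
                "soft_tissue": coeffs.tissues["soft_tissue"],
                "air": coeffs.tissues["air"],
            },
            weights=coeffs.weights,
            skeleton={
                n: SkeletalSite(n, s.rbm_mass, s.shallow_marrow_mass, 1.0, 0.0, 0.0)
                for n, s in coeffs.skeleton.items()
            },
            colon=coeffs.colon,
            attenuation=coeffs.attenuation,
        )
        spec = SpectrumModel([30.0, 50.0], [1.0, 1.0])
        site_water = {n: (float(i + 1), 0.0) for i, n in enumerate(neutral.skeleton)}
        rbm, shallow = marrow_dose_results(site_water, neutral, spec)
        masses = {n: s.rbm_mass for n, s in neutral.skeleton.items()}
        expected = sum(
            site_water[n][0] * masses[n] for n in masses
        ) / sum(masses.values())
        assert rbm.mean_dose == pytest.approx(expected, rel=1e-12)

    def test_bone_surface_exceeds_active_marrow_for_adult_defs(self, coeffs, spectrum_80kvp):
        # shallow DEFs are uniformly larger than the RBM DEFs in the fixture
        site_water = {n: (10.0, 0.5) for n in coeffs.skeleton}
        rbm, shallow = marrow_dose_results(site_water, coeffs, spectrum_80kvp)
        assert shallow.mean_dose > rbm.mean_dose
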