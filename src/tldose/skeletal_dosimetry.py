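"""Red-bone-marrow and shallow-marrow ("bone surface") dosimetry.

Each skeletal site's mean water dose is converted to marrow dose and
enhanced for the photoelectron contribution from adjacent trabecular
bone, then the sites are combined by their marrow mass fractions:

    D = sum_i  D_W,i * conv_i * (1 + S_i) * M_i / M_total

where S_i is the site's dose enhancement factor (DEF) and M_i / M_total
the site's share of the skeleton's red (or shallow) marrow mass.  The
same raw site readings feed both compartments; they differ only through
their conversion factors, DEFs and masses.  Shallow-marrow conversion
accounts for site cellularity by mixing red- and yellow-marrow
mass energy-absorption coefficients before the spectrum weighting.
"""

from __future__ import annotations

import numpy as np

from .coefficients import (
    CoefficientError,
    CoefficientSet,
    SkeletalSite,
    TissueCoefficientTable,
)
from .organ_dosimetry import OrganDoseResult
from .spectrum import SpectrumModel, tissue_conversion_factor

__all__ = [
    "site_marrow_dose",
    "total_marrow_dose",
    "shallow_marrow_conversion",
    "marrow_dose_results",
]

_MASS_CLOSURE_TOL = 1e-6


def site_marrow_dose(water_dose_mean: float, conv_marrow: float, def_site: float) -> float:
    """Marrow dose at one site: D_i = D_W,i * conv * (1 + S_i)."""
    if conv_marrow <= 0:
        raise ValueError("tissue conversion factor must be > 0")
    if def_site < 0:
        raise ValueError("dose enhancement factor must be >= 0")
    return water_dose_mean * conv_marrow * (1.0 + def_site)


def total_marrow_dose(
    site_doses: dict[str, tuple[float, float]],
    sites: dict[str, SkeletalSite],
    compartment: str,
    renormalize_partial: bool = False,
) -> tuple[float, float]:
    """Mass-weighted total marrow dose over skeletal sites, with SD.

    ``site_doses`` maps site name to (dose, sd) *already converted and
    DEF-enhanced*.  ``compartment`` selects which mass column weights
    the sum ("rbm" or "shallow").  The listed sites are exhaustive by
    construction, so their mass fractions must close to 1; computing on
    a partial skeleton requires ``renormalize_partial=True``.
    """
    if compartment not in ("rbm", "shallow"):
        raise ValueError("compartment must be 'rbm' or 'shallow'")
    missing = set(site_doses) - set(sites)
    if missing:
        raise KeyError(f"unknown skeletal sites: {sorted(missing)}")

    def mass(s: SkeletalSite) -> float:
        return s.rbm_mass if compartment == "rbm" else s.shallow_marrow_mass

    m_total = sum(mass(s) for s in sites.values())
    m_used = sum(mass(sites[name]) for name in site_doses)
    if abs(m_used / m_total - 1.0) > _MASS_CLOSURE_TOL:
        if not renormalize_partial:
            raise CoefficientError(
                f"site mass fractions sum to {m_used / m_total:.6f}, not 1; "
                "pass renormalize_partial=True to compute on a partial skeleton"
            )
        m_total = m_used

    dose = 0.0
    var = 0.0
    for name, (d, sd) in site_doses.items():
        frac = mass(sites[name]) / m_total
        dose += frac * d
        var += (frac * sd) ** 2
    return float(dose), float(np.sqrt(var))


def shallow_marrow_conversion(
    site: SkeletalSite,
    coeffs: CoefficientSet,
    spec: SpectrumModel,
) -> float:
    """Spectrum-weighted water-to-shallow-marrow conversion for one site.

    The site's marrow is a red/yellow mix with red fraction c
    (cellularity); the composite coefficient c*[mu_en/rho]_red +
    (1-c)*[mu_en/rho]_yellow is weighted against water over the beam
    spectrum.
    """
    for needed in ("red_marrow", "yellow_marrow"):
        if needed not in coeffs.tissues:
            raise CoefficientError(f"missing marrow coefficient table {needed!r}")
    red = coeffs.tissues["red_marrow"]
    yellow = coeffs.tissues["yellow_marrow"]
    if not np.array_equal(red.energies, yellow.energies):
        raise CoefficientError("red and yellow marrow tables must share a grid")
    c = site.cellularity
    composite = TissueCoefficientTable(
        f"shallow_marrow[{site.site_name}]",
        red.energies,
        c * red.mu_en_over_rho + (1.0 - c) * yellow.mu_en_over_rho,
    )
    return tissue_conversion_factor(spec, composite, coeffs.tissues["water"])


def marrow_dose_results(
    site_water_doses: dict[str, tuple[float, float]],
    coeffs: CoefficientSet,
    spec: SpectrumModel,
) -> tuple[OrganDoseResult, OrganDoseResult]:
    """Active-marrow and bone-surface organ results from site water doses.

    ``site_water_doses`` maps each skeletal site to the (mean, sd) of
    its chips' water doses (both scan sessions pooled).  Returns the two
    reportable rows ("active_marrow", "bone_surface").
    """
    sites = coeffs.skeleton
    water = coeffs.tissues["water"]
    conv_rbm = tissue_conversion_factor(spec, coeffs.tissues["red_marrow"], water)

    rbm_sites: dict[str, tuple[float, float]] = {}
    shallow_sites: dict[str, tuple[float, float]] = {}
    for name, (d, sd) in site_water_doses.items():
        site = sites[name]
        rbm_sites[name] = (
            site_marrow_dose(d, conv_rbm, site.def_rbm),
            sd * conv_rbm * (1.0 + site.def_rbm),
        )
        conv_sh = shallow_marrow_conversion(site, coeffs, spec)
        shallow_sites[name] = (
            site_marrow_dose(d, conv_sh, site.def_shallow),
            sd * conv_sh * (1.0 + site.def_shallow),
        )

    n = sum(1 for _ in site_water_doses)
    rbm_dose, rbm_sd = total_marrow_dose(rbm_sites, sites, "rbm")
    sh_dose, sh_sd = total_marrow_dose(shallow_sites, sites, "shallow")
    return (
        OrganDoseResult("active_marrow", rbm_dose, rbm_sd, max(n, 1)),
        OrganDoseResult("bone_surface", sh_dose, sh_sd, max(n, 1)),
    )
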