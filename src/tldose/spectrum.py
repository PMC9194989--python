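"""Polychromatic beam model and spectrum-weighted dose-to-tissue conversion.

The CT beam is modelled with a simplified analytic spectrum: Kramers-form
bremsstrahlung N(E) proportional to (kVp - E)/E, filtered through
exponential attenuation by the listed filter materials.  Characteristic
anode lines are omitted — they are second order for the mu_en/rho ratios
computed here.  Users with measured or externally simulated spectra can
bypass the model entirely by loading a two-column (keV, fluence) CSV.

Beam quality is summarised the way diagnostic physics does it: aluminium
half-value layer (HVL) and the matching effective (monoenergetic) energy.
The dose-to-tissue conversion weights the mu_en/rho ratio by energy
fluence across the spectrum, using the unattenuated beam (no phantom
scatter or hardening correction is applied).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.optimize import brentq

from .coefficients import (
    CoefficientError,
    CoefficientSet,
    TissueCoefficientTable,
    load_coefficients,
)

__all__ = [
    "SpectrumModel",
    "SpectrumMatchReport",
    "generate_spectrum",
    "half_value_layer",
    "effective_energy",
    "mean_energy",
    "check_spectrum_match",
    "tissue_conversion_factor",
    "load_spectrum_csv",
    "save_spectrum_csv",
]

_HVL_TOL_MM = 1e-4


@dataclass(frozen=True)
class SpectrumModel:
    """Binned photon fluence spectrum.

    ``energies`` are bin centers in keV (ascending); ``fluence`` is the
    relative number of photons per bin (non-negative, zero above the
    tube potential).  Normalisation is irrelevant to every quantity
    computed from the spectrum.
    """

    energies: np.ndarray
    fluence: np.ndarray
    kvp: float | None = None
    filtration: tuple[tuple[str, float], ...] = field(default_factory=tuple)

    def __post_init__(self) -> None:
        e = np.asarray(self.energies, dtype=float)
        f = np.asarray(self.fluence, dtype=float)
        object.__setattr__(self, "energies", e)
        object.__setattr__(self, "fluence", f)
        if e.ndim != 1 or e.size == 0 or f.shape != e.shape:
            raise ValueError("energies and fluence must be equal-length 1-d arrays")
        if not np.all(np.diff(e) > 0):
            raise ValueError("spectrum energies must be strictly ascending")
        if np.any(f < 0):
            raise ValueError("fluence must be non-negative")
        if not np.any(f > 0):
            raise ValueError("spectrum has no nonzero bins")
        if self.kvp is not None and np.any(f[e > self.kvp] > 0):
            raise ValueError("nonzero fluence above the tube potential")

    @property
    def is_monoenergetic(self) -> bool:
        return int(np.count_nonzero(self.fluence)) == 1

    def normalized(self) -> "SpectrumModel":
        return SpectrumModel(
            self.energies, self.fluence / self.fluence.sum(), self.kvp, self.filtration
        )


def generate_spectrum(
    kvp: float,
    filtration: list[tuple[str, float]] | None = None,
    bin_width: float = 1.0,
    emin: float = 10.0,
    coeffs: CoefficientSet | None = None,
) -> SpectrumModel:
    """Simplified analytic x-ray tube spectrum.

    Kramers bremsstrahlung, N(E) ∝ (kVp − E)/E on bins of ``bin_width``
    keV from ``emin`` to the tube potential, attenuated through each
    ``(material, mm)`` filtration pair and normalised to unit total
    fluence.  ``emin`` defaults to 10 keV, the bottom of the bundled
    attenuation grids; photons below that are clinically negligible
    after any realistic inherent filtration.
    """
    if not 40.0 <= kvp <= 150.0:
        raise ValueError(f"kvp {kvp} outside supported range [40, 150]")
    if bin_width <= 0:
        raise ValueError("bin_width must be > 0")
    filtration = list(filtration or [])
    coeffs = coeffs if coeffs is not None else load_coefficients()

    edges = np.arange(emin, kvp + bin_width, bin_width)
    centers = (edges[:-1] + edges[1:]) / 2.0
    centers = centers[centers < kvp]
    fluence = (kvp - centers) / centers
    for material, thickness in filtration:
        if material not in coeffs.attenuation:
            raise CoefficientError(f"unknown filter material {material!r}")
        if thickness < 0:
            raise ValueError("filter thickness must be >= 0")
        mu = coeffs.attenuation[material].mu_linear(centers)  # 1/mm
        fluence = fluence * np.exp(-mu * thickness)
    return SpectrumModel(
        centers, fluence / fluence.sum(), kvp=kvp, filtration=tuple(filtration)
    )


def _kerma_weights(spec: SpectrumModel, coeffs: CoefficientSet) -> np.ndarray:
    """Relative air-kerma contribution per bin: fluence * E * (mu_en/rho)_air."""
    air = coeffs.tissues["air"]
    return spec.fluence * spec.energies * air(spec.energies)


def half_value_layer(
    spec: SpectrumModel,
    material: str = "Al",
    coeffs: CoefficientSet | None = None,
    search_max_mm: float = 50.0,
) -> float:
    """Thickness (mm) of ``material`` halving the air-kerma-weighted intensity.

    Solved by bracketed root finding to 1e-4 mm.  For a monoenergetic
    beam this reduces to ln 2 / mu(E).
    """
    coeffs = coeffs if coeffs is not None else load_coefficients()
    if material not in coeffs.attenuation:
        raise CoefficientError(f"no attenuation table for material {material!r}")
    mu = coeffs.attenuation[material].mu_linear(spec.energies)  # 1/mm
    k0 = _kerma_weights(spec, coeffs)
    total = k0.sum()

    def transmitted_fraction(t: float) -> float:
        return float(np.sum(k0 * np.exp(-mu * t)) / total) - 0.5

    lo, hi = 0.0, search_max_mm
    if transmitted_fraction(hi) > 0:
        raise ValueError(
            f"HVL search range [0, {search_max_mm}] mm does not bracket 50% transmission"
        )
    return float(brentq(transmitted_fraction, lo, hi, xtol=_HVL_TOL_MM))


def mean_energy(spec: SpectrumModel) -> float:
    """Fluence-weighted mean photon energy in keV."""
    return float(np.sum(spec.energies * spec.fluence) / np.sum(spec.fluence))


def effective_energy(
    spec: SpectrumModel,
    material: str = "Al",
    coeffs: CoefficientSet | None = None,
) -> float:
    """Monoenergetic energy whose attenuation matches the beam's HVL.

    Computes mu* = ln 2 / HVL and inverse-interpolates the filter
    material's attenuation table (log-log) to find the energy with that
    linear attenuation coefficient.
    """
    coeffs = coeffs if coeffs is not None else load_coefficients()
    hvl = half_value_layer(spec, material, coeffs)
    mu_star = np.log(2.0) / hvl  # 1/mm
    table = coeffs.attenuation[material]
    mu_grid = table.mu_linear(table.energies)
    # mu decreases with E over the diagnostic range: invert on reversed axes
    log_mu = np.log(mu_grid[::-1])
    log_e = np.log(table.energies[::-1])
    if not (log_mu[0] <= np.log(mu_star) <= log_mu[-1]):
        raise ValueError(
            f"HVL-matched mu {mu_star:.4g}/mm outside the {material} table range"
        )
    return float(np.exp(np.interp(np.log(mu_star), log_mu, log_e)))


@dataclass(frozen=True)
class SpectrumMatchReport:
    """Result of the effective-energy beam-matching check."""

    beam_effective_energy: float
    calibration_effective_energy: float
    tolerance_kev: float
    passed: bool

    @property
    def difference_kev(self) -> float:
        return abs(self.beam_effective_energy - self.calibration_effective_energy)


def check_spectrum_match(
    beam: SpectrumModel,
    calibration: SpectrumModel,
    tol: float = 5.0,
    coeffs: CoefficientSet | None = None,
) -> SpectrumMatchReport:
    """Check that two beams' effective energies agree within ``tol`` keV.

    The bound is inclusive: a difference of exactly ``tol`` passes.
    """
    coeffs = coeffs if coeffs is not None else load_coefficients()
    e_beam = effective_energy(beam, coeffs=coeffs)
    e_cal = effective_energy(calibration, coeffs=coeffs)
    return SpectrumMatchReport(
        beam_effective_energy=e_beam,
        calibration_effective_energy=e_cal,
        tolerance_kev=tol,
        passed=abs(e_beam - e_cal) <= tol,
    )


def tissue_conversion_factor(
    spec: SpectrumModel,
    tissue: TissueCoefficientTable,
    water: TissueCoefficientTable,
) -> float:
    """Spectrum-weighted water-to-tissue dose conversion factor.

    factor = sum_E w(E) [mu_en/rho]_T(E) / sum_E w(E) [mu_en/rho]_W(E)
    with w(E) = fluence(E) * E (energy fluence): absorbed dose is
    proportional to energy fluence times mu_en/rho.  The ratio of
    spectrum-weighted means is taken (not the mean of pointwise ratios),
    and the result is invariant to fluence normalisation.  D_T = D_W *
    factor.
    """
    mask = spec.fluence > 0
    e = spec.energies[mask]
    w = spec.fluence[mask] * e
    num = np.sum(w * tissue(e))
    den = np.sum(w * water(e))
    return float(num / den)


def load_spectrum_csv(path: str | Path, kvp: float | None = None) -> SpectrumModel:
    """Read a two-column (energy_kev, fluence) spectrum CSV."""
    df = pd.read_csv(path)
    missing = {"energy_kev", "fluence"} - set(df.columns)
    if missing:
        raise ValueError(f"{Path(path).name}: missing columns {sorted(missing)}")
    df = df.sort_values("energy_kev")
    return SpectrumModel(
        df["energy_kev"].to_numpy(float), df["fluence"].to_numpy(float), kvp=kvp
    )


def save_spectrum_csv(spec: SpectrumModel, path: str | Path) -> None:
    pd.DataFrame({"energy_kev": spec.energies, "fluence": spec.fluence}).to_csv(
        path, index=False
    )
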