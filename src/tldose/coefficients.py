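"""File-backed physical-constant tables used by every downstream stage.

All coefficient data (mass energy-absorption tables, ICRP 103 tissue
weighting factors, skeletal marrow masses / cellularities / dose
enhancement factors, colon segment mass fractions, filter attenuation
tables) live in editable CSV files with a provenance column.  The code
treats them strictly as configuration: nothing here is hard-coded, and a
differently sourced table directory can be swapped in via
:func:`load_coefficients`.
"""

from __future__ import annotations

import shutil
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "CoefficientError",
    "TissueCoefficientTable",
    "TissueWeighting",
    "SkeletalSite",
    "ColonSegmentWeights",
    "AttenuationTable",
    "CoefficientSet",
    "load_coefficients",
    "write_coefficients",
    "interpolate_mu_en",
    "default_coefficient_dir",
]

_WEIGHT_CLOSURE_TOL = 1e-9


class CoefficientError(ValueError):
    """Raised when a coefficient table fails schema or invariant checks."""


@dataclass(frozen=True)
class TissueCoefficientTable:
    """Mass energy-absorption coefficients mu_en/rho for one tissue.

    Parameters
    ----------
    tissue_name:
        Label of the tissue (``"water"`` must exist in any complete set:
        it is the denominator of every dose-to-tissue conversion).
    energies:
        Strictly ascending photon energy grid in keV.
    mu_en_over_rho:
        Coefficients in cm^2/g, one per grid point, all positive.
    """

    tissue_name: str
    energies: np.ndarray
    mu_en_over_rho: np.ndarray

    def __post_init__(self) -> None:
        e = np.asarray(self.energies, dtype=float)
        mu = np.asarray(self.mu_en_over_rho, dtype=float)
        object.__setattr__(self, "energies", e)
        object.__setattr__(self, "mu_en_over_rho", mu)
        if e.ndim != 1 or e.size < 2:
            raise CoefficientError(
                f"{self.tissue_name}: need at least two grid points"
            )
        if mu.shape != e.shape:
            raise CoefficientError(
                f"{self.tissue_name}: energy grid and coefficients differ in length"
            )
        if not np.all(np.diff(e) > 0):
            raise CoefficientError(
                f"{self.tissue_name}: energy grid must be strictly increasing"
            )
        if not np.all(mu > 0):
            raise CoefficientError(f"{self.tissue_name}: coefficients must be > 0")

    @property
    def energy_range(self) -> tuple[float, float]:
        return float(self.energies[0]), float(self.energies[-1])

    def __call__(self, energy) -> np.ndarray | float:
        return interpolate_mu_en(self, energy)


def interpolate_mu_en(table: TissueCoefficientTable, energy):
    """Log-log interpolate mu_en/rho at ``energy`` (keV).

    Both axes are interpolated in log space: the coefficients span
    decades over 10-150 keV and are near power-law, so log-log is far
    more faithful between grid points than linear interpolation.  Exact
    at grid points; querying outside the grid raises rather than
    extrapolating.
    """
    e = np.asarray(energy, dtype=float)
    lo, hi = table.energy_range
    if np.any(e < lo) or np.any(e > hi):
        raise CoefficientError(
            f"{table.tissue_name}: energy {energy} keV outside grid [{lo}, {hi}]"
        )
    out = np.exp(
        np.interp(np.log(e), np.log(table.energies), np.log(table.mu_en_over_rho))
    )
    return float(out) if np.isscalar(energy) else out


@dataclass(frozen=True)
class TissueWeighting:
    """ICRP 103 tissue weighting factors.

    Remainder-block members share the single block weight (0.12) and are
    counted once, as a block, in the closure check Sum(w_T) = 1.
    """

    table: pd.DataFrame  # columns: tissue, w_T, category

    _CATEGORIES = {"primary", "remainder-member", "non-contributing"}

    def __post_init__(self) -> None:
        df = self.table
        missing = {"tissue", "w_T", "category"} - set(df.columns)
        if missing:
            raise CoefficientError(f"weights table missing columns {sorted(missing)}")
        bad = set(df["category"]) - self._CATEGORIES
        if bad:
            raise CoefficientError(f"unknown weight categories {sorted(bad)}")
        if (df["w_T"] < 0).any():
            raise CoefficientError("tissue weights must be >= 0")
        if df["tissue"].duplicated().any():
            dups = df.loc[df["tissue"].duplicated(), "tissue"].tolist()
            raise CoefficientError(f"duplicate tissues in weights table: {dups}")
        total = df.loc[df["category"] == "primary", "w_T"].sum()
        total += self.remainder_weight
        if abs(total - 1.0) > _WEIGHT_CLOSURE_TOL:
            raise CoefficientError(
                f"tissue weights (remainder counted once) sum to {total!r}, not 1"
            )

    @property
    def remainder_weight(self) -> float:
        members = self.table[self.table["category"] == "remainder-member"]
        if members.empty:
            return 0.0
        w = members["w_T"].unique()
        if len(w) != 1:
            raise CoefficientError(
                "remainder members must all carry the shared block weight"
            )
        return float(w[0])

    @property
    def remainder_members(self) -> list[str]:
        m = self.table.loc[self.table["category"] == "remainder-member", "tissue"]
        return sorted(m.tolist())

    def weight(self, tissue: str) -> float:
        row = self.table.loc[self.table["tissue"] == tissue, "w_T"]
        if row.empty:
            raise KeyError(f"tissue {tissue!r} not in weighting table")
        return float(row.iloc[0])

    def weighted_tissues(self) -> list[str]:
        """Primary tissues with nonzero weight (remainder handled as a block)."""
        df = self.table
        sel = (df["category"] == "primary") & (df["w_T"] > 0)
        return sorted(df.loc[sel, "tissue"].tolist())


@dataclass(frozen=True)
class SkeletalSite:
    """Per-site inputs of the marrow dose model.

    ``def_rbm`` / ``def_shallow`` are scalar spectrum-averaged dose
    enhancement factors S_i (extra fractional dose to marrow from
    photoelectrons released in adjacent trabecular bone); cellularity is
    the red fraction of total marrow at the site.
    """

    site_name: str
    rbm_mass: float
    shallow_marrow_mass: float
    cellularity: float
    def_rbm: float
    def_shallow: float

    def __post_init__(self) -> None:
        if self.rbm_mass <= 0 or self.shallow_marrow_mass <= 0:
            raise CoefficientError(f"{self.site_name}: marrow masses must be > 0")
        if not 0.0 <= self.cellularity <= 1.0:
            raise CoefficientError(f"{self.site_name}: cellularity outside [0, 1]")
        if self.def_rbm < 0 or self.def_shallow < 0:
            raise CoefficientError(f"{self.site_name}: DEFs must be >= 0")


@dataclass(frozen=True)
class ColonSegmentWeights:
    """Colon segment mass fractions (must sum to 1)."""

    fractions: dict[str, float]

    def __post_init__(self) -> None:
        total = sum(self.fractions.values())
        if abs(total - 1.0) > _WEIGHT_CLOSURE_TOL:
            raise CoefficientError(f"colon mass fractions sum to {total}, not 1")
        if any(f < 0 for f in self.fractions.values()):
            raise CoefficientError("colon mass fractions must be >= 0")


@dataclass(frozen=True)
class AttenuationTable:
    """Total mass attenuation mu/rho for a filter material, with density."""

    material: str
    energies: np.ndarray
    mu_over_rho: np.ndarray
    density: float  # g/cm^3

    def __post_init__(self) -> None:
        e = np.asarray(self.energies, dtype=float)
        mu = np.asarray(self.mu_over_rho, dtype=float)
        object.__setattr__(self, "energies", e)
        object.__setattr__(self, "mu_over_rho", mu)
        if not np.all(np.diff(e) > 0):
            raise CoefficientError(f"{self.material}: energy grid must increase")
        if not np.all(mu > 0) or self.density <= 0:
            raise CoefficientError(f"{self.material}: mu/rho and density must be > 0")

    def mu_linear(self, energy):
        """Linear attenuation coefficient mu (1/mm) at energy (keV)."""
        e = np.asarray(energy, dtype=float)
        if np.any(e < self.energies[0]) or np.any(e > self.energies[-1]):
            raise CoefficientError(
                f"{self.material}: energy {energy} keV outside attenuation grid"
            )
        mu_rho = np.exp(
            np.interp(np.log(e), np.log(self.energies), np.log(self.mu_over_rho))
        )
        out = mu_rho * self.density / 10.0  # cm^2/g * g/cm^3 -> 1/cm -> 1/mm
        return float(out) if np.isscalar(energy) else out


@dataclass
class CoefficientSet:
    """A complete, invariant-checked bundle of coefficient tables."""

    tissues: dict[str, TissueCoefficientTable]
    weights: TissueWeighting
    skeleton: dict[str, SkeletalSite]
    colon: ColonSegmentWeights
    attenuation: dict[str, AttenuationTable]
    source_dir: Path | None = None
    organ_tissue_alias: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if "water" not in self.tissues:
            raise CoefficientError(
                "coefficient set must contain a 'water' tissue table"
            )

    def tissue_for_organ(self, organ: str) -> TissueCoefficientTable:
        """Resolve an organ label to its coefficient table.

        Organs without a dedicated table fall back to ``soft_tissue``
        unless overridden in ``organ_tissue_alias``.
        """
        name = self.organ_tissue_alias.get(organ, organ)
        if name in self.tissues:
            return self.tissues[name]
        return self.tissues["soft_tissue"]


def default_coefficient_dir() -> Path:
    """Directory of the bundled coefficient CSVs."""
    return Path(str(resources.files("tldose").joinpath("data/coefficients")))


def _read_csv(path: Path, required: set[str]) -> pd.DataFrame:
    if not path.is_file():
        raise CoefficientError(f"missing coefficient table: {path.name}")
    try:
        df = pd.read_csv(path)
    except Exception as exc:  # malformed CSV
        raise CoefficientError(f"{path.name}: cannot parse ({exc})") from exc
    missing = required - set(df.columns)
    if missing:
        raise CoefficientError(f"{path.name}: missing columns {sorted(missing)}")
    if df.isna().any().any():
        row = int(df[df.isna().any(axis=1)].index[0])
        raise CoefficientError(f"{path.name}: empty/NaN value at data row {row}")
    return df


def load_coefficients(path: str | Path | None = None) -> CoefficientSet:
    """Load and validate a full coefficient set from a directory of CSVs.

    Any missing tissue, malformed row or broken closure invariant fails
    here, at load time, rather than mid-pipeline.  ``path=None`` loads
    the bundled defaults.
    """
    d = Path(path) if path is not None else default_coefficient_dir()

    tis = _read_csv(d / "tissues.csv", {"tissue", "energy_kev", "mu_en_over_rho"})
    tissues: dict[str, TissueCoefficientTable] = {}
    for name, grp in tis.groupby("tissue", sort=False):
        grp = grp.sort_values("energy_kev")
        tissues[str(name)] = TissueCoefficientTable(
            str(name),
            grp["energy_kev"].to_numpy(float),
            grp["mu_en_over_rho"].to_numpy(float),
        )

    wdf = _read_csv(d / "weights.csv", {"tissue", "w_T", "category"})
    weights = TissueWeighting(wdf[["tissue", "w_T", "category"]].copy())

    sdf = _read_csv(
        d / "skeleton.csv",
        {"site", "rbm_mass_g", "shallow_mass_g", "cellularity", "def_rbm", "def_shallow"},
    )
    skeleton = {
        str(r.site): SkeletalSite(
            str(r.site),
            float(r.rbm_mass_g),
            float(r.shallow_mass_g),
            float(r.cellularity),
            float(r.def_rbm),
            float(r.def_shallow),
        )
        for r in sdf.itertuples()
    }

    cdf = _read_csv(d / "colon.csv", {"segment", "mass_fraction"})
    colon = ColonSegmentWeights(
        dict(zip(cdf["segment"].astype(str), cdf["mass_fraction"].astype(float)))
    )

    adf = _read_csv(
        d / "attenuation.csv", {"material", "energy_kev", "mu_over_rho", "density_g_cm3"}
    )
    attenuation: dict[str, AttenuationTable] = {}
    for name, grp in adf.groupby("material", sort=False):
        grp = grp.sort_values("energy_kev")
        attenuation[str(name)] = AttenuationTable(
            str(name),
            grp["energy_kev"].to_numpy(float),
            grp["mu_over_rho"].to_numpy(float),
            float(grp["density_g_cm3"].iloc[0]),
        )

    return CoefficientSet(
        tissues=tissues,
        weights=weights,
        skeleton=skeleton,
        colon=colon,
        attenuation=attenuation,
        source_dir=d,
    )


def write_coefficients(cset: CoefficientSet, out_dir: str | Path) -> Path:
    """Write a coefficient set back to CSVs (round-trips bit-identically).

    When the set was loaded from disk the original files are copied
    verbatim, preserving provenance columns and formatting.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    if cset.source_dir is not None:
        for name in ("tissues.csv", "weights.csv", "skeleton.csv", "colon.csv",
                     "attenuation.csv"):
            src = cset.source_dir / name
            if src.is_file():
                shutil.copy(src, out / name)
        return out

    rows = [
        {"tissue": t.tissue_name, "energy_kev": e, "mu_en_over_rho": m}
        for t in cset.tissues.values()
        for e, m in zip(t.energies, t.mu_en_over_rho)
    ]
    pd.DataFrame(rows).to_csv(out / "tissues.csv", index=False)
    cset.weights.table.to_csv(out / "weights.csv", index=False)
    pd.DataFrame(
        [
            {
                "site": s.site_name,
                "rbm_mass_g": s.rbm_mass,
                "shallow_mass_g": s.shallow_marrow_mass,
                "cellularity": s.cellularity,
                "def_rbm": s.def_rbm,
                "def_shallow": s.def_shallow,
            }
            for s in cset.skeleton.values()
        ]
    ).to_csv(out / "skeleton.csv", index=False)
    pd.DataFrame(
        [{"segment": k, "mass_fraction": v} for k, v in cset.colon.fractions.items()]
    ).to_csv(out / "colon.csv", index=False)
    pd.DataFrame(
        [
            {
                "material": a.material,
                "energy_kev": e,
                "mu_over_rho": m,
                "density_g_cm3": a.density,
            }
            for a in cset.attenuation.values()
            for e, m in zip(a.energies, a.mu_over_rho)
        ]
    ).to_csv(out / "attenuation.csv", index=False)
    return out
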