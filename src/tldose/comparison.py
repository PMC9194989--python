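"""Compare Monte Carlo dosimetry-software organ doses to measured references.

The software packages report sex-specific organ doses; the physical
phantom is hermaphroditic, so non-reproductive organ doses whose male
and female values agree within 5% are averaged into a single
hermaphroditic dose (larger splits are still averaged but flagged;
reproductive organs pass through per sex).  Agreement is quantified by
the signed percentage variation

    variation% = (D_soft - D_ref) / D_ref * 100

and summarised as the mean of |variation| over organ x protocol cells,
optionally excluding named organs (e.g. the bone-surface outlier).
Organ vocabularies differ between packages; an alias CSV maps them onto
the canonical organ names, and an unmatched name is a hard error.
Organs a package does not report stay "not reported" — never zero.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "SoftwareDoseTable",
    "HermaphroditicDose",
    "hermaphroditic_dose",
    "variation_percent",
    "average_variation",
    "compare_to_reference",
    "load_alias_map",
    "SEX_SPECIFIC_ORGANS",
    "HERMAPHRODITIC_TOLERANCE",
]

SEX_SPECIFIC_ORGANS = frozenset({"prostate", "testes", "ovaries", "uterus"})
HERMAPHRODITIC_TOLERANCE = 0.05  # 5% male/female split for silent averaging

# Canonical organ vocabulary used by the measured reference table.
CANONICAL_ORGANS = frozenset(
    {
        "active_marrow", "bladder", "bone_surface", "brain", "breast", "colon",
        "liver", "lung", "esophagus", "ovaries", "salivary_glands", "skin",
        "stomach", "testes", "thyroid", "heart", "kidney", "muscle", "pancreas",
        "prostate", "small_bowel", "spleen", "uterus", "lens", "spine",
    }
)


def load_alias_map(path: str | Path | None = None) -> dict[str, str]:
    """Alias -> canonical organ name map (case-insensitive on lookup)."""
    p = (
        Path(path)
        if path is not None
        else Path(str(resources.files("tldose").joinpath("data/coefficients/aliases.csv")))
    )
    df = pd.read_csv(p)
    return {str(a).strip().lower(): str(c) for a, c in zip(df["alias"], df["canonical"])}


def canonical_organ(name: str, aliases: dict[str, str]) -> str:
    snake = name.strip().lower().replace(" ", "_")
    if snake in CANONICAL_ORGANS:
        return snake
    key = name.strip().lower().replace("_", " ")
    if key in aliases:
        return aliases[key]
    raise KeyError(f"organ name {name!r} has no canonical mapping")


@dataclass(frozen=True)
class HermaphroditicDose:
    organ: str
    dose: float | None  # averaged dose; None for per-sex pass-through
    dose_male: float
    dose_female: float
    flagged: bool  # male/female split exceeded 5% on a non-reproductive organ
    passthrough: bool  # reproductive organ, not averaged


def hermaphroditic_dose(male: float, female: float, organ: str) -> HermaphroditicDose:
    """Average male/female doses into a hermaphroditic organ dose.

    Reproductive organs (prostate, testes, ovaries, uterus) pass through
    unaveraged.  Other organs are averaged; if the male/female split
    exceeds 5% of their mean the average is still returned but flagged.
    """
    if male < 0 or female < 0:
        raise ValueError("doses must be >= 0")
    if organ in SEX_SPECIFIC_ORGANS:
        return HermaphroditicDose(organ, None, male, female, False, True)
    mean = (male + female) / 2.0
    split = abs(male - female) / mean if mean > 0 else 0.0
    return HermaphroditicDose(
        organ, mean, male, female, split > HERMAPHRODITIC_TOLERANCE, False
    )


def variation_percent(d_soft: float, d_ref: float) -> float:
    """Signed percentage variation of a software dose from the reference."""
    if d_ref <= 0:
        raise ValueError("reference dose must be > 0 for a percentage variation")
    return (d_soft - d_ref) / d_ref * 100.0


def average_variation(
    variations,
    exclude: set[str] | frozenset[str] = frozenset(),
    signed: bool = False,
) -> float:
    """Mean variation over organ x protocol cells.

    ``variations`` is either a sequence of percentages or a mapping from
    (organ, ...) keys to percentages; keys whose organ is in ``exclude``
    are dropped.  By default magnitudes are averaged — signed means
    would let over- and underestimates cancel.  ``signed=True`` averages
    the raw signed values instead.
    """
    vals = _included_values(variations, exclude)
    if not vals:
        raise ValueError("no variation cells left after exclusion")
    arr = np.asarray(vals, dtype=float)
    return float(arr.mean() if signed else np.abs(arr).mean())


def _included_values(variations, exclude) -> list[float]:
    if isinstance(variations, dict):
        out = []
        for key, v in variations.items():
            organ = key[0] if isinstance(key, tuple) else key
            if organ not in exclude:
                out.append(float(v))
        return out
    return [float(v) for v in variations]


class SoftwareDoseTable:
    """Organ doses reported by one or more dosimetry packages.

    Long-form table with columns software, protocol, organ,
    dose_male_mgy, dose_female_mgy.  Organ names are canonicalised
    through the alias map on construction.  Effective doses ride along
    as the pseudo-organ ``"effective"`` (per-sex, in mSv).
    """

    COLUMNS = ("software", "protocol", "organ", "dose_male_mgy", "dose_female_mgy")

    def __init__(self, table: pd.DataFrame, aliases: dict[str, str] | None = None):
        missing = set(self.COLUMNS) - set(table.columns)
        if missing:
            raise ValueError(f"software dose table missing columns {sorted(missing)}")
        aliases = aliases if aliases is not None else load_alias_map()
        t = table[list(self.COLUMNS)].copy()
        t["organ"] = [
            o if o == "effective" else canonical_organ(str(o), aliases)
            for o in t["organ"]
        ]
        if (t[["dose_male_mgy", "dose_female_mgy"]] < 0).any().any():
            raise ValueError("software doses must be >= 0")
        self.table = t

    @classmethod
    def from_csv(cls, path: str | Path, aliases: dict[str, str] | None = None):
        return cls(pd.read_csv(path), aliases)

    def hermaphroditic(self) -> pd.DataFrame:
        """Averaged (hermaphroditic) dose per software/protocol/organ."""
        rows = []
        for r in self.table.itertuples():
            h = hermaphroditic_dose(
                float(r.dose_male_mgy), float(r.dose_female_mgy), str(r.organ)
            )
            rows.append(
                {
                    "software": r.software,
                    "protocol": r.protocol,
                    "organ": r.organ,
                    "dose_mgy": h.dose if not h.passthrough else None,
                    "dose_male_mgy": h.dose_male,
                    "dose_female_mgy": h.dose_female,
                    "flagged": h.flagged,
                    "passthrough": h.passthrough,
                }
            )
        return pd.DataFrame(rows)


def compare_to_reference(
    software: SoftwareDoseTable,
    reference: dict[str, dict[str, float]],
) -> pd.DataFrame:
    """Tidy per-cell variation report against measured reference doses.

    ``reference`` maps protocol -> organ -> measured dose.  Software
    cells without a matching reference organ are reported with a null
    variation ("not reported" in the reference), never as zero.
    """
    herm = software.hermaphroditic()
    rows = []
    for r in herm.itertuples():
        ref_organs = reference.get(str(r.protocol), {})
        if r.passthrough:
            # reproductive organs compared per sex
            for sex, d in (("male", r.dose_male_mgy), ("female", r.dose_female_mgy)):
                ref = ref_organs.get(str(r.organ))
                rows.append(
                    {
                        "software": r.software,
                        "protocol": r.protocol,
                        "organ": r.organ,
                        "sex": sex,
                        "dose_mgy": d,
                        "reference_mgy": ref,
                        "variation_pct": variation_percent(d, ref)
                        if ref is not None
                        else None,
                    }
                )
            continue
        ref = ref_organs.get(str(r.organ))
        rows.append(
            {
                "software": r.software,
                "protocol": r.protocol,
                "organ": r.organ,
                "sex": "hermaphroditic",
                "dose_mgy": r.dose_mgy,
                "reference_mgy": ref,
                "variation_pct": variation_percent(float(r.dose_mgy), ref)
                if ref is not None
                else None,
                "flagged": r.flagged,
            }
        )
    return pd.DataFrame(rows)
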