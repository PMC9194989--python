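"""Aggregate per-chip doses into per-organ absorbed doses with uncertainties.

Chips are mapped to organs through a placement map mirroring the layout
used in the physical 1-year-old phantom.  The organ mean pools every
contributing measurement from both repeat scan sessions; the quoted
uncertainty is one sample standard deviation (n-1) of that pooled set.
Organ-specific rules: the colon is a mass-fraction-weighted sum over its
five segments, muscle is approximated as the mean over all torso and
leg chips, and skin uses only the dedicated surface chips.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .coefficients import ColonSegmentWeights

__all__ = [
    "PlacementMap",
    "OrganDoseResult",
    "organ_mean_dose",
    "colon_dose",
    "muscle_dose",
    "skin_dose",
    "standard_infant_placement",
    "MUSCLE_EXCLUDED_ORGANS",
]

# Organs excluded from the muscle (torso + legs) averaging pool: the skin
# chips sit on the surface, and the lens / spine chips report dedicated
# rows of their own.
MUSCLE_EXCLUDED_ORGANS = frozenset({"skin", "lens"})
MUSCLE_EXCLUDED_SUBSITES = frozenset({"spine"})


@dataclass(frozen=True)
class OrganDoseResult:
    """Mean +/- 1 SD absorbed dose for one organ under one protocol."""

    organ: str
    mean_dose: float  # mGy
    sd: float  # mGy, sample SD over pooled measurements
    n: int  # contributing measurements (chips x sessions)
    tissue_converted: bool = True

    def __post_init__(self) -> None:
        if self.mean_dose < 0 or self.sd < 0 or self.n < 1:
            raise ValueError(f"invalid organ dose result for {self.organ!r}")

    def scaled(self, factor: float) -> "OrganDoseResult":
        return OrganDoseResult(
            self.organ, self.mean_dose * factor, self.sd * factor, self.n,
            self.tissue_converted,
        )


class PlacementMap:
    """Chip-to-organ placement: chip_id -> (organ, sub_site, region).

    ``sub_site`` carries the colon segment for colon chips and the
    skeletal site for skeleton chips; ``region`` tags the gross body
    region (head / torso / legs / surface) used by the muscle rule.
    """

    COLUMNS = ("chip_id", "organ", "sub_site", "region")

    def __init__(self, table: pd.DataFrame):
        missing = set(self.COLUMNS) - set(table.columns)
        if missing:
            raise ValueError(f"placement map missing columns {sorted(missing)}")
        t = table[list(self.COLUMNS)].copy()
        t["chip_id"] = t["chip_id"].astype(str)
        if t["chip_id"].duplicated().any():
            dup = t.loc[t["chip_id"].duplicated(), "chip_id"].tolist()
            raise ValueError(f"chips placed more than once: {dup[:5]}")
        t["sub_site"] = t["sub_site"].fillna("")
        self.table = t

    def __len__(self) -> int:
        return len(self.table)

    @property
    def organs(self) -> list[str]:
        return sorted(self.table["organ"].unique())

    def chips_for(self, organ: str, sub_site: str | None = None) -> list[str]:
        sel = self.table["organ"] == organ
        if sub_site is not None:
            sel &= self.table["sub_site"] == sub_site
        return self.table.loc[sel, "chip_id"].tolist()

    def organ_of(self, chip_id: str) -> str:
        row = self.table.loc[self.table["chip_id"] == str(chip_id)]
        if row.empty:
            raise KeyError(f"chip {chip_id!r} not placed")
        return str(row["organ"].iloc[0])

    @classmethod
    def from_csv(cls, path: str | Path) -> "PlacementMap":
        return cls(pd.read_csv(path))

    def to_csv(self, path: str | Path) -> None:
        self.table.to_csv(path, index=False)


def _pool(chip_doses: pd.DataFrame, chip_ids: list[str]) -> np.ndarray:
    missing = {"chip_id", "dose"} - set(chip_doses.columns)
    if missing:
        raise ValueError(f"chip dose table missing columns {sorted(missing)}")
    sel = chip_doses["chip_id"].astype(str).isin([str(c) for c in chip_ids])
    return chip_doses.loc[sel, "dose"].to_numpy(float)


def _mean_sd(values: np.ndarray) -> tuple[float, float]:
    mean = float(values.mean())
    sd = float(values.std(ddof=1)) if values.size > 1 else 0.0
    return mean, sd


def organ_mean_dose(
    chip_doses: pd.DataFrame,
    placement: PlacementMap,
    organ: str,
    conv: float = 1.0,
) -> OrganDoseResult:
    """Tissue-converted mean +/- SD over every chip measurement in the organ.

    ``chip_doses`` is long-form (chip_id, session, dose) with both
    repeat sessions pooled; each measurement is multiplied by the
    water-to-tissue conversion factor ``conv`` before averaging, so the
    SD scales with it too.
    """
    chip_ids = placement.chips_for(organ)
    if not chip_ids:
        raise KeyError(
            f"no chips placed in organ {organ!r}; available: {placement.organs}"
        )
    values = _pool(chip_doses, chip_ids) * conv
    if values.size == 0:
        raise ValueError(f"no dose measurements for organ {organ!r}")
    mean, sd = _mean_sd(values)
    return OrganDoseResult(organ, mean, sd, int(values.size))


def colon_dose(
    segment_results: dict[str, OrganDoseResult],
    weights: ColonSegmentWeights,
) -> OrganDoseResult:
    """Mass-fraction-weighted colon dose over its five segments.

    mean = sum_s f_s * mean_s with uncorrelated propagation
    sd = sqrt(sum_s f_s^2 * sd_s^2).
    """
    missing = set(weights.fractions) - set(segment_results)
    if missing:
        raise ValueError(f"missing colon segments: {sorted(missing)}")
    mean = sum(
        weights.fractions[s] * segment_results[s].mean_dose for s in weights.fractions
    )
    var = sum(
        (weights.fractions[s] * segment_results[s].sd) ** 2 for s in weights.fractions
    )
    n = sum(segment_results[s].n for s in weights.fractions)
    return OrganDoseResult("colon", float(mean), float(np.sqrt(var)), int(n))


def muscle_dose(
    chip_doses: pd.DataFrame,
    placement: PlacementMap,
    conv: float = 1.0,
) -> OrganDoseResult:
    """Muscle dose approximated as the mean over all torso and leg chips.

    Surface (skin) and lens chips never enter the pool, nor do the
    spine chips (they report their own rows).
    """
    t = placement.table
    sel = (
        t["region"].isin(["torso", "legs"])
        & ~t["organ"].isin(MUSCLE_EXCLUDED_ORGANS)
        & ~t["sub_site"].isin(MUSCLE_EXCLUDED_SUBSITES)
    )
    chip_ids = t.loc[sel, "chip_id"].tolist()
    if not chip_ids:
        raise ValueError("no torso/leg chips available for the muscle average")
    values = _pool(chip_doses, chip_ids) * conv
    mean, sd = _mean_sd(values)
    return OrganDoseResult("muscle", mean, sd, int(values.size))


def skin_dose(
    chip_doses: pd.DataFrame,
    placement: PlacementMap,
    conv: float = 1.0,
) -> OrganDoseResult:
    """Mean +/- SD over the dedicated surface chips only."""
    chip_ids = placement.chips_for("skin")
    if not chip_ids:
        raise ValueError("no surface (skin) chips in the placement map")
    values = _pool(chip_doses, chip_ids) * conv
    mean, sd = _mean_sd(values)
    return OrganDoseResult("skin", mean, sd, int(values.size))


def standard_infant_placement() -> PlacementMap:
    """Default placement map for the 1-year-old phantom campaign.

    Chip counts follow the physical layout: brain 7, lung 12, stomach 5,
    liver 7, thyroid 2, salivary glands 4, testes 2, ovaries 2, bladder
    4, colon 10 (3 ascending / 3 transverse / 2 descending / 2 sigmoid /
    1 rectum), skeleton 16 (3 legs / 3 pelvis / 2 rib / 4 spine / 4
    skull), skin 6, esophagus 3, breast 2, plus single-chip remainder
    organs (heart, kidney, spleen, uterus, prostate), 4 small-bowel
    chips, 2 lens chips and one mid-abdomen pancreas chip.  The spine
    skeletal chips double as the "spine" additional-organ row.
    """
    layout: list[tuple[str, int, str, str]] = [
        # organ, n chips, sub_site, region
        ("brain", 7, "", "head"),
        ("lens", 2, "", "head"),
        ("salivary_glands", 4, "", "head"),
        ("thyroid", 2, "", "head"),
        ("lung", 12, "", "torso"),
        ("esophagus", 3, "", "torso"),
        ("breast", 2, "", "torso"),
        ("heart", 1, "", "torso"),
        ("stomach", 5, "", "torso"),
        ("liver", 7, "", "torso"),
        ("spleen", 1, "", "torso"),
        ("kidney", 1, "", "torso"),
        ("pancreas", 1, "", "torso"),
        ("small_bowel", 4, "", "torso"),
        ("bladder", 4, "", "torso"),
        ("uterus", 1, "", "torso"),
        ("prostate", 1, "", "torso"),
        ("ovaries", 2, "", "torso"),
        ("testes", 2, "", "torso"),
        ("colon", 3, "ascending", "torso"),
        ("colon", 3, "transverse", "torso"),
        ("colon", 2, "descending", "torso"),
        ("colon", 2, "sigmoid", "torso"),
        ("colon", 1, "rectum", "torso"),
        ("skeleton", 3, "legs", "legs"),
        ("skeleton", 3, "pelvis", "torso"),
        ("skeleton", 2, "rib", "torso"),
        ("skeleton", 4, "spine", "torso"),
        ("skeleton", 4, "skull", "head"),
        ("skin", 6, "", "surface"),
    ]
    rows = []
    counter = 1
    for organ, n, sub_site, region in layout:
        for _ in range(n):
            rows.append(
                {
                    "chip_id": f"c{counter:03d}",
                    "organ": organ,
                    "sub_site": sub_site,
                    "region": region,
                }
            )
            counter += 1
    return PlacementMap(pd.DataFrame(rows))
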