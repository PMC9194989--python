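"""ICRP 103 sex-specific effective dose with propagated uncertainty.

E = sum_T w_T * D_T over the weighted tissues, with the gonad dose taken
from the testes (male) or ovaries (female) and the remainder block
evaluated as the unweighted mean of the measured remainder organs
(prostate entering the male set, uterus the female set).  The standard
error follows first-order uncorrelated propagation of the weighted sum:
SE = sqrt(sum_T w_T^2 sd_T^2), with the remainder's sd propagated
through its mean as sqrt(sum sd_i^2)/k.  Effective doses are also
reported normalised to the protocol's CTDI_vol (32-cm reference
phantom), the scanner-output metric that makes protocols comparable.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd

from .coefficients import TissueWeighting
from .organ_dosimetry import OrganDoseResult

__all__ = [
    "Protocol",
    "EffectiveDoseResult",
    "remainder_dose",
    "effective_dose",
    "normalize_to_ctdi",
    "load_protocols",
    "load_reference_organ_doses",
    "GONAD_ORGAN",
    "SEX_SPECIFIC_ORGANS",
]

GONAD_ORGAN = {"male": "testes", "female": "ovaries"}
# The opposite-sex reproductive organs drop out of each sex's remainder set.
_EXCLUDED_FROM_REMAINDER = {"male": {"uterus", "ovaries"}, "female": {"prostate", "testes"}}
SEX_SPECIFIC_ORGANS = frozenset({"testes", "ovaries", "prostate", "uterus"})


@dataclass(frozen=True)
class Protocol:
    """CT acquisition descriptor; CTDI_vol on the 32-cm reference phantom."""

    name: str
    scanner: str
    kvp: float
    ma: float
    rotation_s: float
    pitch: float
    collimation: str
    ctdi_vol: float  # mGy

    def __post_init__(self) -> None:
        if self.ctdi_vol <= 0:
            raise ValueError(f"{self.name}: CTDI_vol must be > 0")
        if self.pitch <= 0:
            raise ValueError(f"{self.name}: pitch must be > 0")


@dataclass(frozen=True)
class EffectiveDoseResult:
    sex: str
    effective_dose: float  # mSv
    se: float  # mSv
    normalized: float | None  # mSv per mGy CTDI_vol
    remainder_dose: float  # mGy (mean over remainder members)
    remainder_members: tuple[str, ...]

    def __post_init__(self) -> None:
        if self.effective_dose < 0 or self.se < 0:
            raise ValueError("effective dose and SE must be >= 0")


def remainder_dose(
    organ_results: dict[str, OrganDoseResult],
    sex: str,
    members: list[str] | None = None,
    weights: TissueWeighting | None = None,
) -> tuple[float, float]:
    """Unweighted mean dose (and propagated SD) of the remainder organs.

    The member list defaults to the weighting table's remainder block
    with the opposite sex's reproductive organ removed.  Every member
    must be present in ``organ_results`` — an absent organ is an error
    naming it, not a silent drop.
    """
    if sex not in GONAD_ORGAN:
        raise ValueError(f"sex must be 'male' or 'female', got {sex!r}")
    if members is None:
        if weights is None:
            raise ValueError("provide either an explicit member list or weights")
        members = [
            m
            for m in weights.remainder_members
            if m not in _EXCLUDED_FROM_REMAINDER[sex]
        ]
    missing = [m for m in members if m not in organ_results]
    if missing:
        raise KeyError(f"remainder organ(s) not measured: {missing}")
    k = len(members)
    mean = sum(organ_results[m].mean_dose for m in members) / k
    sd = float(np.sqrt(sum(organ_results[m].sd ** 2 for m in members))) / k
    return float(mean), sd


def effective_dose(
    organ_results: dict[str, OrganDoseResult],
    weights: TissueWeighting,
    sex: str,
    ctdi_vol: float | None = None,
    remainder_members: list[str] | None = None,
) -> EffectiveDoseResult:
    """ICRP 103 effective dose E = sum_T w_T D_T for one sex.

    Gonads resolve to testes/ovaries, the remainder block to the mean of
    the measured remainder organs.  Organ doses in mGy yield E in mSv
    (photon radiation weighting factor 1).  When ``ctdi_vol`` is given
    the CTDI_vol-normalised value is reported alongside.
    """
    if sex not in GONAD_ORGAN:
        raise ValueError(f"sex must be 'male' or 'female', got {sex!r}")

    rem_mean, rem_sd = remainder_dose(
        organ_results, sex, members=remainder_members, weights=weights
    )
    if remainder_members is None:
        remainder_members = [
            m
            for m in weights.remainder_members
            if m not in _EXCLUDED_FROM_REMAINDER[sex]
        ]

    total = 0.0
    var = 0.0
    unresolved: list[str] = []
    for tissue in weights.weighted_tissues():
        w = weights.weight(tissue)
        organ = GONAD_ORGAN[sex] if tissue == "gonads" else tissue
        res = organ_results.get(organ)
        if res is None:
            unresolved.append(tissue)
            continue
        total += w * res.mean_dose
        var += (w * res.sd) ** 2
    if unresolved:
        raise KeyError(f"weighted tissue(s) without an organ dose: {unresolved}")

    w_rem = weights.remainder_weight
    total += w_rem * rem_mean
    var += (w_rem * rem_sd) ** 2

    se = float(np.sqrt(var))
    return EffectiveDoseResult(
        sex=sex,
        effective_dose=float(total),
        se=se,
        normalized=(float(total) / ctdi_vol) if ctdi_vol else None,
        remainder_dose=rem_mean,
        remainder_members=tuple(remainder_members),
    )


def normalize_to_ctdi(dose: float, protocol: Protocol) -> float:
    """Divide a dose (mGy or mSv) by the protocol's CTDI_vol."""
    return dose / protocol.ctdi_vol


def _reference_dir() -> Path:
    return Path(str(resources.files("tldose").joinpath("data/reference")))


def load_protocols(path: str | Path | None = None) -> dict[str, Protocol]:
    """Load protocol descriptors (bundled campaign protocols by default)."""
    p = Path(path) if path is not None else _reference_dir() / "protocols.csv"
    df = pd.read_csv(p)
    return {
        str(r.name): Protocol(
            name=str(r.name),
            scanner=str(r.scanner),
            kvp=float(r.kvp),
            ma=float(r.ma),
            rotation_s=float(r.rotation_s),
            pitch=float(r.pitch),
            collimation=str(r.collimation),
            ctdi_vol=float(r.ctdi_vol_mgy),
        )
        for r in df.itertuples()
    }


def load_reference_organ_doses(
    path: str | Path | None = None,
) -> dict[str, dict[str, OrganDoseResult]]:
    """Bundled measured CTDI_vol-normalised organ doses per protocol.

    Returns ``{protocol: {organ: OrganDoseResult}}`` with doses in
    mGy per mGy CTDI_vol (mean +/- 1 SD).  These are the campaign's
    published measured values and serve as reference inputs for
    effective-dose computation and software comparison.
    """
    p = Path(path) if path is not None else _reference_dir() / "tld_organ_doses.csv"
    df = pd.read_csv(p)
    out: dict[str, dict[str, OrganDoseResult]] = {}
    for r in df.itertuples():
        out.setdefault(str(r.protocol), {})[str(r.organ)] = OrganDoseResult(
            str(r.organ), float(r.mean_per_ctdi), float(r.sd_per_ctdi), n=1
        )
    return out
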