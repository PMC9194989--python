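"""Raw TLD charge readings to water-equivalent absorbed dose per chip.

The processing chain mirrors standard TLD practice: per-chip sensitivity
factors (SFs) from repeated uniform irradiations with a +/-10% batch
rejection rule, a calibration factor (CF, Gy/nC) from chips exposed to a
known dose, background subtraction, and a 20% repeat-scan consistency
check between the two scan sessions.

The charge-to-dose conversion is

    D_n = (SF_n * r_n - b) * CF

i.e. the background charge b is removed from the sensitivity-corrected
charge *before* the charge-to-dose conversion — b is a raw-charge
quantity and subtracting it after multiplying by CF would mix units.
The alternative reading SF*r - (b*CF) is selectable for sensitivity
studies via ``background_in_dose=True``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "TldChip",
    "Reading",
    "CalibrationResult",
    "DoseValue",
    "QcReport",
    "SF_REJECTION_BAND",
    "REPEAT_QC_THRESHOLD",
    "compute_sensitivity_factors",
    "compute_calibration_factor",
    "background_level",
    "reading_to_dose",
    "repeat_scan_qc",
    "resolve_triplicate",
    "readings_from_csv",
    "chips_to_csv",
]

SF_REJECTION_BAND = 0.10  # +/-10% around the batch mean, and replicate spread
REPEAT_QC_THRESHOLD = 0.20  # 20% between repeat scan sessions


@dataclass(frozen=True)
class TldChip:
    """Per-chip sensitivity state after batch characterisation."""

    chip_id: str
    sensitivity_factor: float
    sf_replicates: tuple[float, ...] = ()
    status: str = "active"  # or "rejected"
    reason: str | None = None

    @property
    def active(self) -> bool:
        return self.status == "active"


@dataclass(frozen=True)
class Reading:
    """One raw charge readout.

    ``session`` labels the exposure: a protocol/repeat label, or the
    special sessions ``"background"`` and ``"calibration"``.
    """

    chip_id: str
    session: str
    charge: float  # nC

    def __post_init__(self) -> None:
        if self.charge < 0:
            raise ValueError(f"{self.chip_id}/{self.session}: charge must be >= 0")


@dataclass(frozen=True)
class CalibrationResult:
    cf: float  # Gy per nC
    nominal_dose: float  # Gy
    n_chips: int

    def __post_init__(self) -> None:
        if self.cf <= 0:
            raise ValueError("calibration factor must be > 0")


@dataclass(frozen=True)
class DoseValue:
    chip_id: str
    session: str
    dose: float  # Gy, water
    clamped: bool = False  # sub-background reading clamped to zero


def compute_sensitivity_factors(runs: pd.DataFrame) -> list[TldChip]:
    """Characterise a chip batch from repeated uniform irradiations.

    ``runs`` is long-form with columns ``chip_id``, ``run``, ``charge_nc``
    (all charges > 0); every run must cover the same chip set.  Per run,
    SF = chip charge / batch mean charge of that run; a chip's SF is the
    mean over runs.  A chip is rejected when any per-run SF falls outside
    [0.9, 1.1] or its replicate SFs are not reproducible within +/-10%
    of their own mean.  Rejection happens once, here; it is never
    re-evaluated downstream.
    """
    required = {"chip_id", "run", "charge_nc"}
    missing = required - set(runs.columns)
    if missing:
        raise ValueError(f"runs table missing columns {sorted(missing)}")
    if runs.empty:
        raise ValueError("no sensitivity runs provided")
    if (runs["charge_nc"] <= 0).any():
        raise ValueError("all sensitivity-run charges must be > 0")

    chip_ids = sorted(runs["chip_id"].unique())
    run_labels = sorted(runs["run"].unique())
    sf = pd.DataFrame(index=chip_ids, columns=run_labels, dtype=float)
    for label, grp in runs.groupby("run"):
        present = set(grp["chip_id"])
        absent = set(chip_ids) - present
        if absent:
            raise ValueError(
                f"run {label!r} missing chips: {sorted(absent)[:5]}"
            )
        if grp["chip_id"].duplicated().any():
            raise ValueError(f"run {label!r} has duplicate chip readings")
        batch_mean = grp["charge_nc"].mean()
        s = grp.set_index("chip_id")["charge_nc"] / batch_mean
        sf.loc[s.index, label] = s

    chips: list[TldChip] = []
    lo, hi = 1.0 - SF_REJECTION_BAND, 1.0 + SF_REJECTION_BAND
    for cid in chip_ids:
        reps = sf.loc[cid].to_numpy(float)
        mean_sf = float(reps.mean())
        status, reason = "active", None
        if np.any((reps < lo) | (reps > hi)):
            status, reason = "rejected", "SF outside +/-10% of batch mean"
        elif np.any(np.abs(reps / mean_sf - 1.0) > SF_REJECTION_BAND):
            status, reason = "rejected", "SF replicates not reproducible within +/-10%"
        chips.append(
            TldChip(str(cid), mean_sf, tuple(float(r) for r in reps), status, reason)
        )
    return chips


def _corrected_charges(
    readings: list[Reading], chips: dict[str, TldChip]
) -> np.ndarray:
    out = []
    for r in readings:
        chip = chips.get(r.chip_id)
        if chip is None:
            raise KeyError(f"no characterised chip {r.chip_id!r}")
        if not chip.active:
            raise ValueError(f"chip {r.chip_id!r} was rejected: {chip.reason}")
        out.append(chip.sensitivity_factor * r.charge)
    return np.asarray(out, dtype=float)


def compute_calibration_factor(
    calibration_readings: list[Reading],
    chips: dict[str, TldChip] | list[TldChip],
    nominal_dose: float = 0.5,
) -> CalibrationResult:
    """CF = nominal delivered dose / mean SF-corrected charge.

    The default nominal dose is the 0.5 Gy delivered to the calibration
    chips on a matched-beam-quality orthovoltage unit.
    """
    if nominal_dose <= 0:
        raise ValueError("nominal_dose must be > 0")
    if not calibration_readings:
        raise ValueError("need at least one calibration reading")
    chip_map = _as_chip_map(chips)
    corrected = _corrected_charges(calibration_readings, chip_map)
    mean_charge = float(corrected.mean())
    if mean_charge <= 0:
        raise ValueError("mean calibration charge is zero")
    return CalibrationResult(
        cf=nominal_dose / mean_charge,
        nominal_dose=nominal_dose,
        n_chips=len(set(r.chip_id for r in calibration_readings)),
    )


def background_level(
    background_readings: list[Reading], chips: dict[str, TldChip] | list[TldChip]
) -> float:
    """Background charge b (nC): mean SF-corrected charge of unexposed chips."""
    if not background_readings:
        raise ValueError("need at least one background reading")
    corrected = _corrected_charges(background_readings, _as_chip_map(chips))
    return float(corrected.mean())


def reading_to_dose(
    reading: Reading,
    chip: TldChip,
    background: float,
    cal: CalibrationResult,
    background_in_dose: bool = False,
) -> DoseValue:
    """Convert one raw reading to water dose: D = (SF*r - b) * CF.

    Negative net signal (reading below background) is clamped to zero
    and flagged rather than reported as a negative dose.
    """
    if not chip.active:
        raise ValueError(f"chip {chip.chip_id!r} was rejected: {chip.reason}")
    if background_in_dose:
        dose = chip.sensitivity_factor * reading.charge - background * cal.cf
    else:
        dose = (chip.sensitivity_factor * reading.charge - background) * cal.cf
    if dose < 0:
        return DoseValue(reading.chip_id, reading.session, 0.0, clamped=True)
    return DoseValue(reading.chip_id, reading.session, float(dose))


@dataclass(frozen=True)
class QcReport:
    """Repeat-scan consistency report."""

    passed: tuple[str, ...]
    flagged: tuple[str, ...]
    relative_difference: dict[str, float] = field(default_factory=dict)


def repeat_scan_qc(
    doses_run1: dict[str, float], doses_run2: dict[str, float]
) -> QcReport:
    """Flag chips whose two repeat-scan doses differ by more than 20%.

    The relative difference is |d1 - d2| / mean(d1, d2).  A zero mean
    with a nonzero difference is flagged unconditionally.  Flagged chips
    require a third measurement (see :func:`resolve_triplicate`).
    """
    if set(doses_run1) != set(doses_run2):
        raise ValueError("repeat runs must cover the same chip set")
    passed, flagged, rel = [], [], {}
    for cid in sorted(doses_run1):
        d1, d2 = doses_run1[cid], doses_run2[cid]
        m = (d1 + d2) / 2.0
        if m == 0.0:
            if d1 != d2:
                flagged.append(cid)
                rel[cid] = float("inf")
            else:
                passed.append(cid)
                rel[cid] = 0.0
            continue
        r = abs(d1 - d2) / m
        rel[cid] = r
        (flagged if r > REPEAT_QC_THRESHOLD else passed).append(cid)
    return QcReport(tuple(passed), tuple(flagged), rel)


def resolve_triplicate(d1: float, d2: float, d3: float) -> tuple[float, float]:
    """Keep the two of three repeat measurements closest to their median.

    The run farthest from the median of the three is treated as the
    outlier and dropped.
    """
    vals = np.asarray([d1, d2, d3], dtype=float)
    med = float(np.median(vals))
    drop = int(np.argmax(np.abs(vals - med)))
    kept = np.delete(vals, drop)
    return float(kept[0]), float(kept[1])


def _as_chip_map(chips: dict[str, TldChip] | list[TldChip]) -> dict[str, TldChip]:
    if isinstance(chips, dict):
        return chips
    return {c.chip_id: c for c in chips}


def readings_from_csv(path) -> list[Reading]:
    """Read a readings.csv (chip_id, session, charge_nc) into Reading records."""
    df = pd.read_csv(path)
    missing = {"chip_id", "session", "charge_nc"} - set(df.columns)
    if missing:
        raise ValueError(f"readings file missing columns {sorted(missing)}")
    return [
        Reading(str(r.chip_id), str(r.session), float(r.charge_nc))
        for r in df.itertuples()
    ]


def chips_to_csv(chips: list[TldChip], path) -> None:
    pd.DataFrame(
        [
            {
                "chip_id": c.chip_id,
                "sf": c.sensitivity_factor,
                "status": c.status,
                "reason": c.reason or "",
            }
            for c in chips
        ]
    ).to_csv(path, index=False)
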