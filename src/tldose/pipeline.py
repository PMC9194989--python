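"""End-to-end campaign processing: raw readings to effective doses.

Glue over the stage modules: sensitivity-corrected charge-to-dose
conversion, repeat-scan consistency, organ aggregation with
spectrum-weighted tissue conversion, skeletal marrow dosimetry, and
ICRP 103 effective dose, all per protocol.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .coefficients import CoefficientSet, load_coefficients
from .effective_dose import EffectiveDoseResult, Protocol, effective_dose
from .organ_dosimetry import (
    OrganDoseResult,
    PlacementMap,
    colon_dose,
    muscle_dose,
    organ_mean_dose,
    skin_dose,
)
from .skeletal_dosimetry import marrow_dose_results
from .spectrum import SpectrumModel, generate_spectrum, tissue_conversion_factor
from .tld_processing import (
    CalibrationResult,
    QcReport,
    Reading,
    TldChip,
    background_level,
    compute_calibration_factor,
    reading_to_dose,
    repeat_scan_qc,
)

__all__ = ["CampaignResult", "process_campaign", "chip_doses_frame"]

_SPECIAL_ORGANS = {"colon", "skeleton", "skin"}


@dataclass
class CampaignResult:
    protocol: Protocol
    organ_results: dict[str, OrganDoseResult]  # mGy (tissue-converted)
    effective: dict[str, EffectiveDoseResult]  # per sex
    chip_doses: pd.DataFrame  # chip_id, session, dose (mGy, water)
    calibration: CalibrationResult
    background_nc: float
    qc: QcReport

    def normalized_organ_results(self) -> dict[str, OrganDoseResult]:
        """Organ results divided by the protocol's CTDI_vol (mGy/mGy)."""
        return {
            organ: res.scaled(1.0 / self.protocol.ctdi_vol)
            for organ, res in self.organ_results.items()
        }


def chip_doses_frame(
    readings: pd.DataFrame,
    chips: list[TldChip],
    scan_sessions: tuple[str, ...],
    background: float,
    cal: CalibrationResult,
) -> pd.DataFrame:
    """Per-chip water doses (mGy) for the scan sessions."""
    chip_map = {c.chip_id: c for c in chips}
    rows = []
    for r in readings.itertuples():
        if str(r.session) not in scan_sessions:
            continue
        dv = reading_to_dose(
            Reading(str(r.chip_id), str(r.session), float(r.charge_nc)),
            chip_map[str(r.chip_id)],
            background,
            cal,
        )
        rows.append(
            {
                "chip_id": dv.chip_id,
                "session": dv.session,
                "dose": dv.dose * 1000.0,  # Gy -> mGy
                "clamped": dv.clamped,
            }
        )
    return pd.DataFrame(rows)


def process_campaign(
    readings: pd.DataFrame,
    chips: list[TldChip],
    placement: PlacementMap,
    protocol: Protocol,
    coeffs: CoefficientSet | None = None,
    spec: SpectrumModel | None = None,
    scan_sessions: tuple[str, ...] = ("run1", "run2"),
    nominal_calibration_dose: float = 0.5,
) -> CampaignResult:
    """Process one protocol's raw readings into organ and effective doses.

    ``readings`` is long-form (chip_id, session, charge_nc) containing
    the scan sessions plus the special ``"background"`` and
    ``"calibration"`` sessions.  ``spec`` defaults to the simplified
    analytic spectrum at the protocol's tube potential.
    """
    coeffs = coeffs if coeffs is not None else load_coefficients()
    if spec is None:
        spec = generate_spectrum(protocol.kvp, [("Al", 5.0)], coeffs=coeffs)

    def session_readings(name: str) -> list[Reading]:
        sel = readings["session"] == name
        return [
            Reading(str(r.chip_id), str(r.session), float(r.charge_nc))
            for r in readings.loc[sel].itertuples()
        ]

    cal = compute_calibration_factor(
        session_readings("calibration"), chips, nominal_calibration_dose
    )
    background = background_level(session_readings("background"), chips)
    doses = chip_doses_frame(readings, chips, scan_sessions, background, cal)

    # repeat-scan consistency between the first two sessions
    if len(scan_sessions) >= 2:
        d1 = doses[doses["session"] == scan_sessions[0]].set_index("chip_id")["dose"]
        d2 = doses[doses["session"] == scan_sessions[1]].set_index("chip_id")["dose"]
        common = sorted(set(d1.index) & set(d2.index))
        qc = repeat_scan_qc(
            {c: float(d1[c]) for c in common}, {c: float(d2[c]) for c in common}
        )
    else:
        qc = QcReport(tuple(sorted(doses["chip_id"].unique())), ())

    water = coeffs.tissues["water"]
    conv_cache: dict[str, float] = {}

    def conv_for(organ: str) -> float:
        table = coeffs.tissue_for_organ(organ)
        if table.tissue_name not in conv_cache:
            conv_cache[table.tissue_name] = tissue_conversion_factor(spec, table, water)
        return conv_cache[table.tissue_name]

    organ_results: dict[str, OrganDoseResult] = {}
    for organ in placement.organs:
        if organ in _SPECIAL_ORGANS:
            continue
        organ_results[organ] = organ_mean_dose(
            doses, placement, organ, conv=conv_for(organ)
        )

    # colon: per-segment means combined by mass fraction
    segment_results = {
        seg: _subset_mean(doses, placement.chips_for("colon", seg), conv_for("colon"), seg)
        for seg in coeffs.colon.fractions
    }
    organ_results["colon"] = colon_dose(segment_results, coeffs.colon)

    organ_results["skin"] = skin_dose(doses, placement, conv=conv_for("skin"))
    organ_results["muscle"] = muscle_dose(doses, placement, conv=conv_for("muscle"))

    # skeletal compartments from per-site water doses
    site_water: dict[str, tuple[float, float]] = {}
    n_marrow = 0
    for site in coeffs.skeleton:
        vals = _chip_values(doses, placement.chips_for("skeleton", site))
        if vals.size == 0:
            raise ValueError(f"no chips for skeletal site {site!r}")
        site_water[site] = (
            float(vals.mean()),
            float(vals.std(ddof=1)) if vals.size > 1 else 0.0,
        )
        n_marrow += int(vals.size)
    rbm, shallow = marrow_dose_results(site_water, coeffs, spec)
    organ_results["active_marrow"] = OrganDoseResult(
        rbm.organ, rbm.mean_dose, rbm.sd, n_marrow
    )
    organ_results["bone_surface"] = OrganDoseResult(
        shallow.organ, shallow.mean_dose, shallow.sd, n_marrow
    )

    # the spine skeletal chips double as the soft-tissue "spine" row
    spine_vals = _chip_values(doses, placement.chips_for("skeleton", "spine"))
    organ_results["spine"] = OrganDoseResult(
        "spine",
        float(spine_vals.mean()) * conv_for("spine"),
        (float(spine_vals.std(ddof=1)) if spine_vals.size > 1 else 0.0)
        * conv_for("spine"),
        int(spine_vals.size),
    )

    effective = {
        sex: effective_dose(
            organ_results, coeffs.weights, sex, ctdi_vol=protocol.ctdi_vol
        )
        for sex in ("male", "female")
    }

    return CampaignResult(
        protocol=protocol,
        organ_results=organ_results,
        effective=effective,
        chip_doses=doses,
        calibration=cal,
        background_nc=background,
        qc=qc,
    )


def _chip_values(doses: pd.DataFrame, chip_ids: list[str]) -> np.ndarray:
    sel = doses["chip_id"].astype(str).isin([str(c) for c in chip_ids])
    return doses.loc[sel, "dose"].to_numpy(float)


def _subset_mean(
    doses: pd.DataFrame, chip_ids: list[str], conv: float, label: str
) -> OrganDoseResult:
    vals = _chip_values(doses, chip_ids) * conv
    if vals.size == 0:
        raise ValueError(f"no measurements for {label!r}")
    sd = float(vals.std(ddof=1)) if vals.size > 1 else 0.0
    return OrganDoseResult(label, float(vals.mean()), sd, int(vals.size))
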