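"""AKI staging, inclusion-time determination and exclusion screening.

Staging follows the consensus creatinine and urine-output criteria,
approximated on a daily grid:

* creatinine stage: 1 if the ratio to the patient's baseline value is
  >= 1.5, 2 if >= 2.0, 3 if >= 3.0 or the absolute value is >= 4.0 mg/dl;
* urine-output stage 2: one day with mean rate < 0.5 ml/kg/h (the >= 12 h
  window is necessarily contained in such a day);
* urine-output stage 3: a full 24 h below 0.3 ml/kg/h, i.e. the current
  and the previous day both have mean rate < 0.3 (confirmed 24-36 h after
  oliguria onset).

The combined stage is the maximum of the two components and the inclusion
day is the first day on which the combined stage reaches 2.  Baseline
creatinine is the first recorded value per patient.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

EXCLUSION_AGE = "age"
EXCLUSION_RRT_HISTORY = "rrt-history"
EXCLUSION_MISSING_WEIGHT = "missing baseline weight"
EXCLUSION_DNR = "dnr-restriction"
EXCLUSION_MISSING_FIELD = "missing-field"


@dataclass
class StagingResult:
    """Per-patient daily AKI stages and inclusion day."""

    patient_id: object
    days: np.ndarray
    creatinine_stage: np.ndarray
    urine_output_stage: np.ndarray
    combined_stage: np.ndarray = field(init=False)
    inclusion_day: int | None = field(init=False)

    def __post_init__(self) -> None:
        self.combined_stage = np.maximum(self.creatinine_stage, self.urine_output_stage)
        hits = np.nonzero(self.combined_stage >= 2)[0]
        self.inclusion_day = int(self.days[hits[0]]) if hits.size else None


def creatinine_stage(creatinine: np.ndarray, baseline: float) -> np.ndarray:
    """Daily creatinine stage (0-3) relative to `baseline`."""
    if not np.isfinite(baseline) or baseline <= 0:
        raise ValueError("baseline creatinine must be positive and finite")
    creatinine = np.asarray(creatinine, dtype=float)
    ratio = creatinine / baseline
    stage = np.zeros(creatinine.shape, dtype=np.int8)
    stage[ratio >= 1.5] = 1
    stage[ratio >= 2.0] = 2
    stage[(ratio >= 3.0) | (creatinine >= 4.0)] = 3
    return stage


def urine_output_stage(urine_output_rate: np.ndarray) -> np.ndarray:
    """Daily urine-output stage (0, 2 or 3) from daily mean rates.

    Stage 1 (< 0.5 ml/kg/h for 6-12 h) is not resolvable on a daily grid
    and is never emitted.
    """
    uo = np.asarray(urine_output_rate, dtype=float)
    if np.any(uo < 0):
        raise ValueError("urine output rate must be >= 0")
    stage = np.zeros(uo.shape, dtype=np.int8)
    stage[uo < 0.5] = 2
    below_03 = uo < 0.3
    sustained = below_03.copy()
    sustained[1:] &= below_03[:-1]
    sustained[0] = False  # no prior day: 24-h window cannot be confirmed
    stage[sustained] = 3
    return stage


def stage_patient(
    days: np.ndarray,
    creatinine: np.ndarray,
    urine_output_rate: np.ndarray,
    patient_id: object,
    baseline_creatinine: float | None = None,
) -> StagingResult:
    """Stage a single patient's daily trajectory."""
    if baseline_creatinine is None:
        if len(creatinine) == 0 or not np.isfinite(creatinine[0]):
            raise ValueError(f"missing baseline creatinine for patient {patient_id}")
        baseline_creatinine = float(creatinine[0])
    return StagingResult(
        patient_id=patient_id,
        days=np.asarray(days),
        creatinine_stage=creatinine_stage(np.asarray(creatinine), baseline_creatinine),
        urine_output_stage=urine_output_stage(np.asarray(urine_output_rate)),
    )


def compute_kdigo_stages(
    person_days: pd.DataFrame,
    baseline_creatinine: dict | pd.Series | None = None,
) -> dict[object, StagingResult]:
    """Stage every patient in a long person-day table.

    Parameters
    ----------
    person_days:
        long table with columns patient_id, day, creatinine,
        urine_output_rate (sorted or sortable by day within patient).
    baseline_creatinine:
        optional per-patient baseline creatinine; defaults to the first
        recorded value.

    Returns
    -------
    dict mapping patient_id -> StagingResult.
    """
    results: dict[object, StagingResult] = {}
    for pid, grp in person_days.sort_values("day").groupby("patient_id", sort=False):
        base = None
        if baseline_creatinine is not None:
            base = baseline_creatinine.get(pid) if hasattr(baseline_creatinine, "get") else None
        results[pid] = stage_patient(
            grp["day"].to_numpy(),
            grp["creatinine"].to_numpy(dtype=float),
            grp["urine_output_rate"].to_numpy(dtype=float),
            patient_id=pid,
            baseline_creatinine=base,
        )
    return results


def apply_exclusion_criteria(baseline: pd.DataFrame) -> pd.DataFrame:
    """Screen the baseline table; returns per-patient eligibility flags.

    A patient is eligible iff age > 18, no dialysis history, baseline
    weight present and no registered do-not-resuscitate restriction on
    starting dialysis.  Missing flag fields are treated as exclusions
    (reason "missing-field").

    Returns a table with columns patient_id, eligible, reasons
    (semicolon-joined codes, empty when eligible).
    """
    rows = []
    for _, row in baseline.iterrows():
        reasons: list[str] = []
        age = row.get("age")
        if age is None or (isinstance(age, float) and np.isnan(age)):
            reasons.append(EXCLUSION_MISSING_FIELD)
        elif age <= 18:
            reasons.append(EXCLUSION_AGE)
        weight = row.get("weight")
        if weight is None or (isinstance(weight, float) and np.isnan(weight)):
            reasons.append(EXCLUSION_MISSING_WEIGHT)
        for col, code in (
            ("rrt_history_flag", EXCLUSION_RRT_HISTORY),
            ("dnr_restriction_flag", EXCLUSION_DNR),
        ):
            val = row.get(col)
            if val is None or (isinstance(val, float) and np.isnan(val)):
                reasons.append(EXCLUSION_MISSING_FIELD)
            elif bool(val):
                reasons.append(code)
        rows.append(
            {
                "patient_id": row["patient_id"],
                "eligible": not reasons,
                "reasons": ";".join(reasons),
            }
        )
    return pd.DataFrame(rows, columns=["patient_id", "eligible", "reasons"])
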