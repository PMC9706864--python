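"""Follow-up data arrays: the pipeline's internal working representation.

Long person-day tables are convenient on disk but slow to scan per regime.
This module converts a staged, eligibility-screened cohort into padded
``(n_patients, horizon)`` matrices indexed by follow-up day (day 0 = the
day the stage >= 2 inclusion criteria were first met).  Absorbing staging
flags are computed over the *full* recorded history, including days before
inclusion.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import eligibility
from .synthetic import EVENT_DEATH, EVENT_DISCHARGE, EVENT_NONE

#: sentinel for "on dialysis already at inclusion"
PRE_INCLUSION_INIT = -2

_CORE_DAILY = [
    "creatinine",
    "potassium",
    "ph",
    "urine_output_rate",
    "sofa",
]


@dataclass
class FollowUpData:
    """Padded per-patient follow-up arrays for the eligible, included cohort.

    All ``(n, horizon)`` matrices are indexed by follow-up day ``u``;
    cells with ``valid[p, u]`` False are padding.  A patient's rows run
    from u = 0 to the day of their event, their artificial end of
    follow-up (``horizon - 1``) or the end of their recorded data.
    """

    horizon: int
    patient_ids: np.ndarray  # (n,)
    inclusion_day: np.ndarray  # (n,) absolute day of inclusion
    n_days: np.ndarray  # (n,) number of follow-up rows
    valid: np.ndarray  # (n, horizon) bool
    event_type: np.ndarray  # (n,) 0 none / 1 death / 2 discharge
    event_u: np.ndarray  # (n,) follow-up day of the event, -1 if none
    obs_init_u: np.ndarray  # (n,) observed start day, -1 never, -2 pre-inclusion
    covariates: dict[str, np.ndarray] = field(default_factory=dict)  # (n, horizon)
    baseline: pd.DataFrame | None = None  # one row per patient, aligned

    @property
    def n_patients(self) -> int:
        return len(self.patient_ids)

    def require(self, *names: str) -> tuple[np.ndarray, ...]:
        missing = [nm for nm in names if nm not in self.covariates]
        if missing:
            raise KeyError(f"follow-up covariate(s) not available: {missing}")
        return tuple(self.covariates[nm] for nm in names)


def build_followup(
    baseline: pd.DataFrame,
    person_days: pd.DataFrame,
    horizon: int = 30,
    extra_daily_columns: tuple[str, ...] = (),
) -> FollowUpData:
    """Stage, screen and re-index a cohort onto the follow-up grid.

    Applies the exclusion criteria, computes daily AKI stages over the full
    recorded history, keeps patients whose combined stage reaches 2, and
    relabels their days relative to the inclusion day.  Events occurring
    after ``horizon - 1`` follow-up days are administratively ignored
    (the patient counts as still in the ICU at the horizon).
    """
    elig = eligibility.apply_exclusion_criteria(baseline)
    eligible_ids = set(elig.loc[elig["eligible"], "patient_id"])

    df = person_days.sort_values(["patient_id", "day"], kind="mergesort").copy()
    df = df[df["patient_id"].isin(eligible_ids)]
    g = df.groupby("patient_id", sort=False)

    creat = df["creatinine"].to_numpy(dtype=float)
    base_creat = g["creatinine"].transform("first").to_numpy(dtype=float)
    ratio = creat / base_creat
    uo = df["urine_output_rate"].to_numpy(dtype=float)

    creat_crit = (ratio >= 2.0) | (creat >= 4.0)
    uo_lt_05 = uo < 0.5
    uo_lt_03 = uo < 0.3
    prev_uo_lt_03 = g["urine_output_rate"].shift(1).to_numpy(dtype=float) < 0.3
    uo_stage3 = uo_lt_03 & prev_uo_lt_03

    df["_creat_ratio"] = ratio
    df["_creat_crit_met"] = creat_crit.astype(bool)
    df["_uo_lt_05"] = uo_lt_05
    df["_uo_stage3"] = uo_stage3
    g = df.groupby("patient_id", sort=False)
    df["_creat_crit_met"] = g["_creat_crit_met"].cummax()
    df["_olig2_met"] = g["_uo_lt_05"].cummax()
    combined2 = df["_creat_crit_met"].to_numpy() | df["_olig2_met"].to_numpy() | df["_uo_stage3"].to_numpy()
    df["_combined2"] = combined2

    # inclusion day: first day with combined stage >= 2
    incl = (
        df.loc[df["_combined2"], :]
        .groupby("patient_id", sort=False)["day"]
        .min()
        .rename("inclusion_day")
    )
    df = df.merge(incl, on="patient_id", how="inner")
    df["_u"] = df["day"] - df["inclusion_day"]
    df = df[(df["_u"] >= 0) & (df["_u"] < horizon)]

    pid_order = df["patient_id"].drop_duplicates().to_numpy()
    n = len(pid_order)
    pid_index = pd.Series(np.arange(n), index=pid_order)
    rows_p = pid_index[df["patient_id"]].to_numpy()
    rows_u = df["_u"].to_numpy(dtype=np.int64)

    valid = np.zeros((n, horizon), dtype=bool)
    valid[rows_p, rows_u] = True

    def _scatter(values, dtype=float, fill=np.nan):
        out = np.full((n, horizon), fill, dtype=dtype)
        out[rows_p, rows_u] = values
        return out

    covs: dict[str, np.ndarray] = {}
    for col in _CORE_DAILY:
        covs[col] = _scatter(df[col].to_numpy(dtype=float))
    for col in extra_daily_columns:
        if col in df.columns:
            covs[col] = _scatter(df[col].to_numpy(dtype=float))
    covs["creat_ratio"] = _scatter(df["_creat_ratio"].to_numpy(dtype=float))
    # threshold indicators for the initiation/weight model
    k = df["potassium"].to_numpy(dtype=float)
    ph = df["ph"].to_numpy(dtype=float)
    covs["k_ge_60"] = _scatter(k >= 6.0, dtype=bool, fill=False)
    covs["k_ge_65"] = _scatter(k >= 6.5, dtype=bool, fill=False)
    covs["k_ge_70"] = _scatter(k >= 7.0, dtype=bool, fill=False)
    covs["ph_lt_720"] = _scatter(ph < 7.20, dtype=bool, fill=False)
    covs["ph_lt_715"] = _scatter(ph < 7.15, dtype=bool, fill=False)
    covs["ph_lt_700"] = _scatter(ph < 7.00, dtype=bool, fill=False)
    covs["creat_crit_met"] = _scatter(df["_creat_crit_met"].to_numpy(), dtype=bool, fill=False)
    covs["olig2_met"] = _scatter(df["_olig2_met"].to_numpy(), dtype=bool, fill=False)
    covs["uo_lt_05"] = _scatter(df["_uo_lt_05"].to_numpy(), dtype=bool, fill=False)
    covs["uo_stage3"] = _scatter(df["_uo_stage3"].to_numpy(), dtype=bool, fill=False)

    # --- events ---
    event_type = np.zeros(n, dtype=np.int8)
    event_u = np.full(n, -1, dtype=np.int64)
    if "event_today" in df.columns:
        ev_rows = df[df["event_today"].isin([EVENT_DEATH, EVENT_DISCHARGE])]
        p = pid_index[ev_rows["patient_id"]].to_numpy()
        event_u[p] = ev_rows["_u"].to_numpy(dtype=np.int64)
        event_type[p] = np.where(ev_rows["event_today"].to_numpy() == EVENT_DEATH, 1, 2)

    # --- observed initiation ---
    obs_init_u = np.full(n, -1, dtype=np.int64)
    if "rrt_started_today" in df.columns:
        st_rows = df[df["rrt_started_today"].astype(bool)]
        first_start = st_rows.groupby("patient_id", sort=False)["_u"].min()
        p = pid_index[first_start.index].to_numpy()
        obs_init_u[p] = first_start.to_numpy(dtype=np.int64)
    if "rrt_active" in df.columns:
        # active on follow-up day 0 without a recorded start: pre-inclusion start
        day0 = df[df["_u"] == 0]
        active0 = day0["rrt_active"].astype(bool).to_numpy()
        started0 = (
            day0["rrt_started_today"].astype(bool).to_numpy()
            if "rrt_started_today" in day0.columns
            else np.zeros(len(day0), dtype=bool)
        )
        p = pid_index[day0["patient_id"]].to_numpy()
        pre = active0 & ~started0
        obs_init_u[p[pre]] = PRE_INCLUSION_INIT

    n_days = valid.sum(axis=1)
    incl_by_pid = incl.reindex(pid_order).to_numpy(dtype=np.int64)

    base_aligned = (
        baseline.set_index("patient_id").loc[pid_order].reset_index()
        if baseline is not None
        else None
    )

    return FollowUpData(
        horizon=horizon,
        patient_ids=pid_order,
        inclusion_day=incl_by_pid,
        n_days=n_days,
        valid=valid,
        event_type=event_type,
        event_u=event_u,
        obs_init_u=obs_init_u,
        covariates=covs,
        baseline=base_aligned,
    )
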