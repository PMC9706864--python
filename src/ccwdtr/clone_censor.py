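"""Cloning and artificial censoring.

One clone is created per (eligible patient, regime).  A clone is censored
at the first follow-up day on which the regime's prescription deviates
from the observed initiation behaviour: either the regime prescribes
initiation on a day the patient did not start (type a), or the patient
started on a day the regime prescribed nothing (type b).  Once a clone's
regime prescribes initiation on the very day the patient started, all
later days are automatically concordant (dialysis is absorbing).

An event occurring on the same day as a deviation takes precedence: the
clone experiences the event and is not counted as censored.

Two routes are provided: a vectorised matrix core used by the pipeline,
and long-format table operations (`expand_clones` / `apply_censoring`)
that walk each clone day by day through the scalar decision function.
The two must agree; the test suite compares them.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .followup import PRE_INCLUSION_INIT, FollowUpData, build_followup
from .regimes import DecisionState, Regime, prescribes_initiation, prescription_matrix

_STATE_COLS = [
    "creatinine",
    "potassium",
    "ph",
    "urine_output_rate",
    "sofa",
    "creat_ratio",
    "creat_crit_met",
    "olig2_met",
    "uo_stage3",
]


#: pseudo-regime that never prescribes initiation
NEVER_INITIATE = "never"


def prescriptions(fu: FollowUpData, regime: Regime | str) -> np.ndarray:
    """(n, horizon) boolean matrix of regime prescriptions on valid days."""
    if isinstance(regime, str):
        if regime != NEVER_INITIATE:
            raise ValueError(f"unknown pseudo-regime: {regime!r}")
        return np.zeros_like(fu.valid)
    mat = prescription_matrix(
        regime,
        fu.covariates["creat_crit_met"],
        fu.covariates["olig2_met"],
        fu.covariates["ph"],
        fu.covariates["potassium"],
        fu.covariates["uo_stage3"],
    )
    return mat & fu.valid


def effective_init_day(fu: FollowUpData) -> np.ndarray:
    """Observed initiation day with the pre-inclusion sentinel mapped to 0."""
    o = fu.obs_init_u.copy()
    o[o == PRE_INCLUSION_INIT] = 0
    return o


def censor_days_matrix(
    fu: FollowUpData, prescribed: np.ndarray, event_precedence: bool = False
) -> np.ndarray:
    """First deviation day per clone (-1 if never censored).

    The daily decision happens before that day's event, so by default a
    deviation censors the clone even when an event occurs the same day
    (the event is then not attributed to the clone).  With
    ``event_precedence=True`` a same-day event rescues the clone instead;
    this convention biases the weighted estimator upward and is kept only
    for comparison.
    """
    n, horizon = fu.valid.shape
    u = np.arange(horizon)[None, :]
    o = effective_init_day(fu)[:, None]

    dev = prescribed.copy()
    started_today = (o >= 0) & (u == o)
    dev[started_today.nonzero()] = ~prescribed[started_today.nonzero()]
    dev &= ~((o >= 0) & (u > o))  # concordant forever after a matched start
    dev &= fu.valid
    if event_precedence:
        has_event = fu.event_type > 0
        dev[has_event, fu.event_u[has_event]] = False

    any_dev = dev.any(axis=1)
    first = dev.argmax(axis=1)
    return np.where(any_dev, first, -1)


def clone_row_mask(fu: FollowUpData, censor_u: np.ndarray) -> np.ndarray:
    """Valid clone-day cells, keeping the censoring-day row itself."""
    horizon = fu.valid.shape[1]
    u = np.arange(horizon)[None, :]
    c = censor_u[:, None]
    return fu.valid & ((c < 0) | (u <= c))


def uncensored_mask(fu: FollowUpData, censor_u: np.ndarray) -> np.ndarray:
    """Clone-day cells still uncensored (the censoring day excluded)."""
    horizon = fu.valid.shape[1]
    u = np.arange(horizon)[None, :]
    c = censor_u[:, None]
    return fu.valid & ((c < 0) | (u < c))


# ---------------------------------------------------------------------------
# long-format contract operations (independent day-by-day walker)
# ---------------------------------------------------------------------------


def expand_clones(
    baseline: pd.DataFrame,
    person_days: pd.DataFrame,
    regimes: list[Regime],
    horizon: int = 30,
    fu: FollowUpData | None = None,
) -> pd.DataFrame:
    """One clone trajectory per (eligible included patient, regime).

    Days are re-indexed to follow-up time (day 0 = inclusion).  The
    source tables are not modified.  The returned table carries the
    decision-state columns needed to apply censoring, plus
    ``uncensored_flag`` (all True), ``event`` and a ``weight`` placeholder.
    """
    if fu is None:
        fu = build_followup(baseline, person_days, horizon=horizon)
    rows_p, rows_u = np.nonzero(fu.valid)
    base = pd.DataFrame(
        {
            "patient_id": fu.patient_ids[rows_p],
            "day": rows_u,
        }
    )
    for col in _STATE_COLS:
        if col in fu.covariates:
            base[col] = fu.covariates[col][rows_p, rows_u]
    o = fu.obs_init_u[rows_p]
    base["rrt_started_today"] = (o >= 0) & (rows_u == o)
    eff_o = effective_init_day(fu)[rows_p]
    base["rrt_active"] = (eff_o >= 0) & (rows_u >= eff_o)
    ev = np.full(len(rows_p), "none", dtype=object)
    has_ev = (fu.event_type[rows_p] > 0) & (rows_u == fu.event_u[rows_p])
    ev[has_ev] = np.where(fu.event_type[rows_p][has_ev] == 1, "death", "discharge")
    base["event"] = ev

    parts = []
    for regime in regimes:
        part = base.copy()
        part.insert(1, "regime_index", regime.index)
        parts.append(part)
    out = pd.concat(parts, ignore_index=True)
    out["uncensored_flag"] = True
    out["weight"] = np.nan
    return out


def apply_censoring(
    clone_table: pd.DataFrame, regimes: list[Regime], event_precedence: bool = False
) -> pd.DataFrame:
    """Walk each clone day by day and censor at the first deviation.

    Returns a new table in which rows after a clone's censoring day are
    dropped and the censoring-day row has ``uncensored_flag`` False; a
    ``censor_day`` column holds the deviation day (NaN if uncensored).
    See `censor_days_matrix` for the same-day event convention.
    """
    by_index = {r.index: r for r in regimes}
    out_parts = []
    for (pid, ridx), grp in clone_table.groupby(["patient_id", "regime_index"], sort=False):
        regime = by_index[int(ridx)]
        grp = grp.sort_values("day")
        censor_day: float = np.nan
        started = False
        for _, row in grp.iterrows():
            day = int(row["day"])
            if started:
                break
            state = DecisionState(
                day=day,
                creatinine_criterion_met=bool(row["creat_crit_met"]),
                oliguric_stage2_met=bool(row["olig2_met"]),
                min_ph_last_24h=float(row["ph"]),
                max_k_last_24h=float(row["potassium"]),
                oliguric_stage3_last_24h=bool(row["uo_stage3"]),
            )
            prescribed = prescribes_initiation(regime, state)
            observed_start = bool(row["rrt_started_today"])
            if prescribed != observed_start:
                if not (event_precedence and row["event"] != "none"):
                    censor_day = day
                break
            if observed_start:
                started = True
        keep = grp if np.isnan(censor_day) else grp[grp["day"] <= censor_day]
        keep = keep.copy()
        keep["censor_day"] = censor_day
        if not np.isnan(censor_day):
            keep.loc[keep["day"] == censor_day, "uncensored_flag"] = False
        out_parts.append(keep)
    return pd.concat(out_parts, ignore_index=True)
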