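"""Weighted discrete-time Aalen-Johansen estimation with competing events.

Estimator (daily product-limit form): at each follow-up day ``u`` the
weighted hazard of event ``k`` is the weighted count of clones
experiencing ``k`` on day ``u`` divided by the weighted count at risk at
the start of day ``u``; overall in-ICU survival is the running product of
one minus the total hazard, and the cumulative incidence of ``k`` at day
``t`` accumulates survival-weighted hazards up to ``t``.  With unit
weights and a single event type this reduces exactly to one minus the
Kaplan-Meier estimator.

Pointwise variance is available via the infinitesimal jackknife (influence
contributions aggregated per source patient, weights treated as fixed) or
a patient-level bootstrap in which all clones of a patient move together.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .followup import FollowUpData
from .clone_censor import effective_init_day, uncensored_mask

Z975 = 1.959963984540054


@dataclass
class IncidenceCurve:
    """Cumulative incidence curves on the daily grid 0..horizon."""

    days: np.ndarray
    cif_death: np.ndarray
    cif_discharge: np.ndarray
    surv: np.ndarray
    n_risk: np.ndarray  # unweighted clones at risk per event day
    w_risk: np.ndarray  # weighted risk-set size per event day
    hazard_death: np.ndarray = field(repr=False, default=None)
    hazard_discharge: np.ndarray = field(repr=False, default=None)
    var_death: np.ndarray | None = None
    var_discharge: np.ndarray | None = None

    @property
    def horizon(self) -> int:
        return len(self.days) - 1

    def mortality(self, day: int | None = None) -> float:
        day = self.horizon if day is None else day
        return float(self.cif_death[day])

    def ci_death(self, day: int | None = None) -> tuple[float, float]:
        if self.var_death is None:
            raise ValueError("variance has not been estimated")
        day = self.horizon if day is None else day
        se = float(np.sqrt(self.var_death[day]))
        p = self.cif_death[day]
        return (max(0.0, p - Z975 * se), min(1.0, p + Z975 * se))

    def to_frame(self) -> pd.DataFrame:
        h = self.horizon
        return pd.DataFrame(
            {
                "day": self.days,
                "cif_death": self.cif_death,
                "cif_discharge": self.cif_discharge,
                "surv": self.surv,
                "var_death": np.full(h + 1, np.nan) if self.var_death is None else self.var_death,
                "var_discharge": (
                    np.full(h + 1, np.nan) if self.var_discharge is None else self.var_discharge
                ),
                "n_risk": np.append(self.n_risk, 0),
                "w_risk": np.append(self.w_risk, 0.0),
            }
        )

    def check_invariants(self, atol: float = 1e-9) -> None:
        total = self.cif_death + self.cif_discharge + self.surv
        if np.max(np.abs(total - 1.0)) > atol:
            raise AssertionError("CIF additivity violated")
        for cif in (self.cif_death, self.cif_discharge):
            if np.any(np.diff(cif) < -atol) or cif.min() < -atol or cif.max() > 1 + atol:
                raise AssertionError("CIF monotonicity/range violated")


def _hazards(y: np.ndarray, n1: np.ndarray, n2: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    h = len(y)
    later_events = (np.cumsum((n1 + n2)[::-1])[::-1]) > 0
    empty = (y <= 0) & later_events
    if np.any(empty):
        raise ValueError(f"empty risk set at day {int(np.nonzero(empty)[0][0])} with later events")
    with np.errstate(divide="ignore", invalid="ignore"):
        h1 = np.where(y > 0, n1 / y, 0.0)
        h2 = np.where(y > 0, n2 / y, 0.0)
    return h1, h2


def _curves_from_hazards(h1: np.ndarray, h2: np.ndarray):
    s_run = np.cumprod(1.0 - h1 - h2)
    s_prev = np.concatenate([[1.0], s_run[:-1]])
    cif1 = np.cumsum(s_prev * h1)
    cif2 = np.cumsum(s_prev * h2)
    # extend to the closing grid point (no events on day `horizon`)
    return (
        np.append(cif1, cif1[-1]),
        np.append(cif2, cif2[-1]),
        np.append(s_run, s_run[-1]),
        s_prev,
    )


def aalen_johansen_matrices(
    risk: np.ndarray,
    d_death: np.ndarray,
    d_discharge: np.ndarray,
    weight: np.ndarray,
) -> IncidenceCurve:
    """Weighted Aalen-Johansen from clone-day indicator matrices.

    ``risk``, ``d_death``, ``d_discharge`` are (n_clones, horizon) boolean
    matrices; ``weight`` holds the cumulative IPC weight per clone-day
    (ignored where ``risk`` is False).
    """
    w = np.where(risk, np.nan_to_num(weight, nan=0.0), 0.0)
    if np.any(w < 0):
        raise ValueError("negative weights are not allowed")
    if not np.all(np.isfinite(w)):
        raise ValueError("weights must be finite")
    y = w.sum(axis=0)
    n1 = (w * d_death).sum(axis=0)
    n2 = (w * d_discharge).sum(axis=0)
    h1, h2 = _hazards(y, n1, n2)
    cif1, cif2, surv, _ = _curves_from_hazards(h1, h2)
    horizon = risk.shape[1]
    return IncidenceCurve(
        days=np.arange(horizon + 1),
        cif_death=cif1,
        cif_discharge=cif2,
        surv=surv,
        n_risk=risk.sum(axis=0),
        w_risk=y,
        hazard_death=h1,
        hazard_discharge=h2,
    )


def ij_variance_matrices(
    risk: np.ndarray,
    d_death: np.ndarray,
    d_discharge: np.ndarray,
    weight: np.ndarray,
    curve: IncidenceCurve,
    patient_index: np.ndarray | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Infinitesimal-jackknife pointwise variance of both CIFs.

    Per-clone influence contributions to each daily hazard are propagated
    through the product-limit recursion, summed over the clones of each
    source patient, and the variance is the sum of squared patient-level
    influences.  Weights are treated as fixed.
    """
    n, horizon = risk.shape
    w = np.where(risk, np.nan_to_num(weight, nan=0.0), 0.0)
    y = w.sum(axis=0)
    h1 = curve.hazard_death
    h2 = curve.hazard_discharge
    h_tot = h1 + h2
    s_prev = np.concatenate([[1.0], np.cumprod(1.0 - h_tot)[:-1]])

    with np.errstate(divide="ignore", invalid="ignore"):
        inv_y = np.where(y > 0, 1.0 / y, 0.0)
    # influence of clone i on hazard_k(u)
    a1 = w * (d_death - h1[None, :]) * inv_y[None, :] * risk
    a2 = w * (d_discharge - h2[None, :]) * inv_y[None, :] * risk
    with np.errstate(divide="ignore", invalid="ignore"):
        denom = np.where(h_tot < 1.0, 1.0 - h_tot, np.inf)
    b = (a1 + a2) / denom[None, :]
    b_cum_prev = np.concatenate(
        [np.zeros((n, 1)), np.cumsum(b, axis=1)[:, :-1]], axis=1
    )  # B_i(u-1)

    psi1 = np.cumsum(s_prev[None, :] * (a1 - h1[None, :] * b_cum_prev), axis=1)
    psi2 = np.cumsum(s_prev[None, :] * (a2 - h2[None, :] * b_cum_prev), axis=1)

    if patient_index is not None:
        n_pat = int(patient_index.max()) + 1
        agg1 = np.zeros((n_pat, horizon))
        agg2 = np.zeros((n_pat, horizon))
        np.add.at(agg1, patient_index, psi1)
        np.add.at(agg2, patient_index, psi2)
        psi1, psi2 = agg1, agg2

    var1 = np.sum(psi1**2, axis=0)
    var2 = np.sum(psi2**2, axis=0)
    return np.append(var1, var1[-1]), np.append(var2, var2[-1])


def bootstrap_cif_samples(
    risk: np.ndarray,
    d_death: np.ndarray,
    d_discharge: np.ndarray,
    weight: np.ndarray,
    patient_index: np.ndarray,
    n_boot: int,
    rng: np.random.Generator,
) -> tuple[np.ndarray, np.ndarray]:
    """Patient-level bootstrap samples of both CIF curves.

    All clones of a patient are resampled together.  Returns two
    (n_boot, horizon + 1) arrays of CIF curves.
    """
    if n_boot < 2:
        raise ValueError("number of bootstrap resamples must be >= 2")
    w = np.where(risk, np.nan_to_num(weight, nan=0.0), 0.0)
    n_pat = int(patient_index.max()) + 1
    horizon = risk.shape[1]
    y_pat = np.zeros((n_pat, horizon))
    n1_pat = np.zeros((n_pat, horizon))
    n2_pat = np.zeros((n_pat, horizon))
    np.add.at(y_pat, patient_index, w)
    np.add.at(n1_pat, patient_index, w * d_death)
    np.add.at(n2_pat, patient_index, w * d_discharge)

    counts = rng.multinomial(n_pat, np.full(n_pat, 1.0 / n_pat), size=n_boot).astype(float)
    y_b = counts @ y_pat
    n1_b = counts @ n1_pat
    n2_b = counts @ n2_pat
    with np.errstate(divide="ignore", invalid="ignore"):
        h1 = np.where(y_b > 0, n1_b / y_b, 0.0)
        h2 = np.where(y_b > 0, n2_b / y_b, 0.0)
    s_run = np.cumprod(1.0 - h1 - h2, axis=1)
    s_prev = np.concatenate([np.ones((n_boot, 1)), s_run[:, :-1]], axis=1)
    cif1 = np.cumsum(s_prev * h1, axis=1)
    cif2 = np.cumsum(s_prev * h2, axis=1)
    cif1 = np.concatenate([cif1, cif1[:, -1:]], axis=1)
    cif2 = np.concatenate([cif2, cif2[:, -1:]], axis=1)
    return cif1, cif2


# ---------------------------------------------------------------------------
# matrix builders for the two estimands
# ---------------------------------------------------------------------------


def mortality_matrices(
    fu: FollowUpData, censor_u: np.ndarray
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """(risk, d_death, d_discharge) matrices for one regime's clones."""
    unc = uncensored_mask(fu, censor_u)
    n, horizon = unc.shape
    d1 = np.zeros((n, horizon), dtype=bool)
    d2 = np.zeros((n, horizon), dtype=bool)
    has1 = fu.event_type == 1
    has2 = fu.event_type == 2
    d1[has1, fu.event_u[has1]] = True
    d2[has2, fu.event_u[has2]] = True
    return unc, d1 & unc, d2 & unc


def initiation_matrices(
    fu: FollowUpData, prescribed: np.ndarray, censor_u: np.ndarray
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """(risk, d_init, d_competing) matrices for the initiation estimand.

    Initiation (on the regime-concordant start day) is the event of
    interest; death or discharge occurring before initiation is the
    competing event.  The within-day decision-before-event ordering means
    an initiation on the day of death still counts as an initiation.
    """
    unc = uncensored_mask(fu, censor_u)
    n, horizon = unc.shape
    o = effective_init_day(fu)
    u = np.arange(horizon)[None, :]

    started = o >= 0
    init_unc = np.zeros(n, dtype=bool)
    init_unc[started] = unc[started, np.clip(o[started], 0, horizon - 1)]
    d_init = np.zeros((n, horizon), dtype=bool)
    d_init[started & init_unc, o[started & init_unc]] = True

    ev = fu.event_u
    comp = (fu.event_type > 0) & ((o < 0) | (ev < o))
    comp_unc = np.zeros(n, dtype=bool)
    comp_unc[comp] = unc[comp, ev[comp]]
    d_comp = np.zeros((n, horizon), dtype=bool)
    d_comp[comp & comp_unc, ev[comp & comp_unc]] = True

    t_first = np.full(n, horizon, dtype=np.int64)
    t_first[started & init_unc] = o[started & init_unc]
    t_first[comp & comp_unc] = ev[comp & comp_unc]
    risk = unc & (u <= t_first[:, None])
    return risk, d_init, d_comp


# ---------------------------------------------------------------------------
# long-format (table) interfaces
# ---------------------------------------------------------------------------


def _table_to_matrices(clone_days: pd.DataFrame, weights: np.ndarray | None):
    df = clone_days
    if "uncensored_flag" in df.columns:
        df = df[df["uncensored_flag"].astype(bool)]
        if weights is not None:
            weights = np.asarray(weights, dtype=float)[
                clone_days["uncensored_flag"].astype(bool).to_numpy()
            ]
    if weights is None:
        weights = (
            df["weight"].to_numpy(dtype=float)
            if "weight" in df.columns and df["weight"].notna().all()
            else np.ones(len(df))
        )
    else:
        weights = np.asarray(weights, dtype=float)
    if np.any(weights < 0):
        raise ValueError("negative weights are not allowed")

    if "regime_index" in df.columns:
        clone_idx, clone_ids = pd.factorize(
            pd.Series(list(zip(df["patient_id"], df["regime_index"])))
        )
        pids = [c[0] for c in clone_ids]
    else:
        clone_idx, clone_ids = pd.factorize(df["patient_id"])
        pids = list(clone_ids)
    days = df["day"].to_numpy(dtype=np.int64)
    horizon = max(30, int(days.max()) + 1)
    n = len(clone_ids)
    risk = np.zeros((n, horizon), dtype=bool)
    w = np.zeros((n, horizon))
    d1 = np.zeros((n, horizon), dtype=bool)
    d2 = np.zeros((n, horizon), dtype=bool)
    risk[clone_idx, days] = True
    w[clone_idx, days] = weights
    ev = df["event"].to_numpy() if "event" in df.columns else df["event_today"].to_numpy()
    d1[clone_idx[ev == "death"], days[ev == "death"]] = True
    d2[clone_idx[ev == "discharge"], days[ev == "discharge"]] = True
    _, patient_index = np.unique(pids, return_inverse=True)
    return risk, d1, d2, w, patient_index


def weighted_aalen_johansen(
    clone_days: pd.DataFrame, weights: np.ndarray | None = None
) -> IncidenceCurve:
    """Weighted Aalen-Johansen from a long clone-day table.

    The table needs columns patient_id, day, event ("none"/"death"/
    "discharge"); weights come from the ``weight`` column, the
    ``weights`` argument (aligned to rows), or default to 1.
    """
    risk, d1, d2, w, _ = _table_to_matrices(clone_days, weights)
    return aalen_johansen_matrices(risk, d1, d2, w)


def estimate_variance(
    curve: IncidenceCurve,
    clone_days: pd.DataFrame,
    weights: np.ndarray | None = None,
    method: str = "infinitesimal-jackknife",
    n_boot: int = 500,
    seed: int | None = None,
) -> IncidenceCurve:
    """Attach pointwise variance (and thereby 95% CIs) to a curve.

    method is "infinitesimal-jackknife" or "patient-bootstrap".
    """
    risk, d1, d2, w, patient_index = _table_to_matrices(clone_days, weights)
    if method == "infinitesimal-jackknife":
        var1, var2 = ij_variance_matrices(risk, d1, d2, w, curve, patient_index)
    elif method == "patient-bootstrap":
        if n_boot < 2:
            raise ValueError("number of bootstrap resamples must be >= 2")
        rng = np.random.default_rng(seed)
        cif1, cif2 = bootstrap_cif_samples(risk, d1, d2, w, patient_index, n_boot, rng)
        var1 = cif1.var(axis=0, ddof=1)
        var2 = cif2.var(axis=0, ddof=1)
    else:
        raise ValueError(f"unknown variance method: {method}")
    curve.var_death = var1
    curve.var_discharge = var2
    return curve


@dataclass
class RegimeEvaluation:
    """Summary of one regime's estimated performance."""

    regime_index: int
    mortality_30d: float
    ci_low: float
    ci_high: float
    expected_rrt_initiations: float
    rrt_ci_low: float
    rrt_ci_high: float
    effective_sample_size: float

    def as_dict(self) -> dict:
        return {
            "regime_index": self.regime_index,
            "mortality_30d": self.mortality_30d,
            "ci_low": self.ci_low,
            "ci_high": self.ci_high,
            "expected_rrt_initiations": self.expected_rrt_initiations,
            "rrt_ci_low": self.rrt_ci_low,
            "rrt_ci_high": self.rrt_ci_high,
            "effective_sample_size": self.effective_sample_size,
        }


def expected_initiations_matrices(
    fu: FollowUpData,
    prescribed: np.ndarray,
    censor_u: np.ndarray,
    weight: np.ndarray,
    cohort_size: int,
    n_boot: int = 500,
    seed: int | None = None,
) -> tuple[float, float, float]:
    """Expected number of patients started on dialysis under a regime.

    IPC-weighted cumulative incidence of (concordant) initiation by the
    horizon, with death and discharge as competing events, scaled to
    ``cohort_size``.  CI from the patient-level bootstrap.
    """
    risk, d_init, d_comp = initiation_matrices(fu, prescribed, censor_u)
    curve = aalen_johansen_matrices(risk, d_init, d_comp, weight)
    point = curve.cif_death[-1] * cohort_size  # "death" slot holds initiation here
    if n_boot >= 2:
        rng = np.random.default_rng(seed)
        patient_index = np.arange(fu.n_patients)
        cif_b, _ = bootstrap_cif_samples(risk, d_init, d_comp, weight, patient_index, n_boot, rng)
        lo, hi = np.quantile(cif_b[:, -1] * cohort_size, [0.025, 0.975])
    else:
        lo = hi = float("nan")
    return float(point), float(lo), float(hi)
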