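"""Inverse-probability-of-censoring weights from a pooled logistic model.

A single discrete-time (pooled) logistic regression for the daily
probability of dialysis initiation is fitted on the original, un-cloned
person-days still at risk of initiation (not yet on dialysis, pre-event).
Because every regime's artificial censoring is fully determined by the one
observed initiation process, this single model serves all regimes: on a
day a clone's regime prescribes no initiation, the probability of
remaining uncensored is one minus the predicted initiation probability;
on the day it prescribes initiation it is the predicted probability
itself; after a concordant start the clone can no longer deviate and
contributes probability one.  The weight is the running product of the
reciprocals.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .followup import FollowUpData

DEFAULT_DAILY = (
    "potassium",
    "ph",
    "k_ge_60",
    "ph_lt_720",
    "uo_lt_05",
    "uo_stage3",
    "olig2_met",
    "sofa",
    "creat_ratio",
)
DEFAULT_BASELINE = ("age",)

_PCLIP = 1e-6


@dataclass(frozen=True)
class CovariateSpec:
    """Which columns enter the pooled initiation model (main effects only)."""

    daily: tuple[str, ...] = DEFAULT_DAILY
    baseline: tuple[str, ...] = DEFAULT_BASELINE
    time_effect: str = "spline"  # "spline" | "linear" | "none"
    spline_df: int = 4


def natural_spline_basis(x: np.ndarray, knots: np.ndarray) -> np.ndarray:
    """Natural cubic spline basis (linear beyond boundary knots).

    Truncated-power construction with K knots giving K - 1 columns
    (a linear term plus K - 2 curvature terms).
    """
    x = np.asarray(x, dtype=float)
    knots = np.asarray(knots, dtype=float)
    k_max = knots[-1]
    k_pen = knots[-2]

    def d(k):
        return (np.maximum(x - k, 0) ** 3 - np.maximum(x - k_max, 0) ** 3) / (k_max - k)

    cols = [x]
    d_pen = d(k_pen)
    for k in knots[:-2]:
        cols.append(d(k) - d_pen)
    return np.column_stack(cols)


@dataclass
class InitiationModel:
    """Fitted pooled logistic model for daily initiation probability."""

    spec: CovariateSpec
    coefficients: pd.Series
    converged: bool
    penalized: bool
    n_rows: int
    n_events: int
    time_knots: np.ndarray | None = None
    diagnostics: dict = field(default_factory=dict)

    # --- design construction -------------------------------------------------
    def _design(self, fu: FollowUpData, rows_p: np.ndarray, rows_u: np.ndarray) -> np.ndarray:
        cols = [np.ones(len(rows_p))]
        names = ["intercept"]
        for name in self.spec.daily:
            mat = fu.covariates[name]
            cols.append(np.asarray(mat[rows_p, rows_u], dtype=float))
            names.append(name)
        for name in self.spec.baseline:
            vals = np.asarray(fu.baseline[name].to_numpy(), dtype=float)[rows_p]
            cols.append(vals)
            names.append(name)
        if self.spec.time_effect == "spline" and self.time_knots is not None:
            basis = natural_spline_basis(rows_u.astype(float), self.time_knots)
            for j in range(basis.shape[1]):
                cols.append(basis[:, j])
                names.append(f"time_s{j + 1}")
        elif self.spec.time_effect == "linear":
            cols.append(rows_u.astype(float))
            names.append("time")
        self._names = names
        return np.column_stack(cols)

    def predict_matrix(self, fu: FollowUpData) -> np.ndarray:
        """Predicted daily initiation probability on every valid cell.

        Returns an (n_patients, horizon) array; padding cells are NaN.
        Probabilities are clipped away from 0 and 1 (positivity guard).
        """
        rows_p, rows_u = np.nonzero(fu.valid)
        x = self._design(fu, rows_p, rows_u)
        eta = x @ self.coefficients.to_numpy()
        p = 1.0 / (1.0 + np.exp(-eta))
        n_clipped = int(np.sum((p < _PCLIP) | (p > 1 - _PCLIP)))
        p = np.clip(p, _PCLIP, 1 - _PCLIP)
        out = np.full(fu.valid.shape, np.nan)
        out[rows_p, rows_u] = p
        self.diagnostics["n_predictions_clipped"] = n_clipped
        return out


def _at_risk_rows(fu: FollowUpData) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """(patient, day) indices of person-days at risk of initiation, and y."""
    rows_p, rows_u = np.nonzero(fu.valid)
    o = fu.obs_init_u[rows_p]
    at_risk = (o == -1) | ((o >= 0) & (rows_u <= o))
    rows_p, rows_u, o = rows_p[at_risk], rows_u[at_risk], o[at_risk]
    y = (rows_u == o).astype(float)
    return rows_p, rows_u, y


def fit_initiation_model(fu: FollowUpData, spec: CovariateSpec | None = None) -> InitiationModel:
    """Fit the pooled logistic initiation model by maximum likelihood.

    Raises
    ------
    ValueError
        if the cohort contains no initiation events ("degenerate outcome").
    """
    spec = spec or CovariateSpec()
    rows_p, rows_u, y = _at_risk_rows(fu)
    if y.sum() == 0:
        raise ValueError("degenerate outcome: no dialysis initiations in the cohort")

    time_knots = None
    if spec.time_effect == "spline":
        qs = np.quantile(rows_u.astype(float), [0.05, 0.35, 0.65, 0.95])
        knots = np.unique(np.round(qs, 6))
        if len(knots) < 3:  # fall back on too little time spread
            time_knots = None
            spec = CovariateSpec(spec.daily, spec.baseline, "linear", spec.spline_df)
        else:
            time_knots = knots

    model = InitiationModel(
        spec=spec,
        coefficients=pd.Series(dtype=float),
        converged=False,
        penalized=False,
        n_rows=len(y),
        n_events=int(y.sum()),
        time_knots=time_knots,
    )
    x = model._design(fu, rows_p, rows_u)
    names = model._names

    penalized = False
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        try:
            res = sm.Logit(y, x).fit(disp=0, maxiter=200)
            converged = bool(res.mle_retvals.get("converged", False))
            beta = np.asarray(res.params, dtype=float)
            bse = np.asarray(res.bse, dtype=float)
        except Exception:
            converged = False
            beta = None
            bse = None
    separation = (
        beta is not None
        and bse is not None
        and (not np.all(np.isfinite(bse)) or np.max(bse) > 1e3)
    )
    if beta is None or not converged or not np.all(np.isfinite(beta)) or separation:
        warnings.warn(
            "initiation model did not converge cleanly (possible separation); "
            "refitting with a ridge penalty",
            stacklevel=2,
        )
        from sklearn.linear_model import LogisticRegression

        # mild ridge on standardized columns; intercept unpenalized
        x1 = x[:, 1:]
        mu = x1.mean(axis=0)
        sd = x1.std(axis=0)
        sd[sd == 0] = 1.0
        z = (x1 - mu) / sd
        lr = LogisticRegression(C=1.0, solver="lbfgs", max_iter=5000)
        lr.fit(z, y)
        slopes = lr.coef_.ravel() / sd
        intercept = lr.intercept_[0] - float(mu @ slopes)
        beta = np.concatenate([[intercept], slopes])
        bse = np.full(len(beta), np.nan)
        converged = True
        penalized = True

    model.coefficients = pd.Series(beta, index=names)
    model.converged = converged
    model.penalized = penalized
    model.diagnostics.update(
        {
            "standard_errors": pd.Series(bse, index=names),
            "n_rows": len(y),
            "n_events": int(y.sum()),
        }
    )
    return model


@dataclass
class WeightSeries:
    """Per-clone-day uncensored-probabilities and cumulative weights.

    ``weight[p, u]`` multiplies clone ``p``'s contribution on follow-up
    day ``u``; cells that are censored or padding are NaN.
    """

    p_uncensored: np.ndarray  # (n, horizon)
    weight: np.ndarray  # (n, horizon) cumulative product of reciprocals
    truncated: bool = False
    truncation_cap: float | None = None
    untruncated_weight: np.ndarray | None = None

    def max_weight(self) -> float:
        w = self.weight[np.isfinite(self.weight)]
        return float(w.max()) if w.size else float("nan")


def compute_ipc_weights(
    model_or_p: InitiationModel | np.ndarray,
    fu: FollowUpData,
    prescribed: np.ndarray,
    censor_u: np.ndarray,
) -> WeightSeries:
    """Cumulative inverse-probability-of-censoring weights per clone-day.

    Parameters
    ----------
    model_or_p:
        fitted initiation model, or a precomputed (n, horizon) matrix of
        daily initiation probabilities.
    prescribed:
        (n, horizon) boolean matrix of the regime's prescriptions.
    censor_u:
        per-clone artificial censoring day (-1 if uncensored).

    Raises
    ------
    ValueError
        on an exact positivity violation (probability of remaining
        uncensored equal to zero on an uncensored clone-day).
    """
    if isinstance(model_or_p, InitiationModel):
        p_init = model_or_p.predict_matrix(fu)
    else:
        p_init = np.asarray(model_or_p, dtype=float)
    n, horizon = fu.valid.shape
    u_grid = np.arange(horizon)[None, :]
    o = fu.obs_init_u[:, None]

    p_unc = np.where(prescribed, p_init, 1.0 - p_init)
    # after a concordant start no deviation is possible
    p_unc = np.where((o >= 0) & (u_grid > o), 1.0, p_unc)
    p_unc = np.where(fu.valid, p_unc, np.nan)

    # limit to uncensored rows
    cens = censor_u[:, None]
    uncensored = (cens < 0) | (u_grid < cens)
    p_unc = np.where(uncensored, p_unc, np.nan)

    bad = np.nan_to_num(p_unc, nan=1.0) <= 0
    if bad.any():
        p_idx, u_idx = np.nonzero(bad)
        raise ValueError(
            "positivity violation: probability of remaining uncensored is 0 "
            f"for clone of patient {fu.patient_ids[p_idx[0]]} at follow-up day {u_idx[0]}"
        )

    log_terms = np.where(np.isfinite(p_unc), -np.log(np.where(np.isfinite(p_unc), p_unc, 1.0)), 0.0)
    weight = np.exp(np.cumsum(log_terms, axis=1))
    weight = np.where(np.isfinite(p_unc), weight, np.nan)
    return WeightSeries(p_uncensored=p_unc, weight=weight)


def truncate_weights(series: WeightSeries, upper_percentile: float = 0.995) -> WeightSeries:
    """Cap weights at a percentile of the pooled finite weight distribution."""
    if not 0.5 < upper_percentile <= 1.0:
        raise ValueError("upper_percentile must be in (0.5, 1]")
    if upper_percentile == 1.0:
        return series
    finite = series.weight[np.isfinite(series.weight)]
    # lower-order statistic, so the cap is an observed weight
    cap = float(np.quantile(finite, upper_percentile, method="lower")) if finite.size else float("inf")
    return WeightSeries(
        p_uncensored=series.p_uncensored,
        weight=np.minimum(series.weight, cap),
        truncated=True,
        truncation_cap=cap,
        untruncated_weight=series.weight,
    )
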