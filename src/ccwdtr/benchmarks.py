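"""Reference simulation studies exercising the full pipeline.

Each function recomputes one verifiable property of the package from
scratch — enumerating the regime grid, checking estimator reduction
identities against closed forms and an independent Kaplan-Meier
implementation, and running Monte Carlo comparisons of the
cloning-censoring-weighting pipeline against the forced-simulation
oracle.  They are shared by the acceptance test suite and the
acceptance-report script.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd

from . import clone_censor as cc
from . import estimation as est
from . import evaluation as ev
from . import ipcw
from . import synthetic as syn
from .followup import build_followup
from .regimes import enumerate_regimes

#: 3x3 oliguric (pH x K) subgrid with the non-oliguric thresholds fixed at
#: (7.0, 7.0); includes the full-grid row 27.
DEFAULT_SUBGRID = (7, 8, 9, 16, 17, 18, 25, 26, 27)


def _fast_config(**kw) -> ev.PipelineConfig:
    base = dict(n_boot_rrt=0, n_boot_risk_difference=0)
    base.update(kw)
    return ev.PipelineConfig(**base)


# ---------------------------------------------------------------------------
# criterion 1 — regime grid
# ---------------------------------------------------------------------------


def regime_grid_check() -> dict:
    regimes = enumerate_regimes()
    tuples = [r.as_tuple() for r in regimes]
    expected_rows = {
        1: (7.0, 7.0, 6.0, 6.0),
        27: (7.2, 7.0, 7.0, 7.0),
        28: (7.0, 7.1, 6.0, 6.0),
        81: (7.2, 7.2, 7.0, 7.0),
    }
    rows_match = all(regimes[i - 1].as_tuple() == t for i, t in expected_rows.items())
    return {
        "n_regimes": len(regimes),
        "n_distinct": len(set(tuples)),
        "rows_match": rows_match,
    }


# ---------------------------------------------------------------------------
# criterion 2 — estimator reduction identities
# ---------------------------------------------------------------------------


def _random_single_event_table(rng, n, horizon=10, p_death=0.06) -> pd.DataFrame:
    rows = []
    for pid in range(n):
        for day in range(horizon):
            dead = rng.random() < p_death
            rows.append({"patient_id": pid, "day": day, "event": "death" if dead else "none"})
            if dead:
                break
    return pd.DataFrame(rows)


def km_reduction_check(seed: int = 0, n_datasets: int = 50) -> dict:
    from lifelines import KaplanMeierFitter

    rng = np.random.default_rng(seed)
    max_diff = 0.0
    for _ in range(n_datasets):
        table = _random_single_event_table(rng, n=int(rng.integers(5, 40)))
        curve = est.weighted_aalen_johansen(table)
        durations = table.groupby("patient_id")["day"].max() + 1
        observed = table.groupby("patient_id")["event"].apply(lambda s: (s == "death").any())
        km = KaplanMeierFitter().fit(durations, observed)
        for day in range(10):
            s_km = float(km.survival_function_at_times(day + 1).iloc[0])
            max_diff = max(max_diff, abs(curve.cif_death[day] - (1 - s_km)))

    rows = []
    for pid, (event, day) in enumerate(
        [("death", 1), ("discharge", 2), ("death", 3), (None, None)]
    ):
        last = 29 if event is None else day
        for d in range(last + 1):
            ev_val = event if (event is not None and d == day) else "none"
            rows.append({"patient_id": pid, "day": d, "event": ev_val})
    hand = est.weighted_aalen_johansen(pd.DataFrame(rows))
    return {
        "km_max_abs_diff": max_diff,
        "hand_cif_death_30": float(hand.cif_death[30]),
        "hand_cif_discharge_30": float(hand.cif_discharge[30]),
        "hand_surv_30": float(hand.surv[30]),
    }


# ---------------------------------------------------------------------------
# criterion 3 — non-informative censoring
# ---------------------------------------------------------------------------


def noninformative_ipcw_check(n: int = 2000, seed: int = 0, n_mc: int = 30000) -> dict:
    """Covariate-independent initiation at 10%/day; never-initiate regime."""
    params = syn.random_initiation_scenario(rate=0.1, n_patients=n, seed=seed)
    baseline, days = syn.generate_cohort(params)
    fu = build_followup(baseline, days)
    config = _fast_config()
    model = ipcw.fit_initiation_model(fu, config.covariate_spec)
    p_init = model.predict_matrix(fu)

    weighted, _, censor_u, series = ev.regime_weighted_curve(fu, cc.NEVER_INITIATE, p_init, config)
    unweighted, *_ = ev.regime_weighted_curve(
        fu, cc.NEVER_INITIATE, p_init, config, with_variance=True, unit_weights=True
    )
    oracle = syn.simulate_counterfactual_cif(params, syn.NEVER, n_mc=n_mc, seed=seed + 1)

    unc = cc.uncensored_mask(fu, censor_u)
    ratios = []
    for day in range(0, 15):
        alive = fu.valid[:, day].sum()
        if alive < 50:
            break
        mass = np.nansum(np.where(unc[:, day], series.weight[:, day], 0.0))
        ratios.append(mass / alive)

    se_pair = float(np.sqrt(weighted.var_death[-1] + unweighted.var_death[-1]))
    se_oracle = float(np.sqrt(weighted.var_death[-1] + oracle.se_death[-1] ** 2))
    return {
        "weighted_cif30": weighted.mortality(),
        "unweighted_cif30": unweighted.mortality(),
        "weighted_unweighted_diff": weighted.mortality() - unweighted.mortality(),
        "pair_se": se_pair,
        "oracle_cif30": float(oracle.cif_death[-1]),
        "oracle_diff": weighted.mortality() - float(oracle.cif_death[-1]),
        "oracle_se": se_oracle,
        "mean_weight_ratio": float(np.mean(ratios)),
        "max_weight_ratio_dev": float(np.max(np.abs(np.array(ratios) - 1.0))),
    }


# ---------------------------------------------------------------------------
# criterion 4 — counterfactual recovery
# ---------------------------------------------------------------------------


def counterfactual_recovery(
    n: int = 2000,
    n_mc: int = 50000,
    seed: int = 0,
    subgrid: tuple[int, ...] = DEFAULT_SUBGRID,
) -> dict:
    """Pipeline vs oracle on the confounded default scenario."""
    params = syn.default_scenario(n_patients=n, seed=seed)
    regimes = [r for r in enumerate_regimes() if r.index in set(subgrid)]
    oracle = syn.simulate_counterfactual_grid(params, regimes, n_mc=n_mc, seed=seed + 1)

    baseline, days = syn.generate_cohort(params)
    fu = build_followup(baseline, days)
    config = _fast_config()
    model = ipcw.fit_initiation_model(fu, config.covariate_spec)
    p_init = model.predict_matrix(fu)

    per_regime = {}
    for regime in regimes:
        curve, prescribed, censor_u, series = ev.regime_weighted_curve(fu, regime, p_init, config)
        naive, *_ = ev.regime_weighted_curve(
            fu, regime, p_init, config, with_variance=False, unit_weights=True
        )
        e_init, e_lo, e_hi = est.expected_initiations_matrices(
            fu, prescribed, censor_u, series.weight, fu.n_patients, n_boot=200, seed=seed
        )
        oc = oracle[regime.index]
        per_regime[regime.index] = {
            "oracle": float(oc.cif_death[-1]),
            "weighted": curve.mortality(),
            "se": float(np.sqrt(curve.var_death[-1])),
            "naive": naive.mortality(),
            "abs_err_weighted": abs(curve.mortality() - oc.cif_death[-1]),
            "abs_err_naive": abs(naive.mortality() - oc.cif_death[-1]),
            "oracle_initiations": float(oc.initiated_fraction * fu.n_patients),
            "estimated_initiations": float(e_init),
            "initiations_boot_se": float((e_hi - e_lo) / (2 * est.Z975)),
        }
    mae_w = float(np.mean([v["abs_err_weighted"] for v in per_regime.values()]))
    mae_n = float(np.mean([v["abs_err_naive"] for v in per_regime.values()]))
    return {
        "per_regime": per_regime,
        "mae_weighted": mae_w,
        "mae_naive": mae_n,
        "n_included": fu.n_patients,
    }


# ---------------------------------------------------------------------------
# criterion 5 — variance calibration
# ---------------------------------------------------------------------------


def variance_calibration(
    n_replicates: int = 100,
    n: int = 1000,
    seed: int = 0,
    n_boot: int = 200,
    n_mc_truth: int = 100000,
) -> dict:
    """Coverage of IJ and bootstrap CIs for the observed-care CIF."""
    params = syn.default_scenario(n_patients=n)
    oracle = syn.simulate_counterfactual_cif(params, syn.OBSERVATIONAL, n_mc=n_mc_truth, seed=seed)
    truth = float(oracle.cif_death[-1])

    cover_ij = 0
    cover_boot = 0
    for rep in range(n_replicates):
        rep_params = params.replace(seed=seed + 1000 + rep)
        baseline, days = syn.generate_cohort(rep_params)
        fu = build_followup(baseline, days)
        censor_u = np.full(fu.n_patients, -1, dtype=np.int64)
        risk, d1, d2 = est.mortality_matrices(fu, censor_u)
        w = np.ones(fu.valid.shape)
        curve = est.aalen_johansen_matrices(risk, d1, d2, w)
        var1, _ = est.ij_variance_matrices(risk, d1, d2, w, curve, np.arange(fu.n_patients))
        se = np.sqrt(var1[-1])
        if abs(curve.mortality() - truth) <= est.Z975 * se:
            cover_ij += 1
        rng = np.random.default_rng(seed + 5000 + rep)
        cif_b, _ = est.bootstrap_cif_samples(
            risk, d1, d2, w, np.arange(fu.n_patients), n_boot, rng
        )
        lo, hi = np.quantile(cif_b[:, -1], [0.025, 0.975])
        if lo <= truth <= hi:
            cover_boot += 1
    return {
        "truth": truth,
        "ij_coverage": cover_ij / n_replicates,
        "bootstrap_coverage": cover_boot / n_replicates,
        "n_replicates": n_replicates,
    }


# ---------------------------------------------------------------------------
# criterion 6 — cross-validation overoptimism
# ---------------------------------------------------------------------------


def cv_overoptimism(
    n_replicates: int = 100,
    n: int = 600,
    seed: int = 0,
    subgrid: tuple[int, ...] = DEFAULT_SUBGRID,
    k_folds: int = 5,
) -> dict:
    """Mean fivefold CV benchmark vs mean full-data optimal estimate."""
    regimes = [r for r in enumerate_regimes() if r.index in set(subgrid)]
    config = _fast_config()
    full_optimal = []
    cv_benchmark = []
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        for rep in range(n_replicates):
            params = syn.default_scenario(n_patients=n, seed=seed + 100 + rep)
            baseline, days = syn.generate_cohort(params)
            fu = build_followup(baseline, days)
            try:
                report = ev.evaluate_all_regimes(
                    None,
                    None,
                    regimes=regimes,
                    config=config,
                    fu=fu,
                    compute_risk_difference_ci=False,
                )
                result = ev.cross_validated_benchmark(
                    None, None, regimes=regimes, k_folds=k_folds, seed=seed + rep, fu=fu, config=config
                )
            except ValueError:
                continue
            full_optimal.append(report.optimal_mortality)
            cv_benchmark.append(result.benchmark_mortality)
    return {
        "mean_full_data_optimal": float(np.mean(full_optimal)),
        "mean_cv_benchmark": float(np.mean(cv_benchmark)),
        "overoptimism": float(np.mean(cv_benchmark) - np.mean(full_optimal)),
        "n_valid_replicates": len(cv_benchmark),
    }


# ---------------------------------------------------------------------------
# criterion 7 — closed forms
# ---------------------------------------------------------------------------


def closed_forms_check(seed: int = 0) -> dict:
    # weight product
    from .followup import FollowUpData

    valid = np.zeros((1, 30), dtype=bool)
    valid[0, :3] = True
    fu = FollowUpData(
        horizon=30,
        patient_ids=np.array([1]),
        inclusion_day=np.array([0]),
        n_days=np.array([3]),
        valid=valid,
        event_type=np.array([0], dtype=np.int8),
        event_u=np.array([-1]),
        obs_init_u=np.array([-1]),
        covariates={},
    )
    prescribed = np.zeros((1, 30), dtype=bool)
    censor_u = np.array([-1])
    series = ipcw.compute_ipc_weights(np.full((1, 30), 0.2), fu, prescribed, censor_u)
    weight_product = float(series.weight[0, 2])

    # constant-hazard survival
    p0 = 0.02
    params = syn.default_scenario(
        n_patients=1,
        death_intercept=float(np.log(p0 / (1 - p0))),
        death_sofa=0.0,
        death_k=0.0,
        death_ph=0.0,
        death_age=0.0,
        death_creat=0.0,
        death_rrt_unindicated=0.0,
        death_rrt_indicated=0.0,
        discharge_intercept=-30.0,
        discharge_sofa=0.0,
        discharge_creat=0.0,
    )
    oracle = syn.simulate_counterfactual_cif(params, syn.NEVER, n_mc=30000, seed=seed + 1)

    # logit-intercept recovery under constant initiation
    rate_params = syn.random_initiation_scenario(rate=0.1, n_patients=3000, seed=seed + 2)
    baseline, days = syn.generate_cohort(rate_params)
    fu2 = build_followup(baseline, days)
    spec = ipcw.CovariateSpec(daily=(), baseline=(), time_effect="none")
    model = ipcw.fit_initiation_model(fu2, spec)

    return {
        "weight_product": weight_product,
        "weight_product_expected": 1.0 / 0.8**3,
        "constant_hazard_cif30": float(oracle.cif_death[-1]),
        "constant_hazard_se": float(oracle.se_death[-1]),
        "constant_hazard_expected": 1 - (1 - p0) ** 30,
        "logit_intercept": float(model.coefficients["intercept"]),
        "logit_intercept_expected": float(np.log(0.1 / 0.9)),
    }
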