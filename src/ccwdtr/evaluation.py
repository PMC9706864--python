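"""Per-regime evaluation, observed-care reference and cross-validation.

`evaluate_all_regimes` runs the full clone -> censor -> weight -> estimate
pipeline for every regime of the grid and assembles a report with the
observed standard-of-care reference, the mortality-minimising regime and
the observed-minus-optimal risk difference.  `cross_validated_benchmark`
assesses selection overoptimism: the optimal regime is chosen on the
training folds and its mortality re-estimated on the held-out fold, with
the censoring model refit on each side.
"""

from __future__ import annotations

import dataclasses
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import clone_censor, estimation, ipcw
from .followup import FollowUpData, build_followup
from .regimes import Regime, enumerate_regimes


@dataclass(frozen=True)
class PipelineConfig:
    """Knobs of the estimation pipeline."""

    horizon: int = 30
    covariate_spec: ipcw.CovariateSpec = field(default_factory=ipcw.CovariateSpec)
    truncation_percentile: float = 1.0  # 1.0 = no truncation
    variance_method: str = "infinitesimal-jackknife"
    n_boot_rrt: int = 500  # bootstrap resamples for the initiation-count CI
    n_boot_risk_difference: int = 500
    refit_weights_in_bootstrap: bool = True
    seed: int = 0


@dataclass
class EvaluationReport:
    """Full regime-grid evaluation."""

    regime_table: pd.DataFrame  # one row per regime
    observed_mortality: float
    observed_ci: tuple[float, float]
    observed_rrt_count: float
    observed_rrt_ci: tuple[float, float]
    optimal_regime_index: int
    optimal_mortality: float
    risk_difference: float
    risk_difference_ci: tuple[float, float]
    n_patients: int
    tied_optimum: bool = False
    weight_diagnostics: pd.DataFrame | None = None
    cv_benchmark: float | None = None

    def summary(self) -> str:
        lines = [
            f"patients analysed: {self.n_patients}",
            f"observed-care 30-day mortality: {self.observed_mortality:.4f} "
            f"[{self.observed_ci[0]:.4f}, {self.observed_ci[1]:.4f}]",
            f"observed-care initiations: {self.observed_rrt_count:.1f} "
            f"[{self.observed_rrt_ci[0]:.1f}, {self.observed_rrt_ci[1]:.1f}]",
            f"optimal regime: {self.optimal_regime_index} "
            f"(mortality {self.optimal_mortality:.4f})"
            + (" [tied]" if self.tied_optimum else ""),
            f"risk difference (observed - optimal): {self.risk_difference:.4f} "
            f"[{self.risk_difference_ci[0]:.4f}, {self.risk_difference_ci[1]:.4f}]",
        ]
        if self.cv_benchmark is not None:
            lines.append(f"cross-validated benchmark mortality: {self.cv_benchmark:.4f}")
        return "\n".join(lines)


def _subset_followup(fu: FollowUpData, idx: np.ndarray) -> FollowUpData:
    """Row-subset (with possible repetition) of a follow-up bundle."""
    return FollowUpData(
        horizon=fu.horizon,
        patient_ids=np.arange(len(idx)),  # re-labelled; duplicates must stay distinct
        inclusion_day=fu.inclusion_day[idx],
        n_days=fu.n_days[idx],
        valid=fu.valid[idx],
        event_type=fu.event_type[idx],
        event_u=fu.event_u[idx],
        obs_init_u=fu.obs_init_u[idx],
        covariates={k: v[idx] for k, v in fu.covariates.items()},
        baseline=None if fu.baseline is None else fu.baseline.iloc[idx].reset_index(drop=True),
    )


def regime_weighted_curve(
    fu: FollowUpData,
    regime: Regime,
    p_init: np.ndarray,
    config: PipelineConfig,
    with_variance: bool = True,
    unit_weights: bool = False,
):
    """Run censoring + weighting + estimation for one regime.

    Returns (curve, prescribed, censor_u, weight_series).
    """
    prescribed = clone_censor.prescriptions(fu, regime)
    censor_u = clone_censor.censor_days_matrix(fu, prescribed)
    series = ipcw.compute_ipc_weights(p_init, fu, prescribed, censor_u)
    if config.truncation_percentile < 1.0:
        series = ipcw.truncate_weights(series, config.truncation_percentile)
    weight = np.ones_like(series.weight) if unit_weights else series.weight
    risk, d1, d2 = estimation.mortality_matrices(fu, censor_u)
    curve = estimation.aalen_johansen_matrices(risk, d1, d2, weight)
    if with_variance:
        var1, var2 = estimation.ij_variance_matrices(
            risk, d1, d2, weight, curve, np.arange(fu.n_patients)
        )
        curve.var_death = var1
        curve.var_discharge = var2
    return curve, prescribed, censor_u, series


def observed_care_estimate(
    baseline: pd.DataFrame | None,
    person_days: pd.DataFrame | None = None,
    fu: FollowUpData | None = None,
    config: PipelineConfig | None = None,
) -> tuple[estimation.IncidenceCurve, float, tuple[float, float]]:
    """Unweighted Aalen-Johansen on the observed data from inclusion.

    Returns (curve with IJ variance, observed initiation count within the
    horizon, bootstrap CI for the count).
    """
    config = config or PipelineConfig()
    if fu is None:
        if baseline is None or person_days is None:
            raise ValueError("either a follow-up bundle or raw tables are required")
        fu = build_followup(baseline, person_days, horizon=config.horizon)
    if fu.n_patients == 0:
        raise ValueError("empty cohort")
    censor_u = np.full(fu.n_patients, -1, dtype=np.int64)
    risk, d1, d2 = estimation.mortality_matrices(fu, censor_u)
    weight = np.ones(fu.valid.shape)
    curve = estimation.aalen_johansen_matrices(risk, d1, d2, weight)
    var1, var2 = estimation.ij_variance_matrices(
        risk, d1, d2, weight, curve, np.arange(fu.n_patients)
    )
    curve.var_death = var1
    curve.var_discharge = var2

    started = fu.obs_init_u != -1  # includes pre-inclusion starts
    count = float(started.sum())
    rng = np.random.default_rng(config.seed)
    if config.n_boot_rrt >= 2:
        draws = rng.multinomial(
            fu.n_patients, np.full(fu.n_patients, 1 / fu.n_patients), size=config.n_boot_rrt
        )
        boot = draws @ started.astype(float)
        lo, hi = np.quantile(boot, [0.025, 0.975])
    else:
        lo = hi = float("nan")
    return curve, count, (float(lo), float(hi))


def evaluate_all_regimes(
    baseline: pd.DataFrame | None,
    person_days: pd.DataFrame | None = None,
    regimes: list[Regime] | None = None,
    config: PipelineConfig | None = None,
    fu: FollowUpData | None = None,
    model: ipcw.InitiationModel | None = None,
    compute_risk_difference_ci: bool = True,
) -> EvaluationReport:
    """Evaluate every regime and assemble the full report."""
    config = config or PipelineConfig()
    regimes = regimes if regimes is not None else enumerate_regimes()
    if fu is None:
        fu = build_followup(baseline, person_days, horizon=config.horizon)
    if model is None:
        model = ipcw.fit_initiation_model(fu, config.covariate_spec)
    p_init = model.predict_matrix(fu)

    rows = []
    diag_rows = []
    curves: dict[int, estimation.IncidenceCurve] = {}
    for regime in regimes:
        try:
            curve, prescribed, censor_u, series = regime_weighted_curve(
                fu, regime, p_init, config, with_variance=True
            )
        except ValueError as exc:
            raise ValueError(f"regime {regime.index}: {exc}") from exc
        curves[regime.index] = curve
        m30 = curve.mortality()
        lo, hi = curve.ci_death()
        rrt, rrt_lo, rrt_hi = estimation.expected_initiations_matrices(
            fu,
            prescribed,
            censor_u,
            series.weight,
            cohort_size=fu.n_patients,
            n_boot=config.n_boot_rrt,
            seed=config.seed + regime.index,
        )
        unc = clone_censor.uncensored_mask(fu, censor_u)
        w_last = np.array(
            [
                series.weight[p, np.nonzero(unc[p])[0][-1]] if unc[p].any() else np.nan
                for p in range(fu.n_patients)
            ]
        )
        w_last = w_last[np.isfinite(w_last)]
        ess = float(w_last.sum() ** 2 / np.sum(w_last**2)) if w_last.size else 0.0
        rows.append(
            estimation.RegimeEvaluation(
                regime_index=regime.index,
                mortality_30d=m30,
                ci_low=lo,
                ci_high=hi,
                expected_rrt_initiations=rrt,
                rrt_ci_low=rrt_lo,
                rrt_ci_high=rrt_hi,
                effective_sample_size=ess,
            ).as_dict()
        )
        finite_w = series.weight[np.isfinite(series.weight)]
        diag_rows.append(
            {
                "regime_index": regime.index,
                "n_uncensored_day0": int(unc[:, 0].sum()),
                "mean_weight": float(finite_w.mean()) if finite_w.size else np.nan,
                "max_weight": float(finite_w.max()) if finite_w.size else np.nan,
                "truncation_cap": series.truncation_cap,
            }
        )

    table = pd.DataFrame(rows).sort_values("regime_index").reset_index(drop=True)
    obs_curve, obs_count, obs_count_ci = observed_care_estimate(None, None, fu=fu, config=config)
    obs_m = obs_curve.mortality()
    obs_ci = obs_curve.ci_death()

    best_pos = int(np.argmin(table["mortality_30d"].to_numpy()))
    best = table.iloc[best_pos]
    tied = bool((table["mortality_30d"] == best["mortality_30d"]).sum() > 1)
    optimal_index = int(best["regime_index"])
    optimal_regime = next(r for r in regimes if r.index == optimal_index)
    rd = obs_m - float(best["mortality_30d"])

    rd_ci = (float("nan"), float("nan"))
    if compute_risk_difference_ci and config.n_boot_risk_difference >= 2:
        rd_ci = _risk_difference_ci(fu, optimal_regime, config, model)

    return EvaluationReport(
        regime_table=table,
        observed_mortality=obs_m,
        observed_ci=obs_ci,
        observed_rrt_count=obs_count,
        observed_rrt_ci=obs_count_ci,
        optimal_regime_index=optimal_index,
        optimal_mortality=float(best["mortality_30d"]),
        risk_difference=rd,
        risk_difference_ci=rd_ci,
        n_patients=fu.n_patients,
        tied_optimum=tied,
        weight_diagnostics=pd.DataFrame(diag_rows),
    )


def _risk_difference_ci(
    fu: FollowUpData,
    optimal_regime: Regime,
    config: PipelineConfig,
    model: ipcw.InitiationModel,
) -> tuple[float, float]:
    """Patient-level bootstrap CI of (observed - optimal) mortality.

    The two arms share patients, so both are recomputed on each resample;
    the censoring model is refit per resample when configured.
    """
    rng = np.random.default_rng(config.seed + 10_000)
    diffs = []
    n = fu.n_patients
    for _ in range(config.n_boot_risk_difference):
        idx = rng.integers(0, n, size=n)
        sub = _subset_followup(fu, idx)
        try:
            m = (
                ipcw.fit_initiation_model(sub, config.covariate_spec)
                if config.refit_weights_in_bootstrap
                else model
            )
            p_init = m.predict_matrix(sub)
            curve, *_ = regime_weighted_curve(sub, optimal_regime, p_init, config, with_variance=False)
            obs_curve, _, _ = observed_care_estimate(
                None, None, fu=sub, config=dataclasses.replace(config, n_boot_rrt=0)
            )
        except ValueError:
            continue
        diffs.append(obs_curve.mortality() - curve.mortality())
    if len(diffs) < 2:
        return (float("nan"), float("nan"))
    lo, hi = np.quantile(diffs, [0.025, 0.975])
    return (float(lo), float(hi))


@dataclass
class CVResult:
    """Fivefold (by default) cross-validation benchmark."""

    benchmark_mortality: float
    fold_estimates: list[float]
    fold_sizes: list[int]
    selected_regimes: list[int]
    n_valid_folds: int
    fold_assignment: np.ndarray


def cross_validated_benchmark(
    baseline: pd.DataFrame | None,
    person_days: pd.DataFrame | None = None,
    regimes: list[Regime] | None = None,
    k_folds: int = 5,
    seed: int = 0,
    config: PipelineConfig | None = None,
    fu: FollowUpData | None = None,
) -> CVResult:
    """Overoptimism-corrected mortality estimate for the selected regime.

    For each fold the mortality-minimising regime is chosen on the other
    folds (censoring weights fit there) and its mortality re-estimated on
    the held-out fold (weights refit on the held-out data).  The benchmark
    is the fold-size-weighted average over valid folds.
    """
    if k_folds < 2:
        raise ValueError("k_folds must be >= 2")
    config = config or PipelineConfig()
    regimes = regimes if regimes is not None else enumerate_regimes()
    if fu is None:
        fu = build_followup(baseline, person_days, horizon=config.horizon)
    n = fu.n_patients
    if k_folds > n:
        raise ValueError("more folds than patients")
    rng = np.random.default_rng(seed)
    assignment = rng.permutation(np.arange(n) % k_folds)

    def _predict_or_zero(sub: FollowUpData) -> np.ndarray:
        # a fold with no initiations has zero estimated initiation risk
        try:
            return ipcw.fit_initiation_model(sub, config.covariate_spec).predict_matrix(sub)
        except ValueError as exc:
            if "degenerate outcome" not in str(exc):
                raise
            return np.where(sub.valid, 1e-6, np.nan)

    estimates, sizes, selected = [], [], []
    for fold in range(k_folds):
        test_idx = np.nonzero(assignment == fold)[0]
        train_idx = np.nonzero(assignment != fold)[0]
        train = _subset_followup(fu, train_idx)
        test = _subset_followup(fu, test_idx)
        try:
            p_train = _predict_or_zero(train)
            mortalities = []
            for regime in regimes:
                curve, *_ = regime_weighted_curve(
                    train, regime, p_train, config, with_variance=False
                )
                mortalities.append(curve.mortality())
            best = regimes[int(np.argmin(mortalities))]
            p_test = _predict_or_zero(test)
            curve, _, censor_u, _ = regime_weighted_curve(
                test, best, p_test, config, with_variance=False
            )
            if clone_censor.uncensored_mask(test, censor_u)[:, 0].sum() == 0:
                raise ValueError("no at-risk clones for the selected regime")
        except ValueError as exc:
            warnings.warn(f"fold {fold} skipped: {exc}", stacklevel=2)
            continue
        estimates.append(curve.mortality())
        sizes.append(len(test_idx))
        selected.append(getattr(best, "index", -1))  # -1 for pseudo-regimes

    if not estimates:
        raise ValueError("no valid folds in cross-validation")
    if len(estimates) < k_folds:
        warnings.warn(
            f"benchmark averaged over {len(estimates)}/{k_folds} valid folds", stacklevel=2
        )
    benchmark = float(np.average(estimates, weights=sizes))
    return CVResult(
        benchmark_mortality=benchmark,
        fold_estimates=estimates,
        fold_sizes=sizes,
        selected_regimes=selected,
        n_valid_folds=len(estimates),
        fold_assignment=assignment,
    )
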