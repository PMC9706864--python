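import numpy as np
import pandas as pd
import pytest
from scipy.stats import spearmanr

from ccwdtr import clone_censor as cc
from ccwdtr import estimation as est
from ccwdtr import evaluation as ev
from ccwdtr import ipcw
from ccwdtr import synthetic as syn
from ccwdtr.followup import build_followup
from ccwdtr.regimes import enumerate_regimes, regime_by_index

SUBGRID = [7, 17, 27]


def fast_config(**kw):
    defaults = dict(n_boot_rrt=0, n_boot_risk_difference=0)
    defaults.update(kw)
    return ev.PipelineConfig(**defaults)


@pytest.fixture(scope="module")
def quiet_cohort():
    """Cohort with no dialysis starts and no regime triggers (creatinine-only
    inclusion): no clone is ever censored."""
    params = syn.default_scenario(
        n_patients=500,
        seed=42,
        init_intercept=-30.0,
        k_prop_coef=0.0,
        k_ratio_coef=0.0,
        olig_aki_loading=0.0,
        olig_sev_loading=0.0,
        olig_noise_sd=0.1,
        uo_log_base=1.5,
        ph_ratio_coef=0.0,
        ph_sev_coef=0.0,
    )
    return syn.generate_cohort(params)


class TestObservedCare:
    def test_no_deaths_gives_zero_mortality(self):
        params = syn.default_scenario(n_patients=300, seed=9, death_intercept=-30.0)
        baseline, days = syn.generate_cohort(params)
        curve, count, _ = ev.observed_care_estimate(baseline, days, config=fast_config())
        assert curve.mortality() == 0.0
        assert count >= 0

    def test_equals_unit_weight_aj_on_uncloned_data(self, small_fu):
        curve, _, _ = ev.observed_care_estimate(None, None, fu=small_fu, config=fast_config())
        table = cc.expand_clones(None, None, [regime_by_index(1)], fu=small_fu).drop(
            columns=["regime_index"]
        )
        direct = est.weighted_aalen_johansen(table)
        assert np.allclose(curve.cif_death, direct.cif_death)
        assert np.allclose(curve.cif_discharge, direct.cif_discharge)

    def test_matches_natural_course_oracle(self, medium_params, medium_fu):
        curve, _, _ = ev.observed_care_estimate(None, None, fu=medium_fu, config=fast_config())
        oracle = syn.simulate_counterfactual_cif(
            medium_params, syn.OBSERVATIONAL, n_mc=40000, seed=5150
        )
        se = np.sqrt(curve.var_death[-1] + oracle.se_death[-1] ** 2)
        assert abs(curve.mortality() - oracle.cif_death[-1]) <= 3 * se

    def test_empty_cohort_rejected(self, small_fu):
        from ccwdtr.evaluation import _subset_followup

        empty = _subset_followup(small_fu, np.array([], dtype=int))
        with pytest.raises(ValueError, match="empty cohort"):
            ev.observed_care_estimate(None, None, fu=empty, config=fast_config())


class TestEvaluateAllRegimes:
    @pytest.fixture(scope="class")
    def report(self, medium_cohort):
        baseline, days = medium_cohort
        regimes = [regime_by_index(i) for i in SUBGRID]
        return ev.evaluate_all_regimes(
            baseline,
            days,
            regimes=regimes,
            config=fast_config(n_boot_rrt=50, n_boot_risk_difference=30),
        )

    def test_one_row_per_regime(self, report):
        assert len(report.regime_table) == len(SUBGRID)
        assert sorted(report.regime_table["regime_index"]) == SUBGRID

    def test_optimal_is_argmin_with_lowest_index_tiebreak(self, report):
        tab = report.regime_table
        min_m = tab["mortality_30d"].min()
        first = int(tab.loc[tab["mortality_30d"] == min_m, "regime_index"].min())
        assert report.optimal_regime_index == first

    def test_risk_difference_definition_and_ci(self, report):
        assert report.risk_difference == pytest.approx(
            report.observed_mortality - report.optimal_mortality
        )
        lo, hi = report.risk_difference_ci
        assert lo <= report.risk_difference <= hi

    def test_ci_bounds_ordered(self, report):
        tab = report.regime_table
        assert (tab["ci_low"] <= tab["mortality_30d"]).all()
        assert (tab["mortality_30d"] <= tab["ci_high"]).all()
        assert (tab["expected_rrt_initiations"] >= 0).all()
        assert (tab["expected_rrt_initiations"] <= report.n_patients).all()

    def test_invariant_to_patient_ordering(self, medium_cohort):
        baseline, days = medium_cohort
        regimes = [regime_by_index(7)]
        r1 = ev.evaluate_all_regimes(
            baseline, days, regimes=regimes, config=fast_config(), compute_risk_difference_ci=False
        )
        rng = np.random.default_rng(0)
        shuffled_days = days.sample(frac=1.0, random_state=1).reset_index(drop=True)
        shuffled_base = baseline.sample(frac=1.0, random_state=2).reset_index(drop=True)
        r2 = ev.evaluate_all_regimes(
            shuffled_base,
            shuffled_days,
            regimes=regimes,
            config=fast_config(),
            compute_risk_difference_ci=False,
        )
        assert r1.regime_table["mortality_30d"].iloc[0] == pytest.approx(
            r2.regime_table["mortality_30d"].iloc[0], abs=1e-8
        )

    def test_null_effect_spread_consistent_with_noise(self):
        params = syn.null_effect_scenario(n_patients=2000, seed=88)
        baseline, days = syn.generate_cohort(params)
        regimes = [regime_by_index(i) for i in (7, 8, 9, 16, 17, 18, 25, 26, 27)]
        report = ev.evaluate_all_regimes(
            baseline, days, regimes=regimes, config=fast_config(), compute_risk_difference_ci=False
        )
        tab = report.regime_table
        grand = np.average(tab["mortality_30d"])
        se = (tab["ci_high"] - tab["ci_low"]) / (2 * 1.96)
        within = np.abs(tab["mortality_30d"] - grand) <= 3 * se
        assert within.mean() >= 0.95

    def test_regime_ranking_tracks_oracle(self):
        """Rank correlation >= 0.7 against the oracle on a spread-out
        subgrid under amplified treatment effects."""
        sub = [1, 5, 9, 37, 41, 45, 73, 77, 81]
        regimes = [r for r in enumerate_regimes() if r.index in sub]
        params = syn.default_scenario(
            n_patients=4000, seed=31, death_rrt_unindicated=2.0, death_rrt_indicated=-1.5
        )
        oracle = syn.simulate_counterfactual_grid(params, regimes, n_mc=40000, seed=99)
        baseline, days = syn.generate_cohort(params)
        report = ev.evaluate_all_regimes(
            baseline, days, regimes=regimes, config=fast_config(), compute_risk_difference_ci=False
        )
        ests = report.regime_table.sort_values("regime_index")["mortality_30d"].to_numpy()
        truth = [oracle[i].cif_death[-1] for i in sub]
        assert spearmanr(ests, truth).statistic >= 0.7


class TestCrossValidation:
    def test_single_fold_rejected(self, small_cohort):
        baseline, days = small_cohort
        with pytest.raises(ValueError, match="k_folds"):
            ev.cross_validated_benchmark(baseline, days, k_folds=1)

    def test_stability_limit_without_censoring(self, quiet_cohort):
        """One regime, no censoring: CV benchmark ~ full-data estimate."""
        baseline, days = quiet_cohort
        fu = build_followup(baseline, days)
        regimes = [cc.NEVER_INITIATE]
        result = ev.cross_validated_benchmark(
            None, None, regimes=regimes, k_folds=5, seed=3, fu=fu, config=fast_config()
        )
        full, *_ = ev.regime_weighted_curve(
            fu,
            cc.NEVER_INITIATE,
            np.full(fu.valid.shape, 1e-6),
            fast_config(),
            with_variance=False,
        )
        assert result.n_valid_folds == 5
        assert result.benchmark_mortality == pytest.approx(full.mortality(), abs=0.03)

    def test_fold_with_no_at_risk_clones_is_flagged(self):
        """Everyone starts dialysis on day 0, so the never-initiate
        pseudo-regime censors every clone immediately."""
        params = syn.default_scenario(n_patients=300, seed=11, init_intercept=30.0)
        baseline, days = syn.generate_cohort(params)
        fu = build_followup(baseline, days)
        with pytest.warns(UserWarning, match="skipped"):
            with pytest.raises(ValueError, match="no valid folds"):
                ev.cross_validated_benchmark(
                    None,
                    None,
                    regimes=[cc.NEVER_INITIATE],
                    k_folds=3,
                    seed=1,
                    fu=fu,
                    config=fast_config(),
                )

    def test_more_folds_than_patients_rejected(self, small_fu):
        from ccwdtr.evaluation import _subset_followup

        tiny = _subset_followup(small_fu, np.arange(3))
        with pytest.raises(ValueError, match="folds"):
            ev.cross_validated_benchmark(
                None, None, regimes=[regime_by_index(1)], k_folds=5, fu=tiny, config=fast_config()
            )

    def test_fold_assignment_seeded(self, quiet_cohort):
        baseline, days = quiet_cohort
        fu = build_followup(baseline, days)
        a = ev.cross_validated_benchmark(
            None, None, regimes=[cc.NEVER_INITIATE], k_folds=3, seed=5, fu=fu, config=fast_config()
        )
        b = ev.cross_validated_benchmark(
            None, None, regimes=[cc.NEVER_INITIATE], k_folds=3, seed=5, fu=fu, config=fast_config()
        )
        assert np.array_equal(a.fold_assignment, b.fold_assignment)
        assert a.benchmark_mortality == b.benchmark_mortality
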