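import numpy as np
import pytest

from ccwdtr import clone_censor as cc
from ccwdtr import ipcw
from ccwdtr import synthetic as syn
from ccwdtr.followup import build_followup
from ccwdtr.regimes import regime_by_index

from test_clone_censor import make_fu


@pytest.fixture(scope="module")
def fitted(medium_fu):
    return ipcw.fit_initiation_model(medium_fu)


class TestFit:
    def test_no_initiations_is_degenerate(self):
        params = syn.default_scenario(n_patients=200, seed=3, init_intercept=-30.0)
        baseline, days = syn.generate_cohort(params)
        fu = build_followup(baseline, days)
        with pytest.raises(ValueError, match="degenerate outcome"):
            ipcw.fit_initiation_model(fu)

    def test_constant_rate_intercept_recovery(self):
        """Intercept-only fit on covariate-independent 10%/day initiation."""
        params = syn.random_initiation_scenario(rate=0.1, n_patients=3000, seed=21)
        baseline, days = syn.generate_cohort(params)
        fu = build_followup(baseline, days)
        spec = ipcw.CovariateSpec(daily=(), baseline=(), time_effect="none")
        model = ipcw.fit_initiation_model(fu, spec)
        assert model.coefficients["intercept"] == pytest.approx(np.log(0.1 / 0.9), abs=0.12)

    def test_model_converges_on_default_scenario(self, fitted):
        assert fitted.converged
        assert fitted.n_events > 50

    def test_coefficient_recovery_default_scenario(self):
        """Mean estimates across replicates track the generator's truth."""
        reps = []
        for seed in range(8):
            params = syn.default_scenario(n_patients=2500, seed=400 + seed)
            baseline, days = syn.generate_cohort(params)
            fu = build_followup(baseline, days)
            model = ipcw.fit_initiation_model(fu)
            reps.append(model.coefficients)
        mean = sum(reps) / len(reps)
        assert mean["k_ge_60"] == pytest.approx(4.0, abs=0.8)
        assert mean["ph_lt_720"] == pytest.approx(4.2, abs=0.8)
        assert mean["uo_stage3"] == pytest.approx(3.2, abs=0.6)

    def test_predictions_in_unit_interval(self, fitted, medium_fu):
        p = fitted.predict_matrix(medium_fu)
        finite = p[np.isfinite(p)]
        assert ((finite > 0) & (finite < 1)).all()


class TestWeights:
    def test_zero_initiation_probability_never_regime_gives_unit_weights(self):
        fu = make_fu(horizon=5)
        p = np.zeros((1, 30))
        presc = cc.prescriptions(fu, cc.NEVER_INITIATE)
        censor = cc.censor_days_matrix(fu, presc)
        series = ipcw.compute_ipc_weights(p, fu, presc, censor)
        w = series.weight[0, :5]
        assert np.allclose(w, 1.0)

    def test_closed_form_cumulative_product(self):
        """p_uncensored 0.8 on 3 consecutive days -> W = 1/0.8^3."""
        fu = make_fu(horizon=3)
        p = np.full((1, 30), 0.2)
        presc = cc.prescriptions(fu, cc.NEVER_INITIATE)  # never prescribes
        censor = cc.censor_days_matrix(fu, presc)
        series = ipcw.compute_ipc_weights(p, fu, presc, censor)
        assert series.weight[0, 2] == pytest.approx(1.953125, rel=1e-12)

    def test_concordant_start_day_uses_initiation_probability(self):
        fu = make_fu(horizon=4, obs_init_u=2, prescribe_days=(2,))
        p = np.full((1, 30), 0.25)
        presc = cc.prescriptions(fu, regime_by_index(1))
        censor = cc.censor_days_matrix(fu, presc)
        series = ipcw.compute_ipc_weights(p, fu, presc, censor)
        # days 0,1: 1/0.75; day 2 (start): additional 1/0.25; day 3: flat
        assert series.weight[0, 1] == pytest.approx((1 / 0.75) ** 2)
        assert series.weight[0, 2] == pytest.approx((1 / 0.75) ** 2 / 0.25)
        assert series.weight[0, 3] == pytest.approx(series.weight[0, 2])

    def test_exact_positivity_violation_raises(self):
        fu = make_fu(horizon=3, obs_init_u=1, prescribe_days=(1,))
        p = np.full((1, 30), 0.0)  # prescribed day has p_uncensored = 0
        presc = cc.prescriptions(fu, regime_by_index(1))
        censor = cc.censor_days_matrix(fu, presc)
        with pytest.raises(ValueError, match="positivity"):
            ipcw.compute_ipc_weights(p, fu, presc, censor)

    def test_weights_nondecreasing_and_at_least_one(self, medium_fu, fitted):
        p = fitted.predict_matrix(medium_fu)
        presc = cc.prescriptions(medium_fu, regime_by_index(27))
        censor = cc.censor_days_matrix(medium_fu, presc)
        series = ipcw.compute_ipc_weights(p, fu=medium_fu, prescribed=presc, censor_u=censor)
        w = series.weight
        assert np.nanmin(w) >= 1.0 - 1e-12
        diffs = np.diff(w, axis=1)
        assert np.nanmin(diffs) >= -1e-9

    def test_pseudo_population_reconstructs_original_size(self, medium_fu, fitted):
        """Weighted uncensored mass per day ~ number of clones still in
        follow-up (censored or not) at that day."""
        p = fitted.predict_matrix(medium_fu)
        for idx in (1, 27, 81):
            presc = cc.prescriptions(medium_fu, regime_by_index(idx))
            censor = cc.censor_days_matrix(medium_fu, presc)
            series = ipcw.compute_ipc_weights(p, medium_fu, presc, censor)
            unc = cc.uncensored_mask(medium_fu, censor)
            for day in (0, 3, 7):
                alive = medium_fu.valid[:, day].sum()
                mass = np.nansum(np.where(unc[:, day], series.weight[:, day], 0.0))
                assert mass / alive == pytest.approx(1.0, abs=0.12), (idx, day)


class TestNoninformativeCensoringOracle:
    """With covariate-independent initiation, the weighted never-initiate
    curve matches the full-cohort counterfactual wherever the risk set is
    still populated."""

    @pytest.mark.parametrize("rate,day", [(0.1, 15), (0.05, 30)])
    def test_matches_counterfactual(self, rate, day):
        import ccwdtr.estimation as est

        params = syn.random_initiation_scenario(rate=rate, n_patients=4000, seed=0)
        baseline, days = syn.generate_cohort(params)
        fu = build_followup(baseline, days)
        oracle = syn.simulate_counterfactual_cif(params, syn.NEVER, n_mc=60000, seed=77)
        censor = cc.censor_days_matrix(fu, cc.prescriptions(fu, cc.NEVER_INITIATE))
        risk, d1, d2 = est.mortality_matrices(fu, censor)
        w = np.ones(fu.valid.shape)
        curve = est.aalen_johansen_matrices(risk, d1, d2, w)
        var1, _ = est.ij_variance_matrices(risk, d1, d2, w, curve, np.arange(fu.n_patients))
        se = np.sqrt(var1[day] + oracle.se_death[day] ** 2)
        assert abs(curve.cif_death[day] - oracle.cif_death[day]) <= 3 * se


class TestTruncation:
    def test_percentile_one_is_identity(self):
        fu = make_fu(horizon=3)
        p = np.full((1, 30), 0.2)
        presc = cc.prescriptions(fu, cc.NEVER_INITIATE)
        series = ipcw.compute_ipc_weights(p, fu, presc, cc.censor_days_matrix(fu, presc))
        out = ipcw.truncate_weights(series, 1.0)
        assert out is series

    def test_order_statistic_cap(self):
        series = ipcw.WeightSeries(
            p_uncensored=np.full((4, 1), 0.5),
            weight=np.array([[1.0], [1.0], [1.0], [100.0]]),
        )
        out = ipcw.truncate_weights(series, 0.75)
        assert np.allclose(out.weight, 1.0)
        assert out.truncation_cap == 1.0
        assert out.untruncated_weight[3, 0] == 100.0

    def test_default_percentile_reduces_max_weight(self, medium_fu, fitted):
        p = fitted.predict_matrix(medium_fu)
        presc = cc.prescriptions(medium_fu, regime_by_index(9))
        censor = cc.censor_days_matrix(medium_fu, presc)
        series = ipcw.compute_ipc_weights(p, medium_fu, presc, censor)
        out = ipcw.truncate_weights(series, 0.995)
        assert out.max_weight() < series.max_weight()

    def test_invalid_percentile(self):
        series = ipcw.WeightSeries(p_uncensored=np.ones((1, 1)), weight=np.ones((1, 1)))
        with pytest.raises(ValueError):
            ipcw.truncate_weights(series, 0.4)


def test_spline_basis_is_linear_beyond_boundaries():
    knots = np.array([0.0, 5.0, 12.0, 25.0])
    x = np.array([26.0, 28.0, 30.0])
    basis = ipcw.natural_spline_basis(x, knots)
    # second differences vanish where the spline is linear
    second = np.diff(basis, n=2, axis=0)
    assert np.allclose(second, 0.0, atol=1e-8)
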