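import numpy as np
import pandas as pd
import pytest
from lifelines import KaplanMeierFitter

from ccwdtr import clone_censor as cc
from ccwdtr import estimation as est
from ccwdtr import synthetic as syn
from ccwdtr.followup import build_followup
from ccwdtr.regimes import regime_by_index

from conftest import random_survival_table
from test_clone_censor import make_fu


def hand_example_table():
    """4 unit-weight subjects: death day 1, discharge day 2, death day 3,
    in-ICU through day 30."""
    rows = []
    for pid, (event, day) in enumerate(
        [("death", 1), ("discharge", 2), ("death", 3), (None, None)]
    ):
        last = 29 if event is None else day
        for d in range(last + 1):
            ev = event if (event is not None and d == day) else "none"
            rows.append({"patient_id": pid, "day": d, "event": ev})
    return pd.DataFrame(rows)


class TestAalenJohansen:
    def test_hand_example(self):
        curve = est.weighted_aalen_johansen(hand_example_table())
        assert curve.cif_death[1] == pytest.approx(0.25)
        assert curve.cif_death[2] == pytest.approx(0.25)
        assert curve.cif_death[3] == pytest.approx(0.50)
        assert curve.cif_death[30] == pytest.approx(0.50)
        assert curve.cif_discharge[1] == pytest.approx(0.0)
        assert curve.cif_discharge[30] == pytest.approx(0.25)
        assert curve.surv[30] == pytest.approx(0.25)

    def test_reduces_to_one_minus_km(self, rng):
        """Unit weights + single event type == 1 - Kaplan-Meier, exactly."""
        for _ in range(50):
            table = random_survival_table(rng, n=rng.integers(5, 40), horizon=10)
            curve = est.weighted_aalen_johansen(table)
            durations = table.groupby("patient_id")["day"].max() + 1
            observed = table.groupby("patient_id")["event"].apply(lambda s: (s == "death").any())
            km = KaplanMeierFitter().fit(durations, observed)
            for day in range(10):
                s_km = float(km.survival_function_at_times(day + 1).iloc[0])
                assert curve.cif_death[day] == pytest.approx(1 - s_km, abs=1e-12)

    def test_weight_scale_invariance(self, rng):
        table = random_survival_table(rng, n=25, horizon=8)
        w = np.ones(len(table))
        a = est.weighted_aalen_johansen(table, weights=w)
        b = est.weighted_aalen_johansen(table, weights=2.0 * w)
        assert np.allclose(a.cif_death, b.cif_death)
        assert np.allclose(a.surv, b.surv)

    def test_negative_weights_rejected(self, rng):
        table = random_survival_table(rng, n=10, horizon=5)
        with pytest.raises(ValueError, match="negative"):
            est.weighted_aalen_johansen(table, weights=np.full(len(table), -1.0))

    def test_empty_risk_set_with_later_events_errors(self):
        risk = np.zeros((2, 5), dtype=bool)
        d1 = np.zeros((2, 5), dtype=bool)
        risk[0, 0] = True
        risk[1, 3] = True  # gap at days 1-2
        d1[1, 3] = True
        with pytest.raises(ValueError, match="empty risk set"):
            est.aalen_johansen_matrices(risk, d1, np.zeros_like(d1), np.ones((2, 5)))

    def test_invariants_on_generated_data(self, medium_fu):
        censor = np.full(medium_fu.n_patients, -1, dtype=np.int64)
        risk, d1, d2 = est.mortality_matrices(medium_fu, censor)
        curve = est.aalen_johansen_matrices(risk, d1, d2, np.ones_like(risk, dtype=float))
        curve.check_invariants()


class TestVariance:
    def test_single_patient_has_zero_ij_variance(self):
        table = pd.DataFrame(
            [{"patient_id": 1, "day": 0, "event": "none"}, {"patient_id": 1, "day": 1, "event": "death"}]
        )
        curve = est.weighted_aalen_johansen(table)
        est.estimate_variance(curve, table)
        assert np.allclose(curve.var_death, 0.0)

    def test_ij_close_to_greenwood(self, rng):
        """Single event, unit weights: IJ within 10% of Greenwood on 50
        random datasets (moderate daily hazards)."""
        checked = 0
        for _ in range(50):
            table = random_survival_table(rng, n=100, horizon=10, p_death=0.02)
            curve = est.weighted_aalen_johansen(table)
            est.estimate_variance(curve, table)
            # Greenwood from the same risk/death counts
            y = curve.w_risk
            d = curve.hazard_death * y
            with np.errstate(divide="ignore", invalid="ignore"):
                terms = np.where(y > d, d / (y * (y - d)), 0.0)
            s = np.append(np.cumprod(1 - curve.hazard_death), np.nan)
            greenwood = (s[:-1] ** 2) * np.cumsum(terms)
            day = 9
            if greenwood[day] > 0:
                checked += 1
                assert curve.var_death[day] == pytest.approx(greenwood[day], rel=0.10)
        assert checked >= 40

    def test_bootstrap_and_ij_agree_roughly(self, rng):
        table = random_survival_table(rng, n=150, horizon=10, p_death=0.04)
        curve = est.weighted_aalen_johansen(table)
        est.estimate_variance(curve, table, method="infinitesimal-jackknife")
        ij = curve.var_death[-1]
        est.estimate_variance(curve, table, method="patient-bootstrap", n_boot=400, seed=7)
        boot = curve.var_death[-1]
        assert boot == pytest.approx(ij, rel=0.5)

    def test_ci_clipped_and_ordered(self, rng):
        table = random_survival_table(rng, n=30, horizon=10, p_death=0.05)
        curve = est.weighted_aalen_johansen(table)
        est.estimate_variance(curve, table)
        lo, hi = curve.ci_death()
        assert 0.0 <= lo <= curve.mortality() <= hi <= 1.0

    def test_small_bootstrap_rejected(self, rng):
        table = random_survival_table(rng, n=10, horizon=5)
        curve = est.weighted_aalen_johansen(table)
        with pytest.raises(ValueError):
            est.estimate_variance(curve, table, method="patient-bootstrap", n_boot=1)

    def test_unknown_method_rejected(self, rng):
        table = random_survival_table(rng, n=10, horizon=5)
        curve = est.weighted_aalen_johansen(table)
        with pytest.raises(ValueError, match="unknown variance method"):
            est.estimate_variance(curve, table, method="jackknife-of-doom")


class TestExpectedInitiations:
    def test_observed_care_reduces_to_raw_count(self, medium_fu):
        """No censoring + unit weights: the estimate equals the observed
        number of initiations within the horizon."""
        presc = np.zeros_like(medium_fu.valid)
        o = medium_fu.obs_init_u
        presc[o >= 0, o[o >= 0]] = True  # concordant with observed behaviour
        censor = np.full(medium_fu.n_patients, -1, dtype=np.int64)
        count, lo, hi = est.expected_initiations_matrices(
            medium_fu,
            presc,
            censor,
            np.ones(medium_fu.valid.shape),
            cohort_size=medium_fu.n_patients,
            n_boot=100,
            seed=2,
        )
        raw = int((medium_fu.obs_init_u >= 0).sum())
        assert count == pytest.approx(raw, abs=1e-9)
        assert lo <= count <= hi

    def test_never_initiate_cohort_gives_zero(self):
        fu = make_fu(horizon=6)
        presc = cc.prescriptions(fu, cc.NEVER_INITIATE)
        censor = cc.censor_days_matrix(fu, presc)
        count, _, _ = est.expected_initiations_matrices(
            fu, presc, censor, np.ones(fu.valid.shape), cohort_size=1, n_boot=0
        )
        assert count == 0.0

    def test_initiation_on_death_day_counts(self):
        fu = make_fu(obs_init_u=2, prescribe_days=(2,), event_type=1, event_u=2)
        presc = cc.prescriptions(fu, regime_by_index(1))
        censor = cc.censor_days_matrix(fu, presc)
        count, _, _ = est.expected_initiations_matrices(
            fu, presc, censor, np.ones(fu.valid.shape), cohort_size=1, n_boot=0
        )
        assert count == pytest.approx(1.0)


def test_regime_evaluation_dict_round_trip():
    ev = est.RegimeEvaluation(3, 0.1, 0.05, 0.15, 40.0, 30.0, 50.0, 900.0)
    d = ev.as_dict()
    assert d["regime_index"] == 3 and d["effective_sample_size"] == 900.0
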