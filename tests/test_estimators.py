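"""Nelson-Aalen, Aalen-Johansen, KM, competing risks, chi-squared."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

import msmtrial as m
from msmtrial.estimators import (
    NumericalValidityError,
    StepCurve,
    aalen_johansen,
    chisq_2x2_yates,
    cuminc_competing,
    inverse_km_followup,
    km_survival,
    nelson_aalen,
)
from msmtrial.state_space import StateSpace, stack_transitions
from msmtrial.synthetic_data import PiecewiseRate, SimConfig, simulate_trial

TWO_STATE = StateSpace(("alive", "dead"), (("alive", "dead"),), name="two-state")


def _two_state_table(times, events):
    rows = [
        (f"P{i}", 1, "alive", "dead", 0.0, float(t), int(e), "control")
        for i, (t, e) in enumerate(zip(times, events))
    ]
    return pd.DataFrame(
        rows, columns=["patient_id", "transition_id", "from_state", "to_state",
                       "t_start", "t_stop", "status", "arm"])


class TestNelsonAalen:
    def test_single_event_among_three(self):
        table = _two_state_table([100.0, 200.0, 300.0], [1, 0, 0])
        h = nelson_aalen(table, 1)
        assert h.jump_times.tolist() == [100.0]
        assert h.increments.tolist() == [1 / 3]
        assert h.at_risk.tolist() == [3]

    def test_no_events_gives_zero_function(self):
        table = _two_state_table([100.0, 200.0], [0, 0])
        h = nelson_aalen(table, 1)
        assert h.jump_times.size == 0

    def test_increment_is_exactly_events_over_at_risk(self, default_cohort, model1):
        table = stack_transitions(default_cohort, model1)
        for tid in model1.transition_ids.values():
            h = nelson_aalen(table, tid)
            assert np.all(h.increments == h.n_events / h.at_risk)
            assert np.all(np.diff(h.jump_times) > 0)
            assert np.all((h.increments >= 0) & (h.increments <= 1))

    def test_constant_intensity_slope_recovered(self):
        """With a constant true intensity the cumulative hazard is ~linear;
        its empirical slope over early follow-up is within 5% of the rate."""
        lam = 1 / 500.0
        space = StateSpace(("Ind&Cons", "NRM"), (("Ind&Cons", "NRM"),))
        cfg = SimConfig(
            n_control=5000, n_clo=0, space=space,
            baseline={1: PiecewiseRate.constant(lam)},
            horizon_days=3000.0, accrual_days=0.0, seed=5)
        table = stack_transitions(simulate_trial(cfg), space)
        h = nelson_aalen(table, 1)
        curve = h.cumulative()
        q1 = 750.0  # first quartile of Exp(1/500) truncated follow-up
        slope = curve.at(q1) / q1
        assert abs(slope - lam) / lam < 0.05


class TestAalenJohansen:
    def test_two_state_equals_one_minus_km(self):
        rng = np.random.default_rng(11)
        times = np.round(rng.exponential(300, size=200), 0) + 1
        events = (rng.uniform(size=200) < 0.7).astype(int)
        table = _two_state_table(times, events)
        h = nelson_aalen(table, 1)
        path = aalen_johansen([h], TWO_STATE, s=0.0)
        km = km_survival(times, events)
        for t in km.times:
            assert path.at(t)[0, 1] == pytest.approx(1 - km.at(t), abs=1e-12)

    def test_origin_equals_identity(self, fixture_records, model1):
        table = stack_transitions(fixture_records, model1)
        hz = [nelson_aalen(table, tid) for tid in model1.transition_ids.values()]
        path = aalen_johansen(hz, model1, s=0.0)
        assert np.array_equal(path.at(0.0), np.eye(5))

    def test_rows_sum_to_one(self, default_cohort, model1):
        table = stack_transitions(default_cohort, model1)
        hz = [nelson_aalen(table, tid) for tid in model1.transition_ids.values()]
        path = aalen_johansen(hz, model1, s=0.0)
        sums = path.matrices.sum(axis=2)
        assert np.max(np.abs(sums - 1.0)) < 1e-10
        assert path.matrices.min() >= -1e-15

    def test_chapman_kolmogorov(self, default_cohort, model1):
        table = stack_transitions(default_cohort, model1)
        hz = [nelson_aalen(table, tid) for tid in model1.transition_ids.values()]
        p0 = aalen_johansen(hz, model1, s=0.0)
        u = float(np.median(p0.eval_times))
        pu = aalen_johansen(hz, model1, s=u)
        for t in p0.eval_times[p0.eval_times > u][::7]:
            lhs = p0.at(u) @ pu.at(t)
            assert np.max(np.abs(lhs - p0.at(t))) < 1e-10

    def test_absorbing_columns_nondecreasing(self, default_cohort, model1):
        table = stack_transitions(default_cohort, model1)
        hz = [nelson_aalen(table, tid) for tid in model1.transition_ids.values()]
        path = aalen_johansen(hz, model1, s=0.0)
        for absorbing in ("RM", "NRM"):
            j = path.states.index(absorbing)
            col = path.matrices[:, 0, j]
            assert np.all(np.diff(col) >= -1e-12)

    def test_excess_tied_increment_raises(self):
        space = StateSpace(("A", "B", "C"), (("A", "B"), ("A", "C")))
        bad = [
            m.CumulativeHazard(1, np.array([5.0]), np.array([0.6]),
                               np.array([5]), np.array([3])),
            m.CumulativeHazard(2, np.array([5.0]), np.array([0.6]),
                               np.array([5]), np.array([3])),
        ]
        with pytest.raises(NumericalValidityError, match="tie"):
            aalen_johansen(bad, space, s=0.0)


class TestKaplanMeierFollowup:
    def test_all_censored_at_seven_years(self):
        t = np.full(50, 7 * 365.25)
        assert inverse_km_followup(t, np.zeros(50)) == pytest.approx(7 * 365.25)

    def test_no_censoring_gives_absent(self):
        t = np.arange(1, 51, dtype=float)
        assert inverse_km_followup(t, np.ones(50)) is None

    def test_uniform_censoring_median_near_seven_years(self):
        rng = np.random.default_rng(23)
        n = 4000
        censor = rng.uniform(0, 14 * 365.25, size=n)
        death = rng.exponential(80 * 365.25, size=n)  # deaths rare
        t = np.minimum(censor, death)
        e = (death <= censor).astype(int)
        med = inverse_km_followup(t, e)
        assert med == pytest.approx(7 * 365.25, rel=0.05)


class TestCompetingRisks:
    def test_single_cause_no_censoring_is_ecdf(self):
        times = np.array([3.0, 1.0, 2.0, 2.0])
        causes = np.array(["relapse"] * 4, dtype=object)
        out = cuminc_competing(times, causes)
        curve = out["relapse"]
        assert curve.times.tolist() == [1.0, 2.0, 3.0]
        assert curve.values.tolist() == [0.25, 0.75, 1.0]

    def test_conservation(self):
        rng = np.random.default_rng(7)
        n = 300
        times = rng.integers(1, 50, size=n).astype(float)
        causes = rng.choice(["relapse", "NRM", "censored"], size=n).astype(object)
        out = cuminc_competing(times, causes)
        total = out["relapse"].values + out["NRM"].values + out["event_free"].values
        assert np.max(np.abs(total - 1.0)) < 1e-12

    def test_unknown_cause_label_rejected(self):
        with pytest.raises(ValueError):
            cuminc_competing([1.0], np.array(["event_free"], dtype=object))

    def test_equals_three_state_aalen_johansen(self):
        """The CIF estimator is an Aalen-Johansen special case: running the
        product integral on the equivalent 3-state space must agree to 1e-12."""
        rng = np.random.default_rng(19)
        n = 250
        times = rng.integers(1, 60, size=n).astype(float)
        causes = rng.choice(
            ["relapse", "NRM", "censored"], size=n, p=[0.4, 0.3, 0.3]).astype(object)
        out = cuminc_competing(times, causes)

        space = StateSpace(("event-free", "relapse", "NRM"),
                           (("event-free", "relapse"), ("event-free", "NRM")))
        rows = []
        for i, (t, c) in enumerate(zip(times, causes)):
            rows.append((f"P{i}", 1, "event-free", "relapse", 0.0, t,
                         int(c == "relapse"), "control"))
            rows.append((f"P{i}", 2, "event-free", "NRM", 0.0, t,
                         int(c == "NRM"), "control"))
        table = pd.DataFrame(rows, columns=[
            "patient_id", "transition_id", "from_state", "to_state",
            "t_start", "t_stop", "status", "arm"])
        hz = [nelson_aalen(table, 1), nelson_aalen(table, 2)]
        path = aalen_johansen(hz, space, s=0.0)
        for t in out["relapse"].times:
            P = path.at(t)
            assert P[0, 1] == pytest.approx(out["relapse"].at(t), abs=1e-12)
            assert P[0, 2] == pytest.approx(out["NRM"].at(t), abs=1e-12)
            assert P[0, 0] == pytest.approx(out["event_free"].at(t), abs=1e-12)


class TestChiSquared:
    def test_off_protocol_table_matches_published_p(self):
        # 35/168 vs 18/166 off-protocol patients
        stat, p = chisq_2x2_yates(35, 133, 18, 148)
        assert round(p, 3) == 0.019

    def test_equal_proportions_statistic_zero(self):
        stat, p = chisq_2x2_yates(10, 90, 10, 90)
        assert stat == 0.0 and p == 1.0

    def test_direct_formula_evaluation(self):
        # hand evaluation for the balanced 5/5/5/5 table: |ad-bc| = 0 -> 0
        stat, p = chisq_2x2_yates(5, 5, 5, 5)
        assert stat == 0.0 and p == 1.0
        # and for (10, 5, 3, 12): N=30, |ad-bc|=105, corrected 90,
        # stat = 30*90^2 / (15*15*13*17) = 243000/49725
        stat, p = chisq_2x2_yates(10, 5, 3, 12)
        assert stat == pytest.approx(243000 / 49725, abs=1e-12)
        assert p == pytest.approx(float(stats.chi2.sf(243000 / 49725, 1)), abs=1e-15)

    def test_agrees_with_scipy_contingency(self):
        obs = np.array([[35, 133], [18, 148]])
        ref_stat, ref_p, _, _ = stats.chi2_contingency(obs, correction=True)
        stat, p = chisq_2x2_yates(35, 133, 18, 148)
        assert stat == pytest.approx(ref_stat, abs=1e-12)
        assert p == pytest.approx(ref_p, abs=1e-12)

    def test_zero_margin_is_absent_with_warning(self):
        with pytest.warns(UserWarning):
            stat, p = chisq_2x2_yates(0, 0, 5, 5)
        assert np.isnan(stat) and np.isnan(p)


class TestStepCurve:
    def test_baseline_before_first_jump(self):
        c = StepCurve(np.array([2.0, 4.0]), np.array([0.5, 0.25]))
        assert c.at(1.0) == 1.0
        assert c.at(2.0) == 0.5
        assert c.at(5.0) == 0.25
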