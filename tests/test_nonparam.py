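import numpy as np
import pandas as pd
import pytest
from scipy.linalg import expm

from recurms import (CENSORED, DEAD, HOME, HOSPITAL, EventHistory,
                     TransitionRecord, aalen_johansen,
                     average_length_of_stay, basic_bootstrap_ci,
                     get_scenario, kaplan_meier, marginal_mean,
                     marginal_mean_path, nelson_aalen, resample_subjects,
                     rr_ratio, simulate_dataset, state_occupation,
                     validate_history)
from recurms.stepfun import StepFunction

from conftest import no_censoring_config


def rec(sid, frm, to, start, stop, status=1):
    return TransitionRecord(sid, frm, to, start, stop, status, {"Z": 0.0})


@pytest.fixture(scope="module")
def three_subject_history():
    """0->1 events at t=1 (3 at risk) and t=3 (1 at risk; one censored at 2)."""
    return validate_history([
        rec("A", 0, 1, 0, 1),
        rec("B", 0, CENSORED, 0, 2, status=0),
        rec("C", 0, 1, 0, 3),
    ])


class TestNelsonAalen:
    def test_no_transitions_gives_zero_function(self, three_subject_history):
        na = nelson_aalen(three_subject_history, (HOME, DEAD))
        assert na(100.0) == 0.0

    def test_hand_computed_increments(self, three_subject_history):
        na = nelson_aalen(three_subject_history)
        assert na(0.5) == 0.0
        assert na(1.0) == pytest.approx(1 / 3)
        assert na(2.9) == pytest.approx(1 / 3)
        assert na(3.0) == pytest.approx(1 / 3 + 1.0)

    def test_invariant_to_subject_relabeling(self, scenario1_dataset):
        df = scenario1_dataset.table.copy()
        relabeled = df.assign(id=df["id"].map(lambda i: f"x{997 * (i + 1) % 1811}"))
        a = nelson_aalen(scenario1_dataset)
        b = nelson_aalen(EventHistory(relabeled, validate=False))
        np.testing.assert_array_equal(a.times, b.times)
        np.testing.assert_allclose(a.values, b.values, rtol=1e-12)

    def test_invariant_to_splitting_a_record(self, three_subject_history):
        # split C's sojourn at an interior point; risk windows are unchanged
        df = three_subject_history.table
        split = pd.concat([
            df[df["id"] != "C"],
            pd.DataFrame({"id": ["C", "C"], "from": [0, 0], "to": [0, 1],
                          "start": [0.0, 1.7], "stop": [1.7, 3.0],
                          "status": [0, 1], "Z": [0.0, 0.0]}),
        ])
        a = nelson_aalen(three_subject_history)
        b = nelson_aalen(EventHistory(split, validate=False))
        np.testing.assert_array_equal(a.times, b.times)
        np.testing.assert_allclose(a.values, b.values, rtol=1e-15)


class TestKaplanMeier:
    def test_no_events_constant_one(self):
        km = kaplan_meier([5.0, 7.0], [0, 0])
        assert km(100.0) == 1.0

    def test_hand_computed_product_limit(self):
        km = kaplan_meier([1.0, 2.0, 3.0], [1, 0, 1])
        assert km(1.0) == pytest.approx(2 / 3)
        assert km(2.5) == pytest.approx(2 / 3)
        assert km(3.0) == 0.0

    def test_no_censoring_is_empirical_survival(self, rng):
        t = rng.exponential(10, 50)
        km = kaplan_meier(t, np.ones(50))
        grid = np.quantile(t, [0.1, 0.5, 0.9]) + 1e-9
        np.testing.assert_allclose(km(grid), [(t > g).mean() for g in grid],
                                   atol=1e-12)

    def test_agrees_with_lifelines(self, rng):
        from lifelines import KaplanMeierFitter
        t = rng.exponential(30, 80)
        e = rng.random(80) < 0.6
        km = kaplan_meier(t, e)
        ref = KaplanMeierFitter().fit(t, e)
        grid = np.linspace(0, t.max(), 37)
        np.testing.assert_allclose(
            km(grid), ref.survival_function_at_times(grid).to_numpy(),
            atol=1e-12)


class TestAalenJohansen:
    def test_identity_at_start_time(self, three_subject_history):
        path = aalen_johansen(three_subject_history, s=0.0)
        np.testing.assert_array_equal(path(0.0), np.eye(3))

    def test_rows_sum_to_one_everywhere(self, scenario1_dataset):
        path = aalen_johansen(scenario1_dataset)
        np.testing.assert_allclose(path.matrices.sum(axis=2), 1.0, atol=1e-10)

    def test_competing_risks_entry_equals_cumulative_incidence(self):
        # without recovery, P_01(0,t) = int S(u-) dLambda_01(u)
        records, rng = [], np.random.default_rng(8)
        for i in range(60):
            u, w = rng.exponential(50), rng.exponential(120)
            cause = HOSPITAL if rng.random() < 0.6 else DEAD
            t = min(u, w)
            records.append(rec(i, HOME, cause if w > u else CENSORED,
                               0, t, status=int(w > u)))
        h = validate_history(records)
        path = aalen_johansen(h)
        na01 = nelson_aalen(h, (HOME, HOSPITAL))
        tf = h.table[h.table["status"] == 1]["stop"].max()
        km = kaplan_meier(h.table["stop"],
                          (h.table["status"] == 1).astype(int))
        cif = float(np.sum(km.left_limit(na01.times) * na01.increments))
        assert path(tf)[HOME, HOSPITAL] == pytest.approx(cif, abs=1e-12)

    def test_uncensored_occupation_equals_empirical_fraction(
            self, uncensored_history):
        h = uncensored_history
        occ = state_occupation(h)
        for t in (100.0, 700.0, 2000.0):
            for s in (HOME, HOSPITAL, DEAD):
                emp = h.risk_set_size(s, t + 1e-9) / h.n_subjects
                assert occ[s](t) == pytest.approx(emp, abs=1e-12)

    def test_occupation_matches_matrix_exponential_oracle(self):
        cfg = no_censoring_config(n_subjects=4000, seed=17)
        occ = state_occupation(simulate_dataset(cfg, 0, validate=False))
        Q = np.array([[-0.0027, 0.002, 0.0007],
                      [0.004, -0.00475, 0.00075],
                      [0.0, 0.0, 0.0]])
        for t in (300.0, 1000.0, 2500.0):
            truth = expm(Q * t)[0]
            for s in (HOME, HOSPITAL, DEAD):
                assert occ[s](t) == pytest.approx(truth[s], abs=0.03)


class TestMarginalSummaries:
    def test_alos_zero_without_hospitalizations(self):
        q1 = StepFunction(np.array([]), np.array([]), 0.0)
        assert average_length_of_stay(q1, 500.0) == 0.0

    def test_alos_rectangle(self):
        q1 = StepFunction(np.array([10.0]), np.array([0.0]), 0.5)
        assert average_length_of_stay(q1, 20.0) == pytest.approx(5.0)
        with pytest.raises(ValueError):
            average_length_of_stay(q1, -1.0)

    def test_uncensored_alos_is_mean_hospital_time(self, uncensored_history):
        h = uncensored_history
        occ = state_occupation(h)
        for t in (500.0, 2000.0):
            alos = average_length_of_stay(occ[HOSPITAL], t)
            hosp = h.table[h.table["from"] == HOSPITAL]
            emp = (np.minimum(hosp["stop"], t)
                   - np.minimum(hosp["start"], t)).sum() / h.n_subjects
            assert alos == pytest.approx(emp, abs=1e-9)

    def test_uncensored_marginal_mean_is_mean_event_count(
            self, uncensored_history):
        h = uncensored_history
        occ = state_occupation(h)
        na = nelson_aalen(h)
        df = h.table
        for t in (400.0, 1500.0, 4000.0):
            mu = marginal_mean(occ[HOME], na, t)
            emp = ((df["from"] == HOME) & (df["to"] == HOSPITAL)
                   & (df["stop"] <= t)).sum() / h.n_subjects
            assert mu == pytest.approx(emp, abs=1e-12)

    def test_single_subject_single_event(self):
        h = validate_history([rec("s", 0, 1, 0, 5), rec("s", 1, 2, 5, 8)])
        occ = state_occupation(h)
        na = nelson_aalen(h)
        assert marginal_mean(occ[HOME], na, 100.0) == pytest.approx(1.0)
        path = marginal_mean_path(occ[HOME], na)
        assert path(4.9) == 0.0 and path(5.0) == pytest.approx(1.0)


class TestRRRatio:
    def test_identical_arms_give_one(self, uncensored_history):
        occ = state_occupation(uncensored_history)
        na = nelson_aalen(uncensored_history)
        mu = marginal_mean_path(occ[HOME], na)
        r = rr_ratio(mu, occ[DEAD], mu, occ[DEAD], 1000.0)
        assert r.ratio == 1.0

    def test_linear_in_event_count(self, uncensored_history):
        occ = state_occupation(uncensored_history)
        na = nelson_aalen(uncensored_history)
        mu = marginal_mean_path(occ[HOME], na)
        doubled = StepFunction(mu.times, 2 * mu.values, 0.0)
        r1 = rr_ratio(mu, occ[DEAD], mu, occ[DEAD], 1000.0)
        r2 = rr_ratio(doubled, occ[DEAD], mu, occ[DEAD], 1000.0)
        assert r2.ratio == pytest.approx(2 * r1.ratio)

    def test_null_scenario_ratio_near_one(self):
        h = simulate_dataset(get_scenario(1, n_subjects=2000, n_treated=1000,
                                          seed=29), 0, validate=False)
        by_arm = {}
        for arm in (0, 1):
            sub = EventHistory(h.table[h.table["Z"] == arm], validate=False)
            occ = state_occupation(sub)
            mu = marginal_mean_path(occ[HOME], nelson_aalen(sub))
            by_arm[arm] = (mu, occ[DEAD])
        r = rr_ratio(*by_arm[1], *by_arm[0], 1000.0)
        assert r.ratio == pytest.approx(1.0, abs=0.2)


class TestBootstrap:
    def test_constant_statistic_zero_width(self, toy_history, rng):
        lo, hi = basic_bootstrap_ci(lambda h: 42.0, toy_history, B=25, rng=rng)
        assert lo == hi == 42.0

    def test_basic_interval_reflection_identity(self, scenario1_dataset):
        # basic limits are the point estimate reflected around the
        # bootstrap quantiles: midpoint(lo, hi) = 2*theta - midpoint(q)
        stat = lambda h: nelson_aalen(h)(500.0)
        rng = np.random.default_rng(4)
        theta = stat(scenario1_dataset)
        draws = np.array([stat(resample_subjects(scenario1_dataset, rng))
                          for _ in range(40)])
        q_lo, q_hi = np.quantile(draws, [0.025, 0.975])
        lo, hi = 2 * theta - q_hi, 2 * theta - q_lo
        assert (lo + hi) / 2 == pytest.approx(2 * theta - (q_lo + q_hi) / 2)
        assert lo <= hi

    def test_bootstrap_interval_covers_point_estimate(self, scenario1_dataset):
        stat = lambda h: nelson_aalen(h)(800.0)
        lo, hi = basic_bootstrap_ci(stat, scenario1_dataset, B=60,
                                    rng=np.random.default_rng(5))
        assert lo < stat(scenario1_dataset) < hi

    def test_b_too_small_rejected(self, toy_history):
        with pytest.raises(ValueError):
            basic_bootstrap_ci(lambda h: 0.0, toy_history, B=1)

    def test_resample_preserves_cohort_size(self, scenario1_dataset, rng):
        r = resample_subjects(scenario1_dataset, rng)
        assert r.n_subjects == scenario1_dataset.n_subjects
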