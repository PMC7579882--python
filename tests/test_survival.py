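"""Product-limit estimation, median CI, log-rank test, delay combination."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from sitepace import (
    AllCensoredError,
    KaplanMeierEstimator,
    SurvivalSample,
    combine_delays,
    km_fit,
    km_median_ci,
    logrank_test,
)

# independent oracle for the from-scratch estimator
from lifelines import KaplanMeierFitter
from lifelines.statistics import logrank_test as lifelines_logrank


class TestKaplanMeier:
    def test_no_censoring_equals_empirical_survival(self):
        est = KaplanMeierEstimator().fit([1, 2, 3, 4, 5])
        np.testing.assert_allclose(est.survival_, [0.8, 0.6, 0.4, 0.2, 0.0])

    def test_hand_computed_censored_table(self):
        # subjects at 1, 2 (censored), 3: S(1) = 1 - 1/3, S(3) = S(1)*(1 - 1/1)
        est = KaplanMeierEstimator().fit([1, 2, 3], [True, False, True])
        np.testing.assert_allclose(est.event_times_, [1, 3])
        np.testing.assert_allclose(est.survival_, [2 / 3, 0.0])
        np.testing.assert_allclose(est.at_risk_, [3, 1])

    def test_single_subject(self):
        est = KaplanMeierEstimator().fit([7.0])
        assert est.predict(7.0) == 0.0
        assert est.predict(6.9) == 1.0

    def test_tied_event_and_censoring_keeps_censored_at_risk(self):
        # events precede censorings: the subject censored at t=2 is still
        # in the risk set for the event at t=2
        est = KaplanMeierEstimator().fit([2, 2, 5], [True, False, True])
        np.testing.assert_allclose(est.at_risk_, [3, 1])
        np.testing.assert_allclose(est.survival_, [2 / 3, 0.0])

    def test_all_censored_error_distinct_from_empty(self):
        with pytest.raises(AllCensoredError):
            KaplanMeierEstimator().fit([1, 2], [False, False])
        with pytest.raises(ValueError, match="empty"):
            KaplanMeierEstimator().fit([])

    def test_matches_lifelines_on_random_censored_samples(self, rng):
        worst = 0.0
        for _ in range(100):
            n = int(rng.integers(2, 51))
            d = rng.exponential(100, n).round(1)
            e = rng.random(n) < 0.7
            if not e.any():
                e[rng.integers(n)] = True
            est = KaplanMeierEstimator().fit(d, e)
            oracle = np.atleast_1d(
                np.asarray(KaplanMeierFitter().fit(d, e).predict(est.event_times_))
            )
            worst = max(worst, np.abs(est.survival_ - oracle).max())
        assert worst < 1e-12

    def test_sklearn_param_interface(self):
        est = KaplanMeierEstimator(conf_level=0.9)
        assert est.get_params() == {"conf_level": 0.9}
        est.set_params(conf_level=0.95)
        assert est.conf_level == 0.95

    @given(
        data=st.lists(
            st.tuples(st.floats(0, 1000), st.booleans()), min_size=1, max_size=60
        ).filter(lambda rows: any(e for _, e in rows))
    )
    def test_survival_is_monotone_in_unit_interval(self, data):
        d = np.array([t for t, _ in data])
        e = np.array([ev for _, ev in data])
        est = KaplanMeierEstimator().fit(d, e)
        s = est.survival_
        assert np.all((0 <= s) & (s <= 1))
        assert np.all(np.diff(s) <= 1e-15)
        assert np.all(np.diff(est.event_times_) > 0)
        assert np.all(np.diff(est.at_risk_) < 0)


class TestMedianCI:
    def test_median_all_events(self):
        curve = km_fit(SurvivalSample(np.arange(1, 6), np.ones(5, bool)))
        assert km_median_ci(curve).median == 3  # first time with S <= 0.5

    def test_median_not_reached(self):
        # heavy censoring keeps S above 0.5 throughout
        sample = SurvivalSample([1, 2, 3, 4], [True, False, False, False])
        est = km_median_ci(km_fit(sample))
        assert est.median is None
        assert est.ci_high is None

    def test_no_censoring_median_equals_empirical(self, rng):
        for _ in range(20):
            d = rng.exponential(100, int(rng.integers(5, 80)))
            est = KaplanMeierEstimator().fit(d)
            # earliest order statistic at which at most half survive
            expected = np.sort(d)[int(np.ceil(d.size / 2)) - 1]
            assert est.median_.median == pytest.approx(expected)

    def test_ci_matches_lifelines_band_inversion(self, rng):
        from lifelines.utils import median_survival_times

        d = rng.exponential(200, 48)
        e = rng.random(48) < 0.9
        ours = KaplanMeierEstimator().fit(d, e).median_
        kmf = KaplanMeierFitter().fit(d, e)
        lo, hi = median_survival_times(kmf.confidence_interval_).to_numpy().ravel()
        assert ours.median == pytest.approx(kmf.median_survival_time_)
        assert ours.ci_low == pytest.approx(lo)
        assert ours.ci_high == pytest.approx(hi)

    def test_parameter_recovery_from_known_lognormal(self, rng):
        """A large uncensored log-normal sample recovers its 182-day median."""
        d = rng.lognormal(mean=np.log(182), sigma=0.62, size=4000)
        est = KaplanMeierEstimator().fit(d).median_
        assert est.ci_low < 182 < est.ci_high
        assert est.median == pytest.approx(182, rel=0.05)


class TestLogRank:
    def test_identical_groups_give_null_result(self):
        d = np.array([3, 5, 8, 3, 5, 8], float)
        e = np.ones(6, bool)
        g = np.array(["a", "a", "a", "b", "b", "b"])
        res = logrank_test(SurvivalSample(d, e, group=g))
        assert res.chi_square == pytest.approx(0.0)
        assert res.p_value == pytest.approx(1.0)

    def test_hand_computed_two_groups_of_three(self):
        # groups A={1,3,5}, B={2,4,6}, no censoring; O-E and hypergeometric
        # variance accumulated over the six distinct event times by hand:
        # t : n  nA  O_A - E_A          V
        # 1 : 6  3   1 - 3/6 = 1/2      (3/6)(3/6)(5/5) = 1/4
        # 2 : 5  2   0 - 2/5            (2/5)(3/5)      = 6/25
        # 3 : 4  2   1 - 2/4 = 1/2      (2/4)(2/4)      = 1/4
        # 4 : 3  1   0 - 1/3            (1/3)(2/3)      = 2/9
        # 5 : 2  1   1 - 1/2 = 1/2      (1/2)(1/2)      = 1/4
        # 6 : 1  0   0                  0 (risk set of one)
        d = np.array([1, 3, 5, 2, 4, 6], float)
        g = np.array(["A"] * 3 + ["B"] * 3)
        res = logrank_test(SurvivalSample(d, np.ones(6, bool), group=g))
        o_minus_e = 1 / 2 - 2 / 5 + 1 / 2 - 1 / 3 + 1 / 2
        var = 1 / 4 + 6 / 25 + 1 / 4 + 2 / 9 + 1 / 4
        assert res.chi_square == pytest.approx(o_minus_e**2 / var)
        assert res.df == 1 and 0 <= res.p_value <= 1

    def test_matches_lifelines(self, rng):
        for _ in range(20):
            n = int(rng.integers(4, 40))
            d = rng.exponential(50, n)
            e = rng.random(n) < 0.8
            g = rng.integers(0, 2, n)
            if len(np.unique(g)) < 2 or not e.any():
                continue
            ours = logrank_test(SurvivalSample(d, e, group=g))
            oracle = lifelines_logrank(d[g == 0], d[g == 1], e[g == 0], e[g == 1])
            assert ours.chi_square == pytest.approx(oracle.test_statistic, rel=1e-9)
            assert ours.p_value == pytest.approx(oracle.p_value, rel=1e-9)

    def test_requires_two_groups(self):
        with pytest.raises(ValueError, match="two groups"):
            logrank_test(SurvivalSample([1, 2], [True, True], group=np.array(["a", "a"])))
        with pytest.raises(ValueError, match="group"):
            logrank_test(SurvivalSample([1, 2], [True, True]))


class TestCombineDelays:
    def test_observed_components_sum(self):
        a = SurvivalSample([100.0], [True], site_ids=np.array(["s1"]))
        b = SurvivalSample([50.0], [True], site_ids=np.array(["s1"]))
        c = combine_delays(a, b)
        assert c.durations[0] == 150.0 and c.event_observed[0]

    def test_censoring_propagates(self):
        # opened at day 100, never recruited before study end at day 300
        a = SurvivalSample([100.0], [True])
        b = SurvivalSample([200.0], [False])
        c = combine_delays(a, b)
        assert c.durations[0] == 300.0 and not c.event_observed[0]

    def test_alignment_by_site_id(self):
        a = SurvivalSample([10.0, 20.0], [True, True], site_ids=np.array(["x", "y"]))
        b = SurvivalSample([2.0, 1.0], [True, True], site_ids=np.array(["y", "x"]))
        c = combine_delays(a, b)
        np.testing.assert_allclose(c.durations, [11.0, 22.0])

    def test_mismatched_site_sets_error(self):
        a = SurvivalSample([10.0], [True], site_ids=np.array(["x"]))
        b = SurvivalSample([2.0], [True], site_ids=np.array(["z"]))
        with pytest.raises(ValueError, match="site sets"):
            combine_delays(a, b)
        with pytest.raises(ValueError, match="lengths"):
            combine_delays(SurvivalSample([1.0], [True]), SurvivalSample([1.0, 2.0], [True, True]))

    def test_slow_region_signal_strongest_in_combined_delay(self):
        """Combined approval-to-first-patient times separate the slow
        region more sharply than either component delay, mirroring the
        observed pattern (only the combined comparison reached p < 0.05).

        Averaged over 80 generator seeds on the clean cohort (every site
        opens, no pharmacy hold-ups) that isolates the multiplicative
        region effect: summing two delays that both carry the factor
        shrinks the relative spread, so the combined log-rank p is the
        smallest."""
        from dataclasses import replace

        from sitepace import SiteGenerationConfig, generate_site_table
        from sitepace.io import (
            combined_delay_sample,
            first_patient_sample,
            opening_delay_sample,
        )

        base = SiteGenerationConfig(
            n_sites=100, region_fraction_slow=0.3,
            slow_region_delay_multiplier=242 / 182, study_end_day=1500,
            open_probability=1.0, pharmacy_holdup_probability=0.0,
        )
        p_open, p_fp, p_combined = [], [], []
        for seed in range(80):
            records = generate_site_table(replace(base, seed=seed))
            p_open.append(logrank_test(opening_delay_sample(records)).p_value)
            p_fp.append(logrank_test(first_patient_sample(records)).p_value)
            p_combined.append(logrank_test(combined_delay_sample(records)).p_value)
        assert np.mean(p_combined) < np.mean(p_open)
        assert np.mean(p_combined) < np.mean(p_fp)
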