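import numpy as np
import pytest

from fitfatigue import (
    ModelParams,
    TrainingSeries,
    influence_decomposition,
    predict_2comp,
    response_characteristics,
)
from fitfatigue.fitting import FitResult
from fitfatigue.impulse import Variant
from fitfatigue.quantification import ladder_calendar
from fitfatigue.response import (
    cohort_influence_summary,
    cohort_response_summary,
)


def continuous_impulse_response(k1, tau1, k2, tau2, t):
    return k1 * np.exp(-t / tau1) - k2 * np.exp(-t / tau2)


class TestResponseCharacteristics:
    def test_population_scale_parameters(self):
        rc = response_characteristics(
            k1=0.0186, tau1=5.31, k2=0.0200, tau2=4.3
        )
        assert rc.tn == pytest.approx(1.641, abs=2e-3)
        assert rc.tg == pytest.approx(6.41, abs=5e-3)
        assert rc.pg == pytest.approx(0.00106, abs=2e-5)
        assert rc.tn_defined and rc.tg_defined

    def test_equal_gains_recover_immediately(self):
        rc = response_characteristics(k1=0.02, tau1=5.0, k2=0.02, tau2=3.0)
        assert rc.tn == 0.0
        assert rc.tn_defined

    def test_never_dipping_response_flags_tn_undefined(self):
        rc = response_characteristics(k1=0.03, tau1=5.0, k2=0.01, tau2=3.0)
        assert not rc.tn_defined
        assert np.isnan(rc.tn)
        # with tau1 > tau2 and k2 < k1 the response is maximal at t -> 0+,
        # so a strictly positive peak time does not exist either
        assert not rc.tg_defined

    def test_equal_time_constants_singular(self):
        with pytest.raises(ValueError, match="singular"):
            response_characteristics(k1=0.02, tau1=4.0, k2=0.03, tau2=4.0)

    def test_nonpositive_parameter_rejected(self):
        with pytest.raises(ValueError, match="k2"):
            response_characteristics(k1=0.02, tau1=4.0, k2=0.0, tau2=3.0)

    def test_formulas_match_dense_simulation(self):
        rng = np.random.default_rng(99)
        t = np.arange(1e-4, 80.0, 1e-3)
        for _ in range(10):
            tau2 = rng.uniform(1.0, 8.0)
            tau1 = tau2 * rng.uniform(1.1, 3.0)
            k1 = rng.uniform(0.005, 0.03)
            k2 = k1 * rng.uniform(1.01, 2.0)  # k2 > k1: response dips
            rc = response_characteristics(k1, tau1, k2, tau2)
            r = continuous_impulse_response(k1, tau1, k2, tau2, t)
            tg_sim = t[np.argmax(r)]
            crossing = np.flatnonzero((r[:-1] < 0) & (r[1:] >= 0))
            tn_sim = t[crossing[0]] if crossing.size else np.nan
            assert rc.tg == pytest.approx(tg_sim, abs=2e-3)
            assert rc.tn == pytest.approx(tn_sim, abs=2e-3)

    def test_pg_homogeneous_in_gains(self):
        rc1 = response_characteristics(0.01, 6.0, 0.015, 3.0)
        rc2 = response_characteristics(0.03, 6.0, 0.045, 3.0)
        assert rc2.pg == pytest.approx(3.0 * rc1.pg, rel=1e-12)
        assert rc2.tn == pytest.approx(rc1.tn, rel=1e-12)
        assert rc2.tg == pytest.approx(rc1.tg, rel=1e-12)


def two_comp(p0=0.5, k1=0.02, tau1=5.31, k2=0.021, tau2=4.3):
    return ModelParams(
        variant="2comp", p0=p0, k1=k1, tau1=tau1, k2=k2, tau2=tau2
    )


class TestInfluenceDecomposition:
    def test_identity_with_prediction(self, series_factory):
        for _ in range(5):
            s = series_factory(n_days=35)
            p = two_comp()
            inf = influence_decomposition(p, s)
            np.testing.assert_allclose(
                inf.ip_n + inf.in_n, predict_2comp(p, s) - p.p0,
                rtol=1e-10, atol=1e-12,
            )
            assert np.all(inf.in_n <= 0)
            assert np.all(inf.ip_n >= 0)

    def test_pure_adaptation_has_no_negative_influence(self, series_factory):
        s = series_factory()
        p = two_comp(k2=1e-300)  # k2 -> 0 limit (strictly positive gains)
        inf = influence_decomposition(p, s)
        np.testing.assert_allclose(inf.in_n, 0.0, atol=1e-250)
        np.testing.assert_allclose(
            inf.ip_n, predict_2comp(p, s) - p.p0, rtol=1e-10
        )

    def test_no_training_no_influence(self):
        s = TrainingSeries("r", np.zeros(10), np.array([1]), np.array([1.0]))
        inf = influence_decomposition(two_comp(), s)
        np.testing.assert_array_equal(inf.ip_n, 0.0)
        np.testing.assert_array_equal(inf.in_n, 0.0)

    def test_requires_two_component_params(self, series_factory):
        p = ModelParams(variant="1comp", p0=0.5, k1=0.02, tau1=5.0)
        with pytest.raises(ValueError, match="2comp"):
            influence_decomposition(p, series_factory())


def program_series(rat_id="r1"):
    days = ladder_calendar(19)
    w = np.zeros(25)
    w[days - 1] = np.linspace(40.0, 90.0, 19)
    return TrainingSeries(rat_id, w, days, np.full(19, 1.0))


def fit_stub(params, rat_ids):
    return FitResult(
        variant=Variant.TWO_COMP, shared={}, per_rat=params,
        predictions={}, rss=0.0, df=0, n_obs=0, converged=True,
        n_starts=1, best_start_seed=0, rat_ids=rat_ids,
    )


class TestCohortSummaries:
    def test_identical_rats_have_zero_sem(self):
        params = [two_comp(), two_comp()]
        cohort = type("C", (), {"rats": [program_series("a"),
                                         program_series("b")]})()
        out = cohort_influence_summary(fit_stub(params, ["a", "b"]), cohort)
        assert np.allclose(out["ip_sem"], 0.0)
        assert np.allclose(out["in_sem"], 0.0)

    def test_two_rat_mean_and_sem(self):
        # gains scaled 1x and 3x => influences 1x and 3x (homogeneity)
        p1 = two_comp(k1=0.01, k2=0.012)
        p3 = two_comp(k1=0.03, k2=0.036)
        cohort = type("C", (), {"rats": [program_series("a"),
                                         program_series("b")]})()
        out = cohort_influence_summary(fit_stub([p1, p3], ["a", "b"]), cohort)
        one = cohort_influence_summary(fit_stub([p1], ["a"]),
                                       type("C", (), {"rats":
                                            [program_series("a")]})())
        d = 20  # a mid-program day
        assert out["ip_mean"][d] == pytest.approx(2 * one["ip_mean"][d])
        # SEM of {x, 3x} = x: equals the single-rat value
        assert out["ip_sem"][d] == pytest.approx(one["ip_mean"][d])

    def test_single_rat_sem_missing(self):
        cohort = type("C", (), {"rats": [program_series("a")]})()
        out = cohort_influence_summary(fit_stub([two_comp()], ["a"]), cohort)
        assert out["ip_sem"].isna().all()

    def test_program_trends(self):
        """Adaptation accumulates over the program; fatigue clears in rests."""
        p = two_comp(k1=0.0186, k2=0.0200)
        s = program_series()
        inf = influence_decomposition(p, s)
        ip = inf.ip_n[s.measured_days - 1]
        # cumulative upward trend session over session (small local dips
        # at week boundaries allowed)
        assert ip[-1] > ip[0]
        assert np.polyfit(np.arange(ip.size), ip, 1)[0] > 0
        # |in| relaxes toward zero across each 2-day rest gap
        for last_training_day in (5, 12, 19):
            before = abs(inf.in_n[last_training_day])      # first rest day
            after = abs(inf.in_n[last_training_day + 1])   # second rest day
            assert after < before

    def test_response_summary_skips_undefined(self):
        params = [
            two_comp(k1=0.01, k2=0.02),   # dips: tn defined
            two_comp(k1=0.02, k2=0.01),   # never dips: tn undefined
        ]
        out = cohort_response_summary(fit_stub(params, ["a", "b"]))
        assert out.shape[0] == 4  # 2 rats + mean + sd
        per_rat = out[out.rat_id.isin(["a", "b"])]
        assert per_rat["tn_days"].isna().sum() == 1
        mean_row = out[out.rat_id == "mean"].iloc[0]
        assert mean_row["tn_days"] == pytest.approx(
            per_rat["tn_days"].dropna().iloc[0]
        )
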