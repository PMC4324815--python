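import dataclasses

import numpy as np
import pytest

from fitfatigue import (
    ModelParams,
    TrainingSeries,
    Variant,
    k2_series,
    predict,
    predict_1comp,
    predict_2comp,
    predict_3comp,
)


def impulse_series(w1=1.0, n_days=10):
    w = np.zeros(n_days)
    w[0] = w1
    return TrainingSeries(
        rat_id="r", w=w, measured_days=np.array([1]), p_obs=np.array([1.0])
    )


class TestClosedForms:
    def test_no_training_returns_baseline(self):
        s = TrainingSeries(
            "r", np.zeros(8), np.array([1]), np.array([1.0])
        )
        p = ModelParams(variant="1comp", p0=0.7, k1=0.02, tau1=5.0)
        np.testing.assert_allclose(predict_1comp(p, s), 0.7)

    def test_single_impulse_one_component(self):
        p = ModelParams(variant="1comp", p0=0.0, k1=1.0, tau1=1.0)
        out = predict_1comp(p, impulse_series())
        assert out[1] == pytest.approx(np.exp(-1.0), rel=1e-12)

    def test_single_impulse_two_components(self):
        p = ModelParams(
            variant="2comp", p0=0.0, k1=2.0, tau1=5.0, k2=1.0, tau2=2.0
        )
        out = predict_2comp(p, impulse_series(w1=10.0))
        expected = 20 * np.exp(-1.0) - 10 * np.exp(-2.5)
        assert out[5] == pytest.approx(expected, rel=1e-12)
        assert out[5] == pytest.approx(6.5367, abs=1e-4)

    def test_equal_components_cancel(self, series_factory):
        s = series_factory()
        p = ModelParams(
            variant="2comp", p0=0.4, k1=0.01, tau1=3.0, k2=0.01, tau2=3.0
        )
        np.testing.assert_allclose(predict_2comp(p, s), 0.4, rtol=1e-12)

    def test_gain_filter_single_impulse(self):
        p = ModelParams(
            variant="3comp", p0=0.0, k1=0.01, tau1=5.0, tau2=2.0,
            k2_0=0.01, k3=1e-4, tau3=4.0,
        )
        s = impulse_series(w1=50.0, n_days=12)
        dk2, _ = k2_series(p, s)
        i = np.arange(1, 13)
        np.testing.assert_allclose(
            dk2, 1e-4 * 50.0 * np.exp(-(i - 1) / 4.0), rtol=1e-12
        )


class TestNesting:
    def test_two_comp_reduces_to_one_comp(self, series_factory):
        s = series_factory()
        p1 = ModelParams(variant="1comp", p0=0.5, k1=0.02, tau1=6.0)
        p2 = ModelParams(
            variant="2comp", p0=0.5, k1=0.02, tau1=6.0, k2=0.0, tau2=3.0
        )
        np.testing.assert_allclose(
            predict_2comp(p2, s), predict_1comp(p1, s), rtol=0, atol=0
        )

    def test_three_comp_reduces_to_two_comp(self, series_factory):
        s = series_factory()
        p2 = ModelParams(
            variant="2comp", p0=0.5, k1=0.02, tau1=6.0, k2=0.013, tau2=3.0
        )
        p3 = ModelParams(
            variant="3comp", p0=0.5, k1=0.02, tau1=6.0, tau2=3.0,
            k2_0=0.013, k3=0.0, tau3=8.0,
        )
        np.testing.assert_allclose(
            predict_3comp(p3, s), predict_2comp(p2, s), rtol=1e-14
        )

    def test_zero_filter_gain_keeps_k2_constant(self, series_factory):
        s = series_factory()
        p3 = ModelParams(
            variant="3comp", p0=0.5, k1=0.02, tau1=6.0, tau2=3.0,
            k2_0=0.013, k3=0.0, tau3=8.0,
        )
        dk2, k2 = k2_series(p3, s)
        np.testing.assert_array_equal(dk2, 0.0)
        np.testing.assert_array_equal(k2, 0.013)


class TestOracleEquivalence:
    @pytest.mark.parametrize("variant", ["1comp", "2comp", "3comp"])
    @pytest.mark.parametrize("trial", range(5))
    def test_recursive_matches_direct(
        self, variant, trial, series_factory, params_factory
    ):
        s = series_factory(n_days=40)
        p = params_factory(variant)
        fast = predict(p, s)
        slow = predict(p, s, direct=True)
        np.testing.assert_allclose(fast, slow, rtol=1e-10, atol=1e-12)

    def test_gain_filter_recursion_matches_direct(
        self, series_factory, params_factory
    ):
        s = series_factory(n_days=40)
        p = params_factory("3comp")
        dk_fast, k_fast = k2_series(p, s)
        dk_slow, k_slow = k2_series(p, s, direct=True)
        np.testing.assert_allclose(dk_fast, dk_slow, rtol=1e-10)
        np.testing.assert_allclose(k_fast, k_slow, rtol=1e-10)


class TestStructuralProperties:
    def test_causality(self, params_factory, series_factory):
        s = series_factory(n_days=20)
        p = params_factory("2comp")
        base = predict(p, s)
        w2 = s.w.copy()
        w2[9] += 123.0  # day 10
        s2 = TrainingSeries("r", w2, s.measured_days, s.p_obs)
        out = predict(p, s2)
        np.testing.assert_array_equal(out[:10], base[:10])
        assert not np.allclose(out[10:], base[10:])

    def test_linearity_in_training(self, params_factory, series_factory):
        s = series_factory(n_days=20)
        p = params_factory("2comp")
        scaled = TrainingSeries("r", 3.0 * s.w, s.measured_days, s.p_obs)
        np.testing.assert_allclose(
            predict(p, scaled) - p.p0, 3.0 * (predict(p, s) - p.p0),
            rtol=1e-12,
        )

    def test_minus_sign_floors_fatigue_gain(self):
        p = ModelParams(
            variant="3comp", p0=0.0, k1=0.01, tau1=5.0, tau2=2.0,
            k2_0=0.005, k3=1e-3, tau3=4.0, third_sign="minus",
        )
        s = impulse_series(w1=100.0, n_days=8)
        _, k2 = k2_series(p, s)
        assert np.all(k2 >= 0.0)
        assert k2[0] == 0.0  # dk2(1) = 0.1 > k2_0, floored

    def test_sign_conventions_differ(self, series_factory):
        s = series_factory()
        kw = dict(p0=0.0, k1=0.01, tau1=5.0, tau2=2.0, k2_0=0.01,
                  k3=1e-5, tau3=4.0)
        plus = ModelParams(variant="3comp", third_sign="plus", **kw)
        minus = ModelParams(variant="3comp", third_sign="minus", **kw)
        assert not np.allclose(predict(plus, s), predict(minus, s))


class TestParamsValidation:
    def test_variant_mismatch_raises(self, params_factory, series_factory):
        s = series_factory()
        p = params_factory("1comp")
        with pytest.raises(ValueError, match="expected"):
            predict_2comp(p, s)
        with pytest.raises(ValueError, match="expected"):
            predict_3comp(p, s)
        with pytest.raises(ValueError, match="expected"):
            k2_series(p, s)

    def test_missing_fields_raise(self):
        with pytest.raises(ValueError, match="k2"):
            ModelParams(variant="2comp", p0=1.0, k1=0.01, tau1=5.0)
        with pytest.raises(ValueError, match="tau3|k3|k2_0"):
            ModelParams(variant="3comp", p0=1.0, k1=0.01, tau1=5.0, tau2=2.0)

    def test_nonpositive_time_constant_raises(self):
        with pytest.raises(ValueError, match="tau1"):
            ModelParams(variant="1comp", p0=1.0, k1=0.01, tau1=0.0)

    def test_unknown_variant_raises(self):
        with pytest.raises(ValueError, match="unknown"):
            ModelParams(variant="4comp", p0=1.0, k1=0.01, tau1=5.0)

    def test_serialization_round_trip(self, params_factory):
        p = params_factory("3comp")
        q = ModelParams.from_dict(p.to_dict())
        assert q == p
        assert q.variant is Variant.THREE_COMP
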