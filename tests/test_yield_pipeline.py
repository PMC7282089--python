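"""Yield, growth-rate and carbon-balance estimation."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

import fermflux as ff
from fermflux.yield_pipeline import CarbonBalance, _lnfit


def make_batch(times, glucose, od=None, **products):
    conc = {"glucose": np.asarray(glucose, float)}
    conc.update({k: np.asarray(v, float) for k, v in products.items()})
    return ff.TimeSeries(mode="batch", times=np.asarray(times, float), conc=conc,
                         od600=None if od is None else np.asarray(od, float))


class TestBatchYields:
    def test_two_point_ratio(self):
        ts = make_batch([0, 24], [100, 0], succinate=[0, 47])
        with pytest.warns(UserWarning):  # other product columns absent
            prof = ff.estimate_yields_batch(ts)
        assert prof.yields["succinate"] == pytest.approx(0.47)
        assert prof.glucose_consumed == pytest.approx(100.0)

    def test_window_is_max_consumption_point(self):
        # glucose stalls, then OD-independent lactate appears late: the
        # default window must reach the maximal-consumption sample
        ts = make_batch(
            [0, 10, 20, 30],
            [100, 30, 5, 5],
            succinate=[0, 35, 47.5, 47.5],
            lactate=[0, 0, 9.5, 19],
        )
        with pytest.warns(UserWarning):
            prof = ff.estimate_yields_batch(ts)
        assert prof.yields["succinate"] == pytest.approx(0.5)
        assert prof.yields["lactate"] == pytest.approx(0.1)

    def test_no_consumption_is_error(self):
        ts = make_batch([0, 5], [50, 50], succinate=[0, 1])
        with pytest.raises(ValueError, match="non-positive glucose consumption"):
            ff.estimate_yields_batch(ts)

    def test_missing_product_warns_and_zero(self):
        ts = make_batch([0, 10], [100, 0], succinate=[0, 47])
        with pytest.warns(UserWarning, match="ethanol"):
            prof = ff.estimate_yields_batch(ts)
        assert prof.yields["ethanol"] == 0.0

    def test_dilution_correction_applied_only_when_present(self):
        raw = make_batch([0, 10], [100, 40], succinate=[0, 24])
        diluted = ff.TimeSeries(
            mode="batch",
            times=raw.times,
            conc=raw.conc,
            dilution_factor=np.array([1.0, 1.25]),  # broth diluted by titrant
        )
        with pytest.warns(UserWarning):
            y_raw = ff.estimate_yields_batch(raw).yields["succinate"]
        with pytest.warns(UserWarning):
            y_corr = ff.estimate_yields_batch(diluted).yields["succinate"]
        assert y_raw == pytest.approx(24 / 60)
        assert y_corr == pytest.approx(30 / 50)

    @given(st.floats(min_value=0.01, max_value=100.0))
    def test_yields_invariant_to_common_rescaling(self, k):
        base = dict(times=[0, 6, 12], glucose=[100, 50, 10],
                    succinate=[0, 25, 45], ethanol=[0, 5, 9])
        ts1 = make_batch(base["times"], base["glucose"],
                         succinate=base["succinate"], ethanol=base["ethanol"])
        ts2 = make_batch(base["times"], np.array(base["glucose"]) * k,
                         succinate=np.array(base["succinate"]) * k,
                         ethanol=np.array(base["ethanol"]) * k)
        with pytest.warns(UserWarning):
            p1 = ff.estimate_yields_batch(ts1)
        with pytest.warns(UserWarning):
            p2 = ff.estimate_yields_batch(ts2)
        for p in ("succinate", "ethanol"):
            assert p2.yields[p] == pytest.approx(p1.yields[p], rel=1e-9)

    def test_regression_mode_matches_on_exact_data(self):
        times = np.arange(6.0)
        consumed = np.array([0, 10, 25, 45, 70, 100.0])
        ts = make_batch(times, 120 - consumed, succinate=0.47 * consumed)
        with pytest.warns(UserWarning):
            prof = ff.estimate_yields_batch(ts, method="regression")
        assert prof.yields["succinate"] == pytest.approx(0.47, abs=1e-12)


class TestGrowthRate:
    def test_exact_doubling(self):
        ts = make_batch(np.arange(5), 100 - 10 * np.arange(5),
                        od=0.1 * 2.0 ** np.arange(5))
        assert ff.estimate_growth_rate(ts) == pytest.approx(np.log(2), abs=1e-12)

    def test_constant_od_gives_zero(self):
        ts = make_batch(np.arange(6), np.linspace(100, 10, 6), od=np.full(6, 2.0))
        assert ff.estimate_growth_rate(ts) == pytest.approx(0.0, abs=1e-12)

    def test_exponential_phase_picked_out_of_mixed_curve(self):
        # growth at 0.3/h for 12 h, then a slow decline: the automatic window
        # must recover 0.3 despite the log-linear decline segment
        t = np.arange(0.0, 30.0, 3.0)
        od = np.where(t <= 12, 0.1 * np.exp(0.3 * t), 0.1 * np.exp(0.3 * 12))
        od = np.where(t > 12, od * np.exp(-0.005 * np.maximum(t - 12, 0)), od)
        ts = make_batch(t, np.linspace(100, 1, t.size), od=od)
        assert ff.estimate_growth_rate(ts) == pytest.approx(0.3, abs=1e-9)

    def test_too_few_points_is_error(self):
        ts = make_batch([0, 5], [100, 10], od=[0.1, 0.5])
        with pytest.raises(ValueError, match=">= 3"):
            ff.estimate_growth_rate(ts)

    def test_lnfit_r2_of_flat_data(self):
        slope, r2 = _lnfit(np.arange(4.0), np.zeros(4))
        assert slope == pytest.approx(0.0) and r2 == 1.0


class TestChemostat:
    def make_steady(self, residual, succinate, feed=27.8, D=0.1):
        n = len(residual)
        meta = ff.ConditionMeta(feed_glucose_mM=feed, dilution_rate_per_h=D)
        return ff.TimeSeries(
            mode="chemostat",
            times=(3.0 + np.arange(n)) / D,
            conc={"glucose": np.asarray(residual, float),
                  "succinate": np.asarray(succinate, float)},
            meta=meta,
        )

    def test_steady_state_arithmetic(self):
        ts = self.make_steady([0, 0, 0], [16.7, 16.7, 16.7])
        with pytest.warns(UserWarning):
            prof = ff.estimate_yields_chemostat(ts)
        assert prof.yields["succinate"] == pytest.approx(16.7 / 27.8)
        assert prof.yields_std["succinate"] == 0.0
        assert prof.growth_rate == pytest.approx(0.1)
        assert prof.meta.extras["steady_state_ok"]

    def test_washout_record_is_error(self):
        ts = self.make_steady([28.0, 27.9, 28.1], [0.1, 0.1, 0.1])
        with pytest.raises(ValueError, match="washout"):
            ff.estimate_yields_chemostat(ts)

    def test_early_samples_flagged_not_steady(self):
        ts = self.make_steady([0, 0, 0], [16.7, 16.7, 16.7])
        ts.times = np.array([1.0, 2.0, 3.0])  # < 3 retention times
        with pytest.warns(UserWarning):
            prof = ff.estimate_yields_chemostat(ts)
        assert not prof.meta.extras["steady_state_ok"]


class TestCarbonBalance:
    def test_low_co2_condition_leaves_20pct_unaccounted(self, model, low_profile):
        cb = ff.carbon_balance(low_profile, model)
        assert cb.unaccounted_fraction == pytest.approx(0.20, abs=1e-12)

    def test_high_co2_condition(self, model, high_profile):
        cb = ff.carbon_balance(high_profile, model)
        assert cb.accounted_cmol == pytest.approx(5.01, abs=1e-12)
        assert cb.unaccounted_fraction == pytest.approx(0.165, abs=1e-12)

    def test_zero_yields_fully_unaccounted(self, model):
        prof = ff.YieldProfile(yields={}, glucose_consumed=10.0)
        cb = ff.carbon_balance(prof, model)
        assert cb.unaccounted_fraction == 1.0 and cb.accounted_cmol == 0.0

    def test_infeasible_yields_rejected_at_construction(self):
        with pytest.raises(ValueError, match="C-mol"):
            ff.YieldProfile(yields={"succinate": 2.0, "lactate": 0.1},
                            glucose_consumed=1.0)

    @given(
        st.lists(st.floats(min_value=0, max_value=0.5), min_size=4, max_size=4)
    )
    def test_fractions_lie_in_unit_interval(self, model, ys):
        prof = ff.YieldProfile(
            yields=dict(zip(("succinate", "acetate", "lactate", "ethanol"), ys)),
            glucose_consumed=1.0,
        )
        cb = ff.carbon_balance(prof, model)
        assert 0.0 <= cb.accounted_fraction <= 1.0
        assert 0.0 <= cb.unaccounted_fraction <= 1.0

    def test_fraction_consistency_enforced(self):
        with pytest.raises(ValueError, match="sum to 1"):
            CarbonBalance(accounted_cmol=3.0, accounted_fraction=0.5,
                          unaccounted_fraction=0.4)


def test_profile_dict_roundtrip(low_profile):
    clone = ff.YieldProfile.from_dict(low_profile.to_dict())
    assert clone.yields == low_profile.yields
    assert clone.meta.co2_fraction == low_profile.meta.co2_fraction


def test_relative_yield_change(low_profile, high_profile):
    drop = ff.relative_yield_change(low_profile, high_profile, "succinate")
    assert drop == pytest.approx((0.64 - 0.47) / 0.64)
    with pytest.raises(ValueError, match="zero"):
        ff.relative_yield_change(
            low_profile,
            ff.YieldProfile(yields={"succinate": 0.0}, glucose_consumed=1.0),
            "succinate",
        )
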