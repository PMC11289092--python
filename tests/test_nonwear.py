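import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from wearqc import (
    BoettcherParams,
    NonwearDetector,
    Recording,
    RefinedParams,
    UniformSeries,
    ValidationError,
    channel_sqi,
    combine_boettcher,
    combine_refined,
    detect_nonwear,
    rolling_sd,
    sqi_to_intervals,
)
from wearqc.timebase import SQISeries

from conftest import brute_force_rolling_mean, brute_force_rolling_sd


def _series(values, rate=4.0, start=0.0, name="EDA", units="μS"):
    return UniformSeries(name, start, rate, np.asarray(values, float), units)


def _sqi(values, rate=4.0, start=0.0, name="SQI"):
    return SQISeries(name, start, rate, np.asarray(values, bool))


class TestRollingSd:
    def test_constant_series_gives_zero(self):
        out = rolling_sd(_series(np.full(50, 3.3)), 2.0)
        np.testing.assert_array_equal(out.values, np.zeros(50))

    @pytest.mark.parametrize("w_s", [0.5, 1.0, 2.5])
    def test_alternating_signal_matches_oracle(self, w_s):
        x = np.tile([1.0, -1.0], 40)
        out = rolling_sd(_series(x, rate=4.0), w_s)
        np.testing.assert_allclose(
            out.values, brute_force_rolling_sd(x, round(w_s * 4)), atol=1e-12)

    def test_random_series_matches_brute_force(self):
        rng = np.random.default_rng(0)
        x = rng.normal(size=211)
        out = rolling_sd(_series(x, rate=8.0), 1.375)  # 11-sample window
        np.testing.assert_allclose(
            out.values, brute_force_rolling_sd(x, 11), atol=1e-10)

    def test_multicomponent_per_axis(self):
        rng = np.random.default_rng(1)
        x = rng.normal(size=(100, 3))
        out = rolling_sd(_series(x, rate=32.0, name="ACC", units="g"), 0.25)
        for axis in range(3):
            np.testing.assert_allclose(
                out.values[:, axis], brute_force_rolling_sd(x[:, axis], 8),
                atol=1e-10)

    def test_window_shorter_than_two_samples_rejected(self):
        with pytest.raises(ValidationError):
            rolling_sd(_series(np.ones(10), rate=4.0), 0.25)


class TestChannelSqi:
    def test_temp_30c_splits_the_variants(self):
        temp = _series(np.full(20, 30.0), name="TEMP", units="°C")
        assert not channel_sqi(temp, "TEMP", "refined").values.any()
        assert channel_sqi(temp, "TEMP", "boettcher").values.all()

    def test_eda_between_thresholds_splits_the_variants(self):
        eda = _series(np.full(20, 0.04))
        assert channel_sqi(eda, "EDA", "refined").values.all()
        assert not channel_sqi(eda, "EDA", "boettcher").values.any()

    def test_threshold_comparisons_are_inclusive(self):
        assert channel_sqi(_series([0.03]), "EDA", "refined").values.all()
        temp = _series([32.0, 25.0, 40.0], name="TEMP", units="°C")
        assert channel_sqi(temp, "TEMP", "refined").values[0]
        assert channel_sqi(temp, "TEMP", "boettcher").values.all()

    def test_acc_x_axis_sd_above_refined_threshold(self):
        # alternating ±0.15 g on x: 1-s sample SD ≈ 0.152 g >= 0.1 g
        x = np.tile([0.15, -0.15], 64)
        acc = np.column_stack([x, np.zeros(128), np.ones(128)])
        sqi = channel_sqi(_series(acc, rate=32.0, name="ACC", units="g"),
                          "ACC", "refined")
        assert sqi.values.all()

    def test_acc_sd_sum_boettcher(self):
        # quiet on all axes: sum of three per-axis SDs stays below 0.2 g
        rng = np.random.default_rng(2)
        acc = rng.normal(0, 0.004, size=(640, 3))
        sqi = channel_sqi(_series(acc, rate=32.0, name="ACC", units="g"),
                          "ACC", "boettcher")
        assert not sqi.values.any()

    def test_unknown_channel_or_variant_rejected(self):
        with pytest.raises(ValidationError):
            channel_sqi(_series(np.ones(8)), "PPG")
        with pytest.raises(ValidationError):
            channel_sqi(_series(np.ones(8)), "EDA", variant="novel")

    @given(st.integers(0, 2**31 - 1))
    @settings(max_examples=25, deadline=None)
    def test_raising_eda_threshold_never_grows_onbody(self, seed):
        rng = np.random.default_rng(seed)
        eda = _series(rng.uniform(0.0, 0.1, size=64))
        lo = channel_sqi(eda, "EDA", "refined", RefinedParams(eda_threshold_us=0.02))
        hi = channel_sqi(eda, "EDA", "refined", RefinedParams(eda_threshold_us=0.05))
        assert not np.any(hi.values & ~lo.values)


class TestCombineRefined:
    def test_all_false_stays_false(self):
        f = _sqi(np.zeros(960))
        assert not combine_refined(f, f, f).values.any()

    def test_or_semantics_single_true_signal(self):
        t = _sqi(np.ones(960))
        f = _sqi(np.zeros(960))
        assert combine_refined(f, t, f).values.all()

    def test_brief_flicker_is_smoothed_out(self):
        # 10 s false inside a long true run: 40 of 240 window samples < 50 %
        v = np.ones(1920, bool)
        v[960:1000] = False
        out = combine_refined(_sqi(v), _sqi(np.zeros(1920)), _sqi(v))
        assert out.values[960:1000].all()

    def test_smoothing_matches_rolling_mean_oracle(self):
        rng = np.random.default_rng(3)
        v = rng.random(600) < 0.5
        out = combine_refined(_sqi(np.zeros(600)), _sqi(np.zeros(600)), _sqi(v))
        expected = brute_force_rolling_mean(v.astype(float), 240) >= 0.5
        np.testing.assert_array_equal(out.values, expected)

    def test_output_on_eda_grid(self):
        acc = _sqi(np.ones(3200), rate=32.0)
        temp = _sqi(np.ones(400), rate=4.0)
        eda = _sqi(np.ones(400), rate=4.0)
        out = combine_refined(acc, temp, eda)
        assert out.sample_rate_hz == 4.0
        assert len(out) == 400

    def test_empty_overlap_rejected(self):
        a = _sqi(np.ones(40), start=0.0)
        b = _sqi(np.ones(40), start=1000.0)
        with pytest.raises(ValidationError):
            combine_refined(a, b, b)

    @given(st.integers(0, 2**31 - 1))
    @settings(max_examples=25, deadline=None)
    def test_or_monotonicity(self, seed):
        """Making any input pointwise more on-body never turns combined
        output samples off."""
        rng = np.random.default_rng(seed)
        base = rng.random(480) < 0.3
        more = base | (rng.random(480) < 0.3)
        f = _sqi(np.zeros(480))
        out_base = combine_refined(_sqi(base), f, _sqi(base)).values
        out_more = combine_refined(_sqi(more), f, _sqi(base)).values
        assert not np.any(out_base & ~out_more)


class TestCombineBoettcher:
    def test_all_false_gives_false_windows(self):
        f = _sqi(np.zeros(960))
        out = combine_boettcher(f, f, f)
        assert not out.values.any()
        assert out.sample_rate_hz == pytest.approx(1 / 60)

    def test_one_percent_rule_inclusive(self):
        # 4 of 240 samples true (1.67 %) -> window on-body
        v = np.zeros(240, bool)
        v[100:104] = True
        f = _sqi(np.zeros(240))
        assert combine_boettcher(f, f, _sqi(v)).values[0]

    def test_below_one_percent_stays_false(self):
        # 2 of 240 samples true (0.83 %) -> window off-body
        v = np.zeros(240, bool)
        v[100:102] = True
        f = _sqi(np.zeros(240))
        assert not combine_boettcher(f, f, _sqi(v)).values[0]

    def test_short_recording_yields_single_truncated_window(self):
        v = _sqi(np.ones(40))  # 10 s of data
        out = combine_boettcher(v, v, v)
        assert len(out) == 1 and out.values[0]


class TestSqiToIntervals:
    def test_all_true_patterns(self):
        sqi = _sqi(np.ones(20), rate=4.0, start=100.0)
        assert len(sqi_to_intervals(sqi, "nonwear")) == 0
        on = sqi_to_intervals(sqi, "onbody")
        np.testing.assert_allclose(on.intervals, [[100.0, 105.0]])

    def test_run_length_encoding(self):
        sqi = _sqi([True, True, False, False, True], rate=1.0, start=0.0)
        np.testing.assert_allclose(
            sqi_to_intervals(sqi, "nonwear").intervals, [[2.0, 4.0]])
        np.testing.assert_allclose(
            sqi_to_intervals(sqi, "onbody").intervals, [[0.0, 2.0], [4.0, 5.0]])

    @given(st.integers(0, 2**31 - 1))
    @settings(max_examples=25, deadline=None)
    def test_onbody_and_nonwear_tile_the_span(self, seed):
        rng = np.random.default_rng(seed)
        sqi = _sqi(rng.random(97) < 0.5, rate=4.0, start=50.0)
        on = sqi_to_intervals(sqi, "onbody")
        off = sqi_to_intervals(sqi, "nonwear")
        assert on.total_duration + off.total_duration == pytest.approx(
            sqi.duration_s)
        merged = np.sort(np.vstack([on.intervals.reshape(-1, 2),
                                    off.intervals.reshape(-1, 2)]), axis=0)
        if len(merged):
            assert merged[0, 0] == pytest.approx(50.0)
            np.testing.assert_allclose(merged[1:, 0], merged[:-1, 1])


class TestDetectNonwear:
    def test_all_wear_scenario_detects_nothing(self, allwear_scenario):
        _, rec, _ = allwear_scenario
        _, nonwear = detect_nonwear(rec, "refined")
        assert len(nonwear) == 0

    def test_refined_output_granularity(self, allwear_scenario):
        _, rec, _ = allwear_scenario
        sqi, _ = detect_nonwear(rec, "refined")
        spacing = np.diff(sqi.timestamps())
        assert np.allclose(spacing, 0.25)

    def test_boettcher_output_granularity(self, allwear_scenario):
        _, rec, _ = allwear_scenario
        sqi, _ = detect_nonwear(rec, "boettcher")
        assert np.allclose(np.diff(sqi.timestamps()), 60.0)

    def test_bout_recovered_with_high_iou(self, bout_scenario):
        cfg, rec, truth = bout_scenario
        _, nonwear = detect_nonwear(rec, "refined")
        assert len(nonwear) == 1
        (ds, de), = nonwear.intervals
        ts, te = cfg.start_time + 600.0, cfg.start_time + 1200.0
        inter = max(0.0, min(de, te) - max(ds, ts))
        union = max(de, te) - min(ds, ts)
        assert inter / union >= 0.8

    def test_sample_level_sensitivity_and_specificity(self, bout_scenario):
        """On the default scenario with a >= 5-min bout the refined detector
        reaches >= 0.9 sensitivity (non-wear) and specificity (wear)."""
        _, rec, truth = bout_scenario
        sqi, _ = detect_nonwear(rec, "refined")
        wear_true = truth.contains(sqi.timestamps())
        pred_onbody = sqi.values
        sens = np.mean(~pred_onbody[~wear_true])
        spec = np.mean(pred_onbody[wear_true])
        assert sens >= 0.9
        assert spec >= 0.9

    def test_missing_channel_named_in_error(self, allwear_scenario):
        _, rec, _ = allwear_scenario
        partial = Recording(channels={k: v for k, v in rec.channels.items()
                                      if k != "TEMP"})
        with pytest.raises(ValidationError, match="TEMP"):
            detect_nonwear(partial, "refined")

    def test_estimator_params_round_trip(self):
        det = NonwearDetector(variant="boettcher")
        assert det.get_params()["variant"] == "boettcher"
        det.set_params(variant="refined")
        assert det.fit().params_ == RefinedParams()
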