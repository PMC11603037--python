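"""Window algebra, grid resampling, composites, cumulative doses,
missingness indicators, imputation, and scaling."""

import numpy as np
import pandas as pd
import pytest

from trapod.preprocess import (
    ObservationWindow,
    ScalerStats,
    SequenceTensor,
    StaticMatrix,
    add_missing_indicators,
    apply_scaler,
    assemble_inputs,
    broadcast_static,
    cumulative_doses,
    fit_scaler,
    impute,
    merge_composites,
    parse_window,
    resample_to_grid,
    resolve_window,
)


class TestWindows:
    @pytest.mark.parametrize(
        "text,t_end,expected",
        [
            ("0:30", 120.0, (0.0, 30.0)),  # first intraoperative 30 min
            ("-30:end", 120.0, (90.0, 120.0)),  # last 30 min
            ("begin:end", 45.0, (0.0, 45.0)),
            ("full", 45.0, (0.0, 45.0)),
            ("30:60", 100.0, (30.0, 60.0)),
        ],
    )
    def test_resolution(self, text, t_end, expected):
        assert resolve_window(parse_window(text), t_end) == expected

    def test_empty_window_errors(self):
        # [20, -30] resolves to [20, 10) for a 40-minute surgery
        with pytest.raises(ValueError, match="empty"):
            resolve_window(parse_window("20:-30"), 40.0)

    def test_nonpositive_t_end_errors(self):
        with pytest.raises(ValueError):
            resolve_window(parse_window("0:30"), 0.0)


def make_events(rows):
    return pd.DataFrame(
        rows, columns=["surgery_id", "patient_id", "feature_name",
                       "t_offset_min", "value"]
    )


class TestResample:
    def test_mean_aggregation_in_bin(self):
        ev = make_events([("s1", "p1", "bp", 0.0, 1.0),
                          ("s1", "p1", "bp", 1.0, 2.0),
                          ("s1", "p1", "bp", 2.0, 3.0)])
        t = resample_to_grid(ev, parse_window("0:30"), 3.0, ["bp"], ["s1"],
                             {"s1": 120.0})
        assert t.values[0, 0, 0] == 2.0
        assert t.mask[0, 0, 0] == 0

    def test_empty_bin_missing_with_mask(self):
        ev = make_events([("s1", "p1", "bp", 0.0, 1.0)])
        t = resample_to_grid(ev, parse_window("0:30"), 3.0, ["bp"], ["s1"],
                             {"s1": 120.0})
        assert np.isnan(t.values[0, 0, 1]) and t.mask[0, 0, 1] == 1

    def test_thirty_minutes_at_three_gives_ten_steps(self):
        ev = make_events([("s1", "p1", "bp", 0.0, 1.0)])
        t = resample_to_grid(ev, parse_window("0:30"), 3.0, ["bp"], ["s1"],
                             {"s1": 120.0})
        assert t.n_steps == 10

    def test_window_shorter_than_interval_errors(self):
        ev = make_events([("s1", "p1", "bp", 0.0, 1.0)])
        with pytest.raises(ValueError):
            resample_to_grid(ev, parse_window("0:2"), 3.0, ["bp"], ["s1"],
                             {"s1": 120.0})

    def test_pre_window_events_ignored(self):
        ev = make_events([("s1", "p1", "bp", -5.0, 999.0),
                          ("s1", "p1", "bp", 1.0, 2.0)])
        t = resample_to_grid(ev, parse_window("0:30"), 3.0, ["bp"], ["s1"],
                             {"s1": 120.0})
        assert t.values[0, 0, 0] == 2.0


class TestComposites:
    def test_concatenate_then_mean(self, toy_events, toy_specs):
        merged = merge_composites(toy_events, toy_specs)
        t = resample_to_grid(merged, parse_window("0:30"), 3.0,
                             ["map_combined"], ["s1"], {"s1": 120.0})
        assert t.values[0, 0, 0] == 85.0  # mean of 80 (nibp) and 90 (ibp)

    def test_members_retained(self, toy_events, toy_specs):
        merged = merge_composites(toy_events, toy_specs)
        assert {"nibp_map", "ibp_map"} <= set(merged.feature_name)

    def test_no_member_observations_leaves_composite_missing(self, toy_specs):
        ev = make_events([("s1", "p1", "bp", 0.0, 1.0)])
        merged = merge_composites(ev, toy_specs)
        t = resample_to_grid(merged, parse_window("0:30"), 3.0,
                             ["map_combined"], ["s1"], {"s1": 120.0})
        assert t.mask[0, 0].all()


def seq(values, mask=None, names=None):
    values = np.asarray(values, dtype=float)[None, :, :]
    if mask is None:
        mask = np.isnan(values).astype(np.int8)
    else:
        mask = np.asarray(mask, dtype=np.int8)[None, :, :]
    names = names or [f"ch{i}" for i in range(values.shape[1])]
    return SequenceTensor(values, mask, names, ["s1"], 3.0)


class TestCumulative:
    def test_running_sum(self, toy_specs):
        t = seq([[2.0, np.nan, 3.0]], names=["propofol"])
        out = cumulative_doses(t, toy_specs)
        assert out.channel_names[-1] == "propofol__cum"
        np.testing.assert_array_equal(out.values[0, 1], [2.0, 2.0, 5.0])
        assert (out.mask[0, 1] == 0).all()

    def test_all_empty_gives_zeros(self, toy_specs):
        t = seq([[np.nan, np.nan, np.nan]], names=["propofol"])
        out = cumulative_doses(t, toy_specs)
        np.testing.assert_array_equal(out.values[0, 1], [0.0, 0.0, 0.0])

    def test_matches_prefix_sum_oracle(self, toy_specs):
        rng = np.random.default_rng(3)
        doses = rng.random(12)
        t = seq([doses], names=["propofol"])
        out = cumulative_doses(t, toy_specs)
        expected = [sum(doses[: i + 1]) for i in range(12)]  # brute force
        np.testing.assert_allclose(out.values[0, 1], expected)

    def test_negative_dose_rejected(self, toy_specs):
        t = seq([[1.0, -2.0, 0.0]], names=["propofol"])
        with pytest.raises(ValueError, match="negative dose"):
            cumulative_doses(t, toy_specs)


class TestIndicators:
    def test_indicator_copies_mask(self, toy_specs):
        t = seq([[np.nan, 5.0, np.nan]], names=["bp"])
        out = add_missing_indicators(t, toy_specs)
        assert out.channel_names[-1] == "bp__missing"
        np.testing.assert_array_equal(out.values[0, 1], [1.0, 0.0, 1.0])

    def test_only_flagged_features_get_indicators(self, toy_specs):
        t = seq([[1.0, 2.0], [3.0, 4.0]], names=["bp", "nibp_map"])
        out = add_missing_indicators(t, toy_specs)
        assert out.channel_names == ["bp", "nibp_map", "bp__missing"]

    def test_fully_observed_gives_zero_indicator(self, toy_specs):
        t = seq([[1.0, 2.0, 3.0]], names=["bp"])
        out = add_missing_indicators(t, toy_specs)
        assert (out.values[0, 1] == 0).all()


class TestImpute:
    def stats(self, **means):
        s = ScalerStats()
        s.impute_mean.update(means)
        return s

    def test_locf_with_leading_mean(self):
        t = seq([[np.nan, 5.0, np.nan, 7.0]], names=["bp"])
        out = impute(t, self.stats(bp=4.0))
        np.testing.assert_array_equal(out.values[0, 0], [4.0, 5.0, 5.0, 7.0])

    def test_fully_observed_unchanged(self):
        t = seq([[1.0, 2.0, 3.0]], names=["bp"])
        out = impute(t, self.stats(bp=99.0))
        np.testing.assert_array_equal(out.values[0, 0], [1.0, 2.0, 3.0])

    def test_all_missing_gets_train_mean(self):
        t = seq([[np.nan] * 4], names=["bp"])
        out = impute(t, self.stats(bp=2.5))
        np.testing.assert_array_equal(out.values[0, 0], [2.5] * 4)

    def test_mask_not_altered(self):
        t = seq([[np.nan, 5.0, np.nan, 7.0]], names=["bp"])
        mask_before = t.mask.copy()
        out = impute(t, self.stats(bp=0.0))
        np.testing.assert_array_equal(out.mask, mask_before)

    def test_unknown_channel_errors(self):
        t = seq([[1.0, np.nan]], names=["bp"])
        with pytest.raises(KeyError):
            impute(t, self.stats(other=0.0))


class TestScaler:
    def test_train_data_standardized_to_unit(self):
        rng = np.random.default_rng(1)
        vals = rng.normal(50, 9, size=(20, 2, 6))
        t = SequenceTensor(vals, np.zeros_like(vals, dtype=np.int8),
                           ["a", "b"], [f"s{i}" for i in range(20)], 3.0)
        scaler = fit_scaler(t)
        out = apply_scaler(t, scaler)
        for j in range(2):
            assert abs(out.values[:, j, :].mean()) < 1e-9
            assert abs(out.values[:, j, :].std() - 1) < 1e-9

    def test_constant_channel_maps_to_zero(self):
        vals = np.full((3, 1, 4), 7.0)
        t = SequenceTensor(vals, np.zeros_like(vals, dtype=np.int8), ["c"],
                           ["s1", "s2", "s3"], 3.0)
        out = apply_scaler(t, fit_scaler(t))
        assert (out.values == 0).all()

    def test_train_stats_differ_from_test_fitted(self):
        rng = np.random.default_rng(2)
        tr = SequenceTensor(rng.normal(0, 1, (10, 1, 5)),
                            np.zeros((10, 1, 5), dtype=np.int8), ["a"],
                            list(range(10)), 3.0)
        te = SequenceTensor(rng.normal(5, 1, (10, 1, 5)),
                            np.zeros((10, 1, 5), dtype=np.int8), ["a"],
                            list(range(10)), 3.0)
        with_train = apply_scaler(te, fit_scaler(tr)).values
        with_test = apply_scaler(te, fit_scaler(te)).values
        assert not np.allclose(with_train, with_test)

    def test_apply_before_fit_errors(self):
        t = seq([[1.0, 2.0]], names=["a"])
        with pytest.raises(RuntimeError):
            apply_scaler(t, ScalerStats())


class TestBroadcastStatic:
    def test_constant_channel(self):
        sm = StaticMatrix(np.array([[60.0], [45.0]]), ["age"], ["s1", "s2"])
        t = broadcast_static(sm, 10)
        assert t.values.shape == (2, 1, 10)
        assert (t.values[0, 0] == 60.0).all()

    def test_time_slice_recovers_matrix(self):
        rng = np.random.default_rng(0)
        vals = rng.random((4, 3))
        sm = StaticMatrix(vals, ["a", "b", "c"], list(range(4)))
        t = broadcast_static(sm, 7)
        for step in range(7):
            np.testing.assert_array_equal(t.values[:, :, step], vals)


class TestPipeline:
    def test_rerun_byte_identical(self, small_cohort):
        from trapod.simulate import default_config, simulated_feature_specs

        events, statics, nudesc, truth = small_cohort
        specs = simulated_feature_specs(default_config())
        ids = list(statics["surgery_id"])[:40]
        t_end = dict(zip(statics["surgery_id"], statics["op_length_min"]))
        a = assemble_inputs(events, statics, specs, parse_window("0:30"), 3.0,
                            ids, t_end)
        b = assemble_inputs(events, statics, specs, parse_window("0:30"), 3.0,
                            ids, t_end)
        np.testing.assert_array_equal(a[0].values, b[0].values)
        np.testing.assert_array_equal(a[0].mask, b[0].mask)

    def test_channel_budget(self, small_cohort):
        # channels = dynamic + composites + cumulative + indicators
        from trapod.simulate import default_config, simulated_feature_specs

        events, statics, nudesc, truth = small_cohort
        specs = simulated_feature_specs(default_config())
        ids = list(statics["surgery_id"])[:25]
        t_end = dict(zip(statics["surgery_id"], statics["op_length_min"]))
        tensor, _, _ = assemble_inputs(events, statics, specs,
                                       parse_window("0:30"), 3.0, ids, t_end)
        n_dynamic = sum(s.is_dynamic for s in specs)
        n_cum = sum(s.cumulative for s in specs)
        n_ind = sum(s.missing_indicator for s in specs)
        assert len(tensor.channel_names) == n_dynamic + n_cum + n_ind
        assert not np.isnan(tensor.values).any()
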