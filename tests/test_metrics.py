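"""Ultradian power statistics: thresholds, periods, onset/offset, groups."""

import copy

import numpy as np
import pytest
from scipy import stats

from urwave import (
    PeriodBand,
    TimeSeriesTrace,
    TraceModel,
    analyze_trace,
    average_ur_power,
    classify_ur,
    compare_groups,
    cwt,
    detect_window,
    estimate_period,
    generate_trace,
    instantaneous_ur_power,
    preprocess,
    screen_mutants,
    ur_spectrum,
)
from urwave.wavelet import UR_BAND_DEFAULT


def spectra_for(models_or_traces):
    return [ur_spectrum(tr) for tr in models_or_traces]


class TestInstantaneousPower:
    def test_pure_ultradian_cosine_is_high_and_flat(self, cosine_trace):
        sp = cwt(preprocess(cosine_trace(3.0)))
        times, mean, sem, per = instantaneous_ur_power([sp])
        interior = (times > 10) & (times < 62)
        assert np.nanmin(mean[interior]) > 1.0
        assert np.nanstd(mean[interior]) < 0.2 * np.nanmean(mean[interior])

    def test_zero_trace_gives_zero_series(self, times_72h):
        sp = cwt(preprocess(TimeSeriesTrace("z", times_72h, np.zeros(145))))
        _, mean, _, _ = instantaneous_ur_power([sp])
        assert np.all(np.nan_to_num(mean) == 0.0)

    def test_group_series_follows_the_envelope(self):
        traces = [generate_trace(TraceModel(seed=s)) for s in range(1, 25)]
        times, mean, sem, _ = instantaneous_ur_power(spectra_for(traces))
        m = np.nan_to_num(mean)
        before = m[(times > 8) & (times < 17)].mean()
        during = m[(times > 25) & (times < 55)].mean()
        after_idx = (times > 62) & (times < 69)
        assert during > 3 * before
        assert during > 3 * m[after_idx].mean()

    def test_mismatched_grids_rejected(self, cosine_trace):
        sp1 = cwt(preprocess(cosine_trace(3.0)))
        tr2 = TimeSeriesTrace("b", 0.5 * np.arange(97), np.cos(np.arange(97)))
        sp2 = cwt(preprocess(tr2))
        with pytest.raises(ValueError, match="time grid"):
            instantaneous_ur_power([sp1, sp2])


class TestAveragePower:
    def test_zero_traces_score_zero(self, times_72h):
        sp = cwt(preprocess(TimeSeriesTrace("z", times_72h, np.zeros(145))))
        per_sample, group = average_ur_power([sp])
        assert group == 0.0

    def test_white_noise_group_power_near_one(self, times_72h):
        # normalization calibration: mean over replicate sets of n=24
        rng = np.random.default_rng(123)
        means = []
        for _ in range(100):
            spectra = []
            for _ in range(24):
                x = rng.standard_normal(145)
                spectra.append(ur_spectrum(TimeSeriesTrace("w", times_72h, x)))
            means.append(average_ur_power(spectra)[1])
        assert 0.8 < np.mean(means) < 1.2

    def test_rhythmic_exceeds_noise_only(self):
        rhythmic = [generate_trace(TraceModel(seed=s)) for s in range(1, 13)]
        noise = [
            generate_trace(TraceModel(seed=s, ur_amplitude=0.0, cr_amplitude=0.0))
            for s in range(1, 13)
        ]
        _, g_r = average_ur_power(spectra_for(rhythmic))
        _, g_n = average_ur_power(spectra_for(noise))
        assert g_r > g_n

    def test_empty_window_rejected(self, cosine_trace):
        sp = cwt(preprocess(cosine_trace(3.0)))
        with pytest.raises(ValueError, match="window"):
            average_ur_power([sp], window=(100.0, 200.0))

    def test_monotone_in_ultradian_amplitude(self):
        prev = -np.inf
        for amp in (0.0, 4.0, 8.0, 12.0, 20.0):
            tr = generate_trace(TraceModel(seed=7, ur_amplitude=amp))
            _, g = average_ur_power([ur_spectrum(tr)])
            assert g >= prev
            prev = g

    def test_scale_invariance(self):
        tr = generate_trace(TraceModel(seed=3))
        scaled = copy.deepcopy(tr)
        scaled.values = tr.values * 7.3
        _, g1 = average_ur_power([ur_spectrum(tr)])
        _, g2 = average_ur_power([ur_spectrum(scaled)])
        assert abs(g1 - g2) < 1e-6


class TestClassify:
    def test_strict_threshold_boundary(self):
        assert classify_ur(1.0) is False
        assert classify_ur(0.0) is False
        assert classify_ur(1.0001) is True

    def test_negative_power_rejected(self):
        with pytest.raises(ValueError):
            classify_ur(-0.1)

    def test_default_rhythmic_group_detected(self):
        traces = [generate_trace(TraceModel(seed=s)) for s in range(1, 13)]
        _, group = average_ur_power(spectra_for(traces))
        assert classify_ur(group) is True


class TestEstimatePeriod:
    @pytest.mark.parametrize("period", [3.0, 4.0])
    def test_cosine_period_recovered_within_grid_step(self, cosine_trace, period):
        sp = cwt(preprocess(cosine_trace(period)))
        est = estimate_period(sp, UR_BAND_DEFAULT)
        assert abs(est - period) <= period * (2**0.05 - 1)

    def test_all_zero_power_returns_none(self, times_72h):
        sp = cwt(preprocess(TimeSeriesTrace("z", times_72h, np.zeros(145))))
        assert estimate_period(sp, UR_BAND_DEFAULT) is None

    def test_recovery_across_periods_and_seeds(self):
        # generator truth recovered within 10% in >= 95% of replicates
        hits = total = 0
        for period in (2.5, 3.0, 4.0, 5.0):
            for seed in range(1, 26):
                tr = generate_trace(TraceModel(seed=seed, ur_period_h=period))
                est = estimate_period(ur_spectrum(tr))
                hits += abs(est - period) <= 0.1 * period
                total += 1
        assert hits / total >= 0.95

    def test_white_noise_period_scatters_over_band(self, times_72h):
        rng = np.random.default_rng(17)
        estimates = [
            estimate_period(
                cwt(preprocess(TimeSeriesTrace("w", times_72h, rng.standard_normal(145)))),
                UR_BAND_DEFAULT,
            )
            for _ in range(200)
        ]
        estimates = np.array(estimates)
        # occupies both halves of the band rather than piling on one edge
        assert ((estimates < 3.5).mean() > 0.15) and ((estimates > 3.5).mean() > 0.15)


class TestDetectWindow:
    def test_below_threshold_series_has_no_window(self):
        t = np.arange(0, 72.5, 0.5)
        assert detect_window(t, np.full(t.size, 0.5)) == (None, None)

    def test_step_function_bounds_recovered(self):
        t = np.arange(0, 72.5, 0.5)
        y = np.where((t >= 30) & (t <= 40), 2.0, 0.0)
        onset, offset = detect_window(t, y, threshold=1.0, min_run_h=2.0)
        assert onset == 30.0 and offset == 40.0

    def test_short_blips_ignored(self):
        t = np.arange(0, 72.5, 0.5)
        y = np.zeros(t.size)
        y[10:12] = 5.0  # 0.5 h blip, below min_run
        assert detect_window(t, y, min_run_h=2.0) == (None, None)

    def test_min_run_below_sampling_step_rejected(self):
        t = np.arange(0, 72.5, 0.5)
        with pytest.raises(ValueError):
            detect_window(t, np.zeros(t.size), min_run_h=0.1)

    def test_generator_onset_offset_recovered(self):
        # group series from the default model: onset ~19 h (+-2), offset ~60 (+-4)
        onsets, offsets = [], []
        for rep in range(20):
            traces = [generate_trace(TraceModel(seed=1000 * rep + s)) for s in range(24)]
            times, mean, _, _ = instantaneous_ur_power(spectra_for(traces))
            onset, offset = detect_window(times, mean, threshold=1.0, min_run_h=2.0)
            onsets.append(onset)
            offsets.append(offset)
        assert all(o is not None for o in onsets)
        assert all(abs(o - 19.0) <= 2.0 for o in onsets)
        assert all(abs(f - 60.0) <= 4.0 for f in offsets)


class TestScreen:
    def test_wildtype_vs_ur_null_flags(self):
        wt = [generate_trace(TraceModel(seed=s)) for s in range(1, 9)]
        null = [generate_trace(TraceModel(seed=s, ur_amplitude=0.0)) for s in range(1, 9)]
        table = screen_mutants({"WT": wt, "null": null})
        flags = dict(zip(table.line, table.ur_absent))
        assert flags == {"WT": False, "null": True}

    def test_identical_lines_identical_flags(self):
        traces = [generate_trace(TraceModel(seed=s)) for s in range(1, 7)]
        table = screen_mutants({"A": traces, "B": list(traces)})
        assert table.ur_absent.nunique() == 1

    def test_empty_line_skipped_with_warning(self):
        wt = [generate_trace(TraceModel(seed=1))]
        with pytest.warns(UserWarning, match="skipped"):
            table = screen_mutants({"WT": wt, "empty": []})
        assert table.line.tolist() == ["WT"]

    def test_null_lines_among_many_recovered(self):
        # 4 ultradian-null lines among 16: exactly those flagged
        lines = {}
        null_names = set()
        for i in range(16):
            amp = 0.0 if i % 4 == 0 else 12.0
            name = f"M{i:02d}"
            if amp == 0.0:
                null_names.add(name)
            lines[name] = [
                generate_trace(TraceModel(seed=100 * i + s, ur_amplitude=amp))
                for s in range(6)
            ]
        table = screen_mutants(lines)
        flagged = set(table.loc[table.ur_absent, "line"])
        assert flagged == null_names


class TestCompareGroups:
    def test_identical_groups_share_a_letter(self):
        rng = np.random.default_rng(0)
        a = rng.normal(1.0, 0.1, 24)
        summary = compare_groups({"g1": a, "g2": a.copy()})
        assert summary.letters["g1"] == summary.letters["g2"]

    def test_separated_groups_get_distinct_letters(self):
        rng = np.random.default_rng(1)
        summary = compare_groups(
            {"low": rng.normal(0.2, 0.1, 24), "high": rng.normal(5.0, 0.1, 24)}
        )
        assert set(summary.letters["low"]).isdisjoint(summary.letters["high"])
        assert summary.anova_p < 1e-10

    def test_three_groups_one_shifted(self):
        rng = np.random.default_rng(2)
        summary = compare_groups(
            {
                "a": rng.normal(1.0, 0.2, 24),
                "b": rng.normal(1.0, 0.2, 24),
                "shifted": rng.normal(4.0, 0.2, 24),
            }
        )
        assert summary.letters["a"] == summary.letters["b"]
        assert set(summary.letters["shifted"]).isdisjoint(summary.letters["a"])

    def test_anova_against_scipy_oracle(self):
        rng = np.random.default_rng(3)
        groups = {k: rng.normal(m, 1.0, 20) for k, m in [("x", 0), ("y", 1), ("z", 3)]}
        summary = compare_groups(groups)
        f, p = stats.f_oneway(*groups.values())
        assert np.isclose(summary.anova_f, f) and np.isclose(summary.anova_p, p)

    def test_tukey_against_statsmodels_oracle(self):
        from statsmodels.stats.multicomp import pairwise_tukeyhsd

        rng = np.random.default_rng(4)
        data = {k: rng.normal(m, 1.0, 15) for k, m in [("a", 0.0), ("b", 0.5), ("c", 2.5)]}
        summary = compare_groups(data, alpha=0.01)
        values = np.concatenate(list(data.values()))
        labels = np.repeat(list(data.keys()), [len(v) for v in data.values()])
        sm = pairwise_tukeyhsd(values, labels, alpha=0.01)
        sm_p = dict(zip(map(tuple, sm._results_table.data[1:][:]), sm.pvalues))
        for row, p_sm in zip(sm._results_table.data[1:], sm.pvalues):
            g1, g2 = row[0], row[1]
            mine = summary.tukey.query("group1 == @g1 and group2 == @g2")["p_adj"].iloc[0]
            assert abs(mine - p_sm) < 1e-6

    def test_degenerate_variance_rejected(self):
        with pytest.raises(ValueError, match="variance"):
            compare_groups({"a": np.ones(5), "b": np.full(5, 2.0)})

    def test_single_group_rejected(self):
        with pytest.raises(ValueError):
            compare_groups({"a": np.arange(5.0)})


class TestAnalyzeTrace:
    def test_default_trace_full_analysis(self):
        res = analyze_trace(generate_trace(TraceModel(seed=2)))
        assert res.detected
        assert abs(res.dominant_period_h - 3.0) < 0.3
        assert res.onset_h is not None and res.offset_h is not None
        assert res.onset_h < res.offset_h


class TestDetectWindowProperties:
    """detect_window on arbitrary boolean run patterns."""

    from hypothesis import given, settings
    from hypothesis import strategies as st

    @given(st.lists(st.booleans(), min_size=16, max_size=80), st.integers(1, 6))
    @settings(derandomize=True, max_examples=100, deadline=None)
    def test_window_consistent_with_runs(self, flags, min_run_steps):
        t = 0.5 * np.arange(len(flags))
        y = np.where(flags, 2.0, 0.0)
        min_run_h = 0.5 * min_run_steps
        onset, offset = detect_window(t, y, threshold=1.0, min_run_h=min_run_h)
        if onset is None:
            # no run of the required duration exists
            longest = run = 0
            for f in flags:
                run = run + 1 if f else 0
                longest = max(longest, run)
            assert (longest - 1) * 0.5 < min_run_h
            assert offset is None
        else:
            assert onset <= offset
            i, j = int(onset / 0.5), int(offset / 0.5)
            assert flags[i] and flags[j]
            assert (not flags[i - 1]) if i > 0 else True
            assert (not flags[j + 1]) if j + 1 < len(flags) else True
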