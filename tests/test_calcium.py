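"""Astrocyte calcium transient pipeline: baselines, dF/F0, detection,
splitting, the percentile cut-off and FT/ST classification."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as hst

from epiphys.calcium import (
    BaselineEstimate,
    CaEvent,
    analyze_trace,
    classify_events,
    compute_dff,
    derive_cutoff,
    detect_events,
    find_baseline,
    split_multipeak,
    summarize_cell,
    summarize_group,
)
from epiphys.recordings import FluorTrace
from epiphys.synthetic import CaSimConfig, gen_calcium_traces

from conftest import make_flat_trace


class TestComputeDff:
    def test_constant_trace_gives_zero(self):
        tr = make_flat_trace(level=3000.0)
        dff = compute_dff(tr, BaselineEstimate(3000.0, 1.0, (0, 29)))
        assert np.allclose(dff, 0.0)

    def test_direct_arithmetic(self):
        # F0 - bg = 1000, F - bg = 1500 at one frame -> dff = 0.5
        values = np.full(100, 1200.0)
        values[50] = 1700.0
        tr = FluorTrace("c", 1.0, values, background=200.0)
        dff = compute_dff(tr, BaselineEstimate(1200.0, 1.0, (0, 29)))
        assert dff[50] == pytest.approx(0.5)
        assert dff[0] == pytest.approx(0.0)

    @pytest.mark.parametrize("gain", [0.5, 2.0, 7.3])
    def test_gain_invariance(self, gain):
        # scaling (F - bg) by any positive gain leaves dff unchanged
        rng = np.random.default_rng(3)
        base = 1000.0 + rng.normal(0, 10, 200)
        bg = 200.0
        tr1 = FluorTrace("a", 1.0, base + bg, background=bg)
        tr2 = FluorTrace("b", 1.0, gain * base + bg, background=bg)
        b1 = find_baseline(tr1)
        b2 = find_baseline(tr2)
        assert np.allclose(compute_dff(tr1, b1), compute_dff(tr2, b2), atol=1e-12)

    def test_degenerate_baseline_errors(self):
        tr = make_flat_trace(level=100.0, background=200.0)
        with pytest.raises(ValueError, match="background"):
            compute_dff(tr, BaselineEstimate(150.0, 1.0, (0, 29)))


class TestFindBaseline:
    def test_event_free_trace_recovers_level(self):
        cfg = CaSimConfig(n_cells=1, event_rate_per_min=0.0, seed=11)
        traces, _ = gen_calcium_traces(cfg)
        est = find_baseline(traces[0])
        sem = cfg.noise_sd / np.sqrt(30)
        assert abs(est.f0 - cfg.baseline_level) < 3 * sem
        assert est.window[1] - est.window[0] + 1 == 30

    def test_window_excludes_event(self):
        # a single event in frames 100-150 must not intersect the window
        values = np.full(300, 3000.0) + np.random.default_rng(5).normal(0, 30, 300)
        values[100:151] += 400.0
        tr = FluorTrace("c", 1.0, values, background=200.0)
        est = find_baseline(tr)
        assert est.window[1] < 100 or est.window[0] > 150

    def test_plateau_of_long_event_rejected(self):
        # a long flat transient is as low-variance as baseline but sits high
        values = np.full(300, 3000.0)
        values[100:180] += 500.0
        tr = FluorTrace("c", 1.0, values, background=200.0)
        est = find_baseline(tr)
        assert est.f0 == pytest.approx(3000.0)

    def test_constant_trace(self):
        est = find_baseline(make_flat_trace())
        assert est.f0 == 3000.0 and est.sd0 == 0.0
        with pytest.raises(ValueError, match="flat baseline"):
            detect_events(np.zeros(300), est.sd0)

    def test_manual_window_override(self):
        tr = make_flat_trace(noise_sd=10.0, seed=2)
        est = find_baseline(tr, manual_window=(40, 99))
        assert est.window == (40, 99)
        with pytest.raises(ValueError, match="manual window"):
            find_baseline(tr, manual_window=(280, 310))


class TestDetectEvents:
    @pytest.mark.parametrize(
        "amp_sd,n_frames,expected",
        [
            (2.5, 6, 1),  # above threshold, long enough
            (3.0, 4, 0),  # above threshold, too short
            (1.5, 10, 0),  # long enough, below threshold
        ],
    )
    def test_threshold_and_duration_rule(self, amp_sd, n_frames, expected):
        dff = np.zeros(100)
        dff[40 : 40 + n_frames] = amp_sd  # in units of sd0
        assert len(detect_events(dff, sd0_dff=1.0)) == expected

    def test_events_ordered_nonoverlapping_with_peaks(self):
        dff = np.zeros(200)
        dff[20:30] = 5.0
        dff[50:60] = [3, 4, 5, 6, 7, 6, 5, 4, 3, 2.5]
        events = detect_events(dff, sd0_dff=1.0)
        assert [e.onset_frame for e in events] == [20, 50]
        assert events[0].offset_frame < events[1].onset_frame
        assert events[1].peak_dff == pytest.approx(7.0)

    def test_injection_recovery_noiseless(self, noiseless_ca_dataset):
        cfg, traces, truth = noiseless_ca_dataset
        for tr in traces:
            base = find_baseline(tr, manual_window=(0, 29))
            dff = compute_dff(tr, base)
            sd0_dff = cfg.unit_au / (base.f0 - tr.background)
            events = detect_events(dff, sd0_dff, frame_period_s=tr.frame_period_s)
            gt = truth.events[truth.events.signal_id == tr.cell_id]
            gt = gt.sort_values("onset_frame")
            assert len(events) == len(gt)
            for ev, (_, row) in zip(events, gt.iterrows()):
                assert abs(ev.onset_frame - row.onset_frame) <= 1
                assert abs(ev.n_frames - row.n_frames) <= 1

    def test_flat_baseline_errors(self):
        with pytest.raises(ValueError, match="sd0"):
            detect_events(np.ones(50), sd0_dff=0.0)

    def test_duration_frame_second_duality(self):
        dff = np.zeros(100)
        dff[10:22] = 5.0
        for period in (0.5, 1.0, 2.0):
            (ev,) = detect_events(dff, 1.0, frame_period_s=period)
            assert ev.duration_s == pytest.approx(ev.n_frames * period)


class TestSplitMultipeak:
    def _event_for(self, dff):
        (ev,) = detect_events(dff, sd0_dff=1.0)
        return ev

    def test_monotone_event_unchanged(self):
        dff = np.zeros(60)
        dff[20:30] = [3, 5, 7, 9, 10, 8, 6, 5, 4, 3]
        ev = self._event_for(dff)
        assert split_multipeak(ev, dff) == [ev]

    def test_deep_trough_splits(self):
        # two 10-sd peaks, trough at 40% of the smaller -> two transients
        dff = np.zeros(60)
        dff[20:32] = [4, 8, 10, 8, 6, 4, 5, 8, 10, 8, 6, 4]
        dff[25] = 4.0  # trough = 40% of 10
        ev = self._event_for(dff)
        parts = split_multipeak(ev, dff, min_frames=3)
        assert len(parts) == 2
        assert parts[0].offset_frame == 25  # cut at the trough
        assert parts[1].onset_frame == 26
        assert parts[0].offset_frame >= parts[0].onset_frame

    def test_shallow_trough_no_split(self):
        # trough at 80% of both peaks -> one event
        dff = np.zeros(60)
        dff[20:29] = [6, 8, 10, 9, 8, 9, 10, 8, 6]
        ev = self._event_for(dff)
        assert len(split_multipeak(ev, dff)) == 1

    def test_split_modes_use_different_references(self):
        # trough 4 between peaks 10 and 5: 80% of the smaller adjacent
        # peak (no split in adjacent mode) but 40% of the event maximum
        # (split in global mode)
        dff = np.zeros(60)
        dff[20:31] = [4, 8, 10, 8, 6, 4, 4.5, 5, 4.5, 4, 3]
        ev = self._event_for(dff)
        assert len(split_multipeak(ev, dff, min_frames=3, mode="adjacent")) == 1
        assert len(split_multipeak(ev, dff, min_frames=3, mode="global")) == 2
        with pytest.raises(ValueError, match="split mode"):
            split_multipeak(ev, dff, mode="bogus")

    def test_short_fragments_dropped(self):
        dff = np.zeros(60)
        dff[20:29] = [4, 8, 10, 3, 8, 10, 8, 6, 4]  # trough at frame 23
        ev = self._event_for(dff)
        parts = split_multipeak(ev, dff, min_frames=5)
        # the 4-frame fragment before the trough is discarded
        assert len(parts) == 1
        assert parts[0].onset_frame == 24

    def test_merged_generator_events_recovered(self):
        cfg = CaSimConfig(n_cells=3, noise_sd=0.0, amp_unit_au=30.0,
                          merged_fraction=1.0, event_rate_per_min=0.8, seed=21)
        traces, truth = gen_calcium_traces(cfg)
        for tr in traces:
            base = find_baseline(tr, manual_window=(0, 29))
            dff = compute_dff(tr, base)
            sd0 = cfg.unit_au / (base.f0 - tr.background)
            events = []
            for ev in detect_events(dff, sd0, frame_period_s=1.0):
                events.extend(split_multipeak(ev, dff))
            gt = truth.events[truth.events.signal_id == tr.cell_id]
            gt = gt.sort_values("onset_frame")
            assert len(events) == len(gt)
            for ev, (_, row) in zip(events, gt.iterrows()):
                assert ev.onset_frame == row.onset_frame
                assert ev.n_frames == row.n_frames


class TestDeriveCutoff:
    def test_constant_sample(self):
        assert derive_cutoff([7.0] * 12) == 7.0

    def test_linear_interpolation_example(self):
        assert derive_cutoff([10.0, 20.0, 30.0, 40.0]) == pytest.approx(32.5)

    def test_empty_errors(self):
        with pytest.raises(ValueError):
            derive_cutoff([])

    @settings(deadline=None, max_examples=100)
    @given(hst.lists(hst.floats(0.1, 300.0), min_size=1, max_size=50),
           hst.floats(0.0, 100.0))
    def test_matches_brute_force_order_statistics(self, sample, pct):
        # independent oracle: sort, locate the fractional order statistic,
        # interpolate linearly between the two bracketing values
        xs = sorted(sample)
        h = (len(xs) - 1) * pct / 100.0
        lo = int(np.floor(h))
        hi = min(lo + 1, len(xs) - 1)
        expected = xs[lo] + (h - lo) * (xs[hi] - xs[lo])
        assert derive_cutoff(sample, pct) == pytest.approx(expected, rel=1e-12)
        assert min(xs) <= derive_cutoff(sample, pct) <= max(xs)


class TestClassify:
    @pytest.mark.parametrize(
        "duration,expected",
        [(30.0, "ST"), (5.0, "FT"), (23.1, "ST"), (23.0999, "FT")],
    )
    def test_cutoff_rule(self, duration, expected):
        n = int(duration)
        ev = CaEvent(0, n - 1, duration, 1.0)
        (out,) = classify_events([ev])
        assert out.label == expected

    def test_input_order_preserved_and_not_mutated(self):
        events = [CaEvent(0, 9, 10.0, 1.0), CaEvent(20, 60, 41.0, 2.0)]
        out = classify_events(events)
        assert [e.label for e in out] == ["FT", "ST"]
        assert all(e.label == "unclassified" for e in events)


class TestSummaries:
    def test_counts_and_ratio(self):
        events = classify_events(
            [CaEvent(0, 9, 10.0, 1.0)] * 3 + [CaEvent(50, 99, 50.0, 1.0)]
        )
        s = summarize_cell(events, "c1")
        assert s.n_events == 4 and s.ft_count == 3 and s.st_count == 1
        assert s.st_percent == pytest.approx(25.0)
        assert s.ft_st_ratio == pytest.approx(3.0)
        assert s.mean_duration_s == pytest.approx(20.0)

    def test_no_st_ratio_missing(self):
        events = classify_events([CaEvent(0, 9, 10.0, 1.0)] * 2)
        s = summarize_cell(events)
        assert s.st_percent == 0.0
        assert np.isnan(s.ft_st_ratio)

    def test_group_pooled_durations(self):
        by_cell = {
            "a": classify_events([CaEvent(0, 9, 10.0, 1.0)]),
            "b": classify_events([CaEvent(0, 29, 30.0, 1.0),
                                  CaEvent(40, 49, 10.0, 1.0)]),
        }
        table, pooled = summarize_group(by_cell)
        assert len(table) == 2
        assert sorted(pooled) == [10.0, 10.0, 30.0]

    def test_higher_st_fraction_lowers_ftst_ratio(self):
        ratios = []
        for st_frac in (0.15, 0.55):
            traces, _ = gen_calcium_traces(
                CaSimConfig(n_cells=15, st_fraction=st_frac, seed=31)
            )
            per_cell = []
            for tr in traces:
                events, _ = analyze_trace(tr)
                per_cell.append(summarize_cell(events, tr.cell_id).ft_st_ratio)
            ratios.append(np.nanmean(per_cell))
        assert ratios[1] < ratios[0]
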