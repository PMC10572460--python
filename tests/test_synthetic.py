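"""Ground-truth generators: determinism, bookkeeping closure, class
separation, and generator/analyzer self-consistency contracts."""

import numpy as np
import pytest
from scipy import stats as sps

from epiphys import lfp as lf
from epiphys import psc
from epiphys.synthetic import (
    CaSimConfig,
    LfpSimConfig,
    PscSimConfig,
    biexp_kernel,
    gen_calcium_traces,
    gen_compound_psc,
    gen_fepsp_family,
    gen_lfp,
    gen_paired_pulse,
    gen_psc_sweep,
)


class TestDeterminism:
    def test_calcium_repeatable(self):
        cfg = CaSimConfig(n_cells=3, seed=9)
        t1, g1 = gen_calcium_traces(cfg)
        t2, g2 = gen_calcium_traces(cfg)
        for a, b in zip(t1, t2):
            assert np.array_equal(a.values, b.values)
        assert g1.events.equals(g2.events)

    def test_psc_repeatable(self):
        cfg = PscSimConfig(seed=9)
        s1, g1 = gen_psc_sweep(cfg)
        s2, g2 = gen_psc_sweep(cfg)
        assert np.array_equal(s1.values, s2.values)
        assert g1.events.equals(g2.events)

    def test_lfp_repeatable(self):
        cfg = LfpSimConfig(duration_s=20.0, seed=9)
        r1, _ = gen_lfp(cfg)
        r2, _ = gen_lfp(cfg)
        assert np.array_equal(r1.values, r2.values)


class TestCalciumGenerator:
    def test_zero_rate_pure_noise(self):
        cfg = CaSimConfig(n_cells=2, event_rate_per_min=0.0, seed=3)
        traces, truth = gen_calcium_traces(cfg)
        assert truth.n_events == 0
        for tr in traces:
            assert np.all(np.abs(tr.values - cfg.baseline_level)
                          < 6 * cfg.noise_sd)

    def test_all_st_durations_exceed_cutoff(self):
        cfg = CaSimConfig(n_cells=4, st_fraction=1.0, seed=4)
        _, truth = gen_calcium_traces(cfg)
        assert truth.n_events >= 10
        assert (truth.events.duration_s > 23.1).all()

    def test_class_separation_99_percent(self):
        # pool many cells so both duration distributions are well sampled
        cfg = CaSimConfig(n_cells=60, st_fraction=0.5, seed=5)
        _, truth = gen_calcium_traces(cfg)
        ft = truth.events[truth.events.label == "FT"].duration_s
        st = truth.events[truth.events.label == "ST"].duration_s
        assert len(ft) > 100 and len(st) > 100
        assert (ft < 23.1).mean() >= 0.99
        assert (st > 23.1).mean() >= 0.99

    def test_quiet_window_reserved(self):
        cfg = CaSimConfig(n_cells=5, seed=6)
        _, truth = gen_calcium_traces(cfg)
        assert (truth.events.onset_frame >= 30).all()

    def test_ground_truth_closure(self):
        # every injected event appears exactly once: per-cell event spans
        # are disjoint and match the supra-threshold support of the trace
        cfg = CaSimConfig(n_cells=4, noise_sd=0.0, amp_unit_au=25.0, seed=8)
        traces, truth = gen_calcium_traces(cfg)
        for tr in traces:
            gt = truth.events[truth.events.signal_id == tr.cell_id]
            gt = gt.sort_values("onset_frame")
            prev_end = -1
            total = 0
            for _, row in gt.iterrows():
                assert row.onset_frame > prev_end
                prev_end = row.onset_frame + row.n_frames - 1
                total += row.n_frames
            supra = int((tr.values - cfg.baseline_level >= 2 * cfg.unit_au).sum())
            assert supra == total

    def test_infeasible_geometry_rejected(self):
        cfg = CaSimConfig(n_cells=1, n_frames=40, st_fraction=1.0,
                          event_rate_per_min=20.0, seed=2)
        with pytest.raises(ValueError, match="too small"):
            gen_calcium_traces(cfg)

    @pytest.mark.parametrize("bad", [
        dict(st_fraction=1.5),
        dict(n_frames=20),
        dict(noise_sd=-1.0),
        dict(noise_sd=0.0),  # needs amp_unit_au when noiseless
        dict(baseline_level=100.0),
    ])
    def test_config_validation(self, bad):
        with pytest.raises(ValueError):
            gen_calcium_traces(CaSimConfig(n_cells=1, **bad))


class TestPscGenerator:
    def test_zero_rate_noise_only(self):
        sweep, truth = gen_psc_sweep(
            PscSimConfig(event_rate_hz=0.0, sweep_duration_s=5.0, seed=1)
        )
        assert truth.n_events == 0
        assert np.abs(sweep.values).max() < 6 * 2.0

    def test_inward_polarity_negative_going(self):
        cfg = PscSimConfig(event_rate_hz=1.0, noise_sd_pa=0.0,
                           sweep_duration_s=10.0, seed=2)
        sweep, truth = gen_psc_sweep(cfg)
        assert truth.n_events > 0
        assert sweep.values.min() < 0
        assert sweep.values.max() <= 1e-9

    def test_poisson_count_in_confidence_interval(self):
        # rate 2 Hz for 60 s: the injected count must sit inside the
        # central 99% Poisson interval around 120
        sweep, truth = gen_psc_sweep(
            PscSimConfig(event_rate_hz=2.0, sweep_duration_s=60.0, seed=3)
        )
        lo, hi = sps.poisson.ppf([0.005, 0.995], 120.0)
        assert lo <= truth.n_events <= hi

    def test_rise_slower_than_decay_rejected(self):
        with pytest.raises(ValueError, match="rise_tau"):
            gen_psc_sweep(PscSimConfig(rise_tau_ms=12.0, decay_tau_ms=2.0))


class TestPairedPulseGenerator:
    def test_unity_ppr_equal_peaks(self):
        sweep = gen_paired_pulse(100.0, 1.0,
                                 kernel=PscSimConfig(noise_sd_pa=0.0))
        assert psc.paired_pulse_ratio(sweep) == pytest.approx(1.0, abs=1e-3)

    def test_true_ratio_recovered_noiseless(self):
        sweep = gen_paired_pulse(100.0, 0.8,
                                 kernel=PscSimConfig(noise_sd_pa=0.0))
        assert psc.paired_pulse_ratio(sweep) == pytest.approx(0.8, rel=1e-2)

    def test_default_isi_is_100_ms(self):
        sweep = gen_paired_pulse(100.0, 0.8,
                                 kernel=PscSimConfig(noise_sd_pa=0.0))
        t1, t2 = sweep.stim_times_ms
        assert t2 - t1 == pytest.approx(100.0)

    def test_isi_shorter_than_rise_rejected(self):
        with pytest.raises(ValueError, match="isi"):
            gen_paired_pulse(100.0, 0.8, isi_ms=1.0)


class TestCompoundGenerator:
    def test_pure_excitatory_all_inward(self):
        sweep = gen_compound_psc(200.0, 4000.0, 0.0, 0.0)
        assert sweep.values.min() < -190
        assert sweep.values.max() <= 1e-9

    def test_peak_ratio_recovered_noiseless(self):
        res = psc.compound_ei(gen_compound_psc(200.0, 4000.0, 100.0, 3000.0))
        assert res.ei_peak_ratio == pytest.approx(2.0, rel=1e-3)
        assert res.ei_area_ratio == pytest.approx(4000.0 / 3000.0, rel=1e-3)

    def test_doubling_excitation_doubles_ratio(self):
        r1 = psc.compound_ei(gen_compound_psc(200.0, 4000.0, 100.0, 3000.0))
        r2 = psc.compound_ei(gen_compound_psc(400.0, 8000.0, 100.0, 3000.0))
        assert r2.ei_peak_ratio == pytest.approx(2 * r1.ei_peak_ratio, rel=1e-3)
        assert r2.ei_area_ratio == pytest.approx(2 * r1.ei_area_ratio, rel=1e-3)


class TestFepspGenerator:
    def test_zero_intensity_artifact_only(self):
        (inten, sweep), = gen_fepsp_family([0.0], 1.0, 60.0)
        # beyond the 2 ms artifact window the sweep is flat
        idx = sweep.index_at_ms(10.0 + 2.0)
        assert np.abs(sweep.values[idx:]).max() < 1e-9

    def test_scale_ratio_preserved_at_every_intensity(self):
        ints = [20, 40, 60, 80, 100]
        fam1 = gen_fepsp_family(ints, 1.0, 1000.0)
        fam2 = gen_fepsp_family(ints, 2.0, 1000.0)
        for (i1, s1), (i2, s2) in zip(fam1, fam2):
            m1 = np.abs(s1.values[s1.index_at_ms(15.0):]).max()
            m2 = np.abs(s2.values[s2.index_at_ms(15.0):]).max()
            assert m2 == pytest.approx(2 * m1, rel=1e-9)

    def test_ps_appears_first_at_threshold(self):
        fam = gen_fepsp_family([20, 40, 60, 80], 1.0, 60.0)
        from epiphys.fepsp import build_io, measure_fepsp
        curve = build_io([measure_fepsp(s, intensity_ua=i) for i, s in fam])
        flags = [m.ps_present for m in curve.measures]
        assert flags == [False, False, True, True]

    def test_unsorted_intensities_rejected(self):
        with pytest.raises(ValueError, match="sorted"):
            gen_fepsp_family([40, 20], 1.0, 60.0)


class TestLfpGenerator:
    def test_empty_schedule_background_only(self):
        rec, truth = gen_lfp(LfpSimConfig(duration_s=30.0, seed=1))
        assert truth.n_events == 0
        assert np.abs(rec.values).max() < 8 * 0.05

    def test_ad_spectral_peak_in_low_band(self):
        cfg = LfpSimConfig(duration_s=30.0,
                           ad_schedule=[(10.0, 10.0, 2.0, 0.5)], seed=2)
        rec, _ = gen_lfp(cfg)
        seg = rec.values[int(10 * 1000) : int(20 * 1000)]
        from epiphys.recordings import LfpRecording
        psd = lf.multitaper_psd(LfpRecording(1000.0, seg),
                                segment_ms=4000, overlap_ms=500)
        peak_f = psd.freqs_hz[np.argmax(psd.power)]
        assert 1.0 <= peak_f <= 3.0

    def test_ad_duration_recoverable(self):
        cfg = LfpSimConfig(duration_s=60.0,
                           ad_schedule=[(20.0, 8.0, 2.5, 2.0)], seed=3)
        rec, _ = gen_lfp(cfg)
        summary = lf.detect_afterdischarges(rec)
        assert summary.n_ads == 1
        assert summary.durations_s[0] == pytest.approx(8.0, abs=0.5)

    def test_overlapping_ads_rejected(self):
        with pytest.raises(ValueError, match="overlap"):
            gen_lfp(LfpSimConfig(
                duration_s=60.0,
                ad_schedule=[(10.0, 10.0, 2.0, 0.5), (15.0, 5.0, 2.0, 0.5)],
            ))

    @pytest.mark.parametrize("width", [10.0, 80.0])
    def test_spike_width_bounds_enforced(self, width):
        with pytest.raises(ValueError, match="20-70"):
            gen_lfp(LfpSimConfig(duration_s=30.0,
                                 spike_schedule=[(10.0, width, 0.5)]))


def test_biexp_kernel_unit_peak():
    cfg = PscSimConfig()
    k = biexp_kernel(cfg)
    assert k.max() == pytest.approx(1.0)
    assert k[0] == 0.0
    # peak position matches the analytic time-to-peak
    dt_ms = 1000.0 / cfg.sample_rate_hz
    assert np.argmax(k) * dt_ms == pytest.approx(cfg.time_to_peak_ms, abs=dt_ms)
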