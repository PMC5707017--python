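"""Spike detection and per-cell metric extraction."""

from dataclasses import replace

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import furawave as fw
from furawave.errors import InsufficientDataError, ProtocolError


def _clean_cohort(seed=3, **kw):
    cfg = fw.CohortConfig(n_cells=6, noise_sd=0.0, responder_prob=1.0,
                          stimulus_time=300.0, seed=seed, **kw)
    return cfg, fw.simulate_cohort(cfg)


class TestDetectSpikes:
    def test_flat_noise_free_trace_has_no_events(self, flat_trace):
        assert fw.detect_spikes(flat_trace) == []

    def test_single_kernel_recovered_within_one_sample(self):
        cfg, coh = _clean_cohort(max_spikes=1)
        for tr in coh:
            events = fw.detect_spikes(tr)
            log = coh.ground_truth[tr.roi_id]
            assert len(events) == 1 == len(log)
            assert abs(events[0].peak_time - log[0]["peak_time"]) <= cfg.dt

    def test_two_kernels_in_onset_order(self):
        cfg = fw.CohortConfig(n_cells=1, noise_sd=0.0, responder_prob=1.0,
                              latency_mean=60.0, latency_sd=0.0, max_spikes=2,
                              isi_shape=300.0, isi_scale=1.0,  # ISI tight at 300 s
                              stimulus_time=300.0, seed=0)
        coh = fw.simulate_cohort(cfg)
        tr = coh.traces[0]
        events = fw.detect_spikes(tr)
        assert len(events) == 2
        assert events[0].onset_time < events[1].onset_time

    def test_detection_invariant_to_constant_offset(self):
        _, coh = _clean_cohort()
        tr = coh.traces[0]
        shifted = fw.RatioTrace(times=tr.times, values=tr.values + 0.7,
                                roi_id="s", stimulus_time=tr.stimulus_time)
        a = fw.detect_spikes(tr)
        b = fw.detect_spikes(shifted)
        assert [e.onset_time for e in a] == [e.onset_time for e in b]

    @settings(derandomize=True, max_examples=20)
    @given(k_lo=st.floats(min_value=5.0, max_value=8.0),
           bump=st.floats(min_value=1.0, max_value=4.0))
    def test_raising_k_peak_never_adds_events(self, k_lo, bump):
        cfg = fw.CohortConfig(n_cells=1, noise_sd=0.01, responder_prob=1.0,
                              stimulus_time=300.0, seed=42)
        tr = fw.simulate_trace(cfg, 0)
        lo = fw.DetectionParams(k_peak=k_lo)
        hi = fw.DetectionParams(k_peak=k_lo + bump)
        assert len(fw.detect_spikes(tr, hi)) <= len(fw.detect_spikes(tr, lo))

    def test_short_trace_raises(self):
        t = np.arange(0, 30, 3.0)
        tr = fw.RatioTrace(times=t, values=np.ones_like(t), roi_id="short")
        with pytest.raises(InsufficientDataError):
            fw.detect_spikes(tr)

    def test_spike_count_recovery_with_noise(self):
        # >= 95% of cells match the generator log exactly at noise_sd 0.01
        match = total = 0
        for seed in (0, 1):
            coh = fw.simulate_cohort(fw.preset("n_like", n_cells=20, seed=seed))
            for tr in coh:
                m = fw.compute_spike_metrics(tr)
                match += m.spike_count == len(coh.ground_truth[tr.roi_id])
                total += 1
        assert match / total >= 0.95


class TestLatency:
    def test_configured_latency_recovered_noise_free(self, clean_config):
        coh = fw.simulate_cohort(clean_config)
        for tr in coh:
            events = fw.detect_spikes(tr)
            lat = fw.first_spike_latency(tr, events)
            assert abs(lat - 120.0) <= clean_config.dt

    def test_no_events_gives_absent_latency(self, flat_trace):
        assert fw.first_spike_latency(flat_trace, []) is None

    def test_latency_from_explicit_stimulus(self, flat_trace):
        ev = [fw.SpikeEvent(onset_time=90.0, peak_time=100.0,
                            peak_value=1.5, end_time=130.0)]
        assert fw.first_spike_latency(flat_trace, ev, stimulus_time=0.0) == 90.0

    def test_pre_stimulus_onset_warns_spontaneous(self, flat_trace):
        ev = [fw.SpikeEvent(onset_time=30.0, peak_time=45.0,
                            peak_value=1.5, end_time=60.0)]
        with pytest.warns(UserWarning, match="spontaneous"):
            fw.first_spike_latency(flat_trace, ev, stimulus_time=120.0)


class TestAmplitude:
    def test_peak_minus_one_minute_baseline(self):
        t = np.arange(0, 300, 3.0)
        v = np.ones_like(t)
        v[t == 150.0] = 1.8
        tr = fw.RatioTrace(times=t, values=v, roi_id="a")
        ev = [fw.SpikeEvent(onset_time=147.0, peak_time=150.0,
                            peak_value=1.8, end_time=156.0)]
        amp = fw.first_spike_amplitude(tr, ev)
        assert amp == pytest.approx(0.8, abs=1e-12)

    def test_generated_kernel_amplitude_within_five_percent(self):
        cfg, coh = _clean_cohort(kernel=fw.SpikeKernelParams(amplitude=0.5))
        for tr in coh:
            m = fw.compute_spike_metrics(tr)
            assert m.first_amplitude == pytest.approx(0.5, rel=0.05)

    def test_no_events_gives_absent_amplitude(self, flat_trace):
        assert fw.first_spike_amplitude(flat_trace, []) is None

    def test_truncated_baseline_warns(self):
        t = np.arange(0, 300, 3.0)
        tr = fw.RatioTrace(times=t, values=np.ones_like(t), roi_id="tr")
        ev = [fw.SpikeEvent(onset_time=30.0, peak_time=36.0,
                            peak_value=1.4, end_time=60.0)]
        with pytest.warns(UserWarning, match="truncated"):
            amp = fw.first_spike_amplitude(tr, ev)
        assert amp == pytest.approx(0.4, abs=1e-12)


class TestCountSpikes:
    def test_counts_match_generator_log(self):
        _, coh = _clean_cohort()
        for tr in coh:
            m = fw.compute_spike_metrics(tr)
            assert m.spike_count == len(coh.ground_truth[tr.roi_id])

    def test_zero_events(self, flat_trace):
        assert fw.count_spikes(flat_trace, [], window=400.0, stimulus_time=120.0) == 0

    def test_event_after_window_excluded(self, flat_trace):
        ev = [fw.SpikeEvent(onset_time=500.0, peak_time=510.0,
                            peak_value=1.5, end_time=540.0)]
        with pytest.warns(UserWarning, match="counting to the end"):
            n = fw.count_spikes(flat_trace, ev, window=3600.0, stimulus_time=0.0)
        assert n == 1
        assert fw.count_spikes(flat_trace, ev, window=400.0, stimulus_time=0.0) == 0

    def test_responder_iff_at_least_one_spike(self):
        cfg = fw.CohortConfig(n_cells=30, responder_prob=0.5, noise_sd=0.0,
                              max_spikes=3, seed=2)
        coh = fw.simulate_cohort(cfg)
        for tr in coh:
            m = fw.compute_spike_metrics(tr)
            assert m.is_responder == (m.spike_count >= 1)
            assert (m.latency is None) == (m.spike_count == 0)


class TestAddBackAmplitudes:
    def test_closed_form_release_and_entry(self):
        cfg = fw.AddBackConfig(noise_sd=0.0, release_amplitude=0.5,
                               entry_amplitude=0.4, release_decay_tau=60.0)
        tr = fw.simulate_addback_trace(cfg)
        m = fw.addback_amplitudes(tr)
        assert m.release_amplitude == pytest.approx(0.5, rel=0.01)
        # the release tail has decayed by ~readdition, entry rides on it
        assert m.entry_amplitude == pytest.approx(0.4, rel=0.05)

    def test_zero_release_config(self):
        cfg = fw.AddBackConfig(noise_sd=0.01, release_amplitude=0.0, seed=9)
        m = fw.addback_amplitudes(fw.simulate_addback_trace(cfg))
        assert abs(m.release_amplitude) <= 3 * 0.01

    def test_flat_trace_gives_near_zero_amplitudes(self):
        cfg = fw.AddBackConfig(noise_sd=0.01, release_amplitude=0.0,
                               entry_amplitude=0.0, seed=4)
        m = fw.addback_amplitudes(fw.simulate_addback_trace(cfg))
        tol = 3 * 0.01 / np.sqrt(20) + 3 * 0.01  # window mean + single-sample max
        assert abs(m.release_amplitude) <= tol
        assert abs(m.entry_amplitude) <= tol

    def test_missing_annotations_raise(self, flat_trace):
        with pytest.raises(ProtocolError):
            fw.addback_amplitudes(flat_trace)
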