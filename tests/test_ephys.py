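"""Electrophysiology tests: spike detection, the burst rule against a
brute-force oracle, ISI/timing statistics and spike-Δf/f calibration."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from burstcode import ephys, imaging, synthgen as sg


def _spike_template(n=40):
    # biphasic extracellular waveform, trough-dominated
    t = np.linspace(0, 2, n)
    return -np.exp(-((t - 0.5) ** 2) / 0.02) + 0.3 * np.exp(-((t - 1.1) ** 2) / 0.08)


class TestDetectSpikes:
    def test_zero_trace_has_no_spikes(self):
        train = ephys.detect_spikes(np.zeros(4000))
        assert train.spike_times_ms.size == 0

    def test_injected_templates_recovered_at_injected_times(self, rng):
        sr = 20000.0
        v = rng.normal(0.0, 0.5, size=int(sr))  # 1 s of noise
        tpl = 40.0 * _spike_template()
        inject_ms = [100.0, 250.0, 400.0, 700.0, 950.0]
        for t_ms in inject_ms:
            i = int(t_ms / 1000.0 * sr)
            v[i : i + tpl.size] += tpl
        train = ephys.detect_spikes(v, sample_rate_hz=sr, threshold_sd=6.0)
        assert train.spike_times_ms.size == 5
        trough_offset = np.argmin(tpl) / sr * 1000.0
        for t_ms, det in zip(inject_ms, train.spike_times_ms):
            assert det == pytest.approx(t_ms + trough_offset, abs=0.5)

    def test_events_within_refractory_interval_merge(self):
        sr = 20000.0
        v = np.zeros(int(sr))
        v += np.random.default_rng(0).normal(0, 0.1, v.size)
        i = int(0.5 * sr)
        v[i] = -30.0
        v[i + int(0.001 * sr)] = -40.0  # 1 ms later, larger
        train = ephys.detect_spikes(v, sample_rate_hz=sr, threshold_sd=8.0)
        assert train.spike_times_ms.size == 1
        assert train.peak_amplitudes[0] == pytest.approx(40.0)

    def test_short_trace_is_an_error(self):
        with pytest.raises(ValueError):
            ephys.detect_spikes(np.zeros(100), sample_rate_hz=20000.0)


def _oracle_burst_scan(times, amps, onsets, window=150.0, k_min=3):
    """Independent brute-force implementation of the burst rule."""
    out = []
    for onset in onsets:
        sel = [i for i, t in enumerate(times) if onset < t <= onset + window]
        if len(sel) < k_min:
            continue
        tt = np.array([times[i] for i in sel])
        aa = np.array([amps[i] for i in sel])
        A = np.vstack([tt - tt[0], np.ones(len(sel))]).T
        slope, _ = np.linalg.lstsq(A, np.log(aa), rcond=None)[0]
        if slope < 0 and aa[-1] < aa[0]:
            out.append((float(onset), len(sel)))
    return out


class TestBurstDetection:
    def test_three_decaying_spikes_make_one_burst(self):
        train = ephys.SpikeTrain(np.array([110.0, 125.0, 140.0]), np.array([5.0, 4.0, 3.0]))
        events = ephys.detect_burst_events(train, [100.0])
        assert len(events) == 1
        assert events[0].n_spikes == 3
        assert events[0].decay_ok and events[0].decay_tau_ms > 0

    def test_sparse_spikes_do_not_burst(self):
        train = ephys.SpikeTrain(np.array([110.0, 300.0, 450.0]), np.array([5.0, 5.0, 5.0]))
        assert ephys.detect_burst_events(train, [100.0]) == []

    def test_increasing_amplitudes_fail_decay_criterion(self):
        train = ephys.SpikeTrain(np.array([110.0, 125.0, 140.0]), np.array([3.0, 4.0, 5.0]))
        assert ephys.detect_burst_events(train, [100.0]) == []

    def test_equal_amplitudes_fail_decay_criterion(self):
        train = ephys.SpikeTrain(np.array([110.0, 125.0, 140.0]), np.array([4.0, 4.0, 4.0]))
        assert ephys.detect_burst_events(train, [100.0]) == []

    def test_onset_coincident_spike_excluded_by_half_open_window(self):
        train = ephys.SpikeTrain(
            np.array([100.0, 120.0, 140.0]), np.array([5.0, 4.0, 3.0])
        )
        assert ephys.detect_burst_events(train, [100.0]) == []

    @given(data=st.data())
    @settings(max_examples=100, deadline=None, derandomize=True)
    def test_equals_brute_force_window_scan(self, data):
        n = data.draw(st.integers(min_value=0, max_value=20))
        gaps = data.draw(
            st.lists(st.floats(1.0, 120.0), min_size=n, max_size=n)
        )
        amps = data.draw(
            st.lists(st.floats(0.5, 10.0), min_size=n, max_size=n)
        )
        times = np.cumsum(np.asarray(gaps)) + 50.0
        train = ephys.SpikeTrain(times, np.asarray(amps))
        onsets = [0.0, 100.0, 400.0]
        got = [(e.onset_ms, e.n_spikes) for e in ephys.detect_burst_events(train, onsets)]
        assert got == _oracle_burst_scan(times, np.asarray(amps), onsets)

    def test_every_event_satisfies_the_count_predicate(self, rng):
        (cell,) = sg.make_population({"HB": 1}, paradigm="BBN", seed=0)
        cell.burst_prob = 1.0
        onsets = np.arange(30) * 7000.0 + 2000.0
        all_times, all_amps = [], []
        for onset in onsets:
            trial = sg.Trial(1, "BBN", onset, 50.0, onset + 150.0, "single")
            tr = sg.sample_spike_train(cell, trial, rng)
            all_times.append(tr.times_ms)
            all_amps.append(tr.amplitudes)
        train = ephys.SpikeTrain(np.concatenate(all_times), np.concatenate(all_amps))
        events = ephys.detect_burst_events(train, onsets)
        for e in events:
            recount = np.sum(
                (train.spike_times_ms > e.onset_ms)
                & (train.spike_times_ms <= e.onset_ms + 150.0)
            )
            assert recount >= 3


class TestBurstStatistics:
    def _events_from_generator(self, n_events, rng):
        (cell,) = sg.make_population({"HB": 1}, paradigm="BBN", seed=0)
        cell.burst_prob = 1.0
        onsets = np.arange(n_events) * 7000.0 + 2000.0
        times, amps = [], []
        for onset in onsets:
            trial = sg.Trial(1, "BBN", onset, 50.0, onset + 150.0, "single")
            tr = sg.sample_spike_train(cell, trial, rng)
            times.append(tr.times_ms)
            amps.append(tr.amplitudes)
        train = ephys.SpikeTrain(np.concatenate(times), np.concatenate(amps))
        return ephys.detect_burst_events(train, onsets)

    def test_single_event_worked_example(self):
        train = ephys.SpikeTrain(np.array([110.0, 120.0, 130.0]), np.array([5.0, 4.0, 3.0]))
        events = ephys.detect_burst_events(train, [100.0])
        stats = ephys.burst_statistics(events)
        assert sorted(stats.isis_ms.tolist()) == [10.0, 10.0]
        assert stats.rate_median_iqr_hz[0] == pytest.approx(100.0)

    def test_pooled_isi_median_near_configured_law(self, rng):
        events = self._events_from_generator(239, rng)
        assert len(events) >= 230
        stats = ephys.burst_statistics(events)
        assert stats.isi_median_iqr[0] == pytest.approx(11.0, rel=0.15)

    def test_bursts_precede_licks(self, rng):
        events = self._events_from_generator(100, rng)
        lick_latencies = sg.BehaviorModel().lick_latency_law.sample(rng, size=100)
        stats = ephys.burst_statistics(events, lick_onsets_ms=lick_latencies)
        assert stats.timing.burst_onset[0] < stats.timing.lick_onset[0]
        # quartiles ordered
        for q in (stats.timing.burst_onset, stats.timing.burst_end, stats.timing.lick_onset):
            assert q[1] <= q[0] <= q[2]

    def test_no_events_is_an_error(self):
        with pytest.raises(ValueError):
            ephys.burst_statistics([])


class TestCalibration:
    def _pairs(self, indicator, counts, rng, noise_sd=None):
        model = sg.default_indicator(indicator)
        if noise_sd is not None:
            model = sg.IndicatorModel(**{**model.__dict__, "noise_sd": noise_sd})
        trial = sg.Trial(1, "BBN", 1000.0, 50.0, 1150.0, "single")
        ns, amps = [], []
        for k in counts:
            lat = sg.DEFAULT_LATENCY_LAW.sample(rng)
            isis = sg.DEFAULT_ISI_LAW.sample(rng, size=k - 1) if k > 1 else np.empty(0)
            times = 1000.0 + lat + np.concatenate([[0.0], np.cumsum(np.atleast_1d(isis))])[:k]
            tr = sg.SimSpikeTrain(times, np.ones(k), k >= 3, k)
            trace = sg.spikes_to_fluorescence(tr, model, 4000.0, rng)
            ns.append(k)
            amps.append(imaging.trial_response_amplitude(trace, trial).amplitude)
        return np.array(ns), np.array(amps)

    def test_singlet_events_below_cal520_threshold_at_zero_noise(self, rng):
        counts = [1, 2] * 25
        ns, amps = self._pairs("Cal520", counts, rng, noise_sd=0.0)
        assert np.all(amps < 1.5)

    def test_threshold_lies_between_3_and_4_spike_medians(self, rng):
        counts = list(np.repeat([1, 2, 3, 4, 5, 6], 40))
        ns, amps = self._pairs("Cal520", counts, rng)
        table = ephys.spike_dff_calibration(ns, amps, threshold=1.5)
        med = table.table.set_index("n_spikes")["median"]
        assert med[3] < 1.5 < med[4]
        assert table.max_count_below is not None and table.max_count_below <= 3

    def test_median_amplitude_monotone_in_spike_count_at_zero_noise(self, rng):
        counts = list(np.repeat([1, 2, 3, 4, 5, 6, 8], 25))
        ns, amps = self._pairs("Cal520", counts, rng, noise_sd=0.0)
        table = ephys.spike_dff_calibration(ns, amps, threshold=1.5)
        med = table.table.sort_values("n_spikes")["median"].to_numpy()
        assert np.all(np.diff(med) >= 0)

    def test_needs_two_distinct_counts(self):
        with pytest.raises(ValueError):
            ephys.spike_dff_calibration([3, 3, 3], [1.0, 1.1, 1.2], threshold=1.5)
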