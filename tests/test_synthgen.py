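"""Generator tests: protocol timing, planted populations, spike/burst
laws, the indicator forward model, licking, movies and determinism."""

import math

import numpy as np
import pytest
from scipy import stats

from burstcode import imaging, synthgen as sg


class TestProtocol:
    def test_pump_fires_150ms_after_sound_onset(self):
        trials = sg.make_protocol(sg.ProtocolConfig(paradigm="BBN", n_trials=12))
        assert len(trials) == 12
        for t in trials:
            assert t.pump_onset_ms - t.onset_ms == pytest.approx(150.0)

    def test_single_trial_at_reference_zero(self):
        cfg = sg.ProtocolConfig(
            paradigm="BBN",
            stimulus_set=[sg.Stimulus("BBN", components=sg.TEST_TONES)],
            n_trials=1,
        )
        (trial,) = sg.make_protocol(cfg)
        assert trial.onset_ms == 0.0

    def test_onset_gaps_are_iti_plus_sound_duration(self):
        trials = sg.make_protocol(sg.ProtocolConfig(paradigm="BBN", n_trials=40, seed=9))
        gaps = np.diff([t.onset_ms for t in trials])
        assert np.all(gaps >= 5000.0 + 50.0)
        assert np.all(gaps <= 10000.0 + 50.0)

    def test_randomized_session_covers_every_stimulus(self):
        cfg = sg.ProtocolConfig(paradigm="two_chord", n_trials=10, seed=0)
        trials = sg.make_protocol(cfg)
        assert {t.stimulus_id for t in trials} == {s.stim_id for s in cfg.stimulus_set}

    def test_deterministic_under_seed(self):
        cfg = sg.ProtocolConfig(paradigm="two_chord", n_trials=30, seed=5)
        a = sg.make_protocol(cfg)
        b = sg.make_protocol(cfg)
        assert a == b

    def test_empty_stimulus_set_is_a_configuration_error(self):
        cfg = sg.ProtocolConfig(paradigm="BBN", n_trials=3)
        cfg.stimulus_set = []
        with pytest.raises(ValueError):
            sg.make_protocol(cfg)


class TestPopulation:
    def test_chord_composition_counts(self):
        comp = {"NB": 528, "AB": 19, "qHB_c1": 2, "HB_c1": 3, "qHB_c2": 3, "HB_c2": 15}
        cells = sg.make_population(comp, paradigm="two_chord", seed=0)
        assert len(cells) == 570
        for key, n in comp.items():
            assert sum(c.label_key() == key for c in cells) == n

    def test_nb_cells_have_empty_preferred_sets(self):
        cells = sg.make_population({"NB": 10}, paradigm="BBN", seed=0)
        assert len(cells) == 10
        assert all(not c.preferred_stimuli for c in cells)

    def test_qhb_gets_strict_proper_component_subset(self):
        cells = sg.make_population({"qHB_c1": 30}, paradigm="two_chord", seed=1)
        for c in cells:
            comps = set(sg.CHORD1_TONES) & c.preferred_stimuli
            assert "chord1" in c.preferred_stimuli
            assert 0 < len(comps) < len(sg.CHORD1_TONES)

    def test_qhb_without_complex_structure_is_an_error(self):
        with pytest.raises(ValueError):
            sg.make_population({"qHB": 1}, paradigm="two_tone", seed=0)

    def test_hb_preferred_amplitude_law_median_near_observed(self, rng):
        # Monte-Carlo on the configured law: median close to the 2.93
        # holistic-cell anchor (within 20%).
        cells = sg.make_population({"HB_c1": 300}, paradigm="two_chord", seed=2)
        jitter = np.exp(rng.normal(0.0, sg.AMP_TRIAL_JITTER_SIGMA, size=300))
        amps = np.array([c.burst_amp["chord1"] for c in cells]) * jitter
        assert np.median(amps) == pytest.approx(2.93, rel=0.20)

    def test_negative_count_rejected(self):
        with pytest.raises(ValueError):
            sg.make_population({"NB": -1}, paradigm="BBN", seed=0)


class TestSpikes:
    def _trial(self, stim="BBN", onset=2000.0):
        return sg.Trial(1, stim, onset, 50.0, onset + 150.0, "single")

    def test_burst_spike_count_in_observed_range(self, rng):
        (cell,) = sg.make_population({"HB": 1}, paradigm="BBN", seed=0)
        cell.burst_prob = 1.0
        for _ in range(200):
            tr = sg.sample_spike_train(cell, self._trial(), rng)
            assert tr.is_burst
            assert 3 <= tr.n_spikes <= 27

    def test_nb_cell_never_bursts(self, rng):
        (cell,) = sg.make_population({"NB": 1}, paradigm="BBN", seed=0)
        window = 150.0
        for _ in range(300):
            tr = sg.sample_spike_train(cell, self._trial(), rng)
            in_win = np.sum((tr.times_ms > 2000.0) & (tr.times_ms <= 2000.0 + window))
            assert in_win < 3

    def test_pooled_isi_median_matches_configured_law(self, rng):
        (cell,) = sg.make_population({"HB": 1}, paradigm="BBN", seed=0)
        cell.burst_prob = 1.0
        isis = []
        for _ in range(2000):
            tr = sg.sample_spike_train(cell, self._trial(), rng)
            isis.append(np.diff(tr.times_ms))
        med = np.median(np.concatenate(isis))
        assert med == pytest.approx(11.0, rel=0.15)

    def test_burst_amplitudes_decay(self, rng):
        (cell,) = sg.make_population({"HB": 1}, paradigm="BBN", seed=0)
        cell.burst_prob = 1.0
        n_decaying = 0
        for _ in range(100):
            tr = sg.sample_spike_train(cell, self._trial(), rng)
            if tr.amplitudes[-1] < tr.amplitudes[0]:
                n_decaying += 1
        assert n_decaying >= 99


class TestForwardModel:
    def test_no_spikes_no_noise_gives_flat_dff(self, rng):
        model = sg.default_indicator("Cal520")
        model = sg.IndicatorModel(**{**model.__dict__, "noise_sd": 0.0})
        tr = sg.SimSpikeTrain(np.empty(0), np.empty(0), False, 0)
        trace = sg.spikes_to_fluorescence(tr, model, 2000.0, rng)
        assert np.allclose(trace.dff, 0.0)

    def test_single_spike_cal520_stays_below_burst_threshold(self, rng):
        model = sg.default_indicator("Cal520")
        model = sg.IndicatorModel(**{**model.__dict__, "noise_sd": 0.0})
        tr = sg.SimSpikeTrain(np.array([2030.0]), np.array([1.0]), False, 1)
        trace = sg.spikes_to_fluorescence(tr, model, 5000.0, rng)
        trial = sg.Trial(1, "BBN", 2000.0, 50.0, 2150.0, "single")
        amp = imaging.trial_response_amplitude(trace, trial).amplitude
        assert amp < 1.5

    def test_five_spikes_gcamp_exceed_threshold(self, rng):
        model = sg.default_indicator("GCaMP6f")
        model = sg.IndicatorModel(**{**model.__dict__, "noise_sd": 0.0})
        times = 2030.0 + np.arange(5) * 25.0  # 5 spikes in 100 ms
        tr = sg.SimSpikeTrain(times, np.ones(5), True, 5)
        trace = sg.spikes_to_fluorescence(tr, model, 5000.0, rng)
        trial = sg.Trial(1, "BBN", 2000.0, 50.0, 2150.0, "single")
        assert imaging.trial_response_amplitude(trace, trial).amplitude >= 1.0

    def test_spike_outside_duration_is_an_error(self, rng):
        model = sg.default_indicator("Cal520")
        tr = sg.SimSpikeTrain(np.array([2500.0]), np.array([1.0]), False, 1)
        with pytest.raises(ValueError):
            sg.spikes_to_fluorescence(tr, model, 2000.0, rng)

    @pytest.mark.parametrize("indicator", ["Cal520", "GCaMP6f"])
    def test_calibration_soundness(self, indicator, rng):
        """1-2 spike events never reach the burst threshold; >= 4 spike
        events essentially always do, at default noise."""
        model = sg.default_indicator(indicator)
        theta = model.threshold
        trial = sg.Trial(1, "BBN", 1000.0, 50.0, 1150.0, "single")

        def amp_of(k):
            lat = sg.DEFAULT_LATENCY_LAW.sample(rng)
            isis = sg.DEFAULT_ISI_LAW.sample(rng, size=k - 1) if k > 1 else np.empty(0)
            times = 1000.0 + lat + np.concatenate([[0.0], np.cumsum(np.atleast_1d(isis))])
            tr = sg.SimSpikeTrain(times[:k], np.ones(k), k >= 3, k)
            trace = sg.spikes_to_fluorescence(tr, model, 4000.0, rng)
            return imaging.trial_response_amplitude(trace, trial).amplitude

        singlet = np.array([amp_of(int(k)) for k in rng.integers(1, 3, size=500)])
        multi = np.array([amp_of(int(k)) for k in rng.integers(4, 9, size=500)])
        assert np.mean(singlet >= theta) == 0.0
        assert np.mean(multi >= theta) >= 0.99

    def test_trial_averaged_nb_amplitudes_are_lognormal(self):
        # KS on logs of 1000 generated trial-averaged amplitudes
        # (9 trials each) against the fitted normal, alpha = 0.01.
        g = np.random.default_rng(42)
        law = sg._baseline_amp_law(1.5)
        traits = law.sample(g, size=1000)
        trial_amps = traits[:, None] * np.exp(
            g.normal(0.0, sg.AMP_TRIAL_JITTER_SIGMA, size=(1000, 9))
        )
        logs = np.log(trial_amps.mean(axis=1))
        res = stats.kstest(logs, "norm", args=(logs.mean(), logs.std()))
        assert res.pvalue > 0.01


class TestLicking:
    def _trials(self, n, iti_ms=6000.0):
        return [
            sg.Trial(i + 1, "BBN", 2000.0 + i * iti_ms, 50.0, 2150.0 + i * iti_ms, "single")
            for i in range(n)
        ]

    def test_certain_schedule_with_fixed_latency(self, rng):
        model = sg.BehaviorModel(
            p_early=1.0, p_late=1.0,
            lick_latency_law=sg.TruncatedLogNormal(math.log(250.0), 1e-12),
            spontaneous_rate=0.0, spout_error_prob=0.0,
        )
        trials = self._trials(10)
        licks = sg.sample_licking(trials, model, rng)
        starts = licks.bout_start_times()
        for t in trials:
            assert np.any(np.abs(starts - (t.onset_ms + 250.0)) < 1.0)

    def test_zero_schedule_and_zero_spontaneous_rate(self, rng):
        model = sg.BehaviorModel(p_early=0.0, p_late=0.0, spontaneous_rate=0.0)
        licks = sg.sample_licking(self._trials(20), model, rng)
        assert licks.times_ms.size == 0

    def test_motivational_decay_reaches_low_late_probability(self):
        # Monte-Carlo of the configured schedule: late-session evoked
        # licking falls to <= 20%.
        model = sg.BehaviorModel()
        fracs = []
        g = np.random.default_rng(11)
        for rep in range(200):
            hits = [g.random() < model.evoked_lick_prob(i) for i in range(51, 81)]
            fracs.append(np.mean(hits))
        assert np.mean(fracs) <= 0.20
        assert all(model.evoked_lick_prob(i) >= 0.9 for i in range(1, 21))


class TestMovie:
    def test_zero_shifts_zero_noise_frames_follow_traces_only(self, rng):
        traces = np.zeros((1, 5))
        shifts = np.zeros((5, 2), dtype=int)
        stack = sg.render_movie([(10, 10, 3)], traces, shifts, rng)
        assert all(np.array_equal(stack[0], f) for f in stack)

    def test_constant_planted_shift_found_by_brute_force_ssd(self, rng):
        traces = np.zeros((1, 4))
        shifts = np.tile([2, 3], (4, 1))
        stack = sg.render_movie([(20, 20, 4)], traces, shifts, rng)
        template = sg.render_movie(
            [(20, 20, 4)], traces[:, :1], np.zeros((1, 2), int), rng
        )[0].astype(float)
        best, best_ssd = None, np.inf
        for dy in range(-5, 6):
            for dx in range(-5, 6):
                shifted = imaging._translate(stack[1].astype(float), dy, dx)
                ssd = np.sum((shifted - template)[5:-5, 5:-5] ** 2)
                if ssd < best_ssd:
                    best, best_ssd = (dy, dx), ssd
        assert best == (-2, -3)

    def test_seeded_render_is_reproducible(self):
        traces = np.linspace(0, 1, 6).reshape(1, 6)
        shifts = np.array([[0, 0], [1, 1], [-1, 0], [0, 2], [2, -2], [0, 0]])
        a = sg.render_movie([(15, 15, 3)], traces, shifts, np.random.default_rng(0), noise_sd=2.0)
        b = sg.render_movie([(15, 15, 3)], traces, shifts, np.random.default_rng(0), noise_sd=2.0)
        assert np.array_equal(a, b)

    def test_roi_leaving_frame_is_an_error(self, rng):
        with pytest.raises(ValueError):
            sg.render_movie(
                [(4, 4, 3)], np.zeros((1, 2)), np.tile([-3, -3], (2, 1)), rng
            )


class TestExperiment:
    def test_identical_seeds_give_identical_experiments(self):
        protocol = sg.ProtocolConfig(paradigm="BBN", n_trials=12, seed=7, start_ms=2000.0)
        cells = sg.make_population({"NB": 2, "HB": 1}, paradigm="BBN", seed=8)
        a = sg.simulate_experiment(protocol, cells, seed=9)
        b = sg.simulate_experiment(protocol, cells, seed=9)
        assert a.trials == b.trials
        assert np.array_equal(a.licks.times_ms, b.licks.times_ms)
        for cid in a.traces:
            assert np.array_equal(a.traces[cid].f, b.traces[cid].f)

    def test_seed_scoping_protocol_shared_spikes_differ(self):
        protocol = sg.ProtocolConfig(paradigm="BBN", n_trials=12, seed=7, start_ms=2000.0)
        cells = sg.make_population({"HB": 1}, paradigm="BBN", seed=8)
        a = sg.simulate_experiment(protocol, cells, seed=1)
        b = sg.simulate_experiment(protocol, cells, seed=2)
        assert a.trials == b.trials  # protocol seed shared
        cid = cells[0].cell_id
        different = any(
            not np.array_equal(a.spike_trains[cid][k].times_ms, b.spike_trains[cid][k].times_ms)
            for k in a.spike_trains[cid]
        )
        assert different
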