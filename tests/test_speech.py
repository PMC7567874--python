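"""Envelope extraction, edge detection, and neural encoding measures."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from audiopred import speech as sp
from audiopred.stimuli import make_speech_like_envelope


class TestEnvelope:
    def test_gated_tone_envelope_approximates_gate(self):
        fs = 8000.0
        t = np.arange(int(2 * fs)) / fs
        gate = ((t > 0.5) & (t < 1.5)).astype(float)
        x = gate * np.sin(2 * np.pi * 1000 * t)
        env = sp.extract_envelope(x, fs, cutoff_hz=10.0)
        rise_limit = 1.5 / 10.0
        assert env.amplitude[int((0.5 + rise_limit) * fs)] > 0.9 * env.amplitude.max()
        assert env.amplitude[int(0.25 * fs)] < 0.1 * env.amplitude.max()

    def test_silence_gives_zeros(self):
        env = sp.extract_envelope(np.zeros(4000), 8000.0)
        assert np.allclose(env.amplitude, 0.0)

    def test_am_stimulus_envelope_matches_modulator(self, am_stimulus):
        env = sp.extract_envelope(am_stimulus.waveform, 8000.0, target_rate_hz=1000.0)
        modulator = np.interp(env.times, am_stimulus.times, am_stimulus.envelope)
        assert np.corrcoef(env.amplitude, modulator)[0, 1] > 0.95


class TestEdges:
    def test_nine_edges_on_3hz_modulator(self, am_stimulus):
        trace = sp.EnvelopeTrace(am_stimulus.times, am_stimulus.envelope, 8000.0, 10.0)
        ann = sp.detect_edges(trace)
        assert len(ann.edge_times) == 9
        assert np.abs(ann.edge_times - am_stimulus.edge_times).max() < 0.01

    def test_monotone_decay_has_no_edges(self):
        t = np.arange(2000) / 1000.0
        trace = sp.EnvelopeTrace(t, np.exp(-t), 1000.0, 10.0)
        assert len(sp.detect_edges(trace).edge_times) == 0

    @settings(deadline=None, max_examples=10)
    @given(st.floats(0.1, 50.0))
    def test_amplitude_scale_invariance(self, scale):
        sentences = make_speech_like_envelope(n_sentences=1, seed=4)
        s = sentences[0]
        t1 = sp.detect_edges(sp.EnvelopeTrace(s.times, s.envelope, s.sample_rate_hz, 10.0))
        t2 = sp.detect_edges(sp.EnvelopeTrace(s.times, scale * s.envelope, s.sample_rate_hz, 10.0))
        assert np.array_equal(t1.edge_times, t2.edge_times)

    def test_planted_recovery_at_20_db(self):
        rng = np.random.default_rng(5)
        sentences = make_speech_like_envelope(n_sentences=20, seed=3)
        tp = fp = fn = 0
        for s in sentences:
            noise_rms = np.sqrt(np.mean(s.envelope**2)) / 10 ** (20 / 20)
            noisy = np.clip(s.envelope + rng.normal(0, noise_rms, len(s.envelope)), 0, None)
            ann = sp.detect_edges(sp.EnvelopeTrace(s.times, noisy, s.sample_rate_hz, 10.0))
            matched = np.zeros(len(s.edge_times), bool)
            for t in ann.edge_times:
                d = np.abs(s.edge_times - t)
                if len(d) and d.min() < 0.06 and not matched[d.argmin()]:
                    matched[d.argmin()] = True
                    tp += 1
                else:
                    fp += 1
            fn += int((~matched).sum())
        assert tp / (tp + fp) >= 0.95
        assert tp / (tp + fn) >= 0.95


class TestLaggedSpearman:
    def _concatenated_speech(self, seed=3):
        sentences = make_speech_like_envelope(n_sentences=12, seed=seed)
        env = np.concatenate([s.envelope for s in sentences])
        mask = sp.trial_boundary_mask([len(s.envelope) for s in sentences], 1000.0)
        return env, mask

    @pytest.mark.parametrize("lag_ms", [45, 135])
    def test_planted_lag_recovered(self, lag_ms):
        rng = np.random.default_rng(7)
        env, mask = self._concatenated_speech()
        neural = np.roll(env, lag_ms) + rng.normal(0, 0.3 * env.std(), len(env))
        curve, peak_lag, rho = sp.lagged_spearman(neural, env, 1000.0, max_lag_ms=300)
        assert abs(peak_lag - lag_ms) <= 5.0
        assert rho > 0.5

    def test_negative_correlation_sign_preserved(self):
        rng = np.random.default_rng(8)
        env, mask = self._concatenated_speech()
        neural = -np.roll(env, 135) + rng.normal(0, 0.3 * env.std(), len(env))
        curve, peak_lag, rho = sp.lagged_spearman(neural, env, 1000.0, max_lag_ms=300)
        assert rho < -0.5
        assert abs(peak_lag - 135) <= 5.0

    def test_independent_series_peak_is_weak(self):
        rng = np.random.default_rng(9)
        env, _ = self._concatenated_speech()
        neural = rng.standard_normal(len(env))
        _, _, rho = sp.lagged_spearman(neural, env, 1000.0, max_lag_ms=200)
        assert abs(rho) < 0.1

    def test_short_series_rejected(self):
        with pytest.raises(ValueError):
            sp.lagged_spearman(np.zeros(100), np.zeros(100), 1000.0, max_lag_ms=500)


class TestPostEdgeItc:
    def test_edge_locked_resets_beat_syllable_onsets(self):
        from audiopred.simulate import simulate_reset_phase_series

        fs = 500.0
        sentences = make_speech_like_envelope(n_sentences=20, seed=3)
        edges, sylls, offset = [], [], 0.5
        for s in sentences:
            edges.extend(offset + s.edge_times)
            sylls.extend(offset + s.syllable_times)
            offset += s.duration_s + 0.5
        phase = simulate_reset_phase_series(12, offset + 0.5, fs, np.array(edges), rng=7)
        table = sp.post_edge_itc(phase, fs, np.array(edges), np.array(sylls))
        assert (table["edge_itc"] > table["syllable_itc"]).mean() > 0.8
        assert sp.edge_vs_syllable_test(table) < 0.01

    def test_random_events_give_null_level_itc(self):
        rng = np.random.default_rng(11)
        phase = rng.uniform(-np.pi, np.pi, (4, 30000))
        events = rng.uniform(1.0, 55.0, 60)
        table = sp.post_edge_itc(phase, 500.0, events)
        expected = np.sqrt(np.pi) / 2 / np.sqrt(60)
        assert table["edge_itc"].mean() == pytest.approx(expected, rel=0.25)

    def test_zero_window_rejected(self):
        with pytest.raises(ValueError):
            sp.post_edge_itc(np.zeros((2, 100)), 500.0, np.arange(25) * 0.01, window_ms=0.0)

    def test_too_few_events_rejected(self):
        with pytest.raises(ValueError, match="at least"):
            sp.post_edge_itc(np.zeros((2, 1000)), 500.0, np.array([0.5, 0.6]))


class TestArticulationOnset:
    def test_burst_onset_within_10_ms(self):
        fs = 8000.0
        rng = np.random.default_rng(0)
        x = 0.01 * rng.standard_normal(int(3 * fs))
        t = np.arange(int(fs)) / fs
        x[int(1.2 * fs) : int(2.2 * fs)] += np.sin(2 * np.pi * 300 * t)
        intervals = sp.detect_articulation_onset(x, fs)
        assert len(intervals) == 1
        assert intervals[0][0] == pytest.approx(1.2, abs=0.01)

    def test_silence_gives_empty(self):
        assert sp.detect_articulation_onset(np.zeros(8000), 8000.0) == []

    def test_two_bursts_in_order(self):
        fs = 8000.0
        rng = np.random.default_rng(0)
        x = 0.01 * rng.standard_normal(int(4 * fs))
        t = np.arange(int(0.5 * fs)) / fs
        for onset in (0.8, 2.6):
            x[int(onset * fs) : int(onset * fs) + len(t)] += np.sin(2 * np.pi * 300 * t)
        intervals = sp.detect_articulation_onset(x, fs)
        assert len(intervals) == 2
        assert intervals[0][0] < intervals[1][0]
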