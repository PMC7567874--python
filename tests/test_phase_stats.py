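"""ITC, bootstrap nulls, KL phase profiles, trajectories, screening."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from audiopred import phase_stats as ph

FS = 500.0


class TestITC:
    def test_perfect_alignment(self):
        phase = np.full((10, 5), 0.7)
        assert np.allclose(ph.itc(phase, trial_axis=0), 1.0)

    def test_antiphase_pair_cancels(self):
        phase = np.array([[0.0], [np.pi]])
        assert ph.itc(phase, trial_axis=0)[0] == pytest.approx(0.0, abs=1e-12)

    def test_orthogonal_pair(self):
        phase = np.array([[0.0], [np.pi / 2]])
        assert ph.itc(phase, trial_axis=0)[0] == pytest.approx(np.sqrt(2) / 2)

    @settings(deadline=None, max_examples=25)
    @given(st.floats(-np.pi, np.pi))
    def test_invariant_under_global_rotation(self, rotation):
        rng = np.random.default_rng(0)
        phase = rng.uniform(-np.pi, np.pi, (8, 16))
        a = ph.itc(phase, trial_axis=0)
        b = ph.itc(phase + rotation, trial_axis=0)
        assert np.allclose(a, b, atol=1e-9)

    def test_copies_of_one_trial_give_unity(self):
        rng = np.random.default_rng(1)
        trial = rng.uniform(-np.pi, np.pi, 32)
        phase = np.tile(trial, (6, 1))
        assert np.allclose(ph.itc(phase, trial_axis=0), 1.0)

    def test_single_trial_rejected(self):
        with pytest.raises(ValueError):
            ph.itc(np.zeros((1, 4)), trial_axis=0)

    def test_nonfinite_rejected(self):
        with pytest.raises(ValueError):
            ph.itc(np.array([[0.0, np.nan], [1.0, 1.0]]), trial_axis=0)

    def test_null_expectation_scaling(self, rng):
        values = [ph.itc(rng.uniform(-np.pi, np.pi, (100, 1)), trial_axis=0)[0] for _ in range(400)]
        assert np.mean(values) == pytest.approx(np.sqrt(np.pi) / 2 / 10, rel=0.1)


class TestItcChange:
    def test_baseline_mean_zero_by_construction(self, rng):
        series = rng.random((3, 100))
        times = np.arange(100) / FS - 0.1
        out = ph.itc_change(series, times, (-0.1, 0.0))
        assert np.allclose(out[:, :50].mean(axis=1), 0.0, atol=1e-12)

    def test_planted_reset_rises_post_onset_only(self, rng):
        phase = rng.uniform(-np.pi, np.pi, (24, 200))
        phase[:, 100:140] = rng.normal(0.0, 0.3, (24, 40))  # aligned segment
        series = ph.itc(phase, trial_axis=0)[None, :]
        times = np.arange(200) / FS - 0.2
        out = ph.itc_change(series, times, (-0.2, 0.0))
        assert out[0, 100:140].mean() > 0.3
        assert abs(out[0, :100].mean()) < 0.1


class TestJitterBootstrap:
    def test_locked_fixture_minimal_p(self, rng):
        phase = np.tile(np.linspace(-np.pi, np.pi, 100), (12, 1))
        phase += rng.normal(0, 0.05, phase.shape)
        stat = lambda p: float(ph.itc(p, trial_axis=0)[40:60].mean())
        _, _, p = ph.jitter_bootstrap_null(phase, stat, n_boot=199, rng=rng)
        assert p == pytest.approx(1.0 / 200.0)

    def test_null_p_values_uniform(self, rng):
        ps = []
        stat = lambda p: float(ph.itc(p, trial_axis=0)[:40].mean())
        for _ in range(100):
            phase = rng.uniform(-np.pi, np.pi, (10, 120))
            _, _, p = ph.jitter_bootstrap_null(phase, stat, n_boot=99, rng=rng)
            ps.append(p)
        from scipy.stats import kstest

        assert kstest(ps, "uniform").pvalue > 0.01

    def test_small_n_boot_warns(self, rng):
        phase = rng.uniform(-np.pi, np.pi, (4, 50))
        with pytest.warns(UserWarning):
            ph.jitter_bootstrap_null(phase, lambda p: 0.0, n_boot=20, rng=rng)


class TestPhaseResolvedAmplitude:
    def test_uniform_amplitude_gives_zero_kl(self, rng):
        stim_phase = np.angle(np.exp(1j * np.linspace(0, 40 * np.pi, 2000)))
        amp = np.ones((8, 2000)) + rng.normal(0, 0.01, (8, 2000))
        prof = ph.phase_resolved_amplitude(amp, stim_phase, n_boot=200, rng=rng)
        assert prof.kl_divergence < 1e-3
        assert prof.p_value > 0.05

    def test_degenerate_profile_reaches_log_b(self):
        assert ph._kl_from_uniform(np.array([1.0] + [0.0] * 17)) == pytest.approx(np.log(18))

    def test_planted_in_phase_amplitude_significant(self, rng):
        stim_phase = np.angle(np.exp(1j * 2 * np.pi * 3.0 * np.arange(0, 2.667, 1 / FS)))
        amp = 1 + 0.5 * np.cos(stim_phase) + rng.normal(0, 0.3, (24, len(stim_phase)))
        prof = ph.phase_resolved_amplitude(amp, stim_phase, n_boot=1000, rng=rng)
        assert prof.p_value < 0.001
        assert prof.kl_divergence > 0


class TestIntervals:
    @pytest.mark.parametrize("freq, delay", [(3.0, 83), (5.0, 50), (7.0, 36)])
    def test_quarter_period_delay(self, freq, delay):
        assert ph.quarter_period_delay(freq) == delay

    def test_default_intervals_ordered_non_overlapping(self):
        iv = ph.default_intervals(3.0)
        order = ["baseline", "onset", "sustained", "early_prediction", "late_prediction"]
        bounds = [iv[name] for name in order]
        for (a0, a1), (b0, b1) in zip(bounds, bounds[1:]):
            assert a1 <= b0 + 1e-12

    def test_signed_r2_of_perfect_tracker_is_one(self):
        t = np.linspace(0, 1, 300)
        ref = np.cos(2 * np.pi * 3 * t)
        assert ph.signed_r2(ref, ref) == pytest.approx(1.0)
        assert ph.signed_r2(-ref, ref) == pytest.approx(-1.0)


class TestPhaseSpace:
    def test_constant_series_is_a_point(self):
        x, y, _ = ph.phase_space_trajectory(np.full(500, 2.0), 83.0, FS)
        assert np.ptp(x) == 0 and np.ptp(y) == 0

    def test_sinusoid_quadrature_embedding_is_circle(self):
        f = 3.0
        t = np.arange(int(4 * FS)) / FS
        series = np.cos(2 * np.pi * f * t)
        x, y, _ = ph.phase_space_trajectory(series, ph.quarter_period_delay(f), FS)
        radius = np.sqrt(x**2 + y**2)
        assert np.ptp(radius) / radius.mean() < 0.02

    def test_delay_longer_than_series_rejected(self):
        with pytest.raises(ValueError):
            ph.phase_space_trajectory(np.zeros(10), 1000.0, FS)

    def test_state_labels_follow_intervals(self):
        t = np.arange(int(4 * FS)) / FS - 0.5
        x, y, labels = ph.phase_space_trajectory(
            np.sin(t), 83.0, FS, times=t, intervals=ph.default_intervals(3.0)
        )
        assert set(labels) >= {"baseline", "onset", "sustained"}


class TestPredictiveScreen:
    def test_alpha_zero_empty(self):
        df = pd.DataFrame({"p_sustained": [0.001, 0.2], "p_early_prediction": [0.001, 0.3]})
        out = ph.predictive_electrode_screen(df, alpha=0.0)
        assert not out["predictive"].any()

    def test_requires_both_criteria(self):
        df = pd.DataFrame(
            {"p_sustained": [0.001, 0.001, 0.5], "p_early_prediction": [0.001, 0.5, 0.001]}
        )
        out = ph.predictive_electrode_screen(df, alpha=0.05)
        assert out["predictive"].tolist() == [True, False, False]
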