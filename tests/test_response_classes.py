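"""NNMF classification, archetype transfer, gradients, wave fitting."""

import numpy as np
import pandas as pd
import pytest

from audiopred import response_classes as rc
from audiopred.simulate import make_response_feature_cohort, simulate_wave_peak_times


def _sustained_template(times, mod_freq=3.0, rhythmic_dur=3.0):
    template = 0.5 + 0.5 * np.cos(2 * np.pi * mod_freq * times)
    template[times > rhythmic_dur] = 0.0
    return template


class TestRectify:
    def test_all_sub_baseline_becomes_zero(self):
        assert np.array_equal(rc.rectify(np.array([-3.0, -0.1, 0.0])), np.zeros(3))

    def test_positive_input_unchanged(self):
        x = np.array([0.5, 2.0, 7.0])
        assert np.array_equal(rc.rectify(x), x)

    def test_mixed_input_clips_only_negative_part(self):
        x = np.array([-1.0, 4.0, -0.5, 2.0])
        out = rc.rectify(x)
        assert out.min() == 0.0
        assert np.array_equal(out[[1, 3]], x[[1, 3]])


class TestNNMF:
    def test_exact_rank_two_recovered(self):
        rng = np.random.default_rng(0)
        A = rng.uniform(0.5, 2.0, (60, 2)) @ rng.uniform(0.5, 2.0, (2, 80))
        model = rc.nnmf_fit(A, n_replicates=5, max_iter=5000, tol=1e-12, seed=0)
        rel = model.residual / np.linalg.norm(A, "fro")
        assert rel < 1e-4

    def test_objective_monotone_nonincreasing(self):
        rng = np.random.default_rng(1)
        A = rng.uniform(0, 1, (30, 50))
        model = rc.nnmf_fit(A, n_replicates=1, max_iter=200, tol=0.0, seed=1)
        diffs = np.diff(model.objective_history)
        assert (diffs <= 1e-9 * model.objective_history[0]).all()

    def test_agrees_with_reference_nmf(self):
        sklearn = pytest.importorskip("sklearn.decomposition")
        rng = np.random.default_rng(2)
        A = rng.uniform(0, 1, (40, 60)) + 2.0 * np.outer(rng.uniform(0, 1, 40), rng.uniform(0, 1, 60))
        ours = rc.nnmf_fit(A, n_replicates=10, max_iter=2000, tol=1e-10, seed=2)
        ref = sklearn.NMF(n_components=2, solver="mu", init="random", max_iter=2000, random_state=0)
        ref_residual = np.linalg.norm(A - ref.fit_transform(A) @ ref.components_, "fro")
        assert ours.residual <= ref_residual * 1.02

    def test_zero_matrix_rejected(self):
        with pytest.raises(ValueError):
            rc.nnmf_fit(np.zeros((5, 5)))

    def test_planted_cohort_classification(self):
        A, _, truth, times = make_response_feature_cohort(n_electrodes=100, seed=1)
        model = rc.nnmf_fit(A, n_replicates=10, max_iter=300, seed=1)
        rc.orient_model(model, _sustained_template(times))
        labels = rc.classify(model.class_bias)
        mask = truth["archetype"].isin(["sustained", "transient"]).to_numpy()
        accuracy = np.mean(labels[mask] == truth["archetype"].to_numpy()[mask])
        assert accuracy >= 0.95

    def test_classify_invariant_to_archetype_rescaling(self):
        # bias is computed after H-row max-normalization, so a simultaneous
        # rescale of W column / H row leaves classifications unchanged
        A, _, truth, times = make_response_feature_cohort(n_electrodes=60, seed=3)
        model = rc.nnmf_fit(A, n_replicates=5, max_iter=300, seed=3)
        rc.orient_model(model, _sustained_template(times))
        before = rc.classify(model.class_bias).copy()
        model.W[:, 0] /= 7.0
        model.H[0] *= 7.0
        norms = model.H.max(axis=1)
        model.H /= norms[:, None]
        model.W *= norms[None, :]
        assert np.array_equal(rc.classify(model.class_bias), before)


class TestFullPipelineRecovery:
    def test_classes_cluster_in_planted_regions(self, small_recording):
        """Raw simulated recording -> epochs -> rectified high-gamma
        features -> NNMF recovers the planted anatomical organization."""
        sklearn_metrics = pytest.importorskip("sklearn.metrics")
        from audiopred.containers import epoch
        from audiopred.spectral import HIGH_GAMMA_BAND, band_decompose, percent_change_power

        stim, electrodes, truth, rec = small_recording
        ep = epoch(rec, "stimulus_onset", (-0.5, 4.5))
        hg = band_decompose(ep.data, ep.sample_rate_hz, HIGH_GAMMA_BAND)
        pct = percent_change_power(hg, ep.times, ep.baseline_window).mean(axis=1)
        A = rc.rectify(pct[:, ep.times >= 0])
        model = rc.nnmf_fit(A, n_replicates=10, max_iter=300, seed=0)
        times = ep.times[ep.times >= 0]
        rc.orient_model(model, _sustained_template(times))
        labels = rc.classify(model.class_bias, bias_threshold=10.0)
        planted = truth.electrodes["archetype"].to_numpy()
        mask = planted != "null"
        ari = sklearn_metrics.adjusted_rand_score(planted[mask], labels[mask])
        assert ari >= 0.8


class TestClassify:
    def test_threshold_logic(self):
        bias = np.array([50.0, -50.0, 3.0, 0.0])
        assert rc.classify(bias).tolist() == ["sustained", "transient", "unclassified", "unclassified"]

    def test_joint_mixed_requires_opposite_signs(self):
        power = np.array([50.0, 50.0, 3.0])
        itc = np.array([-50.0, 50.0, 2.0])
        assert rc.classify_joint(power, itc).tolist() == ["mixed", "sustained", "unclassified"]


class TestTransfer:
    def test_self_transfer_recovers_weights(self):
        rng = np.random.default_rng(4)
        W0 = rng.uniform(0.5, 2.0, (50, 2))
        H0 = np.abs(np.vstack([np.sin(np.linspace(0, 3, 80)) + 1.1, np.cos(np.linspace(0, 3, 80)) + 1.1]))
        A = W0 @ H0
        model = rc.nnmf_fit(A, n_replicates=5, max_iter=4000, tol=1e-12, seed=4)
        W_new = rc.transfer_weights(model, A)
        for k in range(2):
            rho = np.corrcoef(W_new[:, k], model.W[:, k])[0, 1]
            assert rho > 0.99

    def test_sustained_only_rows_have_no_transient_weight(self):
        A, _, truth, times = make_response_feature_cohort(n_electrodes=60, snr=50.0, seed=5)
        model = rc.nnmf_fit(A, n_replicates=5, max_iter=500, seed=5)
        rc.orient_model(model, _sustained_template(times))
        sustained_rows = truth["archetype"].to_numpy() == "sustained"
        pure = np.outer(
            model.W[sustained_rows, model.sustained_index], model.H[model.sustained_index]
        )
        W_new = rc.transfer_weights(model, pure)
        transient = 1 - model.sustained_index
        assert W_new[:, transient].max() < 0.05 * W_new[:, model.sustained_index].mean()

    def test_time_axis_mismatch_rejected(self):
        A, _, _, _ = make_response_feature_cohort(n_electrodes=20, seed=6)
        model = rc.nnmf_fit(A, n_replicates=2, max_iter=100, seed=6)
        with pytest.raises(ValueError):
            rc.transfer_weights(model, A[:, :-5])


class TestGradient:
    def test_planted_anteroposterior_gradient(self):
        A, _, truth, times = make_response_feature_cohort(n_electrodes=200, seed=7)
        model = rc.nnmf_fit(A, n_replicates=5, max_iter=300, seed=7)
        rc.orient_model(model, _sustained_template(times))
        rho, p, n = rc.gradient_correlation(
            model.class_bias, model.response_magnitude, truth["anteroposterior_pos_mm"].to_numpy()
        )
        # sustained-positive bias anterior, transient posterior -> negative rho
        assert rho < -0.4
        assert p < 1e-4

    def test_randomized_positions_null(self):
        rng = np.random.default_rng(8)
        A, _, truth, times = make_response_feature_cohort(n_electrodes=200, seed=8)
        model = rc.nnmf_fit(A, n_replicates=5, max_iter=300, seed=8)
        rho, p, _ = rc.gradient_correlation(
            model.class_bias, model.response_magnitude, rng.permutation(truth["anteroposterior_pos_mm"].to_numpy())
        )
        assert abs(rho) < 0.2

    def test_too_few_qualifying_rejected(self):
        with pytest.raises(ValueError):
            rc.gradient_correlation(np.zeros(10), np.ones(10), np.arange(10.0), magnitude_min=10.0)


class TestPeakElectrode:
    def test_argmax_with_lexicographic_tie_break(self):
        summary = pd.DataFrame(
            {
                "subject": ["s1", "s1", "s1", "s2"],
                "electrode": ["b", "a", "c", "z"],
                "power": [5.0, 5.0, 1.0, 2.0],
            }
        )
        out = rc.select_peak_electrode(summary, "power")
        assert out.loc[out.subject == "s1", "electrode"].item() == "a"
        assert out.loc[out.subject == "s2", "electrode"].item() == "z"


class TestTravelingWave:
    def test_noiseless_inversion(self):
        pos = np.linspace(0, 16, 8)
        peaks = np.tile(pos / 0.1, (8, 1))  # mm / (m/s) == ms
        fit = rc.traveling_wave_fit(peaks, pos)
        assert fit.defined
        assert fit.velocity_m_per_s == pytest.approx(0.1)
        assert fit.direction == "medial_to_lateral"

    def test_shuffled_positions_flagged_undefined(self):
        rng = np.random.default_rng(9)
        pos = np.linspace(0, 16, 8)
        peaks = np.tile(rng.permutation(pos / 0.1), (8, 1)) + rng.normal(0, 1, (8, 8))
        fit = rc.traveling_wave_fit(peaks, pos)
        assert not fit.defined

    def test_jittered_recovery_within_10_percent(self):
        pos = np.linspace(0, 16, 8)
        velocities = []
        for seed in range(30):
            peaks = simulate_wave_peak_times(pos, jitter_ms=10.0, rng=seed)
            velocities.append(rc.traveling_wave_fit(peaks, pos).velocity_m_per_s)
        assert np.all(np.abs(np.array(velocities) - 0.1) <= 0.01)

    def test_too_few_electrodes_rejected(self):
        with pytest.raises(ValueError):
            rc.traveling_wave_fit(np.zeros((3, 3)), np.arange(3.0))
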