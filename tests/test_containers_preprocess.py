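"""Recording container round-trips and preprocessing contracts."""

import numpy as np
import pandas as pd
import pytest

from audiopred.containers import EVENT_COLUMNS, FormatError, Recording, epoch, read_recording, write_recording
from audiopred.preprocess import common_average_reference, exclude_channels, notch_line_noise


def _recording(n_channels=4, n_samples=8000, fs=1000.0, seed=0, events=None):
    rng = np.random.default_rng(seed)
    if events is None:
        events = pd.DataFrame(
            {
                "onset_s": [1.0, 3.0, 5.0],
                "duration_s": 0.5,
                "type": "stimulus_onset",
                "trial_id": [0, 1, 2],
            }
        )[EVENT_COLUMNS]
    return Recording(
        rng.standard_normal((n_channels, n_samples)),
        fs,
        [f"ch{i}" for i in range(n_channels)],
        events,
    )


class TestContainerIO:
    def test_hdf5_round_trip_lossless(self, tmp_path):
        rec = _recording()
        path = tmp_path / "rec.h5"
        write_recording(rec, path)
        back = read_recording(path)
        assert np.array_equal(back.data, rec.data)
        assert back.sample_rate_hz == rec.sample_rate_hz
        assert back.channel_ids == rec.channel_ids
        pd.testing.assert_frame_equal(
            back.events.astype({"trial_id": int}), rec.events.astype({"trial_id": int})
        )

    def test_missing_sample_rate_is_format_error(self, tmp_path):
        import h5py

        path = tmp_path / "bad.h5"
        with h5py.File(path, "w") as f:
            f.create_dataset("data", data=np.zeros((2, 10)))
            f.create_dataset("channel_ids", data=np.asarray(["a", "b"], dtype="S"))
        with pytest.raises(FormatError):
            read_recording(path)

    def test_nan_data_rejected(self):
        with pytest.raises(ValueError):
            Recording(np.full((2, 10), np.nan), 100.0, ["a", "b"])


class TestNotch:
    def test_line_frequency_strongly_attenuated(self):
        fs = 1000.0
        t = np.arange(8000) / fs
        rec = _recording(n_channels=1)
        rec.data[0] = np.sin(2 * np.pi * 60.0 * t)
        out = notch_line_noise(rec)
        assert np.sqrt(np.mean(out.data[0, 500:-500] ** 2)) < 0.1 * np.sqrt(0.5)

    def test_passband_untouched_within_1_db(self):
        fs = 1000.0
        t = np.arange(8000) / fs
        rec = _recording(n_channels=1)
        rec.data[0] = np.sin(2 * np.pi * 30.0 * t)
        out = notch_line_noise(rec)
        ratio_db = 20 * np.log10(
            np.sqrt(np.mean(out.data[0, 500:-500] ** 2)) / np.sqrt(np.mean(rec.data[0, 500:-500] ** 2))
        )
        assert abs(ratio_db) < 1.0

    def test_zero_phase(self):
        # cross-correlation between filtered and raw broadband peaks at lag 0
        rec = _recording(n_channels=1, seed=3)
        out = notch_line_noise(rec)
        x, y = rec.data[0], out.data[0]
        lags = np.arange(-5, 6)
        xc = [np.corrcoef(x[500 + s : 7000 + s], y[500:7000])[0, 1] for s in lags]
        assert lags[int(np.argmax(xc))] == 0

    def test_nyquist_violation_rejected(self):
        rec = _recording(fs=300.0)
        with pytest.raises(ValueError):
            notch_line_noise(rec, base_hz=60.0, n_harmonics=3)


class TestExclusion:
    def test_injected_line_noise_excluded(self):
        fs = 1000.0
        t = np.arange(20000) / fs
        rec = _recording(n_channels=3, n_samples=20000)
        noise_rms = np.sqrt(np.mean(rec.data[0] ** 2))
        rec.data[0] += 10 ** (20 / 20) * noise_rms * np.sin(2 * np.pi * 60 * t)
        out, report = exclude_channels(rec)
        assert report.loc[report.channel == "ch0", "excluded"].item()
        assert "line_noise" in report.loc[report.channel == "ch0", "reason"].item()
        assert out.n_channels == 2

    def test_clean_channels_kept(self):
        rec = _recording(n_channels=4, n_samples=20000)
        out, report = exclude_channels(rec)
        assert not report["excluded"].any()
        assert out.n_channels == 4

    def test_clipped_channel_excluded_as_saturated(self):
        rec = _recording(n_channels=2, n_samples=20000)
        rec.data[1] = np.clip(rec.data[1], -0.8, 0.8)
        out, report = exclude_channels(rec)
        assert "saturation" in report.loc[report.channel == "ch1", "reason"].item()

    def test_all_excluded_signaled(self):
        rec = _recording(n_channels=2, n_samples=20000)
        rec.data[:] = np.clip(rec.data, -0.5, 0.5)
        with pytest.raises(ValueError, match="all channels"):
            exclude_channels(rec)


class TestCommonAverage:
    def test_per_sample_channel_mean_is_zero(self):
        rec = _recording(n_channels=8)
        out = common_average_reference(rec)
        assert np.allclose(out.data.mean(axis=0), 0.0, atol=1e-12)

    def test_idempotent(self):
        rec = _recording(n_channels=8)
        once = common_average_reference(rec)
        twice = common_average_reference(once)
        assert np.allclose(once.data, twice.data)

    def test_antisymmetric_pair_unchanged_and_offset_removed(self):
        rec = _recording(n_channels=2)
        rec.data[1] = -rec.data[0]
        out = common_average_reference(rec)
        assert np.allclose(out.data, rec.data)
        rec.data += 5.0
        out = common_average_reference(rec)
        assert np.allclose(out.data.mean(axis=0), 0.0)

    def test_single_channel_rejected(self):
        rec = _recording(n_channels=2)
        with pytest.raises(ValueError):
            common_average_reference(rec.select_channels(["ch0"]))


class TestEpoch:
    def test_trial_count_and_shape(self):
        rec = _recording()
        ep = epoch(rec, "stimulus_onset", (-0.5, 1.0))
        assert ep.data.shape == (4, 3, 1500)
        assert ep.times[0] == pytest.approx(-0.5)

    def test_boundary_event_dropped_with_warning(self):
        events = pd.DataFrame(
            {
                "onset_s": [0.1, 3.0, 5.0],
                "duration_s": 0.5,
                "type": "stimulus_onset",
                "trial_id": [0, 1, 2],
            }
        )[EVENT_COLUMNS]
        rec = _recording(events=events)
        with pytest.warns(UserWarning, match="dropped 1"):
            ep = epoch(rec, "stimulus_onset", (-0.5, 1.0))
        assert ep.n_trials == 2
        assert ep.n_dropped == 1

    def test_trial_average_converges_to_planted_sinusoid(self):
        fs = 1000.0
        rng = np.random.default_rng(0)
        onsets = 1.0 + np.arange(20) * 2.0
        data = rng.standard_normal((1, int(42 * fs)))
        t_rel = np.arange(int(0.5 * fs)) / fs
        wave = np.sin(2 * np.pi * 7 * t_rel)
        for onset in onsets:
            i0 = int(onset * fs)
            data[0, i0 : i0 + len(t_rel)] += wave
        events = pd.DataFrame(
            {"onset_s": onsets, "duration_s": 0.5, "type": "stimulus_onset", "trial_id": np.arange(20)}
        )[EVENT_COLUMNS]
        rec = Recording(data, fs, ["ch0"], events)
        ep = epoch(rec, "stimulus_onset", (0.0, 0.5), baseline_window=(0.0, 0.1))
        avg = ep.data[0].mean(axis=0)
        assert np.corrcoef(avg, wave)[0, 1] > 0.9
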