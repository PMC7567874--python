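"""Forward model: synthetic supratemporal cohorts with planted ground truth.

The generator emulates the statistical structure that the analyses assume,
not biophysics. Each electrode realizes one archetype:

``sustained`` (early auditory cortex, HG/TTS)
    High-gamma amplitude tracks the stimulus envelope at a planted lag
    (plus a mediolateral traveling-wave lag, position / velocity); a noisy
    theta-band phase oscillator is captured (reset) at every acoustic edge
    and keeps resetting at the stimulus cadence for ``persist_cycles``
    cycles after the last pulse; beta bursts re-synchronize at envelope
    troughs. The persisted (predicted) reset is anticipatory: it leads the
    extrapolated edge time by ``anticipation_lead_s``, mirroring phase
    alignment that precedes an expected event.

``transient`` (planum temporale)
    A single onset-locked high-gamma burst about one pulse long with a
    broadband low-frequency deflection, no sustained tracking; suppressed
    in articulation-aligned epochs when ``articulation_suppressed``. Only
    assigned in the language-dominant hemisphere.

``null``
    1/f^1.5 background noise only (false-positive control).

Phase decoherence between resets is produced by Brownian phase diffusion,
so inter-trial coherence decays within a fraction of a modulation cycle of
the last reset; this is what terminates the prediction signature in the
second post-stimulus cycle.

All amplitudes are expressed relative to the unit-variance 1/f^1.5
background; ``snr_db`` scales every planted component of an electrode
around the 10 dB reference condition.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import signal as sp_signal

from ._util import as_rng
from .containers import EVENT_COLUMNS, Recording
from .stimuli import SpeechSentence, Stimulus, make_speech_like_envelope

__all__ = [
    "GroundTruth",
    "make_electrode_table",
    "make_ground_truth",
    "one_over_f_noise",
    "simulate_neural_response",
    "simulate_articulation_response",
    "make_response_feature_cohort",
    "simulate_wave_peak_times",
    "simulate_detection_behavior",
    "simulate_edge_locked_phases",
]

ARCHETYPES = ("sustained", "transient", "mixed", "null")


@dataclass
class GroundTruth:
    """Planted per-electrode parameters plus behavioral effect sizes."""

    electrodes: pd.DataFrame  # archetype, hg_lag_ms, theta_reset_persist_cycles,
    # wave_velocity_m_per_s, articulation_suppressed, snr_db per electrode id
    psychometric_slope: float = 0.35
    psychometric_intercept: float = 0.9
    position2_bonus: float = 0.9

    def __post_init__(self) -> None:
        bad = set(self.electrodes["archetype"]) - set(ARCHETYPES)
        if bad:
            raise ValueError(f"unknown archetypes {bad}")
        if (self.electrodes["theta_reset_persist_cycles"] < 0).any():
            raise ValueError("persist_cycles must be >= 0")

    def for_channel(self, channel_id: str) -> pd.Series:
        row = self.electrodes[self.electrodes["id"] == channel_id]
        if row.empty:
            raise KeyError(channel_id)
        return row.iloc[0]


def make_electrode_table(
    n_sustained: int = 10,
    n_transient: int = 6,
    n_null: int = 4,
    array_extent_mm: float = 16.0,
    seed=0,
) -> pd.DataFrame:
    """Electrode geometry along a supratemporal depth-probe trajectory.

    Sustained electrodes sit anteriorly (HG/TTS) spread along the
    mediolateral axis (for traveling-wave fits); transient electrodes sit
    posteriorly (PT) in the dominant hemisphere; null electrodes elsewhere.
    """
    rng = as_rng(seed)
    rows = []
    ml = np.linspace(0.0, array_extent_mm, max(n_sustained, 2))
    for i in range(n_sustained):
        rows.append(("HG/TTS", "left", True, ml[i % len(ml)], rng.normal(10.0, 3.0)))
    for _ in range(n_transient):
        rows.append(("PT", "left", True, rng.uniform(0, array_extent_mm), rng.normal(28.0, 3.0)))
    for _ in range(n_null):
        rows.append(("other", "left", True, rng.uniform(0, array_extent_mm), rng.normal(20.0, 8.0)))
    table = pd.DataFrame(rows, columns=["region", "hemisphere", "dominant", "mediolateral_pos_mm", "anteroposterior_pos_mm"])
    table.insert(0, "id", [f"e{i:03d}" for i in range(len(table))])
    table["x"] = table["mediolateral_pos_mm"] - 40.0
    table["y"] = -table["anteroposterior_pos_mm"]
    table["z"] = rng.normal(8.0, 1.0, size=len(table))
    return table


def make_ground_truth(
    electrodes: pd.DataFrame,
    hg_lag_ms: float = 10.0,
    theta_reset_persist_cycles: float = 1.0,
    wave_velocity_m_per_s: float = 0.1,
    snr_db: float = 10.0,
    articulation_suppressed: bool = True,
) -> GroundTruth:
    """Default truth: region decides the archetype, PT transients are
    articulation-suppressed and restricted to dominant cortex."""
    region_map = {"HG/TTS": "sustained", "PT": "transient"}
    arch = [region_map.get(r, "null") for r in electrodes["region"]]
    frame = pd.DataFrame(
        {
            "id": electrodes["id"].to_numpy(),
            "archetype": arch,
            "hg_lag_ms": hg_lag_ms,
            "theta_reset_persist_cycles": theta_reset_persist_cycles,
            "wave_velocity_m_per_s": wave_velocity_m_per_s,
            "articulation_suppressed": articulation_suppressed,
            "snr_db": snr_db,
        }
    )
    transient = frame["archetype"] == "transient"
    if not electrodes.loc[transient.to_numpy(), "dominant"].all():
        raise ValueError("transient archetype requires dominant-hemisphere electrodes")
    return GroundTruth(frame)


# ---------------------------------------------------------------------------
# signal components


def one_over_f_noise(shape, sample_rate_hz: float, exponent: float = 1.5, rng=None) -> np.ndarray:
    """Unit-variance Gaussian noise with a 1/f^exponent power spectrum."""
    rng = as_rng(rng)
    shape = tuple(np.atleast_1d(shape))
    n = shape[-1]
    freqs = np.fft.rfftfreq(n, d=1.0 / sample_rate_hz)
    weights = np.zeros_like(freqs)
    weights[1:] = freqs[1:] ** (-exponent / 2.0)
    white = rng.standard_normal(shape)
    shaped = np.fft.irfft(np.fft.rfft(white, axis=-1) * weights, n=n, axis=-1)
    shaped /= shaped.std(axis=-1, keepdims=True)
    return shaped


def _bandpassed_carrier(shape, fs: float, low: float, high: float, rng) -> np.ndarray:
    sos = sp_signal.butter(4, (low, high), btype="bandpass", fs=fs, output="sos")
    x = sp_signal.sosfiltfilt(sos, as_rng(rng).standard_normal(tuple(np.atleast_1d(shape))), axis=-1)
    return x / x.std(axis=-1, keepdims=True)


def _theta_phase(
    n_trials: int,
    times: np.ndarray,
    fs: float,
    reset_times: np.ndarray,
    rng,
    freq_hz: float = 6.0,
    diffusion_rad2_per_s: float = 60.0,
    capture_tau_s: float = 0.02,
    capture_dur_s: float = 0.06,
    target_phase: float = 0.0,
) -> np.ndarray:
    """Noisy phase oscillator with event-triggered capture.

    Between events the phase advances at ``freq_hz`` with Brownian
    diffusion (coherence ~ exp(-D t / 2) after an alignment). During
    ``capture_dur_s`` after each event the phase relaxes exponentially
    toward ``target_phase`` with time constant ``capture_tau_s``.
    """
    dt = 1.0 / fs
    n_t = len(times)
    phase = np.empty((n_trials, n_t))
    phase[:, 0] = as_rng(rng).uniform(-np.pi, np.pi, n_trials)
    sigma = np.sqrt(diffusion_rad2_per_s * dt)
    noise = as_rng(rng).standard_normal((n_trials, n_t)) * sigma
    capture = np.zeros(n_t, dtype=bool)
    for t_r in reset_times:
        capture |= (times >= t_r) & (times < t_r + capture_dur_s)
    gain = dt / capture_tau_s
    for i in range(1, n_t):
        p = phase[:, i - 1] + 2 * np.pi * freq_hz * dt + noise[:, i]
        if capture[i]:
            err = np.angle(np.exp(1j * (target_phase - p)))
            p = p + gain * err
        phase[:, i] = p
    return phase


def _transient_lf_kernel(times: np.ndarray) -> np.ndarray:
    """Deterministic biphasic low-frequency deflection (~200 ms) at onset."""
    dur = 0.2
    mask = (times >= 0) & (times < dur)
    k = np.zeros_like(times)
    tt = times[mask]
    k[mask] = np.sin(2 * np.pi * 5.0 * tt) * np.hanning(mask.sum())
    return k


def _resample_envelope(stimulus: Stimulus, times: np.ndarray, lag_s: float) -> np.ndarray:
    """Stimulus envelope on the neural clock, delayed by ``lag_s``; zero
    before onset and after stimulus end."""
    src_t = stimulus.times
    return np.interp(times - lag_s, src_t, stimulus.envelope, left=0.0, right=0.0)


def simulate_neural_response(
    stimulus: Stimulus,
    electrodes: pd.DataFrame,
    truth: GroundTruth,
    n_trials: int = 24,
    sample_rate_hz: float = 400.0,
    pre_s: float = 0.8,
    post_s: float = 1.2,
    seed=0,
    hg_gain: float = 0.7,
    theta_gain: float = 1.1,
    beta_gain: float = 0.25,
    onset_burst_gain: float = 1.2,
    sustained_onset_gain: float = 1.0,
    anticipation_lead_s: float = 0.16,
    theta_freq_hz: float = 6.0,
    theta_diffusion_rad2_per_s: float = 80.0,
) -> Recording:
    """Continuous multichannel recording of repeated stimulus presentations.

    Trials are laid out back to back (``pre_s`` + stimulus + ``post_s``
    per trial) with one ``stimulus_onset`` event each; gains are in units
    of the in-band background noise at the 10 dB reference SNR.
    """
    if len(electrodes) != len(truth.electrodes):
        raise ValueError("electrode table and ground truth differ in length")
    rng = as_rng(seed)
    fs = sample_rate_hz
    spec = stimulus.spec
    stim_dur = spec.rhythmic_dur_s + spec.constant_dur_s
    block_s = pre_s + stim_dur + post_s
    n_block = int(round(block_s * fs))
    times_rel = np.arange(n_block) / fs - pre_s  # 0 at stimulus onset

    mod_period = 1.0 / spec.mod_freq_hz
    edge_times = stimulus.edge_times
    trough_times = (np.arange(spec.n_pulses) + 0.5) * mod_period

    data = np.empty((len(electrodes), n_trials * n_block))
    for e, (_, elec) in enumerate(electrodes.iterrows()):
        info = truth.for_channel(elec["id"])
        scale = 10.0 ** ((info["snr_db"] - 10.0) / 20.0)
        trial = one_over_f_noise((n_trials, n_block), fs, rng=rng)
        if info["archetype"] in ("sustained", "mixed"):
            wave_lag = elec["mediolateral_pos_mm"] / (info["wave_velocity_m_per_s"] * 1000.0) / 1000.0
            lag = info["hg_lag_ms"] / 1000.0 + wave_lag
            env = _resample_envelope(stimulus, times_rel, lag)
            carrier = _bandpassed_carrier((n_trials, n_block), fs, 65.0, 115.0, rng)
            # low-latency broadband onset response (peaks ~60 ms, decays
            # within half a modulation cycle) on top of envelope tracking
            tt = times_rel
            onset_env = np.where(
                tt >= 0, (tt / 0.06) * np.exp(1.0 - tt / 0.06), 0.0
            )
            trial += scale * hg_gain * (0.15 + env + sustained_onset_gain * onset_env) * carrier
            resets = list(edge_times)
            n_extra = int(round(info["theta_reset_persist_cycles"]))
            for k in range(1, n_extra + 1):
                resets.append(edge_times[-1] + k * mod_period - anticipation_lead_s)
            theta = _theta_phase(
                n_trials,
                times_rel,
                fs,
                np.asarray(resets),
                rng,
                freq_hz=theta_freq_hz,
                diffusion_rad2_per_s=theta_diffusion_rad2_per_s,
            )
            # low-frequency power rides the rising slope: the oscillation
            # amplitude swells transiently at each reset event
            theta_amp = np.ones(n_block)
            for t_r in resets:
                theta_amp += 0.6 * np.exp(-((times_rel - t_r - 0.04) ** 2) / (2 * 0.05**2))
            trial += scale * theta_gain * theta_amp * np.cos(theta)
            for t_b in trough_times:
                burst_mask = np.abs(times_rel - t_b) < 0.09
                tt = times_rel[burst_mask] - t_b
                trial[:, burst_mask] += (
                    scale * beta_gain * np.exp(-(tt**2) / (2 * 0.03**2)) * np.cos(2 * np.pi * 22.0 * tt)
                )
        if info["archetype"] in ("transient", "mixed"):
            burst_mask = (times_rel >= 0) & (times_rel < mod_period)
            burst_env = np.zeros(n_block)
            burst_env[burst_mask] = np.hanning(burst_mask.sum())
            carrier = _bandpassed_carrier((n_trials, n_block), fs, 65.0, 115.0, rng)
            trial += scale * onset_burst_gain * burst_env * carrier
            trial += scale * onset_burst_gain * _transient_lf_kernel(times_rel)
        data[e] = trial.reshape(-1)

    onsets = pre_s + np.arange(n_trials) * block_s
    events = pd.DataFrame(
        {
            "onset_s": onsets,
            "duration_s": stim_dur,
            "type": "stimulus_onset",
            "trial_id": np.arange(n_trials),
        }
    )[EVENT_COLUMNS]
    return Recording(data, fs, list(electrodes["id"]), events, electrodes)


def simulate_articulation_response(
    electrodes: pd.DataFrame,
    truth: GroundTruth,
    n_trials: int = 24,
    sample_rate_hz: float = 400.0,
    pre_s: float = 0.8,
    post_s: float = 0.6,
    speech_dur_s: float = 1.5,
    seed=0,
    hg_gain: float = 0.3,
    onset_burst_gain: float = 1.2,
) -> Recording:
    """Articulation-aligned epochs as an independent recording.

    Sustained electrodes keep (reduced) envelope tracking of the
    self-produced speech envelope; transient electrodes respond at
    articulation onset only when not articulation-suppressed. No acoustic
    self-feedback is modeled.
    """
    rng = as_rng(seed)
    fs = sample_rate_hz
    block_s = pre_s + speech_dur_s + post_s
    n_block = int(round(block_s * fs))
    times_rel = np.arange(n_block) / fs - pre_s
    sentences = make_speech_like_envelope(
        n_sentences=n_trials, dur_s_mean=speech_dur_s, dur_s_sd=0.0, sample_rate_hz=fs, seed=rng
    )

    data = np.empty((len(electrodes), n_trials * n_block))
    for e, (_, elec) in enumerate(electrodes.iterrows()):
        info = truth.for_channel(elec["id"])
        scale = 10.0 ** ((info["snr_db"] - 10.0) / 20.0)
        trial = one_over_f_noise((n_trials, n_block), fs, rng=rng)
        if info["archetype"] in ("sustained", "mixed"):
            carrier = _bandpassed_carrier((n_trials, n_block), fs, 65.0, 115.0, rng)
            for k, sent in enumerate(sentences):
                env = np.interp(
                    times_rel - info["hg_lag_ms"] / 1000.0, sent.times, sent.envelope, left=0.0, right=0.0
                )
                trial[k] += scale * hg_gain * (0.15 + env) * carrier[k]
        if info["archetype"] in ("transient", "mixed") and not info["articulation_suppressed"]:
            burst_mask = (times_rel >= 0) & (times_rel < 0.35)
            burst_env = np.zeros(n_block)
            burst_env[burst_mask] = np.hanning(burst_mask.sum())
            carrier = _bandpassed_carrier((n_trials, n_block), fs, 65.0, 115.0, rng)
            trial += scale * onset_burst_gain * burst_env * carrier
        data[e] = trial.reshape(-1)

    onsets = pre_s + np.arange(n_trials) * block_s
    events = pd.DataFrame(
        {
            "onset_s": onsets,
            "duration_s": speech_dur_s,
            "type": "articulation_onset",
            "trial_id": np.arange(n_trials),
        }
    )[EVENT_COLUMNS]
    return Recording(data, fs, list(electrodes["id"]), events, electrodes)


# ---------------------------------------------------------------------------
# feature-level cohort (for response classification at the scale of the
# full supratemporal sample)


def make_response_feature_cohort(
    n_electrodes: int = 349,
    frac_sustained: float = 0.35,
    frac_transient: float = 0.45,
    snr: float = 5.0,
    mod_freq_hz: float = 3.0,
    rhythmic_dur_s: float = 3.0,
    feature_rate_hz: float = 50.0,
    epoch_dur_s: float = 4.0,
    weight_scale: float = 60.0,
    hg_lag_s: float = 0.045,
    articulation_gain: float = 0.6,
    articulation_pedestal_mix: float = 0.15,
    articulation_snr: float = 2.5,
    seed=0,
):
    """Rectified trial-mean response features for a large planted cohort.

    Returns ``(A_listen, A_articulation, truth_frame, times)`` where the
    rows of A are non-negative per-electrode feature traces (units of
    percent-change-like magnitude): sustained rows follow an envelope-locked
    comb over the rhythmic period, transient rows a single onset bump.
    Row noise is Gaussian with RMS = signal RMS / ``snr``, then half-wave
    rectified. In the articulation matrix the sustained component is
    preserved at ``articulation_gain`` while the transient component is
    absent (suppression), so archetype transfer can be exercised at the
    cohort scale. Anteroposterior positions are drawn class-dependently
    (sustained anterior, transient posterior).
    """
    rng = as_rng(seed)
    times = np.arange(int(round(epoch_dur_s * feature_rate_hz))) / feature_rate_hz
    comb = 0.5 + 0.5 * np.cos(2 * np.pi * mod_freq_hz * (times - hg_lag_s))
    comb[times > rhythmic_dur_s] *= np.exp(-(times[times > rhythmic_dur_s] - rhythmic_dur_s) / 0.15)
    onset = np.zeros_like(times)
    bump = (times >= 0) & (times < 0.35)
    onset[bump] = np.hanning(bump.sum())

    n_sus = int(round(frac_sustained * n_electrodes))
    n_tra = int(round(frac_transient * n_electrodes))
    labels = np.array(
        ["sustained"] * n_sus + ["transient"] * n_tra + ["null"] * (n_electrodes - n_sus - n_tra)
    )
    rng.shuffle(labels)
    weights = np.where(
        labels == "null", 2.0, rng.lognormal(np.log(weight_scale), 0.4, n_electrodes)
    )
    positions = np.where(
        labels == "sustained",
        rng.normal(10.0, 4.0, n_electrodes),
        np.where(
            labels == "transient",
            rng.normal(28.0, 4.0, n_electrodes),
            rng.normal(19.0, 8.0, n_electrodes),
        ),
    )

    archetype = {"sustained": comb, "transient": onset, "null": comb * 0.5 + onset * 0.5}
    a_listen = np.empty((n_electrodes, len(times)))
    a_artic = np.empty_like(a_listen)
    for i, (lab, w) in enumerate(zip(labels, weights)):
        sig = w * archetype[lab]
        sigma = np.sqrt(np.mean(sig**2)) / snr if np.any(sig) else 1.0
        a_listen[i] = np.clip(sig + rng.normal(0, sigma, len(times)), 0.0, None)
        floor = weight_scale * articulation_gain / articulation_snr
        if lab == "sustained":
            # preserved response, scaled down; the noise keeps a partly
            # response-scaled component (rectification pedestals then match
            # the listening features) mixed with a shared floor
            art = w * articulation_gain * comb
            mix = articulation_pedestal_mix
            art_sigma = mix * sigma * articulation_gain + (1 - mix) * floor
        else:
            # suppression: no stimulus-locked component, class-independent
            # noise floor so nothing weight-correlated survives
            art = np.zeros(len(times))
            art_sigma = floor
        a_artic[i] = np.clip(art + rng.normal(0, art_sigma, len(times)), 0.0, None)

    truth_frame = pd.DataFrame(
        {
            "id": [f"c{i:03d}" for i in range(n_electrodes)],
            "archetype": labels,
            "weight": weights,
            "anteroposterior_pos_mm": positions,
        }
    )
    return a_listen, a_artic, truth_frame, times


def simulate_wave_peak_times(
    mediolateral_pos_mm: np.ndarray,
    velocity_m_per_s: float = 0.1,
    n_pulses: int = 8,
    jitter_ms: float = 10.0,
    rng=None,
) -> np.ndarray:
    """High-gamma peak times (ms, n_pulses x n_electrodes) for a planted
    medial-to-lateral traveling wave with Gaussian timing jitter."""
    rng = as_rng(rng)
    pos = np.asarray(mediolateral_pos_mm, dtype=float)
    base = pos / (velocity_m_per_s * 1000.0) * 1000.0  # mm / (mm/ms) -> ms
    return base[None, :] + rng.normal(0.0, jitter_ms, size=(n_pulses, len(pos)))


def simulate_reset_phase_series(
    n_electrodes: int,
    duration_s: float,
    sample_rate_hz: float,
    reset_times_s: np.ndarray,
    rng=None,
    freq_hz: float = 6.0,
    diffusion_rad2_per_s: float = 80.0,
) -> np.ndarray:
    """Continuous low-frequency phase (electrodes x time) with captures at
    the given event times — a fixture for event-locked ITC analyses."""
    times = np.arange(int(round(duration_s * sample_rate_hz))) / sample_rate_hz
    return _theta_phase(
        n_electrodes,
        times,
        sample_rate_hz,
        np.asarray(reset_times_s),
        rng,
        freq_hz=freq_hz,
        diffusion_rad2_per_s=diffusion_rad2_per_s,
    )


def simulate_edge_locked_phases(
    n_electrodes: int,
    n_events: int,
    sample_rate_hz: float,
    window_s: tuple[float, float],
    locked: bool = True,
    reset_itc_target: float = 0.85,
    freq_hz: float = 6.0,
    rng=None,
) -> np.ndarray:
    """Event-locked phase epochs (electrodes x events x time) with an
    instantaneous phase reset at t=0 followed by diffusion; convenience for
    calibration and post-edge ITC fixtures."""
    rng = as_rng(rng)
    n_t = int(round((window_s[1] - window_s[0]) * sample_rate_hz))
    times = window_s[0] + np.arange(n_t) / sample_rate_hz
    dt = 1.0 / sample_rate_hz
    diffusion = 30.0
    phase = np.empty((n_electrodes, n_events, n_t))
    start = rng.uniform(-np.pi, np.pi, (n_electrodes, n_events))
    steps = 2 * np.pi * freq_hz * dt + rng.standard_normal((n_electrodes, n_events, n_t)) * np.sqrt(
        diffusion * dt
    )
    phase[:] = start[..., None] + np.cumsum(steps, axis=-1)
    if locked:
        i0 = int(np.searchsorted(times, 0.0))
        jitter = rng.normal(0, np.sqrt(-2 * np.log(reset_itc_target)), (n_electrodes, n_events))
        # re-anchor the phase at t=0 to a tight distribution; diffusion after
        # the reset is preserved because only a per-event offset is added
        phase[..., i0:] += (jitter - phase[..., i0])[..., None]
    return np.angle(np.exp(1j * phase))


# ---------------------------------------------------------------------------
# behavior


def simulate_detection_behavior(
    n_subjects: int = 37,
    n_trials: int = 100,
    psychometric_slope: float = 0.35,
    psychometric_intercept: float = 0.9,
    position2_bonus: float = 0.9,
    false_alarm_rate: float = 0.1,
    level_dbs: tuple[float, float, float] = (-6.0, 0.0, 6.0),
    seed=0,
) -> pd.DataFrame:
    """Tone-in-noise detection tables with a planted position-2 bonus.

    Half the trials carry a tone, balanced as evenly as possible over the
    5 positions x 3 levels grid. Hits follow a logistic psychometric in
    tone level (dB); the bonus adds to the logit only at the lowest level
    and second temporal position — the planted analogue of improved
    detection at the first missing pulse's rising edge. Tone-absent
    responses are false alarms at a fixed rate.
    """
    rng = as_rng(seed)
    cells = [(p, l) for p in range(1, 6) for l in range(1, 4)]
    rows = []
    for s in range(n_subjects):
        n_present = n_trials // 2
        grid = (cells * (n_present // len(cells) + 1))[:n_present]
        rng.shuffle(grid)
        present = [True] * n_present + [False] * (n_trials - n_present)
        rng.shuffle(present)
        it = iter(grid)
        for trial_id, has_tone in enumerate(present):
            if has_tone:
                pos, level = next(it)
                logit = psychometric_intercept + psychometric_slope * level_dbs[level - 1]
                if pos == 2 and level == 1:
                    logit += position2_bonus
                response = rng.random() < 1.0 / (1.0 + np.exp(-logit))
            else:
                pos, level = 0, 0
                response = rng.random() < false_alarm_rate
            rows.append(
                {
                    "subject_id": f"s{s:02d}",
                    "trial_id": trial_id,
                    "tone_present": has_tone,
                    "position_index": pos,
                    "level_index": level,
                    "response": bool(response),
                }
            )
    return pd.DataFrame(rows)
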