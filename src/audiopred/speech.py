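"""Acoustic envelope and edge extraction, and their neural encoding.

The envelope is the modulus of the broadband analytic signal, low-pass
filtered (default 10 Hz) and resampled to the neural clock. Acoustic edges
— moments of rapid amplitude gain — are local maxima of the envelope
derivative above a slope quantile, with a minimum separation. Neural
encoding is quantified three ways: a lagged Spearman correlation between
band amplitude and the envelope (frequency-specific delays), low-frequency
ITC in the window following edges (contrasted against syllable onsets),
and discrete-event contrasts (pre/post edge, envelope peak/valley).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import signal as sp_signal
from scipy import stats

from ._util import as_rng
from .phase_stats import itc

__all__ = [
    "EnvelopeTrace",
    "EdgeAnnotation",
    "extract_envelope",
    "detect_edges",
    "lagged_spearman",
    "epoch_at_events",
    "post_edge_itc",
    "envelope_peaks_valleys",
    "discrete_event_contrasts",
    "detect_articulation_onset",
]


@dataclass
class EnvelopeTrace:
    times: np.ndarray
    amplitude: np.ndarray
    sample_rate_hz: float
    cutoff_hz: float

    def __post_init__(self) -> None:
        self.amplitude = np.asarray(self.amplitude, dtype=float)


@dataclass
class EdgeAnnotation:
    edge_times: np.ndarray
    slopes: np.ndarray
    syllable_onset_times: np.ndarray | None = None


def extract_envelope(
    waveform: np.ndarray,
    sample_rate_hz: float,
    cutoff_hz: float = 10.0,
    target_rate_hz: float | None = None,
) -> EnvelopeTrace:
    """|analytic signal|, low-passed at ``cutoff_hz``, optionally resampled."""
    waveform = np.asarray(waveform, dtype=float)
    if waveform.ndim != 1 or not np.isfinite(waveform).all():
        raise ValueError("waveform must be a finite 1-D array")
    env = np.abs(sp_signal.hilbert(waveform))
    sos = sp_signal.butter(4, cutoff_hz, btype="lowpass", fs=sample_rate_hz, output="sos")
    env = sp_signal.sosfiltfilt(sos, env)
    fs = sample_rate_hz
    if target_rate_hz is not None and target_rate_hz != sample_rate_hz:
        from fractions import Fraction

        frac = Fraction(float(target_rate_hz) / sample_rate_hz).limit_denominator(1000)
        env = sp_signal.resample_poly(env, frac.numerator, frac.denominator)
        fs = target_rate_hz
    env = np.clip(env, 0.0, None)
    return EnvelopeTrace(np.arange(len(env)) / fs, env, fs, cutoff_hz)


def detect_edges(
    envelope: EnvelopeTrace,
    slope_quantile: float = 0.9,
    min_separation_ms: float = 120.0,
    smooth_cutoff_hz: float | None = 10.0,
) -> EdgeAnnotation:
    """Acoustic edges: local derivative maxima above a slope quantile.

    Candidates are local maxima of d(envelope)/dt; those above the
    ``slope_quantile`` of the derivative are kept, greedily enforcing
    ``min_separation_ms`` in favor of the larger slope. Invariant under
    global amplitude scaling. A light low-pass (``smooth_cutoff_hz``)
    stabilizes the derivative on noisy envelopes; pass ``None`` to skip.
    """
    fs = envelope.sample_rate_hz
    if fs < 100:
        raise ValueError("envelope must be sampled at >= 100 Hz")
    env = envelope.amplitude
    if smooth_cutoff_hz is not None and smooth_cutoff_hz < fs / 2:
        sos = sp_signal.butter(4, smooth_cutoff_hz, btype="lowpass", fs=fs, output="sos")
        env = sp_signal.sosfiltfilt(sos, env)
    deriv = np.gradient(env) * fs
    peaks, _ = sp_signal.find_peaks(deriv)
    if len(peaks) == 0:
        return EdgeAnnotation(np.empty(0), np.empty(0))
    threshold = np.quantile(deriv, slope_quantile)
    peaks = peaks[deriv[peaks] >= max(threshold, 0.0)]
    order = peaks[np.argsort(deriv[peaks])[::-1]]
    min_sep = int(round(min_separation_ms / 1000.0 * fs))
    accepted: list[int] = []
    for p in order:
        if all(abs(p - a) >= min_sep for a in accepted):
            accepted.append(int(p))
    accepted = np.sort(np.asarray(accepted, dtype=int))
    return EdgeAnnotation(accepted / fs, deriv[accepted])


def lagged_spearman(
    neural: np.ndarray,
    envelope: np.ndarray,
    sample_rate_hz: float,
    max_lag_ms: float = 500.0,
    step_ms: float = 5.0,
    valid_mask: np.ndarray | None = None,
) -> tuple[pd.DataFrame, float, float]:
    """Spearman correlation of a neural series with the acoustic envelope
    as a function of neural lag (positive = neural after audio).

    Series are assumed time-aligned and may be concatenations across
    trials; ``valid_mask`` masks out trial boundaries. Returns the
    (lag_ms, rho) curve plus the peak lag and rho (largest ``|rho|``).
    """
    neural = np.asarray(neural, dtype=float)
    envelope = np.asarray(envelope, dtype=float)
    if neural.shape != envelope.shape:
        raise ValueError("series must share a time axis")
    n = len(neural)
    max_lag = int(round(max_lag_ms / 1000.0 * sample_rate_hz))
    if n <= 2 * max_lag + 10:
        raise ValueError("series shorter than the lag range")
    step = max(1, int(round(step_ms / 1000.0 * sample_rate_hz)))
    if valid_mask is None:
        valid_mask = np.ones(n, dtype=bool)
    lags = np.arange(-max_lag, max_lag + 1, step)
    rhos = np.empty(len(lags))
    for i, lag in enumerate(lags):
        if lag >= 0:
            x, y = neural[lag:], envelope[: n - lag]
            m = valid_mask[lag:] & valid_mask[: n - lag]
        else:
            x, y = neural[:lag], envelope[-lag:]
            m = valid_mask[:lag] & valid_mask[-lag:]
        rhos[i] = stats.spearmanr(x[m], y[m]).statistic
    curve = pd.DataFrame({"lag_ms": lags / sample_rate_hz * 1000.0, "rho": rhos})
    best = int(np.argmax(np.abs(rhos)))
    return curve, float(curve["lag_ms"][best]), float(rhos[best])


def trial_boundary_mask(trial_lengths, sample_rate_hz: float, margin_ms: float = 250.0) -> np.ndarray:
    """Mask that blanks a margin around boundaries of concatenated trials."""
    margin = int(round(margin_ms / 1000.0 * sample_rate_hz))
    mask = np.ones(int(np.sum(trial_lengths)), dtype=bool)
    edges = np.cumsum(trial_lengths)[:-1]
    for e in edges:
        mask[max(0, e - margin) : e + margin] = False
    return mask


def epoch_at_events(
    series: np.ndarray,
    sample_rate_hz: float,
    event_times_s: np.ndarray,
    window_s: tuple[float, float],
) -> np.ndarray:
    """Re-epoch a (..., time) array at event times -> (..., events, window).

    Events whose window falls outside the series are dropped.
    """
    w0, w1 = window_s
    n_t = int(round((w1 - w0) * sample_rate_hz))
    if n_t <= 0:
        raise ValueError("empty event window")
    n = series.shape[-1]
    out = []
    for t0 in np.asarray(event_times_s, dtype=float):
        start = int(round((t0 + w0) * sample_rate_hz))
        if start < 0 or start + n_t > n:
            continue
        out.append(series[..., start : start + n_t])
    if not out:
        raise ValueError("no events fall inside the series")
    return np.stack(out, axis=-2)


def post_edge_itc(
    phase: np.ndarray,
    sample_rate_hz: float,
    edge_times_s: np.ndarray,
    syllable_times_s: np.ndarray | None = None,
    window_ms: float = 125.0,
    min_events: int = 20,
) -> pd.DataFrame:
    """Mean low-frequency ITC in the window after acoustic edges.

    ``phase`` is electrodes x time (a continuous low-frequency phase
    series). Phase is re-epoched at the events; ITC across events is
    averaged over [0, window]. When syllable onsets are supplied the same
    measure is computed for them, giving the edge-vs-syllable contrast.
    """
    if window_ms <= 0:
        raise ValueError("window must be positive")
    if len(edge_times_s) < min_events:
        raise ValueError(f"need at least {min_events} events")

    def mean_itc(events: np.ndarray) -> np.ndarray:
        ep = epoch_at_events(phase, sample_rate_hz, events, (0.0, window_ms / 1000.0))
        return itc(ep, trial_axis=-2).mean(axis=-1)

    out = pd.DataFrame({"electrode": np.arange(phase.shape[0]), "edge_itc": mean_itc(edge_times_s)})
    if syllable_times_s is not None:
        out["syllable_itc"] = mean_itc(np.asarray(syllable_times_s))
        out["contrast"] = out["edge_itc"] - out["syllable_itc"]
    return out


def edge_vs_syllable_test(table: pd.DataFrame) -> float:
    """Paired Wilcoxon across electrodes: edges better encoded than
    syllable onsets (one-sided)."""
    return float(
        stats.wilcoxon(table["edge_itc"], table["syllable_itc"], alternative="greater").pvalue
    )


def envelope_peaks_valleys(
    envelope: EnvelopeTrace, min_separation_ms: float = 120.0, prominence_frac: float = 0.1
) -> tuple[np.ndarray, np.ndarray]:
    """Times of envelope local maxima and minima (matched prominence)."""
    fs = envelope.sample_rate_hz
    dist = int(round(min_separation_ms / 1000.0 * fs))
    prom = prominence_frac * (envelope.amplitude.max() - envelope.amplitude.min())
    peaks, _ = sp_signal.find_peaks(envelope.amplitude, distance=dist, prominence=prom)
    valleys, _ = sp_signal.find_peaks(-envelope.amplitude, distance=dist, prominence=prom)
    return peaks / fs, valleys / fs


def discrete_event_contrasts(
    band_amplitude: dict[str, np.ndarray],
    band_phase: dict[str, np.ndarray],
    sample_rate_hz: float,
    edge_times_s: np.ndarray,
    peak_times_s: np.ndarray,
    valley_times_s: np.ndarray,
    window_ms: float = 50.0,
) -> pd.DataFrame:
    """Per-band power and phase-organization contrasts at discrete events.

    Two contrasts per band and measure: post-minus-pre edge (windows of
    ``window_ms`` on each side of the edge) and envelope peak-minus-valley
    (windows centred on the events). Power uses mean squared amplitude;
    phase organization uses ITC across events. One row per electrode, band,
    contrast and measure.
    """
    if min(len(peak_times_s), len(valley_times_s)) < 5:
        raise ValueError("need at least 5 envelope peaks and valleys")
    w = window_ms / 1000.0
    rows = []
    for band in band_amplitude:
        amp, ph = band_amplitude[band], band_phase[band]

        def power_at(events, window):
            ep = epoch_at_events(amp**2, sample_rate_hz, events, window)
            return ep.mean(axis=(-2, -1))

        def itc_at(events, window):
            ep = epoch_at_events(ph, sample_rate_hz, events, window)
            return itc(ep, trial_axis=-2).mean(axis=-1)

        contrasts = {
            ("edge_post_pre", "power"): power_at(edge_times_s, (0, w)) - power_at(edge_times_s, (-w, 0)),
            ("edge_post_pre", "itc"): itc_at(edge_times_s, (0, w)) - itc_at(edge_times_s, (-w, 0)),
            ("peak_valley", "power"): power_at(peak_times_s, (-w / 2, w / 2))
            - power_at(valley_times_s, (-w / 2, w / 2)),
            ("peak_valley", "itc"): itc_at(peak_times_s, (-w / 2, w / 2))
            - itc_at(valley_times_s, (-w / 2, w / 2)),
        }
        for (contrast, measure), values in contrasts.items():
            for e, v in enumerate(np.atleast_1d(values)):
                rows.append(
                    {
                        "electrode": e,
                        "band": band,
                        "contrast": contrast,
                        "measure": measure,
                        "value": float(v),
                    }
                )
    return pd.DataFrame(rows)


def contrast_group_test(table: pd.DataFrame, alternative: str = "greater") -> pd.DataFrame:
    """Group Wilcoxon per (band, contrast, measure) across electrodes."""
    rows = []
    for (band, contrast, measure), sub in table.groupby(["band", "contrast", "measure"]):
        values = sub["value"].to_numpy()
        p = 1.0 if np.allclose(values, 0) else float(
            stats.wilcoxon(values, alternative=alternative).pvalue
        )
        rows.append(
            {
                "band": band,
                "contrast": contrast,
                "measure": measure,
                "median": float(np.median(values)),
                "p": p,
            }
        )
    return pd.DataFrame(rows)


def detect_articulation_onset(
    audio: np.ndarray,
    sample_rate_hz: float,
    threshold_factor: float = 3.0,
    baseline_s: float = 0.25,
    min_dur_ms: float = 50.0,
) -> list[tuple[float, float]]:
    """Articulation intervals from a microphone channel.

    Onset = first time the smoothed envelope exceeds ``threshold_factor``
    times the baseline RMS for at least ``min_dur_ms``, refined to the
    half-maximum crossing of the local plateau (the zero-phase smoothing
    spreads energy symmetrically, so the half-maximum point recovers the
    true edge). Offsets are symmetric. Returns possibly-empty, ordered
    (onset, offset) pairs.
    """
    env = extract_envelope(audio, sample_rate_hz, cutoff_hz=20.0).amplitude
    n_base = max(1, int(round(baseline_s * sample_rate_hz)))
    baseline = np.sqrt(np.mean(audio[:n_base] ** 2))
    above = env > threshold_factor * baseline
    min_run = max(1, int(round(min_dur_ms / 1000.0 * sample_rate_hz)))
    intervals = []
    i = 0
    n = len(above)
    while i < n:
        if above[i]:
            j = i
            while j < n and above[j]:
                j += 1
            if j - i >= min_run:
                half = 0.5 * np.median(env[i:j])
                k0 = i
                while k0 < j and env[k0] < half:
                    k0 += 1
                k1 = j
                while k1 > k0 and env[k1 - 1] < half:
                    k1 -= 1
                intervals.append((k0 / sample_rate_hz, k1 / sample_rate_hz))
            i = j
        else:
            i += 1
    return intervals
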