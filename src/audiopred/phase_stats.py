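"""Phase-alignment statistics and prediction-interval analysis.

Inter-trial coherence (ITC) is the modulus of the complex mean of unit
phasors across trials,

    L(t) = | (1/N) sum_n exp(i * theta_n(t)) |,

1 when every trial carries the same phase, with expectation
sqrt(pi)/(2 sqrt(N)) for fully random phases. Significance at the single
electrode level uses a temporally jittered bootstrap: every replicate
circularly shifts each trial's phase series by an independent uniform
offset and recomputes the statistic, destroying event locking while
preserving each trial's marginal phase dynamics.

The prediction-interval analysis divides an amplitude-modulated-noise epoch
into baseline / onset (first pulse) / sustained (remaining pulses) / early
prediction (first post-stimulus cycle) / late prediction (second cycle),
and quantifies per interval the engagement of low-frequency phase (mean
filter-bank ITC) and of high-gamma power (signed r^2 of the Spearman
correlation between the trial-mean power and a sinusoid at the modulation
frequency, cosine-aligned with the extrapolated stimulus envelope).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from ._util import as_rng, window_slice
from .containers import EpochSet
from .spectral import HIGH_GAMMA_BAND, band_decompose, filter_bank_specs, percent_change_power

__all__ = [
    "itc",
    "itc_change",
    "jitter_bootstrap_null",
    "PhaseAmplitudeProfile",
    "phase_resolved_amplitude",
    "default_intervals",
    "bank_itc",
    "signed_r2",
    "interval_engagement",
    "interval_group_test",
    "quarter_period_delay",
    "phase_space_trajectory",
    "predictive_electrode_screen",
]


def itc(phase: np.ndarray, trial_axis: int = -2) -> np.ndarray:
    """Inter-trial coherence: modulus of the mean unit phasor across trials."""
    phase = np.asarray(phase)
    if not np.isfinite(phase).all():
        raise ValueError("phase contains non-finite values")
    if phase.shape[trial_axis] < 2:
        raise ValueError("ITC requires at least 2 trials")
    return np.abs(np.mean(np.exp(1j * phase), axis=trial_axis))


def itc_change(itc_series: np.ndarray, times: np.ndarray, baseline_window) -> np.ndarray:
    """ITC minus its mean over the baseline window (per leading axis)."""
    mask = window_slice(np.asarray(times), tuple(baseline_window))
    if not mask.any():
        raise ValueError("baseline window outside epoch")
    base = np.asarray(itc_series)[..., mask].mean(axis=-1, keepdims=True)
    return itc_series - base


def _circular_shift_rows(x: np.ndarray, shifts: np.ndarray) -> np.ndarray:
    n_t = x.shape[-1]
    idx = (np.arange(n_t)[None, :] + shifts[:, None]) % n_t
    return np.take_along_axis(x, idx, axis=-1)


def jitter_bootstrap_null(
    phase: np.ndarray,
    statistic,
    n_boot: int = 1000,
    rng=None,
) -> tuple[float, np.ndarray, float]:
    """One-sided bootstrap p-value under a temporally jittered null.

    ``phase`` is trials x time; ``statistic`` maps such an array to a
    scalar. Returns ``(observed, null_distribution, p)`` with
    ``p = (1 + #{null >= observed}) / (n_boot + 1)``.
    """
    rng = as_rng(rng)
    if n_boot < 100:
        warnings.warn("n_boot < 100 gives a coarse p-value lattice", stacklevel=2)
    phase = np.asarray(phase)
    n_trials, n_t = phase.shape
    observed = float(statistic(phase))
    null = np.empty(n_boot)
    for b in range(n_boot):
        shifts = rng.integers(0, n_t, size=n_trials)
        null[b] = statistic(_circular_shift_rows(phase, shifts))
    p = (1.0 + np.sum(null >= observed)) / (n_boot + 1.0)
    return observed, null, float(p)


@dataclass
class PhaseAmplitudeProfile:
    """Band amplitude binned by stimulus phase, with KL-from-uniform test."""

    bin_centers: np.ndarray
    profile: np.ndarray  # normalized to sum 1
    kl_divergence: float
    p_value: float
    null_kl: np.ndarray


def _kl_from_uniform(profile: np.ndarray) -> float:
    b = len(profile)
    p = profile / profile.sum()
    nz = p > 0
    return float(np.sum(p[nz] * np.log(p[nz] * b)))


def phase_resolved_amplitude(
    amplitude: np.ndarray,
    stimulus_phase: np.ndarray,
    n_bins: int = 18,
    n_boot: int = 1000,
    rng=None,
) -> PhaseAmplitudeProfile:
    """Mean amplitude by stimulus-phase bin, KL divergence from uniform.

    ``amplitude`` is trials x time (restricted to the sustained window by
    the caller); ``stimulus_phase`` is the stimulus modulator phase per time
    point. Significance comes from temporally jittering the amplitude rows
    against the fixed stimulus phase.
    """
    rng = as_rng(rng)
    amplitude = np.atleast_2d(np.asarray(amplitude, dtype=float))
    stimulus_phase = np.asarray(stimulus_phase)
    if amplitude.shape[-1] != stimulus_phase.shape[-1]:
        raise ValueError("amplitude and stimulus phase must share the time axis")

    def binned_profile(amp: np.ndarray, bins: int) -> np.ndarray:
        edges = np.linspace(-np.pi, np.pi, bins + 1)
        which = np.clip(np.digitize(stimulus_phase, edges) - 1, 0, bins - 1)
        sums = np.zeros(bins)
        counts = np.zeros(bins)
        np.add.at(sums, which, amp.mean(axis=0))
        np.add.at(counts, which, 1.0)
        if np.any(counts == 0):
            return None
        return sums / counts

    profile = binned_profile(amplitude, n_bins)
    while profile is None and n_bins > 4:
        n_bins -= 2
        warnings.warn(f"empty phase bin; reducing to {n_bins} bins", stacklevel=2)
        profile = binned_profile(amplitude, n_bins)
    if profile is None:
        raise ValueError("cannot bin stimulus phase")

    observed = _kl_from_uniform(profile)
    n_t = amplitude.shape[-1]
    null = np.empty(n_boot)
    for b in range(n_boot):
        shifts = rng.integers(0, n_t, size=amplitude.shape[0])
        null[b] = _kl_from_uniform(binned_profile(_circular_shift_rows(amplitude, shifts), n_bins))
    p = (1.0 + np.sum(null >= observed)) / (n_boot + 1.0)
    edges = np.linspace(-np.pi, np.pi, n_bins + 1)
    centers = (edges[:-1] + edges[1:]) / 2.0
    return PhaseAmplitudeProfile(centers, profile / profile.sum(), observed, float(p), null)


# ---------------------------------------------------------------------------
# prediction intervals


def default_intervals(
    mod_freq_hz: float,
    rhythmic_dur_s: float = 3.0,
    baseline: tuple[float, float] = (-0.300, -0.050),
) -> dict[str, tuple[float, float]]:
    """Named analysis windows for the rhythmic-noise epoch.

    onset = first modulation cycle, sustained = the remaining pulses,
    early/late prediction = the first and second cycle after the rhythm
    stops (where the stimulus amplitude is constant).
    """
    c = 1.0 / mod_freq_hz
    return {
        "baseline": baseline,
        "onset": (0.0, c),
        "sustained": (c, rhythmic_dur_s),
        "early_prediction": (rhythmic_dur_s, rhythmic_dur_s + c),
        "late_prediction": (rhythmic_dur_s + c, rhythmic_dur_s + 2 * c),
    }


def bank_itc(
    epochs: EpochSet,
    center_range_hz: tuple[float, float] = (2.0, 15.0),
    specs=None,
) -> np.ndarray:
    """Mean ITC across filter-bank bands with centres inside a range.

    Returns electrodes x time. Bands are processed one at a time and the
    resulting ITC averaged (the convention used for "low-frequency ITC"
    throughout the package).
    """
    if specs is None:
        specs = [
            s
            for s in filter_bank_specs()
            if center_range_hz[0] <= s.center_hz <= center_range_hz[1]
        ]
    acc = None
    for spec in specs:
        dec = band_decompose(epochs.data, epochs.sample_rate_hz, spec)
        value = itc(dec.phase, trial_axis=1)
        acc = value if acc is None else acc + value
    return acc / len(specs)


def signed_r2(x: np.ndarray, reference: np.ndarray) -> float:
    """sign(rho) * rho^2 for the Spearman correlation of x with a reference."""
    rho = stats.spearmanr(x, reference).statistic
    if np.isnan(rho):
        return 0.0
    return float(np.sign(rho) * rho**2)


def interval_engagement(
    epochs: EpochSet,
    mod_freq_hz: float,
    intervals: dict[str, tuple[float, float]] | None = None,
    hg_band=HIGH_GAMMA_BAND,
    itc_series: np.ndarray | None = None,
) -> pd.DataFrame:
    """Per-electrode engagement of low-frequency phase and high-gamma power.

    For every interval: ``itc`` = mean low-frequency (filter bank) ITC over
    the window; ``hg_r2`` = signed Spearman r^2 between the trial-mean
    high-gamma percent-change power and a reference sinusoid at the
    modulation frequency, cosine-phase-aligned to the (extrapolated)
    stimulus envelope (peaks at integer multiples of the period).
    """
    if intervals is None:
        intervals = default_intervals(mod_freq_hz)
    times = epochs.times
    for name, win in intervals.items():
        if win[0] < times[0] - 1e-9 or win[1] > times[-1] + 1 / epochs.sample_rate_hz + 1e-9:
            raise ValueError(f"interval {name!r} outside epoch")
    if itc_series is None:
        itc_series = bank_itc(epochs)
    hg = band_decompose(epochs.data, epochs.sample_rate_hz, hg_band)
    pct = percent_change_power(hg, times, epochs.baseline_window)
    mean_pct = pct.mean(axis=1)  # electrodes x time
    reference = np.cos(2 * np.pi * mod_freq_hz * times)

    rows = []
    for name, win in intervals.items():
        mask = window_slice(times, tuple(win))
        for e, cid in enumerate(epochs.channel_ids):
            rows.append(
                {
                    "electrode": cid,
                    "interval": name,
                    "itc": float(itc_series[e, mask].mean()),
                    "hg_r2": signed_r2(mean_pct[e, mask], reference[mask]),
                }
            )
    return pd.DataFrame(rows)


def interval_group_test(engagement: pd.DataFrame, alpha: float = 0.01) -> pd.DataFrame:
    """Group Wilcoxon signed-rank of each interval against baseline.

    One-sided (engagement only meaningfully exceeds baseline), per measure.
    Returns one row per (interval, measure) with the p-value and a
    significance flag at ``alpha``.
    """
    wide = engagement.pivot(index="electrode", columns="interval")
    rows = []
    for measure in ("itc", "hg_r2"):
        base = wide[(measure, "baseline")].to_numpy()
        for interval in engagement["interval"].unique():
            if interval == "baseline":
                continue
            value = wide[(measure, interval)].to_numpy()
            diff = value - base
            if np.allclose(diff, 0):
                p = 1.0
            else:
                p = float(stats.wilcoxon(value, base, alternative="greater").pvalue)
            rows.append(
                {
                    "measure": measure,
                    "interval": interval,
                    "median_change": float(np.median(diff)),
                    "p": p,
                    "significant": p < alpha,
                }
            )
    return pd.DataFrame(rows)


def quarter_period_delay(mod_freq_hz: float) -> int:
    """Quarter of the modulation period, rounded to integer milliseconds."""
    if mod_freq_hz <= 0:
        raise ValueError("modulation frequency must be positive")
    return int(round(1000.0 / (4.0 * mod_freq_hz)))


def phase_space_trajectory(
    series: np.ndarray,
    delay_ms: float,
    sample_rate_hz: float,
    times: np.ndarray | None = None,
    intervals: dict[str, tuple[float, float]] | None = None,
):
    """Delay-embedded trajectory ``(x(t), x(t - delay))`` with state labels.

    With a quarter-period delay a sinusoid at the modulation frequency traces
    a circle (quadrature embedding); rest, onset, and sustained states
    occupy separable regions of the plane. Labels are taken from
    ``intervals`` when ``times`` is given.
    """
    series = np.asarray(series, dtype=float)
    d = int(round(delay_ms * sample_rate_hz / 1000.0))
    if d >= len(series):
        raise ValueError("delay exceeds series length")
    x = series[d:]
    y = series[: len(series) - d]
    labels = None
    if times is not None and intervals is not None:
        t = np.asarray(times)[d:]
        labels = np.full(len(t), "other", dtype=object)
        for name, win in intervals.items():
            labels[window_slice(t, tuple(win))] = name
    return x, y, labels


def predictive_electrode_screen(
    results: pd.DataFrame,
    alpha: float = 0.05,
    sustained_col: str = "p_sustained",
    prediction_col: str = "p_early_prediction",
) -> pd.DataFrame:
    """Electrodes with both a significant sustained response and a
    significant early-prediction phase reset (per-electrode bootstrap p)."""
    mask = (results[sustained_col] < alpha) & (results[prediction_col] < alpha)
    out = results.copy()
    out["predictive"] = mask
    return out
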