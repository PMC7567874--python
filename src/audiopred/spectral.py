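"""Analytic-signal decomposition with frequency-domain Hilbert filters.

The bandpass is built directly in the frequency domain as a one-sided
(analytic) response: zero gain at negative frequencies, twice the bandpass
gain at positive frequencies. The passband is the product of two logistic
("sigmoid") flanks centred on the band edges, so gain is 0.5 exactly at each
nominal edge; the flank half-width (default 1 Hz) sets the steepness, with
gain rising from 0.12 to 0.88 over two half-widths. The inverse FFT of the
filtered spectrum is the analytic signal, whose modulus and argument give
instantaneous amplitude and phase.

Standard band conventions used throughout the package: low 2-15 Hz (phase
statistics), theta 4-8 Hz, beta 15-30 Hz, high-gamma 65-115 Hz. For
spectrograms, a 50-band bank with log-spaced centres (2-16 Hz) and
log-spaced widths (1-4 Hz), paired index-wise.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.signal import savgol_filter

from ._util import window_slice
from .containers import EpochSet

__all__ = [
    "BandSpec",
    "BandDecomposition",
    "LOW_BAND",
    "THETA_BAND",
    "BETA_BAND",
    "HIGH_GAMMA_BAND",
    "design_filter",
    "analytic_signal",
    "band_decompose",
    "filter_bank_specs",
    "bank_decompose",
    "percent_change_power",
    "smooth_for_display",
]

# logistic scale such that the flank passes 0.12 / 0.88 one half-width from
# the band edge: s = half_width / ln(0.88 / 0.12)
_FLANK_LOG_RATIO = float(np.log(0.88 / 0.12))


@dataclass(frozen=True)
class BandSpec:
    """A bandpass definition: centre, bandwidth, and sigmoid-flank width."""

    center_hz: float
    bandwidth_hz: float
    flank_half_width_hz: float = 1.0
    name: str = ""

    @property
    def low_hz(self) -> float:
        return self.center_hz - self.bandwidth_hz / 2.0

    @property
    def high_hz(self) -> float:
        return self.center_hz + self.bandwidth_hz / 2.0

    @classmethod
    def from_edges(cls, low_hz: float, high_hz: float, name: str = "", flank: float = 1.0):
        return cls((low_hz + high_hz) / 2.0, high_hz - low_hz, flank, name)


LOW_BAND = BandSpec.from_edges(2.0, 15.0, name="low")
THETA_BAND = BandSpec.from_edges(4.0, 8.0, name="theta")
BETA_BAND = BandSpec.from_edges(15.0, 30.0, name="beta")
HIGH_GAMMA_BAND = BandSpec.from_edges(65.0, 115.0, name="high_gamma")


@dataclass
class BandDecomposition:
    """Instantaneous amplitude and phase of one band (same shape as input)."""

    amplitude: np.ndarray
    phase: np.ndarray
    band: BandSpec
    sample_rate_hz: float


def _flank_gain(freqs: np.ndarray, band: BandSpec) -> np.ndarray:
    s = band.flank_half_width_hz / _FLANK_LOG_RATIO
    rising = 1.0 / (1.0 + np.exp(-(freqs - band.low_hz) / s))
    falling = 1.0 / (1.0 + np.exp(-(band.high_hz - freqs) / s))
    return rising * falling


def design_filter(n_samples: int, sample_rate_hz: float, band: BandSpec) -> np.ndarray:
    """One-sided frequency response realizing the analytic bandpass.

    Returns a length-``n_samples`` gain vector aligned with
    ``np.fft.fftfreq(n_samples, 1/sample_rate_hz)``: zero for negative
    frequencies, ``2 * gain`` for positive frequencies.
    """
    nyq = sample_rate_hz / 2.0
    if band.high_hz >= nyq:
        raise ValueError(f"band {band} exceeds Nyquist ({nyq} Hz)")
    if band.low_hz <= 0:
        raise ValueError(f"band {band} extends to or below 0 Hz")
    freqs = np.fft.fftfreq(n_samples, d=1.0 / sample_rate_hz)
    gain = _flank_gain(freqs, band)
    analytic = np.where(freqs > 0, 2.0 * gain, 0.0)
    analytic[freqs == 0] = gain[freqs == 0]
    return analytic


def _analytic(data: np.ndarray, sample_rate_hz: float, band: BandSpec, pad: int) -> np.ndarray:
    padded = np.concatenate(
        [data[..., 1 : pad + 1][..., ::-1], data, data[..., -pad - 1 : -1][..., ::-1]], axis=-1
    ) if pad else data
    gain = design_filter(padded.shape[-1], sample_rate_hz, band)
    spectrum = np.fft.fft(padded, axis=-1) * gain
    z = np.fft.ifft(spectrum, axis=-1)
    return z[..., pad : pad + data.shape[-1]] if pad else z


def band_decompose(
    data: np.ndarray, sample_rate_hz: float, band: BandSpec, pad_s: float = 1.0
) -> BandDecomposition:
    """Analytic amplitude and phase of ``data`` (any shape, time last).

    Epochs are reflection-padded by ``pad_s`` seconds before FFT filtering
    to suppress wrap-around edge artifacts; the padding is trimmed again.
    """
    n = data.shape[-1]
    min_cycles = 2.0
    if n / sample_rate_hz * band.center_hz < min_cycles:
        warnings.warn(
            f"epoch shorter than {min_cycles} cycles of {band.center_hz} Hz; "
            "amplitude/phase estimates unreliable",
            stacklevel=2,
        )
    pad = min(n - 1, int(round(pad_s * sample_rate_hz)))
    z = _analytic(np.asarray(data, dtype=float), sample_rate_hz, band, pad)
    return BandDecomposition(np.abs(z), np.angle(z), band, sample_rate_hz)


def analytic_signal(epochs: EpochSet, band: BandSpec, pad_s: float = 1.0) -> BandDecomposition:
    """Band decomposition of an :class:`EpochSet` (electrodes x trials x time)."""
    return band_decompose(epochs.data, epochs.sample_rate_hz, band, pad_s=pad_s)


def filter_bank_specs(
    n_bands: int = 50,
    center_lo_hz: float = 2.0,
    center_hi_hz: float = 16.0,
    width_lo_hz: float = 1.0,
    width_hi_hz: float = 4.0,
) -> list[BandSpec]:
    """Log-spaced spectrogram bank: centres 2-16 Hz, widths 1-4 Hz, paired
    index-wise (narrow bands at low centres, wide bands at high centres)."""
    centers = np.geomspace(center_lo_hz, center_hi_hz, n_bands)
    widths = np.geomspace(width_lo_hz, width_hi_hz, n_bands)
    return [
        BandSpec(c, w, name=f"bank{i:02d}") for i, (c, w) in enumerate(zip(centers, widths))
    ]


def bank_decompose(data: np.ndarray, sample_rate_hz: float, specs=None, pad_s: float = 1.0):
    """Yield ``(BandSpec, BandDecomposition)`` per bank band.

    A generator rather than a stacked array: a 50-band decomposition of a
    cohort-sized epoch array would not fit in memory, and most consumers
    (ITC accumulation, spectrogram summaries) reduce each band immediately.
    """
    if specs is None:
        specs = filter_bank_specs()
    for spec in specs:
        yield spec, band_decompose(data, sample_rate_hz, spec, pad_s=pad_s)


def percent_change_power(
    decomposition: BandDecomposition,
    times: np.ndarray,
    baseline_window: tuple[float, float],
) -> np.ndarray:
    """Power (amplitude squared) as percent change from the baseline window.

    The baseline mean is taken per electrode and per trial, so the output
    over the baseline window averages to zero by construction.
    """
    mask = window_slice(np.asarray(times), baseline_window)
    if not mask.any():
        raise ValueError("baseline window outside epoch")
    power = decomposition.amplitude**2
    base = power[..., mask].mean(axis=-1, keepdims=True)
    if np.any(base <= 0):
        raise ValueError("zero baseline power (degenerate input)")
    return 100.0 * (power - base) / base


def smooth_for_display(
    series: np.ndarray, sample_rate_hz: float, order: int = 3, frame_ms: float = 83.0
) -> np.ndarray:
    """Savitzky-Golay smoothing (3rd order, 83 ms frame) for presentation.

    Polynomial-preserving: any input that is a polynomial of degree <= order
    passes through unchanged. Applied only for display, never before
    statistics.
    """
    window = int(round(frame_ms * sample_rate_hz / 1000.0))
    if window % 2 == 0:
        window += 1
    if window <= order:
        raise ValueError("frame length must exceed polynomial order")
    return savgol_filter(np.asarray(series, dtype=float), window, order, axis=-1)
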