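"""Synthetic auditory stimuli: rhythmic amplitude-modulated noise with an
optional peri-threshold probe tone, and quasi-rhythmic speech-like
envelopes with planted edge and syllable annotations.

The rhythmic stimulus is wideband Gaussian noise multiplied by a raised-
cosine modulator (default 3 Hz, 80 % depth, 3 s), which ends on the cosine
peak of the next cycle and continues as constant-amplitude noise (default
833 ms). Depth convention: envelope = 1 - depth * (1 - cos(2 pi f t)) / 2,
so the envelope peaks at 1 and depth = (peak - trough) / peak. Acoustic
edges are the maxima of the envelope derivative on each rising slope, at
(k + 3/4) periods from onset; a 3 Hz / 3 s stimulus carries exactly nine
pulses and nine edges.

Probe tones (1 kHz, 50 ms, 5 ms raised-cosine rise/decay) are embedded in
the constant segment at one of five temporal positions separated by a
quarter modulation cycle, at one of three levels spanning 12 dB.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.io import wavfile

from ._util import as_rng

__all__ = [
    "ToneSpec",
    "StimulusSpec",
    "Stimulus",
    "make_am_noise_stimulus",
    "embed_probe_tone",
    "SpeechSentence",
    "make_speech_like_envelope",
    "write_wav",
]


@dataclass(frozen=True)
class ToneSpec:
    freq_hz: float = 1000.0
    dur_ms: float = 50.0
    rise_decay_ms: float = 5.0
    position_index: int = 1  # 1..5, quarter-cycle steps from constant onset
    level_index: int = 1  # 1..3, spanning level_range_db
    level_range_db: float = 12.0
    base_amplitude: float = 0.05  # level-1 amplitude, carrier-RMS units


@dataclass(frozen=True)
class StimulusSpec:
    sample_rate_hz: float = 44100.0
    mod_freq_hz: float = 3.0
    mod_depth: float = 0.8
    rhythmic_dur_s: float = 3.0
    constant_dur_s: float = 0.833
    tone: ToneSpec | None = None
    seed: int = 0

    def validate(self) -> None:
        if not 0.0 <= self.mod_depth <= 1.0:
            raise ValueError("mod_depth must lie in [0, 1]")
        cycles = self.mod_freq_hz * self.rhythmic_dur_s
        if abs(cycles - round(cycles)) > 1e-9:
            raise ValueError("rhythmic_dur_s must span an integer number of cycles")
        if self.tone is not None and self.tone.freq_hz >= self.sample_rate_hz / 2:
            raise ValueError("tone frequency at or above Nyquist")

    @property
    def n_pulses(self) -> int:
        return int(round(self.mod_freq_hz * self.rhythmic_dur_s))


@dataclass
class Stimulus:
    """Generated waveform with its modulator and edge ground truth."""

    waveform: np.ndarray
    envelope: np.ndarray
    edge_times: np.ndarray
    sample_rate_hz: float
    spec: StimulusSpec
    tone_onset_s: float | None = None

    @property
    def times(self) -> np.ndarray:
        return np.arange(len(self.waveform)) / self.sample_rate_hz

    @property
    def constant_start_s(self) -> float:
        return self.spec.rhythmic_dur_s

    def modulator_phase(self, times: np.ndarray) -> np.ndarray:
        """Extrapolated stimulus-modulator phase, 0 at envelope peaks."""
        phase = 2 * np.pi * self.spec.mod_freq_hz * np.asarray(times)
        return np.angle(np.exp(1j * phase))


def make_am_noise_stimulus(spec: StimulusSpec, rng=None) -> Stimulus:
    """Raised-cosine amplitude-modulated Gaussian noise + constant tail."""
    spec.validate()
    rng = as_rng(spec.seed if rng is None else rng)
    fs = spec.sample_rate_hz
    n_rhythmic = int(round(spec.rhythmic_dur_s * fs))
    n_constant = int(round(spec.constant_dur_s * fs))
    t = np.arange(n_rhythmic + n_constant) / fs
    envelope = np.ones_like(t)
    rhythmic = t < spec.rhythmic_dur_s - 0.5 / fs
    envelope[rhythmic] = 1.0 - spec.mod_depth * (
        1.0 - np.cos(2 * np.pi * spec.mod_freq_hz * t[rhythmic])
    ) / 2.0
    carrier = rng.standard_normal(len(t))
    waveform = carrier * envelope
    if spec.mod_depth > 0:
        edges = (np.arange(spec.n_pulses) + 0.75) / spec.mod_freq_hz
    else:
        edges = np.empty(0)
    return Stimulus(waveform, envelope, edges, fs, spec)


def _cosine_gate(n: int, n_ramp: int) -> np.ndarray:
    gate = np.ones(n)
    ramp = 0.5 * (1 - np.cos(np.pi * np.arange(n_ramp) / n_ramp))
    gate[:n_ramp] = ramp
    gate[-n_ramp:] = ramp[::-1]
    return gate


def embed_probe_tone(stimulus: Stimulus, tone: ToneSpec | None = None) -> Stimulus:
    """Add a gated probe tone inside the constant-amplitude segment.

    Position index 1 starts at the constant-segment onset; successive
    positions step by one quarter of the modulation cycle. Level indices
    1..3 span ``level_range_db`` (6 dB steps by default).
    """
    spec = stimulus.spec
    tone = tone if tone is not None else spec.tone
    if tone is None:
        raise ValueError("no tone specification supplied")
    fs = stimulus.sample_rate_hz
    quarter = 1.0 / (4.0 * spec.mod_freq_hz)
    onset = spec.rhythmic_dur_s + (tone.position_index - 1) * quarter
    dur = tone.dur_ms / 1000.0
    total = spec.rhythmic_dur_s + spec.constant_dur_s
    if not (spec.rhythmic_dur_s <= onset and onset + dur <= total):
        raise ValueError("tone position falls outside the constant segment")

    n = int(round(dur * fs))
    n_ramp = max(1, int(round(tone.rise_decay_ms / 1000.0 * fs)))
    step_db = tone.level_range_db / 2.0
    carrier_rms = float(np.std(stimulus.waveform))
    amp = tone.base_amplitude * carrier_rms * 10 ** ((tone.level_index - 1) * step_db / 20.0)
    tt = np.arange(n) / fs
    burst = amp * np.sin(2 * np.pi * tone.freq_hz * tt) * _cosine_gate(n, n_ramp)
    waveform = stimulus.waveform.copy()
    i0 = int(round(onset * fs))
    waveform[i0 : i0 + n] += burst
    return Stimulus(
        waveform,
        stimulus.envelope,
        stimulus.edge_times,
        fs,
        spec,
        tone_onset_s=onset,
    )


# ---------------------------------------------------------------------------
# speech-like envelopes


@dataclass
class SpeechSentence:
    envelope: np.ndarray
    sample_rate_hz: float
    edge_times: np.ndarray
    syllable_times: np.ndarray
    duration_s: float

    @property
    def times(self) -> np.ndarray:
        return np.arange(len(self.envelope)) / self.sample_rate_hz


def _pulse_kernel(fs: float, rise_s: float = 0.035, decay_s: float = 0.09):
    """Asymmetric envelope pulse (fast rise, slow decay) and the offset of
    its maximum-slope point, used as the planted edge time."""
    t = np.arange(int(round((rise_s + 4 * decay_s) * fs))) / fs
    kernel = (t / rise_s) ** 2 * np.exp(2.0 - 2.0 * t / rise_s)
    kernel[t > rise_s] = np.exp(-(t[t > rise_s] - rise_s) / decay_s)
    edge_offset = float(np.argmax(np.diff(kernel)) / fs)
    return kernel, edge_offset


def make_speech_like_envelope(
    n_sentences: int = 20,
    dur_s_mean: float = 1.97,
    dur_s_sd: float = 0.36,
    edge_rate_hz: float = 3.5,
    syllable_rate_hz: float = 3.9,
    sample_rate_hz: float = 1000.0,
    seed=0,
) -> list[SpeechSentence]:
    """Quasi-rhythmic positive envelopes with planted annotations.

    Each sentence is a sum of asymmetric amplitude pulses with jittered
    inter-pulse intervals; planted edges are the maximum-derivative points
    of the pulses (about ``edge_rate_hz * duration`` per sentence, matching
    ~6.9 edges over ~1.97 s at the defaults). Syllable onsets are a
    dissociable annotation: edge times shifted earlier and jittered, plus
    extra events making up the higher syllable rate (~7.7 per sentence).
    """
    rng = as_rng(seed)
    fs = sample_rate_hz
    kernel, edge_offset = _pulse_kernel(fs)
    sentences = []
    for _ in range(n_sentences):
        dur = max(1.0, rng.normal(dur_s_mean, dur_s_sd))
        n = int(round(dur * fs))
        n_pulses = int(round(edge_rate_hz * dur))
        envelope = np.zeros(n + len(kernel))
        min_gap = 0.18  # pulses closer than this merge into one amplitude event
        span = dur - 0.53
        n_pulses = min(n_pulses, int(span / min_gap) + 1)
        if n_pulses > 0:
            if n_pulses > 1:
                jitter = rng.gamma(shape=4.0, scale=1.0, size=n_pulses - 1)
                slack = span - min_gap * (n_pulses - 1)
                intervals = min_gap + jitter / jitter.sum() * max(slack, 0.0)
                starts = 0.08 + np.concatenate([[0.0], np.cumsum(intervals)])
            else:
                starts = np.array([0.08])
            amps = rng.lognormal(mean=0.0, sigma=0.15, size=n_pulses)
            for t0, a in zip(starts, amps):
                i0 = int(round(t0 * fs))
                envelope[i0 : i0 + len(kernel)] += a * kernel
            edges = starts + edge_offset
        else:
            edges = np.empty(0)
        envelope = envelope[:n]
        n_syll = int(round(syllable_rate_hz * dur))
        syll = edges - 0.060 + rng.normal(0.0, 0.03, size=len(edges))
        extra = rng.uniform(0.05, dur - 0.1, size=max(0, n_syll - len(edges)))
        syll = np.sort(np.clip(np.concatenate([syll, extra]), 0.0, dur - 1.0 / fs))
        sentences.append(SpeechSentence(envelope, fs, np.sort(edges), syll, dur))
    return sentences


def write_wav(path, waveform: np.ndarray, sample_rate_hz: float) -> None:
    """16-bit PCM WAV output, peak-normalized to 90 % full scale."""
    peak = np.abs(waveform).max()
    scaled = waveform / peak * 0.9 if peak > 0 else waveform
    wavfile.write(path, int(round(sample_rate_hz)), (scaled * 32767).astype(np.int16))
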