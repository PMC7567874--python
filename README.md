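# audiopred

Analyses of predictive dynamics in human early auditory cortex, built around a
synthetic-cohort forward model. Intracranial depth recordings along the
supratemporal plane show two distinct predictive mechanisms during listening
and speaking:

1. **Temporal prediction in Heschl's gyrus / transverse temporal sulcus
   (HG/TTS)**: low-frequency (theta) phase resets at *acoustic edges* — moments
   of rapid amplitude gain — and keeps resetting for one cycle after a rhythmic
   stimulus ends, while high-gamma (65–115 Hz) power tracks the acoustic
   envelope and sweeps mediolaterally as a traveling wave (~0.1 m/s).
2. **Predictive coding in planum temporale (PT)**: a transient onset response
   in high-gamma power that is selectively suppressed during self-generated
   speech (the efference-copy signature), restricted to language-dominant
   cortex.

Because patient recordings of this kind are not publicly distributable, the
package pairs every analysis with a generator that plants these phenomena with
known ground truth, so each method is validated by parameter recovery and
statistical calibration rather than by a frozen data snapshot.

## Core quantities

- **Inter-trial coherence (ITC)** of instantaneous phase θₙ(t) over N trials:
  `L(t) = |(1/N) Σₙ exp(i θₙ(t))|`, computed per band of a 50-band
  frequency-domain Hilbert filter bank (log-spaced centres 2–16 Hz, widths
  1–4 Hz, paired sigmoid flanks of 1 Hz half-width). Under the null,
  `E[L] ≈ √π / (2√N)`; electrode-level significance uses a temporally jittered
  bootstrap.
- **Percent-change power**: squared analytic amplitude normalized to the
  −300…−50 ms pre-stimulus baseline.
- **Interval engagement**: the rhythmic-noise epoch is split into baseline /
  onset / sustained (pulses 2–9) / early prediction / late prediction; phase
  engagement is mean 2–15 Hz ITC, envelope tracking is the signed r² of the
  Spearman correlation between trial-mean high-gamma power and the
  extrapolated 3 Hz modulator.
- **Response classes**: rank-2 NNMF `A ≈ WH` (multiplicative updates, best of
  many replicates) of rectified response features; class bias = difference of
  the two weights (threshold 10 → sustained / transient / mixed), response
  magnitude = their sum; archetype transfer to articulation epochs via
  `W = A H⁺`.
- **Behavior / stimulation**: Wilcoxon signed-rank contrasts of tone-detection
  hit rates by temporal position, and one-sided pooled two-proportion z tests
  for chronometric-stimulation outcomes.

## Worked example

```python
>>> from audiopred import behavior as beh
>>> from audiopred.phase_stats import quarter_period_delay
>>> beh.two_proportion_z(10, 31, 11, 18)   # edge-locked HG/TTS vs uniform stimulation
(-1.9675186814441857, 0.024561907692385872)
>>> beh.two_proportion_z(10, 31, 17, 21)   # edge-locked HG/TTS vs edge-locked PT
(-3.4482573914440376, 0.00028195151870644727)
>>> quarter_period_delay(3.0)              # delay-embedding lag for the 3 Hz stimulus
83
```

The first call says naming accuracy under stimulation of early auditory cortex
at acoustic edges (10/31 correct) is significantly worse than under the same
charge delivered uniformly in time (11/18; one-sided p ≈ 0.0246): edge-locked
disruption is what hurts. The second shows the same edge-locked stimulation is
far more disruptive in HG/TTS than in PT (17/21; p ≈ 2.8 × 10⁻⁴). The third is
the quarter-period lag (83 ms) used for phase-space trajectories of the 3 Hz
response.

The numbered drivers under `analysis/` run the full synthetic study and write
tables under `results/`:

```bash
python analysis/01_simulate_cohort.py       # stimuli, cohort, recordings
python analysis/02_rhythm_encoding.py       # multiplexed envelope encoding + wave
python analysis/03_prediction_intervals.py  # persistence of the sustained state
python analysis/04_speech_encoding.py       # envelope lags, edges vs syllables
python analysis/05_response_classification.py  # NNMF classes, gradient, transfer
python analysis/06_behavior_stimulation.py  # detection + stimulation statistics
```

For example, `03_prediction_intervals.py` prints the interval pattern on a
16-electrode sustained cohort (24 trials): low-frequency ITC significantly
engaged in onset, sustained and the *first* prediction interval (p < 10⁻⁵ each)
but not the second (p = 0.27), while high-gamma tracking is confined to onset
and sustained — prediction outlives the stimulus in phase, not in power.
`05_response_classification.py` classifies a 349-electrode cohort into 122
sustained / 157 transient / 70 unclassified electrodes (accuracy 1.000 against
the planted archetypes), recovers the anteroposterior gradient (Spearman
ρ = −0.76), and shows that after transfer to articulation the sustained weights
stay correlated (ρ = 0.70) while the transient weights decouple (ρ = −0.07,
p = 0.17; 157 transient classifications while listening → 0 during
articulation).

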