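# Methods

This note documents the models, defaults and design decisions behind the
package: what the analyses compute, what the synthetic cohorts plant, and
where genuinely open choices were resolved.

## Signal model and preprocessing

Recordings are channels × samples at a nominal 2 kHz clinical rate; the
synthetic cohorts use 400 Hz (Nyquist comfortably above the 115 Hz upper
high-gamma edge) to keep simulation and filtering tractable at desk scale.
Preprocessing follows the standard intracranial chain: zero-phase 2nd-order
Butterworth band-stops at 60/120/180 Hz, exclusion of channels with >10 dB of
line noise or regular saturation, then common-average referencing over the
survivors. Two details are package choices because the underlying rules are
qualitative:

- the line-noise reference baseline is the median PSD over 50–70 Hz excluding
  58–62 Hz, with line power taken as the PSD peak within ±1 Hz of 60 Hz;
- "regular saturation" is operationalized as ≥0.1 % of samples at the rail
  (the channel's absolute maximum when no hardware rail is supplied).

Epochs are half-open sample windows, time 0 at the alignment event, baseline
−300…−50 ms. Trial rejection for epileptiform activity is modeled as an
externally supplied bad-trial list (it is a clinical judgment, not an
algorithm); behavioral trials can be filtered on correctness and a 2 s
latency cutoff.

Note on referencing synthetic cohorts: with a handful of electrodes, the
common average contains a visible share of the planted evoked response, so
subtracting it leaks an inverted copy into every channel (including nulls).
The end-to-end pipeline therefore exposes `car` as a switch (default on, as
in the recording convention), while the parameter-recovery suites feed the
simulated recordings to the analyses directly; the preprocessing operators
have their own unit tests.

## Spectral decomposition

Bandpassing is done in the frequency domain on the analytic (one-sided)
spectrum. The passband is a product of two logistic flanks centred on the
band edges; gain is exactly 0.5 at each nominal edge and traverses 0.12→0.88
over two half-widths (default half-width 1 Hz, i.e. scale
s = 1 / ln(0.88/0.12) Hz). Epochs are reflection-padded by 1 s before the FFT
and trimmed afterwards. Named bands: low 2–15 Hz (phase statistics), theta
4–8 Hz, beta 15–30 Hz (the beta range is a package convention), high-gamma
65–115 Hz. The spectrogram bank pairs 50 log-spaced centres (2–16 Hz) with 50
log-spaced widths (1–4 Hz) index-wise — narrow bands at low centres — since
grid pairing is the only stated alternative and index-wise matching keeps
relative bandwidth roughly constant. "Low-frequency ITC" always means the
mean ITC across the bank bands with centres in 2–15 Hz.

Narrow bands have long impulse responses: a 2 Hz-wide band smears coherence
by roughly ±0.25 s. Every windowed contrast in the package (and any analysis
of this family on real data) inherits that resolution limit; it drove two
generator decisions noted below. Savitzky–Golay smoothing (3rd order, 83 ms)
is applied to traces for display only, never before statistics.

## Phase statistics

ITC is the modulus of the mean unit phasor across trials; under random
phases E[ITC] = √π/(2√N). Electrode-level p-values come from a temporally
jittered bootstrap: each replicate circularly shifts every trial's phase
series by an independent uniform offset, which destroys event locking while
preserving marginal phase dynamics; p = (1 + #{null ≥ obs})/(n_boot + 1),
one-sided, since ITC and KL divergence only meaningfully exceed their nulls.
Phase-resolved amplitude profiles use 18 bins of 20°, normalized to a
probability profile, scored by KL divergence from uniform with the same
jittered null. Group-level interval contrasts use the Wilcoxon signed-rank
across electrodes against the baseline interval. Interval boundaries for the
3 Hz stimulus: onset [0, ⅓ s), sustained [⅓, 3 s), early/late prediction are
the two ⅓ s cycles after the rhythm ends. The reference sinusoid for the
signed-r² envelope-tracking measure is cosine-aligned to the extrapolated
modulator (envelope peaks at phase 0).

## Stimuli

Rhythmic noise: Gaussian carrier × raised-cosine modulator,
env = 1 − d(1 − cos 2πft)/2 with d = 0.8, f = 3 Hz for 3 s (so the modulator
starts and ends on the cosine peak), then 833 ms of constant-amplitude noise.
Depth is (peak − trough)/peak. Acoustic-edge ground truth is the maximum of
the envelope derivative on each rising slope, (k + ¾)/f — nine edges for
nine pulses. Probe tones (1 kHz, 50 ms, 5 ms raised-cosine ramps) occupy one
of five quarter-cycle positions starting at the constant-segment onset, at
one of three levels spanning 12 dB (6 dB steps); tone level is specified
relative to carrier RMS.

Speech-like envelopes are sums of asymmetric pulses (35 ms rise, 90 ms decay)
with jittered inter-pulse intervals (minimum 180 ms — amplitude events closer
than that merge perceptually and are generated as one), amplitudes lognormal
(σ = 0.15). Defaults emulate short task sentences: duration 1.97 ± 0.36 s,
~6.9 edges and ~7.7 syllable onsets per sentence; syllable onsets are the
edge times shifted 60 ms earlier with 30 ms jitter plus extra events, so the
two annotations are correlated but dissociable. No formant structure is
modeled: these are envelope-level surrogates only.

## The neural forward model

Each electrode realizes an archetype on top of unit-variance 1/f^1.5
background noise; component gains are expressed relative to that background
and scaled by the electrode's SNR (dB) around a 10 dB reference.

**Sustained (HG/TTS).** High-gamma: band-limited (65–115 Hz) noise carrier
whose amplitude is 0.15 + envelope delayed by `hg_lag_ms` plus a low-latency
onset burst (gamma-shaped, 60 ms peak). For the rhythm task the default lag
is 10 ms — high-gamma is in phase with this stimulus; the 45/95/135 ms
frequency-specific delays are speech-envelope phenomena and are planted in
the speech simulations. The traveling wave adds a per-electrode lag of
mediolateral position / velocity (default 0.1 m/s; 16 mm span → 160 ms).
Theta: a noisy phase oscillator (6 Hz, Brownian phase diffusion
80 rad²/s) captured toward a fixed target phase for 60 ms after each acoustic
edge (relaxation τ = 20 ms), with a transient amplitude swell at each reset
(low-frequency power rides the rising slope). After the last pulse the
oscillator keeps being captured at the stimulus cadence for
`theta_reset_persist_cycles` (default 1) — this is the planted prediction.
Beta: short Gabor bursts re-synchronized at envelope troughs.

Two generator decisions exist specifically because of the filter-bank
resolution limit. First, the persisted (predicted) reset is *anticipatory*,
leading the extrapolated edge time by 160 ms (~one theta cycle): phase
aligns in advance of the expected event, consistent with detection improving
at the predicted edge itself, and it lets coherence decay fully before the
late-prediction window despite narrowband smearing. Second, sustained
electrodes carry no deterministic broadband deflection at stimulus onset:
zero-phase narrowband filtering would smear such a coherent component
backward into the −300…−50 ms baseline and bias every baseline-referenced
contrast. The diffusion constant means raw coherence decays as
exp(−40·t) after a capture ends, so each cycle's ITC elevation is a sharp
post-edge pulse rather than a plateau.

**Transient (PT).** A single onset-locked high-gamma burst one pulse long
plus a deterministic biphasic low-frequency deflection (~200 ms), nothing
else; assigned only in the language-dominant hemisphere, and absent from
articulation-aligned epochs when `articulation_suppressed`. Articulation
epochs are independent trials aligned to articulation onset; sustained
electrodes keep reduced (0.3×) tracking of a self-produced speech envelope.
No acoustic self-feedback is modeled.

**Null.** Background noise only; the false-positive control for every
screen.

## Feature-level cohort for response classification

Classification at the full supratemporal scale (m = 349) operates on
rectified trial-mean response features generated directly: sustained rows are
an envelope-locked comb over the rhythmic period, transient rows a single
onset bump, weights lognormal around 60, row noise with RMS = signal RMS / 5,
then half-wave rectified. Anteroposterior positions are drawn
class-dependently (sustained anterior ~10 mm, transient posterior ~28 mm) to
plant the functional gradient. Articulation features preserve the sustained
component at 0.6 gain and remove the transient component entirely.

One estimator artifact deserves note: transferring archetypes with the
rectified pseudo-inverse (negative weights clipped to zero) creates two small
opposing spurious correlations between listening and articulation transient
weights — weight-proportional clipped noise pulls positive, and any mismatch
between the rectification pedestals of the listening and articulation
features pulls negative. The articulation noise model mixes a
response-scaled pedestal (0.15) with a class-independent floor (SNR 2.5) to
centre this artifact near zero; across cohort seeds the residual transient
correlation is typically |ρ| < 0.08, with occasional seeds reaching ~0.2.
The same clipping applies to real data, so a small nonzero transfer
correlation for a suppressed class should not by itself be over-read.

NNMF uses Lee–Seung multiplicative updates (Frobenius objective, provably
non-increasing), replicates seeded from a master seed and a counter, best
replicate by residual, ties to the first. Rows of H are max-normalized with
the scale folded into W before biases are computed — without fixing the scale
degeneracy a numeric bias threshold is meaningless. Class identity is
assigned by correlating archetypes with a canonical sustained comb template.
The rank is fixed at 2 (exposed as a parameter, not auto-selected).
Degenerate (rank-deficient) H is rejected in transfer; Theil–Sen slopes make
the traveling-wave fit robust, with velocity = 1/slope per pulse, pulses with
R² < 0.5 or non-positive slope flagged, and the mean wave averaged over valid
pulses (undefined if fewer than half are valid).

## Behavior and stimulation statistics

Detection tables: 50 % tone-present trials, the 5 × 3 position/level grid
filled as evenly as possible; hits follow a logistic psychometric in dB
(slope 0.35/dB, intercept 0.9) with a +0.9 logit bonus at position 2 for the
lowest level only, and a 10 % false-alarm rate on tone-absent trials. These
effect sizes give the position-2 contrast ~full power at 37 subjects × 100
trials while leaving low-level accuracy clearly sub-ceiling. Per-position
results use hit rate on tone-present trials; overall per-level accuracy
includes correct rejections. Position contrasts are one-sided Wilcoxon
signed-rank (position 2 hypothesized better), Holm-adjusted; all-tied
contrasts report p = 1.

The two-proportion z test pools the variance and is one-sided by default
(alternative: group 1's proportion is lower), because that sidedness
reproduces the printed p = 0.0246 for the 10/31 vs 11/18 stimulation contrast
exactly (two-sided gives 0.049); two-sided is available. Printed percentages
are inverted to integer counts by rounding, with an ambiguity flag when a
neighbouring count prints identically. Trial counts for the second
stimulation patient are not published, so those contrasts are not
reproduced.

## Problem sizes and what the tests show

The validation suites run at deliberately modest sizes chosen as desk-scale
study conditions: 16 sustained electrodes × 24 trials × 20 seeds for the
prediction-interval pattern (reproduced in 20/20 development runs at the
defaults); 349 electrodes × 50 NNMF replicates for classification and
transfer; 100 jittered-wave simulations at 10 ms timing jitter; 200 runs for
bootstrap calibration (Kolmogorov–Smirnov test of p-value uniformity); 100
null electrodes for the screen's false-positive rate. Passing these shows
the analysis code recovers what the generator plants and that its nulls are
calibrated — it cannot certify performance on real recordings, whose noise
is neither Gaussian-1/f nor stationary, whose electrodes mix archetypes, and
whose artifacts (epileptiform activity, movement, reference contamination)
are only crudely represented here.

## Known limitations

- The generator's theta dynamics are phenomenological (captured noisy phase
  oscillator), not a biophysical oscillator model; any mechanism with the
  same observable post-edge ITC behavior would be indistinguishable to these
  analyses.
- Edge detection assumes the envelope's rising slopes are its fastest
  positive derivatives; heavily co-articulated speech without amplitude
  troughs will defeat the slope-quantile rule.
- The bias threshold of 10 is meaningful only under this package's H
  max-normalization; with other normalizations it must be recalibrated.
- EDF/BrainVision ingestion, surface reconstruction, electrode localization
  and cortical surface mapping are out of scope.
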