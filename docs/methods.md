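# Methods

## Signal model

A recording is a 1- or 2-channel sampled voltage trace in arbitrary units
(full scale ±1), AC-coupled, with a stimulus-marker log in seconds.
Default study conditions throughout: 10 kHz sampling, 120 s duration,
stimulus onset at 30 s, stimulus duration 3 s (the midpoint of the 2–4 s
flame application window).

### Waveforms

Wound and action potentials are modelled phenomenologically as double
exponentials `w(t) = exp(−t/τ_d) − exp(−t/τ_r)` (unit peak, zero before
onset); no ion-channel or cable-equation biophysics is attempted.

- **Wound potential**: τ_r = 0.4 s, τ_d = 8 s; onset latency drawn
  uniformly from 3–6 s after stimulus onset; polarity ±1 with equal
  probability unless pinned (recorded polarity depends on electrode
  placement and is not interpreted).
- **Action potential** (flytrap, mimosa): parameterised by total duration
  `D` with τ_r = D/8, τ_d = D/3, latency 0.5–1.5 s after the tactile
  stimulus. Defaults: flytrap 2.0 s, mimosa 2.5 s (mid-range of the fast
  1–3 s class; a "slow" mimosa preset uses 8 s). Durations near 1.5 s were
  avoided for the default presets because the resulting half-prominence
  width sits exactly on the 0.5 s fast-spike rejection boundary.

### Amplifier

Causal Butterworth band-pass, implemented as cascaded order-2 high-pass and
low-pass SOS sections (a joint band-pass design at a 0.07 Hz / 10 kHz corner
ratio is numerically ill-conditioned). Causality matters: zero-phase
filtering would smear a response acausally several seconds before its own
onset and destroy stimulus-locked latency semantics. Single-channel band
0.07–8.8 Hz (gain 72), two-channel band 0.2–130 Hz (gain 55). Gains are
informational only — amplitudes stay in normalised units.

The generator synthesizes 25 s of real padding signal beyond each end and
trims it after filtering, so sub-Hz corner transients never contaminate the
recording. The embedded waveform is rescaled *after* filtering so that the
preset amplitude is the recorded-trace peak; amplitude / white-noise sd is
therefore the trace SNR by construction.

### Noise

White noise (parameterised by its post-amplifier, in-band sd; the raw
broadband input is scaled by the filter's measured white-noise gain),
sinusoidal drift (default period 50 s), and mains hum (50 Hz). Defaults:
single-channel white sd 0.02 (so the default responsive presets have
SNR 25; the cohort generator requirement is SNR ≥ 10), two-channel white sd
0.002 (a cleaner rig; peak-lag timing is jitter-sensitive at the tomato
speed of 9 mm/s). What the generator does *not* emulate: movement
artifacts correlated with the stimulus, non-stationary baseline wander,
plant-to-plant amplitude variability, and multi-peak responses — so green
tests demonstrate correctness of the pipeline's logic on its assumed signal
model, not performance on arbitrary real recordings.

## Detection

The 75 % criterion is evaluated on the baseline-subtracted raw trace
(before any normalisation): with pre-stimulus range `(lo, hi)` over a 30 s
window and `R = hi − lo`, responsive ⇔ some sample in the 60 s response
window is `> hi + 0.75 R` or `< lo − 0.75 R` (strict inequalities). The
baseline statistic is the pre-stimulus *median* (robust to pre-stimulus
artifacts). Degenerate flat baselines are widened to a configurable range
floor (10⁻⁴ full scale) and flagged, so a perfectly quiet trace cannot be
trivially responsive to quantization noise. Onset latency is the first
crossing; with the default presets the crossing bias is ≈ 0.1–0.2 s
(the rise must climb from onset to the criterion level), well inside the
0.5 s recovery tolerance. Epochs are built from the global extremum
(sign-invert if negative → normalise to unit peak → align at −10 s/+60 s
around the peak, zero-padded and flagged at recording bounds).

Multiple stimulations per recording yield one result per stimulus-on
marker; a recording is responsive if any trial is.

## Artifact rejection

Three trace-level filters produce machine-readable reports
(accepted ⇔ no reasons):

1. **fast_spike** — any prominent excursion with half-prominence width
   < 0.5 s.
2. **clipping** — ≥ 50 ms of samples within 1 % of ±1 full scale.
3. **elevated_baseline** — an excursion whose preceding 5 s rolling-median
   baseline magnitude exceeds 75 % of the trace extremum. The baseline is
   evaluated on the window *before* each excursion because a genuine
   seconds-scale response raises a centred rolling median at its own peak;
   this interpretation choice is recorded in the report notes.

Excursion detection works on the residual against a 20 s rolling-median
baseline — deliberately much longer than any response, so a response
cannot pollute its own baseline (a centred 5 s median is biased by an
upcoming response ~3 robust sigmas before onset, which would let ordinary
noise dips register as spikes). Candidate peaks are found with
`scipy.signal.find_peaks` on a 4 Hz-smoothed residual using height *and
prominence* thresholds of 5 robust sigmas (scaled MAD, estimated on the
pre-stimulus residual only); prominence rejects noise tips riding on the
shoulders of genuine slow structure. Narrow candidates must additionally
stand out in a second residual taken against a 1 s rolling median (twice
the fast-spike bound: real sub-half-second transients pass it exactly,
slow structure and its tracking error vanish), and every candidate must
clear the threshold in unsmoothed robust sigmas as well, which keeps the
detector calibrated on broadband inputs. Widths are then measured on the
raw residual by walking from the peak to the first *sustained* (100 ms)
half-prominence crossing with linear interpolation — exact on clean
monotone excursions, robust to momentary noise dips inside wide ones.
Spikes within 1 s of the recording edges are ignored (the rolling baseline
is one-sided there). The rolling median itself is evaluated on a coarse
grid (window/200) and linearly interpolated, keeping cost independent of
the sampling rate.

These choices were fixed by design analysis of the detection problem: at
10 kHz × 120 s a literal per-sample 5-sigma rule fires on pure in-band
Gaussian noise several times per few dozen traces, which is incompatible
with a zero-false-rejection specificity target.

### Injected artifacts (for sensitivity testing)

`fast_spike`: Gaussian transient, half-prominence width 50–300 ms,
amplitude 10× the trace sd capped so the trace stays inside full scale.
`clipping`: 300 ms pinned at ±1. `baseline_jump`: a sustained step of 5×
the pre-injection extremum starting in the first fifth of the recording;
the factor follows from the rule's geometry — a response of amplitude `p`
on a step `S` satisfies `S > 0.75 (S + p)` only when `S > 3p` — and the
step may legitimately co-trigger the clipping rule when it leaves full
scale.

## Conduction velocity

Both channels must individually pass the response criterion; the lag is
the channel-2 minus channel-1 extremum time inside the response window,
after identical gentle zero-phase smoothing (0.5 Hz low-pass) of both
channels — smoothing suppresses broadband peak-position jitter and, being
the same linear filter on both channels, cannot bias the lag. A windowed
cross-correlation argmax is available as an alternative method. Velocity
is separation / |lag| with direction from the lag sign;
`quantization_bound_mm_s = d·(1/|Δt| − 1/(|Δt| + T))` bounds the error
from one sample period `T` of lag error. Lags below one sample period are
refused as unresolvable. Two-channel generation delays channel 2 by an
integer number of samples, so noiseless recovery is exact to the bound by
construction.

Preset true velocities: sundew = the fixed series 2.2, 2.4, …, 4.2 mm/s
(11 recordings, mean exactly 3.2 mm/s); tomato 9 mm/s; mimosa 8 mm/s.
Default electrode separations 16–18 mm (the physical setup places wires
1–2 cm apart).

## Spectral behaviour of the amplifier model

The amplifier's suppression of out-of-band interference (50 Hz hum, slow
drift) is verified against a periodogram oracle. Note that total
out-of-band *power fraction* of a generated trace is not driven to zero:
a 2nd-order high-pass at 0.07 Hz attenuates the genuine sub-corner content
of an 8 s-decay wound potential by only ~80 % near the corner, and white
noise through any low-order Butterworth keeps a percent-level spectral
tail. The tests therefore assert the filter's attenuation behaviour
(tones, drift, band dominance) rather than an absolute out-of-band power
bound.

## Numerical and interface choices

- Integer WAV full scale maps to ±1; writing scales by 2¹⁵ with saturation
  at +2¹⁵−1, bounding the write→read round trip by one 16-bit step.
- Event files: `marker,time_s` CSV with `#` comments (default) or
  `time_s<TAB>marker` behind a dialect flag; logs are sorted and validated
  (every stimulus-off needs a preceding stimulus-on).
- Ties in |min| = |max| are not inverted; library SD uses the n−1
  denominator (zero for a single epoch).
- The "at least 10 peaks" library rule is implemented as ≥ 10 included
  peak-aligned epochs per species entry; too few epochs raise an explicit
  insufficient-peaks outcome rather than silently omitting the species.
- CLI exit codes: 0 success, 2 configuration error, 3 data error. All
  outputs are byte-deterministic for fixed inputs, config and seed.
- All randomness flows from one explicit integer seed per generator call;
  cohort and study helpers derive child seeds from a single parent seed.

## Problem sizes

Unit tests run the same presets re-rated to 1 kHz (band edges unchanged);
study-level checks use the full 10 kHz × 120 s conditions: a 16-species
cohort, 100 latency fixtures, 100 noise-only fixtures, 50 clean + 150
artifact-injected traces, and 21 two-channel recordings. The acceptance
script regenerates the 21 two-channel recordings per run.

## Known limitations

- Waveforms are monophasic and unimodal; multi-peak or oscillatory
  responses are not modelled, and the peak-lag method assumes a single
  dominant extremum per channel.
- The 75 % criterion's false-negative behaviour at low SNR is untested
  below SNR ≈ 10; near the criterion threshold the latency estimate is
  biased late by the rise time.
- Electrode separation is user-supplied; no attempt is made to infer
  geometry or propagation paths from more than two electrodes.
- Absolute calibration is out of scope end to end: nothing converts
  arbitrary units to millivolts.
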