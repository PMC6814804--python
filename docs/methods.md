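# Methods

This document describes the numerical methods implemented in `ephyskit`,
the synthetic generative model used for validation, and the rationale
behind the defaults. Conventions used throughout: time is in seconds
(float64), sample indices are 0-based, and every window `[t0, t1)` is
half-open — a sample or spike exactly at `t1` is excluded, one at `t0`
included. Signals are channels x samples in microvolts.

## File formats

**Raw recordings** are flat little-endian binary payloads (`.dat`),
sample-major (frame interleaved: all channels of sample 0, then sample 1,
…), either `int16` counts with a per-channel gain (µV/count) or `float32`
µV. A JSON sidecar header declares the format name/version, sampling rate,
sample count, encoding, unit and the channel list (label, optional 3-D
position in meters, group, gain). On open, the declared sample count is
checked against the payload byte size and a mismatch reports both numbers.
Reads are lazy (`numpy.memmap`); `read_raw_segment(rec, t0, t1)` returns
samples `[floor(t0*rate), floor(t1*rate))` converted to µV, so adjacent
windows tile the recording exactly.

**Events** are TSV tables with columns `label`, `kind` (`stimulus`,
`spike`, or `annotation`), `time_s`, `channel`, `cell`. Times are written
with `repr` precision so a round trip is exact to the double. Spike trains
use the label grammar `Spikes Channel <chan> |<cell>|`; within a series,
times are sorted and de-duplicated.

**LFP containers** are single files: an 8-byte magic (`EPHYSLFP`), a
version, a JSON metadata block (rate, channels, all event series, the full
provenance history, storage encoding and gains), then the sample-major
signal payload. When the source recording was int16, the container stores
int16 + gain as well — this is what preserves the ~30x size reduction of
30 kHz -> 1 kHz conversion (float32 storage would halve it); the cost is
quantization at gain/2 (~0.1 µV at the common 0.195 µV/count). Containers
created from float data store float32, for which the round-trip tolerance
is 1e-6 relative. `content_digest()` hashes the signal payload, events and
metadata but not the provenance timestamps; that digest is what
reproducibility guarantees are stated over.

## Synthetic ground truth

The generator exists so that every estimator can be validated against
known injected parameters; it does not aim at biophysical realism (no
conductance models, drift, or bursting).

- **Trials**: each of 8 direction conditions (`Stim On -3/4 pi` …
  `Stim On pi`) is repeated `n_repeats` times in seeded shuffled order on a
  regular grid (0.5 s stimulus, 1 s inter-trial interval by default).
- **Units**: spiking is an inhomogeneous Poisson process generated by
  thinning a candidate process at the tuning maximum. During a stimulus of
  direction θ the rate follows a von Mises profile
  `rate = base_rate * exp(kappa * (cos(theta - preferred) - 1))`; outside
  stimuli it is `base_rate`. Units with `phase_lock = (f, conc, phi0)` are
  further thinned with acceptance `exp(conc*(cos(2*pi*f*t - phi0) - 1))`,
  which concentrates spikes at phase `phi0` of the `cos(2*pi*f*t)`
  background oscillation without changing tuning.
- **Background**: per-channel Gaussian noise spectrally shaped to
  `1/f^exponent` (default exponent 1) and scaled to `noise_std` µV, plus
  shared sinusoids (`OscillationSpec`) with optional envelopes and
  per-channel gains — channels sharing a component are coherent at that
  frequency, which is how coherent channel blocks are built.
- **Spike waveforms**: a difference-of-Gaussians biphasic template (sharp
  trough at 35% of the 1.5 ms duration, slower rebound of 0.35 relative
  amplitude), peak amplitude defaulting to 5x the channel's background
  RMS. The lobes deliberately do not cancel: extracellular spikes have net
  area, so their spectrum extends to low frequencies — without this,
  spike contamination of the LFP band would be numerically absent and
  de-spiking would have nothing to remove.
- **Leakage**: each waveform is added at 0.3 gain to the next channel down
  the probe, reproducing the duplicate-unit scenario in which a spike
  sorter detects the same neuron on adjacent contacts (the basis of the
  noise-correlation duplicate flag).

## Filtering and preprocessing

All filters are symmetric (linear-phase) windowed-sinc FIRs designed with
a Kaiser window; the order comes from the requested transition width and
stop-band attenuation (default 60 dB), forced odd so every response type
is valid. Application is zero-phase: the signal is reflect-padded by one
filter length (so short epochs show no start-up transients), convolved
(`oaconvolve`, overlap-add) and the integer group delay compensated —
in-band sinusoids come out amplitude- and phase-preserved. A notch at `f0`
expands to a band-stop of `notch_bandwidth` (default 2 Hz) around `f0`.
Resampling is polyphase (`scipy.signal.resample_poly`) over the rational
rate ratio with output length `floor(n * out/in)`. Bad-channel/segment
masks drop channels and flag trials whose window intersects a bad segment;
touching at an endpoint is not an intersection (half-open convention).

## De-spiked LFP extraction

The converter removes spike transients, band-passes (default 0.5–150 Hz,
optional mains notch) and decimates to the target rate (default 1 kHz; the
raw rate must be an integer multiple — rational ratios are available via
the standalone resampler, but the converter keeps decimation exact).

De-spiking replaces a window (default −2 to +4 ms) around every sorted
spike of the channel's units; windows closer than a few samples are
merged, and samples outside the windows are returned bit-unchanged. Two
methods approximate published spectral de-spiking:

- **interpolate**: a cubic bridge through *locally averaged* flanking
  knots (3 knots per side, each a 3 ms mean of the original signal). A
  cubic through raw wideband flank samples chases high-frequency noise and
  can overshoot so badly that de-spiking hurts; averaging makes the bridge
  reconstruct only the LFP-band component.
- **spectral**: each window is replaced by a phase-randomized surrogate
  whose amplitude spectrum is the mean of the two flanking segments of the
  original signal. The DC bin (and the Nyquist bin for even lengths) keeps
  the *signed* mean of the flank spectra so the surrogate sits at the
  local signal level. The surrogate RNG is keyed on (seed, channel,
  absolute start sample), so results do not depend on block boundaries or
  processing order.

The band-pass, notch and (when needed) anti-alias low-pass at 0.45x the
target rate are combined into a single FIR. For recordings shorter than a
few filter lengths, transition bands are widened until the filter fits
(cap: a quarter of the recording); the cap depends only on the recording
length, preserving blockwise equality. Processing is blockwise with
overlapping context (filter half-length plus the de-spiking support), with
reflection only at the true recording edges, so peak memory follows the
configured budget while the output equals whole-file processing to
floating-point rounding (measured ~1e-15 relative; guaranteed 1e-6).

The validation criterion for de-spiking is functional: on synthetic
recordings with a phase-locked unit, the spike-field coherence at the
locking frequency computed from the de-spiked LFP must be at least as
close to the ground-truth SFC (computed from the contamination-free
background through the same chain) as the raw-LFP SFC, in ≥90% of seeded
replicates. Both methods pass at ~100%.

## Epoching

`import_epochs` cuts `[w0, w1)` windows around stimulus onsets: onset
sample `floor(t*rate)`, window samples `[onset + round(w0*rate), onset +
round(w1*rate))`, so all trials have identical length. Onsets whose full
window does not fit are dropped and counted. Spikes are re-expressed
relative to onset, keeping `[w0, w1)`. Baseline correction subtracts the
per-trial, per-channel baseline mean (`subtract_mean`) or also divides by
the baseline SD (`zscore`); zero-variance trials are flagged bad rather
than producing infinities.

## Spike metrics

- **PSTH**: `rate(bin) = total spikes / (n_good_trials * bin_width)`, so
  `sum(rate) * width * n_trials` equals the spike count exactly. The bin
  width must divide the window. Confidence bands are percentile bootstrap
  over trials (seeded).
- **Tuning curve**: mean spike count per condition in a count window
  (default the first 300 ms after onset), bootstrap CI per condition;
  `preferred_condition()` is the argmax.
- **Noise correlation**: per-unit trial-by-trial counts, each condition's
  mean subtracted per unit (signal correlation removed), residuals pooled
  and correlated (Pearson). Zero-variance units are excluded and reported;
  pairs with r above 0.8 are flagged as duplicate candidates. On the
  synthetic leaked-waveform pair this gives r ≈ 0.9; independent Poisson
  units at 500 trials stay within |r| < 0.1 for ~97% of pairs (the Pearson
  sampling SE at n=500 is ~0.045, so a small tail outside 0.1 is expected
  behavior, not an error).

## Spike-LFP measures

The **STA** is the mean LFP snippet (default ±150 ms) centered on each
spike, on every channel; spikes whose window does not fit are dropped (not
zero-padded) and counted. CI is a bootstrap over spikes.

**Spike-field coherence** uses the Fries estimator:
`SFC(f) = 100 * P_STA(f) / mean_i P_snippet_i(f)` with a single Hann taper
(periodic form) over the snippet window; frequency resolution is 1/window
(3.33 Hz at ±150 ms) and results are reported up to `max_freq` (default
50 Hz). Analytic identities used for validation: identical snippets give
exactly 100%; N spikes at independent uniform phases give 100/N % in
expectation; the estimator is invariant to rescaling the LFP. Values are
clipped to [0, 100] and the clip count reported; zero-power denominators
yield 0 and are counted separately.

## Spectral analysis

- **Welch PSD**: Hann windows (default 1 s, 50% overlap), density scaling
  — the integral over frequency recovers the variance (Parseval, within
  5% for broadband noise).
- **Morlet time-frequency**: complex Morlet wavelets with `cycles` cycles
  (default 7), `sigma_t = cycles / (2*pi*f)`, ±4σ support, zero-mean
  (no DC leakage) and unit energy; power is the squared magnitude of the
  convolution. Default grid: 40 log-spaced frequencies, 2–90 Hz.
  Frequencies at/above Nyquist or below one cycle per epoch are rejected.
  Baseline z-scoring standardizes each frequency row against a baseline
  period; zero-variance rows are zeroed and flagged.
- **N x N coherence**: `MSC(f) = |S_xy|^2 / (S_xx * S_yy)` from
  Welch-averaged cross-spectra. At least 2 averaging segments are required
  (one segment is degenerate at 1). Duplicated channels give exactly 1;
  dead (zero-power) channels give 0 off-diagonal; the matrix is symmetric
  with unit diagonal.

## Pipelines and provenance

A pipeline spec (YAML/JSON) is an ordered stage list plus a global seed,
optional input files and an output directory. `validate_spec` dry-runs the
dataflow (unknown operations, missing files, stages whose inputs no
earlier stage provides). Execution appends one provenance record per stage
(operation, input paths, parameters including the stage seed, UTC
timestamp) to `provenance.jsonl` and writes `digests.json` with SHA-256
digests of all TSV artifacts and the container content digest. Stage seeds
are `sha256("<seed>:<stage id>") mod 2^31`, so inserting a stage does not
shift the randomness of downstream stages. Identical spec + seed re-runs
produce identical digests; timestamps are excluded from digests because
wall-clock provenance is intentionally non-reproducible.

## Limitations

- The synthetic model validates estimator correctness, not biological
  claims: Poisson spiking, stationary 1/f noise and pure sinusoids omit
  refractoriness, bursting, drift, and non-stationary rhythms.
- Spike sorting is consumed, not performed; spike times are trusted.
- The converter requires an integer rate ratio; the Bayesian spectral
  de-spiking cited in the literature is approximated by the two methods
  above, with the functional SFC-fidelity criterion standing in for the
  original algorithm.
- int16 container storage quantizes at gain/2; use float32 sources when
  sub-0.1 µV fidelity matters.
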