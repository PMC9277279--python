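# Methods

## Overview

`quakecall` implements a before/after (BACI-style) analysis of blue whale
calling around earthquakes in single-channel hydrophone recordings. The
pipeline is: earthquake selection from a catalog → location of the
earthquake arrival and its relative received level in the audio → D-call
detection by spectrogram template correlation → song-intensity index →
paired before/after window metrics at four temporal scales → paired
t-tests, OLS models and a null-period control. Every stage runs on
synthetic recordings with known ground truth, which is how the package is
tested.

## Spectrograms and the dBFS reference

All measurements use a one-sided magnitude-squared STFT with the
upper-half spectrum folded in, so each column obeys Parseval against the
windowed frame energy. Named presets: `detection` (2048-sample Hann, 50 %
overlap — the working preset), `display` (90 % overlap) and `songfig`
(3072-point, 50 %). At 2 kHz the `detection` preset gives ~0.98 Hz bins
and a 0.512 s hop.

Received levels are relative (dBFS). Since only *differences* matter for a
before/after design, any fixed reference that preserves dB differences is
valid; we use the spectrogram energy of a full-scale DC signal occupying
the same selection duration, `E_ref = n_frames · n_fft · Σw²`. Two
consequences anchor the scale: a full-scale sine measured over the full
band is exactly −3.01 dBFS, and scaling a waveform by g shifts any
measurement by exactly 20·log₁₀ g. Values are ≤ 0 for any unclipped
signal. The proprietary "Energy" measurement this emulates is not publicly
documented; the chosen reference is the package's own convention.

## Earthquake arrival and extent

The arrival is searched in a ±120 s window around the catalog origin time:
1-s frames of 5–100 Hz band energy are thresholded at median + 5·MAD, with
an additional requirement that the peak frame rise ≥ 3 dB above the median
(the MAD criterion alone can fire on the tail of plain-noise fluctuations;
a real rumble exceeds 3 dB trivially). The event extent is the contiguous
run around the peak frame staying above max(noise threshold,
peak − 20 dB). Anchoring the run edges to the peak keeps the measured
duration — and therefore the duration-normalized received level — stable
under changes of event amplitude; with a noise-floor-only edge rule, a
louder event would recruit more decay-tail frames and bias its mean level
downward. All constants (`k_mad`, `min_rise_db`, `edge_drop_db`,
`search_pad_s`) are keyword arguments.

## D-call detector

Detection is multi-template normalized correlation on the `detection`
preset spectrogram. Templates are exemplar spectrogram patches, cropped to
the template band and normalized to zero mean / unit norm, which makes the
score a Pearson correlation in [−1, 1], invariant to call gain. The
shipped library holds 13 synthetic exemplars — durations
{1.5, 2, 2.5, 3} s × sweep ranges {100→20, 90→25, 80→30} Hz plus one
curvilinear 100→20 Hz sweep — and user exemplars are accepted. The per-lag
maximum over templates is thresholded (default 0.80) and collapsed to one
detection per local maximum with a 1 s minimum gap.

The template band is (30, 105) Hz. The floor sits deliberately *above* the
17–24 Hz song band: song chorus is pervasive in the synthetic scenarios
(as it is in recordings from an active breeding/foraging ground), and
including the chorus band in the correlation patch measurably degrades
both recall and precision. D-call sweeps still traverse most of the band;
the truncation of the final ~20→30 Hz of the deepest sweeps costs little
because the correlation is dominated by the sweep's shape, not its tail.

Detection timing resolution is one hop (0.512 s); on the standard fixture
the median start error is ~0.1 s because the winning lag centres the
template on the call. The detector is fully deterministic.

A `merge_annotations` operation represents the manual-review pass of a
human analyst (removals of false positives, additions of missed calls,
flagged `source="manual"`); no automatic reviewer is modelled.

## Song intensity index

Per 1-min bin (anchored at recording start, final partial bin dropped):
mean spectral power across bins inside 23–24 Hz divided by the mean of the
single bins nearest 11 and 39 Hz (equal weight; ±0.5 Hz background bands
are available via `background_halfwidth_hz`). Computed on linear power.
Under flat noise the expected index is ~1; it rises monotonically with
song amplitude and is exactly invariant to recording gain. Bins with zero
background power yield NaN with a warning.

## Catalog operations

Selection chain: magnitude strictly > 3.0, closed study box
(38–43° S, 172–176° E by default) and period; 8-h isolation with symmetric
exclusion (both members of a close pair are dropped; a gap of exactly 8 h
counts as isolated); stratified weekly sampling with 7-day strata anchored
at the period start, one uniform draw per non-empty stratum, remainder
filled without replacement. Distances are haversine on a sphere of radius
6371.0088 km — at regional scales the difference from an ellipsoidal
geodesic (< 0.5 %) is immaterial to the models, and the spherical form is
checkable against a closed form (R·π/180 ≈ 111.195 km per equatorial
degree).

## Windows, tests, models, nulls

Before window `[t_event − s·3600, t_event)`; after window anchored at the
*end* of the earthquake signal, `[t_end, t_end + s·3600)`, so the rumble's
own energy inflates neither side. Window membership of a detection is
decided by its midpoint on a half-open interval; metrics at smaller scales
are exact sub-windowings of the largest-scale extraction (asserted in
tests). Mean RL averages dB values directly; a window with zero calls has
undefined mean RL, and such pairs are dropped for the RL t-test only.

Paired t-tests are two-sided on after − before differences pooled over
(event, station) pairs, df = n − 1; zero-variance differences with nonzero
mean raise a degenerate-input error rather than returning an infinite
statistic. OLS models (statsmodels) regress each Δmetric on earthquake
covariates plus prior metric, day of year (plain linear term) and station
as a dummy-coded factor against the lexicographically first station; a
`context_only` predictor set drops the earthquake covariates. Rank
deficiency is detected before fitting and reported with the collinear
terms named. No multiple-testing correction is applied; tests per
metric/scale are reported raw.

Null periods: one per earthquake, candidate at origin − 24 h, shifted
earlier in seeded whole-hour steps until no catalog event lies within
±8 h and the windows fit the recording. Null windows are verified to
contain no catalog earthquake. The 24-h offset keeps nulls comparable in
diel phase and season; it is configurable because the placement rule is a
design choice, not a measurement.

## Synthetic data: what it emulates and what it does not

The generator states a world matching the study design: 2 kHz mono
recordings on the ±1 full-scale convention (written as 16-bit PCM; the
dBFS reference is pre-quantization); D calls as a Poisson process (default
shape: 2-s logarithmic 100→20 Hz downsweep, 10 % cosine taper; durations
and sweep law for this population are not published, so these defaults are
configurable); song units of three 2-s AM pulses plus a 4-s tonal at
23.5 Hz tiled at a regular interval (structure is documented for this
song type, timings are not); earthquake rumbles as 5–100 Hz noise bursts
≤ 60 s with fast onset and exponential decay; Gaussian background noise.
A rate/gain switch at the first quake time creates configurable
before/after effects. Catalogs contain isolated events (pairwise ≥ 8 h)
and swarm clusters (< 8 h span) with magnitudes uniform on [3.0, 4.5].

Not emulated: propagation/transmission loss, whale movement, diel and
seasonal calling cycles, instrument self-noise spectra, overlapping-call
masking statistics of real choruses, or realistic seismo-acoustic
waveforms (T-phases, dispersion). A green detector test therefore
establishes correctness of the template-correlation machinery and its
calibration on calls of the stated shape and SNR — not field performance
on real recordings.

## Statistical calibration at reduced scale

Rendering 50 replicates × 32 events × hours of audio through the detector
would take orders of magnitude longer than a test budget allows. The
type-I-error and power calibrations therefore draw per-window counts
directly from the generator's Poisson arrival law (`simulate_window_counts`
— identical in distribution to counting the rendered arrivals in the
paired windows) and push them through the real paired-t machinery. The
detector's fidelity is established separately on the rendered standard
fixture. The end-to-end audio path (generation → detection → windows →
t-tests → nulls) is exercised on a shortened two-earthquake scenario with
sub-hour window scales.

## Known limitations

- OLS with station as a fixed factor inherits the original design's
  pseudo-replication across stations; mixed-effects or
  autocorrelation-aware models are out of scope.
- The detector's scores are computed on power spectrograms without
  per-band noise equalization; strongly coloured noise would shift the
  score distribution (the 0.80 threshold is a tunable).
- Null-period placement and the isolation boundary (exact 8-h gaps count
  as isolated) are conventions where the underlying design is silent.
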