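# quakecall

Do blue whales change their calling behaviour after earthquakes?
`quakecall` is a tested Python re-implementation of the passive-acoustic
analysis needed to ask that question: it detects blue whale D calls
(downswept social calls, ~100→20 Hz) by spectrogram template correlation,
summarizes song chorus with a band-energy-ratio intensity index, selects
analysable earthquakes from a seismic catalog, and compares calling metrics
in paired windows before and after each event — including the null-period
control that separates genuine disturbance responses from the
regression-to-the-mean artifact. Because raw multi-month hydrophone
recordings are rarely redistributable, the package ships a synthetic-data
module that generates recordings with known ground truth, so every stage is
validated end to end without any download.

It is aimed at bioacousticians and marine-mammal ecologists who want a
scriptable, reproducible version of a workflow usually spread across Raven
Pro selections, R scripts and spreadsheets.

## The method

For each earthquake *e* and hydrophone *h*, calling metrics
(D-call count *N*, mean received level RL in dBFS, mean song intensity *S*)
are computed in paired windows before and after the event at scales
*s* ∈ {4, 3, 2, 1} h:

- **Detection.** The D-call detector slides 13 normalized time–frequency
  templates over the spectrogram (2048-sample Hann window, 50 % overlap);
  at each lag the score is the Pearson correlation r ∈ [−1, 1] between the
  flattened template and the band-cropped spectrogram patch, and the
  per-lag maximum over templates is thresholded at 0.80.
- **Song intensity.** S = P̄(23–24 Hz) / P̄({11, 39} Hz) per 1-min bin — a
  chorus-level proxy that is invariant to recording gain.
- **Received level.** Relative energy in dBFS: 10·log₁₀(E_sel / E_ref)
  with E_ref the spectrogram energy of a full-scale DC signal over the same
  duration, so a full-scale sine measures −3.01 dBFS and a gain g shifts
  any measurement by exactly 20·log₁₀ g.
- **Inference.** Paired t-tests on after − before differences pooled over
  (event, station) pairs; OLS models
  Δmetric ~ depth + magnitude + distance + RL + prior metric + day-of-year
  + factor(station); and for every earthquake an earthquake-free *null*
  timestamp analysed identically. With independent before/after metrics the
  regression of Δ on the prior value has slope ρ − 1 (ρ = before/after
  correlation), i.e. −1 under independence — so a negative prior-calling
  relationship that also appears in the nulls is calling context, not an
  earthquake effect.

## Worked example

```bash
python examples/02_detect_dcalls.py
```

```
50 injected D calls, 50 detections
recall    1.00
precision 1.00

first detections (start s, score, received level dBFS):
 start_s  score  rl_dbfs
   80.90   0.84   -16.70
  129.54   0.84   -17.61
  250.88   0.98   -16.86
```

The script builds a 2-h synthetic scenario (Poisson D calls at 25/h over
song chorus and noise, seed 7), runs the 13-template detector at threshold
0.80 and scores it against the ground truth: every injected call is
recovered with no false positives, and each detection carries its
correlation score and relative received level.

```bash
python examples/06_regression_to_the_mean.py
```

```
earthquake: slope = -1.030  95% CI [-1.072, -0.987]  p = 0.00e+00
null      : slope = -1.062  95% CI [-1.106, -1.018]  p = 0.00e+00
```

With i.i.d. before/after counts and *no* effect of any kind, the change
regressed on the prior count has slope −1 for "earthquake" and "null"
events alike — the statistical artifact the null-period control is designed
to expose.

The other examples cover scenario generation (`01`), song intensity
(`03`), catalog selection (`04`) and the full pipeline with paired t-tests
and null periods (`05`).

## Acceptance script

```bash
python scripts/acceptance.py --seed 1 --out results/acceptance.json
```

recomputes the package's end-to-end analysis from scratch: it generates a
seeded synthetic scenario with two earthquakes, runs catalog selection,
detection, song-intensity computation, windowed metrics, the null-period
control and the paired t-tests, and writes the results JSON to `--out`.
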