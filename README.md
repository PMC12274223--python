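# atas — automatic temporal analysis of speech

`atas` detects **pause** and **vocal** events in continuous-speech recordings
(oral reading) and turns them into temporal fluency metrics that separate
adults who stutter (AWS) from adults who do not (AWNS). It is aimed at
speech-language researchers and clinicians who want an objective, instrumental
complement to listener-based stuttering assessment.

## The method

A recording is denoised (spectral gating, so true silence comes back as exact
zeros), trimmed, and peak-normalized. The detector then:

1. cuts the signal blindly into non-overlapping 3-s segments;
2. computes short-time root-mean-square energy and zero-crossing rate in
   50-ms windows advanced by 1 ms,

   E_rms = sqrt(mean of x[n]² over the window),
   ZCR = #{n : sign(x[n]) ≠ sign(x[n−1])};

3. labels each frame **non-silent** when its RMSE exceeds the segment's mean
   RMSE *and* its ZCR is non-zero, **silent** when its RMSE is below the mean
   *and* its ZCR is zero (ambiguous frames resolve by the ZCR criterion
   alone, since zero ZCR is the signature of gated silence);
4. run-length encodes labels into regions and applies temporal thresholds:
   silent regions ≥ 50 ms become **pause events**, non-silent regions
   > 100 ms become **vocal events**, shorter regions are absorbed into the
   running event;
5. splits pauses into **short** (50–150 ms) and **long** (> 150 ms).

From the event sequence and the passage word count (236 for the standard
oral-reading passage) it computes 13 metrics: speech rate (words/min), total
pause time, pause count, mean pause/vocal duration, pause/vocal duration
variability (coefficients of variation), and the long/short-pause variants.

On top sit the cohort layers: per-metric GLMs (Gaussian / weighted Gaussian /
weighted gamma / negative binomial, chosen by Shapiro–Wilk, Breusch–Pagan and
overdispersion checks) with group + sex + age predictors and
Benjamini–Hochberg FDR control at q = 0.1; Pearson correlations with percent
syllables stuttered (%SS); and AWS/AWNS classifiers (decision tree on all 13
metrics, random forest on the 7 group-separating metrics, and a sequence
classifier on windows of 20 consecutive events × 9 features).

Synthetic generators (`atas.simulate`) produce utterance audio with exact
ground-truth annotations and cohort tables with the study's group structure,
so the entire pipeline is testable without any recordings.

## Worked example

```python
import numpy as np
from atas import (UtteranceSpec, make_synthetic_utterance, reduce_noise,
                  detect_events, compute_metrics)

# 5 voiced bursts of 600 ms separated by 300-ms silences, light ambient noise
spec = UtteranceSpec(
    intervals=tuple([("voiced", 600.0), ("silent", 300.0)] * 4 + [("voiced", 600.0)]),
    voiced_amplitude=0.6, ambient_noise_amplitude=0.03, seed=7)
audio, truth = make_synthetic_utterance(spec)

events = detect_events(reduce_noise(audio))
print(len(events.vocals()), "vocal,", len(events.pauses()), "pause events")
ms = compute_metrics(events, word_count=236)
print(f"total pause time {ms.total_pause_time_s:.2f} s, "
      f"mean pause {ms.mean_pause_ms:.0f} ms, speech rate {ms.speech_rate_wpm:.1f} wpm")
```

prints

```
5 vocal, 4 pause events
total pause time 1.18 s, mean pause 296 ms, speech rate 3371.4 wpm
```

All 4 pauses are recovered as long pauses within a few milliseconds of their
true 300-ms durations (the gate trims the edges slightly); the absurd speech
rate simply reflects pretending a 4.2-s tone fixture contains a 236-word
passage — on real recordings the denominator is the full trimmed reading
time.

The same flow is available from the shell:

```sh
atas simulate utterance --seed 7 -o fixture.wav --truth truth.csv
atas preprocess fixture.wav -o clean.wav
atas detect clean.wav -o events.csv --plot events.png
atas metrics events.csv --words 236 -o metrics.csv
atas compare metrics.csv covariates.csv --fdr 0.1 -o results/
atas classify metrics.csv covariates.csv --model forest --seed 0 -o report/
```

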