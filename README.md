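# tonecortex

Encoding and decoding of Mandarin lexical tone from cortical high-gamma
activity — a tested, reusable implementation of the full analysis chain,
runnable end-to-end on synthetic data with known ground truth.

## The problem

Mandarin distinguishes word meanings by four pitch patterns on the syllable
(lexical tones: T1 high-level, T2 mid-rising, T3 low-dipping, T4
high-falling). Different speakers realize the same tone at very different
absolute pitches, so the cortex must extract *speaker-normalized* pitch —
relative pitch height (log-F0 z-scored within a speaker's sentence) and
pitch change (the local slope of log-F0) — to identify tones. The analyses
here ask, for electrocorticographic (ECoG) high-gamma recordings over the
superior temporal gyrus:

1. which acoustic features each electrode encodes (lagged linear *temporal
   receptive field* models with unique-variance attribution),
2. which electrodes respond to speech and discriminate tones (calibrated
   detectors), how they are tuned (tuning curves, linearity), and
3. whether the electrode population carries a *categorical* tone code
   (group-lasso decoding and a representational-similarity categorical
   index).

The package is aimed at researchers in auditory/speech neuroscience who
want these methods as library functions with a synthetic-data harness,
since the original patient recordings are not publicly downloadable.

## Core models

**Encoding (TRF).** For electrode response y(t) and stimulus feature sets
x_f (spectrum, intensity, absolute pitch, relative pitch, pitch change,
tone category — the pitch features one-hot binned into 10 bins between
their 2.5th and 97.5th percentiles):

    y(t) = Σ_f Σ_{τ=0}^{T} β_f(τ)ᵀ x_f(t − τ) + ε

fit by ridge regression on contiguous 80/10/10 splits rotated five times.
The unique contribution of a feature set is the drop in held-out R² when it
is removed; significance comes from shuffling the features between phrases
(speech runs bounded by ≥150 ms silence) 200 times and thresholding at the
null's 99th percentile.

**Tuning.** Linearity of an electrode's pitch tuning is the Fisher
transform L = ½ ln((1+r)/(1−r)) of the correlation r between binned feature
value and mean high-gamma.

**Decoding.** Pairwise tone classification by logistic regression with a
group-lasso penalty across electrodes, λ Σ_e ‖w_e‖₂, over 50 ms sliding
windows with nested (5-fold / 10-fold) cross-validation. Categorical
structure is the categorical index CI = mean between-tone − mean
within-tone pairwise accuracy over a 16-group partition (4 tones × 4
quartiles of mean pitch height or change), tested by label permutation.

## Worked example

Simulate a two-minute tonal corpus, one electrode driven only by
speaker-normalized pitch at signal-to-noise 1, and attribute its variance:

```python
import numpy as np
from tonecortex import synth, features as feat, trf

stim = synth.make_stimulus(n_sentences=60, seed=42)
f = feat.build_stimulus_features(stim, seed=0)
full = ["intensity", "rel_pitch", "pitch_change"]
truth = synth.random_truth(f.set_dims(full), [["rel_pitch", "pitch_change"]],
                           n_lags=15, seed=1, noise_sd=1.0)
rec = synth.make_neural(stim, f, truth, seed=2, noise_relative=True)
d = trf.unique_variance(rec.high_gamma[0], f, full,
                        [["rel_pitch", "pitch_change"]],
                        max_lag=15, n_perm=100, seed=3)[0]
probe = "rel_pitch+pitch_change"
print("full model R^2:          %.3f" % d.full_r2)
print("unique R^2:              %.3f" % d.unique_r2[probe])
print("99th pct of null:        %.4f" % d.p_threshold_value[probe])
print("significant:             %s" % d.significant[probe])
```

prints

```
full model R^2:          0.490
unique R^2:              0.300
99th pct of null:        0.0123
significant:             True
```

The full model explains 49% of the held-out variance; removing the
speaker-normalized pitch features costs 30 percentage points of R², far
above the 1.2% that phrase-shuffled surrogates reach — the electrode's
pitch encoding is detected, as planted.

The whole study (stimulus → features → simulated electrodes → detectors →
unique variance → decoding/RSA) also runs as a pipeline:

```bash
tonecortex all --seed 1 --out run/    # JSON report in run/report.json
```

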