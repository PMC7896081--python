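# Methods

`tonecortex` re-implements, as a tested pipeline on synthetic data, a full
analysis of how non-primary auditory cortex encodes Mandarin lexical tone:
from pitch features of continuous speech, through per-electrode temporal
receptive field (TRF) encoding models with unique-variance attribution, to
population-level tone decoding and a representational-similarity test of
categorical structure. This note records the models, the choices that were
genuinely open, and what the synthetic experiments do and do not show.

## Stimulus model (synthetic corpus)

The generator emulates a continuous-speech corpus read by ten speakers
(five female, five male). Sentences of 3–8 syllables (default ~250 ms each,
±15% duration jitter, vowel onset at 20% of the syllable) are separated by
0.5 s silences, so each sentence is also a *phrase* in the sense used by the
permutation machinery (a speech run bounded by ≥150 ms of silence). Each
syllable carries one of the four lexical tones — T1 high-level, T2
mid-rising, T3 low-dipping, T4 high-falling — drawn from a balanced,
shuffled deck.

Voiced log-F0 of a syllable is

    log F0(t) = b_s + sigma_s * c_tone(t/T) + eta(t)

with speaker baseline `b_s` (log-spaced 180–260 Hz for female, 100–140 Hz
for male voices), speaker range `sigma_s = 0.2` log-units, a tone-contour
template `c_tone` time-scaled to the vowel, and smooth within-tone noise
`eta` (Gaussian noise low-pass filtered with a 30 ms kernel, SD 0.15
contour units). The templates satisfy the canonical ordering: T3 has the
lowest minimum, T4 the steepest fall. Within-tone contour variance in real
corpora is not quantified by a single published number; `contour_sd` is
therefore an exposed parameter, defaulted once to a value that makes the
four tones clearly but not trivially separable in the acoustic space.

The non-tonal ("English-like") stimulus uses the same machinery with no
tone labels, longer sentences (6–12 syllables), and smooth random
intonation contours whose dispersion is `range_scale` (default 0.6) times
the pooled dispersion of the tone templates — a narrower pitch dynamic
range, as a non-tonal language presents.

Spectrum features are not synthesized from audio: a 30-dimensional smooth
random field gated by the intensity envelope stands in for the mel
filterbank output. This preserves the timing structure that matters to the
lagged models while making no claim about spectral realism.

## Neural model

Simulated electrodes respond as the generative counterpart of the TRF:

    y(t) = sum_f sum_tau  w_f(tau)^T x_f(t - tau)
         + g_cat * p_tone * boxcar(vowel)  + g_on * k(t - t_onset)  + noise

with smooth random weight matrices `w_f` over the assigned feature sets, an
optional categorical component (a per-tone amplitude `p_tone` over the
vowel, scaled by `g_cat` — the ground-truth categorical population for the
representational analysis), an optional speech-onset transient, and
Gaussian noise. `noise_relative=True` sets the noise SD per electrode as a
multiple of its clean-signal SD, so `noise_sd = 1` means noise power equals
signal power. Responses are z-scored per recording block (default 60 s
blocks), like real high-gamma.

High-gamma extraction from broadband voltage follows the standard recipe:
eight Gaussian bands with log-spaced centers covering 70–150 Hz, analytic
amplitude per band via the one-sided-spectrum (Hilbert) transform, average
over bands, anti-aliased resampling to 100 Hz, z-score per block. The
Gaussian bandwidths are a constant-Q choice (sigma = 0.1 x center
frequency); only the endpoints and band count are pinned by convention, so
the bandwidth is a documented default, not a claim.

## Pitch features

Absolute pitch is ln F0 (Hz). Relative pitch is ln F0 z-scored over the
voiced frames of each sentence/passage of one speaker — the speaker-
normalized pitch height. Pitch change is the first difference of ln F0
within contiguous voiced runs; the first frame of a run has no predecessor
and is treated as undefined for this feature only. Each of the three is
discretized into a 10-dimensional one-hot vector: bins equally spaced
between the 2.5th and 97.5th percentile, tails clipped into the end bins,
all-zero on unvoiced frames. Percentile edges are computed over the whole
corpus (all speakers pooled) so that train/test folds and both languages
share one feature space; per-block edges would make transfer analyses
ill-defined. When two stimuli must share a space (cross-language transfer),
the second build reuses the first build's edges, and the transfer routine
refuses mismatched edges.

The tone-contour PCA linearly resamples each token's voiced relative-pitch
contour to 25 points (250 ms at 100 Hz), centers the token × time matrix,
and decomposes it by SVD (X = L Wᵀ with orthonormal W). Linear
interpolation is the simplest resampling consistent with uniform
time-warping.

## TRF fitting and unique variance

The encoding model is ridge regression on a lagged design matrix: columns
ordered (feature set, dimension, lag), lags 0..T−1 with zero-padded
history, default T = 40 frames (400 ms), configurable. Data are split into
contiguous 80/10/10 train/tune/test partitions; the time axis is cut into
10 contiguous chunks and rotated across 5 repetitions (tune chunk 2r, test
chunk 2r+1). Contiguous splits are deliberate: random-frame CV leaks
through the autocorrelation of both stimulus and response. The ridge
penalty is chosen per repetition on the tuning set from 8 log-spaced values
spanning six orders of magnitude (ties toward stronger regularization);
reported performance is the mean held-out correlation (and its square) over
repetitions; reported weights are the mean over repetitions. R² is the
squared held-out correlation, so differences of R² (unique R²) can be
slightly negative — that is expected behavior, not an error.

Unique variance of a probe set (e.g. the speaker-normalized pair
{relative pitch, pitch change}) is full-model R² minus the R² of a model
refit without that set under identical splits. Significance uses a
phrase-shuffle null: the per-phrase segments of all stimulus features are
re-concatenated in a random order into the speech-frame positions (silences
untouched), the whole fit is repeated, and the observed unique R² is
compared with the 99th percentile of 200 shuffles. Because all electrodes
share the stimulus, each shuffled design matrix is factored once
(eigendecomposition of the training Gram matrix) and reused across
electrodes and the whole ridge path; this is what makes a 200-shuffle null
tractable on one CPU. Inside the null, one CV rotation per shuffle is used
by default (`n_reps_null=1`): the null needs the spread of unique R² under
misalignment, not its five-fold average; the observed statistic always uses
the full rotation scheme.

## Electrode statistics

*Speech-responsive*: per electrode, mean high-gamma 100–400 ms after speech
onset (allowing ~100 ms neural delay) is paired with the −250..50 ms
pre-onset mean across events; two-sided paired t-test, Bonferroni-corrected
over electrodes at p < 0.01. The mirrored comparison at speech offsets
(elevated before, dropped after, using the same two windows around the
offset) catches sustained responders without onset transients. Electrodes
with fewer than five usable events are marked untestable.

*Tone-discriminant*: one-way F across the four tones at every timepoint of
vowel-aligned epochs (canonically −200..1000 ms, 120 points), two-sided
p < 0.05 Bonferroni-corrected over electrodes × timepoints, requiring at
least three consecutive significant points. Correction denominators are
logged with each run.

*Tuning curves*: the electrode's high-gamma, shifted back by a configurable
neural delay (default 100 ms), is binned by relative pitch height or pitch
change into 20 uniform bins over the feature's middle 95-percentile range;
frames outside that range are excluded. Modulation depth is the range of
the bin means. Linearity is L = ½ ln((1+r)/(1−r)) where r is the Pearson
correlation between bin value and mean high-gamma over occupied bins,
unweighted by occupancy (weighting is not pinned down by convention; the
unweighted choice is documented here). The field sometimes labels L a
transformation "of the slope"; r is what the transform is applied to.

*Temporal profiles*: mean |weight| per lag over a feature set's dimensions,
contrasted between electrode groups lag-by-lag with a two-sided
Mann-Whitney U and Benjamini-Hochberg correction at α = 0.05; the contrast
is skipped for single-electrode groups.

## Population decoding and representational analysis

Pairwise tone classification uses logistic regression with a group-lasso
penalty whose groups are electrodes: the objective is mean logistic loss
plus λ Σₑ‖wₑ‖₂ over each electrode's five temporal coefficients, minimized
by monotone FISTA (proximal gradient with momentum, a fixed step from the
spectral norm of the intercept-augmented design, and a descent safeguard,
so the objective is non-increasing by construction; KKT residuals are
reported at exit). λ ≥ λ_max = maxₑ‖∇ₑ‖ at zero provably zeroes every
group, which the block soft-threshold reproduces exactly.

Accuracy comes from nested CV: stratified outer 5-fold for accuracy, inner
10-fold over a λ grid (10 log-spaced values anchored at λ_max of the
standardized data; ties toward the sparser model); features standardized on
each training fold; the larger class subsampled to the smaller so chance is
exactly 0.5. A 50 ms sliding window (five frames, stride 1) over
vowel-aligned epochs yields the accuracy time course; the peak of the
six-pair mean is the headline accuracy. The acoustic baseline applies the
same machinery to the full 25-point × 2-feature warped contour (time points
as penalty groups). Decoding gain over the acoustic space is reported as
the percent change of over-chance accuracy, ((Q_neural−0.5)−(Q_aco−0.5))
/(Q_aco−0.5)×100.

For the representational analysis, syllables are partitioned into 16 groups
— within each tone, quartiles of the token's mean relative pitch height or
mean pitch change (sizes within a tone differ by at most one; ties broken
by stable token order). The "PC1/PC2" labels sometimes attached to these
partition axes are implemented as the raw mean feature values; a PCA-score
partition is available as an option. All 120 group pairs are classified at
the peak decoding window; the categorical index is

    CI = mean(between-tone accuracy) − mean(within-tone accuracy),

tested against a null that shuffles group labels over tokens and reruns the
identical procedure 200 times (significant above the 95th percentile).
Inside the RDM the classifier runs with a fixed small λ and reduced
iteration budget; with ~16 tokens per pair there is nothing for the inner
CV to resolve, and the permutation loop multiplies every cost by 200.

Ablation reruns the sliding decode on the complement of a selector (e.g.
electrodes with strongly negative linearity) and compares peak accuracies
by bootstrapping the per-trial cross-validated correctness (200 resamples).

## What the synthetic experiments show — and what they do not

The generator gives every downstream stage a ground truth: weight recovery
can be scored against the generating weights, detector calibration against
pure-noise electrodes, attribution against the known feature assignment,
and the categorical-index contrast against populations built to be
categorical (tone-indicator responses) or veridical (responses linear in
the continuous feature). Passing these tests shows the *machinery* is
correct and calibrated at realistic SNR and data sizes. It does not show
that cortex behaves this way: the synthetic data are linear, stationary,
and Gaussian; real high-gamma has adaptation, correlated noise across
electrodes, non-Gaussian tails, and stimulus correlations (e.g. between
intensity and voicing) stronger than the generator's. Conclusions about
real cortex rest on the original recordings, not on these simulations.

Problem sizes used by the shipped test suite and the acceptance script are
the package's own desk-scale choices: ~10 minutes of stimulus for weight
recovery at signal-to-noise 1, ~4 minutes for the 20-electrode attribution
experiment with a 100-shuffle null, 200 null electrodes for detector
calibration, 96 tokens in 16 groups for the categorical-index contrasts,
and 20 electrodes for the cross-regime transfer test. The mixed population
used for the ablation experiment is constructed so that the negatively
tuned electrodes carry mostly between-tone information (between-tone
separation of the continuous value dominating its within-tone spread) and
the categorical electrodes alone do not saturate accuracy; at a saturated
operating point an ablation cannot reduce anything, and a population whose
linear electrodes mainly separate within-tone quartiles would *raise* CI
when ablated — the opposite of the regime the analysis is about.

## Degenerate inputs and numerical conventions

- Constant or flat channels z-score to exact zeros with a warning (scale-
  aware variance test), rather than NaNs.
- A constant pitch feature widens its bin range symmetrically so all frames
  share one middle bin.
- Correlations of degenerate (zero-variance) vectors are reported as 0.
- Identical PCA contours report zero explained variance (float residue of
  centering is thresholded away).
- Tuning-curve r is clipped away from ±1 before the Fisher transform.
- All intervals are half-open, 0-based, frame units at 100 Hz; tables carry
  seconds, and seconds × 100 round exactly to frames.
- One global seed fans out to per-stage child seeds via SHA-256, all below
  2³¹, so partial reruns are reproducible.
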