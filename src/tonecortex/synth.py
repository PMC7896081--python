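"""Synthetic Mandarin-like speech stimuli and simulated cortical responses.

The generator emulates the structure of a continuous-speech corpus read by
ten speakers (five female, five male), each with a distinct baseline log-F0:
sentences of ~250 ms syllables are concatenated into phrases separated by
silences, and every syllable carries one of the four Mandarin lexical tones

    T1 high-level, T2 mid-rising, T3 low-dipping, T4 high-falling.

A syllable's voiced log-F0 is the speaker baseline plus a tone-contour
template (time-scaled to the syllable) plus smooth within-tone noise, so
absolute pitch mixes speaker identity with tone shape while speaker-
normalized relative pitch isolates the tone shape — the confound the
downstream encoding analyses are designed to resolve.

Simulated electrodes respond as a lagged linear function of chosen feature
sets (the generative counterpart of a temporal receptive field), optionally
plus a tone-specific boxcar over the vowel (a categorical response) and a
speech-onset transient, plus Gaussian noise; responses are z-scored per
recording block like real high-gamma.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter1d

from .errors import ConfigurationError
from .features import StimulusFeatures, build_design_matrix, syllable_spans
from .preproc import FRAME_RATE, NeuralRecording, default_block_spans, zscore_blocks

LOG_F0_MIN, LOG_F0_MAX = np.log(50.0), np.log(500.0)


@dataclass
class SpeakerProfile:
    speaker_id: str
    baseline_logf0: float  # log-Hz
    logf0_sd: float  # log-Hz; scales the tone contour excursion
    sex_label: str = "F"

    def __post_init__(self):
        if not (LOG_F0_MIN <= self.baseline_logf0 <= LOG_F0_MAX):
            raise ConfigurationError(
                f"baseline_logf0={self.baseline_logf0:.3f} outside plausible "
                f"vocal range [log 50, log 500] Hz"
            )
        if self.logf0_sd <= 0:
            raise ConfigurationError("logf0_sd must be positive")


@dataclass
class ToneTemplate:
    """Normalized-pitch contour of one lexical tone over a unit-duration grid."""

    tone_id: int
    contour: np.ndarray
    contour_sd: float = 0.15  # SD of smooth within-tone noise, in contour units

    def __post_init__(self):
        self.contour = np.asarray(self.contour, dtype=float)
        if self.contour.size < 2:
            raise ConfigurationError("tone contour needs at least 2 points")
        if self.contour_sd < 0:
            raise ConfigurationError("contour_sd must be >= 0")


def default_templates(contour_sd: float = 0.15) -> list[ToneTemplate]:
    """Canonical four-tone contour shapes on a 25-point unit grid.

    T1 near-flat high; T2 rising; T3 low with a dip (lowest minimum of the
    four); T4 high-falling (steepest negative slope).
    """
    t = np.linspace(0.0, 1.0, 25)
    return [
        ToneTemplate(1, 0.8 + 0.05 * np.sin(np.pi * t), contour_sd),
        ToneTemplate(2, -0.5 + 1.3 * t**1.5, contour_sd),
        ToneTemplate(3, -0.9 - 0.5 * np.sin(np.pi * np.clip(t / 0.95, 0, 1)), contour_sd),
        ToneTemplate(4, 1.2 - 2.4 * t, contour_sd),
    ]


def default_speakers(
    n_per_sex: int = 5, logf0_sd: float = 0.2
) -> list[SpeakerProfile]:
    """Ten speakers (5 F, 5 M) with baselines evenly spaced in log-Hz."""
    female = np.linspace(np.log(180.0), np.log(260.0), n_per_sex)
    male = np.linspace(np.log(100.0), np.log(140.0), n_per_sex)
    speakers = [
        SpeakerProfile(f"F{i + 1}", b, logf0_sd, "F") for i, b in enumerate(female)
    ] + [SpeakerProfile(f"M{i + 1}", b, logf0_sd, "M") for i, b in enumerate(male)]
    return speakers


@dataclass
class SyntheticStimulus:
    """Per-frame stimulus tracks at 100 Hz plus syllable/phrase annotations.

    ``f0`` is NaN on unvoiced frames; ``voicing`` is False exactly there.
    """

    f0: np.ndarray
    voicing: np.ndarray
    intensity: np.ndarray
    syllable_table: pd.DataFrame
    phrase_table: pd.DataFrame
    fs: float = FRAME_RATE

    @property
    def n_frames(self) -> int:
        return self.f0.size


def _smooth_noise(rng: np.random.Generator, n: int, sd: float, sigma: float = 3.0) -> np.ndarray:
    """Low-pass filtered Gaussian noise rescaled to the requested SD."""
    if sd == 0 or n == 0:
        return np.zeros(n)
    x = gaussian_filter1d(rng.standard_normal(n + 20), sigma)[10 : 10 + n]
    s = x.std()
    return x * (sd / s) if s > 0 else np.zeros(n)


def _balanced_tone_deck(rng: np.random.Generator, n: int) -> np.ndarray:
    """Tone labels 1-4, balanced to within one token, in random order."""
    deck = np.tile([1, 2, 3, 4], n // 4 + 1)[:n]
    rng.shuffle(deck)
    return deck


def _synthesize(
    rng: np.random.Generator,
    n_sentences: int,
    speakers: list[SpeakerProfile],
    contour_fn,
    tone_deck: np.ndarray | None,
    syllables_per_sentence: tuple[int, int],
    syllable_dur: float,
    vowel_frac: float,
    silence_dur: float,
    duration_jitter: float,
    fs: float,
) -> SyntheticStimulus:
    """Shared synthesis loop; ``contour_fn(rng, tone_or_None, n_frames)`` yields
    the normalized contour for one syllable."""
    lo, hi = syllables_per_sentence
    n_syl = rng.integers(lo, hi + 1, size=n_sentences)
    total = int(n_syl.sum())
    deck_iter = iter(tone_deck) if tone_deck is not None else None

    sil_frames = int(round(silence_dur * fs))
    logf0_segments: list[tuple[int, np.ndarray]] = []
    syl_rows, phrase_rows = [], []
    cursor = sil_frames  # leading silence
    for s in range(n_sentences):
        spk = speakers[rng.integers(len(speakers))]
        sent_start = cursor
        for _ in range(n_syl[s]):
            dur = syllable_dur * (1.0 + duration_jitter * (2 * rng.random() - 1))
            dur_frames = max(int(round(dur * fs)), 4)
            vow_off = int(round(vowel_frac * dur_frames))
            n_voiced = dur_frames - vow_off
            tone = int(next(deck_iter)) if deck_iter is not None else None
            contour = contour_fn(rng, tone, n_voiced)
            logf0 = spk.baseline_logf0 + spk.logf0_sd * contour
            logf0_segments.append((cursor + vow_off, logf0))
            row = {
                "sentence_id": s,
                "speaker_id": spk.speaker_id,
                "syllable_onset_s": cursor / fs,
                "vowel_onset_s": (cursor + vow_off) / fs,
            }
            if tone is not None:
                row["tone"] = tone
            syl_rows.append(row)
            cursor += dur_frames
        phrase_rows.append(
            {"phrase_id": s, "start_s": sent_start / fs, "end_s": cursor / fs}
        )
        cursor += sil_frames

    n_frames = cursor
    f0 = np.full(n_frames, np.nan)
    voicing = np.zeros(n_frames, dtype=bool)
    for start, logf0 in logf0_segments:
        f0[start : start + logf0.size] = np.exp(logf0)
        voicing[start : start + logf0.size] = True

    intensity = np.zeros(n_frames)
    for row in phrase_rows:
        a, b = int(round(row["start_s"] * fs)), int(round(row["end_s"] * fs))
        intensity[a:b] = 1.0 + np.clip(_smooth_noise(rng, b - a, 0.1), -0.8, 0.8)

    return SyntheticStimulus(
        f0=f0,
        voicing=voicing,
        intensity=intensity,
        syllable_table=pd.DataFrame(syl_rows),
        phrase_table=pd.DataFrame(phrase_rows),
        fs=fs,
    )


def make_stimulus(
    n_sentences: int,
    speakers: list[SpeakerProfile] | None = None,
    templates: list[ToneTemplate] | None = None,
    seed: int = 0,
    syllables_per_sentence: tuple[int, int] = (3, 8),
    syllable_dur: float = 0.25,
    vowel_frac: float = 0.2,
    silence_dur: float = 0.5,
    duration_jitter: float = 0.15,
    fs: float = FRAME_RATE,
) -> SyntheticStimulus:
    """Mandarin-like stimulus: tone-labeled syllables in phrase-per-sentence
    structure, deterministic given ``seed``.

    Each syllable's voiced log-F0 = speaker baseline + logf0_sd x (template
    contour time-scaled to the vowel) + smooth noise of SD ``contour_sd``.
    Tone labels are drawn from a balanced shuffled deck, so counts per tone
    are equal to within one token.
    """
    if n_sentences < 1:
        raise ConfigurationError("n_sentences must be >= 1")
    speakers = speakers if speakers is not None else default_speakers()
    if len(speakers) < 1:
        raise ConfigurationError("need at least one speaker")
    templates = templates if templates is not None else default_templates()
    by_tone = {t.tone_id: t for t in templates}
    missing = set(range(1, 5)) - set(by_tone)
    if missing:
        raise ConfigurationError(f"missing tone template(s) for tone(s) {sorted(missing)}")

    rng = np.random.default_rng(seed)
    lo, hi = syllables_per_sentence
    max_total = n_sentences * hi
    deck = _balanced_tone_deck(rng, max_total)

    def contour_fn(rng_, tone, n_voiced):
        tpl = by_tone[tone]
        src = np.linspace(0, 1, tpl.contour.size)
        base = np.interp(np.linspace(0, 1, n_voiced), src, tpl.contour)
        return base + _smooth_noise(rng_, n_voiced, tpl.contour_sd)

    return _synthesize(
        rng, n_sentences, speakers, contour_fn, deck,
        syllables_per_sentence, syllable_dur, vowel_frac, silence_dur,
        duration_jitter, fs,
    )


def make_english_like_stimulus(
    n_sentences: int,
    seed: int = 0,
    speakers: list[SpeakerProfile] | None = None,
    range_scale: float = 0.6,
    syllables_per_sentence: tuple[int, int] = (6, 12),
    syllable_dur: float = 0.25,
    vowel_frac: float = 0.2,
    silence_dur: float = 0.4,
    duration_jitter: float = 0.15,
    fs: float = FRAME_RATE,
) -> SyntheticStimulus:
    """Non-tonal stimulus: no tone labels, smoother random intonation contours
    with a pitch dynamic range scaled by ``range_scale`` relative to the
    tonal stimulus, and longer phrases.

    Syllable contours are smooth random fields normalized so that at
    ``range_scale=1`` their dispersion matches the pooled dispersion of the
    default tone templates.
    """
    if n_sentences < 1:
        raise ConfigurationError("n_sentences must be >= 1")
    speakers = speakers if speakers is not None else default_speakers()
    rng = np.random.default_rng(seed)
    pooled_sd = np.concatenate([t.contour for t in default_templates()]).std()

    def contour_fn(rng_, tone, n_voiced):
        # slow declination plus smooth wiggle, matched in scale to tones
        raw = _smooth_noise(rng_, n_voiced, 1.0, sigma=6.0) + 0.5 * (
            2 * rng_.random() - 1
        )
        return range_scale * pooled_sd * raw

    return _synthesize(
        rng, n_sentences, speakers, contour_fn, None,
        syllables_per_sentence, syllable_dur, vowel_frac, silence_dur,
        duration_jitter, fs,
    )


# ---------------------------------------------------------------------------
# ground truth and neural simulation


@dataclass
class ElectrodeTruth:
    """Generative parameters of one simulated electrode.

    ``weights`` maps feature-set name -> (dim, n_lags) matrix; sets absent
    from the dict have zero weights.  ``tone_pattern`` gives the per-tone
    amplitude of the categorical (vowel-boxcar) component, scaled by
    ``categorical_gain``.
    """

    weights: dict[str, np.ndarray] = field(default_factory=dict)
    noise_sd: float = 1.0
    categorical_gain: float = 0.0
    onset_gain: float = 0.0
    tone_pattern: np.ndarray = field(default_factory=lambda: np.zeros(4))

    def __post_init__(self):
        if self.noise_sd < 0:
            raise ConfigurationError("noise_sd must be >= 0")
        self.tone_pattern = np.asarray(self.tone_pattern, dtype=float)

    @property
    def feature_assignment(self) -> list[str]:
        return [s for s, w in self.weights.items() if np.any(w)]


@dataclass
class SyntheticGroundTruth:
    electrodes: list[ElectrodeTruth]
    max_lag: int

    def __len__(self) -> int:
        return len(self.electrodes)


def smooth_random_weights(
    rng: np.random.Generator, dim: int, n_lags: int, scale: float = 1.0
) -> np.ndarray:
    """Smooth (dim, n_lags) weight matrix, unit RMS before scaling.

    Smoothness across bins and lags mimics realistic receptive fields and
    makes recovery well-posed under one-hot features.
    """
    from scipy.ndimage import gaussian_filter

    w = gaussian_filter(rng.standard_normal((dim, n_lags)), sigma=(1.0, 2.0))
    rms = np.sqrt(np.mean(w**2))
    return w * (scale / rms) if rms > 0 else w


def random_truth(
    feature_dims: dict[str, int],
    assignments: list[list[str]],
    n_lags: int,
    seed: int = 0,
    noise_sd: float = 1.0,
    weight_scale: float = 1.0,
    categorical_gain: float = 0.0,
    onset_gain: float = 0.0,
) -> SyntheticGroundTruth:
    """One electrode per entry of ``assignments`` (the feature sets it encodes)."""
    rng = np.random.default_rng(seed)
    electrodes = []
    for sets in assignments:
        w = {
            s: smooth_random_weights(rng, feature_dims[s], n_lags, weight_scale)
            for s in sets
        }
        electrodes.append(
            ElectrodeTruth(
                weights=w,
                noise_sd=noise_sd,
                categorical_gain=categorical_gain,
                onset_gain=onset_gain,
                tone_pattern=rng.standard_normal(4) if categorical_gain else np.zeros(4),
            )
        )
    return SyntheticGroundTruth(electrodes=electrodes, max_lag=n_lags)


def _onset_kernel(fs: float) -> np.ndarray:
    """Raised-cosine transient peaking ~175 ms after speech onset."""
    t = np.arange(int(round(0.3 * fs))) / fs
    k = np.sin(np.pi * t / t[-1]) ** 2
    return np.concatenate([np.zeros(int(round(0.05 * fs))), k])


def simulate_clean(
    stimulus: SyntheticStimulus,
    features: StimulusFeatures,
    truth: SyntheticGroundTruth,
) -> np.ndarray:
    """Noise-free response of every electrode: lagged-linear drive plus
    categorical and onset components.  Returns (n_electrodes, n_frames)."""
    n = features.n_frames
    fs = features.fs
    used_sets = sorted({s for e in truth.electrodes for s in e.weights})
    dims = features.set_dims(used_sets) if used_sets else {}
    for e in truth.electrodes:
        for s, w in e.weights.items():
            if w.shape != (dims[s], truth.max_lag):
                raise ConfigurationError(
                    f"weights for feature set {s!r} have shape {w.shape}, "
                    f"expected ({dims[s]}, {truth.max_lag})"
                )
    X, colmap = (
        build_design_matrix(features, used_sets, truth.max_lag)
        if used_sets
        else (np.zeros((n, 0)), None)
    )

    syl = syllable_spans(stimulus.syllable_table, stimulus.phrase_table, fs)
    tones = (
        stimulus.syllable_table["tone"].to_numpy()
        if "tone" in stimulus.syllable_table.columns
        else None
    )
    vowel_onsets = np.round(
        stimulus.syllable_table["vowel_onset_s"].to_numpy() * fs
    ).astype(int)
    kern = _onset_kernel(fs)
    phrase_starts = np.round(stimulus.phrase_table["start_s"].to_numpy() * fs).astype(int)

    Y = np.zeros((len(truth.electrodes), n))
    for i, e in enumerate(truth.electrodes):
        y = np.zeros(n)
        if e.weights:
            wflat = np.concatenate(
                [
                    (e.weights[s] if s in e.weights else np.zeros((dims[s], truth.max_lag))).reshape(-1)
                    for s in used_sets
                ]
            )
            y += X @ wflat
        if e.categorical_gain and tones is not None:
            for (a, b), vo, tone in zip(syl, vowel_onsets, tones):
                y[vo:b] += e.categorical_gain * e.tone_pattern[int(tone) - 1]
        if e.onset_gain:
            for p in phrase_starts:
                stop = min(p + kern.size, n)
                y[p:stop] += e.onset_gain * kern[: stop - p]
        Y[i] = y
    return Y


def make_neural(
    stimulus: SyntheticStimulus,
    features: StimulusFeatures,
    truth: SyntheticGroundTruth,
    seed: int = 0,
    block_len_s: float = 60.0,
    noise_relative: bool = False,
    zscore: bool = True,
) -> NeuralRecording:
    """Simulated high-gamma recording: clean drive + Gaussian noise, z-scored
    per block.

    With ``noise_relative=True`` each electrode's noise SD is its
    ``noise_sd`` times the SD of its own clean signal (so ``noise_sd=1``
    means noise power equals signal power).
    """
    rng = np.random.default_rng(seed)
    Y = simulate_clean(stimulus, features, truth)
    n = Y.shape[1]
    for i, e in enumerate(truth.electrodes):
        sd = e.noise_sd * (Y[i].std() if noise_relative else 1.0)
        if sd > 0:
            Y[i] += rng.normal(0.0, sd, size=n)
    block_spans = default_block_spans(n, int(round(block_len_s * features.fs)))
    if zscore:
        Y = zscore_blocks(Y, block_spans)
    meta = pd.DataFrame(
        {
            "electrode_id": np.arange(len(truth.electrodes)),
            "subject_id": "SYN",
            "hemisphere": "L",
            "group_label": ["+".join(e.feature_assignment) for e in truth.electrodes],
        }
    )
    return NeuralRecording(
        high_gamma=Y, block_spans=block_spans, fs=features.fs, electrode_meta=meta
    )
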