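"""Electrode classification and tuning characterization.

Two detectors mirror the standard ECoG selection pipeline:

* speech-responsive — paired t-test of mean high-gamma after vs before
  speech onsets (and, analogously, around speech offsets, which catches
  sustained responders that drop at offset), Bonferroni-corrected over
  electrodes at p < 0.01;
* tone-discriminant — per-timepoint one-way F-test across the four tone
  classes on vowel-aligned epochs (-200..1000 ms, 120 points), Bonferroni-
  corrected over electrodes x timepoints at p < 0.05, requiring >= 3
  consecutive significant points.

Tuning curves bin an electrode's (delay-shifted) high-gamma by a pitch
feature over the middle 95-percentile range; the linearity index is the
Fisher z-transform L = 1/2 ln((1+r)/(1-r)) of the correlation r between bin
value and mean high-gamma.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .preproc import FRAME_RATE, NeuralRecording, epoch

logger = logging.getLogger(__name__)


def fisher_z(r) -> np.ndarray | float:
    """Fisher transformation L = 1/2 ln((1+r)/(1-r))."""
    r = np.asarray(r, dtype=float)
    out = 0.5 * np.log((1.0 + r) / (1.0 - r))
    return float(out) if out.ndim == 0 else out


# ---------------------------------------------------------------------------
# detectors


def detect_speech_responsive(
    recording: NeuralRecording,
    onsets: np.ndarray,
    offsets: np.ndarray,
    alpha: float = 0.01,
    post_window_s: tuple[float, float] = (0.10, 0.40),
    pre_window_s: tuple[float, float] = (-0.25, 0.05),
) -> pd.DataFrame:
    """Flag electrodes whose response differs around speech onsets/offsets.

    For each event the mean high-gamma in the post-onset window (100-400 ms,
    allowing ~100 ms neural delay) is paired with the mean in the pre-onset
    window (-250..50 ms); a two-sided paired t-test across events is
    Bonferroni-corrected over electrodes.  Offsets use the mirrored windows
    (elevated-before vs dropped-after).  An electrode is speech-responsive if
    either test survives.  Electrodes with < 5 usable events are marked
    untestable.
    """
    fs = recording.fs
    n_el = recording.n_electrodes

    def paired_p(events, win_a, win_b):
        events = np.asarray(events, dtype=int)
        a0, a1 = int(round(win_a[0] * fs)), int(round(win_a[1] * fs))
        b0, b1 = int(round(win_b[0] * fs)), int(round(win_b[1] * fs))
        pre = max(-min(a0, b0), 0)
        post = max(a1, b1)
        trials, _ = epoch(recording, events, (pre, post))
        if trials.shape[0] < 5:
            return np.full(n_el, np.nan), trials.shape[0]
        mean_a = np.nanmean(trials[:, :, pre + a0 : pre + a1], axis=2)
        mean_b = np.nanmean(trials[:, :, pre + b0 : pre + b1], axis=2)
        t = stats.ttest_rel(mean_a, mean_b, axis=0)
        return t.pvalue, trials.shape[0]

    onset_p, n_on = paired_p(onsets, post_window_s, pre_window_s)
    # offset: response elevated before the offset, dropped after it
    offset_p, n_off = paired_p(
        offsets, (pre_window_s[0], pre_window_s[1]), post_window_s
    )
    untestable = np.isnan(onset_p) & np.isnan(offset_p)
    thr = alpha / n_el  # Bonferroni over electrodes
    logger.info(
        "speech-responsive: %d onsets, %d offsets, Bonferroni denominator %d",
        n_on, n_off, n_el,
    )
    responsive = (np.nan_to_num(onset_p, nan=1.0) < thr) | (
        np.nan_to_num(offset_p, nan=1.0) < thr
    )
    return pd.DataFrame(
        {
            "electrode_id": np.arange(n_el),
            "onset_p": onset_p,
            "offset_p": offset_p,
            "speech_responsive": responsive,
            "untestable": untestable,
        }
    )


def _f_oneway_timecourse(epochs: np.ndarray, labels: np.ndarray) -> np.ndarray:
    """One-way F statistic per (electrode, timepoint) across label groups.

    ``epochs`` is (trials, n_electrodes, n_frames).
    """
    classes = np.unique(labels)
    n, k = epochs.shape[0], classes.size
    grand = epochs.mean(axis=0)
    ss_between = np.zeros_like(grand)
    ss_within = np.zeros_like(grand)
    for c in classes:
        grp = epochs[labels == c]
        mu = grp.mean(axis=0)
        ss_between += grp.shape[0] * (mu - grand) ** 2
        ss_within += ((grp - mu) ** 2).sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        f = (ss_between / (k - 1)) / (ss_within / (n - k))
    return np.where(np.isfinite(f), f, 0.0)


def _runs_of_true(mask: np.ndarray) -> list[tuple[int, int]]:
    d = np.diff(np.concatenate(([0], mask.astype(int), [0])))
    return list(zip(np.flatnonzero(d == 1), np.flatnonzero(d == -1)))


def detect_tone_discriminant(
    epochs: np.ndarray,
    labels: np.ndarray,
    alpha: float = 0.05,
    min_run: int = 3,
    speech_responsive: np.ndarray | None = None,
) -> pd.DataFrame:
    """Flag electrodes whose vowel-aligned response separates the four tones.

    ``epochs`` is (trials, n_electrodes, n_frames) aligned to vowel onset
    (canonically -200..1000 ms = 120 frames).  Significance is two-sided
    p < ``alpha`` Bonferroni-corrected over electrodes x timepoints, and an
    electrode is tone-discriminant only with >= ``min_run`` consecutive
    significant points (and, if ``speech_responsive`` is given, only among
    responsive electrodes).
    """
    labels = np.asarray(labels)
    classes = np.unique(labels)
    missing = set(range(1, 5)) - set(int(c) for c in classes)
    if missing:
        raise ValueError(f"missing tone class(es) {sorted(missing)}")
    counts = {int(c): int((labels == c).sum()) for c in classes}
    if min(counts.values()) < 10:
        warnings.warn(f"fewer than 10 trials in some tone class: {counts}", stacklevel=2)

    n_trials, n_el, n_frames = epochs.shape
    f = _f_oneway_timecourse(epochs, labels)
    k = classes.size
    pvals = stats.f.sf(f, k - 1, n_trials - k)
    thr = alpha / (n_el * n_frames)  # Bonferroni over electrodes x timepoints
    logger.info(
        "tone-discriminant: Bonferroni denominator %d x %d = %d",
        n_el, n_frames, n_el * n_frames,
    )
    sig = pvals < thr
    rows = []
    for e in range(n_el):
        runs = [(a, b) for a, b in _runs_of_true(sig[e]) if b - a >= min_run]
        flagged = bool(runs)
        if speech_responsive is not None:
            flagged = flagged and bool(speech_responsive[e])
        best = max(runs, key=lambda ab: ab[1] - ab[0]) if runs else (None, None)
        rows.append(
            {
                "electrode_id": e,
                "tone_discriminant": flagged,
                "max_f": float(f[e].max()),
                "run_start": best[0],
                "run_stop": best[1],
            }
        )
    out = pd.DataFrame(rows)
    out.attrs["f_trace"] = f
    return out


# ---------------------------------------------------------------------------
# tuning curves


@dataclass
class TuningCurve:
    """Binned mean response to a continuous pitch feature.

    ``r`` is the correlation between bin center and mean high-gamma over
    occupied bins (unweighted); ``linearity`` its Fisher z-transform;
    ``modulation_depth`` the range of the bin means.
    """

    bin_centers: np.ndarray
    mean_hg: np.ndarray  # NaN for empty bins
    sd_hg: np.ndarray
    counts: np.ndarray
    modulation_depth: float
    r: float
    linearity: float
    valid: bool = True


def tuning_curve(
    hg: np.ndarray,
    feature_val: np.ndarray,
    n_bins: int = 20,
    delay_frames: int = 10,
    min_mean_count: float = 20.0,
) -> TuningCurve:
    """Tuning curve of one electrode for one continuous pitch feature.

    The response is shifted back by ``delay_frames`` (default 100 ms) so the
    neural sample is paired with the stimulus feature that drove it.  Bins
    are uniform over the feature's middle 95-percentile range; frames outside
    that range or with undefined feature are excluded.
    """
    hg = np.asarray(hg, dtype=float).ravel()
    feature_val = np.asarray(feature_val, dtype=float).ravel()
    if delay_frames > 0:
        hg = hg[delay_frames:]
        feature_val = feature_val[: feature_val.size - delay_frames]
    ok = np.isfinite(feature_val) & np.isfinite(hg)
    x, y = feature_val[ok], hg[ok]
    if x.size == 0:
        return TuningCurve(
            np.array([]), np.array([]), np.array([]), np.array([]),
            np.nan, np.nan, np.nan, valid=False,
        )
    lo, hi = np.percentile(x, [2.5, 97.5])
    edges = np.linspace(lo, hi, n_bins + 1)
    centers = 0.5 * (edges[:-1] + edges[1:])
    inside = (x >= lo) & (x <= hi)
    idx = np.clip(np.searchsorted(edges, x[inside], side="right") - 1, 0, n_bins - 1)
    yin = y[inside]
    mean_hg = np.full(n_bins, np.nan)
    sd_hg = np.full(n_bins, np.nan)
    counts = np.bincount(idx, minlength=n_bins)
    for b in range(n_bins):
        sel = idx == b
        if sel.any():
            mean_hg[b] = yin[sel].mean()
            sd_hg[b] = yin[sel].std()
    occupied = counts > 0
    if occupied.sum() < 2:
        return TuningCurve(centers, mean_hg, sd_hg, counts, np.nan, np.nan, np.nan, valid=False)
    if counts[occupied].mean() < min_mean_count:
        warnings.warn(
            f"mean occupancy {counts[occupied].mean():.1f} < {min_mean_count} "
            "frames per bin; tuning curve may be noisy",
            stacklevel=2,
        )
    depth = float(np.nanmax(mean_hg) - np.nanmin(mean_hg))
    r = float(stats.pearsonr(centers[occupied], mean_hg[occupied])[0])
    r = np.clip(r, -1 + 1e-15, 1 - 1e-15)
    return TuningCurve(
        bin_centers=centers, mean_hg=mean_hg, sd_hg=sd_hg, counts=counts,
        modulation_depth=depth, r=float(r), linearity=fisher_z(r),
    )


# ---------------------------------------------------------------------------
# temporal profiles


@dataclass
class TemporalProfile:
    """Per-lag mean absolute TRF weight for a group of electrodes."""

    per_electrode: np.ndarray  # (n_electrodes, n_lags)
    mean_abs_weight: np.ndarray  # (n_lags,) group mean
    peak_lag: int


def temporal_profile(models, sets) -> TemporalProfile:
    """Mean |beta| per lag across the given feature sets, per electrode."""
    sets = list(sets)
    rows = []
    for m in models:
        w = np.concatenate([np.abs(m.weights[s]) for s in sets], axis=0)
        rows.append(w.mean(axis=0))
    per_el = np.asarray(rows)
    mean = per_el.mean(axis=0)
    return TemporalProfile(per_el, mean, int(np.argmax(mean)))


def compare_temporal_profiles(
    profile_a: TemporalProfile,
    profile_b: TemporalProfile,
    alpha: float = 0.05,
) -> pd.DataFrame | None:
    """Per-lag two-sample comparison of two groups' |beta| profiles.

    Two-sided Mann-Whitney U per lag with Benjamini-Hochberg correction at
    ``alpha``.  Returns None (contrast skipped) when either group has a
    single electrode.
    """
    a, b = profile_a.per_electrode, profile_b.per_electrode
    if a.shape[0] < 2 or b.shape[0] < 2:
        logger.info("temporal-profile contrast skipped: single-electrode group")
        return None
    n_lags = a.shape[1]
    pvals = np.ones(n_lags)
    for lag in range(n_lags):
        if np.ptp(a[:, lag]) == 0 and np.ptp(b[:, lag]) == 0:
            continue
        pvals[lag] = stats.mannwhitneyu(a[:, lag], b[:, lag], alternative="two-sided").pvalue
    q = stats.false_discovery_control(pvals)
    return pd.DataFrame(
        {
            "lag": np.arange(n_lags),
            "diff": a.mean(axis=0) - b.mean(axis=0),
            "p": pvals,
            "q": q,
            "significant": q < alpha,
        }
    )


# ---------------------------------------------------------------------------
# population summary


def percent(k: int, n: int) -> float:
    """Percentage reported to one decimal place; 0.0 when n == 0."""
    return round(100.0 * k / n, 1) if n else 0.0


def summarize_population(
    flags: pd.DataFrame,
    decompositions: dict[int, "object"] | None = None,
    probe_names=None,
) -> dict:
    """Counts, percentages, and cross-electrode correlations.

    ``flags`` carries per-electrode booleans (``speech_responsive``,
    optionally ``tone_discriminant`` and ``max_f``); ``decompositions`` maps
    electrode id -> VarianceDecomposition.  Percentages of significant
    encoding are reported out of the speech-responsive count, mirroring how
    such populations are normally summarized.
    """
    n_total = len(flags)
    n_resp = int(flags["speech_responsive"].sum()) if "speech_responsive" in flags else n_total
    summary = {
        "n_electrodes": n_total,
        "n_speech_responsive": n_resp,
        "pct_speech_responsive": percent(n_resp, n_total),
    }
    if "tone_discriminant" in flags:
        n_tone = int(flags["tone_discriminant"].sum())
        summary["n_tone_discriminant"] = n_tone
        summary["pct_tone_discriminant"] = percent(n_tone, n_resp)
    if decompositions:
        any_probe = next(iter(decompositions.values()))
        names = probe_names if probe_names is not None else list(any_probe.significant)
        if "speech_responsive" in flags:
            responsive_ids = set(
                flags.loc[flags["speech_responsive"], "electrode_id"].tolist()
            )
        else:
            responsive_ids = set(flags["electrode_id"].tolist())
        for name in names:
            ids = sorted(set(decompositions) & responsive_ids) or sorted(decompositions)
            sig = [decompositions[i].significant[name] for i in ids]
            k = int(np.sum(sig))
            summary[f"n_significant[{name}]"] = k
            summary[f"pct_significant[{name}]"] = percent(k, n_resp)
            if "max_f" in flags.columns:
                uniq = np.array([decompositions[i].unique_r2[name] for i in ids])
                maxf = flags.set_index("electrode_id").loc[ids, "max_f"].to_numpy()
                if np.ptp(uniq) > 0 and np.ptp(maxf) > 0:
                    summary[f"corr_unique_vs_maxF[{name}]"] = float(
                        stats.pearsonr(uniq, maxf)[0]
                    )
    return summary
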