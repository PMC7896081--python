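"""Pitch feature extraction and design-matrix construction.

Three pitch descriptions are derived from a fundamental-frequency (F0) trace
sampled at 100 Hz:

* absolute pitch  — natural log of F0 in Hz,
* relative pitch  — log-F0 z-scored within each sentence/passage of one
  speaker, removing the speaker's baseline and range (the speaker-normalized
  pitch *height*),
* pitch change    — first temporal difference of log-F0 within contiguous
  voiced runs (the local contour slope).

Each is discretized into a 10-dimensional one-hot vector: bins are equally
spaced between the corpus-wide 2.5th and 97.5th percentiles, with the tails
clipped into the end bins.  Unvoiced frames carry all-zero vectors.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import ConfigurationError, MissingToneError
from .preproc import FRAME_RATE

logger = logging.getLogger(__name__)

N_PITCH_BINS = 10
PITCH_FEATURE_NAMES = ("abs_pitch", "rel_pitch", "pitch_change")
#: feature sets understood by the design-matrix builder, in canonical order
FEATURE_SET_ORDER = ("spectrum", "intensity", "abs_pitch", "rel_pitch", "pitch_change", "tone")


# ---------------------------------------------------------------------------
# binning


def percentile_bin_edges(values: np.ndarray, n_bins: int = N_PITCH_BINS) -> np.ndarray:
    """Edges of ``n_bins`` equal-width bins spanning the middle 95% of ``values``."""
    values = np.asarray(values, dtype=float)
    values = values[np.isfinite(values)]
    if values.size == 0:
        raise ValueError("no finite values to compute bin edges from")
    lo, hi = np.percentile(values, [2.5, 97.5])
    tiny = 1e-9 * max(1.0, abs(lo), abs(hi))
    if hi - lo < tiny:
        # (near-)constant feature: widen so all values share one middle bin
        lo, hi = lo - tiny / 2, lo + tiny / 2
    return np.linspace(lo, hi, n_bins + 1)


def bin_onehot(values: np.ndarray, edges: np.ndarray) -> np.ndarray:
    """One-hot bin assignment with tail clipping; NaN rows are all zero."""
    values = np.asarray(values, dtype=float)
    n_bins = len(edges) - 1
    out = np.zeros((values.size, n_bins))
    finite = np.isfinite(values)
    idx = np.clip(np.searchsorted(edges, values[finite], side="right") - 1, 0, n_bins - 1)
    out[np.flatnonzero(finite), idx] = 1.0
    return out


# ---------------------------------------------------------------------------
# pitch features


@dataclass
class PitchFeatureSet:
    """Continuous and binned pitch features on a common 100 Hz time axis.

    Continuous tracks hold NaN where undefined (unvoiced frames; additionally
    the first frame of each voiced run for pitch change).
    """

    logf0: np.ndarray
    rel_pitch_z: np.ndarray
    pitch_change_val: np.ndarray
    abs_pitch_bins: np.ndarray  # (n, 10)
    rel_pitch_bins: np.ndarray
    pitch_change_bins: np.ndarray
    bin_edges: dict[str, np.ndarray]

    @property
    def n_frames(self) -> int:
        return self.logf0.size


def _voiced_runs(voicing: np.ndarray) -> list[tuple[int, int]]:
    """Half-open intervals of contiguous voiced frames."""
    v = np.asarray(voicing, dtype=bool).astype(int)
    dv = np.diff(np.concatenate(([0], v, [0])))
    starts = np.flatnonzero(dv == 1)
    stops = np.flatnonzero(dv == -1)
    return list(zip(starts, stops))


def extract_pitch_features(
    f0: np.ndarray,
    voicing: np.ndarray,
    sentence_spans: list[tuple[int, int]],
    bin_edges: dict[str, np.ndarray] | None = None,
    fs: float = FRAME_RATE,
) -> PitchFeatureSet:
    """Compute absolute/relative pitch and pitch change with one-hot binning.

    Parameters
    ----------
    f0 : F0 in Hz per frame; values on unvoiced frames are ignored.
    sentence_spans : half-open frame intervals, each covering one
        sentence/passage of a single speaker; relative pitch is z-scored over
        the voiced frames of each span.
    bin_edges : reuse edges from an earlier build (required when two stimuli
        must share one feature space, e.g. cross-language model transfer);
        computed from this corpus when None.
    """
    f0 = np.asarray(f0, dtype=float)
    voicing = np.asarray(voicing, dtype=bool)
    n = f0.size
    if np.any(voicing & ~(f0 > 0)):
        bad = np.flatnonzero(voicing & ~(f0 > 0))
        raise ValueError(f"non-positive F0 on voiced frame(s), first at frame {bad[0]}")

    logf0 = np.full(n, np.nan)
    logf0[voicing] = np.log(f0[voicing])

    # relative pitch: z within each sentence span over voiced frames
    rel = np.full(n, np.nan)
    for start, stop in sentence_spans:
        seg = slice(start, stop)
        v = voicing[seg]
        nv = int(v.sum())
        if nv == 0:
            continue
        if nv < 20:
            warnings.warn(
                f"span [{start},{stop}) has only {nv} voiced frames; "
                "z-scoring may be unstable",
                stacklevel=2,
            )
        vals = logf0[seg][v]
        sd = vals.std()
        z = (vals - vals.mean()) / (sd if sd > 0 else 1.0)
        tmp = rel[seg]
        tmp[v] = z
        rel[seg] = tmp

    # pitch change: finite difference within voiced runs; run starts undefined
    change = np.full(n, np.nan)
    for start, stop in _voiced_runs(voicing):
        if stop - start >= 2:
            change[start + 1 : stop] = np.diff(logf0[start:stop])

    if bin_edges is None:
        if voicing.any():
            bin_edges = {
                "abs_pitch": percentile_bin_edges(logf0),
                "rel_pitch": percentile_bin_edges(rel),
                "pitch_change": percentile_bin_edges(change),
            }
        else:
            # all-unvoiced input: placeholder edges, all-zero features
            bin_edges = {name: np.linspace(0, 1, N_PITCH_BINS + 1) for name in PITCH_FEATURE_NAMES}
    for name, edges in bin_edges.items():
        if np.any(np.diff(edges) <= 0):
            raise ValueError(f"bin edges for {name!r} are not strictly increasing")

    return PitchFeatureSet(
        logf0=logf0,
        rel_pitch_z=rel,
        pitch_change_val=change,
        abs_pitch_bins=bin_onehot(logf0, bin_edges["abs_pitch"]),
        rel_pitch_bins=bin_onehot(rel, bin_edges["rel_pitch"]),
        pitch_change_bins=bin_onehot(change, bin_edges["pitch_change"]),
        bin_edges=bin_edges,
    )


# ---------------------------------------------------------------------------
# full stimulus feature container


@dataclass
class StimulusFeatures:
    """All stimulus feature tracks on one 100 Hz time axis."""

    spectrum: np.ndarray  # (n, 30)
    intensity: np.ndarray  # (n, 1)
    pitch: PitchFeatureSet
    tone_onehot: np.ndarray | None  # (n, 4) or None for toneless stimuli
    syllable_table: pd.DataFrame
    phrase_table: pd.DataFrame
    fs: float = FRAME_RATE

    @property
    def n_frames(self) -> int:
        return self.spectrum.shape[0]

    def matrix(self, name: str) -> np.ndarray:
        """Per-frame matrix for one named feature set."""
        if name == "spectrum":
            return self.spectrum
        if name == "intensity":
            return self.intensity
        if name == "abs_pitch":
            return self.pitch.abs_pitch_bins
        if name == "rel_pitch":
            return self.pitch.rel_pitch_bins
        if name == "pitch_change":
            return self.pitch.pitch_change_bins
        if name == "tone":
            if self.tone_onehot is None:
                raise MissingToneError(
                    "stimulus carries no tone labels; 'tone' features unavailable"
                )
            return self.tone_onehot
        raise KeyError(f"unknown feature set {name!r}; valid: {FEATURE_SET_ORDER}")

    def set_dims(self, names) -> dict[str, int]:
        return {name: self.matrix(name).shape[1] for name in names}


def sentence_spans(
    syllable_table: pd.DataFrame, phrase_table: pd.DataFrame, fs: float = FRAME_RATE
) -> list[tuple[int, int]]:
    """Frame span of each sentence: first syllable onset to end of its phrase."""
    spans = []
    ph_start = phrase_table["start_s"].to_numpy()
    ph_end = phrase_table["end_s"].to_numpy()
    for _, grp in syllable_table.groupby("sentence_id", sort=True):
        t0 = grp["syllable_onset_s"].min()
        t_last = grp["syllable_onset_s"].max()
        # phrase containing the last syllable bounds the sentence
        in_ph = np.flatnonzero((ph_start <= t_last) & (t_last < ph_end))
        end_s = ph_end[in_ph[-1]] if in_ph.size else t_last + 0.5
        spans.append((int(round(t0 * fs)), int(round(end_s * fs))))
    return spans


def syllable_spans(
    syllable_table: pd.DataFrame, phrase_table: pd.DataFrame, fs: float = FRAME_RATE
) -> np.ndarray:
    """(n_syllables, 2) half-open frame intervals.

    A syllable ends at the next syllable's onset within the same sentence, or
    at the end of its phrase for sentence-final syllables.
    """
    tab = syllable_table.reset_index(drop=True)
    onset = tab["syllable_onset_s"].to_numpy()
    ends = np.empty(len(tab))
    ph_start = phrase_table["start_s"].to_numpy()
    ph_end = phrase_table["end_s"].to_numpy()
    for sid, grp in tab.groupby("sentence_id", sort=False):
        idx = grp.index.to_numpy()
        order = idx[np.argsort(onset[idx], kind="stable")]
        for i, j in zip(order[:-1], order[1:]):
            ends[i] = onset[j]
        last = order[-1]
        in_ph = np.flatnonzero((ph_start <= onset[last]) & (onset[last] < ph_end))
        ends[last] = ph_end[in_ph[-1]] if in_ph.size else onset[last] + 0.25
    frames = np.column_stack(
        [np.round(onset * fs).astype(int), np.round(ends * fs).astype(int)]
    )
    return frames


def build_stimulus_features(
    stimulus,
    seed: int | None = 0,
    include_tone: bool | None = None,
    n_spectrum: int = 30,
    bin_edges: dict[str, np.ndarray] | None = None,
    spectrum: np.ndarray | None = None,
) -> StimulusFeatures:
    """Assemble the full feature container from a stimulus.

    The spectrum may be supplied precomputed (e.g. a mel filterbank output);
    otherwise a smooth random field gated by the intensity envelope stands in
    for it, which preserves the timing structure the encoding models need.
    ``include_tone=None`` auto-detects the tone column.
    """
    tab = stimulus.syllable_table
    has_tone = "tone" in tab.columns
    if include_tone is None:
        include_tone = has_tone
    if include_tone and not has_tone:
        raise MissingToneError("stimulus syllable table has no 'tone' column")

    n = stimulus.f0.size
    fs = stimulus.fs
    if spectrum is None:
        rng = np.random.default_rng(seed)
        from scipy.ndimage import gaussian_filter1d

        field_ = gaussian_filter1d(rng.standard_normal((n, n_spectrum)), sigma=5.0, axis=0)
        spectrum = field_ * stimulus.intensity[:, None]
    if spectrum.shape != (n, n_spectrum):
        raise ConfigurationError(
            f"spectrum shape {spectrum.shape} != ({n}, {n_spectrum})"
        )

    spans = sentence_spans(tab, stimulus.phrase_table, fs)
    pitch = extract_pitch_features(stimulus.f0, stimulus.voicing, spans, bin_edges, fs)

    tone_onehot = None
    if include_tone:
        tone_onehot = np.zeros((n, 4))
        syl = syllable_spans(tab, stimulus.phrase_table, fs)
        for (a, b), tone in zip(syl, tab["tone"].to_numpy()):
            tone_onehot[a:b, int(tone) - 1] = 1.0

    return StimulusFeatures(
        spectrum=spectrum,
        intensity=stimulus.intensity[:, None].astype(float),
        pitch=pitch,
        tone_onehot=tone_onehot,
        syllable_table=tab,
        phrase_table=stimulus.phrase_table,
        fs=fs,
    )


# ---------------------------------------------------------------------------
# lagged design matrix


@dataclass
class ColumnMap:
    """Invertible map between flat design-matrix columns and (set, dim, lag).

    Columns are ordered (feature set, dimension, lag): for each set in order,
    dimension-major with ``max_lag`` consecutive lag columns per dimension.
    """

    sets: list[str]
    dims: dict[str, int]
    max_lag: int
    offsets: dict[str, int] = field(init=False)

    def __post_init__(self):
        self.offsets = {}
        off = 0
        for s in self.sets:
            self.offsets[s] = off
            off += self.dims[s] * self.max_lag
        self.n_columns = off

    def column(self, set_name: str, dim: int, lag: int) -> int:
        return self.offsets[set_name] + dim * self.max_lag + lag

    def unflatten(self, w: np.ndarray) -> dict[str, np.ndarray]:
        """Flat weight vector -> per-set (dim, lag) matrices."""
        out = {}
        for s in self.sets:
            off = self.offsets[s]
            out[s] = w[..., off : off + self.dims[s] * self.max_lag].reshape(
                *w.shape[:-1], self.dims[s], self.max_lag
            )
        return out

    def flatten(self, per_set: dict[str, np.ndarray]) -> np.ndarray:
        return np.concatenate([np.asarray(per_set[s]).reshape(-1) for s in self.sets])

    def set_slice(self, set_name: str) -> slice:
        off = self.offsets[set_name]
        return slice(off, off + self.dims[set_name] * self.max_lag)


def lagged(x: np.ndarray, max_lag: int) -> np.ndarray:
    """Stack lags 0..max_lag-1 of a (n, d) track into (n, d*max_lag).

    Lag tau at row t holds ``x[t - tau]``; leading history is zero-padded.
    Column order is dimension-major (all lags of dim 0, then dim 1, ...).
    """
    x = np.nan_to_num(np.asarray(x, dtype=float))
    if x.ndim == 1:
        x = x[:, None]
    n, d = x.shape
    out = np.zeros((n, d * max_lag))
    for tau in range(max_lag):
        shifted = x[: n - tau] if tau else x
        out[tau:, tau::max_lag] = shifted
    return out


def build_design_matrix(
    features: StimulusFeatures | dict[str, np.ndarray],
    feature_sets,
    max_lag: int,
) -> tuple[np.ndarray, ColumnMap]:
    """Time-lagged design matrix for the requested feature sets.

    Rows are time frames; columns are ordered (set, dimension, lag) with
    zero-padding for pre-stimulus history.
    """
    if max_lag < 1:
        raise ConfigurationError("max_lag must be >= 1")
    feature_sets = list(feature_sets)
    if isinstance(features, dict):
        get = features.__getitem__
        valid = set(features)
    else:
        get = features.matrix
        valid = set(FEATURE_SET_ORDER)
    unknown = [s for s in feature_sets if s not in valid]
    if unknown:
        raise KeyError(f"unknown feature set(s) {unknown}; valid: {sorted(valid)}")
    blocks = []
    dims = {}
    for s in feature_sets:
        m = np.atleast_2d(np.asarray(get(s), dtype=float))
        if m.shape[0] == 1 and m.size > 1:
            m = m.T
        dims[s] = m.shape[1]
        blocks.append(lagged(m, max_lag))
    X = np.concatenate(blocks, axis=1) if blocks else np.zeros((0, 0))
    return X, ColumnMap(sets=feature_sets, dims=dims, max_lag=max_lag)


# ---------------------------------------------------------------------------
# PCA of tone contours


@dataclass
class TonePCAResult:
    """Centered PCA of time-warped relative-pitch contours (X = L W^T)."""

    scores: np.ndarray  # (tokens, k)  L
    basis: np.ndarray  # (k, k) orthogonal  W
    explained_variance: np.ndarray  # fraction per component
    mean: np.ndarray  # column means removed before PCA
    warped: np.ndarray  # (tokens, k) the warped contour matrix
    kept: np.ndarray  # indices of tokens with enough voiced frames


def warp_contour(values: np.ndarray, n_points: int = 25) -> np.ndarray:
    """Linear resampling of a contour to ``n_points`` samples."""
    values = np.asarray(values, dtype=float)
    if values.size < 2:
        raise ValueError("need at least 2 samples to warp")
    src = np.linspace(0.0, 1.0, values.size)
    dst = np.linspace(0.0, 1.0, n_points)
    return np.interp(dst, src, values)


def tone_contour_pca(
    syllable_table: pd.DataFrame,
    rel_pitch_z: np.ndarray,
    phrase_table: pd.DataFrame,
    voicing: np.ndarray | None = None,
    n_points: int = 25,
    fs: float = FRAME_RATE,
) -> TonePCAResult:
    """PCA of per-syllable relative-pitch contours time-warped to 250 ms.

    Each token's voiced contour is linearly resampled to ``n_points`` samples
    (25 points = 250 ms at 100 Hz); the token x time matrix is centered and
    decomposed by SVD.  Tokens with fewer than 2 voiced frames are excluded.
    """
    spans = syllable_spans(syllable_table, phrase_table, fs)
    rel = np.asarray(rel_pitch_z, dtype=float)
    rows, kept = [], []
    for i, (a, b) in enumerate(spans):
        seg = rel[a:b]
        seg = seg[np.isfinite(seg)]
        if seg.size < 2:
            continue
        rows.append(warp_contour(seg, n_points))
        kept.append(i)
    n_excluded = len(spans) - len(kept)
    if n_excluded:
        logger.info("tone_contour_pca: excluded %d token(s) with <2 voiced frames", n_excluded)
    warped = np.asarray(rows)
    if warped.shape[0] <= n_points:
        raise ValueError(
            f"need more tokens ({warped.shape[0]}) than time points ({n_points}) for PCA"
        )
    mean = warped.mean(axis=0)
    centered = warped - mean
    u, s, vt = np.linalg.svd(centered, full_matrices=False)
    var = s**2
    total = var.sum()
    # identical contours leave only float residue after centering
    degenerate = total <= 1e-16 * max(1.0, float((warped**2).sum()))
    explained = np.zeros_like(var) if degenerate else var / total
    return TonePCAResult(
        scores=u * s,
        basis=vt.T,
        explained_variance=explained,
        mean=mean,
        warped=warped,
        kept=np.asarray(kept),
    )
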