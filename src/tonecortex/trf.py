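"""Temporal receptive field (TRF) encoding models and unique-variance
attribution.

The TRF is the lagged linear model

    y(t) = sum_f sum_tau  beta_f(tau)^T x_f(t - tau) + eps

mapping stimulus feature sets f (spectrum, intensity, pitch features, tone
category) at lags tau = 0..T-1 to an electrode's high-gamma y(t).  Fitting
uses ridge regression with contiguous 80/10/10 train/tune/test splits rotated
five times; performance is the held-out correlation between predicted and
actual activity (R^2 = its square, reported signed via differences, so unique
R^2 can be slightly negative).

The unique contribution of a feature set is the drop in held-out R^2 when the
set is removed from the full model.  Its significance is assessed against a
null built by shuffling the stimulus features between phrases (speech runs
bounded by >= 150 ms of silence) while leaving the neural data in place,
which preserves the features' local temporal structure but destroys their
alignment to the response.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from scipy.ndimage import gaussian_filter

from .errors import ConfigurationError, FeatureMismatchError
from .features import ColumnMap, StimulusFeatures, build_design_matrix
from .preproc import FRAME_RATE

logger = logging.getLogger(__name__)

DEFAULT_RIDGE_GRID = np.logspace(-2, 4, 8)
DEFAULT_MAX_LAG = 40  # frames = 400 ms
MIN_SILENCE_S = 0.15


# ---------------------------------------------------------------------------
# folds


def make_folds(
    n_frames: int,
    n_reps: int = 5,
    n_chunks: int = 10,
    bad_frames: np.ndarray | None = None,
) -> list[tuple[np.ndarray, np.ndarray, np.ndarray]]:
    """Rotated contiguous 80/10/10 partitions.

    The time axis is cut into ``n_chunks`` contiguous chunks; repetition r
    uses chunk 2r as the tuning set and chunk 2r+1 as the test set, the rest
    as training.  Contiguous (rather than random-frame) splits avoid leakage
    through the autocorrelation of the signals.
    """
    good = np.ones(n_frames, dtype=bool) if bad_frames is None else ~bad_frames
    edges = np.linspace(0, n_frames, n_chunks + 1).astype(int)
    chunks = [np.arange(edges[i], edges[i + 1])[good[edges[i] : edges[i + 1]]] for i in range(n_chunks)]
    folds = []
    for r in range(n_reps):
        tune_c, test_c = (2 * r) % n_chunks, (2 * r + 1) % n_chunks
        train = np.concatenate([c for i, c in enumerate(chunks) if i not in (tune_c, test_c)])
        folds.append((train, chunks[tune_c], chunks[test_c]))
    return folds


def _colwise_corr(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Pearson correlation of matching columns of (n, m) arrays; 0 where degenerate."""
    a = a - a.mean(axis=0)
    b = b - b.mean(axis=0)
    denom = np.sqrt((a**2).sum(axis=0) * (b**2).sum(axis=0))
    with np.errstate(invalid="ignore", divide="ignore"):
        r = (a * b).sum(axis=0) / denom
    return np.where(np.isfinite(r), r, 0.0)


# ---------------------------------------------------------------------------
# ridge core (vectorized over electrodes)


def _fit_population(
    Y: np.ndarray,  # (n_frames, m)
    X: np.ndarray,  # (n_frames, p)
    folds,
    ridge_grid: np.ndarray,
) -> dict:
    """Ridge fits for all electrodes under shared folds.

    Per repetition the Gram matrix of the training block is eigendecomposed
    once and the whole ridge path is swept by diagonal rescaling; the tuning
    set picks lambda per electrode (ties toward the larger lambda), the test
    set yields the held-out correlation.
    """
    m = Y.shape[1]
    n_reps = len(folds)
    n_lam = len(ridge_grid)
    p = X.shape[1]
    weights = np.zeros((m, p))
    test_corr = np.zeros((m, n_reps))
    chosen_lam = np.zeros((m, n_reps))
    for r, (tr, tu, te) in enumerate(folds):
        Xtr = X[tr]
        mx = Xtr.mean(axis=0)
        my = Y[tr].mean(axis=0)
        Xc = Xtr - mx
        G = Xc.T @ Xc
        evals, V = np.linalg.eigh(G)
        evals = np.clip(evals, 0.0, None)
        B = V.T @ (Xc.T @ (Y[tr] - my))  # (p, m)
        Xtu = X[tu] - mx
        Xte = X[te] - mx
        tune_perf = np.zeros((n_lam, m))
        W_all = np.zeros((n_lam, p, m))
        for li, lam in enumerate(ridge_grid):
            W = V @ (B / (evals + lam)[:, None])
            W_all[li] = W
            tune_perf[li] = _colwise_corr(Xtu @ W, Y[tu])
        # ties -> larger lambda (more regularized)
        best = (n_lam - 1) - np.argmax(tune_perf[::-1], axis=0)
        for e in range(m):
            W = W_all[best[e], :, e]
            weights[e] += W / n_reps
            test_corr[e, r] = _colwise_corr((Xte @ W)[:, None], Y[te, e][:, None])[0]
            chosen_lam[e, r] = ridge_grid[best[e]]
    return {
        "weights": weights,
        "test_corr": test_corr,
        "test_r2": test_corr**2,
        "chosen_lambda": chosen_lam,
    }


@dataclass
class TRFModel:
    """Fitted TRF for one electrode."""

    weights: dict[str, np.ndarray]  # set -> (dim, n_lags)
    colmap: ColumnMap
    max_lag: int
    ridge_strength: float  # modal chosen lambda across repetitions
    cv_performance: pd.DataFrame  # one row per repetition: corr, r2, lambda
    feature_sets: list[str]
    bin_edges: dict[str, np.ndarray] | None = None

    @property
    def performance(self) -> float:
        """Mean held-out prediction correlation across repetitions."""
        return float(self.cv_performance["corr"].mean())

    @property
    def r2(self) -> float:
        return float(self.cv_performance["r2"].mean())

    def flat_weights(self) -> np.ndarray:
        return self.colmap.flatten(self.weights)


def fit_trf(
    y: np.ndarray,
    X: np.ndarray,
    colmap: ColumnMap,
    folds=None,
    ridge_grid: np.ndarray | None = None,
    n_reps: int = 5,
    bin_edges: dict[str, np.ndarray] | None = None,
) -> TRFModel:
    """Fit one electrode's TRF; see module docstring for the CV scheme.

    A degenerate (all-zero/constant) response yields a zero-weight model with
    zero performance and a warning rather than an error.
    """
    y = np.asarray(y, dtype=float).ravel()
    ridge_grid = DEFAULT_RIDGE_GRID if ridge_grid is None else np.asarray(ridge_grid, float)
    if folds is None:
        folds = make_folds(y.size, n_reps=n_reps)
    if np.std(y) == 0:
        warnings.warn("degenerate (constant) response; returning zero-weight model", stacklevel=2)
        cv = pd.DataFrame({"corr": np.zeros(len(folds)), "r2": np.zeros(len(folds)), "lambda": np.nan})
        return TRFModel(
            weights=colmap.unflatten(np.zeros(colmap.n_columns)),
            colmap=colmap, max_lag=colmap.max_lag, ridge_strength=np.nan,
            cv_performance=cv, feature_sets=list(colmap.sets), bin_edges=bin_edges,
        )
    res = _fit_population(y[:, None], X, folds, ridge_grid)
    lams = res["chosen_lambda"][0]
    cv = pd.DataFrame({"corr": res["test_corr"][0], "r2": res["test_r2"][0], "lambda": lams})
    vals, counts = np.unique(lams, return_counts=True)
    return TRFModel(
        weights=colmap.unflatten(res["weights"][0]),
        colmap=colmap,
        max_lag=colmap.max_lag,
        ridge_strength=float(vals[np.argmax(counts)]),
        cv_performance=cv,
        feature_sets=list(colmap.sets),
        bin_edges=bin_edges,
    )


def fit_trf_population(
    Y: np.ndarray,
    X: np.ndarray,
    colmap: ColumnMap,
    folds=None,
    ridge_grid: np.ndarray | None = None,
    n_reps: int = 5,
    bin_edges: dict[str, np.ndarray] | None = None,
) -> list[TRFModel]:
    """Fit TRFs for many electrodes sharing one stimulus.

    All electrodes share the design matrix, so the training-block Gram
    factorization is computed once per repetition and reused; the result is
    identical to calling :func:`fit_trf` per electrode.
    """
    Y = np.atleast_2d(np.asarray(Y, dtype=float))
    ridge_grid = DEFAULT_RIDGE_GRID if ridge_grid is None else np.asarray(ridge_grid, float)
    if folds is None:
        folds = make_folds(Y.shape[1], n_reps=n_reps)
    res = _fit_population(Y.T, X, folds, ridge_grid)
    models = []
    for e in range(Y.shape[0]):
        lams = res["chosen_lambda"][e]
        vals, counts = np.unique(lams, return_counts=True)
        cv = pd.DataFrame(
            {"corr": res["test_corr"][e], "r2": res["test_r2"][e], "lambda": lams}
        )
        models.append(
            TRFModel(
                weights=colmap.unflatten(res["weights"][e]),
                colmap=colmap,
                max_lag=colmap.max_lag,
                ridge_strength=float(vals[np.argmax(counts)]),
                cv_performance=cv,
                feature_sets=list(colmap.sets),
                bin_edges=bin_edges,
            )
        )
    return models


# ---------------------------------------------------------------------------
# phrase segmentation and phrase-level shuffling


def segment_phrases(
    track: np.ndarray,
    fs: float = FRAME_RATE,
    min_silence_s: float = MIN_SILENCE_S,
    threshold: float = 0.0,
) -> pd.DataFrame:
    """Phrases = maximal speech runs bounded by silences >= ``min_silence_s``.

    ``track`` is an intensity or voicing track at 100 Hz; frames with value
    above ``threshold`` count as speech.  Speech runs separated by silences
    shorter than the minimum are merged.  Intervals are half-open frames,
    reported in seconds.
    """
    speech = np.asarray(track) > threshold
    min_gap = int(round(min_silence_s * fs))
    d = np.diff(np.concatenate(([0], speech.astype(int), [0])))
    starts = np.flatnonzero(d == 1)
    stops = np.flatnonzero(d == -1)
    rows = []
    for a, b in zip(starts, stops):
        if rows and a - rows[-1][1] < min_gap:
            rows[-1][1] = b  # merge across short gap
        else:
            rows.append([a, b])
    return pd.DataFrame(
        {
            "phrase_id": np.arange(len(rows)),
            "start_s": [a / fs for a, _ in rows],
            "end_s": [b / fs for _, b in rows],
        }
    )


def phrase_frame_spans(phrase_table: pd.DataFrame, fs: float = FRAME_RATE) -> list[tuple[int, int]]:
    return [
        (int(round(a * fs)), int(round(b * fs)))
        for a, b in zip(phrase_table["start_s"], phrase_table["end_s"])
    ]


def permute_phrases(
    tracks: dict[str, np.ndarray],
    phrase_table: pd.DataFrame,
    rng: np.random.Generator,
    fs: float = FRAME_RATE,
    return_spans: bool = False,
):
    """Shuffle per-frame feature tracks between phrases, leaving silences.

    The per-phrase segments of every track are re-concatenated in one random
    order into the original speech-frame positions, so each feature's
    multiset of phrase segments (and its marginal distribution) is preserved
    exactly while the alignment to the neural data is destroyed.  Because
    phrases differ in length, segment boundaries shift (a long segment can
    spill past its slot into the next one); with ``return_spans=True`` the
    frame-index arrays of the permuted segments are returned alongside the
    tracks.
    """
    spans = phrase_frame_spans(phrase_table, fs)
    order = rng.permutation(len(spans))
    src = np.concatenate([np.arange(*spans[i]) for i in order])
    dst = np.concatenate([np.arange(*s) for s in spans])
    out = {}
    for name, x in tracks.items():
        x = np.asarray(x)
        y = x.copy()
        y[dst] = x[src]
        out[name] = y
    if not return_spans:
        return out
    lengths = [spans[i][1] - spans[i][0] for i in order]
    bounds = np.concatenate(([0], np.cumsum(lengths)))
    new_segments = [dst[a:b] for a, b in zip(bounds[:-1], bounds[1:])]
    return out, new_segments


# ---------------------------------------------------------------------------
# unique variance


@dataclass
class VarianceDecomposition:
    """Full/reduced/unique held-out R^2 for one electrode.

    ``significant[probe]`` is True when the observed unique R^2 exceeds the
    99th percentile of its phrase-shuffle null.
    """

    full_r2: float
    reduced_r2: dict[str, float]
    unique_r2: dict[str, float]
    null_unique_r2: dict[str, np.ndarray]
    p_threshold_value: dict[str, float]
    significant: dict[str, bool]
    p_value: dict[str, float]


def _normalize_probes(probe_sets) -> dict[str, list[str]]:
    probes = {}
    for p in probe_sets:
        if isinstance(p, str):
            probes[p] = [p]
        else:
            probes["+".join(p)] = list(p)
    return probes


def unique_variance(
    Y: np.ndarray,
    features: StimulusFeatures | dict[str, np.ndarray],
    full_sets,
    probe_sets,
    max_lag: int = DEFAULT_MAX_LAG,
    phrase_table: pd.DataFrame | None = None,
    n_reps: int = 5,
    n_reps_null: int = 1,
    n_perm: int = 200,
    ridge_grid: np.ndarray | None = None,
    seed: int = 0,
    percentile: float = 99.0,
) -> list[VarianceDecomposition]:
    """Unique-variance attribution with a phrase-shuffle permutation null.

    Parameters
    ----------
    Y : (n_electrodes, n_frames) or (n_frames,) high-gamma.
    probe_sets : feature sets (or groups of sets, e.g.
        ``[["rel_pitch", "pitch_change"]]`` for speaker-normalized pitch)
        whose unique contribution is tested.
    n_reps_null : CV repetitions used inside each permutation (1 by default:
        the null needs the distribution of unique R^2, not its five-fold
        average, and one rotation per shuffle keeps 200 shuffles tractable).

    All electrodes share the stimulus, so each (permuted) design matrix is
    factored once and reused across electrodes.
    """
    Y = np.atleast_2d(np.asarray(Y, dtype=float)).T  # (n_frames, m)
    full_sets = list(full_sets)
    probes = _normalize_probes(probe_sets)
    for name, sets in probes.items():
        missing = [s for s in sets if s not in full_sets]
        if missing:
            raise ConfigurationError(f"probe {name!r} not within full model: {missing}")
    if n_perm < 100:
        warnings.warn(
            f"n_perm={n_perm} < 100: the {percentile}th percentile of the null is unstable",
            stacklevel=2,
        )
    ridge_grid = DEFAULT_RIDGE_GRID if ridge_grid is None else np.asarray(ridge_grid, float)
    if phrase_table is None:
        if isinstance(features, StimulusFeatures):
            phrase_table = features.phrase_table
        else:
            raise ConfigurationError("phrase_table required when features is a plain dict")

    if isinstance(features, StimulusFeatures):
        tracks = {s: features.matrix(s) for s in full_sets}
    else:
        tracks = {s: features[s] for s in full_sets}
    n_frames = Y.shape[0]
    m = Y.shape[1]
    folds = make_folds(n_frames, n_reps=n_reps)
    folds_null = folds[:n_reps_null]

    def fit_r2(trk, use_folds):
        X, colmap = build_design_matrix(trk, full_sets, max_lag)
        full = _fit_population(Y, X, use_folds, ridge_grid)["test_r2"].mean(axis=1)
        uniq = {}
        for name, sets in probes.items():
            keep = np.concatenate(
                [np.arange(colmap.set_slice(s).start, colmap.set_slice(s).stop)
                 for s in full_sets if s not in sets]
            )
            red = _fit_population(Y, X[:, keep], use_folds, ridge_grid)["test_r2"].mean(axis=1)
            uniq[name] = (full - red, red)
        return full, uniq

    full_r2, uniq_obs = fit_r2(tracks, folds)

    rng = np.random.default_rng(seed)
    null = {name: np.zeros((n_perm, m)) for name in probes}
    for k in range(n_perm):
        perm_tracks = permute_phrases(tracks, phrase_table, rng)
        _, uniq_perm = fit_r2(perm_tracks, folds_null)
        for name in probes:
            null[name][k] = uniq_perm[name][0]

    out = []
    for e in range(m):
        reduced = {name: float(uniq_obs[name][1][e]) for name in probes}
        uniq = {name: float(uniq_obs[name][0][e]) for name in probes}
        nulls = {name: null[name][:, e] for name in probes}
        thresh = {name: float(np.percentile(nulls[name], percentile)) for name in probes}
        out.append(
            VarianceDecomposition(
                full_r2=float(full_r2[e]),
                reduced_r2=reduced,
                unique_r2=uniq,
                null_unique_r2=nulls,
                p_threshold_value=thresh,
                significant={name: uniq[name] > thresh[name] for name in probes},
                p_value={
                    name: float((nulls[name] >= uniq[name]).mean()) for name in probes
                },
            )
        )
    return out


# ---------------------------------------------------------------------------
# cross-language model transfer and weight comparison


def cross_language_transfer(
    model_b: TRFModel,
    features_a: StimulusFeatures | dict[str, np.ndarray],
    y_a: np.ndarray,
) -> tuple[np.ndarray, float]:
    """Apply a TRF fitted on stimulus B to stimulus A's features.

    Only feature sets present in the fitted model are used (the common
    features of the two stimuli).  The two feature builds must share pitch
    bin edges; otherwise the binned representations live in different spaces
    and the transfer is invalid.
    """
    if model_b.bin_edges is not None and isinstance(features_a, StimulusFeatures):
        for name, edges in model_b.bin_edges.items():
            other = features_a.pitch.bin_edges.get(name)
            if other is None or not np.allclose(edges, other):
                raise FeatureMismatchError(
                    f"bin edges for {name!r} differ between feature builds; "
                    "rebuild both stimuli with shared edges"
                )
    X, colmap = build_design_matrix(features_a, model_b.feature_sets, model_b.max_lag)
    if colmap.n_columns != model_b.colmap.n_columns:
        raise FeatureMismatchError(
            f"design matrix has {colmap.n_columns} columns, model expects "
            f"{model_b.colmap.n_columns}"
        )
    y_a = np.asarray(y_a, dtype=float).ravel()
    pred = X @ model_b.flat_weights()
    pred = pred - pred.mean() + y_a.mean()
    r = _colwise_corr(pred[:, None], y_a[:, None])[0]
    return pred, float(r)


def compare_model_weights(model_a: TRFModel, model_b: TRFModel, sets) -> float:
    """Correlation of two models' weights after per-set 2D Gaussian blurring.

    Each feature set's (dim, lag) weight matrix is blurred with sigma = 1 (in
    bin and lag index units) to suppress estimation noise, then the selected
    sets are flattened and Pearson-correlated.
    """
    sets = list(sets)
    va, vb = [], []
    for s in sets:
        wa, wb = model_a.weights[s], model_b.weights[s]
        if wa.shape != wb.shape:
            raise ConfigurationError(
                f"weight shape mismatch for set {s!r}: {wa.shape} vs {wb.shape}"
            )
        va.append(gaussian_filter(wa, sigma=1.0).ravel())
        vb.append(gaussian_filter(wb, sigma=1.0).ravel())
    return float(stats.pearsonr(np.concatenate(va), np.concatenate(vb))[0])


def bootstrap_model_comparison(
    pred_a: np.ndarray,
    pred_b: np.ndarray,
    actual: np.ndarray,
    trial_spans,
    n_boot: int = 200,
    n_trials: int = 500,
    seed: int = 0,
) -> dict:
    """Bootstrap distributions of prediction correlation for two models.

    Each bootstrap draws ``n_trials`` trials (epoch frame spans) with
    replacement, concatenates their frames, and correlates actual vs
    predicted for both models; the two ``n_boot``-point distributions are
    compared with a two-sample Kolmogorov-Smirnov test.
    """
    trial_spans = list(trial_spans)
    if len(trial_spans) < 2:
        raise ValueError("need at least 2 trials to bootstrap")
    rng = np.random.default_rng(seed)
    frames = [np.arange(int(a), int(b)) for a, b in trial_spans]
    dist_a = np.zeros(n_boot)
    dist_b = np.zeros(n_boot)
    for i in range(n_boot):
        pick = rng.integers(len(frames), size=n_trials)
        idx = np.concatenate([frames[j] for j in pick])
        dist_a[i] = _colwise_corr(pred_a[idx, None], actual[idx, None])[0]
        dist_b[i] = _colwise_corr(pred_b[idx, None], actual[idx, None])[0]
    ks = stats.ks_2samp(dist_a, dist_b)
    return {
        "dist_a": dist_a,
        "dist_b": dist_b,
        "ks_statistic": float(ks.statistic),
        "p_value": float(ks.pvalue),
    }
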