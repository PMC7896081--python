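"""Population tone decoding and representational similarity analysis.

Pairwise tone classification uses logistic regression with a group-lasso
penalty across electrodes: the L2 norms of each electrode's five temporal
coefficients are summed, giving an L1 penalty over electrodes that keeps
temporal smoothness within an electrode while selecting sparsely between
electrodes.  Accuracy is estimated with nested cross-validation (outer
5-fold for accuracy, inner 10-fold for the penalty lambda) on a sliding
50 ms window (five 100 Hz frames) over vowel-aligned epochs.

The representational analysis partitions syllables into 16 groups (4 tones x
4 quartiles of mean relative pitch height or mean pitch change), classifies
all 120 group pairs at the peak decoding window, and summarizes categorical
structure with the categorical index

    CI = mean between-tone accuracy - mean within-tone accuracy,

tested against a 200-fold group-label permutation null at the 95th
percentile.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np

from .errors import ConfigurationError

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# group-lasso logistic regression (proximal solver)


def _group_starts(groups: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Start indices and sizes of contiguous column groups."""
    groups = np.asarray(groups)
    change = np.flatnonzero(np.diff(groups)) + 1
    starts = np.concatenate(([0], change))
    counts = np.diff(np.concatenate((starts, [groups.size])))
    return starts, counts


def _logistic_loss_grad(X, y, w, b):
    """Mean logistic loss and its gradient; y in {-1, +1}."""
    m = y * (X @ w + b)
    # stable log(1 + exp(-m))
    loss = np.mean(np.logaddexp(0.0, -m))
    s = -y / (1.0 + np.exp(m))  # = -y * sigmoid(-m)
    gw = X.T @ s / X.shape[0]
    gb = s.mean()
    return loss, gw, gb


def _group_norms(w, starts):
    return np.sqrt(np.add.reduceat(w**2, starts))


def _prox_group(w, starts, counts, thresh):
    """Block soft-threshold: shrink each group's L2 norm by ``thresh``."""
    norms = _group_norms(w, starts)
    scale = np.maximum(0.0, 1.0 - thresh / np.maximum(norms, 1e-300))
    return w * np.repeat(scale, counts)


def lambda_max(X: np.ndarray, y: np.ndarray, groups: np.ndarray) -> float:
    """Smallest penalty at which every group is exactly zero.

    With w = 0 and the intercept at its optimum, all groups stay at zero iff
    lambda >= max_g ||grad_g||.
    """
    y = np.asarray(y, dtype=float)
    p_pos = (y > 0).mean()
    b = np.log(p_pos / (1 - p_pos)) if 0 < p_pos < 1 else 0.0
    _, gw, _ = _logistic_loss_grad(X, y, np.zeros(X.shape[1]), b)
    starts, _ = _group_starts(groups)
    return float(_group_norms(gw, starts).max())


def group_lasso_logistic(
    X: np.ndarray,
    y: np.ndarray,
    groups: np.ndarray,
    lam: float,
    max_iter: int = 500,
    tol: float = 1e-7,
    w0: np.ndarray | None = None,
) -> dict:
    """Minimize mean logistic loss + lam * sum_g ||w_g||_2.

    Monotone FISTA with fixed step 1/L (L from the spectral norm of the
    intercept-augmented design), so the objective decreases at every
    iteration.  Returns weights, intercept, objective trace, convergence
    flag, and the maximum KKT residual at exit.
    """
    X = np.asarray(X, dtype=float)
    y = np.where(np.asarray(y) > 0, 1.0, -1.0)
    n, p = X.shape
    starts, counts = _group_starts(groups)
    Xa = np.hstack([X, np.ones((n, 1))])
    L = np.linalg.norm(Xa, 2) ** 2 / (4.0 * n)
    step = 1.0 / max(L, 1e-12)

    w = np.zeros(p) if w0 is None else w0.copy()
    b = 0.0
    t_mom = 1.0
    zw, zb = w.copy(), b

    def objective(w_, b_):
        m = y * (X @ w_ + b_)
        return np.mean(np.logaddexp(0.0, -m)) + lam * _group_norms(w_, starts).sum()

    obj = objective(w, b)
    trace = [obj]
    converged = False
    stall = 0
    for it in range(max_iter):
        _, gw, gb = _logistic_loss_grad(X, y, zw, zb)
        cand_w = _prox_group(zw - step * gw, starts, counts, lam * step)
        cand_b = zb - step * gb
        cand_obj = objective(cand_w, cand_b)
        x_prev_w, x_prev_b = w, b
        if cand_obj <= obj:
            stall = stall + 1 if obj - cand_obj < tol * max(1.0, abs(obj)) else 0
            w, b, obj = cand_w, cand_b, cand_obj
        else:
            # monotone safeguard: keep the best iterate, restart momentum
            stall += 1
            t_mom = 1.0
        t_next = 0.5 * (1.0 + np.sqrt(1.0 + 4.0 * t_mom**2))
        zw = w + (t_mom / t_next) * (cand_w - w) + ((t_mom - 1.0) / t_next) * (w - x_prev_w)
        zb = b + (t_mom / t_next) * (cand_b - b) + ((t_mom - 1.0) / t_next) * (b - x_prev_b)
        t_mom = t_next
        trace.append(obj)
        if stall >= 10 and it > 20:
            converged = True
            break

    # KKT residual
    _, gw, gb = _logistic_loss_grad(X, y, w, b)
    norms = _group_norms(w, starts)
    gnorms = _group_norms(gw, starts)
    kkt = abs(gb)
    for gi, s in enumerate(starts):
        sl = slice(s, s + counts[gi])
        if norms[gi] > 0:
            kkt = max(kkt, float(np.linalg.norm(gw[sl] + lam * w[sl] / norms[gi])))
        else:
            kkt = max(kkt, max(0.0, float(gnorms[gi]) - lam))
    if not converged:
        logger.info("group_lasso_logistic: max_iter=%d reached (kkt=%.2e)", max_iter, kkt)
    return {
        "w": w,
        "b": b,
        "objective": np.asarray(trace),
        "converged": converged,
        "n_iter": len(trace) - 1,
        "kkt": kkt,
        "group_norms": norms,
    }


# ---------------------------------------------------------------------------
# cross-validated pairwise classification


@dataclass
class DecodeConfig:
    """Knobs of the pairwise decoding machinery."""

    window_len: int = 5  # frames = 50 ms
    outer_folds: int = 5
    inner_folds: int = 10
    lambda_grid: np.ndarray | None = None  # None -> adaptive grid per pair
    n_lambdas: int = 10
    stride: int = 1
    seed: int = 0
    electrode_subset: np.ndarray | None = None
    max_iter: int = 400
    tol: float = 1e-7

    def __post_init__(self):
        if self.window_len < 1:
            raise ConfigurationError("window_len must be >= 1")
        if self.outer_folds < 2 or self.inner_folds < 2:
            raise ConfigurationError("folds must be >= 2")


def _stratified_folds(labels: np.ndarray, k: int, rng: np.random.Generator):
    folds = [[] for _ in range(k)]
    for c in np.unique(labels):
        idx = np.flatnonzero(labels == c)
        rng.shuffle(idx)
        for i, ix in enumerate(idx):
            folds[i % k].append(ix)
    return [np.asarray(sorted(f)) for f in folds]


def _standardize(train: np.ndarray, other: np.ndarray):
    mu = train.mean(axis=0)
    sd = train.std(axis=0)
    sd[sd == 0] = 1.0
    return (train - mu) / sd, (other - mu) / sd


def pairwise_group_lasso(
    trials_a: np.ndarray,
    trials_b: np.ndarray,
    groups: np.ndarray,
    config: DecodeConfig,
    rng: np.random.Generator | None = None,
) -> tuple[float, dict]:
    """Cross-validated binary classification accuracy for one class pair.

    The larger class is subsampled to match the smaller (chance stays exactly
    0.5); features are standardized on each training fold.  With a
    single-value ``lambda_grid`` the inner CV is skipped.  Returns the outer
    k-fold accuracy and per-trial correctness (for bootstrap comparisons).
    """
    rng = np.random.default_rng(config.seed) if rng is None else rng
    na, nb = len(trials_a), len(trials_b)
    n_min = min(na, nb)
    if n_min < 2 * config.outer_folds:
        raise ValueError(
            f"class sizes ({na}, {nb}) too small for {config.outer_folds}-fold CV"
        )
    if n_min < 20:
        warnings.warn(f"fewer than 20 trials per class ({na}, {nb})", stacklevel=2)
    ia = rng.permutation(na)[:n_min]
    ib = rng.permutation(nb)[:n_min]
    X = np.concatenate([np.asarray(trials_a)[ia], np.asarray(trials_b)[ib]])
    y = np.concatenate([np.ones(n_min), -np.ones(n_min)])
    X = np.nan_to_num(X)

    if config.lambda_grid is not None:
        grid = np.sort(np.asarray(config.lambda_grid, dtype=float))
    else:
        # adaptive grid anchored at lambda_max of the full standardized data
        Xs = _standardize(X, X)[0]
        grid = lambda_max(Xs, y, groups) * np.logspace(-2.5, -0.25, config.n_lambdas)

    correct = np.zeros(2 * n_min, dtype=bool)
    chosen = []
    for test_idx in _stratified_folds(y, config.outer_folds, rng):
        train_idx = np.setdiff1d(np.arange(y.size), test_idx)
        Xtr, Xte = _standardize(X[train_idx], X[test_idx])
        ytr, yte = y[train_idx], y[test_idx]
        if grid.size > 1:
            inner_acc = np.zeros(grid.size)
            inner_folds = _stratified_folds(ytr, config.inner_folds, rng)
            for vi in inner_folds:
                ti = np.setdiff1d(np.arange(ytr.size), vi)
                Xi, Xv = _standardize(Xtr[ti], Xtr[vi])
                w0 = None
                # descend the path from the sparsest end with warm starts
                for li in range(grid.size - 1, -1, -1):
                    fit = group_lasso_logistic(
                        Xi, ytr[ti], groups, grid[li],
                        max_iter=config.max_iter, tol=config.tol, w0=w0,
                    )
                    w0 = fit["w"]
                    pred = Xv @ fit["w"] + fit["b"]
                    inner_acc[li] += ((pred >= 0) == (ytr[vi] > 0)).mean()
            # ties -> larger lambda (sparser model)
            best = grid.size - 1 - int(np.argmax(inner_acc[::-1]))
            lam = grid[best]
        else:
            lam = grid[0]
        chosen.append(lam)
        fit = group_lasso_logistic(
            Xtr, ytr, groups, lam, max_iter=config.max_iter, tol=config.tol
        )
        pred = Xte @ fit["w"] + fit["b"]
        correct[test_idx] = (pred >= 0) == (yte > 0)
    acc = float(correct.mean())
    info = {
        "correct": correct,
        "labels": y,
        "trial_index_a": ia,
        "trial_index_b": ib,
        "chosen_lambda": np.asarray(chosen),
    }
    return acc, info


# ---------------------------------------------------------------------------
# sliding-window decoding


@dataclass
class DecodeResult:
    """Pairwise accuracies over sliding windows."""

    pairwise_acc: np.ndarray  # (n_pairs, n_windows)
    mean_acc: np.ndarray  # (n_windows,)
    window_starts: np.ndarray
    pairs: list[tuple[int, int]]
    peak_window: int  # index into window_starts
    peak_acc: float
    peak_info: dict = field(default_factory=dict)  # pair -> per-trial correctness
    acoustic_acc: float | None = None

    def relative_change(self, acoustic_acc: float | None = None) -> float:
        """Percent change of over-chance accuracy vs the acoustic baseline."""
        q_aco = self.acoustic_acc if acoustic_acc is None else acoustic_acc
        if q_aco is None:
            raise ConfigurationError("no acoustic baseline accuracy available")
        return float(
            ((self.peak_acc - 0.5) - (q_aco - 0.5)) / (q_aco - 0.5) * 100.0
        )


def _window_features(epochs: np.ndarray, start: int, window_len: int):
    """Concatenate ``window_len`` frames of all electrodes; groups = electrode."""
    n_trials, n_el, _ = epochs.shape
    X = epochs[:, :, start : start + window_len].reshape(n_trials, n_el * window_len)
    groups = np.repeat(np.arange(n_el), window_len)
    return X, groups


def sliding_decode(
    epochs: np.ndarray,
    labels: np.ndarray,
    config: DecodeConfig,
) -> DecodeResult:
    """All six tone-pair classifications at every sliding window position.

    ``epochs`` is (trials, n_electrodes, n_frames) aligned to vowel onset.
    """
    epochs = np.asarray(epochs, dtype=float)
    if config.electrode_subset is not None:
        epochs = epochs[:, np.asarray(config.electrode_subset)]
    labels = np.asarray(labels)
    classes = np.unique(labels)
    pairs = [(int(a), int(b)) for i, a in enumerate(classes) for b in classes[i + 1 :]]
    n_frames = epochs.shape[2]
    starts = np.arange(0, n_frames - config.window_len + 1, config.stride)
    if starts.size == 0:
        raise ConfigurationError(
            f"window_len={config.window_len} exceeds epoch length {n_frames}"
        )
    rng = np.random.default_rng(config.seed)
    acc = np.zeros((len(pairs), starts.size))
    infos: list[dict] = [dict() for _ in starts]
    for wi, s in enumerate(starts):
        Xw, groups = _window_features(epochs, s, config.window_len)
        for pi, (a, b) in enumerate(pairs):
            acc[pi, wi], info = pairwise_group_lasso(
                Xw[labels == a], Xw[labels == b], groups, config, rng
            )
            infos[wi][(a, b)] = info
    mean_acc = acc.mean(axis=0)
    peak = int(np.argmax(mean_acc))
    return DecodeResult(
        pairwise_acc=acc,
        mean_acc=mean_acc,
        window_starts=starts,
        pairs=pairs,
        peak_window=peak,
        peak_acc=float(mean_acc[peak]),
        peak_info=infos[peak],
    )


def acoustic_decode(
    contours: np.ndarray,
    labels: np.ndarray,
    config: DecodeConfig,
) -> tuple[float, np.ndarray]:
    """Baseline classification in the acoustic space.

    ``contours`` is (tokens, 25, 2): the full time-warped 250 ms course of
    relative pitch height and pitch change.  The same classifier machinery is
    applied to the flattened 50-dim representation with time points as
    penalty groups.  Returns mean pairwise accuracy and per-pair accuracies.
    """
    contours = np.asarray(contours, dtype=float)
    n_tok, n_t, n_feat = contours.shape
    X = contours.reshape(n_tok, n_t * n_feat)
    groups = np.repeat(np.arange(n_t), n_feat)
    labels = np.asarray(labels)
    classes = np.unique(labels)
    rng = np.random.default_rng(config.seed)
    accs = []
    for i, a in enumerate(classes):
        for b in classes[i + 1 :]:
            acc, _ = pairwise_group_lasso(X[labels == a], X[labels == b], groups, config, rng)
            accs.append(acc)
    accs = np.asarray(accs)
    return float(accs.mean()), accs


# ---------------------------------------------------------------------------
# RSA: 16-group partition, RDM, categorical index


def rsa_partition(tones: np.ndarray, values: np.ndarray, n_quartiles: int = 4) -> np.ndarray:
    """16-group partition: within each tone, quartile split by mean feature.

    Returns group ids ``(tone - 1) * n_quartiles + quartile``; within each
    tone the quartile sizes differ by at most one.  Ties across a quartile
    boundary are broken by stable token order.
    """
    tones = np.asarray(tones)
    values = np.asarray(values, dtype=float)
    out = np.full(tones.size, -1)
    for tone in np.unique(tones):
        idx = np.flatnonzero(tones == tone)
        if idx.size < 2 * n_quartiles:
            raise ValueError(f"tone {tone} has only {idx.size} tokens; need >= {2 * n_quartiles}")
        order = idx[np.argsort(values[idx], kind="stable")]
        for q, chunk in enumerate(np.array_split(order, n_quartiles)):
            out[chunk] = (int(tone) - 1) * n_quartiles + q
    return out


@dataclass
class RSAResult:
    groups: np.ndarray  # per-token group id 0..15
    rdm: np.ndarray  # (16, 16) pairwise accuracy, NaN diagonal
    ci: float
    null_ci: np.ndarray
    p: float
    n_skipped_pairs: int = 0


def categorical_index(rdm: np.ndarray, n_quartiles: int = 4) -> float:
    """CI = mean between-tone cell - mean within-tone cell of the RDM."""
    n = rdm.shape[0]
    tone_of = np.arange(n) // n_quartiles
    iu, ju = np.triu_indices(n, k=1)
    vals = rdm[iu, ju]
    between = tone_of[iu] != tone_of[ju]
    ok = np.isfinite(vals)
    return float(np.nanmean(vals[between & ok]) - np.nanmean(vals[~between & ok]))


def _rdm_once(
    X: np.ndarray,
    groups: np.ndarray,
    config: DecodeConfig,
    rng: np.random.Generator,
    n_groups: int,
    feature_groups: np.ndarray,
) -> tuple[np.ndarray, int]:
    rdm = np.full((n_groups, n_groups), np.nan)
    skipped = 0
    for i in range(n_groups):
        for j in range(i + 1, n_groups):
            xi, xj = X[groups == i], X[groups == j]
            if min(len(xi), len(xj)) < 2 * config.outer_folds:
                skipped += 1
                continue
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                acc, _ = pairwise_group_lasso(xi, xj, feature_groups, config, rng)
            rdm[i, j] = rdm[j, i] = acc
    return rdm, skipped


def rsa_rdm_and_ci(
    X: np.ndarray,
    groups: np.ndarray,
    config: DecodeConfig,
    feature_groups: np.ndarray | None = None,
    n_perm: int = 200,
    seed: int = 0,
    n_quartiles: int = 4,
) -> RSAResult:
    """RDM of pairwise group classification and the categorical index.

    ``X`` is (tokens, d): the peak-window neural pattern or the flattened
    acoustic contour.  The null shuffles group labels over tokens and reruns
    the identical procedure; p is the fraction of null CIs >= the observed
    CI.  Pairs with too few tokens for the outer CV are skipped (NaN cells).
    """
    X = np.asarray(X, dtype=float)
    groups = np.asarray(groups)
    n_groups = int(groups.max()) + 1
    if feature_groups is None:
        feature_groups = np.arange(X.shape[1])
    rng = np.random.default_rng(seed)
    rdm, skipped = _rdm_once(X, groups, config, rng, n_groups, feature_groups)
    if skipped:
        logger.info("rsa: skipped %d pair(s) with too few tokens", skipped)
    ci = categorical_index(rdm, n_quartiles)
    null = np.zeros(n_perm)
    for k in range(n_perm):
        shuffled = rng.permutation(groups)
        rdm_k, _ = _rdm_once(X, shuffled, config, rng, n_groups, feature_groups)
        null[k] = categorical_index(rdm_k, n_quartiles)
    p = float((null >= ci).mean()) if n_perm else np.nan
    return RSAResult(groups=groups, rdm=rdm, ci=ci, null_ci=null, p=p, n_skipped_pairs=skipped)


# ---------------------------------------------------------------------------
# electrode ablation


def ablate_and_decode(
    epochs: np.ndarray,
    labels: np.ndarray,
    config: DecodeConfig,
    drop: np.ndarray,
    full_result: DecodeResult | None = None,
    n_boot: int = 200,
    seed: int = 0,
) -> tuple[DecodeResult, dict]:
    """Re-decode after removing a subset of electrodes.

    ``drop`` is a boolean mask or index array over electrodes (e.g. the
    strongly negatively tuned ones).  Returns the ablated DecodeResult and a
    bootstrap comparison of peak accuracies (``n_boot`` resamples of the
    per-trial correctness at each result's own peak window).
    """
    epochs = np.asarray(epochs, dtype=float)
    n_el = epochs.shape[1]
    drop_mask = np.zeros(n_el, dtype=bool)
    drop_mask[np.asarray(drop)] = True
    keep = np.flatnonzero(~drop_mask)
    if keep.size == 0:
        raise ValueError("ablation would remove every electrode")
    if keep.size == n_el:
        raise ValueError("drop selector resolves to an empty set")
    if full_result is None:
        full_result = sliding_decode(epochs, labels, config)
    ablated = sliding_decode(epochs[:, keep], labels, config)

    rng = np.random.default_rng(seed)

    def boot(result):
        flags = [info["correct"] for info in result.peak_info.values()]
        out = np.zeros(n_boot)
        for i in range(n_boot):
            out[i] = np.mean(
                [f[rng.integers(f.size, size=f.size)].mean() for f in flags]
            )
        return out

    boot_full = boot(full_result)
    boot_abl = boot(ablated)
    d = boot_full - boot_abl
    p_two = 2.0 * min((d <= 0).mean(), (d >= 0).mean())
    comparison = {
        "delta": full_result.peak_acc - ablated.peak_acc,
        "boot_full": boot_full,
        "boot_ablated": boot_abl,
        "p_value": min(1.0, float(p_two)),
    }
    return ablated, comparison
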