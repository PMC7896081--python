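"""Group-lasso classifier, sliding decoding, acoustic baseline, RSA, ablation."""

import numpy as np
import pytest

from tonecortex import decoding as dec
from tonecortex.errors import ConfigurationError


@pytest.fixture(scope="module")
def fast_cfg():
    return dec.DecodeConfig(outer_folds=3, inner_folds=3, n_lambdas=4, seed=0)


# ---------------------------------------------------------------------------
# solver


def test_full_shrinkage_above_lambda_max(rng):
    X = rng.standard_normal((80, 20))
    y = np.sign(rng.standard_normal(80))
    groups = np.repeat(np.arange(4), 5)
    lmax = dec.lambda_max(X, y, groups)
    fit = dec.group_lasso_logistic(X, y, groups, lam=lmax * 1.01)
    assert np.all(fit["group_norms"] == 0.0)
    fit_below = dec.group_lasso_logistic(X, y, groups, lam=lmax * 0.5, max_iter=1000)
    assert np.any(fit_below["group_norms"] > 0)


def test_objective_monotone_and_kkt_small(rng):
    X = rng.standard_normal((100, 30))
    w_true = np.zeros(30)
    w_true[:5] = 2.0
    y = np.sign(X @ w_true + 0.3 * rng.standard_normal(100))
    groups = np.repeat(np.arange(6), 5)
    fit = dec.group_lasso_logistic(X, y, groups, lam=0.02, max_iter=3000, tol=1e-12)
    obj = fit["objective"]
    assert np.all(np.diff(obj) <= 1e-12)
    assert fit["kkt"] < 1e-3


def test_lambda_zero_matches_unpenalized_logistic_oracle(rng):
    """lambda = 0 on a tiny separable problem: decisions agree 100% with
    scikit-learn's (effectively unpenalized) logistic regression."""
    from sklearn.linear_model import LogisticRegression

    n = 50
    X = rng.standard_normal((2 * n, 10))
    X[n:, :3] += 2.0
    y = np.r_[-np.ones(n), np.ones(n)]
    groups = np.repeat(np.arange(5), 2)
    fit = dec.group_lasso_logistic(X, y, groups, lam=0.0, max_iter=5000, tol=1e-12)
    ours = np.sign(X @ fit["w"] + fit["b"])
    oracle = LogisticRegression(C=1e6, max_iter=10000).fit(X, y)
    theirs = 2.0 * oracle.predict(X) - 0.0  # already in {-1, 1}
    assert np.mean(ours == oracle.predict(X)) == 1.0


def test_planted_sparse_electrodes_recovered(rng):
    """2 informative of 10 electrode groups: moderate lambda selects (a
    superset close to) the informative groups and accuracy >= 0.9."""
    n = 60
    n_el, n_frames = 10, 5
    Xa = rng.standard_normal((n, n_el * n_frames))
    Xb = rng.standard_normal((n, n_el * n_frames))
    for e in (2, 7):
        Xb[:, e * n_frames : (e + 1) * n_frames] += 1.5
    groups = np.repeat(np.arange(n_el), n_frames)
    X = np.vstack([Xa, Xb])
    y = np.r_[-np.ones(n), np.ones(n)]
    Xs = (X - X.mean(axis=0)) / X.std(axis=0)
    lam = 0.4 * dec.lambda_max(Xs, y, groups)
    fit = dec.group_lasso_logistic(Xs, y, groups, lam=lam, max_iter=2000)
    nonzero = set(np.flatnonzero(fit["group_norms"] > 1e-8))
    assert {2, 7} <= nonzero
    assert len(nonzero - {2, 7}) <= 1
    cfg = dec.DecodeConfig(outer_folds=5, inner_folds=5, n_lambdas=6, seed=3)
    acc, _ = dec.pairwise_group_lasso(Xa, Xb, groups, cfg)
    assert acc >= 0.9


def test_chance_accuracy_at_full_shrinkage(rng):
    """A huge fixed lambda zeroes every group; accuracy sits at chance."""
    n = 40
    Xa = rng.standard_normal((n, 20))
    Xb = rng.standard_normal((n, 20)) + 1.0
    groups = np.repeat(np.arange(4), 5)
    cfg = dec.DecodeConfig(
        outer_folds=4, inner_folds=2, lambda_grid=np.array([50.0]), seed=1
    )
    acc, _ = dec.pairwise_group_lasso(Xa, Xb, groups, cfg)
    assert acc == pytest.approx(0.5, abs=0.15)


# ---------------------------------------------------------------------------
# sliding decode


def _categorical_epochs(rng, n_per_tone=25, n_el=6, n_frames=12, gain=2.0, noise=0.5):
    """Electrodes with distinct per-tone boxcar amplitudes (categorical code)."""
    labels = np.repeat([1, 2, 3, 4], n_per_tone)
    patterns = rng.standard_normal((n_el, 4))
    epochs = rng.normal(0, noise, (labels.size, n_el, n_frames))
    for i, lab in enumerate(labels):
        epochs[i, :, 5:15] += gain * patterns[:, lab - 1][:, None]
    return epochs, labels


def test_window_position_count(rng, fast_cfg):
    epochs, labels = _categorical_epochs(rng, n_per_tone=10, n_frames=12)
    res = dec.sliding_decode(epochs, labels, fast_cfg)
    assert res.window_starts.size == 12 - 5 + 1
    assert res.pairwise_acc.shape == (6, 8)


def test_categorical_population_decodes_above_95(rng, fast_cfg):
    epochs, labels = _categorical_epochs(rng, n_per_tone=25, gain=2.5, noise=0.4)
    res = dec.sliding_decode(epochs, labels, fast_cfg)
    assert res.peak_acc >= 0.95


def test_shuffled_labels_fall_in_null_band(rng):
    epochs, labels = _categorical_epochs(rng, n_per_tone=15, gain=2.0)
    cfg = dec.DecodeConfig(
        outer_folds=3, inner_folds=2, lambda_grid=np.array([0.01]), seed=2
    )
    null_peaks = []
    for k in range(6):
        shuf = np.random.default_rng(k).permutation(labels)
        res = dec.sliding_decode(epochs[:, :, 5:12], shuf, cfg)
        null_peaks.append(res.peak_acc)
    # all-null peaks cluster near chance with sampling noise
    assert np.median(null_peaks) < 0.65


def test_window_exceeding_epoch_raises(rng, fast_cfg):
    epochs, labels = _categorical_epochs(rng, n_per_tone=10, n_frames=3)
    with pytest.raises(ConfigurationError, match="window_len"):
        dec.sliding_decode(epochs, labels, fast_cfg)


def test_relative_change_metric():
    res = dec.DecodeResult(
        pairwise_acc=np.zeros((6, 1)), mean_acc=np.array([0.8]),
        window_starts=np.array([0]), pairs=[], peak_window=0, peak_acc=0.8,
        acoustic_acc=0.7,
    )
    # ((0.8-0.5)-(0.7-0.5))/(0.7-0.5) * 100 = 50%
    assert res.relative_change() == pytest.approx(50.0)


# ---------------------------------------------------------------------------
# acoustic baseline


def _tone_contours(rng, n_per_tone, within_sd=0.0):
    from tonecortex.synth import default_templates

    labels = np.repeat([1, 2, 3, 4], n_per_tone)
    tpl = {t.tone_id: t.contour for t in default_templates()}
    height = np.stack([tpl[lab] + within_sd * rng.standard_normal(25) for lab in labels])
    change = np.gradient(height, axis=1)
    return np.stack([height, change], axis=2), labels


def test_acoustic_separable_templates_perfect(rng, fast_cfg):
    contours, labels = _tone_contours(rng, 12, within_sd=0.0)
    contours += 1e-6 * rng.standard_normal(contours.shape)  # break exact ties
    acc, _ = dec.acoustic_decode(contours, labels, fast_cfg)
    assert acc == 1.0


def test_acoustic_identical_templates_chance(rng, fast_cfg):
    labels = np.repeat([1, 2, 3, 4], 12)
    base = np.sin(np.linspace(0, np.pi, 25))
    contours = np.stack(
        [np.stack([base, np.gradient(base)], axis=1) for _ in labels]
    ) + 0.3 * rng.standard_normal((48, 25, 2))
    acc, _ = dec.acoustic_decode(contours, labels, fast_cfg)
    assert acc == pytest.approx(0.5, abs=0.12)


def test_acoustic_accuracy_near_nearest_centroid_oracle(rng, fast_cfg):
    """With calibrated within-tone variance the classifier tracks a
    nearest-centroid oracle (leave-one-out) on the same data to ±0.05."""
    contours, labels = _tone_contours(rng, 15, within_sd=0.6)
    acc, _ = dec.acoustic_decode(contours, labels, fast_cfg)

    X = contours.reshape(len(labels), -1)
    correct = []
    classes = np.unique(labels)
    for i, a in enumerate(classes):
        for b in classes[i + 1 :]:
            idx = np.flatnonzero((labels == a) | (labels == b))
            for j in idx:
                rest = idx[idx != j]
                cen = {
                    c: X[rest[labels[rest] == c]].mean(axis=0) for c in (a, b)
                }
                pred = min(cen, key=lambda c: np.linalg.norm(X[j] - cen[c]))
                correct.append(pred == labels[j])
    oracle = np.mean(correct)
    assert acc == pytest.approx(oracle, abs=0.05)


# ---------------------------------------------------------------------------
# RSA partition and CI


def test_partition_sixteen_tokens_per_tone_exact(rng):
    tones = np.repeat([1, 2, 3, 4], 16)
    vals = rng.standard_normal(64)
    groups = dec.rsa_partition(tones, vals)
    sizes = np.bincount(groups, minlength=16)
    assert np.all(sizes == 4)


def test_partition_constructed_quartiles():
    tones = np.ones(8, dtype=int)
    vals = np.array([3.0, 1.0, 7.0, 5.0, 2.0, 8.0, 4.0, 6.0])
    groups = dec.rsa_partition(tones, vals)
    # values 1,2 -> q0; 3,4 -> q1; 5,6 -> q2; 7,8 -> q3
    expected = {1.0: 0, 2.0: 0, 3.0: 1, 4.0: 1, 5.0: 2, 6.0: 2, 7.0: 3, 8.0: 3}
    for v, g in zip(vals, groups):
        assert g == expected[v]


def test_partition_matches_sort_and_slice_oracle(rng):
    tones = np.repeat([1, 2, 3, 4], 13)
    vals = rng.standard_normal(52)
    groups = dec.rsa_partition(tones, vals)
    for tone in (1, 2, 3, 4):
        idx = np.flatnonzero(tones == tone)
        order = idx[np.argsort(vals[idx], kind="stable")]
        chunks = np.array_split(order, 4)
        for q, chunk in enumerate(chunks):
            assert np.all(groups[chunk] == (tone - 1) * 4 + q)


def test_ci_zero_for_uniform_rdm():
    rdm = np.full((16, 16), 0.7)
    np.fill_diagonal(rdm, np.nan)
    assert dec.categorical_index(rdm) == pytest.approx(0.0)


def test_ci_categorical_vs_veridical_structure(rng):
    """Tone-indicator responses give between ~1.0 / within ~0.5 (CI ~ 0.5);
    responses linear in the partition feature give CI near 0."""
    n_per_group = 8
    groups = np.repeat(np.arange(16), n_per_group)
    tone_of = groups // 4
    quart_of = groups % 4

    cfg = dec.DecodeConfig(
        outer_folds=2, inner_folds=2, lambda_grid=np.array([1e-3]), seed=4,
        max_iter=80, tol=1e-4,
    )
    # categorical: pattern depends only on tone
    pat = 3.0 * rng.standard_normal((4, 10))
    X_cat = pat[tone_of] + 0.5 * rng.standard_normal((groups.size, 10))
    res_cat = dec.rsa_rdm_and_ci(X_cat, groups, cfg, n_perm=30, seed=5)
    # veridical: response scales with the continuous feature (quartile value)
    direction = rng.standard_normal(10)
    X_ver = np.outer(quart_of + 0.2 * rng.standard_normal(groups.size), direction)
    X_ver += 0.5 * rng.standard_normal(X_ver.shape)
    res_ver = dec.rsa_rdm_and_ci(X_ver, groups, cfg, n_perm=30, seed=6)

    assert res_cat.ci > 0.3
    assert res_cat.p <= 1 / 30
    assert res_ver.ci < res_cat.ci / 2
    assert res_ver.p > 0.1
    assert res_cat.null_ci.size == 30
    # RDM symmetric with NaN diagonal
    np.testing.assert_allclose(res_cat.rdm, res_cat.rdm.T, equal_nan=True)
    assert np.all(np.isnan(np.diag(res_cat.rdm)))


# ---------------------------------------------------------------------------
# ablation


def test_ablation_of_informative_electrodes_drops_to_chance(rng):
    epochs, labels = _categorical_epochs(rng, n_per_tone=20, n_el=6, gain=2.5, noise=0.4)
    # make electrodes 3..5 uninformative
    epochs[:, 3:, :] = rng.normal(0, 0.4, epochs[:, 3:, :].shape)
    cfg = dec.DecodeConfig(
        outer_folds=3, inner_folds=2, lambda_grid=np.array([0.01]), seed=7
    )
    full = dec.sliding_decode(epochs, labels, cfg)
    ablated, comp = dec.ablate_and_decode(
        epochs, labels, cfg, drop=np.array([0, 1, 2]), full_result=full, n_boot=50
    )
    assert full.peak_acc > 0.8
    assert ablated.peak_acc < 0.65
    assert comp["delta"] > 0.2
    assert comp["boot_full"].size == 50 and comp["boot_ablated"].size == 50

    # dropping the uninformative electrodes barely matters
    ablated2, comp2 = dec.ablate_and_decode(
        epochs, labels, cfg, drop=np.array([3, 4, 5]), full_result=full, n_boot=50
    )
    assert abs(comp2["delta"]) < 0.1


def test_ablation_rejects_empty_or_full_drop(rng):
    epochs, labels = _categorical_epochs(rng, n_per_tone=10, n_el=3)
    cfg = dec.DecodeConfig(outer_folds=2, inner_folds=2, lambda_grid=np.array([0.01]))
    with pytest.raises(ValueError):
        dec.ablate_and_decode(epochs, labels, cfg, drop=np.array([0, 1, 2]))
    with pytest.raises(ValueError):
        dec.ablate_and_decode(epochs, labels, cfg, drop=np.array([], dtype=int))
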