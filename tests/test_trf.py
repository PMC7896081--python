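"""TRF fitting, unique variance, phrase shuffling, transfer, model comparison."""

import numpy as np
import pandas as pd
import pytest

from tonecortex import features as feat
from tonecortex import synth, trf
from tonecortex.errors import ConfigurationError, FeatureMismatchError


def _design(rng, n=300, d=4, max_lag=5):
    x = rng.standard_normal((n, d))
    X, cm = feat.build_design_matrix({"f": x}, ["f"], max_lag)
    return x, X, cm


def test_ridge_solution_matches_closed_form_oracle(rng):
    """On a tiny problem with a single-value grid, the fitted weights equal
    the penalized normal-equations solution computed independently."""
    _, X, cm = _design(rng, n=50, d=2, max_lag=3)
    y = rng.standard_normal(50)
    lam = 2.5
    folds = [(np.arange(40), np.arange(40, 45), np.arange(45, 50))]
    model = trf.fit_trf(y, X, cm, folds=folds, ridge_grid=np.array([lam]))
    Xtr, ytr = X[:40], y[:40]
    Xc = Xtr - Xtr.mean(axis=0)
    yc = ytr - ytr.mean()
    w_oracle = np.linalg.solve(Xc.T @ Xc + lam * np.eye(6), Xc.T @ yc)
    np.testing.assert_allclose(model.flat_weights(), w_oracle, atol=1e-8)


def test_noise_free_weight_recovery(rng):
    """Noise-free y from known weights, grid including ~0: recovered weights
    match ground truth to 1e-3 RMS."""
    x, X, cm = _design(rng, n=2000, d=3, max_lag=4)
    w_true = rng.standard_normal(12)
    y = X @ w_true
    model = trf.fit_trf(y, X, cm, ridge_grid=np.array([1e-8, 1e-4]))
    rms = np.sqrt(np.mean((model.flat_weights() - w_true) ** 2))
    assert rms < 1e-3


def test_white_noise_response_has_near_zero_r2(rng):
    _, X, cm = _design(rng, n=3000, d=3, max_lag=4)
    y = rng.standard_normal(3000)
    model = trf.fit_trf(y, X, cm)
    assert abs(model.r2) < 0.02
    assert len(model.cv_performance) == 5  # one entry per repetition


def test_degenerate_response_warns_and_returns_zero_model(rng):
    _, X, cm = _design(rng, n=100)
    with pytest.warns(UserWarning, match="degenerate"):
        model = trf.fit_trf(np.zeros(100), X, cm)
    assert model.performance == 0.0
    assert np.all(model.flat_weights() == 0)


def test_nested_models_full_r2_at_least_reduced(rng):
    """Noise-free y generated by two sets: the full model's held-out R^2 is
    >= the reduced model's on average."""
    n = 2000
    xa = rng.standard_normal((n, 2))
    xb = rng.standard_normal((n, 2))
    Xfull, cm = feat.build_design_matrix({"a": xa, "b": xb}, ["a", "b"], 3)
    w = rng.standard_normal(cm.n_columns)
    y = Xfull @ w
    full = trf.fit_trf(y, Xfull, cm)
    Xred, cmr = feat.build_design_matrix({"a": xa}, ["a"], 3)
    red = trf.fit_trf(y, Xred, cmr)
    assert full.r2 >= red.r2


# ---------------------------------------------------------------------------
# phrase segmentation


def test_segment_phrases_constructed_case():
    track = np.zeros(250)
    track[0:100] = 1.0
    track[131:201] = 1.0
    tab = trf.segment_phrases(track)
    assert len(tab) == 2
    assert (tab["start_s"].tolist(), tab["end_s"].tolist()) == ([0.0, 1.31], [1.0, 2.01])


def test_segment_phrases_merges_short_gaps():
    track = np.zeros(250)
    track[0:100] = 1.0
    track[110:200] = 1.0  # 10-frame gap < 15 frames
    tab = trf.segment_phrases(track)
    assert len(tab) == 1
    assert tab["end_s"][0] == 2.0


def test_segment_phrases_all_silent_empty():
    assert len(trf.segment_phrases(np.zeros(100))) == 0


def test_permutation_preserves_phrase_segment_multiset(rng):
    """Shuffling features between phrases only reorders the per-phrase
    segments; each feature's multiset of segments is preserved exactly."""
    n = 400
    phrases = pd.DataFrame(
        {"phrase_id": [0, 1, 2], "start_s": [0.1, 1.5, 2.8], "end_s": [1.0, 2.5, 3.6]}
    )
    x = rng.standard_normal((n, 3))
    out, new_segments = trf.permute_phrases(
        {"x": x}, phrases, np.random.default_rng(3), return_spans=True
    )
    out = out["x"]
    spans = trf.phrase_frame_spans(phrases)
    orig_segs = sorted(tuple(x[a:b, 0].round(9)) for a, b in spans)
    perm_segs = sorted(tuple(out[idx, 0].round(9)) for idx in new_segments)
    assert orig_segs == perm_segs
    # silence frames untouched
    mask = np.ones(n, dtype=bool)
    for a, b in spans:
        mask[a:b] = False
    np.testing.assert_array_equal(out[mask], x[mask])


# ---------------------------------------------------------------------------
# unique variance


@pytest.fixture(scope="module")
def uv_setup():
    stim = synth.make_stimulus(50, seed=21)
    f = feat.build_stimulus_features(stim, seed=2)
    return stim, f


def test_unique_variance_flags_generating_not_null_set(uv_setup):
    stim, f = uv_setup
    full = ["intensity", "rel_pitch", "pitch_change"]
    dims = f.set_dims(full)
    truth = synth.random_truth(dims, [["rel_pitch"]], 12, seed=4, noise_sd=1.0)
    rec = synth.make_neural(stim, f, truth, seed=5, noise_relative=True)
    with pytest.warns(UserWarning, match="unstable"):
        d = trf.unique_variance(
            rec.high_gamma[0], f, full, ["rel_pitch", "intensity"],
            max_lag=12, n_reps=2, n_perm=30, seed=6,
        )[0]
    assert d.significant["rel_pitch"]
    assert not d.significant["intensity"]
    assert abs(d.unique_r2["intensity"]) < 0.02
    # exact bookkeeping: unique = full - reduced
    for probe in ("rel_pitch", "intensity"):
        assert d.unique_r2[probe] == d.full_r2 - d.reduced_r2[probe]
    assert d.null_unique_r2["rel_pitch"].size == 30


def test_probe_outside_full_model_rejected(uv_setup):
    stim, f = uv_setup
    with pytest.raises(ConfigurationError, match="tone"):
        trf.unique_variance(
            np.zeros(f.n_frames), f, ["intensity"], ["tone"], max_lag=4, n_perm=100
        )


# ---------------------------------------------------------------------------
# cross-language transfer


def test_identity_transfer_matches_within_performance(uv_setup, rng):
    stim, f = uv_setup
    full = ["intensity", "rel_pitch"]
    dims = f.set_dims(full)
    truth = synth.random_truth(dims, [full], 10, seed=8, noise_sd=0.5)
    rec = synth.make_neural(stim, f, truth, seed=9, noise_relative=True)
    X, cm = feat.build_design_matrix(f, full, 10)
    model = trf.fit_trf(rec.high_gamma[0], X, cm, bin_edges=f.pitch.bin_edges)
    _, r = trf.cross_language_transfer(model, f, rec.high_gamma[0])
    # transfer to the same stimulus ~ training-set performance >= CV estimate
    assert r >= model.performance - 0.05


def test_transfer_to_noise_response_near_zero(uv_setup, rng):
    stim, f = uv_setup
    full = ["intensity", "rel_pitch"]
    X, cm = feat.build_design_matrix(f, full, 10)
    y = rng.standard_normal(f.n_frames)
    model = trf.fit_trf(y, X, cm)
    y_new = np.random.default_rng(123).standard_normal(f.n_frames)
    _, r = trf.cross_language_transfer(model, f, y_new)
    assert abs(r) < 0.05


def test_transfer_rejects_mismatched_bin_edges(uv_setup):
    stim, f = uv_setup
    full = ["intensity", "rel_pitch"]
    X, cm = feat.build_design_matrix(f, full, 10)
    model = trf.fit_trf(np.ones(f.n_frames) + np.arange(f.n_frames) * 1e-3, X, cm,
                        bin_edges={k: v + 1.0 for k, v in f.pitch.bin_edges.items()})
    with pytest.raises(FeatureMismatchError, match="bin edges"):
        trf.cross_language_transfer(model, f, np.zeros(f.n_frames))


# ---------------------------------------------------------------------------
# weight comparison


def _model_from_weights(w, cm):
    return trf.TRFModel(
        weights=cm.unflatten(w), colmap=cm, max_lag=cm.max_lag, ridge_strength=1.0,
        cv_performance=pd.DataFrame({"corr": [0.0], "r2": [0.0], "lambda": [1.0]}),
        feature_sets=list(cm.sets),
    )


def test_weight_correlation_identity_and_negation(rng):
    _, X, cm = _design(rng, n=50, d=4, max_lag=6)
    w = rng.standard_normal(cm.n_columns)
    a = _model_from_weights(w, cm)
    assert trf.compare_model_weights(a, _model_from_weights(w.copy(), cm), ["f"]) == pytest.approx(1.0)
    assert trf.compare_model_weights(a, _model_from_weights(-w, cm), ["f"]) == pytest.approx(-1.0)


def test_blurred_correlation_matches_explicit_kernel_oracle(rng):
    """Single-impulse weight matrices offset by one lag: the blurred
    correlation equals the value from an explicit truncated-Gaussian
    convolution implemented independently."""
    d, L = 7, 9
    _, X, cm = _design(rng, n=30, d=d, max_lag=L)
    wa = np.zeros((d, L)); wa[3, 4] = 1.0
    wb = np.zeros((d, L)); wb[3, 5] = 1.0

    def blur_oracle(w, sigma=1.0, radius=4):
        k = np.exp(-0.5 * (np.arange(-radius, radius + 1) / sigma) ** 2)
        k /= k.sum()
        out = np.zeros_like(w)
        for i in range(w.shape[0]):
            for j in range(w.shape[1]):
                acc = 0.0
                for di in range(-radius, radius + 1):
                    # reflect boundary, matching scipy's default
                    ii = min(max(i + di, -(i + di) - 1), 2 * w.shape[0] - (i + di) - 1)
                    for dj in range(-radius, radius + 1):
                        jj = min(max(j + dj, -(j + dj) - 1), 2 * w.shape[1] - (j + dj) - 1)
                        acc += k[di + radius] * k[dj + radius] * w[ii, jj]
                out[i, j] = acc
        return out

    a = _model_from_weights(wa.reshape(-1), cm)
    b = _model_from_weights(wb.reshape(-1), cm)
    got = trf.compare_model_weights(a, b, ["f"])
    ba, bb = blur_oracle(wa), blur_oracle(wb)
    expected = np.corrcoef(ba.ravel(), bb.ravel())[0, 1]
    assert got == pytest.approx(expected, abs=1e-6)


# ---------------------------------------------------------------------------
# bootstrap model comparison


def test_bootstrap_distributions_bookkeeping(rng):
    n = 2000
    actual = rng.standard_normal(n)
    spans = [(i * 20, i * 20 + 20) for i in range(100)]
    res = trf.bootstrap_model_comparison(
        actual + 0.1 * rng.standard_normal(n), actual + 0.1 * rng.standard_normal(n),
        actual, spans, n_boot=50, n_trials=100, seed=0,
    )
    assert res["dist_a"].size == 50 and res["dist_b"].size == 50


def test_bootstrap_separated_models_reject(rng):
    n = 4000
    actual = rng.standard_normal(n)
    pred_a = actual + 0.2 * rng.standard_normal(n)
    pred_b = rng.standard_normal(n)  # pure noise model
    spans = [(i * 20, i * 20 + 20) for i in range(200)]
    res = trf.bootstrap_model_comparison(
        pred_a, pred_b, actual, spans, n_boot=100, n_trials=200, seed=1
    )
    assert res["p_value"] < 0.001


def test_bootstrap_identical_models_fail_to_reject():
    """pred_a == pred_b gives identical distributions: p is 1 under KS."""
    rng = np.random.default_rng(5)
    n = 2000
    actual = rng.standard_normal(n)
    pred = actual + 0.3 * rng.standard_normal(n)
    spans = [(i * 20, i * 20 + 20) for i in range(100)]
    res = trf.bootstrap_model_comparison(pred, pred, actual, spans, n_boot=60, seed=2)
    assert res["p_value"] > 0.05


def test_bootstrap_requires_two_trials():
    with pytest.raises(ValueError, match="2 trials"):
        trf.bootstrap_model_comparison(
            np.zeros(10), np.zeros(10), np.zeros(10), [(0, 5)]
        )
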