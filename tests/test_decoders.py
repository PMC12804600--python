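"""Decoder pipeline: metrics, PCA/padding, window bookkeeping, training."""

import numpy as np
import pytest
from hypothesis import given, strategies as st

from navscope.decoders import (FutureTrajectoryRegressor, MazeZoneClassifier,
                               PathTransformerClassifier,
                               PositionWindowClassifier, evaluate,
                               reduce_and_pad, window_count, window_starts)


# --------------------------------------------------------------------------
# evaluation metrics
# --------------------------------------------------------------------------
def test_perfect_confusion_gives_unit_metrics():
    y = ["a"] * 10 + ["b"] * 10
    rep = evaluate(y, y)
    assert rep.accuracy == 1.0 and rep.f1 == 1.0
    np.testing.assert_array_equal(rep.confusion, [[10, 0], [0, 10]])


def test_coin_flip_confusion():
    y_true = ["a"] * 10 + ["b"] * 10
    y_pred = (["a"] * 5 + ["b"] * 5) * 2
    rep = evaluate(y_true, y_pred)
    assert rep.accuracy == pytest.approx(0.5)
    assert rep.f1 == pytest.approx(0.5)


def test_degenerate_single_class_predictions():
    # balanced 2-class data, all predictions one class:
    # accuracy 0.5, macro-F1 = (2/3 + 0) / 2 = 1/3
    y_true = ["a"] * 10 + ["b"] * 10
    y_pred = ["a"] * 20
    rep = evaluate(y_true, y_pred)
    assert rep.accuracy == pytest.approx(0.5)
    assert rep.f1 == pytest.approx(1 / 3)
    assert rep.accuracy == pytest.approx(np.trace(rep.confusion) / rep.confusion.sum())


def test_empty_evaluation_rejected():
    with pytest.raises(ValueError, match="empty"):
        evaluate([], [])


# --------------------------------------------------------------------------
# window bookkeeping
# --------------------------------------------------------------------------
def test_window_count_printed_example():
    # 100-s session at 10 Hz, 2-s windows, step twice the window: 25 windows
    assert window_count(1000, 20, 40) == 25


@given(st.integers(0, 500), st.integers(1, 50), st.integers(1, 100))
def test_window_count_matches_enumeration(n, w, step):
    brute = sum(1 for s in range(0, n + 1, step) if s + w <= n)
    assert window_count(n, w, step) == brute
    starts = window_starts(n, w, step)
    assert len(starts) == brute
    assert all(s + w <= n for s in starts)


# --------------------------------------------------------------------------
# PCA reduction and padding
# --------------------------------------------------------------------------
def test_orthonormal_projection_preserves_variance():
    rng = np.random.default_rng(0)
    trials = [rng.standard_normal((80, 64)) for _ in range(8)]
    tset = reduce_and_pad(trials, n_components=64, max_len=100)
    stack = np.concatenate(trials)
    proj = np.concatenate([tset.X[i, :80, :64] for i in range(8)])
    assert proj.var(axis=0).sum() == pytest.approx(stack.var(axis=0).sum(),
                                                   rel=1e-6)


def test_missing_components_zero_filled():
    rng = np.random.default_rng(1)
    trials = [rng.standard_normal((30, 10)) for _ in range(4)]
    tset = reduce_and_pad(trials, n_components=256, max_len=196)
    assert tset.X.shape == (4, 196, 256)
    assert np.all(tset.X[:, :, 10:] == 0.0)
    assert np.all(tset.pad_mask[:, 30:])
    assert not tset.pad_mask[:, :30].any()


def test_rank_one_population_concentrates_in_first_component():
    rng = np.random.default_rng(2)
    latent = rng.standard_normal(200)
    loadings = rng.standard_normal(20)
    data = np.outer(latent, loadings) + 1e-3 * rng.standard_normal((200, 20))
    tset = reduce_and_pad([data], n_components=20, max_len=200)
    ratio = tset.pca.explained_variance_ratio_
    assert ratio[0] >= 0.99


def test_long_trial_truncated_head_preserving():
    rng = np.random.default_rng(3)
    trials = [rng.standard_normal((50, 5))]
    with pytest.warns(UserWarning, match="truncated"):
        tset = reduce_and_pad(trials, n_components=5, max_len=20)
    assert tset.n_truncated == 1
    np.testing.assert_allclose(tset.X[0, :20, :5],
                               tset.pca.transform(trials[0][:20]))


def test_pca_basis_fit_on_training_trials_only():
    """No leakage: the component basis must equal a recomputation from the
    training subset alone."""
    rng = np.random.default_rng(4)
    trials = [rng.standard_normal((40, 12)) for _ in range(10)]
    fit_idx = np.array([0, 2, 4, 6])
    tset = reduce_and_pad(trials, n_components=12, max_len=40, fit_idx=fit_idx)
    from sklearn.decomposition import PCA
    ref = PCA(n_components=12, svd_solver="full").fit(
        np.concatenate([trials[i] for i in fit_idx]))
    np.testing.assert_allclose(tset.pca.components_, ref.components_)


# --------------------------------------------------------------------------
# trial decoder (transformer)
# --------------------------------------------------------------------------
def _direction_trials(n_trials=40, T=16, N=20, snr=3.0, seed=0):
    rng = np.random.default_rng(seed)
    labels = np.array(["arm1->arm2", "arm2->arm1"] * (n_trials // 2))
    trials = []
    for lab in labels:
        X = rng.standard_normal((T, N))
        sel = slice(0, 4) if lab == "arm1->arm2" else slice(4, 8)
        X[:, sel] += snr
        trials.append(X)
    return trials, labels


def _tiny_transformer(seed=0, epochs=25):
    return PathTransformerClassifier(n_components=12, max_len=16, d_model=16,
                                     n_heads=2, n_layers=1, d_ff=32,
                                     epochs=epochs, lr=1e-3, random_state=seed)


def test_transformer_learns_separable_directions():
    trials, labels = _direction_trials()
    clf = _tiny_transformer().fit(trials, labels)
    assert clf.report_.accuracy >= 0.9
    assert set(clf.predict(trials[:2])) <= set(clf.classes_)


def test_transformer_single_class_rejected():
    trials, labels = _direction_trials()
    with pytest.raises(ValueError, match="class"):
        _tiny_transformer().fit(trials, ["arm1->arm2"] * len(trials))


def test_transformer_deterministic_given_seed():
    trials, labels = _direction_trials()
    r1 = _tiny_transformer(seed=3).fit(trials, labels).report_
    r2 = _tiny_transformer(seed=3).fit(trials, labels).report_
    assert r1.accuracy == r2.accuracy
    np.testing.assert_array_equal(r1.confusion, r2.confusion)


def test_transformer_hyperparameters_serialized():
    trials, labels = _direction_trials()
    clf = _tiny_transformer().fit(trials, labels)
    assert clf.report_.config_hash
    assert clf.get_params()["dropout"] == 0.3


# --------------------------------------------------------------------------
# window classifiers
# --------------------------------------------------------------------------
def _window_session(n_frames=2400, N=16, seed=0, n_classes=4):
    rng = np.random.default_rng(seed)
    names = np.array(["arm1", "arm2", "arm3", "center", "extra"][:n_classes])
    labels = names[(np.arange(n_frames) // 60) % n_classes]
    frames = rng.standard_normal((n_frames, N))
    for k in range(n_classes):
        frames[labels == names[k], k] += 3.0
    return frames, labels


def test_position_classifier_learns_and_counts_windows():
    frames, labels = _window_session(n_frames=6000)
    clf = PositionWindowClassifier(d_embed=12, conv_channels=12, lstm_hidden=12,
                                   epochs=25, random_state=0)
    clf.fit(frames, labels)
    assert clf.n_windows_ == window_count(len(frames), 20, 40)
    assert clf.report_.accuracy >= 0.9
    assert len(clf.classes_) == 4


def test_position_classifier_requires_enough_classes():
    frames, labels = _window_session(n_classes=2)
    clf = PositionWindowClassifier(epochs=2, random_state=0)
    with pytest.raises(ValueError, match="need >= 4"):
        clf.fit(frames, labels)


def test_position_classifier_excluded_frames_drop_windows():
    frames, labels = _window_session()
    drop = np.zeros(len(frames), dtype=bool)
    drop[:200] = True
    clf = PositionWindowClassifier(d_embed=8, conv_channels=8, lstm_hidden=8,
                                   epochs=2, random_state=0)
    clf.fit(frames, labels, exclude_frames=drop)
    full = window_count(len(frames), 20, 40)
    assert clf.n_windows_ == full - 5  # five windows overlap frames [0, 200)


def test_zone_modal_label_majority_rule():
    zones = np.array(["hub"] * 6 + ["reward1"] * 4)
    assert MazeZoneClassifier.modal_label(zones) == "hub"
    zones = np.array(["reward1"] * 6 + ["hub"] * 4)
    assert MazeZoneClassifier.modal_label(zones) == "reward1"


def test_zone_classifier_learns_planted_zone_code():
    frames, labels = _window_session(n_classes=5)
    clf = MazeZoneClassifier(d_embed=12, conv_channels=12, lstm_hidden=12,
                             epochs=30, random_state=0)
    clf.fit(frames, labels)
    assert clf.report_.accuracy >= 0.9


def test_zone_classifier_missing_zone_error():
    frames, labels = _window_session(n_classes=4)
    clf = MazeZoneClassifier(expected_zones=("reward1", "arm1_path", "hub",
                                             "arm2_path", "reward2"),
                             epochs=2, random_state=0)
    with pytest.raises(ValueError, match="missing"):
        clf.fit(frames, labels)


def test_noise_only_windows_stay_at_majority_rate():
    rng = np.random.default_rng(5)
    frames = rng.standard_normal((2400, 16))
    labels = np.array(["arm1", "arm2", "arm3", "center"])[
        (np.arange(2400) // 60) % 4]
    clf = PositionWindowClassifier(d_embed=8, conv_channels=8, lstm_hidden=8,
                                   epochs=10, random_state=0)
    clf.fit(frames, labels)
    counts = np.array(list(clf.report_.per_class_counts.values()), dtype=float)
    majority = counts.max() / counts.sum()
    n = clf.report_.n_eval
    from scipy.stats import binom
    hi = binom.ppf(0.999, n, max(majority, 0.3)) / n
    assert clf.report_.accuracy <= hi


# --------------------------------------------------------------------------
# trajectory regressor
# --------------------------------------------------------------------------
def test_regressor_converges_on_stationary_target():
    rng = np.random.default_rng(6)
    frames = rng.standard_normal((1500, 10))
    xy = np.full((1500, 2), 10.0)
    reg = FutureTrajectoryRegressor(d_embed=8, lstm_hidden=8, epochs=25,
                                    random_state=0)
    reg.fit(frames, xy)
    assert reg.report_.rmse <= 0.5
    pred = reg.predict(frames[None, :15])
    np.testing.assert_allclose(pred, 10.0, atol=1.0)
    assert pred.shape == (1, 5, 2)


def test_regressor_shuffled_targets_no_better_than_mean():
    rng = np.random.default_rng(7)
    frames = rng.standard_normal((1500, 10))
    t = np.arange(1500) / 10.0
    xy = np.column_stack([10 * np.sin(t / 5), 10 * np.cos(t / 7)])
    xy_shuffled = xy[rng.permutation(1500)]
    reg = FutureTrajectoryRegressor(d_embed=8, lstm_hidden=8, epochs=15,
                                    random_state=0)
    reg.fit(frames, xy_shuffled)
    assert reg.report_.rmse >= 0.9 * reg.report_.baseline_rmse


def test_regressor_session_too_short():
    with pytest.raises(ValueError, match="short"):
        FutureTrajectoryRegressor().fit(np.zeros((25, 4)), np.zeros((25, 2)))
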