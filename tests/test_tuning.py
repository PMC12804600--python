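"""Tuning classification: binning, permutation test, recovery, exports."""

import numpy as np
import pandas as pd
import pytest

from navscope.kinematics import KinematicSeries
from navscope.tuning import (NeuronTuningClassifier, batch_condition_test,
                             bin_acceleration, classify_neurons,
                             deconvolve_ar1, export_spatial_map)
from navscope.tuning import test_condition_tuning as condition_tuning


def _kin(accel):
    accel = np.asarray(accel, dtype=float)
    return KinematicSeries(timestamps=np.arange(len(accel)) / 10.0,
                           speed=np.ones_like(accel), acceleration=accel)


# --------------------------------------------------------------------------
# acceleration binning
# --------------------------------------------------------------------------
@pytest.mark.parametrize("a,expected", [
    (30.0, "high"), (-3.0, "excluded"), (25.0, "high"), (5.0, "low"),
    (24.999, "low"), (2.0, "excluded"), (55.0, "excluded"), (50.0, "high"),
    (np.nan, "excluded"),
])
def test_acceleration_bin_boundaries(a, expected):
    bins = bin_acceleration(_kin([a]))
    assert bins.category[0] == expected


def test_bins_partition_valid_frames():
    rng = np.random.default_rng(0)
    bins = bin_acceleration(_kin(rng.uniform(-60, 60, 500)))
    assert set(bins.category) <= {"low", "high", "excluded"}


# --------------------------------------------------------------------------
# permutation test mechanics
# --------------------------------------------------------------------------
def _labels(n, period=40):
    lab = np.full(n, "a", dtype="U4")
    lab[(np.arange(n) // period) % 2 == 1] = "b"
    return lab


def test_constant_trace_gives_p_one():
    n = 600
    per, combined, pref = condition_tuning(
        np.full(n, 2.5), _labels(n), n_permutations=200, seed=0)
    assert combined == 1.0
    assert all(p == 1.0 for p in per.values())


def test_obvious_modulation_detected():
    n = 1200
    lab = _labels(n)
    rng = np.random.default_rng(1)
    trace = rng.normal(0, 0.1, n) + 2.0 * (lab == "a")
    per, combined, pref = condition_tuning(trace, lab, n_permutations=500,
                                                seed=0)
    assert per["a"] < 0.01
    assert pref == "a"


def test_pvalues_in_unit_interval_and_flags_consistent(default_session):
    res = classify_neurons(default_session["session"], n_permutations=200, seed=0)
    t = res.table
    for col in [c for c in t.columns if c.startswith("p_")]:
        vals = t[col].dropna()
        assert ((vals > 0) & (vals <= 1)).all()
    for name in ("acceleration", "position", "path"):
        flag = t[f"is_{name}_tuned"].dropna().astype(bool)
        assert (flag == (t.loc[flag.index, f"p_{name}"] < 0.05)).all()
    conj = t["is_conjunctive_accel_position"]
    both = t["is_acceleration_tuned"].fillna(False) & t["is_position_tuned"].fillna(False)
    assert (conj == both).all()


def test_determinism_given_seed(default_session):
    a = classify_neurons(default_session["session"], n_permutations=100, seed=9)
    b = classify_neurons(default_session["session"], n_permutations=100, seed=9)
    pd.testing.assert_frame_equal(a.table, b.table)


def test_short_trace_rejected_for_min_shift():
    with pytest.raises(ValueError, match="too short"):
        condition_tuning(np.zeros(60), _labels(60), n_permutations=50,
                              seed=0, min_shift_s=5.0, sample_rate=10.0)


def test_mismatched_labels_rejected():
    with pytest.raises(ValueError, match="length"):
        batch_condition_test(np.zeros((1, 100)), _labels(99), ("a", "b"))


def test_sparse_condition_skipped_with_warning():
    n = 600
    lab = _labels(n)
    lab[lab == "b"] = ""
    lab[:5] = "b"  # only 5 frames of condition b
    with pytest.warns(UserWarning, match="skipped"):
        per, combined, _ = condition_tuning(
            np.random.default_rng(0).normal(size=n), lab,
            n_permutations=100, seed=0, conditions=("a", "b"))
    assert np.isnan(per["b"])


def test_ranksum_backend_agrees_on_obvious_case():
    n = 1000
    lab = _labels(n)
    rng = np.random.default_rng(3)
    trace = rng.normal(0, 0.1, n) + 1.0 * (lab == "b")
    per, combined, pref = condition_tuning(trace, lab, backend="ranksum")
    assert per["b"] < 1e-6
    assert pref == "b"


def test_label_shift_destroys_detection():
    """Circularly shifting all labels far from the trace kills the effect."""
    n = 2000
    lab = _labels(n)
    rng = np.random.default_rng(4)
    trace = rng.normal(0, 0.3, n) + 1.0 * (lab == "a")
    hits_true = hits_shift = 0
    for seed in range(8):
        _, p_true, _ = condition_tuning(trace, lab, n_permutations=300,
                                             seed=seed)
        shifted = np.roll(lab, 920 + 7 * seed)
        _, p_shift, _ = condition_tuning(trace, shifted,
                                              n_permutations=300, seed=seed)
        hits_true += p_true < 0.05
        hits_shift += p_shift < 0.05
    assert hits_true == 8
    assert hits_shift <= 2


def test_deconvolve_inverts_exponential_kernel():
    from scipy.signal import lfilter
    rng = np.random.default_rng(0)
    events = rng.poisson(0.1, size=(3, 400)).astype(float)
    decay = np.exp(-1.0 / (10.0 * 0.4))
    traces = lfilter([1.0], [1.0, -decay], events, axis=1)
    back = deconvolve_ar1(traces, 0.4, 10.0)
    np.testing.assert_allclose(back, events, atol=1e-10)


# --------------------------------------------------------------------------
# session-level classification
# --------------------------------------------------------------------------
def test_all_zero_traces_yield_no_tuned_neurons(default_session):
    session = default_session["session"]
    zeros = type(session.traces)(values=np.zeros_like(session.traces.values),
                                 sample_rate=session.traces.sample_rate)
    import dataclasses
    silent = dataclasses.replace(session, traces=zeros)
    res = classify_neurons(silent, n_permutations=100, seed=1)
    assert sum(res.counts().values()) == 0


def test_planted_recovery_and_preferred_condition(default_session):
    res = classify_neurons(default_session["session"], n_permutations=500, seed=2)
    t = res.table.merge(default_session["ground_truth"], on="neuron_id")
    pos = t[t.cell_class == "position"]
    assert pos["is_position_tuned"].fillna(False).mean() >= 0.8
    hit = pos[pos["is_position_tuned"].fillna(False)]
    assert (hit["preferred_position"] == hit["preferred"]).mean() >= 0.8
    path = t[t.cell_class == "path"]
    assert path["is_path_tuned"].fillna(False).mean() >= 0.8
    acc = t[t.cell_class == "acceleration"]
    assert acc["is_acceleration_tuned"].fillna(False).mean() >= 0.8


def test_unannotated_session_rejected(default_session):
    import dataclasses
    bare = dataclasses.replace(default_session["session"], regions=None,
                               phases=None)
    with pytest.raises(ValueError, match="annotated"):
        NeuronTuningClassifier().fit(bare)


def test_path_flags_absent_without_qualified_trials(default_session):
    import dataclasses
    session = default_session["session"]
    nophase = dataclasses.replace(
        session, phases=np.full(session.n_frames, "none", dtype="U10"),
        directions=np.full(session.n_frames, "", dtype="U12"))
    with pytest.warns(UserWarning):
        res = classify_neurons(nophase, n_permutations=100, seed=0)
    assert res.table["is_path_tuned"].isna().all()  # untestable, not False


# --------------------------------------------------------------------------
# spatial map export
# --------------------------------------------------------------------------
def test_spatial_map_faithful_flags(short_session):
    res = classify_neurons(short_session["session"], n_permutations=100, seed=0)
    table = export_spatial_map(res, short_session["session"].traces)
    assert len(table) == short_session["session"].traces.n_neurons
    np.testing.assert_array_equal(
        table["is_position_tuned"].to_numpy(),
        res.table["is_position_tuned"].fillna(False).to_numpy(dtype=bool))


def test_spatial_map_requires_centroids(short_session):
    import dataclasses
    res = classify_neurons(short_session["session"], n_permutations=100, seed=0)
    tr = short_session["session"].traces
    bare = type(tr)(values=tr.values, sample_rate=tr.sample_rate)
    with pytest.raises(ValueError, match="centroid"):
        export_spatial_map(res, bare)


def test_spatial_map_round_trip(tmp_path, short_session):
    from navscope.io import load_results, save_results
    res = classify_neurons(short_session["session"], n_permutations=100, seed=0)
    table = export_spatial_map(res, short_session["session"].traces)
    save_results(table, tmp_path / "map.csv")
    back = load_results(tmp_path / "map.csv")
    pd.testing.assert_frame_equal(back, table)
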