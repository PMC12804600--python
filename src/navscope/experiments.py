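"""Validation experiments: closed-form checks and planted-recovery studies.

Each function runs one self-contained experiment at desk scale — small enough
for a laptop CPU, large enough for its statistical check to be meaningful —
and returns plain measured quantities. The test suite asserts on them at the
documented tolerances; the reproduction script reports them.

Problem sizes used here (session lengths, neuron counts, permutation draws,
seed counts) are the package's validation conditions and are stated in the
methods note.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy.stats import binom

from . import kinematics as bk
from .decoders import (PathTransformerClassifier, PositionWindowClassifier,
                       window_count)
from .dissociation import (ablation_contribution, compute_dprime, dprime,
                           fit_trajectory_glm, lick_removal_control)
from .io import Trajectory
from .simulate import (SimConfig, high_snr_decoding_config,
                       simulate_glm_session, simulate_session)
from .tuning import TuningResult, classify_neurons, deconvolve_ar1


def _quiet(fn, *a, **kw):
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return fn(*a, **kw)


# --------------------------------------------------------------------------
# tortuosity closed forms
# --------------------------------------------------------------------------
def tortuosity_checks() -> dict:
    """Straight-line and circular-path closed forms for momentary tortuosity.

    A straight constant-speed path has T(t) = 1 exactly; on a circle of
    radius 10 cm at 4 cm/s the +/-1.25-s window spans a 10-cm arc (1 rad),
    so T = arc/chord = 1 / (2 sin 0.5) ~ 1.0429.
    """
    t = np.arange(3000) / 100.0
    straight = Trajectory(timestamps=t, x=4.0 * t, y=3.0 * t, frame_rate=100.0)
    kin = bk.compute_speed_accel(straight)
    T, _ = bk.compute_tortuosity(straight, kin)
    straight_dev = float(np.nanmax(np.abs(T - 1.0)))

    R, v = 10.0, 4.0
    theta = v * t / R
    circle = Trajectory(timestamps=t, x=R * np.cos(theta), y=R * np.sin(theta),
                        frame_rate=100.0)
    Tc, _ = bk.compute_tortuosity(circle, bk.compute_speed_accel(circle))
    return {
        "straight_max_abs_dev": straight_dev,
        "circle_tortuosity": float(np.nanmedian(Tc)),
        "circle_expected": float(1.0 / (2.0 * np.sin(0.5))),
    }


# --------------------------------------------------------------------------
# d-prime
# --------------------------------------------------------------------------
def dprime_checks(seed: int = 0, n_frames: int = 10_000) -> dict:
    """Hand-substituted d' values plus convergence on a planted neuron."""
    rng = np.random.default_rng(seed)
    d_true = 1.5
    hi = rng.normal(d_true, 1.0, n_frames)
    lo = rng.normal(0.0, 1.0, n_frames)
    traces = np.concatenate([hi, lo])[None, :]
    cat = np.array(["high"] * n_frames + ["low"] * n_frames)
    reg = np.full(2 * n_frames, "arm1")
    res = compute_dprime(traces, cat, reg, ("arm1",))
    return {
        "d_unit": dprime(2.0, 1.0, 1.0, 1.0),
        "d_pooled_var2": dprime(3.0, 1.0, 2.0, 2.0),
        "planted_d_empirical": float(res.table["d_prime"].iloc[0]),
        "planted_d_true": d_true,
    }


# --------------------------------------------------------------------------
# GLM recovery
# --------------------------------------------------------------------------
def glm_experiment(seed: int = 0, n_seeds: int = 200, n: int = 5000) -> dict:
    """Noiseless exact recovery, and Monte-Carlo bias of the OLS estimates."""
    beta = (0.5, 2.0, -1.0)
    x, p, a = simulate_glm_session(*beta, 0.0, 2000, seed)
    fit = fit_trajectory_glm(x, p, a)
    noiseless_err = max(abs(fit.beta0 - beta[0]), abs(fit.beta1 - beta[1]),
                        abs(fit.beta2 - beta[2]))
    errs = np.empty((n_seeds, 3))
    base = np.random.SeedSequence(seed).generate_state(n_seeds) % (2**31)
    for i, s in enumerate(base):
        x, p, a = simulate_glm_session(*beta, 1.0, n, int(s))
        f = fit_trajectory_glm(x, p, a)
        errs[i] = (f.beta0 - beta[0], f.beta1 - beta[1], f.beta2 - beta[2])
    mc_se = errs.std(axis=0, ddof=1) / np.sqrt(n_seeds)
    bias = errs.mean(axis=0)
    return {
        "noiseless_max_abs_err": float(noiseless_err),
        "bias": bias.tolist(),
        "mc_se": mc_se.tolist(),
        "max_abs_bias_over_se": float(np.max(np.abs(bias) / mc_se)),
    }


# --------------------------------------------------------------------------
# tuning-test calibration on untuned neurons
# --------------------------------------------------------------------------
def calibration_experiment(seed: int = 0, n_neurons: int = 3000,
                           n_permutations: int = 4999) -> dict:
    """Per-condition false-positive rates of the three tests on untuned neurons.

    All neurons are planted untuned on one default-condition session; for each
    test the condition-level p-values are pooled and the rate of p < 0.05 is
    compared with the exact binomial 95% interval around 0.05.
    """
    cfg = SimConfig(seed=seed, n_neurons=n_neurons,
                    class_counts={"untuned": n_neurons})
    session, gt, kin, regions, trials = _quiet(simulate_session, cfg)
    res = _quiet(classify_neurons, session, n_permutations=n_permutations,
                 seed=seed + 1)
    t = res.table
    out = {}
    cond_cols = {
        "acceleration": ["p_acceleration_low", "p_acceleration_high"],
        "position": ["p_position_arm1", "p_position_center", "p_position_arm2"],
        "path": ["p_path_starting", "p_path_central", "p_path_terminal"],
    }
    for name, cols in cond_cols.items():
        p = t[cols].to_numpy().ravel()
        p = p[np.isfinite(p)]
        rate = float((p < 0.05).mean())
        n = len(p)
        lo = binom.ppf(0.025, n, 0.05) / n
        hi = binom.ppf(0.975, n, 0.05) / n
        out[name] = {"fpr": rate, "n": n, "lo": float(lo), "hi": float(hi),
                     "inside": bool(lo <= rate <= hi)}
    return out


# --------------------------------------------------------------------------
# planted-class recovery
# --------------------------------------------------------------------------
def recovery_experiment(seed: int = 0, n_seeds: int = 10) -> dict:
    """Recovery of planted tuning classes on default sessions across seeds.

    Reports, pooled over seeds: per-class sensitivity (fraction of planted
    neurons flagged with their class), conjunctive detection, cross-flagging
    of pure path vs position cells, untuned false-positive rates, and the raw
    flag counts.
    """
    rows = []
    seeds = np.random.SeedSequence(seed).generate_state(n_seeds) % (2**31)
    for s in seeds:
        cfg = SimConfig(seed=int(s))
        session, gt, kin, regions, trials = _quiet(simulate_session, cfg)
        res = _quiet(classify_neurons, session, seed=int(s) + 1)
        t = res.table.merge(gt, on="neuron_id")
        t["seed"] = int(s)
        rows.append(t)
    t = pd.concat(rows, ignore_index=True)

    def rate(sub, col):
        return float(sub[col].fillna(False).mean()), int(len(sub))

    out = {"planted_per_seed": dict(SimConfig().class_counts)}
    for cls, col in (("position", "is_position_tuned"),
                     ("path", "is_path_tuned"),
                     ("acceleration", "is_acceleration_tuned")):
        out[f"sensitivity_{cls}"] = rate(t[t.cell_class == cls], col)[0]
    conj = t[t.cell_class.str.startswith("conjunctive")]
    conj_hit = (conj["is_conjunctive_accel_position"]
                & (conj.cell_class == "conjunctive_accel_position")) | (
        conj["is_conjunctive_accel_path"]
        & (conj.cell_class == "conjunctive_accel_path"))
    out["sensitivity_conjunctive"] = float(conj_hit.mean())
    un = t[t.cell_class == "untuned"]
    out["untuned_fpr_position"] = rate(un, "is_position_tuned")[0]
    out["untuned_fpr_path"] = rate(un, "is_path_tuned")[0]
    out["untuned_fpr_acceleration"] = rate(un, "is_acceleration_tuned")[0]
    out["untuned_fpr_conjunctive"] = float(
        (un["is_conjunctive_accel_position"]
         | un["is_conjunctive_accel_path"]).mean())
    out["cross_path_flagged_position"] = rate(t[t.cell_class == "path"],
                                              "is_position_tuned")
    out["cross_position_flagged_path"] = rate(t[t.cell_class == "position"],
                                              "is_path_tuned")
    out["n_seeds"] = n_seeds
    return out


# --------------------------------------------------------------------------
# decoder experiments
# --------------------------------------------------------------------------
def _desk_transformer(seed: int) -> PathTransformerClassifier:
    return PathTransformerClassifier(n_components=32, max_len=64, d_model=32,
                                     n_heads=2, n_layers=1, d_ff=64,
                                     epochs=60, random_state=seed)


def _desk_position(seed: int) -> PositionWindowClassifier:
    return PositionWindowClassifier(d_embed=24, conv_channels=24,
                                    lstm_hidden=32, epochs=40,
                                    random_state=seed)


def _prepared_session(seed: int, duration: float = 1200.0):
    """High-SNR session plus a deconvolved frame matrix.

    The frame-labeled window decoders work best on the approximately
    deconvolved activity (the calcium transient otherwise lags region
    boundaries); the trial-sequence transformer reads the raw traces, whose
    temporal integration it can exploit.
    """
    cfg = high_snr_decoding_config(seed, session_duration=duration)
    session, gt, kin, regions, trials = _quiet(simulate_session, cfg)
    deconv = deconvolve_ar1(session.traces.values, cfg.calcium_decay_tau,
                            cfg.neural_rate).T
    return session, trials, deconv


def _trial_data(session, trials):
    frames = session.traces.values.T
    q = [t for t in trials if t.qualified]
    return [frames[t.start_frame:t.end_frame] for t in q], np.array(
        [t.direction for t in q])


def decoder_signal_experiment(seed: int = 0, n_seeds: int = 3) -> dict:
    """Path-transformer and position-classifier accuracy on high-SNR sessions."""
    seeds = np.random.SeedSequence(seed).generate_state(n_seeds) % (2**31)
    path_c = path_n = pos_c = pos_n = 0
    for s in seeds:
        session, trials, deconv = _prepared_session(int(s))
        data, labels = _trial_data(session, trials)
        tf = _quiet(_desk_transformer(int(s)).fit, data, labels)
        path_c += int(round(tf.report_.accuracy * tf.report_.n_eval))
        path_n += tf.report_.n_eval
        pc = _quiet(_desk_position(int(s)).fit, deconv, session.regions)
        pos_c += int(round(pc.report_.accuracy * pc.report_.n_eval))
        pos_n += pc.report_.n_eval
    return {"path_accuracy": path_c / path_n, "path_n": path_n,
            "position_accuracy": pos_c / pos_n, "position_n": pos_n,
            "path_chance": 0.5, "position_chance": 0.25}


def decoder_null_experiment(seed: int = 0, n_seeds: int = 5) -> dict:
    """Label-shuffled training: accuracy must sit at its chance level.

    For the balanced two-class path task chance is 0.5. For the position
    task a label-blind model lands between uniform chance (0.25) and the
    majority-class rate depending on how it spreads its predictions, so the
    null band runs from the lower binomial bound at 0.25 to the upper bound
    at the majority rate.
    """
    session, trials, deconv = _prepared_session(seed)
    data, labels = _trial_data(session, trials)
    frames = deconv
    rng = np.random.default_rng(seed + 1)
    path_c = path_n = pos_c = pos_n = 0
    majority = []
    for k in range(n_seeds):
        sl = rng.permutation(labels)
        tf = _quiet(_desk_transformer(seed + 10 + k).fit, data, sl)
        path_c += int(round(tf.report_.accuracy * tf.report_.n_eval))
        path_n += tf.report_.n_eval
        # shuffle region labels within the labeled frames
        lab = np.asarray(session.regions).copy()
        ok = ~np.isin(lab, ("", "none"))
        vals = lab[ok]
        lab[ok] = vals[rng.permutation(len(vals))]
        pc = _quiet(_desk_position(seed + 20 + k).fit, frames, lab)
        pos_c += int(round(pc.report_.accuracy * pc.report_.n_eval))
        pos_n += pc.report_.n_eval
        counts = np.array(list(pc.report_.per_class_counts.values()), float)
        majority.append(counts.max() / counts.sum())
    path_rate = path_c / path_n
    pos_rate = pos_c / pos_n
    maj = float(np.mean(majority))
    return {
        "path_null_accuracy": path_rate, "path_null_n": path_n,
        "path_null_lo": float(binom.ppf(0.025, path_n, 0.5) / path_n),
        "path_null_hi": float(binom.ppf(0.975, path_n, 0.5) / path_n),
        "position_null_accuracy": pos_rate, "position_null_n": pos_n,
        "position_null_majority": maj,
        "position_null_lo": float(binom.ppf(0.025, pos_n, 0.25) / pos_n),
        "position_null_hi": float(binom.ppf(0.975, pos_n, maj) / pos_n),
    }


def lick_control_experiment(seed: int = 0, n_seeds: int = 5) -> dict:
    """Position decoding with vs without lick-period frames (paired seeds)."""
    session, _, deconv = _prepared_session(seed, duration=1500.0)
    session.traces.values[:] = deconv.T  # window decoding reads deconvolved activity
    factory = lambda s: PositionWindowClassifier(
        d_embed=24, conv_channels=24, lstm_hidden=32, epochs=30,
        random_state=s)
    df = _quiet(lick_removal_control, session, factory,
                seeds=tuple(seed + k for k in range(n_seeds)))
    return {
        "acc_with": float(df["acc_with"].mean()),
        "acc_without": float(df["acc_without"].mean()),
        "mean_paired_delta": float(df["delta"].mean()),
        "n_seeds": n_seeds,
    }


# --------------------------------------------------------------------------
# ablation
# --------------------------------------------------------------------------
def direction_coded_trials(seed: int, n_trials: int = 60, T: int = 24,
                           n_neurons: int = 40, n_signal: int = 8,
                           snr: float = 2.5):
    """Constructed trial set where ONLY a known subset carries direction signal.

    The first ``n_signal`` neurons respond with a direction-dependent pattern
    (these are the session's acceleration-tuned cells); the rest are white
    noise. Returns (trials, labels, tuning) with the subset flagged in the
    tuning table.
    """
    rng = np.random.default_rng(seed)
    labels = np.array(["arm1->arm2", "arm2->arm1"] * (n_trials // 2))
    trials = []
    for lab in labels:
        X = rng.standard_normal((T, n_neurons))
        half = n_signal // 2
        sel = slice(0, half) if lab == "arm1->arm2" else slice(half, n_signal)
        X[:, sel] += snr
        trials.append(X)
    flags = np.zeros(n_neurons, dtype=bool)
    flags[:n_signal] = True
    table = pd.DataFrame({"neuron_id": np.arange(n_neurons),
                          "is_acceleration_tuned": flags,
                          "is_position_tuned": False,
                          "is_path_tuned": False})
    return trials, labels, TuningResult(table=table)


def ablation_experiment(seed: int = 0, n_seeds: int = 5) -> dict:
    """Remove-and-retrain: dropping the coding subset vs a size-matched random one."""
    trials, labels, tuning = direction_coded_trials(seed)
    factory = lambda s: PathTransformerClassifier(
        n_components=16, max_len=24, d_model=16, n_heads=2, n_layers=1,
        d_ff=32, epochs=40, lr=1e-3, random_state=s)
    rep = _quiet(ablation_contribution, trials, labels, tuning, factory,
                 seeds=tuple(seed + k for k in range(n_seeds)),
                 subsets=("acceleration",))
    g = rep.table.groupby("condition")["accuracy"].mean()
    n_eval = int(round(len(trials) * 0.2))
    return {
        "full_accuracy": float(g["full"]),
        "drop_tuned_accuracy": float(g["drop_acceleration_tuned"]),
        "drop_random_accuracy": float(g["drop_random_matched_acceleration"]),
        "chance": 0.5,
        "chance_hi": float(binom.ppf(0.975, n_eval * n_seeds, 0.5)
                           / (n_eval * n_seeds)),
        "n_removed": int(
            rep.table.loc[rep.table.condition == "drop_acceleration_tuned",
                          "n_removed"].iloc[0]),
    }


# --------------------------------------------------------------------------
# pipeline bookkeeping
# --------------------------------------------------------------------------
def bookkeeping_checks(seed: int = 0) -> dict:
    """Scripted-trial recovery, window-count closed form, save/load round trip."""
    cfg = SimConfig(seed=seed, session_duration=200.0, n_neurons=4,
                    class_counts={"position": 2, "untuned": 2},
                    excursion_prob=0.0)
    session, gt, kin, regions, trials = _quiet(simulate_session, cfg)
    script = session.trajectory.meta["script"]
    expected = [s for s in script
                if s["origin"] in ("arm1", "arm2")]  # first traversal starts in arm3
    directions_ok = (len(trials) == len(expected)
                     and all(tr.direction == s["direction"]
                             for tr, s in zip(trials, expected)))
    wc = window_count(1000, 20, 40)  # 100-s session, 2-s windows, 2x step
    wc_ok = wc == 25

    import tempfile
    from pathlib import Path
    from .io import load_results, save_results
    from .tuning import classify_neurons as cn
    res = _quiet(cn, session, n_permutations=100, seed=seed)
    with tempfile.TemporaryDirectory() as d:
        p = Path(d) / "tuning.csv"
        save_results(res.table, p)
        back = load_results(p)
    round_trip_ok = bool(np.allclose(
        back["p_position"].to_numpy(), res.table["p_position"].to_numpy(),
        equal_nan=True))
    return {
        "scripted_trials_expected": len(expected),
        "scripted_trials_recovered": len(trials),
        "directions_match": bool(directions_ok),
        "window_count_value": int(wc),
        "window_count_ok": bool(wc_ok),
        "round_trip_ok": round_trip_ok,
    }
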