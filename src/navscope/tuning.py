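"""Neuron tuning classification: position, path, and acceleration.

A neuron is acceleration-tuned if its dF/F discriminates the low
([5, 25) cm/s^2) from the high ([25, 50] cm/s^2) acceleration bin
(decelerations and very low accelerations excluded); position-tuned if it is
modulated by one or more of the three static maze regions (arm1 / center /
arm2); path-tuned if it is modulated by one or more path-relative trial
phases (starting / central / terminal), evaluated inside qualified
navigation trials.

Significance is assessed with a circular time-shift permutation test, which
respects calcium-trace autocorrelation: the observed statistic is compared
with its value after circularly shifting the trace relative to the fixed
labels (uniform random shifts of at least ``min_shift_s``). Because path
phases are unions of regions (the starting phase is the origin arm, the
central phase is the hub), a plain condition-vs-rest statistic cannot
dissociate path from position tuning. The default statistics are therefore
*balanced contrasts*: arm conditions contrast arm1 against arm2 within
direction strata (a path cell, symmetric across directions, cancels), phase
conditions contrast the origin against the destination phase within the same
arm (a position cell cancels), and the center region / central phase are
separated using non-trial hub frames. A frame-wise rank-sum backend on plain
condition-vs-rest labels is available as an alternative.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import mannwhitneyu
from sklearn.base import BaseEstimator

from .io import AlignedSession, NeuralTraces

ACCEL_LOW = (5.0, 25.0)  # cm/s^2, half-open [5, 25)
ACCEL_HIGH = (25.0, 50.0)  # cm/s^2, closed-right [25, 50]

POSITION_CONDITIONS = ("arm1", "center", "arm2")
PATH_CONDITIONS = ("starting", "central", "terminal")
ACCEL_CONDITIONS = ("low", "high")


@dataclass
class AccelerationBins:
    """Per-frame acceleration category: 'low', 'high' or 'excluded'."""

    category: np.ndarray
    edges_low: tuple = ACCEL_LOW
    edges_high: tuple = ACCEL_HIGH


def bin_acceleration(kin) -> AccelerationBins:
    """Bin signed linear acceleration into the two analysis categories.

    Low is the half-open interval [5, 25) and high is [25, 50] cm/s^2;
    negative accelerations (deceleration), very low accelerations (< 5) and
    values above 50 are excluded, as are invalid frames.
    """
    a = np.asarray(kin.acceleration, dtype=float)
    cat = np.full(a.shape, "excluded", dtype="U10")
    ok = np.isfinite(a)
    cat[ok & (a >= ACCEL_LOW[0]) & (a < ACCEL_LOW[1])] = "low"
    cat[ok & (a >= ACCEL_HIGH[0]) & (a <= ACCEL_HIGH[1])] = "high"
    return AccelerationBins(category=cat)


@dataclass
class TuningResult:
    """Per-neuron tuning p-values and flags, with test metadata."""

    table: pd.DataFrame
    metadata: dict = field(default_factory=dict)

    def counts(self) -> dict:
        t = self.table
        return {
            "position": int(t["is_position_tuned"].fillna(False).sum()),
            "path": int(t["is_path_tuned"].fillna(False).sum()),
            "acceleration": int(t["is_acceleration_tuned"].fillna(False).sum()),
            "conjunctive_accel_position": int(t["is_conjunctive_accel_position"].fillna(False).sum()),
            "conjunctive_accel_path": int(t["is_conjunctive_accel_path"].fillna(False).sum()),
        }


# --------------------------------------------------------------------------
# contrast machinery
# --------------------------------------------------------------------------
@dataclass
class Contrast:
    """A condition statistic defined by matched strata.

    Each stratum is a (positive frames, negative frames) mask pair; the
    statistic is the mean over usable strata of (mean dF/F over positive
    frames - mean over negative frames). Strata with fewer than the minimum
    frame count on either side are dropped.
    """

    name: str
    strata: list

    def weights(self, min_frames: int) -> np.ndarray | None:
        parts = []
        for pos, neg in self.strata:
            mp, mn = int(pos.sum()), int(neg.sum())
            if mp >= min_frames and mn >= min_frames:
                parts.append(pos / mp - neg / mn)
        if not parts:
            return None
        return np.mean(parts, axis=0)


def one_vs_rest_contrasts(labels: np.ndarray, conditions: tuple) -> list[Contrast]:
    """Plain 'condition mean vs mean of all other labeled frames' contrasts."""
    labels = np.asarray(labels)
    indicators = {c: labels == c for c in conditions}
    valid = np.logical_or.reduce(list(indicators.values()))
    return [Contrast(c, [(indicators[c], valid & ~indicators[c])])
            for c in conditions]


def _stats_all_shifts(traces: np.ndarray, w: np.ndarray) -> np.ndarray:
    """w . trace for every circular shift of the traces, via FFT correlation."""
    F = traces.shape[1]
    W = np.conj(np.fft.rfft(w))
    return np.fft.irfft(np.fft.rfft(traces, axis=1) * W[None, :], n=F, axis=1)


def _sample_shifts(rng: np.random.Generator, n_neurons: int, n_perm: int,
                   n_frames: int, min_shift_frames: int) -> np.ndarray:
    lo, hi = min_shift_frames, n_frames - min_shift_frames
    if hi <= lo:
        raise ValueError(
            f"trace of {n_frames} frames too short for minimum shift of "
            f"{min_shift_frames} frames")
    return rng.integers(lo, hi + 1, size=(n_neurons, n_perm))


def batch_contrast_test(
    traces: np.ndarray,
    contrasts: list[Contrast],
    n_permutations: int = 1000,
    seed=None,
    min_shift_s: float = 5.0,
    sample_rate: float = 10.0,
    min_frames: int = 20,
    alpha: float = 0.05,
) -> dict:
    """Circular-shift permutation test of a set of contrasts for many neurons.

    Returns per-contrast one-sided p-values (n_neurons x K), the combined
    p-value (min over testable contrasts, the 'one or more conditions' rule,
    uncorrected), the observed statistics, and each neuron's preferred
    condition (argmax statistic among significant contrasts).
    """
    traces = np.atleast_2d(np.asarray(traces, dtype=float))
    N, F = traces.shape
    K = len(contrasts)
    p = np.full((N, K), np.nan)
    stats = np.full((N, K), np.nan)
    tested = np.zeros(K, dtype=bool)
    names = tuple(c.name for c in contrasts)

    rng = np.random.default_rng(seed)
    shifts = _sample_shifts(rng, N, n_permutations, F,
                            int(round(min_shift_s * sample_rate)))
    rows = np.arange(N)[:, None]
    for k, contrast in enumerate(contrasts):
        w = contrast.weights(min_frames)
        if w is None:
            warnings.warn(
                f"condition '{contrast.name}' has no stratum with >= "
                f"{min_frames} frames on both sides; skipped")
            continue
        tested[k] = True
        stat_all = _stats_all_shifts(traces, w)
        obs = stat_all[:, 0]
        null = stat_all[rows, shifts]
        exceed = (null >= obs[:, None] - 1e-12).sum(axis=1)
        p[:, k] = (1.0 + exceed) / (1.0 + n_permutations)
        stats[:, k] = obs

    if tested.any():
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            p_combined = np.nanmin(np.where(tested[None, :], p, np.nan), axis=1)
    else:
        p_combined = np.full(N, np.nan)
    preferred = np.array([""] * N, dtype="U24")
    for n in range(N):
        finite = [k for k in range(K) if tested[k] and np.isfinite(p[n, k])]
        cands = [k for k in finite if p[n, k] < alpha] or finite
        if cands:
            preferred[n] = names[max(cands, key=lambda k: stats[n, k])]
    return {"p": p, "p_combined": p_combined, "stats": stats,
            "preferred": preferred, "tested": tested, "names": names}


def batch_condition_test(
    traces: np.ndarray,
    labels: np.ndarray,
    conditions: tuple,
    n_permutations: int = 1000,
    seed=None,
    min_shift_s: float = 5.0,
    sample_rate: float = 10.0,
    min_frames: int = 20,
    backend: str = "shift",
    alpha: float = 0.05,
) -> dict:
    """Condition-tuning test against a plain categorical label series.

    The statistic for each condition is its mean dF/F minus the mean over all
    other labeled frames. With the 'shift' backend the null is circular
    time-shifts of the trace; 'ranksum' runs a frame-wise one-sided
    Mann-Whitney U instead.
    """
    traces = np.atleast_2d(np.asarray(traces, dtype=float))
    labels = np.asarray(labels)
    if len(labels) != traces.shape[1]:
        raise ValueError("labels length must match trace frames")
    contrasts = one_vs_rest_contrasts(labels, conditions)
    if backend == "shift":
        return batch_contrast_test(
            traces, contrasts, n_permutations=n_permutations, seed=seed,
            min_shift_s=min_shift_s, sample_rate=sample_rate,
            min_frames=min_frames, alpha=alpha)
    if backend != "ranksum":
        raise ValueError(f"unknown backend '{backend}'")
    N = traces.shape[0]
    K = len(conditions)
    p = np.full((N, K), np.nan)
    stats = np.full((N, K), np.nan)
    tested = np.zeros(K, dtype=bool)
    for k, contrast in enumerate(contrasts):
        pos, neg = contrast.strata[0]
        if pos.sum() < min_frames or neg.sum() < min_frames:
            warnings.warn(f"condition '{contrast.name}' has too few frames; skipped")
            continue
        tested[k] = True
        a, b = traces[:, pos], traces[:, neg]
        for n in range(N):
            if np.ptp(traces[n]) == 0:
                p[n, k], stats[n, k] = 1.0, 0.0
                continue
            p[n, k] = mannwhitneyu(a[n], b[n], alternative="greater").pvalue
            stats[n, k] = a[n].mean() - b[n].mean()
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        p_combined = (np.nanmin(np.where(tested[None, :], p, np.nan), axis=1)
                      if tested.any() else np.full(N, np.nan))
    preferred = np.array([""] * N, dtype="U24")
    for n in range(N):
        finite = [k for k in range(K) if tested[k] and np.isfinite(p[n, k])]
        cands = [k for k in finite if p[n, k] < alpha] or finite
        if cands:
            preferred[n] = conditions[max(cands, key=lambda k: stats[n, k])]
    return {"p": p, "p_combined": p_combined, "stats": stats,
            "preferred": preferred, "tested": tested, "names": conditions}


def test_condition_tuning(
    trace: np.ndarray,
    labels: np.ndarray,
    n_permutations: int = 1000,
    seed=None,
    conditions: tuple | None = None,
    **kw,
) -> tuple[dict, float, str]:
    """Single-neuron condition test; see :func:`batch_condition_test`.

    Returns (per-condition p dict, combined p, preferred condition).
    """
    labels = np.asarray(labels)
    if conditions is None:
        conditions = tuple(c for c in pd.unique(labels)
                           if c not in ("", "none", "excluded"))
    res = batch_condition_test(np.asarray(trace)[None, :], labels, conditions,
                               n_permutations=n_permutations, seed=seed, **kw)
    per = {c: float(res["p"][0, k]) for k, c in enumerate(conditions)}
    return per, float(res["p_combined"][0]), str(res["preferred"][0])


def deconvolve_ar1(traces: np.ndarray, tau: float, sample_rate: float) -> np.ndarray:
    """Approximate event-rate estimate by inverting the exponential kernel.

    For a trace built as events filtered through exp(-t/tau), the AR(1)
    inverse d[t] = f[t] - exp(-dt/tau) f[t-1] recovers the instantaneous
    drive. Testing tuning on the deconvolved signal removes the systematic
    lag a calcium transient carries across region/phase boundaries.
    """
    traces = np.asarray(traces, dtype=float)
    decay = np.exp(-1.0 / (sample_rate * tau))
    out = traces.copy()
    out[:, 1:] -= decay * traces[:, :-1]
    return out


# --------------------------------------------------------------------------
# balanced contrasts for the session-level classifier
# --------------------------------------------------------------------------
def build_position_contrasts(regions, phases, directions) -> list[Contrast]:
    """Arm conditions: arm1 vs arm2 within each direction / non-trial stratum;
    center: non-trial hub frames vs non-trial arm frames."""
    regions = np.asarray(regions)
    phases = np.asarray(phases)
    directions = np.asarray(directions)
    arm1, arm2 = regions == "arm1", regions == "arm2"
    center = regions == "center"
    notrial = directions == ""
    strata_ctx = [directions == "arm1->arm2", directions == "arm2->arm1", notrial]
    return [
        Contrast("arm1", [(arm1 & c, arm2 & c) for c in strata_ctx]),
        Contrast("center", [(center & notrial, (arm1 | arm2) & notrial)]),
        Contrast("arm2", [(arm2 & c, arm1 & c) for c in strata_ctx]),
    ]


def build_path_contrasts(regions, phases, directions) -> list[Contrast]:
    """Phase conditions: origin vs destination phase within the same arm;
    central: in-trial hub frames vs non-trial hub frames."""
    regions = np.asarray(regions)
    phases = np.asarray(phases)
    directions = np.asarray(directions)
    start = phases == "starting"
    central = phases == "central"
    term = phases == "terminal"
    arm1, arm2 = regions == "arm1", regions == "arm2"
    hub_out = (regions == "center") & (directions == "")
    return [
        Contrast("starting", [(start & arm1, term & arm1), (start & arm2, term & arm2)]),
        Contrast("central", [(central, hub_out)]),
        Contrast("terminal", [(term & arm1, start & arm1), (term & arm2, start & arm2)]),
    ]


# --------------------------------------------------------------------------
# estimator
# --------------------------------------------------------------------------
class NeuronTuningClassifier(BaseEstimator):
    """Three-way tuning classification of a neural population.

    Parameters
    ----------
    alpha : float
        Significance level; a neuron is flagged for a modality when its
        combined (min over conditions) p-value is below alpha. No
        multiple-testing correction is applied (the 'one or more conditions'
        rule is used raw).
    n_permutations : int
        Circular-shift draws per test.
    min_shift_s : float
        Minimum circular shift in seconds (breaks trace autocorrelation).
    min_frames : int
        Minimum frames per stratum side; under-sampled strata are dropped
        and conditions without any usable stratum are skipped.
    balanced : bool
        Use the dissociating balanced contrasts (default). False falls back
        to plain condition-vs-rest statistics for all three tests.
    backend : {'shift', 'ranksum'}
        Null model; 'ranksum' implies plain contrasts.
    random_state : int or None
        Seed for the permutation draws.
    """

    def __init__(self, alpha: float = 0.05, n_permutations: int = 1000,
                 min_shift_s: float = 5.0, min_frames: int = 20,
                 balanced: bool = True, backend: str = "shift",
                 deconvolve_tau: float | None = 0.4,
                 random_state: int | None = None):
        self.alpha = alpha
        self.n_permutations = n_permutations
        self.min_shift_s = min_shift_s
        self.min_frames = min_frames
        self.balanced = balanced
        self.backend = backend
        self.deconvolve_tau = deconvolve_tau
        self.random_state = random_state

    def fit(self, session: AlignedSession, accel_category: np.ndarray | None = None):
        """Classify every neuron in the session.

        Needs ``session.regions``, ``session.phases`` and
        ``session.directions`` (fill with
        :func:`navscope.kinematics.annotate_session`); ``accel_category``
        defaults to binning the session's own kinematics.
        """
        if session.regions is None or session.phases is None:
            raise ValueError("session must be annotated (regions/phases) before tuning")
        if accel_category is None:
            from . import kinematics as bk
            kin = bk.compute_speed_accel(bk.smooth_centroid(session.trajectory))
            accel_category = bin_acceleration(kin).category
        traces = session.traces.values
        sr = session.traces.sample_rate
        if self.deconvolve_tau:
            traces = deconvolve_ar1(traces, self.deconvolve_tau, sr)
        directions = session.directions
        if directions is None:
            directions = np.full(session.n_frames, "", dtype="U12")

        accel_labels = np.where(np.asarray(accel_category) == "excluded",
                                "", accel_category)
        common = dict(n_permutations=self.n_permutations,
                      min_shift_s=self.min_shift_s, sample_rate=sr,
                      min_frames=self.min_frames, alpha=self.alpha)
        seeds = np.random.SeedSequence(self.random_state).spawn(3)
        if self.backend == "shift" and self.balanced:
            res_a = batch_contrast_test(
                traces, one_vs_rest_contrasts(accel_labels, ACCEL_CONDITIONS),
                seed=seeds[0], **common)
            res_p = batch_contrast_test(
                traces, build_position_contrasts(session.regions, session.phases,
                                                 directions),
                seed=seeds[1], **common)
            res_t = batch_contrast_test(
                traces, build_path_contrasts(session.regions, session.phases,
                                             directions),
                seed=seeds[2], **common)
        else:
            pos_labels = np.where(np.isin(session.regions, POSITION_CONDITIONS),
                                  session.regions, "")
            path_labels = np.where(np.isin(session.phases, PATH_CONDITIONS),
                                   session.phases, "")
            res_a = batch_condition_test(traces, accel_labels, ACCEL_CONDITIONS,
                                         seed=seeds[0], backend=self.backend, **common)
            res_p = batch_condition_test(traces, pos_labels, POSITION_CONDITIONS,
                                         seed=seeds[1], backend=self.backend, **common)
            res_t = batch_condition_test(traces, path_labels, PATH_CONDITIONS,
                                         seed=seeds[2], backend=self.backend, **common)

        a = self.alpha
        t = pd.DataFrame({"neuron_id": session.traces.neuron_ids})
        for name, res in (("acceleration", res_a), ("position", res_p),
                          ("path", res_t)):
            for k, c in enumerate(res["names"]):
                t[f"p_{name}_{c}"] = res["p"][:, k]
            t[f"p_{name}"] = res["p_combined"]
            flag = pd.array(res["p_combined"] < a, dtype="boolean")
            flag[~np.isfinite(res["p_combined"])] = pd.NA  # untestable, not False
            t[f"is_{name}_tuned"] = flag
            t[f"preferred_{name}"] = res["preferred"]
        t["is_conjunctive_accel_position"] = (
            t["is_acceleration_tuned"].fillna(False)
            & t["is_position_tuned"].fillna(False))
        t["is_conjunctive_accel_path"] = (
            t["is_acceleration_tuned"].fillna(False)
            & t["is_path_tuned"].fillna(False))
        self.results_ = TuningResult(table=t, metadata={
            "method": self.backend,
            "contrasts": "balanced" if self.balanced else "one-vs-rest",
            "n_permutations": self.n_permutations,
            "seed": self.random_state, "alpha": self.alpha,
            "min_shift_s": self.min_shift_s, "min_frames": self.min_frames,
        })
        return self


def classify_neurons(session: AlignedSession, accel_category=None,
                     alpha: float = 0.05, n_permutations: int = 1000,
                     seed: int | None = None, **kw) -> TuningResult:
    """Functional wrapper over :class:`NeuronTuningClassifier`."""
    clf = NeuronTuningClassifier(alpha=alpha, n_permutations=n_permutations,
                                 random_state=seed, **kw)
    clf.fit(session, accel_category=accel_category)
    return clf.results_


def export_spatial_map(result: TuningResult, traces: NeuralTraces) -> pd.DataFrame:
    """Flat per-neuron table of image-plane centroids and class flags."""
    if traces.centroids is None:
        raise ValueError("traces carry no neuron centroids")
    bad = np.flatnonzero(~np.isfinite(traces.centroids).all(axis=1))
    if len(bad):
        raise ValueError(f"neuron {traces.neuron_ids[bad[0]]} has no centroid")
    out = pd.DataFrame({
        "neuron_id": traces.neuron_ids,
        "centroid_x": traces.centroids[:, 0],
        "centroid_y": traces.centroids[:, 1],
    })
    flags = [c for c in result.table.columns if c.startswith("is_")]
    for c in flags:
        out[c] = result.table[c].fillna(False).to_numpy(dtype=bool)
    return out
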