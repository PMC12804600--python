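"""Dissociating acceleration from position coding.

Three complementary analyses: (1) a location-matched d' that asks whether a
neuron discriminates high from low acceleration while spatial location is
held constant, d' = (mu_high - mu_low) / sqrt(0.5 (var_high + var_low));
(2) an encoding-focused linear model of the x-trajectory,
x(t) = b0 + b1 Position(t) + b2 Acceleration(t) + eps, where the regressors
are z-scored class-mean population traces; (3) decoder-based controls:
remove-and-retrain ablation of tuned subsets (with a size-matched random
control) and removal of lick-period frames.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from sklearn.base import BaseEstimator

from .io import AlignedSession
from .tuning import TuningResult

DPRIME_INF_SENTINEL = np.inf  # zero variances with unequal means


@dataclass
class DprimeResult:
    """Per neuron x matched spatial region d' and group moments."""

    table: pd.DataFrame  # neuron_id, region, mu/var/n per group, d_prime
    metadata: dict = field(default_factory=dict)


@dataclass
class GlmFit:
    beta0: float
    beta1: float
    beta2: float
    se: tuple
    resid_var: float
    r_squared: float
    n_frames: int
    metadata: dict = field(default_factory=dict)


def dprime(mu_high, mu_low, var_high, var_low) -> float:
    """Plain d' with the pooled-variance denominator."""
    pooled = 0.5 * (var_high + var_low)
    if pooled == 0:
        if mu_high == mu_low:
            return 0.0
        return float(np.sign(mu_high - mu_low)) * DPRIME_INF_SENTINEL
    return float((mu_high - mu_low) / np.sqrt(pooled))


def compute_dprime(
    traces: np.ndarray,
    accel_category: np.ndarray,
    regions: np.ndarray,
    matched_regions: tuple = ("arm1", "arm2"),
    min_frames: int = 20,
    estimator: str = "framewise",
    trials=None,
    neuron_ids=None,
) -> DprimeResult:
    """Location-matched acceleration d' per neuron per spatial region.

    Within each matched region, frames are split by acceleration bin and
    d' is computed from the group means and unbiased variances. The default
    'framewise' estimator uses every frame in the region; the 'trialmean'
    backend first averages frames within each trial visit and computes d'
    over trial means (requires ``trials``). Regions with fewer than
    ``min_frames`` frames in either group are skipped with a warning entry.
    """
    traces = np.atleast_2d(np.asarray(traces, dtype=float))
    accel_category = np.asarray(accel_category)
    regions = np.asarray(regions)
    if neuron_ids is None:
        neuron_ids = np.arange(traces.shape[0])
    rows = []
    skipped = []
    for reg in matched_regions:
        in_reg = regions == reg
        if estimator == "framewise":
            hi_sel = in_reg & (accel_category == "high")
            lo_sel = in_reg & (accel_category == "low")
            hi_mat, lo_mat = traces[:, hi_sel], traces[:, lo_sel]
        elif estimator == "trialmean":
            if trials is None:
                raise ValueError("trialmean estimator requires trials")
            hi_cols, lo_cols = [], []
            for tr in trials:
                sl = slice(tr.start_frame, tr.end_frame)
                for cat, cols in (("high", hi_cols), ("low", lo_cols)):
                    sel = np.zeros(len(regions), dtype=bool)
                    sel[sl] = True
                    sel &= in_reg & (accel_category == cat)
                    if sel.sum() >= 2:
                        cols.append(traces[:, sel].mean(axis=1))
            hi_mat = np.column_stack(hi_cols) if hi_cols else np.empty((traces.shape[0], 0))
            lo_mat = np.column_stack(lo_cols) if lo_cols else np.empty((traces.shape[0], 0))
        else:
            raise ValueError(f"unknown estimator '{estimator}'")
        n_hi, n_lo = hi_mat.shape[1], lo_mat.shape[1]
        min_n = min_frames if estimator == "framewise" else 3
        if n_hi < min_n or n_lo < min_n:
            skipped.append({"region": reg, "n_high": n_hi, "n_low": n_lo})
            continue
        mu_h, mu_l = hi_mat.mean(axis=1), lo_mat.mean(axis=1)
        var_h = hi_mat.var(axis=1, ddof=1)
        var_l = lo_mat.var(axis=1, ddof=1)
        d = np.array([dprime(a, b, c, e) for a, b, c, e in zip(mu_h, mu_l, var_h, var_l)])
        rows.append(pd.DataFrame({
            "neuron_id": neuron_ids, "region": reg,
            "mu_high": mu_h, "mu_low": mu_l,
            "var_high": var_h, "var_low": var_l,
            "n_high": n_hi, "n_low": n_lo, "d_prime": d,
        }))
    table = pd.concat(rows, ignore_index=True) if rows else pd.DataFrame(
        columns=["neuron_id", "region", "mu_high", "mu_low", "var_high",
                 "var_low", "n_high", "n_low", "d_prime"])
    return DprimeResult(table=table, metadata={
        "estimator": estimator, "min_frames": min_frames,
        "matched_regions": list(matched_regions), "skipped": skipped,
    })


# --------------------------------------------------------------------------
# trajectory GLM
# --------------------------------------------------------------------------
def build_population_regressors(
    traces: np.ndarray,
    tuning: TuningResult,
    valid: np.ndarray | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Scalar per-frame regressors from the tuned populations.

    Each regressor is the z-scored mean dF/F across the flagged population
    (position-tuned and acceleration-tuned respectively); the mapping from
    neuron sets to scalars is recorded in downstream fit metadata.
    """
    t = tuning.table
    out = []
    for flag in ("is_position_tuned", "is_acceleration_tuned"):
        sel = t[flag].fillna(False).to_numpy(dtype=bool)
        if sel.sum() == 0:
            raise ValueError(
                f"no neurons flagged {flag}; increase the synthetic tuning gain "
                "or the session duration")
        reg = np.asarray(traces, dtype=float)[sel].mean(axis=0)
        if valid is not None:
            mu, sd = reg[valid].mean(), reg[valid].std()
        else:
            mu, sd = reg.mean(), reg.std()
        out.append((reg - mu) / sd if sd > 0 else reg - mu)
    return out[0], out[1]


class TrajectoryGLM(BaseEstimator):
    """OLS encoding model of the x-trajectory on population regressors.

    ``fit(X, y)`` takes ``X = column_stack([position, acceleration])`` and the
    x-coordinate series; exposes ``coef_`` (b1, b2), ``intercept_`` (b0),
    standard errors, residual variance and R^2.
    """

    def __init__(self, max_condition_number: float = 1e8):
        self.max_condition_number = max_condition_number

    def fit(self, X, y):
        X = np.asarray(X, dtype=float)
        y = np.asarray(y, dtype=float)
        if X.ndim != 2 or X.shape[1] != 2:
            raise ValueError("X must be (n_frames, 2): position and acceleration")
        if len(y) != len(X) or len(y) < 10:
            raise ValueError("need >= 10 valid frames")
        design = sm.add_constant(X)
        cond = np.linalg.cond(design)
        if cond > self.max_condition_number:
            raise ValueError(
                f"collinear regressors (condition number {cond:.3g})")
        res = sm.OLS(y, design).fit()
        self.intercept_ = float(res.params[0])
        self.coef_ = np.asarray(res.params[1:])
        self.se_ = np.asarray(res.bse)
        self.resid_var_ = float(res.mse_resid)
        self.rsquared_ = float(res.rsquared)
        self.n_frames_ = int(res.nobs)
        self.result_ = res
        return self

    def predict(self, X):
        X = np.asarray(X, dtype=float)
        return self.intercept_ + X @ self.coef_


def fit_trajectory_glm(x_series, position, acceleration) -> GlmFit:
    """Fit x(t) = b0 + b1 Position(t) + b2 Acceleration(t) + eps by OLS."""
    X = np.column_stack([np.asarray(position, float), np.asarray(acceleration, float)])
    ok = np.isfinite(np.asarray(x_series, float)) & np.isfinite(X).all(axis=1)
    glm = TrajectoryGLM().fit(X[ok], np.asarray(x_series, float)[ok])
    return GlmFit(
        beta0=glm.intercept_, beta1=float(glm.coef_[0]), beta2=float(glm.coef_[1]),
        se=tuple(map(float, glm.se_)), resid_var=glm.resid_var_,
        r_squared=glm.rsquared_, n_frames=glm.n_frames_,
        metadata={"regressors": "z-scored class-mean dF/F", "estimator": "OLS"},
    )


# --------------------------------------------------------------------------
# decoder-based controls
# --------------------------------------------------------------------------
@dataclass
class AblationReport:
    """Decoding metric deltas after removing tuned neuron subsets."""

    table: pd.DataFrame  # condition, seed, accuracy, delta_vs_full, n_removed
    metadata: dict = field(default_factory=dict)


def _subset_indices(tuning: TuningResult, flag: str) -> np.ndarray:
    return np.flatnonzero(tuning.table[flag].fillna(False).to_numpy(dtype=bool))


def ablation_contribution(
    trials_data: list,
    labels: np.ndarray,
    tuning: TuningResult,
    decoder_factory,
    seeds=(0, 1, 2, 3, 4),
    subsets: tuple = ("acceleration", "position", "path"),
) -> AblationReport:
    """Remove-and-retrain contribution analysis.

    For each condition the specified decoder is retrained from scratch with
    the neuron subset removed *before* dimensionality reduction; a random
    subset of exactly the same size is removed as a control. ``trials_data``
    is a list of (frames x neurons) trial matrices; ``decoder_factory(seed)``
    must return an unfitted trial decoder.
    """
    n_neurons = trials_data[0].shape[1]
    rows = []
    removed = {"full": np.array([], dtype=int)}
    for name in subsets:
        idx = _subset_indices(tuning, f"is_{name}_tuned")
        if len(idx) >= n_neurons:
            raise ValueError(f"subset '{name}' covers the whole population")
        removed[f"drop_{name}_tuned"] = idx
    for seed in seeds:
        rng = np.random.default_rng(seed)
        accs = {}
        for cond, idx in removed.items():
            keep = np.setdiff1d(np.arange(n_neurons), idx)
            data = [tr[:, keep] for tr in trials_data]
            model = decoder_factory(seed).fit(data, labels)
            accs[cond] = model.report_.accuracy
            rows.append({"condition": cond, "seed": seed,
                         "accuracy": accs[cond], "n_removed": len(idx)})
        # size-matched random removals
        for name in subsets:
            idx = removed[f"drop_{name}_tuned"]
            if len(idx) == 0:
                continue
            rand = rng.choice(n_neurons, size=len(idx), replace=False)
            keep = np.setdiff1d(np.arange(n_neurons), rand)
            data = [tr[:, keep] for tr in trials_data]
            model = decoder_factory(seed).fit(data, labels)
            rows.append({"condition": f"drop_random_matched_{name}", "seed": seed,
                         "accuracy": model.report_.accuracy, "n_removed": len(idx)})
    table = pd.DataFrame(rows)
    full = table[table["condition"] == "full"].set_index("seed")["accuracy"]
    table["delta_vs_full"] = table.apply(
        lambda r: r["accuracy"] - full.loc[r["seed"]], axis=1)
    return AblationReport(table=table, metadata={
        "strategy": "remove-and-retrain", "seeds": list(seeds)})


def lick_frame_mask(session: AlignedSession, pad_s: float = 0.5) -> np.ndarray:
    """True at frames within ``pad_s`` of any lick event."""
    mask = np.zeros(session.n_frames, dtype=bool)
    pad = int(round(pad_s * session.traces.sample_rate))
    for f in session.event_frames("lick"):
        mask[max(0, f - pad):min(session.n_frames, f + pad + 1)] = True
    return mask


def lick_removal_control(
    session: AlignedSession,
    decoder_factory,
    seeds=(0, 1, 2, 3, 4),
    pad_s: float = 0.5,
    labels: np.ndarray | None = None,
) -> pd.DataFrame:
    """Retrain a window decoder with lick-period frames removed.

    Frames within ``pad_s`` of any lick are dropped from both training and
    evaluation; the with/without decoders share seeds, and the paired
    accuracy deltas are returned (columns: seed, acc_with, acc_without,
    delta).
    """
    if labels is None:
        labels = session.regions
    drop = lick_frame_mask(session, pad_s)
    if (~drop).sum() < 50:
        raise ValueError("lick-frame removal leaves too few frames")
    frames = session.traces.values.T
    labels = np.asarray(labels)

    # shared window bookkeeping: validation windows are lick-free for both
    # decoders and the training sets are size-matched, so the paired delta
    # isolates lick-coupled signal content rather than a change in
    # evaluation-set composition or training-set size
    probe = decoder_factory(seeds[0])
    w, starts = probe._windows(len(frames))
    ends = starts + w
    ok = np.array([labels[e - 1] not in ("", "none") for e in ends])
    lickfree = ok & np.array([not drop[s:e].any() for s, e in zip(starts, ends)])
    L = starts[lickfree]
    yL = labels[L + w - 1]
    if len(L) < 20:
        raise ValueError("lick-frame removal leaves too few windows")
    rows = []
    from sklearn.model_selection import train_test_split
    for seed in seeds:
        trL, va = train_test_split(np.arange(len(L)), test_size=0.3,
                                   stratify=yL, random_state=seed)
        va_starts = L[va]
        without_train = L[trL]
        # the with-lick decoder trains on the same lick-free windows plus
        # every lick window; evaluation is identical for both
        with_train = np.concatenate([without_train, starts[ok & ~lickfree]])
        m_with = decoder_factory(seed).fit(frames, labels,
                                           split=(with_train, va_starts))
        m_without = decoder_factory(seed).fit(frames, labels,
                                              split=(without_train, va_starts))
        rows.append({
            "seed": seed,
            "acc_with": m_with.report_.accuracy,
            "acc_without": m_without.report_.accuracy,
            "delta": m_without.report_.accuracy - m_with.report_.accuracy,
        })
    return pd.DataFrame(rows)
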