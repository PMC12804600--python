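"""Synthetic sessions with planted ground truth.

The generator emulates the study conditions: a Y-maze with three 30-cm arms
and alternating 20-ul water rewards, trajectories with realistic speed and
acceleration profiles (accelerating out of a reward zone, decelerating into
the next, accelerations spanning the 0-50 cm/s^2 analysis range), and
GCaMP6f-like dF/F traces built from a Poisson event process convolved with a
causal exponential kernel (tau ~ 0.4 s) plus white Gaussian noise. Neurons
are planted as position-, path-, acceleration-, conjunctive- or un-tuned,
with the planted class and preferred condition recorded so every downstream
stage is testable by recovery.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.signal import lfilter

from .geometry import MazeGeometry, ymaze_geometry
from .io import AlignedSession, EventLog, NeuralTraces, Trajectory, align_behavior_to_neural
from . import kinematics as bk
from .tuning import bin_acceleration

CELL_CLASSES = (
    "position", "path", "acceleration",
    "conjunctive_accel_position", "conjunctive_accel_path", "untuned",
)

_LEGAL_PREFERRED = {
    "position": ["arm1", "center", "arm2"],
    "path": ["starting", "central", "terminal"],
    "acceleration": ["low", "high"],
    # conjunctions are restricted to combinations that co-occur: the hub is
    # crossed at near-zero acceleration, so accel x center/central pairs are
    # essentially never sampled
    "conj_position": ["arm1", "arm2"],
    "conj_path": ["starting", "terminal"],
    # zone-coded populations also carry dedicated empty-arm cells, otherwise
    # arm 3 is only decodable by exclusion (the hub zone pools center + arm3)
    "position_zones": ["reward1", "arm1_path", "hub", "arm2_path", "reward2", "arm3"],
}


@dataclass
class SimConfig:
    """Configuration of one synthetic session (defaults are the study conditions)."""

    seed: int = 0
    session_duration: float = 600.0  # s
    neural_rate: float = 10.0  # Hz
    behavior_rate: float = 19.0  # frames/s (Y-maze camera)
    n_neurons: int = 500
    class_counts: dict = field(default_factory=lambda: {
        "position": 20, "path": 20, "acceleration": 40,
        "conjunctive_accel_position": 5, "conjunctive_accel_path": 5,
        "untuned": 410,
    })
    tuning_gain: float = 6.0  # rate multiplier on top of baseline
    baseline_rate: float = 0.2  # events/s
    calcium_decay_tau: float = 0.4  # s, GCaMP6f-like
    calcium_amplitude: float = 1.0  # dF/F per event
    noise_sigma: float = 0.05  # dF/F
    mean_speed: float = 22.0  # cm/s peak-ish cruise speed
    accel_range: tuple = (8.0, 45.0)  # cm/s^2, per-traversal departure accel
    dwell_time: float = 2.0  # s at the spout
    excursion_prob: float = 0.15  # arm-3 detour probability per traversal
    excursion_pause_s: float = 1.0  # center pause during a detour
    position_jitter: float = 0.08  # cm, per-frame centroid jitter
    lick_rate: float = 7.0  # Hz within a lick bout
    n_licks_per_visit: int = 5
    position_coding: str = "regions"  # 'regions' (3-region cells) | 'zones' (5-zone cells)

    def __post_init__(self):
        if sum(self.class_counts.values()) != self.n_neurons:
            raise ValueError("class counts must sum to n_neurons")
        if any(v < 0 for v in self.class_counts.values()):
            raise ValueError("class counts must be non-negative")
        for name in ("session_duration", "neural_rate", "behavior_rate",
                     "baseline_rate", "calcium_decay_tau"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")


# --------------------------------------------------------------------------
# Y-maze trajectory
# --------------------------------------------------------------------------
def _speed_profile(S: float, a_up: float, a_down: float, v_peak: float, dt: float):
    """Arc-length samples of a trapezoidal speed profile covering distance S."""
    v_lim = np.sqrt(2.0 * S * a_up * a_down / (a_up + a_down))
    v = min(v_peak, v_lim)
    t_up, t_down = v / a_up, v / a_down
    d_up, d_down = 0.5 * v * t_up, 0.5 * v * t_down
    d_cruise = max(S - d_up - d_down, 0.0)
    t_cruise = d_cruise / v
    T = t_up + t_cruise + t_down
    t = np.arange(dt, T + dt, dt)
    s = np.where(
        t < t_up, 0.5 * a_up * t**2,
        np.where(t < t_up + t_cruise, d_up + v * (t - t_up),
                 d_up + d_cruise + v * (t - t_up - t_cruise)
                 - 0.5 * a_down * (t - t_up - t_cruise) ** 2),
    )
    return np.clip(s, 0.0, S)


def _polyline_points(waypoints: np.ndarray, s: np.ndarray) -> np.ndarray:
    seg = np.diff(waypoints, axis=0)
    seglen = np.hypot(seg[:, 0], seg[:, 1])
    cum = np.concatenate([[0.0], np.cumsum(seglen)])
    s = np.clip(s, 0.0, cum[-1])
    xs = np.interp(s, cum, waypoints[:, 0])
    ys = np.interp(s, cum, waypoints[:, 1])
    return np.column_stack([xs, ys])


def simulate_ymaze_trajectory(
    cfg: SimConfig,
    geom: MazeGeometry | None = None,
    n_traversals: int | None = None,
) -> tuple[Trajectory, EventLog]:
    """Simulate alternating arm1<->arm2 reward traversals along arm centerlines.

    The mouse starts in arm 3, navigates to the arm-1 spout, and then shuttles
    between the two reward spouts with smooth trapezoidal speed profiles and
    dwell-and-lick bouts at each spout. Licks at the newly visited spout
    trigger water delivery (alternation-valid); repeat licks at the same spout
    are dry. A scripted record of every traversal is stored in
    ``Trajectory.meta['script']``.
    """
    if geom is None:
        geom = ymaze_geometry()
    rng = np.random.default_rng(cfg.seed)
    dt = 1.0 / cfg.behavior_rate
    spout_s = geom.hub_radius + geom.arm_length - 1.0

    pts: list[np.ndarray] = []
    events: list[tuple[float, str, int]] = []
    script: list[dict] = []
    t_now = 0.0

    def emit(block: np.ndarray) -> None:
        nonlocal t_now
        pts.append(block)
        t_now += len(block) * dt

    def dwell_block(center: np.ndarray, duration: float) -> np.ndarray:
        n = max(1, int(round(duration / dt)))
        return center[None, :] + rng.normal(0.0, 0.05, size=(n, 2))

    # initial dwell in arm 3 (the start arm)
    start_pos = geom.centerline_point("arm3", geom.hub_radius + 10.0)
    emit(dwell_block(start_pos, 1.0))

    spout = {a: np.asarray(geom.spouts[a]) for a in ("arm1", "arm2")}
    spout_id = {"arm1": 1, "arm2": 2}
    here = "arm3"
    here_pos = start_pos
    dest_cycle = ["arm1", "arm2"]
    k = 0
    max_t = cfg.session_duration
    while True:
        dest = dest_cycle[k % 2]
        if n_traversals is not None and k >= n_traversals:
            break
        if n_traversals is None and t_now > max_t - (cfg.dwell_time + 4.0):
            break
        excursion = (here != "arm3") and (rng.random() < cfg.excursion_prob)
        if excursion:  # detour: poke arm 3, pause at the hub, then continue
            probe = geom.centerline_point("arm3", geom.hub_radius + 15.0)
            legs = [[here_pos, np.zeros(2), probe, np.zeros(2)],
                    [np.zeros(2), spout[dest]]]
        else:
            legs = [[here_pos, np.zeros(2), spout[dest]]]
        t_move = t_now
        for leg_i, leg in enumerate(legs):
            waypoints = np.asarray(leg)
            S = float(np.sum(np.hypot(*np.diff(waypoints, axis=0).T)))
            a_up = rng.uniform(*cfg.accel_range)
            a_down = rng.uniform(*cfg.accel_range)
            v_peak = cfg.mean_speed * rng.uniform(0.9, 1.25)
            s = _speed_profile(S, a_up, a_down, v_peak, dt)
            block = _polyline_points(waypoints, s)
            block = block + rng.normal(0.0, cfg.position_jitter, size=block.shape)
            emit(block)
            if excursion and leg_i == 0 and cfg.excursion_pause_s > 0:
                emit(dwell_block(np.zeros(2), cfg.excursion_pause_s))
        t_arrive = t_now
        # dwell + lick bout at the spout
        duration = cfg.dwell_time * rng.uniform(0.8, 1.3)
        emit(dwell_block(spout[dest], duration))
        t_lick0 = t_arrive + 0.2
        sid = spout_id[dest]
        for j in range(cfg.n_licks_per_visit):
            tl = t_lick0 + j / cfg.lick_rate
            if tl >= t_now:
                break
            events.append((tl, "lick", sid))
            if j == 0:  # alternation-valid lick
                events.append((tl, "ir_trigger", sid))
                events.append((tl, "water_delivery", sid))
        script.append({
            "origin": here, "destination": dest,
            "direction": f"{here}->{dest}", "t_move_start": t_move,
            "t_arrive_reward": t_arrive, "excursion": bool(excursion),
        })
        here, here_pos = dest, spout[dest]
        k += 1
        if n_traversals is None and t_now >= max_t:
            break

    if k < 2:
        raise ValueError(
            f"session of {cfg.session_duration}s too short for two traversals")
    xy = np.concatenate(pts, axis=0)
    t = np.arange(len(xy)) * dt
    traj = Trajectory(timestamps=t, x=xy[:, 0], y=xy[:, 1],
                      frame_rate=cfg.behavior_rate, arena_id="ymaze",
                      meta={"script": script, "seed": cfg.seed})
    ev = pd.DataFrame(events, columns=["time", "kind", "spout_id"])
    return traj, EventLog(events=ev)


# --------------------------------------------------------------------------
# open field
# --------------------------------------------------------------------------
def simulate_openfield_trajectory(
    cfg: SimConfig,
    side: float = 40.0,
    turn_noise: float = 0.6,  # rad/sqrt(s) heading diffusion
    center_avoidance: float = 0.0,  # 0..1 bias away from arena center
) -> Trajectory:
    """Smoothed random-walk exploration of a ``side`` x ``side`` cm arena.

    Heading diffuses as a random walk (zero ``turn_noise`` gives a straight
    path until a wall); walls reflect; ``center_avoidance`` adds an outward
    heading bias inside the central zone so center entries stay countable but
    not dominant.
    """
    rng = np.random.default_rng(cfg.seed)
    dt = 1.0 / cfg.behavior_rate
    n = int(round(cfg.session_duration * cfg.behavior_rate))
    half = side / 2.0
    pos = np.empty((n, 2))
    pos[0] = (-half * 0.5, -half * 0.5)
    heading = rng.uniform(0, 2 * np.pi)
    speed = max(cfg.mean_speed * 0.5, 5.0)
    for i in range(1, n):
        heading += turn_noise * np.sqrt(dt) * rng.standard_normal()
        if center_avoidance > 0 and np.all(np.abs(pos[i - 1]) < side / 4):
            out = np.arctan2(pos[i - 1, 1], pos[i - 1, 0] + 1e-9)
            heading += center_avoidance * np.sin(out - heading) * dt * 5.0
        step = speed * dt
        p = pos[i - 1] + step * np.array([np.cos(heading), np.sin(heading)])
        for a in (0, 1):  # reflective boundary
            if p[a] > half:
                p[a] = 2 * half - p[a]
                heading = np.pi - heading if a == 0 else -heading
            elif p[a] < -half:
                p[a] = -2 * half - p[a]
                heading = np.pi - heading if a == 0 else -heading
        pos[i] = p
    t = np.arange(n) * dt
    return Trajectory(timestamps=t, x=pos[:, 0], y=pos[:, 1],
                      frame_rate=cfg.behavior_rate, arena_id="open_field",
                      meta={"seed": cfg.seed})


# --------------------------------------------------------------------------
# planted calcium traces
# --------------------------------------------------------------------------
def _condition_indicators(session: AlignedSession, kin, trials) -> dict[str, np.ndarray]:
    """Boolean per-frame indicators for every plantable condition."""
    bins = bin_acceleration(kin)
    ind = {}
    for r in ("arm1", "center", "arm2"):
        ind[r] = session.regions == r
    for z in _LEGAL_PREFERRED["position_zones"]:
        ind[z] = (session.regions == "arm3") if z == "arm3" else (session.zones == z)
    for p in ("starting", "central", "terminal"):
        ind[p] = session.phases == p
    ind["low"] = bins.category == "low"
    ind["high"] = bins.category == "high"
    return ind


def plant_traces(
    session: AlignedSession,
    cfg: SimConfig,
    geom: MazeGeometry | None = None,
) -> tuple[NeuralTraces, pd.DataFrame]:
    """Plant tuned neurons on an aligned session.

    Each neuron's per-frame event rate is ``baseline * (1 + gain * ind)``
    where ``ind`` is the indicator of its preferred condition (product of two
    indicators for conjunctive neurons); events are Poisson draws per neural
    frame, convolved with a causal exponential kernel (``calcium_decay_tau``),
    plus white Gaussian noise. Returns the trace matrix and the ground-truth
    table (class, preferred condition, gain, active-frame count).
    """
    if geom is None:
        geom = session.geometry or ymaze_geometry()
    if session.regions is None or session.phases is None:
        kin, _, trials = bk.annotate_session(session, geom)
    else:
        sm = bk.smooth_centroid(session.trajectory)
        kin = bk.compute_speed_accel(sm)
        trials = None
    ind = _condition_indicators(session, kin, trials)
    rng = np.random.default_rng(np.random.SeedSequence([cfg.seed, 1]))
    n_frames = session.n_frames
    dt = 1.0 / cfg.neural_rate

    classes, preferred = [], []
    for cls in CELL_CLASSES:
        for _ in range(cfg.class_counts.get(cls, 0)):
            classes.append(cls)
            if cls == "untuned":
                preferred.append("")
            elif cls == "position":
                legal = ("position_zones" if cfg.position_coding == "zones"
                         else "position")
                preferred.append(rng.choice(_LEGAL_PREFERRED[legal]))
            elif cls == "path":
                preferred.append(rng.choice(_LEGAL_PREFERRED["path"]))
            elif cls == "acceleration":
                preferred.append(rng.choice(_LEGAL_PREFERRED["acceleration"]))
            elif cls == "conjunctive_accel_position":
                preferred.append(rng.choice(_LEGAL_PREFERRED["acceleration"])
                                 + "&" + rng.choice(_LEGAL_PREFERRED["conj_position"]))
            else:
                preferred.append(rng.choice(_LEGAL_PREFERRED["acceleration"])
                                 + "&" + rng.choice(_LEGAL_PREFERRED["conj_path"]))

    values = np.empty((len(classes), n_frames))
    active_frames = np.zeros(len(classes), dtype=int)
    decay = np.exp(-dt / cfg.calcium_decay_tau)
    for i, (cls, pref) in enumerate(zip(classes, preferred)):
        if cls == "untuned":
            on = np.zeros(n_frames, dtype=bool)
        elif "&" in pref:
            a, b = pref.split("&")
            on = ind[a] & ind[b]
        else:
            on = ind[pref]
        active_frames[i] = int(on.sum())
        if cls != "untuned" and active_frames[i] == 0:
            warnings.warn(f"neuron {i}: preferred condition '{pref}' never active")
        rate = cfg.baseline_rate * (1.0 + cfg.tuning_gain * on) * dt
        counts = rng.poisson(rate)
        tr = lfilter([cfg.calcium_amplitude], [1.0, -decay], counts.astype(float))
        if cfg.noise_sigma > 0:
            tr = tr + rng.normal(0.0, cfg.noise_sigma, size=n_frames)
        values[i] = tr

    centroids = rng.uniform(0.0, 1000.0, size=(len(classes), 2))  # um, salt-and-pepper
    traces = NeuralTraces(values=values, sample_rate=cfg.neural_rate,
                          neuron_ids=np.arange(len(classes)), centroids=centroids)
    gt = pd.DataFrame({
        "neuron_id": np.arange(len(classes)),
        "cell_class": classes,
        "preferred": preferred,
        "gain": np.where(np.array(classes) == "untuned", 0.0, cfg.tuning_gain),
        "active_frames": active_frames,
    })
    return traces, gt


def simulate_session(
    cfg: SimConfig,
    geom: MazeGeometry | None = None,
    n_traversals: int | None = None,
):
    """End-to-end synthetic session on the neural clock.

    Returns ``(session, ground_truth, kin, regions, trials)`` where the
    session carries planted traces and the behavior annotations are filled.
    """
    if geom is None:
        geom = ymaze_geometry()
    traj, events = simulate_ymaze_trajectory(cfg, geom, n_traversals=n_traversals)
    n_frames = int(np.floor(traj.timestamps[-1] * cfg.neural_rate)) + 1
    placeholder = NeuralTraces(values=np.zeros((1, n_frames)), sample_rate=cfg.neural_rate)
    session = align_behavior_to_neural(traj, placeholder, events)
    kin, regions, trials = bk.annotate_session(session, geom)
    traces, gt = plant_traces(session, cfg, geom)
    session.traces = traces
    _check_accel_coverage(kin)
    return session, gt, kin, regions, trials


def _check_accel_coverage(kin, min_frames: int = 100) -> None:
    bins = bin_acceleration(kin)
    for cat in ("low", "high"):
        n = int(np.sum(bins.category == cat))
        if n < min_frames:
            warnings.warn(
                f"only {n} frames in the '{cat}' acceleration bin "
                f"(expected >= {min_frames} at default durations)")


def high_snr_decoding_config(seed: int, session_duration: float = 1200.0) -> SimConfig:
    """Constructed-separability scenario for decoder validation.

    A strongly tuned population (gain 8, low noise, fast GCaMP kinetics,
    elevated event rate) with generous hub/arm-3 occupancy, so that path and
    position are decodable well above chance and decoder failures indicate
    implementation defects rather than weak signal.
    """
    return SimConfig(
        seed=seed, session_duration=session_duration, n_neurons=200,
        class_counts={"position": 40, "path": 20, "acceleration": 30,
                      "conjunctive_accel_position": 5,
                      "conjunctive_accel_path": 5, "untuned": 100},
        tuning_gain=8.0, baseline_rate=0.4, calcium_decay_tau=0.25,
        noise_sigma=0.02, excursion_prob=0.25, excursion_pause_s=2.0,
        dwell_time=3.0, position_coding="zones",
    )


# --------------------------------------------------------------------------
# GLM forward model
# --------------------------------------------------------------------------
def simulate_glm_session(
    beta0: float,
    beta1: float,
    beta2: float,
    noise_sd: float,
    n_frames: int,
    seed: int,
    position: np.ndarray | None = None,
    acceleration: np.ndarray | None = None,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Generate data exactly under the trajectory encoding model.

    ``x(t) = beta0 + beta1 * Position(t) + beta2 * Acceleration(t) + eps``
    with iid Gaussian noise. Regressors default to iid standard normal series
    (pass explicit arrays to control them).
    """
    if n_frames < 10:
        raise ValueError("n_frames must be >= 10")
    rng = np.random.default_rng(seed)
    if position is None:
        position = rng.standard_normal(n_frames)
    if acceleration is None:
        acceleration = rng.standard_normal(n_frames)
    position = np.asarray(position, dtype=float)
    acceleration = np.asarray(acceleration, dtype=float)
    eps = rng.normal(0.0, noise_sd, size=n_frames) if noise_sd > 0 else 0.0
    x = beta0 + beta1 * position + beta2 * acceleration + eps
    return x, position, acceleration
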