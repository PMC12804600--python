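"""Trajectory kinematics, maze segmentation, and navigation-trial extraction.

Momentary tortuosity T(t) is the ratio of the cumulative path length L(t) to
the straight-line distance D(t) between the boundaries of a symmetric sliding
window of +/-1.25 s, after smoothing the centroid with a 0.5-s moving average.
Turn angle at a frame is the unsigned angle between the displacement vectors
formed by three consecutive frames. Acceleration is the signed time-derivative
of speed (linear acceleration), which is what makes the exclusion of
decelerations from acceleration tuning meaningful.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .geometry import MazeGeometry, openfield_geometry
from .io import AlignedSession, Trajectory

IMMOBILITY_SPEED_CMS = 2.0  # cm/s
IMMOBILITY_MIN_S = 1.0  # s
TURN_MIN_STEP_CM = 0.05  # minimum per-step displacement for turn angles
TORTUOSITY_D_FLOOR_CM = 0.1  # chord degeneracy floor


@dataclass
class KinematicSeries:
    """Per-frame speed, acceleration, tortuosity and turn angle."""

    timestamps: np.ndarray
    speed: np.ndarray  # cm/s
    acceleration: np.ndarray  # cm/s^2, signed d(speed)/dt
    tortuosity: np.ndarray | None = None  # >= 1 where defined, NaN otherwise
    turn_angle: np.ndarray | None = None  # deg in [0, 180], NaN where undefined
    valid: np.ndarray | None = None

    def __post_init__(self):
        if self.valid is None:
            self.valid = np.isfinite(self.speed)


@dataclass
class RegionSeries:
    """Per-frame maze region / 5-zone / path-phase labels."""

    region: np.ndarray  # {'arm1','arm2','arm3','center','none'}
    zone5: np.ndarray  # {'reward1','arm1_path','hub','arm2_path','reward2','none'}
    phase: np.ndarray | None = None  # {'starting','central','terminal','none'}


@dataclass
class NavigationTrial:
    """One origin-arm -> destination-arm traversal, frames half-open [start, end)."""

    start_frame: int
    end_frame: int
    direction: str  # 'arm1->arm2' | 'arm2->arm1'
    qualified: bool
    phases: np.ndarray  # per-frame labels over [start_frame, end_frame)
    origin: str = ""
    destination: str = ""

    def __post_init__(self):
        if self.start_frame >= self.end_frame:
            raise ValueError("trial start must precede end")
        self.origin, self.destination = self.direction.split("->")

    @property
    def n_frames(self) -> int:
        return self.end_frame - self.start_frame


@dataclass
class SessionMetrics:
    accumulated_distance: float = np.nan  # cm
    mean_speed: float = np.nan  # cm/s
    mean_acceleration: float = np.nan  # cm/s^2 (signed mean)
    tortuosity_p75: float = np.nan
    tortuosity_defined: bool = True
    center_entries: int = 0
    turn_angle_hist: dict = field(default_factory=dict)  # bin label -> count
    immobility_bouts: list = field(default_factory=list)
    time_to_30_valid_licks: float = np.nan  # s, NaN if < 30 valid licks
    reward_arm_entry_ratio: float = np.nan  # reward-arm entries / empty-arm entries
    error_lick_rate: float = np.nan  # in [0, 1]


# --------------------------------------------------------------------------
# smoothing, speed, acceleration
# --------------------------------------------------------------------------
def smooth_centroid(traj: Trajectory, window: float = 0.5) -> Trajectory:
    """Centered moving average of the centroid; edges use truncated windows."""
    w = int(round(window * traj.frame_rate))
    if w < 2:
        raise ValueError(f"window of {window}s is under 2 frames at {traj.frame_rate} fps")
    if w > len(traj):
        raise ValueError("smoothing window longer than trajectory")
    if w % 2 == 0:
        w += 1  # keep the window centered
    half = w // 2
    x = _truncated_moving_average(traj.x, half)
    y = _truncated_moving_average(traj.y, half)
    return Trajectory(timestamps=traj.timestamps, x=x, y=y,
                      frame_rate=traj.frame_rate, arena_id=traj.arena_id,
                      valid=traj.valid.copy(), meta=dict(traj.meta))


def _truncated_moving_average(v: np.ndarray, half: int) -> np.ndarray:
    n = len(v)
    c = np.concatenate([[0.0], np.cumsum(v)])
    lo = np.maximum(np.arange(n) - half, 0)
    hi = np.minimum(np.arange(n) + half + 1, n)
    return (c[hi] - c[lo]) / (hi - lo)


def compute_speed_accel(traj: Trajectory) -> KinematicSeries:
    """Frame-to-frame speed and its signed first difference.

    ``speed[t]`` is the displacement from frame t-1 to t over the frame
    interval; ``acceleration[t]`` is ``(speed[t] - speed[t-1]) / dt``. The
    first one (two) frame(s) are masked invalid.
    """
    t = traj.timestamps
    dt = np.diff(t)
    d = np.hypot(np.diff(traj.x), np.diff(traj.y))
    speed = np.full(len(traj), np.nan)
    speed[1:] = d / dt
    accel = np.full(len(traj), np.nan)
    accel[2:] = np.diff(speed[1:]) / dt[1:]
    valid = np.isfinite(speed) & traj.valid
    return KinematicSeries(timestamps=t, speed=speed, acceleration=accel, valid=valid)


# --------------------------------------------------------------------------
# tortuosity
# --------------------------------------------------------------------------
def compute_tortuosity(
    traj: Trajectory,
    kin: KinematicSeries,
    half_window: float = 1.25,
    speed_threshold: float | None = None,
    d_floor: float = TORTUOSITY_D_FLOOR_CM,
) -> tuple[np.ndarray, float]:
    """Momentary tortuosity T(t) = L(t)/D(t) over a +/-``half_window`` s window.

    L(t) sums frame-to-frame displacements over [t - hw, t + hw]; D(t) is the
    Euclidean distance between the window endpoints. Frames without full
    window support, or with D(t) below ``d_floor`` (out-and-back degeneracy),
    are NaN. The summary is the 75th percentile of T over frames whose speed
    exceeds ``speed_threshold`` (NaN, with a warning condition, if no frame
    does or no threshold is given).
    """
    h = int(round(half_window * traj.frame_rate))
    if h < 2:
        raise ValueError("half_window shorter than 2 frames")
    n = len(traj)
    d = np.hypot(np.diff(traj.x), np.diff(traj.y))
    cd = np.concatenate([[0.0], np.cumsum(d)])
    T = np.full(n, np.nan)
    idx = np.arange(h, n - h)
    if len(idx):
        L = cd[idx + h] - cd[idx - h]
        D = np.hypot(traj.x[idx + h] - traj.x[idx - h], traj.y[idx + h] - traj.y[idx - h])
        ok = D >= d_floor
        T[idx[ok]] = L[ok] / D[ok]
    summary = np.nan
    if speed_threshold is not None:
        sel = np.isfinite(T) & np.isfinite(kin.speed) & (kin.speed > speed_threshold)
        if np.any(sel):
            summary = float(np.percentile(T[sel], 75))
    return T, summary


def running_speed_threshold(kinematics: list[KinematicSeries]) -> float:
    """Mean of per-session 75th-percentile speeds, the 'running' threshold.

    The reference cohort is whatever set of sessions the caller passes in.
    """
    if not kinematics:
        raise ValueError("need at least one session")
    p75 = [np.nanpercentile(k.speed, 75) for k in kinematics]
    return float(np.mean(p75))


# --------------------------------------------------------------------------
# turn angles
# --------------------------------------------------------------------------
def compute_turn_angles(
    traj: Trajectory,
    min_step: float = TURN_MIN_STEP_CM,
    bins: np.ndarray | None = None,
) -> tuple[np.ndarray, dict]:
    """Unsigned turn angle (deg) from three consecutive frames, plus histogram.

    The angle at frame t is between the displacement vectors (t-1 -> t) and
    (t -> t+1); steps shorter than ``min_step`` cm are excluded (NaN).
    """
    if len(traj) < 3:
        raise ValueError("need at least 3 frames for turn angles")
    ux = np.diff(traj.x)
    uy = np.diff(traj.y)
    a, b = ux[:-1], ux[1:]
    c, e = uy[:-1], uy[1:]
    dot = a * b + c * e
    cross = a * e - c * b
    ang = np.degrees(np.arctan2(np.abs(cross), dot))
    steplen = np.hypot(ux, uy)
    ang[(steplen[:-1] < min_step) | (steplen[1:] < min_step)] = np.nan
    out = np.full(len(traj), np.nan)
    out[1:-1] = ang
    if bins is None:
        bins = np.arange(0.0, 181.0, 30.0)
    counts, edges = np.histogram(out[np.isfinite(out)], bins=bins)
    hist = {f"[{edges[i]:g},{edges[i+1]:g})": int(counts[i]) for i in range(len(counts))}
    return out, hist


# --------------------------------------------------------------------------
# immobility
# --------------------------------------------------------------------------
def label_immobility(
    kin: KinematicSeries,
    threshold: float = IMMOBILITY_SPEED_CMS,
    min_duration: float = IMMOBILITY_MIN_S,
) -> list[tuple[int, int]]:
    """Maximal half-open frame runs with speed < threshold lasting >= min_duration."""
    slow = np.where(np.isfinite(kin.speed), kin.speed < threshold, False)
    dt = np.median(np.diff(kin.timestamps))
    min_frames = int(np.ceil(min_duration / dt - 1e-9))
    bouts = []
    edges = np.flatnonzero(np.diff(np.r_[False, slow, False].astype(int)))
    for a, b in zip(edges[::2], edges[1::2]):
        if b - a >= min_frames:
            bouts.append((int(a), int(b)))
    return bouts


# --------------------------------------------------------------------------
# regions & trials
# --------------------------------------------------------------------------
def assign_regions(traj: Trajectory, geom: MazeGeometry) -> RegionSeries:
    """Point-in-polygon region and 5-zone labels (first-listed tie-break)."""
    region = geom.assign(traj.x, traj.y, zones=False)
    zone5 = geom.assign(traj.x, traj.y, zones=True)
    return RegionSeries(region=region, zone5=zone5)


def _sustained_at_or_above(mask: np.ndarray, n: int) -> np.ndarray:
    """True at i where mask[i:i+n] is all True (n >= 1)."""
    if n <= 1:
        return mask.copy()
    c = np.convolve(mask.astype(int), np.ones(n, dtype=int), mode="valid")
    out = np.zeros_like(mask)
    out[: len(c)] = c == n
    return out


def extract_navigation_trials(
    regions: RegionSeries,
    kin: KinematicSeries,
    events: pd.DataFrame,
    geom: MazeGeometry,
    traj: Trajectory,
    speed_threshold: float = IMMOBILITY_SPEED_CMS,
    sustain_s: float = 0.5,
    max_arm3_fraction: float = 0.2,
    max_duration_s: float = 60.0,
) -> list[NavigationTrial]:
    """Extract reward-arm traversals from the reward alternation.

    A trial runs from the initiation of movement in the origin arm (first
    frame after the previous water delivery with speed >= ``speed_threshold``
    sustained ``sustain_s`` while in the origin arm) to the first frame inside
    the destination reward zone, strictly before that traversal's water
    delivery. Trials entering arm 3 for more than ``max_arm3_fraction`` of
    their frames, or lasting over ``max_duration_s``, are kept but flagged
    unqualified.
    """
    deliveries = events[events["kind"] == "water_delivery"]
    if len(deliveries) < 2:
        return []
    frames = deliveries["frame"].to_numpy(dtype=int)
    spouts = deliveries["spout_id"].to_numpy(dtype=int)
    dt = np.median(np.diff(kin.timestamps))
    n_sustain = max(1, int(round(sustain_s / dt)))
    fast = np.where(np.isfinite(kin.speed), kin.speed >= speed_threshold, False)
    sustained = _sustained_at_or_above(fast, n_sustain)
    arm_of_spout = {1: "arm1", 2: "arm2"}
    rz1 = geom.in_reward_zone(traj.x, traj.y, "arm1")
    rz2 = geom.in_reward_zone(traj.x, traj.y, "arm2")
    in_rz = {"arm1": rz1, "arm2": rz2}
    trials: list[NavigationTrial] = []
    for k in range(1, len(frames)):
        origin = arm_of_spout[spouts[k - 1]]
        dest = arm_of_spout[spouts[k]]
        if origin == dest:
            continue  # not an alternation (should not happen with valid licks)
        n = len(regions.region)
        lo = min(frames[k - 1] + 1, n)
        hi = min(frames[k], n)  # delivery frame itself excluded
        start = None
        for i in range(lo, hi):
            if sustained[i] and regions.region[i] == origin:
                start = i
                break
        if start is None:
            continue
        end = None
        rz = in_rz[dest]
        for i in range(start + 1, hi):
            if rz[i]:
                end = i + 1  # half-open: include arrival frame
                break
        if end is None:
            continue
        seg = regions.region[start:end]
        arm3_frac = np.mean(seg == "arm3")
        duration = (end - start) * dt
        qualified = (arm3_frac <= max_arm3_fraction) and (duration <= max_duration_s)
        phases = np.full(end - start, "none", dtype="U10")
        phases[seg == origin] = "starting"
        phases[seg == "center"] = "central"
        phases[seg == dest] = "terminal"
        trials.append(NavigationTrial(
            start_frame=int(start), end_frame=int(end),
            direction=f"{origin}->{dest}", qualified=bool(qualified), phases=phases,
        ))
    return trials


def phase_series(trials: list[NavigationTrial], n_frames: int,
                 qualified_only: bool = True) -> np.ndarray:
    """Per-frame path-phase labels; 'none' outside trials."""
    out = np.full(n_frames, "none", dtype="U10")
    for tr in trials:
        if qualified_only and not tr.qualified:
            continue
        out[tr.start_frame:tr.end_frame] = tr.phases
    return out


def direction_series(trials: list[NavigationTrial], n_frames: int,
                     qualified_only: bool = True) -> np.ndarray:
    """Per-frame trial-direction labels; '' outside trials."""
    out = np.full(n_frames, "", dtype="U12")
    for tr in trials:
        if qualified_only and not tr.qualified:
            continue
        out[tr.start_frame:tr.end_frame] = tr.direction
    return out


def count_arm_entries(region: np.ndarray) -> dict[str, int]:
    """Transitions from 'center' into each arm."""
    entries = {"arm1": 0, "arm2": 0, "arm3": 0}
    prev = None
    for r in region:
        if r in entries and prev == "center":
            entries[r] += 1
        if r != "none":
            prev = r
    return entries


def learning_metrics(events: pd.DataFrame, regions: RegionSeries,
                     timestamps: np.ndarray, n_licks: int = 30) -> SessionMetrics:
    """Learning-curve metrics over the first ``n_licks`` valid licks.

    time_to_30_valid_licks is the time of the 30th water-delivered lick from
    session start; reward_arm_entry_ratio counts center->arm transitions into
    reward arms vs. the empty arm; error_lick_rate is the fraction of dry
    licks among all licks within the task period.
    """
    licks = events[events["kind"] == "lick"].reset_index(drop=True)
    deliveries = events[events["kind"] == "water_delivery"]
    if len(licks) == 0:
        raise ValueError("no lick events in session")
    m = SessionMetrics()
    t0 = timestamps[0]
    delivery_times = deliveries["time"].to_numpy()
    if len(delivery_times) >= n_licks:
        t_end = delivery_times[n_licks - 1]
        m.time_to_30_valid_licks = float(t_end - t0)
    else:
        t_end = timestamps[-1]
    task = licks["time"].to_numpy() <= t_end + 1e-9
    n_all = int(task.sum())
    n_valid = int((delivery_times <= t_end + 1e-9).sum())
    m.error_lick_rate = (n_all - n_valid) / n_all if n_all else np.nan
    frame_end = int(np.searchsorted(timestamps, t_end, side="right"))
    entries = count_arm_entries(regions.region[:frame_end])
    if entries["arm3"] > 0:
        m.reward_arm_entry_ratio = (entries["arm1"] + entries["arm2"]) / entries["arm3"]
    else:
        m.reward_arm_entry_ratio = np.inf if entries["arm1"] + entries["arm2"] else np.nan
    return m


# --------------------------------------------------------------------------
# open field
# --------------------------------------------------------------------------
def openfield_metrics(
    traj: Trajectory,
    arena: dict | None = None,
    adaption_s: float = 30.0,
    speed_threshold: float | None = None,
    smoothing_window: float = 0.5,
) -> SessionMetrics:
    """Open-field locomotion metrics, discarding the initial adaption period.

    Computes accumulated distance, mean speed/acceleration, the tortuosity
    75th-percentile summary, center entries and the turn-angle histogram over
    the analysis window.
    """
    if arena is None:
        arena = openfield_geometry()
    if traj.duration <= adaption_s:
        raise ValueError(
            f"session of {traj.duration:.1f}s shorter than {adaption_s}s adaption window")
    keep = traj.timestamps >= traj.timestamps[0] + adaption_s
    sub = Trajectory(timestamps=traj.timestamps[keep], x=traj.x[keep], y=traj.y[keep],
                     frame_rate=traj.frame_rate, arena_id=traj.arena_id,
                     valid=traj.valid[keep])
    sm = smooth_centroid(sub, smoothing_window)
    kin = compute_speed_accel(sm)
    tort, tort_p75 = compute_tortuosity(sm, kin, speed_threshold=speed_threshold)
    _, hist = compute_turn_angles(sm)
    m = SessionMetrics()
    m.accumulated_distance = float(np.nansum(np.hypot(np.diff(sm.x), np.diff(sm.y))))
    m.mean_speed = float(np.nanmean(kin.speed))
    m.mean_acceleration = float(np.nanmean(kin.acceleration))
    m.tortuosity_p75 = tort_p75
    m.tortuosity_defined = np.isfinite(tort_p75)
    import shapely as _sh
    inside = _sh.intersects_xy(arena["center"], sm.x, sm.y)
    m.center_entries = int(np.sum(inside[1:] & ~inside[:-1]) + int(inside[0]))
    m.turn_angle_hist = hist
    m.immobility_bouts = label_immobility(kin)
    return m


# --------------------------------------------------------------------------
# convenience: annotate an aligned session in place
# --------------------------------------------------------------------------
def annotate_session(session: AlignedSession, geom: MazeGeometry,
                     smoothing_window: float = 0.5) -> tuple[KinematicSeries, RegionSeries, list[NavigationTrial]]:
    """Smooth, compute kinematics, label regions/zones/phases and extract trials."""
    sm = smooth_centroid(session.trajectory, smoothing_window)
    kin = compute_speed_accel(sm)
    kin.tortuosity, _ = compute_tortuosity(sm, kin)
    kin.turn_angle, _ = compute_turn_angles(sm)
    regions = assign_regions(sm, geom)
    trials = extract_navigation_trials(regions, kin, session.events, geom, sm)
    regions.phase = phase_series(trials, len(sm))
    session.regions = regions.region
    session.zones = regions.zone5
    session.phases = regions.phase
    session.directions = direction_series(trials, len(sm))
    session.geometry = geom
    session.meta["smoothed"] = True
    return kin, regions, trials
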