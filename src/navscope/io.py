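"""Session artifacts: trajectories, event logs, trace matrices, results.

Behavioral video runs at 19 frames/s in the Y-maze (10 in the open field)
while calcium traces are sampled at 10 Hz; :func:`align_behavior_to_neural`
puts everything on the neural frame clock, which is the canonical clock for
every downstream statistic. Frames are 0-based; intervals half-open
``[start, end)``.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import h5py
import numpy as np
import pandas as pd

from .geometry import MazeGeometry

RESULTS_FORMAT_VERSION = 1

EVENT_KINDS = ("lick", "water_delivery", "ir_trigger")


# --------------------------------------------------------------------------
# domain types
# --------------------------------------------------------------------------
@dataclass
class Trajectory:
    """Timestamped 2-D centroid path in cm."""

    timestamps: np.ndarray  # s, strictly increasing
    x: np.ndarray  # cm
    y: np.ndarray  # cm
    frame_rate: float  # frames/s
    arena_id: str = "ymaze"  # 'ymaze' | 'open_field'
    valid: np.ndarray | None = None  # per-frame validity mask
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        self.timestamps = np.asarray(self.timestamps, dtype=float)
        self.x = np.asarray(self.x, dtype=float)
        self.y = np.asarray(self.y, dtype=float)
        if not (len(self.timestamps) == len(self.x) == len(self.y)):
            raise ValueError("timestamps, x, y must have equal length")
        if self.frame_rate <= 0:
            raise ValueError("frame_rate must be positive")
        dt = np.diff(self.timestamps)
        if np.any(dt <= 0):
            i = int(np.argmax(dt <= 0)) + 1
            raise ValueError(f"timestamps not strictly increasing at row {i}")
        if self.valid is None:
            self.valid = np.isfinite(self.x) & np.isfinite(self.y)
        else:
            self.valid = np.asarray(self.valid, dtype=bool)
        if np.any(~np.isfinite(self.x[self.valid])) or np.any(~np.isfinite(self.y[self.valid])):
            raise ValueError("non-finite coordinates flagged valid")

    def __len__(self) -> int:
        return len(self.timestamps)

    @property
    def duration(self) -> float:
        return float(self.timestamps[-1] - self.timestamps[0])


@dataclass
class EventLog:
    """Lick / reward event records.

    Every ``water_delivery`` co-occurs (within one behavioral frame) with a
    lick at the same spout; licks without delivery are dry (error) licks.
    """

    events: pd.DataFrame  # columns: time, kind, spout_id

    def __post_init__(self):
        ev = self.events
        missing = {"time", "kind", "spout_id"} - set(ev.columns)
        if missing:
            raise ValueError(f"event log missing columns {sorted(missing)}")
        bad = set(ev["kind"].unique()) - set(EVENT_KINDS)
        if bad:
            raise ValueError(f"unknown event kinds {sorted(bad)}")
        self.events = ev.sort_values("time", kind="stable").reset_index(drop=True)

    def of_kind(self, kind: str) -> pd.DataFrame:
        return self.events[self.events["kind"] == kind]

    def validate_against(self, traj: Trajectory) -> None:
        t = self.events["time"].to_numpy()
        if len(t) and (t.min() < traj.timestamps[0] - 1e-9 or t.max() > traj.timestamps[-1] + 1e-9):
            raise ValueError("event times outside session bounds")
        tol = 1.0 / traj.frame_rate + 1e-9
        licks = self.of_kind("lick")["time"].to_numpy()
        for tw in self.of_kind("water_delivery")["time"].to_numpy():
            if len(licks) == 0 or np.min(np.abs(licks - tw)) > tol:
                raise ValueError(f"water_delivery at t={tw:.3f}s has no co-occurring lick")

    def __len__(self) -> int:
        return len(self.events)


@dataclass
class NeuralTraces:
    """Neurons x frames dF/F matrix, nominally sampled at 10 Hz."""

    values: np.ndarray  # (n_neurons, n_frames)
    sample_rate: float = 10.0
    neuron_ids: np.ndarray | None = None
    centroids: np.ndarray | None = None  # (n_neurons, 2), image-plane um

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("trace matrix must be 2-D (neurons x frames)")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("non-finite values in trace matrix")
        if self.sample_rate <= 0:
            raise ValueError("sample_rate must be positive")
        if self.neuron_ids is None:
            self.neuron_ids = np.arange(self.values.shape[0])
        self.neuron_ids = np.asarray(self.neuron_ids)
        if len(self.neuron_ids) != self.values.shape[0]:
            raise ValueError("neuron_ids length mismatch")
        if self.centroids is not None:
            self.centroids = np.asarray(self.centroids, dtype=float)
            if self.centroids.shape != (self.values.shape[0], 2):
                raise ValueError("centroids must be (n_neurons, 2)")

    @property
    def n_neurons(self) -> int:
        return self.values.shape[0]

    @property
    def n_frames(self) -> int:
        return self.values.shape[1]

    @property
    def timestamps(self) -> np.ndarray:
        return np.arange(self.n_frames) / self.sample_rate


@dataclass
class AlignedSession:
    """Behavior resampled onto the neural frame clock.

    ``trajectory.timestamps`` equals the neural timestamps exactly; events
    carry a ``frame`` column (nearest neural frame, ties toward the earlier
    frame); ``regions``/``zones``/``phases`` are filled by the kinematics
    stage.
    """

    trajectory: Trajectory
    traces: NeuralTraces
    events: pd.DataFrame  # events with added 'frame' column
    valid: np.ndarray  # frames with behavioral support
    regions: np.ndarray | None = None
    zones: np.ndarray | None = None
    phases: np.ndarray | None = None
    directions: np.ndarray | None = None  # per-frame trial direction ('' outside)
    geometry: MazeGeometry | None = None
    meta: dict = field(default_factory=dict)

    @property
    def n_frames(self) -> int:
        return self.traces.n_frames

    def event_frames(self, kind: str) -> np.ndarray:
        ev = self.events
        return ev.loc[ev["kind"] == kind, "frame"].to_numpy(dtype=int)


# --------------------------------------------------------------------------
# loading
# --------------------------------------------------------------------------
def load_trajectory(
    path,
    frame_rate: float | None = None,
    arena_id: str = "ymaze",
    max_gap_frames: int = 3,
    max_missing_fraction: float = 0.2,
) -> Trajectory:
    """Load a trajectory table (columns ``time,x,y`` or ``frame,x,y``).

    Gaps of at most ``max_gap_frames`` missing coordinates are linearly
    interpolated; longer gaps are left invalid and recorded in
    ``meta['missing_spans']``. Files with a non-monotone time column or more
    than ``max_missing_fraction`` missing frames are rejected.
    """
    df = pd.read_csv(path)
    if "time" in df.columns:
        t = df["time"].to_numpy(dtype=float)
        if frame_rate is None:
            dt = np.median(np.diff(t))
            frame_rate = 1.0 / dt
    elif "frame" in df.columns:
        if frame_rate is None:
            raise ValueError("frame-indexed trajectory requires frame_rate")
        t = df["frame"].to_numpy(dtype=float) / frame_rate
    else:
        raise ValueError("trajectory file needs a 'time' or 'frame' column")
    dt = np.diff(t)
    if np.any(dt <= 0):
        row = int(np.argmax(dt <= 0)) + 1
        raise ValueError(f"non-monotone time column at row {row}")
    x = df["x"].to_numpy(dtype=float)
    y = df["y"].to_numpy(dtype=float)

    missing = ~(np.isfinite(x) & np.isfinite(y))
    valid = ~missing
    spans = _missing_spans(missing)
    long_spans = []
    for a, b in spans:
        if b - a <= max_gap_frames and a > 0 and b < len(x):
            sl = slice(a, b)
            x[sl] = np.interp(t[sl], [t[a - 1], t[b]], [x[a - 1], x[b]])
            y[sl] = np.interp(t[sl], [t[a - 1], t[b]], [y[a - 1], y[b]])
            valid[sl] = True
        else:
            long_spans.append((int(a), int(b)))
    # reject on the unrecoverable fraction (short gaps interpolate away)
    if (~valid).mean() > max_missing_fraction:
        raise ValueError(
            f"{(~valid).mean():.0%} of frames missing coordinates "
            f"(limit {max_missing_fraction:.0%})"
        )
    return Trajectory(
        timestamps=t, x=x, y=y, frame_rate=float(frame_rate), arena_id=arena_id,
        valid=valid, meta={"missing_spans": long_spans, "source": str(path)},
    )


def _missing_spans(missing: np.ndarray) -> list[tuple[int, int]]:
    """Half-open [start, end) runs of True."""
    idx = np.flatnonzero(np.diff(np.r_[False, missing, False].astype(int)))
    return list(zip(idx[::2].tolist(), idx[1::2].tolist()))


def load_events(path) -> EventLog:
    df = pd.read_csv(path)
    return EventLog(events=df)


def load_traces(path) -> NeuralTraces:
    with h5py.File(path, "r") as fh:
        version = fh.attrs.get("format_version")
        if version != RESULTS_FORMAT_VERSION:
            raise ValueError(
                f"traces format version mismatch: file has {version!r}, "
                f"expected {RESULTS_FORMAT_VERSION}"
            )
        values = fh["/traces"][()]
        sample_rate = float(fh.attrs["sample_rate"])
        neuron_ids = fh["/neuron_ids"][()] if "neuron_ids" in fh else None
        centroids = fh["/centroids"][()] if "centroids" in fh else None
    return NeuralTraces(values=values, sample_rate=sample_rate,
                        neuron_ids=neuron_ids, centroids=centroids)


def save_traces(traces: NeuralTraces, path) -> None:
    with h5py.File(path, "w") as fh:
        fh.attrs["format_version"] = RESULTS_FORMAT_VERSION
        fh.attrs["sample_rate"] = traces.sample_rate
        fh.create_dataset("/traces", data=traces.values)
        fh.create_dataset("/time", data=traces.timestamps)
        ids = traces.neuron_ids
        if ids.dtype.kind in "US":
            ids = ids.astype(h5py.string_dtype())
        fh.create_dataset("/neuron_ids", data=ids)
        if traces.centroids is not None:
            fh.create_dataset("/centroids", data=traces.centroids)


# --------------------------------------------------------------------------
# alignment
# --------------------------------------------------------------------------
def snap_to_frame(times: np.ndarray, sample_rate: float, n_frames: int) -> np.ndarray:
    """Nearest neural frame for each time; exact ties go to the earlier frame."""
    pos = np.asarray(times, dtype=float) * sample_rate
    frac = pos - np.floor(pos)
    idx = np.where(frac > 0.5, np.ceil(pos), np.floor(pos)).astype(int)
    return np.clip(idx, 0, n_frames - 1)


def align_behavior_to_neural(
    traj: Trajectory,
    traces: NeuralTraces,
    events: EventLog | None = None,
    min_overlap: float = 0.95,
) -> AlignedSession:
    """Resample behavior onto the neural frame clock.

    Coordinates are linearly interpolated at the neural timestamps; events
    snap to the nearest neural frame (ties toward the earlier frame); neural
    frames outside the behavioral time support are flagged invalid. Aligning
    an already-aligned session is the identity.
    """
    nt = traces.timestamps
    t0, t1 = traj.timestamps[0], traj.timestamps[-1]
    covered = np.clip(min(t1, nt[-1]) - max(t0, nt[0]), 0.0, None)
    duration = nt[-1] - nt[0] if len(nt) > 1 else 1.0
    overlap = covered / duration if duration > 0 else 0.0
    if overlap < min_overlap:
        raise ValueError(
            f"behavioral/neural overlap {overlap:.1%} below required {min_overlap:.0%}"
        )
    ok = traj.valid
    xs = np.interp(nt, traj.timestamps[ok], traj.x[ok])
    ys = np.interp(nt, traj.timestamps[ok], traj.y[ok])
    valid = (nt >= t0 - 1e-9) & (nt <= t1 + 1e-9)
    aligned_traj = Trajectory(
        timestamps=nt, x=xs, y=ys, frame_rate=traces.sample_rate,
        arena_id=traj.arena_id, valid=valid, meta=dict(traj.meta),
    )
    if events is not None:
        ev = events.events.copy()
        ev["frame"] = snap_to_frame(ev["time"].to_numpy(), traces.sample_rate, traces.n_frames)
    else:
        ev = pd.DataFrame(columns=["time", "kind", "spout_id", "frame"])
    return AlignedSession(trajectory=aligned_traj, traces=traces, events=ev, valid=valid)


# --------------------------------------------------------------------------
# session directories
# --------------------------------------------------------------------------
def save_session(session_dir, traj: Trajectory, events: EventLog,
                 traces: NeuralTraces, geometry: MazeGeometry | None = None,
                 ground_truth: pd.DataFrame | None = None) -> None:
    d = Path(session_dir)
    d.mkdir(parents=True, exist_ok=True)
    pd.DataFrame({"time": traj.timestamps, "x": traj.x, "y": traj.y}).to_csv(
        d / "trajectory.csv", index=False)
    with open(d / "trajectory_meta.json", "w") as fh:
        json.dump({"frame_rate": traj.frame_rate, "arena_id": traj.arena_id},
                  fh)
    events.events.to_csv(d / "events.csv", index=False)
    save_traces(traces, d / "traces.h5")
    if geometry is not None:
        geometry.to_json(d / "geometry.json")
    if ground_truth is not None:
        ground_truth.to_csv(d / "ground_truth.csv", index=False)


def load_session(session_dir):
    d = Path(session_dir)
    with open(d / "trajectory_meta.json") as fh:
        meta = json.load(fh)
    traj = load_trajectory(d / "trajectory.csv", frame_rate=meta["frame_rate"],
                           arena_id=meta["arena_id"])
    events = load_events(d / "events.csv")
    traces = load_traces(d / "traces.h5")
    geometry = None
    if (d / "geometry.json").exists():
        geometry = MazeGeometry.from_json(d / "geometry.json")
    ground_truth = None
    if (d / "ground_truth.csv").exists():
        ground_truth = pd.read_csv(d / "ground_truth.csv")
    return traj, events, traces, geometry, ground_truth


# --------------------------------------------------------------------------
# result bundles
# --------------------------------------------------------------------------
def save_results(bundle, path) -> None:
    """Serialize a result bundle (dataclass or DataFrame) losslessly.

    DataFrames go to CSV with a JSON sidecar header; dataclasses go to JSON
    with numpy arrays converted to nested lists at full precision.
    """
    path = Path(path)
    if isinstance(bundle, pd.DataFrame):
        payload = {"format_version": RESULTS_FORMAT_VERSION, "type": "DataFrame"}
        with open(path.with_suffix(path.suffix + ".meta.json"), "w") as fh:
            json.dump(payload, fh)
        bundle.to_csv(path, index=False)
        return
    if dataclasses.is_dataclass(bundle):
        payload = {
            "format_version": RESULTS_FORMAT_VERSION,
            "type": type(bundle).__name__,
            "fields": _jsonify(dataclasses.asdict(bundle)),
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=1)
        return
    raise TypeError(f"cannot serialize result of type {type(bundle).__name__}")


def load_results(path, result_type=None):
    """Inverse of :func:`save_results`; returns a dict of fields (or DataFrame)."""
    path = Path(path)
    sidecar = path.with_suffix(path.suffix + ".meta.json")
    if sidecar.exists():
        with open(sidecar) as fh:
            payload = json.load(fh)
        _check_version(payload)
        return pd.read_csv(path)
    try:
        with open(path) as fh:
            payload = json.load(fh)
    except (json.JSONDecodeError, UnicodeDecodeError) as err:
        raise ValueError(f"corrupt results file {path}: {err}") from err
    if not isinstance(payload, dict) or "fields" not in payload:
        raise ValueError(f"corrupt results file {path}: missing fields")
    _check_version(payload)
    fields = payload["fields"]
    if result_type is not None:
        if payload["type"] != result_type.__name__:
            raise ValueError(
                f"expected {result_type.__name__}, file holds {payload['type']}")
        names = {f.name for f in dataclasses.fields(result_type)}
        return result_type(**{k: _unjsonify(v) for k, v in fields.items() if k in names})
    return fields


def _check_version(payload: dict) -> None:
    version = payload.get("format_version")
    if version != RESULTS_FORMAT_VERSION:
        raise ValueError(
            f"results format version mismatch: file has {version!r}, "
            f"expected {RESULTS_FORMAT_VERSION}"
        )


def _jsonify(obj):
    if isinstance(obj, dict):
        return {k: _jsonify(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonify(v) for v in obj]
    if isinstance(obj, np.ndarray):
        return {"__ndarray__": obj.tolist(), "dtype": str(obj.dtype)}
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, pd.DataFrame):
        return {"__dataframe__": obj.to_dict(orient="list")}
    return obj


def _unjsonify(obj):
    if isinstance(obj, dict):
        if "__ndarray__" in obj:
            return np.asarray(obj["__ndarray__"], dtype=obj["dtype"])
        if "__dataframe__" in obj:
            return pd.DataFrame(obj["__dataframe__"])
        return {k: _unjsonify(v) for k, v in obj.items()}
    if isinstance(obj, list):
        return [_unjsonify(v) for v in obj]
    return obj
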