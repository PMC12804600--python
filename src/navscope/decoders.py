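"""Population decoders of path and position.

Four models, all trained from dF/F population activity:

* a transformer encoder over PCA-reduced trial sequences whose [CLS] token
  classifies the traversal direction (arm1->arm2 vs arm2->arm1);
* a conv + bidirectional-LSTM classifier of the maze region at the end of
  non-overlapping 2-s windows (step twice the window length);
* a bidirectional-LSTM regressor of the future trajectory (15 input frames
  -> 5 future (x, y) frames);
* a 5-zone classifier over 10-frame windows (modal zone within the window).

Defaults follow the printed training schedules (transformer: AdamW 1e-4,
weight decay 1e-4, cosine annealing, 30 epochs, dropout 0.3, 8:2 split;
position classifier: Adam 1e-3, weight decay 1e-5, plateau halving,
50 epochs, batch 16, 70:30; regressor/zone models: 5e-4, batch 64, 80
epochs, 80:20). Architecture dims are configurable and serialized with
every report.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass

import numpy as np
from sklearn.base import BaseEstimator
from sklearn.decomposition import PCA
from sklearn.metrics import confusion_matrix, precision_recall_fscore_support
from sklearn.model_selection import train_test_split

from . import _nn as nn
from ._nn import Tensor, no_grad


# --------------------------------------------------------------------------
# reports
# --------------------------------------------------------------------------
@dataclass
class DecodingReport:
    """Accuracy / macro precision / recall / F1 and the confusion matrix."""

    accuracy: float
    precision: float
    recall: float
    f1: float
    confusion: np.ndarray
    classes: list
    per_class_counts: dict
    config_hash: str = ""
    n_eval: int = 0


@dataclass
class RegressionReport:
    rmse_x: float
    rmse_y: float
    rmse: float
    n_eval: int
    config_hash: str = ""
    baseline_rmse: float = np.nan  # predict-the-training-mean reference


def evaluate(y_true, y_pred, classes=None, config_hash: str = "") -> DecodingReport:
    """Macro-averaged classification metrics from the confusion matrix."""
    y_true = np.asarray(y_true)
    y_pred = np.asarray(y_pred)
    if len(y_true) == 0:
        raise ValueError("empty evaluation set")
    if classes is None:
        classes = sorted(np.unique(np.concatenate([y_true, y_pred])).tolist())
    cm = confusion_matrix(y_true, y_pred, labels=classes)
    acc = float(np.trace(cm) / cm.sum())
    p, r, f1, _ = precision_recall_fscore_support(
        y_true, y_pred, labels=classes, average="macro", zero_division=0)
    counts = {c: int(n) for c, n in zip(classes, cm.sum(axis=1))}
    return DecodingReport(accuracy=acc, precision=float(p), recall=float(r),
                          f1=float(f1), confusion=cm, classes=list(classes),
                          per_class_counts=counts, config_hash=config_hash,
                          n_eval=int(len(y_true)))


def _config_hash(params: dict) -> str:
    blob = json.dumps({k: repr(v) for k, v in sorted(params.items())})
    return hashlib.md5(blob.encode()).hexdigest()[:12]


# --------------------------------------------------------------------------
# PCA reduction + padding of trial sequences
# --------------------------------------------------------------------------
@dataclass
class TrialTensorSet:
    """Padded PCA-space trial sequences with an explicit padding mask."""

    X: np.ndarray  # (n_trials, max_len, n_components)
    pad_mask: np.ndarray  # (n_trials, max_len), True where padded
    lengths: np.ndarray  # true pre-padding lengths
    pca: PCA | None
    n_truncated: int = 0


def reduce_and_pad(
    trials: list,
    n_components: int = 256,
    max_len: int = 196,
    pca: PCA | None = None,
    fit_idx: np.ndarray | None = None,
) -> TrialTensorSet:
    """Project trial matrices (time x neurons) to PCA space, pad to max_len.

    The component basis is fit on the time-concatenated frames of the
    ``fit_idx`` trials only (all trials if None); pass a fitted ``pca`` to
    reuse a training-set basis. If fewer than ``n_components`` components
    exist, the missing ones are zero-filled; trials longer than ``max_len``
    are truncated head-preserving (count reported).
    """
    if len(trials) < 1:
        raise ValueError("need at least one trial")
    trials = [np.asarray(t, dtype=float) for t in trials]
    n_neurons = trials[0].shape[1]
    if pca is None:
        sel = range(len(trials)) if fit_idx is None else fit_idx
        stack = np.concatenate([trials[i] for i in sel], axis=0)
        n_eff = int(min(n_components, n_neurons, stack.shape[0]))
        pca = PCA(n_components=n_eff, svd_solver="full")
        pca.fit(stack)
    n_eff = pca.n_components_
    X = np.zeros((len(trials), max_len, n_components))
    mask = np.ones((len(trials), max_len), dtype=bool)
    lengths = np.empty(len(trials), dtype=int)
    n_trunc = 0
    for i, tr in enumerate(trials):
        proj = pca.transform(tr)
        if len(proj) > max_len:
            proj = proj[:max_len]  # head-preserving truncation
            n_trunc += 1
        L = len(proj)
        X[i, :L, :n_eff] = proj
        mask[i, :L] = False
        lengths[i] = L
    if n_trunc:
        import warnings
        warnings.warn(f"{n_trunc} trial(s) longer than {max_len} frames truncated")
    return TrialTensorSet(X=X, pad_mask=mask, lengths=lengths, pca=pca,
                          n_truncated=n_trunc)


# --------------------------------------------------------------------------
# window bookkeeping
# --------------------------------------------------------------------------
def window_count(n_frames: int, window: int, step: int) -> int:
    """Closed-form number of windows: floor((n - w)/step) + 1 (0 if n < w)."""
    if n_frames < window:
        return 0
    return (n_frames - window) // step + 1


def window_starts(n_frames: int, window: int, step: int) -> np.ndarray:
    return np.arange(window_count(n_frames, window, step)) * step


# --------------------------------------------------------------------------
# model bodies
# --------------------------------------------------------------------------
class _PathTransformer(nn.Module):
    def __init__(self, n_components, max_len, d_model, n_heads, n_layers,
                 d_ff, dropout, n_classes, rng):
        self.proj = nn.Linear(n_components, d_model, rng)
        self.cls = nn.Parameter(rng.normal(0.0, 0.02, size=(1, 1, d_model)))
        self.pos = nn.Parameter(rng.normal(0.0, 0.02, size=(max_len + 1, d_model)))
        self.layers = [nn.TransformerEncoderLayer(d_model, n_heads, d_ff, dropout, rng)
                       for _ in range(n_layers)]
        self.head1 = nn.Linear(d_model, d_model, rng)
        self.drop = nn.Dropout(dropout, rng)
        self.head2 = nn.Linear(d_model, n_classes, rng)

    def forward(self, X: np.ndarray, pad_mask: np.ndarray) -> Tensor:
        B, T, _ = X.shape
        h = self.proj(Tensor(X))
        cls = self.cls * np.ones((B, 1, 1))  # broadcast [CLS] over the batch
        h = nn.concatenate([cls, h], axis=1)
        h = h + self.pos[: T + 1]
        full_mask = np.concatenate(
            [np.zeros((B, 1), dtype=bool), pad_mask], axis=1)  # CLS never masked
        for layer in self.layers:
            h = layer(h, full_mask)
        z = h[:, 0, :]  # [CLS]
        z = self.drop(self.head1(z).relu())
        return self.head2(z)


class _WindowNet(nn.Module):
    """Linear embed + layer norm + temporal conv + biLSTM + linear head."""

    def __init__(self, n_inputs, d_embed, conv_channels, kernel, lstm_hidden,
                 n_out, rng, use_conv=True, readout="mean"):
        self.embed = nn.Linear(n_inputs, d_embed, rng)
        self.ln = nn.LayerNorm(d_embed)
        self.use_conv = use_conv
        if use_conv:
            self.conv = nn.Conv1d(d_embed, conv_channels, kernel, rng)
            lstm_in = conv_channels
        else:
            lstm_in = d_embed
        self.lstm = nn.BiLSTM(lstm_in, lstm_hidden, rng)
        self.head = nn.Linear(2 * lstm_hidden, n_out, rng)
        self.readout = readout

    def forward(self, X: np.ndarray) -> Tensor:
        h = self.ln(self.embed(Tensor(X)))
        if self.use_conv:
            h = self.conv(h).relu()
        h = self.lstm(h)
        if self.readout == "last":
            h = h[:, -1, :]
        else:
            h = h.mean(axis=1)
        return self.head(h)


def _minibatches(n: int, batch_size: int, rng: np.random.Generator):
    order = rng.permutation(n)
    for i in range(0, n, batch_size):
        yield order[i:i + batch_size]


# --------------------------------------------------------------------------
# estimators
# --------------------------------------------------------------------------
class PathTransformerClassifier(BaseEstimator):
    """Transformer [CLS] classifier of the traversal direction of a trial.

    ``fit`` takes a list of (time x neurons) trial matrices and one label per
    trial; PCA (top ``n_components``), padding to ``max_len`` tokens with an
    attention mask, and all normalization statistics are computed on the
    training split only.
    """

    def __init__(self, n_components=256, max_len=196, d_model=128, n_heads=4,
                 n_layers=2, d_ff=256, dropout=0.3, lr=1e-4, weight_decay=1e-4,
                 epochs=30, batch_size=16, val_fraction=0.2, random_state=0):
        self.n_components = n_components
        self.max_len = max_len
        self.d_model = d_model
        self.n_heads = n_heads
        self.n_layers = n_layers
        self.d_ff = d_ff
        self.dropout = dropout
        self.lr = lr
        self.weight_decay = weight_decay
        self.epochs = epochs
        self.batch_size = batch_size
        self.val_fraction = val_fraction
        self.random_state = random_state

    def fit(self, trials: list, labels):
        labels = np.asarray(labels)
        self.classes_ = np.unique(labels)
        if len(self.classes_) < 2:
            raise ValueError("need both path classes in the data")
        y = np.searchsorted(self.classes_, labels)
        idx = np.arange(len(trials))
        tr_idx, va_idx = train_test_split(
            idx, test_size=self.val_fraction, stratify=y,
            random_state=self.random_state)
        for split_name, split in (("training", tr_idx), ("validation", va_idx)):
            if len(np.unique(y[split])) < len(self.classes_):
                raise ValueError(f"a path class is missing from the {split_name} split")
        tset = reduce_and_pad([trials[i] for i in tr_idx], self.n_components,
                              self.max_len)
        self.pca_ = tset.pca
        rng = np.random.default_rng(self.random_state)
        model = _PathTransformer(self.n_components, self.max_len, self.d_model,
                                 self.n_heads, self.n_layers, self.d_ff,
                                 self.dropout, len(self.classes_), rng)
        opt = nn.AdamW(model.parameters(), lr=self.lr,
                       weight_decay=self.weight_decay)
        sched = nn.CosineAnnealingLR(opt, self.epochs)
        Xtr, mtr, ytr = tset.X, tset.pad_mask, y[tr_idx]
        model.train()
        for _ in range(self.epochs):
            for batch in _minibatches(len(Xtr), self.batch_size, rng):
                logits = model(Xtr[batch], mtr[batch])
                loss = nn.cross_entropy(logits, ytr[batch])
                opt.zero_grad()
                loss.backward()
                opt.step()
            sched.step()
        self.model_ = model
        self.train_idx_, self.val_idx_ = tr_idx, va_idx
        yhat = self.predict([trials[i] for i in va_idx])
        self.report_ = evaluate(labels[va_idx], yhat, classes=list(self.classes_),
                                config_hash=_config_hash(self.get_params()))
        return self

    def decision_scores(self, trials: list) -> np.ndarray:
        tset = reduce_and_pad(trials, self.n_components, self.max_len,
                              pca=self.pca_)
        self.model_.eval()
        with no_grad():
            logits = self.model_(tset.X, tset.pad_mask)
        return logits.data

    def predict(self, trials: list):
        return self.classes_[np.argmax(self.decision_scores(trials), axis=1)]


class _WindowEstimatorBase(BaseEstimator):
    """Shared window extraction / normalization / training machinery."""

    def _normalize(self, frames: np.ndarray, fit_frames: np.ndarray | None = None):
        if fit_frames is not None:
            self.norm_mu_ = fit_frames.mean(axis=0)
            sd = fit_frames.std(axis=0)
            self.norm_sd_ = np.where(sd > 0, sd, 1.0)
        return (frames - self.norm_mu_) / self.norm_sd_


class PositionWindowClassifier(_WindowEstimatorBase):
    """Conv + biLSTM classifier of the maze region at the end of 2-s windows.

    Windows are non-overlapping with a step of twice the window length;
    the frame-level label at each window's final frame is the target.
    """

    def __init__(self, window_s=2.0, sample_rate=10.0, step_factor=2,
                 d_embed=32, conv_channels=32, kernel=3, lstm_hidden=64,
                 lr=1e-3, weight_decay=1e-5, epochs=50, batch_size=16,
                 val_fraction=0.3, plateau_factor=0.5, patience=5,
                 min_classes=4, random_state=0):
        self.window_s = window_s
        self.sample_rate = sample_rate
        self.step_factor = step_factor
        self.d_embed = d_embed
        self.conv_channels = conv_channels
        self.kernel = kernel
        self.lstm_hidden = lstm_hidden
        self.lr = lr
        self.weight_decay = weight_decay
        self.epochs = epochs
        self.batch_size = batch_size
        self.val_fraction = val_fraction
        self.plateau_factor = plateau_factor
        self.patience = patience
        self.min_classes = min_classes
        self.random_state = random_state

    def _windows(self, n_frames):
        w = int(round(self.window_s * self.sample_rate))
        return w, window_starts(n_frames, w, self.step_factor * w)

    def fit(self, frames: np.ndarray, labels,
            exclude_frames: np.ndarray | None = None,
            split: tuple | None = None):
        """``frames`` is (n_frames, n_neurons); ``labels`` one region per frame.

        ``exclude_frames`` drops every window overlapping a flagged frame
        (from training and evaluation alike); ``split`` overrides the
        stratified split with explicit (train_starts, val_starts) window
        start-frame arrays.
        """
        frames = np.asarray(frames, dtype=float)
        labels = np.asarray(labels)
        w, starts = self._windows(len(frames))
        ends = starts + w
        ok = np.array([labels[e - 1] not in ("", "none") for e in ends])
        if exclude_frames is not None:
            drop = np.asarray(exclude_frames, dtype=bool)
            ok &= np.array([not drop[s:e].any() for s, e in zip(starts, ends)])
        starts, ends = starts[ok], ends[ok]
        if split is not None:
            tr_starts, va_starts = (np.asarray(s, dtype=int) for s in split)
            starts = np.concatenate([tr_starts, va_starts])
            ends = starts + w
        ywin = labels[ends - 1]
        self.classes_ = np.unique(ywin)
        if len(self.classes_) < self.min_classes:
            raise ValueError(
                f"only classes {sorted(self.classes_)} present; "
                f"need >= {self.min_classes}")
        y = np.searchsorted(self.classes_, ywin)
        idx = np.arange(len(starts))
        if split is not None:
            tr_idx = idx[: len(split[0])]
            va_idx = idx[len(split[0]):]
        else:
            tr_idx, va_idx = train_test_split(
                idx, test_size=self.val_fraction, stratify=y,
                random_state=self.random_state)
        train_frame_sel = np.concatenate(
            [np.arange(starts[i], ends[i]) for i in tr_idx])
        self._normalize(frames[:1], fit_frames=frames[train_frame_sel])
        X = np.stack([self._normalize(frames[s:e]) for s, e in zip(starts, ends)])
        rng = np.random.default_rng(self.random_state)
        model = _WindowNet(frames.shape[1], self.d_embed, self.conv_channels,
                           self.kernel, self.lstm_hidden, len(self.classes_), rng,
                           readout="last")  # label is the region at window end
        opt = nn.Adam(model.parameters(), lr=self.lr,
                      weight_decay=self.weight_decay)
        sched = nn.ReduceLROnPlateau(opt, factor=self.plateau_factor,
                                     patience=self.patience)
        Xtr, ytr = X[tr_idx], y[tr_idx]
        Xva, yva = X[va_idx], y[va_idx]
        for _ in range(self.epochs):
            model.train()
            for batch in _minibatches(len(Xtr), self.batch_size, rng):
                loss = nn.cross_entropy(model(Xtr[batch]), ytr[batch])
                opt.zero_grad()
                loss.backward()
                opt.step()
            model.eval()
            with no_grad():
                val_loss = nn.cross_entropy(model(Xva), yva).data.item()
            sched.step(val_loss)
        self.model_ = model
        model.eval()
        with no_grad():
            yhat = self.classes_[np.argmax(model(Xva).data, axis=1)]
        self.report_ = evaluate(ywin[va_idx], yhat, classes=list(self.classes_),
                                config_hash=_config_hash(self.get_params()))
        self.window_ = w
        self.n_windows_ = len(starts)
        self.val_starts_ = starts[va_idx]
        self.val_labels_ = ywin[va_idx]
        return self

    def predict(self, windows: np.ndarray):
        X = np.stack([self._normalize(win) for win in windows])
        self.model_.eval()
        with no_grad():
            return self.classes_[np.argmax(self.model_(X).data, axis=1)]


class FutureTrajectoryRegressor(_WindowEstimatorBase):
    """biLSTM regression of the future trajectory from recent activity.

    Inputs are ``input_len`` frames of population activity; targets are the
    (x, y) coordinates of the following ``horizon`` frames. Loss is mean
    squared error; the report carries per-axis RMSE on the held-out split
    and the predict-the-training-mean baseline RMSE.
    """

    def __init__(self, input_len=15, horizon=5, stride=5, d_embed=32,
                 lstm_hidden=64, lr=5e-4, epochs=80, batch_size=64,
                 test_fraction=0.2, random_state=0):
        self.input_len = input_len
        self.horizon = horizon
        self.stride = stride
        self.d_embed = d_embed
        self.lstm_hidden = lstm_hidden
        self.lr = lr
        self.epochs = epochs
        self.batch_size = batch_size
        self.test_fraction = test_fraction
        self.random_state = random_state

    def fit(self, frames: np.ndarray, xy: np.ndarray):
        frames = np.asarray(frames, dtype=float)
        xy = np.asarray(xy, dtype=float)
        total = self.input_len + self.horizon
        starts = window_starts(len(frames), total, self.stride)
        if len(starts) < 5:
            raise ValueError("session too short for any training window")
        X = np.stack([frames[s:s + self.input_len] for s in starts])
        Y = np.stack([xy[s + self.input_len:s + total] for s in starts])
        idx = np.arange(len(starts))
        tr_idx, te_idx = train_test_split(idx, test_size=self.test_fraction,
                                          random_state=self.random_state)
        flat = X[tr_idx].reshape(-1, frames.shape[1])
        self._normalize(frames[:1], fit_frames=flat)
        Xn = (X - self.norm_mu_) / self.norm_sd_
        # targets are z-scored with training statistics and un-scaled at
        # predict time (RMSE is invariant under the round trip)
        self.y_mu_ = Y[tr_idx].mean(axis=(0, 1))
        y_sd = Y[tr_idx].std(axis=(0, 1))
        self.y_sd_ = np.where(y_sd > 0, y_sd, 1.0)
        Yn = (Y - self.y_mu_) / self.y_sd_
        rng = np.random.default_rng(self.random_state)
        model = _WindowNet(frames.shape[1], self.d_embed, 0, 1,
                           self.lstm_hidden, 2 * self.horizon, rng,
                           use_conv=False)
        opt = nn.Adam(model.parameters(), lr=self.lr)
        Ytr = Yn[tr_idx].reshape(len(tr_idx), -1)
        for _ in range(self.epochs):
            model.train()
            for batch in _minibatches(len(tr_idx), self.batch_size, rng):
                pred = model(Xn[tr_idx][batch])
                loss = nn.mse_loss(pred, Ytr[batch])
                opt.zero_grad()
                loss.backward()
                opt.step()
        self.model_ = model
        model.eval()
        with no_grad():
            pred = model(Xn[te_idx]).data.reshape(len(te_idx), self.horizon, 2)
        pred = pred * self.y_sd_ + self.y_mu_
        true = Y[te_idx]
        err = pred - true
        rmse_x = float(np.sqrt(np.mean(err[..., 0] ** 2)))
        rmse_y = float(np.sqrt(np.mean(err[..., 1] ** 2)))
        mean_traj = Y[tr_idx].mean(axis=0)
        base = float(np.sqrt(np.mean((true - mean_traj) ** 2)))
        self.report_ = RegressionReport(
            rmse_x=rmse_x, rmse_y=rmse_y,
            rmse=float(np.sqrt(np.mean(err**2))), n_eval=len(te_idx),
            config_hash=_config_hash(self.get_params()), baseline_rmse=base)
        return self

    def predict(self, windows: np.ndarray) -> np.ndarray:
        Xn = (np.asarray(windows, float) - self.norm_mu_) / self.norm_sd_
        self.model_.eval()
        with no_grad():
            out = self.model_(Xn).data
        return out.reshape(len(Xn), self.horizon, 2) * self.y_sd_ + self.y_mu_


class MazeZoneClassifier(_WindowEstimatorBase):
    """5-zone classifier over 10-frame windows (modal zone within the window)."""

    def __init__(self, window=10, stride=10, d_embed=32, conv_channels=32,
                 kernel=3, lstm_hidden=64, lr=5e-4, epochs=80, batch_size=64,
                 test_fraction=0.2, expected_zones=None, random_state=0):
        self.window = window
        self.stride = stride
        self.d_embed = d_embed
        self.conv_channels = conv_channels
        self.kernel = kernel
        self.lstm_hidden = lstm_hidden
        self.lr = lr
        self.epochs = epochs
        self.batch_size = batch_size
        self.test_fraction = test_fraction
        self.expected_zones = expected_zones
        self.random_state = random_state

    @staticmethod
    def modal_label(window_labels: np.ndarray) -> str:
        vals, counts = np.unique(window_labels, return_counts=True)
        return vals[np.argmax(counts)]  # ties: lexicographically first

    def fit(self, frames: np.ndarray, zones):
        frames = np.asarray(frames, dtype=float)
        zones = np.asarray(zones)
        starts = window_starts(len(frames), self.window, self.stride)
        labels = np.array([self.modal_label(zones[s:s + self.window]) for s in starts])
        keep = ~np.isin(labels, ("", "none"))
        starts, labels = starts[keep], labels[keep]
        self.classes_ = np.unique(labels)
        if self.expected_zones is not None:
            missing = sorted(set(self.expected_zones) - set(self.classes_))
            if missing:
                raise ValueError(f"zones missing from data: {missing}")
        y = np.searchsorted(self.classes_, labels)
        idx = np.arange(len(starts))
        tr_idx, te_idx = train_test_split(idx, test_size=self.test_fraction,
                                          stratify=y, random_state=self.random_state)
        sel = np.concatenate([np.arange(s, s + self.window) for s in starts[tr_idx]])
        self._normalize(frames[:1], fit_frames=frames[sel])
        X = np.stack([self._normalize(frames[s:s + self.window]) for s in starts])
        rng = np.random.default_rng(self.random_state)
        model = _WindowNet(frames.shape[1], self.d_embed, self.conv_channels,
                           self.kernel, self.lstm_hidden, len(self.classes_), rng)
        opt = nn.Adam(model.parameters(), lr=self.lr)
        for _ in range(self.epochs):
            model.train()
            for batch in _minibatches(len(tr_idx), self.batch_size, rng):
                loss = nn.cross_entropy(model(X[tr_idx][batch]), y[tr_idx][batch])
                opt.zero_grad()
                loss.backward()
                opt.step()
        self.model_ = model
        model.eval()
        with no_grad():
            yhat = self.classes_[np.argmax(model(X[te_idx]).data, axis=1)]
        self.report_ = evaluate(labels[te_idx], yhat, classes=list(self.classes_),
                                config_hash=_config_hash(self.get_params()))
        return self

    def predict(self, windows: np.ndarray):
        X = np.stack([self._normalize(win) for win in windows])
        self.model_.eval()
        with no_grad():
            return self.classes_[np.argmax(self.model_(X).data, axis=1)]
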