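"""Wide-and-deep trajectory classifiers and their training schedule.

The flagship architecture (DW-TSF-CNN) joins three branches into a two-way
softmax head:

* a *time-series-forest* branch: mean, standard deviation and least-squares
  slope over randomized intervals of each trajectory channel, passed through
  a dense layer;
* a 1-D convolutional branch over the per-year trajectory channels;
* a *wide* branch: a purely linear model on the scalar features
  (demographics and diagnosis-code indicators).

Comparison models share the training machinery: TSF-CNN (BMI trajectory
only), a most-recent-BMI logistic regression (a single-predictor network,
which reduces to logistic regression), a random forest on flattened inputs,
a convolutional-recurrent network (CRNN) and a small Transformer encoder,
the latter two with residual connections, layer normalization and dropout
on each sublayer.

Training uses Adam with categorical cross-entropy, initial learning rate
0.001 and batch size 32; the learning rate is multiplied by 0.92 whenever
the training loss fails to improve for 3 consecutive epochs, and training
stops early after 15 epochs without improvement in the monitored loss
(an internal stratified validation split when the class counts allow one,
otherwise the training loss).
"""

from __future__ import annotations

import dataclasses
import math

import numpy as np
from sklearn.ensemble import RandomForestClassifier

from .cohorts import CohortDataset
from .nn import Adam, Conv1D, Dense, Dropout, GRU, LayerNorm, Module, MultiHeadSelfAttention, Tensor, concat, softmax_cross_entropy
from .trajectories import NormParams, zscore_apply, zscore_fit

__all__ = [
    "ModelConfig",
    "TrainedModel",
    "MODEL_KINDS",
    "tsf_interval_features",
    "random_intervals",
    "build_model",
    "train",
    "predict_proba",
    "hyperparameter_search",
    "DEFAULT_SEARCH_SPACE",
]

MODEL_KINDS = (
    "dw_tsf_cnn",
    "tsf_cnn",
    "recent_bmi_logistic",
    "random_forest",
    "crnn",
    "transformer",
)


@dataclasses.dataclass
class ModelConfig:
    kind: str = "dw_tsf_cnn"
    learning_rate: float = 0.001
    batch_size: int = 32
    max_epochs: int = 500
    lr_decay: float = 0.92
    lr_patience: int = 3
    early_stop_patience: int = 15
    seed: int = 0
    # architecture parameters
    n_filters: int = 8
    kernel_size: int = 3
    n_intervals: int | None = None  # default: ceil(sqrt(T)) * 3
    hidden: int = 16
    n_heads: int = 2
    head_size: int = 8
    ff_size: int = 32
    dropout: float = 0.1
    n_estimators: int = 200  # random forest
    val_frac: float = 0.15  # internal early-stopping split

    def __post_init__(self) -> None:
        if self.kind not in MODEL_KINDS:
            raise ValueError(f"unknown model kind {self.kind!r}; choose from {MODEL_KINDS}")
        if not 0.0 < self.lr_decay < 1.0:
            raise ValueError("lr_decay must lie in (0, 1)")
        if self.lr_patience < 1 or self.early_stop_patience < 1:
            raise ValueError("patiences must be >= 1")


# --------------------------------------------------------------------------
# time-series-forest interval features
# --------------------------------------------------------------------------

def tsf_interval_features(series: np.ndarray, intervals: list[tuple[int, int]]) -> np.ndarray:
    """Per-interval (mean, population SD, least-squares slope) of a series.

    ``series`` may be (T,) or batched (B, T); intervals are half-open index
    ranges.  Length-1 intervals have SD and slope 0 by convention.
    """
    x = np.atleast_2d(np.asarray(series, dtype=float))
    T = x.shape[1]
    feats = []
    for a, b in intervals:
        if not (0 <= a < b <= T):
            raise IndexError(f"interval [{a}, {b}) outside series of length {T}")
        seg = x[:, a:b]
        mean = seg.mean(axis=1)
        sd = seg.std(axis=1)  # population SD
        L = b - a
        if L == 1:
            slope = np.zeros_like(mean)
        else:
            t = np.arange(L) - (L - 1) / 2.0
            slope = (seg * t).sum(axis=1) / (t * t).sum()
        feats.extend([mean, sd, slope])
    out = np.column_stack(feats) if feats else np.zeros((x.shape[0], 0))
    return out[0] if np.asarray(series).ndim == 1 else out


def random_intervals(window_length: int, n_intervals: int, seed: int) -> list[tuple[int, int]]:
    """Randomized intervals in the time-series-forest style, reproducible
    from the seed.  Minimum length 1; each interval lies within the window."""
    rng = np.random.default_rng(seed)
    out = []
    for _ in range(n_intervals):
        a = int(rng.integers(0, window_length))
        length = int(rng.integers(1, window_length - a + 1))
        out.append((a, a + length))
    return out


# --------------------------------------------------------------------------
# architectures
# --------------------------------------------------------------------------

class _DeepWideNet(Module):
    """DW-TSF-CNN; with ``use_wide=False`` it degrades to TSF-CNN."""

    def __init__(self, cfg: ModelConfig, window_length: int, n_channels: int, n_wide: int,
                 n_tsf: int, rng: np.random.Generator, use_wide: bool):
        self.use_wide = use_wide
        k = min(cfg.kernel_size, window_length)
        self.conv = Conv1D(n_channels, cfg.n_filters, k, rng)
        self.tsf_dense = Dense(n_tsf, cfg.hidden, rng)
        self.merge = Dense(cfg.n_filters + cfg.hidden, cfg.hidden, rng)
        self.dropout = Dropout(cfg.dropout, rng)
        head_in = cfg.hidden + (cfg.hidden if use_wide else 0)
        self.wide = Dense(n_wide, cfg.hidden, rng) if use_wide else None
        self.head = Dense(head_in, 2, rng)

    def __call__(self, traj: Tensor, wide: Tensor, tsf: Tensor, training: bool) -> Tensor:
        conv_out = self.conv(traj).relu().mean(axis=1)  # (B, F)
        tsf_out = self.tsf_dense(tsf).relu()
        deep = self.merge(self.dropout(concat([conv_out, tsf_out]), training)).relu()
        if self.use_wide:
            return self.head(concat([deep, self.wide(wide)]))  # wide branch stays linear
        return self.head(deep)


class _LogisticNet(Module):
    """Single linear layer to a 2-way softmax (logistic regression)."""

    def __init__(self, n_in: int, rng: np.random.Generator):
        self.head = Dense(n_in, 2, rng)

    def __call__(self, x: Tensor) -> Tensor:
        return self.head(x)


class _CRNNNet(Module):
    def __init__(self, cfg: ModelConfig, window_length: int, n_channels: int, n_wide: int,
                 rng: np.random.Generator):
        k = min(cfg.kernel_size, window_length)
        self.conv = Conv1D(n_channels, cfg.n_filters, k, rng)
        self.gru = GRU(cfg.n_filters, cfg.hidden, rng)
        self.norm = LayerNorm(cfg.hidden)
        self.dropout = Dropout(cfg.dropout, rng)
        self.head = Dense(cfg.hidden + n_wide, 2, rng)

    def __call__(self, traj: Tensor, wide: Tensor, training: bool) -> Tensor:
        h = self.gru(self.conv(traj).relu())
        h = self.dropout(self.norm(h), training)
        return self.head(concat([h, wide]))


class _TransformerNet(Module):
    """One encoder block: self-attention and feed-forward sublayers, each with
    a residual connection, layer normalization and dropout."""

    def __init__(self, cfg: ModelConfig, window_length: int, n_channels: int, n_wide: int,
                 rng: np.random.Generator):
        dm = cfg.n_heads * cfg.head_size
        self.proj = Dense(n_channels, dm, rng)
        pos = np.zeros((window_length, dm))
        t = np.arange(window_length)[:, None]
        div = np.exp(np.arange(0, dm, 2) * (-math.log(10000.0) / dm))
        pos[:, 0::2] = np.sin(t * div)
        pos[:, 1::2] = np.cos(t * div[: pos[:, 1::2].shape[1]])
        self.pos = Tensor(pos)
        self.att = MultiHeadSelfAttention(dm, cfg.n_heads, cfg.head_size, rng)
        self.norm1 = LayerNorm(dm)
        self.norm2 = LayerNorm(dm)
        self.ff1 = Dense(dm, cfg.ff_size, rng)
        self.ff2 = Dense(cfg.ff_size, dm, rng)
        self.drop1 = Dropout(cfg.dropout, rng)
        self.drop2 = Dropout(cfg.dropout, rng)
        self.head = Dense(dm + n_wide, 2, rng)

    def __call__(self, traj: Tensor, wide: Tensor, training: bool) -> Tensor:
        x = self.proj(traj) + self.pos
        x = self.norm1(x + self.drop1(self.att(x), training))
        x = self.norm2(x + self.drop2(self.ff2(self.ff1(x).relu()), training))
        return self.head(concat([x.mean(axis=1), wide]))


# --------------------------------------------------------------------------
# build / train / predict
# --------------------------------------------------------------------------

@dataclasses.dataclass
class UntrainedModel:
    kind: str
    config: ModelConfig
    net: Module | RandomForestClassifier | None
    intervals: list[tuple[int, int]]
    window_length: int
    n_channels: int
    n_wide: int


@dataclasses.dataclass
class TrainedModel:
    """A fitted classifier plus everything needed to score new patients."""

    kind: str
    config: ModelConfig
    net: Module | RandomForestClassifier
    intervals: list[tuple[int, int]]
    traj_norm: NormParams
    wide_norm: NormParams
    feature_names: list[str]
    history: dict[str, list]
    window_length: int = 0
    n_channels: int = 2


def _n_tsf(cfg: ModelConfig, window_length: int, n_channels: int) -> tuple[int, int]:
    n_int = cfg.n_intervals or int(math.ceil(math.sqrt(window_length)) * 3)
    return n_int, n_int * 3 * n_channels


def build_model(cfg: ModelConfig, window_length: int, n_channels: int, n_wide: int) -> UntrainedModel:
    """Instantiate an untrained model; same config and seed give identical
    initial parameters."""
    if window_length < 1 or n_channels < 1 or n_wide < 0:
        raise ValueError("dimensions must be positive")
    rng = np.random.default_rng(cfg.seed)
    n_int, n_tsf = _n_tsf(cfg, window_length, n_channels)
    intervals = random_intervals(window_length, n_int, cfg.seed)
    if cfg.kind == "dw_tsf_cnn":
        net = _DeepWideNet(cfg, window_length, n_channels, n_wide, n_tsf, rng, use_wide=True)
    elif cfg.kind == "tsf_cnn":
        n_int_b, n_tsf_b = _n_tsf(cfg, window_length, 1)
        intervals = random_intervals(window_length, n_int_b, cfg.seed)
        net = _DeepWideNet(cfg, window_length, 1, 0, n_tsf_b, rng, use_wide=False)
    elif cfg.kind == "recent_bmi_logistic":
        net = _LogisticNet(1, rng)
    elif cfg.kind == "crnn":
        net = _CRNNNet(cfg, window_length, n_channels, n_wide, rng)
    elif cfg.kind == "transformer":
        net = _TransformerNet(cfg, window_length, n_channels, n_wide, rng)
    elif cfg.kind == "random_forest":
        net = RandomForestClassifier(n_estimators=cfg.n_estimators, random_state=cfg.seed)
    else:  # pragma: no cover - guarded by ModelConfig
        raise ValueError(cfg.kind)
    return UntrainedModel(cfg.kind, cfg, net, intervals, window_length, n_channels, n_wide)


def _model_inputs(model, traj_z: np.ndarray, wide_z: np.ndarray):
    """Arrange normalized arrays into the inputs each architecture consumes."""
    kind = model.kind
    if kind == "tsf_cnn":
        traj_z = traj_z[:, :, :1]  # BMI channel only
    if kind == "recent_bmi_logistic":
        return (traj_z[:, -1, 0:1],)  # most recent (final-year) BMI
    if kind == "random_forest":
        return (np.hstack([traj_z.reshape(len(traj_z), -1), wide_z]),)
    tsf = None
    if kind in ("dw_tsf_cnn", "tsf_cnn"):
        tsf = np.hstack(
            [tsf_interval_features(traj_z[:, :, c], model.intervals) for c in range(traj_z.shape[2])]
        )
    return traj_z, wide_z, tsf


def _forward(model, inputs, training: bool) -> Tensor:
    kind = model.kind
    if kind == "recent_bmi_logistic":
        return model.net(Tensor(inputs[0]))
    if kind in ("dw_tsf_cnn", "tsf_cnn"):
        traj_z, wide_z, tsf = inputs
        return model.net(Tensor(traj_z), Tensor(wide_z), Tensor(tsf), training)
    traj_z, wide_z, _ = inputs
    return model.net(Tensor(traj_z), Tensor(wide_z), training)


def _subset(inputs, idx):
    return tuple(x[idx] if x is not None else None for x in inputs)


def train(model: UntrainedModel, dataset: CohortDataset, cfg: ModelConfig | None = None) -> TrainedModel:
    """Fit on a training cohort.  Z-score normalization parameters are
    estimated here, on this data only, and travel with the model."""
    cfg = cfg or model.config
    y = np.asarray(dataset.labels, dtype=int)
    if len(np.unique(y)) < 2:
        raise ValueError("training requires both classes present")

    traj = dataset.trajectory_tensor
    n, T, C = traj.shape
    traj_norm = zscore_fit(traj.reshape(n, T * C))
    wide_norm = zscore_fit(dataset.wide_matrix)
    traj_z = zscore_apply(traj.reshape(n, T * C), traj_norm).reshape(n, T, C)
    wide_z = zscore_apply(dataset.wide_matrix, wide_norm)

    history: dict[str, list] = {"epoch": [], "train_loss": [], "val_loss": [], "lr": []}

    if model.kind == "random_forest":
        X = np.hstack([traj_z.reshape(n, -1), wide_z])
        model.net.fit(X, y)
        return TrainedModel(model.kind, cfg, model.net, model.intervals, traj_norm,
                            wide_norm, list(dataset.feature_names), history, T, C)

    inputs = _model_inputs(model, traj_z, wide_z)
    onehot = np.eye(2)[y]

    # internal stratified validation split for early stopping, when feasible
    rng = np.random.default_rng(cfg.seed + 10_007)
    val_idx = np.array([], dtype=int)
    if cfg.val_frac > 0:
        vi = []
        for cls in (0, 1):
            idx = np.flatnonzero(y == cls)
            n_val = int(round(cfg.val_frac * len(idx)))
            if 0 < n_val < len(idx):
                rng.shuffle(idx)
                vi.append(idx[:n_val])
        if len(vi) == 2:
            val_idx = np.concatenate(vi)
    tr_idx = np.setdiff1d(np.arange(n), val_idx)
    tr_inputs, tr_onehot = _subset(inputs, tr_idx), onehot[tr_idx]
    va_inputs, va_onehot = (_subset(inputs, val_idx), onehot[val_idx]) if len(val_idx) else (None, None)

    params = model.net.parameters()
    opt = Adam(params, lr=cfg.learning_rate)
    batch_rng = np.random.default_rng(cfg.seed + 20_011)

    best_train, train_stall = np.inf, 0
    best_monitor, monitor_stall = np.inf, 0
    best_state = model.net.state()
    n_tr = len(tr_idx)
    for epoch in range(cfg.max_epochs):
        order = batch_rng.permutation(n_tr)
        for start in range(0, n_tr, cfg.batch_size):
            b = order[start : start + cfg.batch_size]
            opt.zero_grad()
            loss = softmax_cross_entropy(_forward(model, _subset(tr_inputs, b), True), tr_onehot[b])
            loss.backward()
            opt.step()

        train_loss = float(softmax_cross_entropy(_forward(model, tr_inputs, False), tr_onehot).data)
        if va_inputs is not None:
            monitor = float(softmax_cross_entropy(_forward(model, va_inputs, False), va_onehot).data)
        else:
            monitor = train_loss
        history["epoch"].append(epoch)
        history["train_loss"].append(train_loss)
        history["val_loss"].append(monitor if va_inputs is not None else float("nan"))
        history["lr"].append(opt.lr)

        # learning-rate decay on stalled training loss
        if train_loss < best_train - 1e-9:
            best_train, train_stall = train_loss, 0
        else:
            train_stall += 1
            if train_stall >= cfg.lr_patience:
                opt.lr *= cfg.lr_decay
                train_stall = 0
        # early stopping on the monitored loss
        if monitor < best_monitor - 1e-9:
            best_monitor, monitor_stall = monitor, 0
            best_state = model.net.state()
        else:
            monitor_stall += 1
            if monitor_stall >= cfg.early_stop_patience:
                break
    model.net.load_state(best_state)
    return TrainedModel(model.kind, cfg, model.net, model.intervals, traj_norm,
                        wide_norm, list(dataset.feature_names), history, T, C)


def predict_proba(model: TrainedModel, trajectory_tensor: np.ndarray, wide_matrix: np.ndarray) -> np.ndarray:
    """Case probability per patient; deterministic (dropout disabled)."""
    traj = np.asarray(trajectory_tensor, dtype=float)
    if traj.ndim != 3 or traj.shape[1] != model.window_length or traj.shape[2] != model.n_channels:
        raise ValueError(
            f"trajectory tensor shape {traj.shape} does not match training "
            f"(n, {model.window_length}, {model.n_channels})"
        )
    n, T, C = traj.shape
    traj_z = zscore_apply(traj.reshape(n, T * C), model.traj_norm).reshape(n, T, C)
    wide_z = zscore_apply(wide_matrix, model.wide_norm)
    if model.kind == "random_forest":
        X = np.hstack([traj_z.reshape(n, -1), wide_z])
        return model.net.predict_proba(X)[:, 1]
    logits = _forward(model, _model_inputs(model, traj_z, wide_z), False)
    z = logits.data - logits.data.max(axis=1, keepdims=True)
    ez = np.exp(z)
    return (ez / ez.sum(axis=1, keepdims=True))[:, 1]


def fit_classifier(dataset: CohortDataset, cfg: ModelConfig) -> TrainedModel:
    """Convenience: build + train in one call."""
    model = build_model(cfg, dataset.window.length, dataset.trajectory_tensor.shape[2],
                        dataset.wide_matrix.shape[1])
    return train(model, dataset, cfg)


# --------------------------------------------------------------------------
# hyperparameter search
# --------------------------------------------------------------------------

DEFAULT_SEARCH_SPACE: dict[str, list] = {
    "n_filters": [4, 8],
    "hidden": [8, 16],
    "dropout": [0.0, 0.1],
    "n_heads": [1, 2],
    "head_size": [4, 8],
    "ff_size": [16, 32],
}


def hyperparameter_search(
    dataset: CohortDataset,
    train_ids: np.ndarray,
    base_config: ModelConfig,
    space: dict[str, list] | None = None,
    budget: int = 3,
    tuning_frac: float = 0.2,
    seed: int = 0,
) -> ModelConfig:
    """Random search: sample ``budget`` configs, train each on the training
    ids minus a stratified 20% tuning split, return the config with the best
    tuning AUC.  Test rows are never touched."""
    from .evaluation import roc_auc  # local import to avoid a cycle

    if budget < 1:
        raise ValueError("search budget must be >= 1")
    space = space or DEFAULT_SEARCH_SPACE
    train_ids = np.asarray(train_ids)
    y_train = dataset.labels[train_ids]
    rng = np.random.default_rng(seed)

    # stratified tuning split carved from the training ids only
    tune_local = []
    for cls in np.unique(y_train):
        idx = np.flatnonzero(y_train == cls)
        n_t = max(1, int(round(tuning_frac * len(idx)))) if len(idx) > 1 else 0
        rng.shuffle(idx)
        tune_local.append(idx[:n_t])
    tune_local = np.concatenate(tune_local) if tune_local else np.array([], dtype=int)
    fit_local = np.setdiff1d(np.arange(len(train_ids)), tune_local)
    tune_ids, fit_ids = train_ids[tune_local], train_ids[fit_local]

    best_cfg, best_auc = None, -np.inf
    for trial in range(budget):
        fields = {k: space[k][int(rng.integers(len(space[k])))] for k in space}
        cfg = dataclasses.replace(base_config, **{k: v for k, v in fields.items()
                                                  if hasattr(base_config, k)})
        if len(np.unique(dataset.labels[fit_ids])) < 2 or len(np.unique(dataset.labels[tune_ids])) < 2:
            return base_config  # too small to tune; keep defaults
        fitted = train(build_model(cfg, dataset.window.length,
                                   dataset.trajectory_tensor.shape[2],
                                   dataset.wide_matrix.shape[1]),
                       _rows(dataset, fit_ids), cfg)
        scores = predict_proba(fitted, dataset.trajectory_tensor[tune_ids],
                               dataset.wide_matrix[tune_ids])
        auc = roc_auc(scores, dataset.labels[tune_ids])
        if auc > best_auc:
            best_auc, best_cfg = auc, cfg
    return best_cfg


def _rows(dataset: CohortDataset, idx: np.ndarray) -> CohortDataset:
    return dataclasses.replace(
        dataset,
        trajectory_tensor=dataset.trajectory_tensor[idx],
        wide_matrix=dataset.wide_matrix[idx],
        labels=dataset.labels[idx],
        patient_ids=[dataset.patient_ids[i] for i in idx],
    )
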