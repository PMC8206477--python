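"""SE-attention 3-D VGG classifier.

The full-width architecture is a 3-D VGG with conv widths
32,32 | 64,64 | 128x3 | 256x3 | 256x3, four 2x2x2 max-pools, batch-norm +
LeakyReLU pre-activations, three squeeze-and-excitation blocks (after the
first convolution at width 32, after the first pool at width 32, and after
the second pool at width 64), and a wide head: dropout + a valid
convolution with 2048 filters that consumes the remaining spatial extent
(3x3x3 for a 48x56x48 input), dropout + a 1x1x1 convolution with 1024
filters, then a dense layer to 2 logits.  He initialization throughout.

Three variants share this skeleton: ``baseline`` (no SE blocks), ``scse``
(single network channel, with SE), and ``mcse`` (all network channels, with
SE).  Training is Adam on cross-entropy with L2 decay on convolution
kernels, learning-rate decay on a validation-loss plateau, and early
stopping; evaluation is stratified k-fold cross-validation.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .io_core import (
    ArchitectureError, InputError, ParameterError, TrainingError,
)
from .nn import (
    Adam, BatchNorm3d, Conv3d, Dense, Dropout, Flatten, LeakyReLU, MaxPool3d,
    Network, SEBlock, cross_entropy_with_logits, softmax,
)

__all__ = [
    "ArchitectureSpec", "TrainConfig", "ConfusionCounts", "FoldResult",
    "build_model", "spatial_trace", "stratified_kfold", "train_fold",
    "compute_metrics", "run_cross_validation",
]

# (width, n_convs) per stage of the full-width backbone; a pool follows
# every stage except the last, whose output feeds the head directly.
_STAGES = [(32, 2), (64, 2), (128, 3), (256, 3), (256, 3)]
_HEAD_WIDTHS = (2048, 1024)
# SE insertion points: (stage index, conv index within stage) *after* which
# the block sits; the third block sits after the second pool.
_SE_AFTER_CONV = {(0, 0)}        # after the very first convolution
_SE_AFTER_POOL = {0, 1}          # after pools closing stages 0 and 1


@dataclass
class ArchitectureSpec:
    """Everything needed to build one classifier variant."""

    in_channels: int = 8
    n_classes: int = 2
    width_multiplier: float = 1.0
    with_se: bool = True
    se_reduction: int = 16
    leaky_slope: float = 0.01
    dropout: float = 0.7
    dtype: type = np.float32

    def width(self, base: int) -> int:
        return max(1, int(round(base * self.width_multiplier)))


@dataclass
class TrainConfig:
    """Published training recipe; epochs/stopping are configurable."""

    lr: float = 5e-4
    lr_decay_factor: float = 0.1
    lr_patience_epochs: int = 10
    batch_size: int = 12
    l2_weight: float = 1e-5
    max_epochs: int = 150
    early_stop_patience: int = 30
    seed: int = 0

    def __post_init__(self) -> None:
        if self.batch_size <= 0 or self.max_epochs <= 0 or self.lr <= 0:
            raise ParameterError("lr, batch_size and max_epochs must be positive")


def spatial_trace(shape: tuple[int, int, int], n_pools: int = 4,
                  ) -> list[tuple[int, int, int]]:
    """Spatial shape after each pool (floor halving; axes of size 1 persist)."""
    out = [tuple(shape)]
    cur = tuple(shape)
    for _ in range(n_pools):
        cur = tuple(max(1, s // 2) for s in cur)
        out.append(cur)
    return out


def build_model(spec: ArchitectureSpec,
                input_shape: tuple[int, int, int] = (48, 56, 48),
                seed: int = 0) -> Network:
    """Assemble the network for a given input grid.

    The head's wide convolution is valid and its kernel equals the spatial
    extent left after the four pools, collapsing it to 1x1x1; an input too
    small to support the 3x3x3 stack raises an architecture error carrying
    the pool-by-pool trace.
    """
    if min(input_shape) < 3:
        raise ArchitectureError(
            f"input spatial shape {input_shape} cannot support 3x3x3 "
            f"convolutions; trace: {spatial_trace(input_shape)}")
    rng = np.random.default_rng(seed)
    dt = spec.dtype
    layers: list = []
    prev = spec.in_channels
    for si, (base, n_convs) in enumerate(_STAGES):
        w = spec.width(base)
        for ci in range(n_convs):
            if si == 0 and ci == 0:
                layers.append(Conv3d(prev, w, rng=rng, dtype=dt))
            else:
                layers.append(BatchNorm3d(prev, dtype=dt))
                layers.append(LeakyReLU(spec.leaky_slope))
                layers.append(Conv3d(prev, w, rng=rng, dtype=dt))
            prev = w
            if spec.with_se and (si, ci) in _SE_AFTER_CONV:
                layers.append(SEBlock(prev, spec.se_reduction, rng=rng, dtype=dt))
        if si < len(_STAGES) - 1:
            layers.append(MaxPool3d())
            if spec.with_se and si in _SE_AFTER_POOL:
                layers.append(SEBlock(prev, spec.se_reduction, rng=rng, dtype=dt))
    final_spatial = spatial_trace(input_shape)[-1]
    head_w = spec.width(_HEAD_WIDTHS[0])
    layers.append(Dropout(spec.dropout, rng=rng))
    layers.append(Conv3d(prev, head_w, kernel=final_spatial, padding="valid",
                         rng=rng, dtype=dt))
    layers.append(LeakyReLU(spec.leaky_slope))
    prev = head_w
    head_w2 = spec.width(_HEAD_WIDTHS[1])
    layers.append(Dropout(spec.dropout, rng=rng))
    layers.append(Conv3d(prev, head_w2, kernel=(1, 1, 1), padding="valid",
                         rng=rng, dtype=dt))
    layers.append(LeakyReLU(spec.leaky_slope))
    layers.append(Flatten())
    layers.append(Dense(head_w2, spec.n_classes, rng=rng, dtype=dt))
    return Network(layers)


# ---------------------------------------------------------------------------
# Metrics
# ---------------------------------------------------------------------------

@dataclass
class ConfusionCounts:
    tp: int
    tn: int
    fp: int
    fn: int

    def __post_init__(self) -> None:
        if min(self.tp, self.tn, self.fp, self.fn) < 0:
            raise InputError("confusion counts must be non-negative")

    @property
    def total(self) -> int:
        return self.tp + self.tn + self.fp + self.fn

    @classmethod
    def from_predictions(cls, y_true: np.ndarray, y_pred: np.ndarray,
                         ) -> "ConfusionCounts":
        y_true = np.asarray(y_true).astype(int)
        y_pred = np.asarray(y_pred).astype(int)
        return cls(tp=int(((y_true == 1) & (y_pred == 1)).sum()),
                   tn=int(((y_true == 0) & (y_pred == 0)).sum()),
                   fp=int(((y_true == 0) & (y_pred == 1)).sum()),
                   fn=int(((y_true == 1) & (y_pred == 0)).sum()))


def _safe_div(num: float, den: float) -> tuple[float, bool]:
    return (num / den, False) if den > 0 else (0.0, True)


def compute_metrics(c: ConfusionCounts, convention: str = "standard") -> dict:
    """ACC / precision / recall / F1 from confusion counts.

    ``standard``: precision = TP/(TP+FP), recall = TP/(TP+FN).
    ``as_printed``: precision = TP/(TP+FN), recall = TN/(TN+FP), matching a
    published but nonstandard formula pair.  A zero denominator yields a 0
    metric with ``degenerate=True``.
    """
    if c.total == 0:
        raise InputError("no evaluated subjects")
    acc = (c.tp + c.tn) / c.total
    if convention == "standard":
        prec, d1 = _safe_div(c.tp, c.tp + c.fp)
        rec, d2 = _safe_div(c.tp, c.tp + c.fn)
    elif convention == "as_printed":
        prec, d1 = _safe_div(c.tp, c.tp + c.fn)
        rec, d2 = _safe_div(c.tn, c.tn + c.fp)
    else:
        raise ParameterError(f"unknown convention {convention!r}")
    f1, d3 = _safe_div(2.0 * prec * rec, prec + rec)
    return {"accuracy": acc, "precision": prec, "recall": rec, "f1": f1,
            "degenerate": d1 or d2 or d3}


@dataclass
class FoldResult:
    fold: int
    val_indices: np.ndarray
    y_true: np.ndarray
    prob_case: np.ndarray
    y_pred: np.ndarray
    counts: ConfusionCounts
    metrics: dict
    history: dict = field(default_factory=dict)


# ---------------------------------------------------------------------------
# Cross-validation
# ---------------------------------------------------------------------------

def stratified_kfold(labels: np.ndarray, k: int = 10, seed: int = 0,
                     ) -> list[np.ndarray]:
    """k disjoint validation index sets preserving class proportions."""
    from sklearn.model_selection import StratifiedKFold

    labels = np.asarray(labels).astype(int)
    counts = np.bincount(labels)
    if counts.min() < k:
        raise InputError(
            f"smallest class has {counts.min()} members; cannot make {k} folds")
    skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    return [val for _, val in skf.split(np.zeros(len(labels)), labels)]


def _evaluate(model: Network, X: np.ndarray, batch: int = 12) -> np.ndarray:
    probs = []
    for i in range(0, len(X), batch):
        logits = model.forward(X[i:i + batch], train=False)
        probs.append(softmax(logits.astype(np.float64))[:, 1])
    return np.concatenate(probs)


def train_fold(X_train: np.ndarray, y_train: np.ndarray, X_val: np.ndarray,
               y_val: np.ndarray, config: TrainConfig, spec: ArchitectureSpec,
               fold: int = 0) -> FoldResult:
    """Train one fold to the recipe and score the validation set.

    Adam minimizes cross-entropy; the learning rate decays by the configured
    factor when validation loss has not improved for ``lr_patience_epochs``;
    training stops at ``max_epochs`` or after ``early_stop_patience`` epochs
    without improvement.  Predictions come from the best-validation-loss
    epoch.  Fully deterministic given ``config.seed``.
    """
    if len(X_train) == 0 or len(X_val) == 0:
        raise InputError("empty train or validation set")
    model = build_model(spec, input_shape=X_train.shape[2:], seed=config.seed)
    opt = Adam(model.params(), lr=config.lr, l2_weight=config.l2_weight)
    rng = np.random.default_rng(config.seed + 1)

    best_loss = np.inf
    best_probs: np.ndarray | None = None
    since_improve = 0
    since_decay = 0
    history = {"train_loss": [], "val_loss": [], "lr": []}

    for epoch in range(config.max_epochs):
        order = rng.permutation(len(X_train))
        epoch_loss = 0.0
        n_batches = 0
        for i in range(0, len(order), config.batch_size):
            idx = order[i:i + config.batch_size]
            model.zero_grad()
            logits = model.forward(X_train[idx], train=True)
            loss, grad = cross_entropy_with_logits(logits, y_train[idx])
            if not np.isfinite(loss):
                raise TrainingError(f"non-finite training loss at epoch {epoch}")
            model.backward(grad)
            opt.step()
            epoch_loss += loss
            n_batches += 1

        val_probs = _evaluate(model, X_val, batch=config.batch_size)
        eps = 1e-12
        val_loss = float(-np.mean(
            y_val * np.log(val_probs + eps)
            + (1 - y_val) * np.log(1 - val_probs + eps)))
        history["train_loss"].append(epoch_loss / max(n_batches, 1))
        history["val_loss"].append(val_loss)
        history["lr"].append(opt.lr)

        if val_loss < best_loss - 1e-6:
            best_loss = val_loss
            best_probs = val_probs
            since_improve = 0
            since_decay = 0
        else:
            since_improve += 1
            since_decay += 1
            if since_decay >= config.lr_patience_epochs:
                opt.lr *= config.lr_decay_factor
                since_decay = 0
            if since_improve >= config.early_stop_patience:
                break

    assert best_probs is not None
    y_pred = (best_probs >= 0.5).astype(int)
    counts = ConfusionCounts.from_predictions(y_val, y_pred)
    return FoldResult(fold=fold, val_indices=np.arange(len(y_val)),
                      y_true=np.asarray(y_val), prob_case=best_probs,
                      y_pred=y_pred, counts=counts,
                      metrics=compute_metrics(counts), history=history)


def run_cross_validation(stacks: np.ndarray, labels: np.ndarray,
                         channel_names: list[str], config: TrainConfig,
                         spec: ArchitectureSpec, mode: str = "mcse",
                         k: int = 10, standardize: bool = True,
                         ) -> tuple[list[FoldResult], dict]:
    """Stratified k-fold cross-validation of one classifier variant.

    ``mode`` is ``mcse`` (all channels, SE on), ``baseline`` (all channels,
    no SE) or ``scse:<network>`` (that channel only, SE on).  With
    ``standardize`` each channel is z-scored using the training fold's mean
    and standard deviation before entering the network (the validation fold
    reuses the training statistics, so no information leaks).
    """
    stacks = np.asarray(stacks)
    labels = np.asarray(labels).astype(int)
    if mode == "mcse":
        X = stacks
        with_se = True
    elif mode == "baseline":
        X = stacks
        with_se = False
    elif mode.startswith("scse:"):
        name = mode.split(":", 1)[1]
        if name not in channel_names:
            raise InputError(
                f"unknown network {name!r}; have {channel_names}")
        X = stacks[:, [channel_names.index(name)]]
        with_se = True
    else:
        raise InputError(f"unknown mode {mode!r}")

    spec = ArchitectureSpec(
        in_channels=X.shape[1], n_classes=spec.n_classes,
        width_multiplier=spec.width_multiplier, with_se=with_se,
        se_reduction=spec.se_reduction, leaky_slope=spec.leaky_slope,
        dropout=spec.dropout, dtype=spec.dtype)

    X = X.astype(spec.dtype)
    folds = stratified_kfold(labels, k=k, seed=config.seed)
    all_idx = np.arange(len(labels))
    results = []
    for f, val_idx in enumerate(folds):
        train_idx = np.setdiff1d(all_idx, val_idx)
        X_tr, X_val = X[train_idx], X[val_idx]
        if standardize:
            mu = X_tr.mean(axis=(0, 2, 3, 4), keepdims=True)
            sd = X_tr.std(axis=(0, 2, 3, 4), keepdims=True)
            sd[sd == 0] = 1.0
            X_tr = (X_tr - mu) / sd
            X_val = (X_val - mu) / sd
        res = train_fold(X_tr, labels[train_idx], X_val,
                         labels[val_idx], config, spec, fold=f)
        res.val_indices = val_idx
        results.append(res)

    mean_metrics = {}
    for key in ("accuracy", "precision", "recall", "f1"):
        vals = [r.metrics[key] for r in results]
        mean_metrics[key] = float(np.mean(vals))
        mean_metrics[key + "_sd"] = float(np.std(vals))
    return results, mean_metrics
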