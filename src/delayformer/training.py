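"""Supervised training of a Delayformer.

The loss is the channel-independent mean squared error: squared forecast
errors are summed over every channel, horizon step and batch element and
divided by the total element count, so all channels share one objective and
the model never sees channel identity except through its forecast head.

Normalization is per-channel z-scoring with statistics estimated on the
training split only (the convention of the standard forecasting benchmark
pipeline); all reported "normalized-scale" metrics live on this scale.

Randomness discipline: a single master seed is split into independent
streams for model initialization, batch order, and dropout, so each can be
varied in isolation and a fixed seed reproduces training bit-for-bit.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .embedding import WindowPair
from .model import Delayformer
from .nn import AdamState
from .series import MultivariateSeries

__all__ = [
    "TrainConfig",
    "NormalizationStats",
    "fit_normalizer",
    "ci_loss",
    "train",
    "pretrain_multi",
    "finetune",
    "stack_windows",
    "TrainResult",
    "seed_streams",
]

STD_FLOOR = 1e-8


@dataclass
class TrainConfig:
    learning_rate: float = 1e-4
    batch_size: int = 32
    max_epochs: int = 10
    early_stop_patience: int = 3
    seed: int = 0
    normalization: str = "zscore"  # or "none"
    finetune_fraction: float = 1.0
    #: windows per forward pass during (non-training) evaluation
    eval_batch_size: int = 64

    def __post_init__(self) -> None:
        if self.learning_rate <= 0:
            raise ValueError("learning_rate must be > 0")
        if self.batch_size < 1:
            raise ValueError("batch_size must be >= 1")
        if self.normalization not in ("zscore", "none"):
            raise ValueError(f"unknown normalization {self.normalization!r}")
        if not 0 < self.finetune_fraction <= 1:
            raise ValueError("finetune_fraction must be in (0, 1]")


def seed_streams(master_seed: int, n: int = 3) -> list[np.random.Generator]:
    """Independent generators (init, batch order, dropout, ...) from one master seed."""
    return [np.random.default_rng(s) for s in np.random.SeedSequence(master_seed).spawn(n)]


@dataclass
class NormalizationStats:
    """Per-channel mean/std from the training split; std floored at 1e-8."""

    mean: np.ndarray
    std: np.ndarray

    def apply(self, values: np.ndarray) -> np.ndarray:
        return (values - self.mean) / self.std

    def invert(self, values: np.ndarray) -> np.ndarray:
        return values * self.std + self.mean

    def apply_series(self, series: MultivariateSeries) -> MultivariateSeries:
        return MultivariateSeries(
            self.apply(series.values),
            list(series.channel_names),
            series.dt_sample,
            series.provenance + " [z-scored]",
        )


def fit_normalizer(train_series: MultivariateSeries | np.ndarray) -> NormalizationStats:
    """Channelwise mean/std on the training split; constant channels get the floor std."""
    values = train_series.values if isinstance(train_series, MultivariateSeries) else np.asarray(train_series)
    if values.size == 0:
        raise ValueError("cannot fit a normalizer on an empty training split")
    mean = values.mean(axis=0)
    std = values.std(axis=0)
    std = np.maximum(std, STD_FLOOR)
    return NormalizationStats(mean=mean, std=std)


def identity_normalizer(n_channels: int) -> NormalizationStats:
    return NormalizationStats(mean=np.zeros(n_channels), std=np.ones(n_channels))


def ci_loss(predictions: np.ndarray, targets: np.ndarray) -> float:
    """Channel-independent MSE: per-channel squared errors aggregated over
    all channels, horizon steps and batch items, divided by the element count."""
    predictions = np.asarray(predictions)
    targets = np.asarray(targets)
    if predictions.shape != targets.shape:
        raise ValueError(f"shape mismatch {predictions.shape} vs {targets.shape}")
    diff = predictions.astype(np.float64) - targets.astype(np.float64)
    return float(np.mean(diff * diff))


def stack_windows(pairs: Sequence[WindowPair]) -> tuple[np.ndarray, np.ndarray]:
    """Stack WindowPairs into ``(n, W, N)`` inputs and ``(n, H, N)`` targets."""
    if len(pairs) == 0:
        raise ValueError("empty window collection")
    X = np.stack([p.input for p in pairs])
    Y = np.stack([p.target for p in pairs])
    return X, Y


def predict_batched(model: Delayformer, X: np.ndarray, batch_size: int = 64) -> np.ndarray:
    """Evaluation-mode forward pass in memory-bounded chunks."""
    outs = [model.forward(X[i : i + batch_size]) for i in range(0, X.shape[0], batch_size)]
    return np.concatenate(outs, axis=0)


@dataclass
class TrainResult:
    model: Delayformer
    history: list[dict] = field(default_factory=list)
    best_epoch: int = -1
    best_val_mse: float = math.inf


def _val_mse(model: Delayformer, Xv, Yv, batch: int) -> float:
    return ci_loss(predict_batched(model, Xv, batch), Yv)


def train(
    model: Delayformer,
    train_pairs: Sequence[WindowPair],
    val_pairs: Sequence[WindowPair],
    config: TrainConfig,
) -> TrainResult:
    """Minimize the channel-independent MSE with Adam.

    Early-stops on validation MSE with the configured patience and restores
    the best-validation weights.  ``max_epochs=0`` returns the initialized
    model untouched with an empty history.
    """
    if len(train_pairs) == 0:
        raise ValueError("empty training data")
    result = TrainResult(model=model)
    if config.max_epochs == 0:
        return result
    X, Y = stack_windows(train_pairs)
    have_val = len(val_pairs) > 0
    if have_val:
        Xv, Yv = stack_windows(val_pairs)
    _, batch_rng, drop_rng = seed_streams(config.seed, 3)
    opt = AdamState(model.params, lr=config.learning_rate)
    n = X.shape[0]
    best_params = None

    def current_val() -> float:
        if not have_val:
            return math.nan
        return _val_mse(model, Xv, Yv, config.eval_batch_size)

    val0 = current_val()
    if have_val:
        result.best_val_mse = val0
        result.best_epoch = 0
        best_params = {k: v.copy() for k, v in model.params.items()}
    bad_epochs = 0
    for epoch in range(config.max_epochs):
        order = batch_rng.permutation(n)
        epoch_loss = 0.0
        n_batches = 0
        for i in range(0, n, config.batch_size):
            idx = order[i : i + config.batch_size]
            xb, yb = X[idx], Y[idx]
            pred, cache = model.forward_cached(xb, rng=drop_rng)
            loss = ci_loss(pred, yb)
            if not math.isfinite(loss):
                raise RuntimeError(
                    f"non-finite training loss at epoch {epoch}; "
                    f"try a smaller learning rate than {config.learning_rate}"
                )
            dpred = (2.0 / pred.size) * (pred - yb)
            grads = model.backward(dpred, cache)
            opt.step(model.params, grads)
            epoch_loss += loss
            n_batches += 1
        val = current_val()
        result.history.append(
            {"epoch": epoch, "train_loss": epoch_loss / max(n_batches, 1), "val_mse": val}
        )
        if have_val:
            if val < result.best_val_mse:
                result.best_val_mse = val
                result.best_epoch = epoch + 1
                best_params = {k: v.copy() for k, v in model.params.items()}
                bad_epochs = 0
            else:
                bad_epochs += 1
                if bad_epochs >= config.early_stop_patience:
                    break
    if best_params is not None:
        model.params = best_params
    return result


def pretrain_multi(
    model: Delayformer,
    datasets: Sequence[tuple[Sequence[WindowPair], Sequence[WindowPair]]],
    config: TrainConfig,
) -> TrainResult:
    """Round-robin pretraining over several (train, val) window collections.

    Requires ``decoder_mode="shared"`` (a new dataset would otherwise have no
    trained head).  Datasets must agree on (W, H) geometry but may differ in
    channel count: channel independence makes the encoder and the shared
    head agnostic to the number of channels.  Validation MSE is the mean
    over datasets' validation splits.
    """
    if model.config.decoder_mode != "shared":
        raise ValueError("pretraining requires decoder_mode='shared'")
    if len(datasets) == 0:
        raise ValueError("no datasets to pretrain on")
    stacked = []
    for tr, va in datasets:
        Xt, Yt = stack_windows(tr)
        if Xt.shape[1] != model.config.W or Yt.shape[1] != model.config.H:
            raise ValueError(
                f"dataset geometry ({Xt.shape[1]}, {Yt.shape[1]}) does not match "
                f"model (W={model.config.W}, H={model.config.H})"
            )
        Xv, Yv = (stack_windows(va) if len(va) else (None, None))
        stacked.append((Xt, Yt, Xv, Yv))
    result = TrainResult(model=model)
    if config.max_epochs == 0:
        return result
    _, batch_rng, drop_rng = seed_streams(config.seed, 3)
    opt = AdamState(model.params, lr=config.learning_rate)

    def mean_val() -> float:
        vals = [
            _val_mse(model, Xv, Yv, config.eval_batch_size)
            for _, _, Xv, Yv in stacked
            if Xv is not None
        ]
        return float(np.mean(vals)) if vals else math.nan

    result.best_val_mse = mean_val()
    result.best_epoch = 0
    best_params = (
        {k: v.copy() for k, v in model.params.items()}
        if math.isfinite(result.best_val_mse)
        else None
    )
    bad_epochs = 0
    for epoch in range(config.max_epochs):
        # per-dataset shuffled batch queues, drained round-robin
        queues = []
        for Xt, Yt, _, _ in stacked:
            order = batch_rng.permutation(Xt.shape[0])
            batches = [
                order[i : i + config.batch_size]
                for i in range(0, Xt.shape[0], config.batch_size)
            ]
            queues.append(batches)
        epoch_loss, n_batches = 0.0, 0
        slot = 0
        while any(queues):
            d = slot % len(stacked)
            slot += 1
            if not queues[d]:
                continue
            idx = queues[d].pop(0)
            Xt, Yt, _, _ = stacked[d]
            pred, cache = model.forward_cached(Xt[idx], rng=drop_rng)
            loss = ci_loss(pred, Yt[idx])
            if not math.isfinite(loss):
                raise RuntimeError(f"non-finite pretraining loss at epoch {epoch}")
            dpred = (2.0 / pred.size) * (pred - Yt[idx])
            grads = model.backward(dpred, cache)
            opt.step(model.params, grads)
            epoch_loss += loss
            n_batches += 1
        val = mean_val()
        result.history.append(
            {"epoch": epoch, "train_loss": epoch_loss / max(n_batches, 1), "val_mse": val}
        )
        if math.isfinite(val):
            if val < result.best_val_mse:
                result.best_val_mse = val
                result.best_epoch = epoch + 1
                best_params = {k: v.copy() for k, v in model.params.items()}
                bad_epochs = 0
            else:
                bad_epochs += 1
                if bad_epochs >= config.early_stop_patience:
                    break
    if best_params is not None:
        model.params = best_params
    return result


def finetune(
    model: Delayformer,
    train_pairs: Sequence[WindowPair],
    fraction: float,
    config: TrainConfig,
    val_pairs: Sequence[WindowPair] = (),
    selection: str = "recent",
) -> TrainResult:
    """Fine-tune a pretrained model on a fraction of the target windows.

    ``selection="recent"`` keeps the chronologically last windows (the most
    recent data); ``"random"`` subsamples uniformly with the config seed.
    All weights are updated.
    """
    if not 0 < fraction <= 1:
        raise ValueError("fraction must be in (0, 1]")
    n = len(train_pairs)
    keep = int(round(fraction * n))
    if keep == 0:
        raise ValueError(f"fraction {fraction} of {n} windows yields zero training windows")
    if selection == "recent":
        subset = list(train_pairs)[-keep:]
    elif selection == "random":
        rng = seed_streams(config.seed, 1)[0]
        idx = np.sort(rng.choice(n, size=keep, replace=False))
        subset = [train_pairs[i] for i in idx]
    else:
        raise ValueError(f"unknown selection {selection!r}")
    return train(model, subset, val_pairs, config)
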