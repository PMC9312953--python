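"""Loss, optimizer, data splitting and the two-stage training loop.

The objective is the Pseudo-Huber loss with shape parameter delta = 0.9
(mean over samples): quadratic for small residuals, linear in the tails, so
occasional noisy samples do not dominate the fit.  Optimization is Adagrad
with initial learning rate 0.1 and batch size 256 (configurable); training is
deterministic given the config seed.

Stage one trains the auto-encoder end to end through the straight-through
bottleneck; stage two freezes it and fits the RECN on tenfold-magnified
residual labels.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np

from .bcae import BCAE
from .preprocessing import Beat
from .recn import RECN, residual_label

__all__ = [
    "TrainConfig",
    "SplitSpec",
    "pseudo_huber_loss",
    "pseudo_huber_grad",
    "Adagrad",
    "split_dataset",
    "train_bcae",
    "train_recn",
]


@dataclass(frozen=True)
class TrainConfig:
    delta: float = 0.9
    learning_rate: float = 0.1
    batch_size: int = 256
    epochs: int = 400
    seed: int = 0
    optimizer: str = "adagrad"
    initial_accumulator: float = 0.1
    keep_best_val: bool = True
    early_stopping: bool = False
    patience: int = 20

    def __post_init__(self) -> None:
        if self.delta <= 0:
            raise ValueError("delta must be positive")
        if self.batch_size < 1 or self.epochs < 1:
            raise ValueError("batch_size and epochs must be >= 1")


@dataclass(frozen=True)
class SplitSpec:
    train_frac: float = 0.80
    val_frac: float = 0.15
    test_frac: float = 0.05
    per_record_beats: int = 1000
    test_per_record: int = 50

    def __post_init__(self) -> None:
        total = self.train_frac + self.val_frac + self.test_frac
        if abs(total - 1.0) > 1e-9:
            raise ValueError("split fractions must sum to 1")


def pseudo_huber_loss(y: np.ndarray, y_prime: np.ndarray, delta: float = 0.9) -> float:
    """Mean over elements of delta^2 (sqrt(1 + ((y - y')/delta)^2) - 1)."""
    y = np.asarray(y, dtype=float)
    yp = np.asarray(y_prime, dtype=float)
    if y.shape != yp.shape:
        raise ValueError("inputs must have equal shapes")
    if delta <= 0:
        raise ValueError("delta must be positive")
    r = (y - yp) / delta
    return float(np.mean(delta * delta * (np.sqrt(1.0 + r * r) - 1.0)))


def pseudo_huber_grad(y: np.ndarray, y_prime: np.ndarray, delta: float = 0.9) -> np.ndarray:
    """d(loss)/d(y_prime): smooth, bounded by delta, mean reduction."""
    y = np.asarray(y, dtype=float)
    yp = np.asarray(y_prime, dtype=float)
    r = (yp - y) / delta
    return (delta * r / np.sqrt(1.0 + r * r)) / y.size


class Adagrad:
    """Per-parameter adaptive gradient accumulation."""

    SKIP = ("running_mean", "running_var")  # batch-norm stats: not optimized

    def __init__(self, lr: float = 0.1, initial_accumulator: float = 0.1, eps: float = 1e-7):
        self.lr = lr
        self.eps = eps
        self.initial_accumulator = initial_accumulator
        self._acc: Dict[int, Dict[str, np.ndarray]] = {}

    def step(self, model) -> None:
        for layer, name, arr in model.parameters():
            if name in self.SKIP:
                continue
            g = layer.grads().get(name)
            if g is None:
                continue
            acc = self._acc.setdefault(id(layer), {})
            if name not in acc:
                acc[name] = np.full_like(arr, self.initial_accumulator)
            a = acc[name]
            a += g * g
            arr -= self.lr * g / (np.sqrt(a) + self.eps)


def _group_by_record(beats: Sequence[Beat]) -> Dict[str, List[int]]:
    groups: Dict[str, List[int]] = {}
    for i, b in enumerate(beats):
        groups.setdefault(b.record_id, []).append(i)
    return groups


def split_dataset(
    beats: Sequence[Beat], spec: SplitSpec = SplitSpec(), seed: int = 0
) -> Tuple[List[Beat], List[Beat], List[Beat]]:
    """Stratified-by-record split into train/validation/test.

    From each record up to ``per_record_beats`` beats are sampled;
    ``test_per_record`` of them go to the test set, the remainder is divided
    so the train set holds ``train_frac`` of the record's sampled beats.
    Deterministic for a given seed; partitions are disjoint.
    """
    rng = np.random.default_rng(seed)
    groups = _group_by_record(beats)
    train: List[Beat] = []
    val: List[Beat] = []
    test: List[Beat] = []
    for record_id in sorted(groups):
        idx = np.asarray(groups[record_id])
        if idx.size == 0:
            raise ValueError(f"record {record_id!r} has no beats")
        rng.shuffle(idx)
        idx = idx[: spec.per_record_beats]
        n = idx.size
        n_test = min(spec.test_per_record, n)
        n_train = int(round(n * spec.train_frac))
        n_train = min(n_train, n - n_test)
        test.extend(beats[i] for i in idx[:n_test])
        train.extend(beats[i] for i in idx[n_test : n_test + n_train])
        val.extend(beats[i] for i in idx[n_test + n_train :])
    return train, val, test


def _as_array(beats) -> np.ndarray:
    if isinstance(beats, np.ndarray):
        return np.asarray(beats, dtype=float)
    return np.stack([np.asarray(b.samples, dtype=float) for b in beats], axis=0)


def _epoch_eval(model: BCAE, x: np.ndarray, delta: float, batch_size: int) -> float:
    losses = []
    weights = []
    for i in range(0, x.shape[0], batch_size):
        xb = x[i : i + batch_size]
        recon = model.forward(xb, training=False)
        losses.append(pseudo_huber_loss(xb, recon, delta))
        weights.append(xb.shape[0])
    return float(np.average(losses, weights=weights))


def train_bcae(
    train, val, config: TrainConfig, model: Optional[BCAE] = None
) -> Tuple[BCAE, Dict[str, List[float]]]:
    """Fit the auto-encoder; returns the model and per-epoch loss history.

    With ``keep_best_val`` the parameters of the best-validation epoch are
    restored at the end.  Raises on NaN loss, naming the epoch.
    """
    from .bcae import build_bcae  # local import avoids a cycle at module load

    x_train = _as_array(train)
    x_val = _as_array(val)
    if x_train.shape[0] == 0:
        raise ValueError("empty training set")
    if model is None:
        model = build_bcae()
        model.init_params(config.seed)
    rng = np.random.default_rng(config.seed + 1)
    opt = Adagrad(config.learning_rate, config.initial_accumulator)
    history: Dict[str, List[float]] = {"train": [], "val": []}
    best_val = np.inf
    best_state = None
    since_best = 0
    for epoch in range(config.epochs):
        order = rng.permutation(x_train.shape[0])
        batch_losses = []
        batch_sizes = []
        for i in range(0, order.size, config.batch_size):
            xb = x_train[order[i : i + config.batch_size]]
            recon = model.forward(xb, training=True)
            loss = pseudo_huber_loss(xb, recon, config.delta)
            if not np.isfinite(loss):
                raise FloatingPointError(f"training diverged (NaN loss) at epoch {epoch}")
            model.backward(pseudo_huber_grad(xb, recon, config.delta))
            opt.step(model)
            batch_losses.append(loss)
            batch_sizes.append(xb.shape[0])
        history["train"].append(float(np.average(batch_losses, weights=batch_sizes)))
        if x_val.shape[0]:
            vloss = _epoch_eval(model, x_val, config.delta, config.batch_size)
        else:
            vloss = history["train"][-1]
        history["val"].append(vloss)
        if vloss < best_val:
            best_val = vloss
            since_best = 0
            if config.keep_best_val:
                best_state = _snapshot(model)
        else:
            since_best += 1
            if config.early_stopping and since_best >= config.patience:
                break
    if config.keep_best_val and best_state is not None:
        _restore(model, best_state)
    return model, history


def _snapshot(model) -> list:
    return [(id(layer), name, arr.copy()) for layer, name, arr in model.parameters()]


def _restore(model, state: list) -> None:
    arrays = {(lid, name): arr for lid, name, arr in state}
    for layer, name, arr in model.parameters():
        saved = arrays.get((id(layer), name))
        if saved is not None:
            arr[...] = saved


def train_recn(
    train,
    val,
    bcae_model: BCAE,
    config: TrainConfig,
    recn_model: Optional[RECN] = None,
) -> Tuple[RECN, Dict[str, List[float]]]:
    """Fit the RECN against the frozen auto-encoder.

    Codes and reconstructions for both splits are precomputed once (the
    auto-encoder does not change), then the MLP is trained on magnified
    residual labels with the same loss and optimizer family.
    """
    from .recn import build_recn

    x_train = _as_array(train)
    x_val = _as_array(val)
    if x_train.shape[0] == 0:
        raise ValueError("empty training set")

    def codes_and_labels(x: np.ndarray) -> Tuple[np.ndarray, np.ndarray]:
        codes = []
        labels = []
        for i in range(0, x.shape[0], config.batch_size):
            xb = x[i : i + config.batch_size]
            cb = bcae_model.encode_batch(xb)
            rb = bcae_model.decode_batch(cb)
            codes.append(cb)
            labels.append(residual_label(xb, rb))
        return np.concatenate(codes), np.concatenate(labels)

    c_train, y_train = codes_and_labels(x_train)
    c_val, y_val = (codes_and_labels(x_val) if x_val.shape[0] else (x_val, x_val))

    if recn_model is None:
        recn_model = build_recn()
        recn_model.init_params(config.seed)
    rng = np.random.default_rng(config.seed + 2)
    opt = Adagrad(config.learning_rate, config.initial_accumulator)
    history: Dict[str, List[float]] = {"train": [], "val": []}
    best_val = np.inf
    best_state = None
    for epoch in range(config.epochs):
        order = rng.permutation(c_train.shape[0])
        batch_losses = []
        batch_sizes = []
        for i in range(0, order.size, config.batch_size):
            sel = order[i : i + config.batch_size]
            pred = recn_model.forward(c_train[sel], training=True)
            loss = pseudo_huber_loss(y_train[sel], pred, config.delta)
            if not np.isfinite(loss):
                raise FloatingPointError(f"RECN training diverged at epoch {epoch}")
            recn_model.backward(pseudo_huber_grad(y_train[sel], pred, config.delta))
            opt.step(recn_model)
            batch_losses.append(loss)
            batch_sizes.append(sel.size)
        history["train"].append(float(np.average(batch_losses, weights=batch_sizes)))
        if c_val.shape[0]:
            vpred = recn_model.forward(c_val)
            vloss = pseudo_huber_loss(y_val, vpred, config.delta)
        else:
            vloss = history["train"][-1]
        history["val"].append(vloss)
        if vloss < best_val:
            best_val = vloss
            if config.keep_best_val:
                best_state = _snapshot(recn_model)
    if config.keep_best_val and best_state is not None:
        _restore(recn_model, best_state)
    return recn_model, history
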