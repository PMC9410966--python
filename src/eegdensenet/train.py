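"""Per-subject supervised training.

Adam minimizes softmax cross-entropy at a low learning rate (2e-4) for a
fixed epoch budget; the classifier's max-norm constraint is re-applied
after every step.  The weights returned are those of the epoch with the
best validation accuracy (ties resolved to the earliest epoch), which is
harmless when validation is ignored and standard when it is not.

Two evaluation modes are provided: a fixed stratified
train/validation/test split (70/15/15 by default, largest-remainder
rounding) and stratified K-fold cross-validation with K=12.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from sklearn.model_selection import StratifiedKFold

from .dataset import EEGDataset
from .layers import softmax_cross_entropy
from .model import ModelConfig, ModelHandle, build_model


@dataclass
class TrainConfig:
    """Optimization hyperparameters (tuned-model defaults)."""

    learning_rate: float = 2e-4
    epochs: int = 200
    batch_size: int = 16
    seed: int = 0
    split: tuple[float, float, float] = (0.70, 0.15, 0.15)
    k_folds: int = 12

    def __post_init__(self) -> None:
        if abs(sum(self.split) - 1.0) > 1e-9:
            raise ValueError(f"split fractions must sum to 1, got {self.split}")
        if self.k_folds < 2:
            raise ValueError("k_folds must be at least 2")
        if self.epochs < 1:
            raise ValueError("epochs must be at least 1")
        if self.batch_size < 1:
            raise ValueError("batch_size must be at least 1")


@dataclass
class FitResult:
    """A trained model plus its learning curves."""

    model: ModelHandle
    train_loss: np.ndarray
    train_accuracy: np.ndarray
    val_loss: np.ndarray
    val_accuracy: np.ndarray
    best_epoch: int
    test_accuracy: float | None = None
    meta: dict = field(default_factory=dict)


class Adam:
    """Adam with per-parameter first/second moment state."""

    def __init__(self, learning_rate: float, beta1: float = 0.9,
                 beta2: float = 0.999, eps: float = 1e-8):
        self.lr, self.b1, self.b2, self.eps = learning_rate, beta1, beta2, eps
        self.t = 0
        self._m: dict[str, np.ndarray] = {}
        self._v: dict[str, np.ndarray] = {}

    def step(self, params: dict[str, np.ndarray],
             grads: dict[str, np.ndarray]) -> None:
        self.t += 1
        bc1 = 1.0 - self.b1 ** self.t
        bc2 = 1.0 - self.b2 ** self.t
        for name, p in params.items():
            g = grads[name]
            if name not in self._m:
                self._m[name] = np.zeros_like(p)
                self._v[name] = np.zeros_like(p)
            m, v = self._m[name], self._v[name]
            m *= self.b1
            m += (1 - self.b1) * g
            v *= self.b2
            v += (1 - self.b2) * g * g
            p -= self.lr * (m / bc1) / (np.sqrt(v / bc2) + self.eps)


def _largest_remainder(total: int, fracs: tuple[float, ...]) -> list[int]:
    exact = [total * f for f in fracs]
    sizes = [int(np.floor(e)) for e in exact]
    remainders = [e - s for e, s in zip(exact, sizes)]
    for i in sorted(range(len(fracs)), key=lambda i: -remainders[i])[
        : total - sum(sizes)
    ]:
        sizes[i] += 1
    return sizes


def split_dataset(
    ds: EEGDataset, cfg: TrainConfig
) -> tuple[EEGDataset, EEGDataset, EEGDataset]:
    """Stratified, disjoint train/validation/test split.

    Overall split sizes come from largest-remainder rounding of
    ``N * split``; each split's quota is then filled class by class so
    every split stays class-balanced to within one trial.  Deterministic
    given ``cfg.seed``.
    """
    n = ds.n_trials
    if n == 0:
        raise ValueError("cannot split an empty dataset")
    sizes = _largest_remainder(n, cfg.split)
    classes = np.unique(ds.labels)
    n_nonempty = sum(1 for s in sizes if s > 0)
    if any(0 < s < len(classes) for s in sizes) or any(
        np.sum(ds.labels == c) < n_nonempty for c in classes
    ):
        raise ValueError(
            f"too few trials to stratify a {cfg.split} split of N={n}: "
            f"each non-empty part needs at least one trial of each of the "
            f"{len(classes)} classes, got {ds.class_counts()}"
        )
    rng = np.random.default_rng(cfg.seed)
    pools = {c: list(rng.permutation(np.flatnonzero(ds.labels == c)))
             for c in classes}
    assignments: list[np.ndarray] = []
    for size in sizes:
        if size == 0:
            assignments.append(np.zeros(0, dtype=np.int64))
            continue
        # fill this split's quota proportionally to the remaining pools
        remaining = sum(len(p) for p in pools.values())
        take: list[int] = []
        fracs = tuple(len(pools[c]) / remaining for c in classes)
        per_class = _largest_remainder(size, fracs)
        for c, k in zip(classes, per_class):
            take.extend(pools[c][:k])
            del pools[c][:k]
        assignments.append(np.sort(np.array(take, dtype=np.int64)))
    train_idx, val_idx, test_idx = assignments
    return ds.select(train_idx), ds.select(val_idx), ds.select(test_idx)


def _evaluate(model: ModelHandle, ds: EEGDataset) -> tuple[float, float]:
    """(loss, accuracy) on a dataset in evaluation mode."""
    if ds.n_trials == 0:
        return float("nan"), float("nan")
    logits = model.forward_logits(ds.data)
    loss, _ = softmax_cross_entropy(logits, ds.labels)
    acc = float(np.mean(np.argmax(logits, axis=1) == ds.labels))
    return loss, acc


def fit(
    model: ModelHandle,
    train: EEGDataset,
    val: EEGDataset,
    cfg: TrainConfig,
    test: EEGDataset | None = None,
    learning_rate: float | None = None,
    epochs: int | None = None,
) -> FitResult:
    """Train ``model`` in place with Adam + cross-entropy.

    ``learning_rate``/``epochs`` override the config values when given
    (used by the staged fine-tuning protocol).  Returns the best
    validation epoch's weights; raises on non-finite loss.  A zero
    learning rate performs evaluation-only epochs: no parameter updates
    and no batch-norm statistics updates.
    """
    lr = cfg.learning_rate if learning_rate is None else learning_rate
    n_epochs = cfg.epochs if epochs is None else epochs
    learning = lr > 0
    rng = np.random.default_rng(cfg.seed)
    opt = Adam(lr)

    curves: dict[str, list[float]] = {
        "train_loss": [], "train_acc": [], "val_loss": [], "val_acc": []
    }
    best_acc, best_epoch, best_state = -np.inf, -1, None

    for epoch in range(n_epochs):
        order = rng.permutation(train.n_trials)
        epoch_loss, epoch_correct = 0.0, 0
        for start in range(0, train.n_trials, cfg.batch_size):
            idx = order[start:start + cfg.batch_size]
            batch, labels = train.data[idx], train.labels[idx]
            logits = model.forward_logits(batch, training=learning, rng=rng)
            loss, dlogits = softmax_cross_entropy(logits, labels)
            if not np.isfinite(loss):
                raise RuntimeError(
                    f"training diverged at epoch {epoch}: loss={loss} "
                    f"(lr={lr}, batch_size={cfg.batch_size})"
                )
            if learning:
                model.backward(dlogits)
                params = dict(model.parameters(trainable_only=True))
                grads = dict(model.gradients(trainable_only=True))
                opt.step(params, grads)
                model.apply_constraints()
            epoch_loss += loss * len(idx)
            epoch_correct += int(np.sum(np.argmax(logits, axis=1) == labels))

        curves["train_loss"].append(epoch_loss / train.n_trials)
        curves["train_acc"].append(epoch_correct / train.n_trials)
        val_loss, val_acc = _evaluate(model, val)
        curves["val_loss"].append(val_loss)
        curves["val_acc"].append(val_acc)
        if np.isfinite(val_acc) and val_acc > best_acc:
            best_acc, best_epoch = val_acc, epoch
            best_state = model.state_dict()

    if best_state is not None:
        model.load_state_dict(best_state)
    else:
        best_epoch = n_epochs - 1

    result = FitResult(
        model=model,
        train_loss=np.array(curves["train_loss"]),
        train_accuracy=np.array(curves["train_acc"]),
        val_loss=np.array(curves["val_loss"]),
        val_accuracy=np.array(curves["val_acc"]),
        best_epoch=best_epoch,
    )
    if test is not None:
        _, result.test_accuracy = _evaluate(model, test)
    return result


def fit_subject(
    ds: EEGDataset,
    model_cfg: ModelConfig,
    cfg: TrainConfig,
    **fit_kwargs,
) -> FitResult:
    """Convenience wrapper: split, build a fresh model, fit, test."""
    train, val, test = split_dataset(ds, cfg)
    model = build_model(model_cfg, seed=cfg.seed)
    return fit(model, train, val, cfg, test=test, **fit_kwargs)


@dataclass
class CrossValResult:
    fold_accuracies: np.ndarray
    fold_test_indices: list[np.ndarray]

    @property
    def mean(self) -> float:
        return float(np.mean(self.fold_accuracies))

    @property
    def sd(self) -> float:
        return float(np.std(self.fold_accuracies, ddof=1))


def cross_validate(
    ds: EEGDataset,
    model_cfg: ModelConfig,
    cfg: TrainConfig,
    epochs: int | None = None,
) -> CrossValResult:
    """Stratified K-fold evaluation; every trial is tested exactly once.

    Inside each fold a validation share (the config's validation
    fraction, rescaled to the fold-training portion) is carved out for
    best-epoch selection.
    """
    if ds.n_trials < cfg.k_folds:
        raise ValueError(
            f"N={ds.n_trials} trials cannot form {cfg.k_folds} folds"
        )
    skf = StratifiedKFold(
        n_splits=cfg.k_folds, shuffle=True, random_state=cfg.seed
    )
    val_rel = cfg.split[1] / (cfg.split[0] + cfg.split[1])
    accs, test_indices = [], []
    for fold, (fit_idx, test_idx) in enumerate(
        skf.split(np.zeros(ds.n_trials), ds.labels)
    ):
        inner = ds.select(fit_idx)
        inner_cfg = TrainConfig(
            learning_rate=cfg.learning_rate, epochs=cfg.epochs,
            batch_size=cfg.batch_size, seed=cfg.seed + fold,
            split=(1.0 - val_rel, val_rel, 0.0), k_folds=cfg.k_folds,
        )
        tr, va, _ = split_dataset(inner, inner_cfg)
        model = build_model(model_cfg, seed=cfg.seed + fold)
        fit(model, tr, va, inner_cfg, epochs=epochs)
        _, acc = _evaluate(model, ds.select(test_idx))
        accs.append(acc)
        test_indices.append(test_idx)
    return CrossValResult(np.array(accs), test_indices)
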