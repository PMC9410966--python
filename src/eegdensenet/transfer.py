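"""Transfer learning by layer freezing and re-initialization.

A source model is pretrained on pooled trials from many subjects; a new
subject's model is then derived from it under one of five schemes:

* ``E1`` — re-initialize everything and retrain on the target (the
  from-scratch baseline among the extensions),
* ``E2`` — freeze block 1 (temporal + spatial filters), retrain the rest,
* ``E3`` — freeze both convolutional blocks, retrain the classifier only,
* ``classifier_only`` — E3's freezing with a fresh classifier head
  (a linear probe when stage 2 is skipped),
* ``full_finetune`` — no freezing; every parameter continues training.

Fine-tuning follows a two-stage protocol: first the classifier alone is
adapted at the base learning rate, then the scheme's trainable groups
continue at a comparatively low learning rate (0.1× base by default) for
a short epoch budget.  Frozen groups — including their batch-norm
running statistics — are bit-identical before and after fine-tuning.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .dataset import EEGDataset, concatenate
from .model import GROUPS, ModelConfig, ModelHandle, build_model
from .train import FitResult, TrainConfig, fit, split_dataset

SCHEME_NAMES = ("E1", "E2", "E3", "classifier_only", "full_finetune")


@dataclass(frozen=True)
class TransferScheme:
    """Which parameter groups are frozen or re-initialized on the target."""

    name: str
    frozen_groups: frozenset = frozenset()
    reinit_groups: frozenset = frozenset()
    ft_learning_rate_factor: float = 0.1
    ft_epochs: int = 50
    stage1_epochs: int = 20

    def __post_init__(self) -> None:
        unknown = (set(self.frozen_groups) | set(self.reinit_groups)) - set(GROUPS)
        if unknown:
            raise ValueError(f"unknown parameter groups {sorted(unknown)}")
        overlap = set(self.frozen_groups) & set(self.reinit_groups)
        if overlap:
            raise ValueError(
                f"groups {sorted(overlap)} cannot be both frozen and re-initialized"
            )

    @classmethod
    def from_name(cls, name: str, **overrides) -> "TransferScheme":
        presets = {
            "E1": dict(reinit_groups=frozenset(GROUPS)),
            "E2": dict(frozen_groups=frozenset({"block1"})),
            "E3": dict(frozen_groups=frozenset({"block1", "block2"})),
            "classifier_only": dict(
                frozen_groups=frozenset({"block1", "block2"}),
                reinit_groups=frozenset({"classifier"}),
            ),
            "full_finetune": dict(),
        }
        if name not in presets:
            raise ValueError(
                f"unknown scheme {name!r}; expected one of {SCHEME_NAMES}"
            )
        return cls(name=name, **{**presets[name], **overrides})


def pretrain_source(
    cohort: list[EEGDataset],
    model_cfg: ModelConfig,
    train_cfg: TrainConfig,
    epochs: int | None = None,
) -> FitResult:
    """Train one source model on the pooled trials of all source subjects."""
    if not cohort:
        raise ValueError("source cohort is empty")
    pooled = concatenate(cohort)
    train, val, test = split_dataset(pooled, train_cfg)
    model = build_model(model_cfg, seed=train_cfg.seed)
    return fit(model, train, val, train_cfg, test=test, epochs=epochs)


def apply_scheme(
    source: ModelHandle, scheme: TransferScheme, seed: int
) -> ModelHandle:
    """Derive a target model from ``source`` under ``scheme``.

    The source is untouched; the copy has ``reinit_groups`` re-drawn from
    a seeded generator and ``frozen_groups`` marked non-trainable.
    """
    model = source.copy()
    rng = np.random.default_rng(seed)
    for group in GROUPS:  # fixed order keeps re-initialization deterministic
        if group in scheme.reinit_groups:
            model.reinit_group(group, rng)
    for group in GROUPS:
        model.set_group_trainable(group, group not in scheme.frozen_groups)
    return model


def finetune_target(
    adapted: ModelHandle,
    target: EEGDataset,
    scheme: TransferScheme,
    train_cfg: TrainConfig,
) -> FitResult:
    """Two-stage fine-tuning of an adapted model on a target subject.

    Stage 1 trains the classifier alone at the base learning rate for
    ``scheme.stage1_epochs``; stage 2 restores the scheme's trainable
    groups and continues for ``scheme.ft_epochs`` at the reduced rate.
    Either stage may be skipped by setting its epoch count to zero.
    """
    train, val, test = split_dataset(target, train_cfg)
    scheme_trainable = {
        g: (g not in scheme.frozen_groups) for g in GROUPS
    }

    histories: list[FitResult] = []
    if scheme.stage1_epochs > 0:
        for g in GROUPS:
            adapted.set_group_trainable(g, g == "classifier")
        histories.append(
            fit(adapted, train, val, train_cfg, epochs=scheme.stage1_epochs)
        )
    for g, flag in scheme_trainable.items():
        adapted.set_group_trainable(g, flag)
    if scheme.ft_epochs > 0:
        histories.append(
            fit(
                adapted, train, val, train_cfg,
                epochs=scheme.ft_epochs,
                learning_rate=train_cfg.learning_rate
                * scheme.ft_learning_rate_factor,
            )
        )

    logits = adapted.forward_logits(test.data) if test.n_trials else None
    test_acc = (
        float(np.mean(np.argmax(logits, axis=1) == test.labels))
        if logits is not None else None
    )
    if histories:
        result = FitResult(
            model=adapted,
            train_loss=np.concatenate([h.train_loss for h in histories]),
            train_accuracy=np.concatenate(
                [h.train_accuracy for h in histories]
            ),
            val_loss=np.concatenate([h.val_loss for h in histories]),
            val_accuracy=np.concatenate([h.val_accuracy for h in histories]),
            best_epoch=histories[-1].best_epoch,
            test_accuracy=test_acc,
        )
    else:  # zero-epoch protocol: evaluation only
        empty = np.zeros(0)
        result = FitResult(adapted, empty, empty, empty, empty, -1, test_acc)
    result.meta["scheme"] = scheme.name
    return result
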