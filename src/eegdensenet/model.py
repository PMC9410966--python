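"""The EEG-DenseNet compact CNN.

A two-block convolutional network for single-trial motor-imagery
classification, operating on a preprocessed ``(M, S)`` trial map:

* **Block 1** — a bank of T temporal filters (kernel ``(1, 64)``, same
  padding, linear), batch-normalized, followed by a depthwise *spatial*
  convolution spanning all M electrodes (kernel ``(M, 1)``, depth
  multiplier DP) that collapses the electrode axis, batch norm, ReLU,
  max pooling ``(1, 4)`` and dropout.  Output: ``(DP·T) × 1 × S/4``.
* **Block 2** — a separable convolution (depthwise temporal kernel
  ``(1, 16)`` + pointwise mix into P maps, same padding), batch norm,
  ReLU, max pooling ``(1, 6)`` and dropout.  Output: ``P × 1 × S/24``.
* **Classifier** — flatten to ``P·⌊S/24⌋`` features and a dense softmax
  layer over K classes under a max-norm 0.25 weight constraint.

The three named parameter groups ``block1``, ``block2`` and
``classifier`` are the units that transfer-learning schemes freeze or
re-initialize.
"""

from __future__ import annotations

import copy
import json
from dataclasses import dataclass, asdict
from pathlib import Path

import numpy as np

from . import layers as L


@dataclass(frozen=True)
class ModelConfig:
    """Architecture hyperparameters.

    Defaults follow the tuned configuration: T=8 temporal filters,
    depth multiplier DP=3, P=12 separable filters, dropout 0.6 in both
    blocks, and a max-norm 0.25 constraint on the classifier weights.
    """

    n_channels: int = 64          # M
    n_samples: int = 360          # S (6 s at 60 Hz after preprocessing)
    n_classes: int = 2            # K
    n_temporal_filters: int = 8   # T
    depth_multiplier: int = 3     # DP
    n_pointwise_filters: int = 12  # P
    temporal_kernel: int = 64
    separable_kernel: int = 16
    pool1: int = 4
    pool2: int = 6
    dropout1: float = 0.6
    dropout2: float = 0.6
    classifier_maxnorm: float = 0.25

    def __post_init__(self) -> None:
        counts = (
            self.n_channels, self.n_samples, self.n_classes,
            self.n_temporal_filters, self.depth_multiplier,
            self.n_pointwise_filters, self.temporal_kernel,
            self.separable_kernel, self.pool1, self.pool2,
        )
        if any(c <= 0 for c in counts):
            raise ValueError("all architecture counts must be positive")
        if self.n_samples < self.temporal_kernel:
            raise ValueError(
                f"S={self.n_samples} < temporal kernel {self.temporal_kernel}"
            )
        for d in (self.dropout1, self.dropout2):
            if not 0.0 <= d < 1.0:
                raise ValueError("dropout probabilities must be in [0, 1)")

    # closed-form shape arithmetic -----------------------------------------
    @property
    def block1_out_width(self) -> int:
        return self.n_samples // self.pool1

    @property
    def block2_out_width(self) -> int:
        return self.block1_out_width // self.pool2

    @property
    def n_features(self) -> int:
        """Flattened feature count feeding the classifier: P·⌊S/24⌋."""
        return self.n_pointwise_filters * self.block2_out_width

    def shape_summary(self) -> list[tuple[str, tuple[int, ...]]]:
        """Expected (maps, electrode, time) shape after each stage."""
        t, dp, p = (self.n_temporal_filters, self.depth_multiplier,
                    self.n_pointwise_filters)
        m, s = self.n_channels, self.n_samples
        return [
            ("input", (1, m, s)),
            ("temporal_conv", (t, m, s)),
            ("depthwise_conv", (dp * t, 1, s)),
            ("pool1", (dp * t, 1, s // self.pool1)),
            ("separable_conv", (p, 1, s // self.pool1)),
            ("pool2", (p, 1, self.block2_out_width)),
            ("flatten", (self.n_features,)),
            ("dense", (self.n_classes,)),
        ]


GROUPS = ("block1", "block2", "classifier")


class ModelHandle:
    """An instantiated network with named, freezable parameter groups."""

    def __init__(self, cfg: ModelConfig, layer_list: list[L.Layer],
                 groups: dict[str, list[str]]):
        self.cfg = cfg
        self.layers = layer_list
        self.groups = groups  # group name -> list of layer names
        self._by_name = {layer.name: layer for layer in layer_list}

    # -- plumbing ----------------------------------------------------------
    def layer(self, name: str) -> L.Layer:
        return self._by_name[name]

    def group_layers(self, group: str) -> list[L.Layer]:
        if group not in self.groups:
            raise KeyError(f"unknown parameter group {group!r}")
        return [self._by_name[n] for n in self.groups[group]]

    def parameters(self, trainable_only: bool = False):
        """Yield ``(qualified_name, array)`` over all parameters."""
        for layer in self.layers:
            if trainable_only and not layer.trainable:
                continue
            for pname, arr in layer.params.items():
                yield f"{layer.name}/{pname}", arr

    def gradients(self, trainable_only: bool = True):
        for layer in self.layers:
            if trainable_only and not layer.trainable:
                continue
            for pname, arr in layer.grads.items():
                yield f"{layer.name}/{pname}", arr

    def parameter_groups(self) -> dict[str, int]:
        """Trainable-scalar count per group; a partition of all parameters."""
        return {
            g: sum(layer.n_params() for layer in self.group_layers(g))
            for g in self.groups
        }

    def n_parameters(self, trainable_only: bool = False) -> int:
        return sum(
            layer.n_params() for layer in self.layers
            if layer.params and (layer.trainable or not trainable_only)
        )

    def set_group_trainable(self, group: str, flag: bool) -> None:
        for layer in self.group_layers(group):
            layer.trainable = flag

    def reinit_group(self, group: str, rng: np.random.Generator) -> None:
        for layer in self.group_layers(group):
            layer.init(rng)

    def copy(self) -> "ModelHandle":
        return copy.deepcopy(self)

    # -- computation -------------------------------------------------------
    def forward_logits(self, batch: np.ndarray, training: bool = False,
                       rng: np.random.Generator | None = None) -> np.ndarray:
        batch = np.asarray(batch, dtype=np.float64)
        if batch.ndim != 3 or batch.shape[1:] != (
            self.cfg.n_channels, self.cfg.n_samples
        ):
            raise ValueError(
                f"batch must be (B, {self.cfg.n_channels}, "
                f"{self.cfg.n_samples}), got {batch.shape}"
            )
        x = batch[:, None, :, :]
        for layer in self.layers:
            x = layer.forward(x, training=training, rng=rng)
        return x

    def forward(self, batch: np.ndarray, training: bool = False,
                rng: np.random.Generator | None = None) -> np.ndarray:
        """Class probabilities, one row per trial (rows sum to 1)."""
        if batch.shape[0] == 0:
            return np.zeros((0, self.cfg.n_classes))
        return L.softmax(self.forward_logits(batch, training=training, rng=rng))

    def backward(self, dlogits: np.ndarray) -> None:
        g = dlogits
        for layer in reversed(self.layers):
            g = layer.backward(g)

    def predict(self, batch: np.ndarray) -> np.ndarray:
        return np.argmax(self.forward(batch), axis=1)

    def apply_constraints(self) -> None:
        for layer in self.layers:
            if isinstance(layer, L.Dense) and layer.trainable:
                layer.apply_constraint()

    # -- persistence -------------------------------------------------------
    def state_dict(self) -> dict[str, np.ndarray]:
        state = {name: arr.copy() for name, arr in self.parameters()}
        for layer in self.layers:
            if isinstance(layer, L.BatchNorm):
                state[f"{layer.name}/running_mean"] = layer.running_mean.copy()
                state[f"{layer.name}/running_var"] = layer.running_var.copy()
        return state

    def load_state_dict(self, state: dict[str, np.ndarray]) -> None:
        for layer in self.layers:
            for pname in layer.params:
                layer.params[pname][...] = state[f"{layer.name}/{pname}"]
            if isinstance(layer, L.BatchNorm):
                layer.running_mean[...] = state[f"{layer.name}/running_mean"]
                layer.running_var[...] = state[f"{layer.name}/running_var"]

    def save(self, path: str | Path) -> Path:
        path = Path(path)
        np.savez(path, __config__=json.dumps(asdict(self.cfg)),
                 **self.state_dict())
        return path if path.suffix == ".npz" else path.with_suffix(
            path.suffix + ".npz"
        )


def load_model(path: str | Path) -> ModelHandle:
    with np.load(path, allow_pickle=False) as f:
        cfg = ModelConfig(**json.loads(str(f["__config__"])))
        model = build_model(cfg, seed=0)
        model.load_state_dict({k: f[k] for k in f.files if k != "__config__"})
    return model


def build_model(cfg: ModelConfig, seed: int) -> ModelHandle:
    """Instantiate the network with deterministic, seeded initialization."""
    t, dp, p = (cfg.n_temporal_filters, cfg.depth_multiplier,
                cfg.n_pointwise_filters)
    if cfg.block1_out_width < cfg.separable_kernel:
        raise ValueError(
            f"separable_conv: pooled width {cfg.block1_out_width} shorter "
            f"than kernel {cfg.separable_kernel}"
        )
    if cfg.block2_out_width < 1:
        raise ValueError(
            f"pool2: width {cfg.block1_out_width} shorter than pool {cfg.pool2}"
        )

    layer_list: list[L.Layer] = [
        L.TemporalConv(t, cfg.temporal_kernel, name="temporal_conv"),
        L.BatchNorm(t, name="bn1"),
        L.DepthwiseSpatialConv(t, dp, cfg.n_channels, name="depthwise_conv"),
        L.BatchNorm(dp * t, name="bn2"),
        L.ReLU(name="relu1"),
        L.MaxPoolTime(cfg.pool1, name="pool1"),
        L.Dropout(cfg.dropout1, name="dropout1"),
        L.SeparableConvTime(dp * t, p, cfg.separable_kernel,
                            name="separable_conv"),
        L.BatchNorm(p, name="bn3"),
        L.ReLU(name="relu2"),
        L.MaxPoolTime(cfg.pool2, name="pool2"),
        L.Dropout(cfg.dropout2, name="dropout2"),
        L.Flatten(name="flatten"),
        L.Dense(cfg.n_features, cfg.n_classes,
                maxnorm=cfg.classifier_maxnorm, name="dense"),
    ]
    groups = {
        "block1": ["temporal_conv", "bn1", "depthwise_conv", "bn2"],
        "block2": ["separable_conv", "bn3"],
        "classifier": ["dense"],
    }
    rng = np.random.default_rng(seed)
    for layer in layer_list:
        layer.init(rng)
    return ModelHandle(cfg, layer_list, groups)
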