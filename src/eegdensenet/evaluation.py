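"""Classification metrics, paired significance testing, and complexity.

Two metric conventions are exposed and always labeled in the report:

* ``mode="paper"`` — accuracy ``(TP+TN)/total``, sensitivity
  ``TP/(TP+FP)`` and specificity ``TN/(TN+FN)``.  The latter two place
  the *false positives* (resp. false negatives) in the denominator,
  which is **not** the conventional definition; they are kept verbatim
  because reproducing the published worked example requires them.
* ``mode="standard"`` — the conventional sensitivity ``TP/(TP+FN)`` and
  specificity ``TN/(TN+FP)``.

The two agree exactly whenever ``FP == FN``.

Cohen's kappa is computed from the confusion-matrix marginals; the mean
squared error is the Brier score between one-hot labels and predicted
class probabilities.  Model complexity is reported as one
multiply-accumulate (MAC) per kernel tap per output element for
convolutional and dense layers (normalization, pooling, activations and
dropout contribute no MACs under this convention), plus a per-layer
parameter census.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .dataset import LEFT
from .model import ModelConfig


class UndefinedMetricError(ZeroDivisionError):
    """A metric's denominator is zero for these counts."""


class DegenerateTestError(ValueError):
    """The paired t-test is undefined (zero-variance, nonzero-mean diffs)."""


@dataclass(frozen=True)
class ConfusionMatrix:
    """Binary confusion counts. ``positive`` records the class convention."""

    tp: int
    fn: int
    fp: int
    tn: int
    positive: int = LEFT

    def __post_init__(self) -> None:
        if min(self.tp, self.fn, self.fp, self.tn) < 0:
            raise ValueError("confusion counts must be non-negative")

    @property
    def total(self) -> int:
        return self.tp + self.fn + self.fp + self.tn

    def as_array(self) -> np.ndarray:
        """Rows = actual (positive, negative); columns = predicted."""
        return np.array([[self.tp, self.fn], [self.fp, self.tn]])


@dataclass(frozen=True)
class MetricsReport:
    accuracy: float
    sensitivity: float
    specificity: float
    kappa: float
    definitions_mode: str
    mse: float | None = None


def confusion(
    labels: np.ndarray, predictions: np.ndarray, positive: int = LEFT
) -> ConfusionMatrix:
    """Count binary confusion entries; ``positive`` defaults to left hand."""
    labels = np.asarray(labels)
    predictions = np.asarray(predictions)
    if labels.shape != predictions.shape or labels.ndim != 1:
        raise ValueError(
            f"labels {labels.shape} and predictions {predictions.shape} "
            "must be equal-length vectors"
        )
    values = set(np.unique(labels)) | set(np.unique(predictions))
    if not values <= {0, 1}:
        raise ValueError(f"labels must be binary (0/1), got {sorted(values)}")
    pos_l = labels == positive
    pos_p = predictions == positive
    return ConfusionMatrix(
        tp=int(np.sum(pos_l & pos_p)),
        fn=int(np.sum(pos_l & ~pos_p)),
        fp=int(np.sum(~pos_l & pos_p)),
        tn=int(np.sum(~pos_l & ~pos_p)),
        positive=positive,
    )


def cohens_kappa(cm: ConfusionMatrix) -> float:
    """Chance-corrected agreement from the matrix marginals."""
    n = cm.total
    if n == 0:
        raise UndefinedMetricError("empty confusion matrix")
    po = (cm.tp + cm.tn) / n
    pe = (
        (cm.tp + cm.fn) * (cm.tp + cm.fp)
        + (cm.fp + cm.tn) * (cm.fn + cm.tn)
    ) / (n * n)
    if pe == 1.0:
        return 1.0 if po == 1.0 else 0.0
    return (po - pe) / (1.0 - pe)


def brier_mse(labels: np.ndarray, probabilities: np.ndarray) -> float:
    """Mean squared error between one-hot labels and class probabilities."""
    labels = np.asarray(labels)
    probabilities = np.asarray(probabilities, dtype=np.float64)
    if probabilities.ndim != 2 or probabilities.shape[0] != labels.shape[0]:
        raise ValueError("probabilities must be (n, K) matching labels")
    onehot = np.zeros_like(probabilities)
    onehot[np.arange(labels.shape[0]), labels] = 1.0
    return float(np.mean(np.sum((onehot - probabilities) ** 2, axis=1)))


def metrics(
    cm: ConfusionMatrix,
    mode: str = "paper",
    probabilities: np.ndarray | None = None,
    labels: np.ndarray | None = None,
) -> MetricsReport:
    """Accuracy, sensitivity, specificity, kappa (and MSE if probs given)."""
    if mode not in ("paper", "standard"):
        raise ValueError(f"mode must be 'paper' or 'standard', got {mode!r}")
    if cm.total == 0:
        raise UndefinedMetricError("empty confusion matrix")
    accuracy = (cm.tp + cm.tn) / cm.total
    if mode == "paper":
        sens_den, spec_den = cm.tp + cm.fp, cm.tn + cm.fn
    else:
        sens_den, spec_den = cm.tp + cm.fn, cm.tn + cm.fp
    if sens_den == 0:
        raise UndefinedMetricError(
            f"sensitivity undefined in {mode} mode: denominator is 0"
        )
    if spec_den == 0:
        raise UndefinedMetricError(
            f"specificity undefined in {mode} mode: denominator is 0"
        )
    mse = None
    if probabilities is not None:
        if labels is None:
            raise ValueError("labels are required to compute the MSE")
        mse = brier_mse(labels, probabilities)
    return MetricsReport(
        accuracy=accuracy,
        sensitivity=cm.tp / sens_den,
        specificity=cm.tn / spec_den,
        kappa=cohens_kappa(cm),
        definitions_mode=mode,
        mse=mse,
    )


def paired_ttest(acc_a: np.ndarray, acc_b: np.ndarray) -> tuple[float, float]:
    """Two-sided paired t-test on per-subject accuracies.

    Identical vectors return ``(0.0, 1.0)``; zero-variance differences
    with a nonzero mean raise :class:`DegenerateTestError`.
    """
    a = np.asarray(acc_a, dtype=np.float64)
    b = np.asarray(acc_b, dtype=np.float64)
    if a.shape != b.shape or a.ndim != 1 or a.size < 2:
        raise ValueError("need two equal-length vectors of length >= 2")
    diff = a - b
    if np.all(diff == diff[0]):
        if diff[0] == 0.0:
            return 0.0, 1.0
        raise DegenerateTestError(
            "differences have zero variance and nonzero mean; "
            "the t statistic is unbounded"
        )
    t, p = stats.ttest_rel(a, b)
    return float(t), float(p)


# ---------------------------------------------------------------------------
# Complexity accounting
# ---------------------------------------------------------------------------

MAC_CONVENTION = (
    "one multiply-accumulate per kernel tap per output element for "
    "convolutional and dense layers; normalization, pooling, activation "
    "and dropout layers contribute zero MACs"
)


@dataclass
class LayerCost:
    name: str
    macs: int
    params: int


@dataclass
class ComplexityReport:
    layers: list[LayerCost] = field(default_factory=list)
    convention: str = MAC_CONVENTION

    @property
    def total_macs(self) -> int:
        return sum(c.macs for c in self.layers)

    @property
    def total_params(self) -> int:
        return sum(c.params for c in self.layers)

    @property
    def total_macs_millions(self) -> float:
        return self.total_macs / 1e6

    @property
    def total_params_millions(self) -> float:
        return self.total_params / 1e6

    def as_rows(self) -> list[tuple[str, int, int]]:
        return [(c.name, c.macs, c.params) for c in self.layers]


def conv_macs(n_filters: int, kernel: int, height: int, width: int) -> int:
    """Closed form for a 'same'-padded conv: f·k·H·W multiply-accumulates."""
    return n_filters * kernel * height * width


def complexity(cfg: ModelConfig) -> ComplexityReport:
    """Per-layer MAC and parameter accounting for the architecture."""
    t, dp, p = (cfg.n_temporal_filters, cfg.depth_multiplier,
                cfg.n_pointwise_filters)
    m, s, k = cfg.n_channels, cfg.n_samples, cfg.n_classes
    w1 = cfg.block1_out_width     # S / 4
    feats = cfg.n_features        # P * (S // 24)

    report = ComplexityReport()
    report.layers = [
        LayerCost(
            "temporal_conv",
            conv_macs(t, cfg.temporal_kernel, m, s),
            t * cfg.temporal_kernel + t,
        ),
        LayerCost("bn1", 0, 2 * t),
        # each of the DP*T output rows contracts all M electrodes
        LayerCost("depthwise_conv", dp * t * m * s, dp * t * m + dp * t),
        LayerCost("bn2", 0, 2 * dp * t),
        LayerCost("pool1", 0, 0),
        LayerCost(
            "separable_conv",
            dp * t * cfg.separable_kernel * w1 + p * dp * t * w1,
            dp * t * cfg.separable_kernel + p * dp * t + p,
        ),
        LayerCost("bn3", 0, 2 * p),
        LayerCost("pool2", 0, 0),
        LayerCost("dense", k * feats, k * feats + k),
    ]
    return report
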