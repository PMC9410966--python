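"""Labeled motor-imagery EEG trial container.

Trials are stored as a dense ``(N, M, S)`` array — N trials, M channels,
S samples per channel — together with per-trial class labels, the sampling
rate and channel names.  This is the in-memory map every other module
(preprocessing, the CNN, transfer learning, evaluation) consumes.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

#: Canonical class names; integer labels index into this tuple.
CLASS_NAMES: tuple[str, str] = ("left", "right")

LEFT, RIGHT = 0, 1


@dataclass
class EEGDataset:
    """A set of labeled motor-imagery EEG trials.

    Parameters
    ----------
    data:
        ``(N, M, S)`` float array of trial waveforms (µV-like units).
    labels:
        ``(N,)`` integer array; ``0`` = left hand, ``1`` = right hand.
    fs:
        Sampling rate in Hz.
    channel_names:
        M channel names; generated as ``CH000…`` when omitted.
    subject_id, cohort:
        Optional provenance; cohort is ``"patient"`` or ``"healthy"``.
    meta:
        Free-form processing history (e.g. the preprocessing config applied).
    """

    data: np.ndarray
    labels: np.ndarray
    fs: float
    channel_names: list[str] = field(default_factory=list)
    subject_id: str | None = None
    cohort: str | None = None
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=np.float64)
        self.labels = np.asarray(self.labels, dtype=np.int64)
        if self.data.ndim != 3:
            raise ValueError(
                f"data must be (N, M, S), got shape {self.data.shape}"
            )
        if self.labels.shape != (self.data.shape[0],):
            raise ValueError(
                f"labels length {self.labels.shape} does not match "
                f"N={self.data.shape[0]}"
            )
        if self.fs <= 0:
            raise ValueError("fs must be positive")
        if not self.channel_names:
            self.channel_names = [f"CH{i:03d}" for i in range(self.n_channels)]
        if len(self.channel_names) != self.n_channels:
            raise ValueError("channel_names length must equal M")

    # -- shape accessors ---------------------------------------------------
    @property
    def n_trials(self) -> int:
        return self.data.shape[0]

    @property
    def n_channels(self) -> int:
        return self.data.shape[1]

    @property
    def n_samples(self) -> int:
        return self.data.shape[2]

    def class_counts(self) -> dict[str, int]:
        return {
            name: int(np.sum(self.labels == i))
            for i, name in enumerate(CLASS_NAMES)
        }

    def select(self, idx: Sequence[int] | np.ndarray) -> "EEGDataset":
        """Return a new dataset restricted to trials ``idx`` (order kept)."""
        idx = np.asarray(idx, dtype=np.int64)
        return EEGDataset(
            data=self.data[idx],
            labels=self.labels[idx],
            fs=self.fs,
            channel_names=list(self.channel_names),
            subject_id=self.subject_id,
            cohort=self.cohort,
            meta=dict(self.meta),
        )

    def with_data(self, data: np.ndarray, fs: float | None = None) -> "EEGDataset":
        """Return a copy carrying new waveforms (labels untouched)."""
        return EEGDataset(
            data=data,
            labels=self.labels.copy(),
            fs=self.fs if fs is None else fs,
            channel_names=list(self.channel_names),
            subject_id=self.subject_id,
            cohort=self.cohort,
            meta=dict(self.meta),
        )


def concatenate(datasets: Sequence[EEGDataset]) -> EEGDataset:
    """Pool trials of several datasets sharing (M, S, fs)."""
    if not datasets:
        raise ValueError("need at least one dataset")
    first = datasets[0]
    for ds in datasets[1:]:
        if ds.data.shape[1:] != first.data.shape[1:] or ds.fs != first.fs:
            raise ValueError(
                "datasets are heterogeneous: "
                f"{ds.data.shape[1:]}@{ds.fs} vs {first.data.shape[1:]}@{first.fs}"
            )
    return EEGDataset(
        data=np.concatenate([ds.data for ds in datasets], axis=0),
        labels=np.concatenate([ds.labels for ds in datasets]),
        fs=first.fs,
        channel_names=list(first.channel_names),
        meta={"pooled_from": [ds.subject_id for ds in datasets]},
    )
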