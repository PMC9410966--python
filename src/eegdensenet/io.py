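"""Reading and writing trial datasets.

Two on-disk formats are supported:

* **HDF5** — the package's native container: datasets ``/data`` (N×M×S),
  ``/labels``, ``/fs`` and ``/channels``.  Lossless round trip.
* **EDF+C** — the clinical interchange format.  Trials are concatenated
  into a continuous record with an ``EDF Annotations`` signal marking
  each trial onset and its class label.  Samples are stored as 16-bit
  integers against a symmetric physical range, so a round trip is exact
  only up to one quantization step of that range.

The EDF writer is implemented here directly (16-bit records plus
time-stamped annotation lists); reading goes through :mod:`mne`, which
doubles as an independent check that the written files are conformant.
"""

from __future__ import annotations

import logging
import warnings
from pathlib import Path

import h5py
import numpy as np

from .dataset import CLASS_NAMES, EEGDataset

logger = logging.getLogger(__name__)

_EDF_DIG_MIN, _EDF_DIG_MAX = -32768, 32767


def write_dataset(ds: EEGDataset, path: str | Path, format: str = "hdf5",
                  rest_len: float = 0.0) -> Path:
    """Write ``ds`` to ``path`` in the requested format.

    ``rest_len`` (seconds) inserts a blank inter-trial gap in the
    continuous EDF export; it is ignored for HDF5, which stores epochs
    directly.
    """
    path = Path(path)
    if format == "hdf5":
        return _write_hdf5(ds, path)
    if format == "edf":
        return _write_edf(ds, path, rest_len=rest_len)
    raise ValueError(f"unknown format {format!r} (expected 'hdf5' or 'edf')")


def read_dataset(path: str | Path, format: str | None = None) -> EEGDataset:
    """Read a dataset written by :func:`write_dataset`."""
    path = Path(path)
    if format is None:
        format = "edf" if path.suffix.lower() == ".edf" else "hdf5"
    if format == "hdf5":
        return _read_hdf5(path)
    if format == "edf":
        return _read_edf(path)
    raise ValueError(f"unknown format {format!r}")


# ---------------------------------------------------------------------------
# HDF5
# ---------------------------------------------------------------------------

def _write_hdf5(ds: EEGDataset, path: Path) -> Path:
    with h5py.File(path, "w") as f:
        f.create_dataset("data", data=ds.data)
        f.create_dataset("labels", data=ds.labels)
        f.create_dataset("fs", data=float(ds.fs))
        f.create_dataset(
            "channels",
            data=np.array([c.encode() for c in ds.channel_names]),
        )
        if ds.subject_id is not None:
            f.attrs["subject_id"] = ds.subject_id
        if ds.cohort is not None:
            f.attrs["cohort"] = ds.cohort
    return path


def _read_hdf5(path: Path) -> EEGDataset:
    with h5py.File(path, "r") as f:
        data = f["data"][()]
        if data.size == 0:
            data = data.reshape(data.shape if data.ndim == 3 else (0, 0, 0))
        return EEGDataset(
            data=data,
            labels=f["labels"][()],
            fs=float(f["fs"][()]),
            channel_names=[c.decode() for c in f["channels"][()]],
            subject_id=f.attrs.get("subject_id"),
            cohort=f.attrs.get("cohort"),
        )


# ---------------------------------------------------------------------------
# EDF+C
# ---------------------------------------------------------------------------

def _ascii(value, width: int) -> bytes:
    s = str(value)
    if len(s) > width:
        raise ValueError(f"EDF header field {s!r} exceeds {width} bytes")
    return s.ljust(width).encode("ascii")


def _edf_number(x: float, width: int = 8) -> str:
    """Format a float into EDF's fixed-width ASCII number fields."""
    for fmt in (f"{x:.6g}", f"{x:.4g}", f"{x:.2g}", f"{x:.0f}"):
        if len(fmt) <= width:
            return fmt
    raise ValueError(f"cannot format {x} into {width} chars")


def _write_edf(ds: EEGDataset, path: Path, rest_len: float = 0.0) -> Path:
    fs = ds.fs
    if abs(fs - round(fs)) > 1e-9:
        raise ValueError("EDF export requires an integer sampling rate")
    fs = int(round(fs))
    n, m, s = ds.n_trials, ds.n_channels, ds.n_samples
    rest = int(round(rest_len * fs))
    stride = s + rest
    total = n * stride
    n_records = int(np.ceil(total / fs)) if total else 0

    # physical range: symmetric, covering the data; 16-bit quantization
    amax = float(np.max(np.abs(ds.data))) if ds.data.size else 1.0
    pmax = max(amax, 1e-6) * 1.000001  # guard against clipping the extremes
    if amax > 1e5:
        logger.warning(
            "EDF amplitude range %.3g exceeds typical µV scale; "
            "stored physical range widened accordingly", amax,
        )
    pmin = -pmax
    scale = (_EDF_DIG_MAX - _EDF_DIG_MIN) / (pmax - pmin)

    continuous = np.zeros((m, n_records * fs))
    for i in range(n):
        continuous[:, i * stride:i * stride + s] = ds.data[i]
    digital = np.clip(
        np.round((continuous - pmin) * scale + _EDF_DIG_MIN),
        _EDF_DIG_MIN, _EDF_DIG_MAX,
    ).astype("<i2")

    # --- annotations: one timekeeping TAL per record + trial-onset TALs ---
    record_tals: list[bytes] = []
    for r in range(n_records):
        tal = f"+{r}\x14\x14\x00".encode("ascii")
        for i in range(n):
            onset = i * stride / fs
            if r <= onset < r + 1:
                label = CLASS_NAMES[ds.labels[i]]
                tal += (
                    f"+{onset:g}\x15{s / fs:g}\x14{label}\x14\x00"
                ).encode("ascii")
        record_tals.append(tal)
    ann_bytes = max([len(t) for t in record_tals] + [32])
    ann_samples = (ann_bytes + 1) // 2  # 2 bytes per 16-bit "sample"

    n_signals = m + 1
    header = b"".join([
        _ascii("0", 8),
        _ascii("X X X X", 80),
        _ascii("Startdate 01-JAN-2000 X X X", 80),
        _ascii("01.01.00", 8),
        _ascii("00.00.00", 8),
        _ascii(256 * (n_signals + 1), 8),
        _ascii("EDF+C", 44),
        _ascii(n_records, 8),
        _ascii(1, 8),
        _ascii(n_signals, 4),
    ])

    labels = [c[:16] for c in ds.channel_names] + ["EDF Annotations"]
    fields = [
        (labels, 16),
        ([""] * n_signals, 80),                                   # transducer
        (["uV"] * m + [""], 8),                                   # phys dim
        ([_edf_number(pmin)] * m + ["-1"], 8),
        ([_edf_number(pmax)] * m + ["1"], 8),
        ([str(_EDF_DIG_MIN)] * n_signals, 8),
        ([str(_EDF_DIG_MAX)] * n_signals, 8),
        ([""] * n_signals, 80),                                   # prefilter
        ([str(fs)] * m + [str(ann_samples)], 8),
        ([""] * n_signals, 32),                                   # reserved
    ]
    for values, width in fields:
        header += b"".join(_ascii(v, width) for v in values)

    with open(path, "wb") as f:
        f.write(header)
        for r in range(n_records):
            f.write(digital[:, r * fs:(r + 1) * fs].tobytes())
            tal = record_tals[r]
            f.write(tal + b"\x00" * (2 * ann_samples - len(tal)))
    return path


def _read_edf(path: Path) -> EEGDataset:
    # peek at the record count so empty containers round-trip cleanly
    with open(path, "rb") as f:
        head = f.read(256)
        n_records = int(head[236:244].decode("ascii").strip())
        n_signals = int(head[252:256].decode("ascii").strip())
    if n_records == 0:
        return EEGDataset(
            data=np.zeros((0, n_signals - 1, 0)),
            labels=np.zeros(0, dtype=np.int64),
            fs=1.0,
        )

    import mne

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        raw = mne.io.read_raw_edf(path, preload=True, verbose="error")
    fs = raw.info["sfreq"]
    data = raw.get_data() * 1e6  # MNE scales µV channels to volts
    name_to_idx = {c: i for i, c in enumerate(CLASS_NAMES)}
    trials, labels = [], []
    for onset, duration, desc in zip(
        raw.annotations.onset,
        raw.annotations.duration,
        raw.annotations.description,
    ):
        if desc not in name_to_idx:
            continue
        start = int(round(onset * fs))
        length = int(round(duration * fs))
        trials.append(data[:, start:start + length])
        labels.append(name_to_idx[desc])
    if trials:
        out = np.stack(trials)
    else:
        out = np.zeros((0, data.shape[0], 0))
    return EEGDataset(
        data=out,
        labels=np.array(labels, dtype=np.int64),
        fs=fs,
        channel_names=list(raw.ch_names),
    )


def edf_quantization_step(ds: EEGDataset) -> float:
    """The physical value of one 16-bit step for ``ds``'s EDF export."""
    amax = float(np.max(np.abs(ds.data))) if ds.data.size else 1.0
    pmax = max(amax, 1e-6) * 1.000001
    return 2 * pmax / (_EDF_DIG_MAX - _EDF_DIG_MIN)
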