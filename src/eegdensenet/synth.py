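"""Synthetic motor-imagery EEG generator.

Emulates the acquisition statistics of a 64-channel, 960 Hz clinical
motor-imagery protocol with 6 s task epochs: each trial is a sum of

* power-law ("pink") background noise, independent per channel,
* a weak common-mode alpha oscillation shared by all channels,
* a lateralized sensorimotor rhythm — a mu-band oscillation plus its
  half-amplitude first harmonic (the arch-shaped mu waveform has strong
  power near 2×mu, i.e. in the beta band) — on two lateral channel
  groups, and
* an optional mains-frequency sinusoid.

Event-related desynchronization (ERD) is modeled multiplicatively: on the
channel group contralateral to the imagined hand the sensorimotor
amplitude is scaled by ``(1 - erd_depth)``.  Left-hand trials therefore
attenuate the right-hemisphere group and vice versa, which is the single
class-dependent feature of the simulation.

The generator is a pure function of its configuration: identical configs
(including the seed) produce bit-identical tensors.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .dataset import EEGDataset, LEFT, RIGHT


class ConfigurationError(ValueError):
    """Raised for invalid generator configurations."""


def _default_left_group() -> tuple[int, ...]:
    return tuple(range(8, 16))


def _default_right_group() -> tuple[int, ...]:
    return tuple(range(40, 48))


@dataclass
class SynthConfig:
    """Parameters of one simulated subject.

    Attributes
    ----------
    n_trials_per_class:
        Trials per class; the subject yields twice this many trials.
    n_channels, fs, trial_len:
        Montage size, sampling rate (Hz) and epoch length (s); defaults
        match a 64-channel, 960 Hz device recording 6 s task epochs.
    erd_depth:
        Fractional mu-amplitude reduction on the contralateral group,
        in [0, 1).  0 makes the two classes identically distributed.
    mu_freq:
        Sensorimotor rhythm fundamental (Hz); a half-amplitude harmonic
        at ``2*mu_freq`` is generated alongside it.
    snr_db:
        Power of the mu fundamental per lateral channel over the
        (unit-variance) broadband background, in dB.
    line_freq, line_amp:
        Mains interference frequency and amplitude relative to the mu
        amplitude (0 disables it).
    alpha_amp:
        Amplitude of the common-mode alpha component relative to mu.
        Kept weak by default so the lateral band-power contrast is not
        washed out by a shared in-band rhythm.
    beta_rel:
        Amplitude of the first mu harmonic relative to the fundamental.
    left_group, right_group:
        Disjoint channel-index sets carrying the lateralized rhythm
        (hand-motor-strip analogue; two blocks of 8 by default).
    seed:
        Seed for all randomness.
    """

    n_trials_per_class: int = 50
    n_channels: int = 64
    fs: float = 960.0
    trial_len: float = 6.0
    erd_depth: float = 0.6
    mu_freq: float = 10.0
    snr_db: float = 5.0
    line_freq: float = 50.0
    line_amp: float = 0.1
    alpha_amp: float = 0.05
    beta_rel: float = 0.5
    background_exponent: float = 2.0
    left_group: tuple[int, ...] = field(default_factory=_default_left_group)
    right_group: tuple[int, ...] = field(default_factory=_default_right_group)
    seed: int = 0

    def __post_init__(self) -> None:
        left, right = set(self.left_group), set(self.right_group)
        if left & right:
            raise ConfigurationError(
                f"left_group and right_group overlap: {sorted(left & right)}"
            )
        if not left or not right:
            raise ConfigurationError("channel groups must be non-empty")
        for g in (left, right):
            if min(g) < 0 or max(g) >= self.n_channels:
                raise ConfigurationError(
                    f"group indices {sorted(g)} outside [0, {self.n_channels})"
                )
        if not 0.0 <= self.erd_depth < 1.0:
            raise ConfigurationError("erd_depth must be in [0, 1)")
        n = self.fs * self.trial_len
        if abs(n - round(n)) > 1e-9:
            raise ConfigurationError(
                f"fs*trial_len = {n} is not an integer sample count"
            )
        if self.n_trials_per_class < 0 or self.n_channels <= 0:
            raise ConfigurationError("counts must be positive")

    @property
    def n_samples(self) -> int:
        return int(round(self.fs * self.trial_len))


def _pink_noise(rng: np.random.Generator, shape: tuple[int, ...],
                fs: float, exponent: float) -> np.ndarray:
    """Power-law noise along the last axis, normalized to unit variance.

    The power spectrum falls as ``1/f**exponent`` above 1 Hz and is flat
    below, which concentrates background power at low frequencies the way
    resting EEG spectra do.
    """
    n = shape[-1]
    white = rng.standard_normal(shape)
    spec = np.fft.rfft(white, axis=-1)
    f = np.fft.rfftfreq(n, d=1.0 / fs)
    shaping = np.clip(f, 1.0, None) ** (-exponent / 2.0)
    shaping[0] = 0.0  # no DC offset
    spec *= shaping
    x = np.fft.irfft(spec, n=n, axis=-1)
    sd = x.std(axis=-1, keepdims=True)
    sd[sd == 0] = 1.0
    return x / sd


def simulate_subject(cfg: SynthConfig) -> EEGDataset:
    """Generate one subject's balanced left/right motor-imagery trials.

    Returns ``2 * cfg.n_trials_per_class`` trials with labels in an
    interleaved deterministic order.  The contralateral sensorimotor
    amplitude is multiplied by ``(1 - cfg.erd_depth)``.
    """
    rng = np.random.default_rng(cfg.seed)
    n_per = cfg.n_trials_per_class
    n_trials = 2 * n_per
    m, s = cfg.n_channels, cfg.n_samples
    t = np.arange(s) / cfg.fs

    labels = np.tile([LEFT, RIGHT], n_per)

    data = _pink_noise(rng, (n_trials, m, s), cfg.fs, cfg.background_exponent)

    # mu fundamental amplitude from the per-channel SNR definition:
    # (A**2)/2 = 10**(snr_db/10) * var_background(=1)
    a_mu = np.sqrt(2.0 * 10.0 ** (cfg.snr_db / 10.0))

    # fixed per-subject channel gains inside each lateral group
    gains = {
        "left": rng.uniform(0.8, 1.2, size=len(cfg.left_group)),
        "right": rng.uniform(0.8, 1.2, size=len(cfg.right_group)),
    }

    for i in range(n_trials):
        # common-mode alpha on all channels (weak, class-independent)
        phi = rng.uniform(0, 2 * np.pi)
        data[i] += cfg.alpha_amp * a_mu * np.sin(
            2 * np.pi * cfg.mu_freq * t + phi
        )
        # lateralized sensorimotor rhythm: mu + half-amplitude harmonic
        amp_jitter = np.exp(rng.normal(0.0, 0.1))
        for side, idx in (("left", cfg.left_group), ("right", cfg.right_group)):
            phi1 = rng.uniform(0, 2 * np.pi)
            phi2 = rng.uniform(0, 2 * np.pi)
            osc = (
                np.sin(2 * np.pi * cfg.mu_freq * t + phi1)
                + cfg.beta_rel * np.sin(2 * np.pi * 2 * cfg.mu_freq * t + phi2)
            )
            # ERD: left-hand imagery suppresses the right hemisphere group
            contralateral = (labels[i] == LEFT and side == "right") or (
                labels[i] == RIGHT and side == "left"
            )
            amp = a_mu * amp_jitter * (
                1.0 - cfg.erd_depth if contralateral else 1.0
            )
            data[i, list(idx)] += amp * gains[side][:, None] * osc
        if cfg.line_amp > 0:
            phi = rng.uniform(0, 2 * np.pi)
            data[i] += cfg.line_amp * a_mu * np.sin(
                2 * np.pi * cfg.line_freq * t + phi
            )

    return EEGDataset(
        data=data,
        labels=labels,
        fs=cfg.fs,
        meta={"synth_config": cfg},
    )


def simulate_cohort(
    n_subjects: int,
    patient_fraction: float,
    base_cfg: SynthConfig,
    seed: int,
) -> list[EEGDataset]:
    """Simulate a cohort with subject-level variability.

    ``round(n_subjects * patient_fraction)`` subjects are flagged
    ``"patient"``; their mean ERD depth is 0.15 lower and their mu SNR
    3 dB lower than the base configuration, reflecting that patient EEG
    is noisier and carries weaker sensorimotor modulation.  Every subject
    additionally receives jitter of mu frequency (sd 0.5 Hz), SNR
    (sd 1 dB) and ERD depth (sd 0.05), all deterministic given ``seed``.
    """
    if not 0.0 <= patient_fraction <= 1.0:
        raise ConfigurationError("patient_fraction must be in [0, 1]")
    rng = np.random.default_rng(seed)
    n_patients = int(round(n_subjects * patient_fraction))
    cohorts = ["patient"] * n_patients + ["healthy"] * (n_subjects - n_patients)

    subjects: list[EEGDataset] = []
    for i, cohort in enumerate(cohorts):
        erd_shift = -0.15 if cohort == "patient" else 0.0
        snr_shift = -3.0 if cohort == "patient" else 0.0
        erd = np.clip(
            base_cfg.erd_depth + erd_shift + rng.normal(0.0, 0.05), 0.0, 0.95
        )
        cfg = replace(
            base_cfg,
            mu_freq=base_cfg.mu_freq + rng.normal(0.0, 0.5),
            snr_db=base_cfg.snr_db + snr_shift + rng.normal(0.0, 1.0),
            erd_depth=float(erd),
            seed=int(rng.integers(0, 2**31 - 1)),
        )
        ds = simulate_subject(cfg)
        ds.subject_id = f"S{i:03d}"
        ds.cohort = cohort
        subjects.append(ds)
    return subjects
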