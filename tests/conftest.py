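"""Shared fixtures.

The expensive end-to-end experiments (subject decodability, the transfer
comparison) run once per session and are shared between the unit tests
and the acceptance tests.  All randomness is seeded.
"""

from __future__ import annotations

from dataclasses import replace

import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import eegdensenet as ed

settings.register_profile(
    "default",
    deadline=None,
    derandomize=True,
    max_examples=25,
    suppress_health_check=[HealthCheck.filter_too_much, HealthCheck.too_slow],
)
settings.load_profile("default")


# 16-channel montage used for the reduced-scale training experiments
SMALL_LEFT = tuple(range(0, 4))
SMALL_RIGHT = tuple(range(12, 16))


def small_synth_cfg(**overrides) -> ed.SynthConfig:
    base = dict(
        n_trials_per_class=50,
        n_channels=16,
        left_group=SMALL_LEFT,
        right_group=SMALL_RIGHT,
        erd_depth=0.7,
        snr_db=5.0,
        seed=0,
    )
    base.update(overrides)
    return ed.SynthConfig(**base)


@pytest.fixture(scope="session")
def small_model_cfg() -> ed.ModelConfig:
    return ed.ModelConfig(n_channels=16, n_samples=360)


@pytest.fixture(scope="session")
def tiny_model_cfg() -> ed.ModelConfig:
    """A miniature architecture for fast capacity/gradient tests."""
    return ed.ModelConfig(
        n_channels=8, n_samples=72, temporal_kernel=16, separable_kernel=4,
        n_temporal_filters=4, depth_multiplier=2, n_pointwise_filters=6,
        dropout1=0.0, dropout2=0.0,
    )


@pytest.fixture(scope="session")
def decodability_results(small_model_cfg):
    """Test accuracies of per-subject training at ERD 0.7 and ERD 0.

    100 trials per subject, 16 channels, 60 training epochs, three seeds
    per condition — the reduced-scale recovery experiment.
    """
    out: dict[float, list[float]] = {}
    for erd in (0.7, 0.0):
        accs = []
        for seed in (0, 1, 2):
            ds = ed.simulate_subject(small_synth_cfg(erd_depth=erd, seed=seed))
            prep = ed.run_pipeline(ds)
            res = ed.fit_subject(
                prep, small_model_cfg, ed.TrainConfig(seed=seed), epochs=60
            )
            accs.append(res.test_accuracy)
        out[erd] = accs
    return out


@pytest.fixture(scope="session")
def transfer_experiment(small_model_cfg):
    """Source pretraining + E2/E3 fine-tuning on five target subjects."""
    base = small_synth_cfg(n_trials_per_class=40, erd_depth=0.6)
    cohort = [ed.run_pipeline(s) for s in ed.simulate_cohort(8, 0.0, base, seed=11)]
    sources, targets = cohort[:3], cohort[3:]
    tcfg = ed.TrainConfig(seed=0)
    src = ed.pretrain_source(sources, small_model_cfg, tcfg, epochs=40)

    per_scheme: dict[str, list[float]] = {}
    for name in ("E2", "E3"):
        scheme = ed.TransferScheme.from_name(
            name, stage1_epochs=15, ft_epochs=30
        )
        accs = []
        for i, tgt in enumerate(targets):
            adapted = ed.apply_scheme(src.model, scheme, seed=100 + i)
            res = ed.finetune_target(
                adapted, tgt, scheme, replace(tcfg, seed=200 + i)
            )
            accs.append(res.test_accuracy)
        per_scheme[name] = accs
    return {"source": src, "targets": targets, "accuracies": per_scheme}


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(1234)
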