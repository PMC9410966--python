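"""Transfer-scheme contracts: freezing, re-initialization, protocols."""

import numpy as np
import pytest

import eegdensenet as ed


def _subject(seed=0, n=24):
    rng = np.random.default_rng(seed)
    labels = np.arange(n) % 2
    data = rng.standard_normal((n, 8, 72))
    t = np.arange(72) / 60.0
    data[labels == 1] += 2 * np.sin(2 * np.pi * 10 * t)
    return ed.EEGDataset(data, labels, fs=60.0)


@pytest.fixture(scope="module")
def source_model(tiny_model_cfg):
    model = ed.build_model(tiny_model_cfg, seed=0)
    ds = _subject(0)
    ed.fit(model, ds, ds, ed.TrainConfig(seed=0, epochs=5))
    return model


class TestSchemeDefinitions:
    def test_presets(self):
        e1 = ed.TransferScheme.from_name("E1")
        assert e1.reinit_groups == {"block1", "block2", "classifier"}
        assert not e1.frozen_groups
        assert ed.TransferScheme.from_name("E2").frozen_groups == {"block1"}
        assert ed.TransferScheme.from_name("E3").frozen_groups == {
            "block1", "block2"
        }

    def test_frozen_and_reinit_disjoint(self):
        with pytest.raises(ValueError, match="both frozen and re-initialized"):
            ed.TransferScheme(
                name="bad",
                frozen_groups=frozenset({"block1"}),
                reinit_groups=frozenset({"block1"}),
            )

    def test_unknown_scheme_rejected(self):
        with pytest.raises(ValueError, match="unknown scheme"):
            ed.TransferScheme.from_name("E4")

    def test_unknown_group_rejected(self):
        with pytest.raises(ValueError, match="unknown parameter groups"):
            ed.TransferScheme(name="bad", frozen_groups=frozenset({"block9"}))


class TestApplyScheme:
    def test_trainable_counts_strictly_ordered(self, source_model):
        counts = {
            name: ed.apply_scheme(
                source_model, ed.TransferScheme.from_name(name), seed=0
            ).n_parameters(trainable_only=True)
            for name in ("E1", "E2", "E3")
        }
        assert counts["E1"] > counts["E2"] > counts["E3"]

    def test_e3_trains_classifier_only(self, source_model):
        adapted = ed.apply_scheme(
            source_model, ed.TransferScheme.from_name("E3"), seed=0
        )
        assert adapted.n_parameters(trainable_only=True) == (
            adapted.parameter_groups()["classifier"]
        )

    def test_source_untouched(self, source_model):
        before = source_model.state_dict()
        ed.apply_scheme(source_model, ed.TransferScheme.from_name("E1"), seed=1)
        after = source_model.state_dict()
        for k in before:
            np.testing.assert_array_equal(before[k], after[k])

    def test_e1_reinitializes_every_weight_tensor(self, source_model):
        adapted = ed.apply_scheme(
            source_model, ed.TransferScheme.from_name("E1"), seed=1
        )
        src = dict(source_model.parameters())
        for name, p in adapted.parameters():
            if p.size and p.any() and src[name].any():
                # multi-element weight tensors must differ after re-init
                if p.size > 4:
                    assert not np.allclose(p, src[name]), name

    def test_e2_copies_source_weights(self, source_model):
        adapted = ed.apply_scheme(
            source_model, ed.TransferScheme.from_name("E2"), seed=1
        )
        src = dict(source_model.parameters())
        for name, p in adapted.parameters():
            np.testing.assert_array_equal(p, src[name])


class TestFinetune:
    def test_frozen_groups_bit_identical_after_finetuning(self, source_model):
        scheme = ed.TransferScheme.from_name(
            "E2", stage1_epochs=2, ft_epochs=2
        )
        adapted = ed.apply_scheme(source_model, scheme, seed=0)
        before = {
            f"{layer.name}/{k}": v.copy()
            for layer in adapted.group_layers("block1")
            for k, v in list(layer.params.items())
        }
        bn_stats = {
            layer.name: (layer.running_mean.copy(), layer.running_var.copy())
            for layer in adapted.group_layers("block1")
            if hasattr(layer, "running_mean")
        }
        ed.finetune_target(adapted, _subject(5), scheme, ed.TrainConfig(seed=1))
        for layer in adapted.group_layers("block1"):
            for k, v in layer.params.items():
                np.testing.assert_array_equal(v, before[f"{layer.name}/{k}"])
            if hasattr(layer, "running_mean"):
                rm, rv = bn_stats[layer.name]
                np.testing.assert_array_equal(layer.running_mean, rm)
                np.testing.assert_array_equal(layer.running_var, rv)

    def test_zero_ft_rate_keeps_stage1_result(self, source_model):
        scheme = ed.TransferScheme.from_name(
            "E2", stage1_epochs=3, ft_epochs=3, ft_learning_rate_factor=0.0
        )
        adapted = ed.apply_scheme(source_model, scheme, seed=0)
        res = ed.finetune_target(
            adapted, _subject(6), scheme, ed.TrainConfig(seed=2)
        )
        # stage 2 ran at lr=0: validation accuracy constant across it
        stage2 = res.val_accuracy[3:]
        assert np.all(stage2 == stage2[0])

    def test_classifier_only_zero_epochs_is_linear_probe(self, source_model):
        scheme = ed.TransferScheme.from_name(
            "classifier_only", stage1_epochs=4, ft_epochs=0
        )
        adapted = ed.apply_scheme(source_model, scheme, seed=0)
        before_conv = {
            name: p.copy() for name, p in adapted.parameters()
            if not name.startswith("dense")
        }
        res = ed.finetune_target(
            adapted, _subject(7), scheme, ed.TrainConfig(seed=3)
        )
        assert len(res.train_loss) == 4
        for name, p in adapted.parameters():
            if not name.startswith("dense"):
                np.testing.assert_array_equal(p, before_conv[name])


class TestPretrain:
    def test_pooling_counts(self, tiny_model_cfg):
        cohort = [_subject(s) for s in range(3)]
        pooled = ed.concatenate(cohort)
        assert pooled.n_trials == sum(c.n_trials for c in cohort)

    def test_single_subject_equals_plain_fit(self, tiny_model_cfg):
        ds = _subject(9, n=40)
        cfg = ed.TrainConfig(seed=4)
        res_a = ed.pretrain_source([ds], tiny_model_cfg, cfg, epochs=3)
        train, val, test = ed.split_dataset(ds, cfg)
        model = ed.build_model(tiny_model_cfg, seed=cfg.seed)
        res_b = ed.fit(model, train, val, cfg, test=test, epochs=3)
        np.testing.assert_array_equal(res_a.train_loss, res_b.train_loss)
        assert res_a.test_accuracy == res_b.test_accuracy

    def test_heterogeneous_cohort_rejected(self, tiny_model_cfg):
        a = _subject(0)
        b = ed.EEGDataset(
            np.zeros((4, 6, 72)), np.array([0, 1, 0, 1]), fs=60.0
        )
        with pytest.raises(ValueError, match="heterogeneous"):
            ed.pretrain_source([a, b], tiny_model_cfg, ed.TrainConfig())

    def test_empty_cohort_rejected(self, tiny_model_cfg):
        with pytest.raises(ValueError, match="empty"):
            ed.pretrain_source([], tiny_model_cfg, ed.TrainConfig())
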