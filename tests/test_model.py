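import numpy as np
import pytest

from oralseg import nn
from oralseg.model import (ConfigError, ModelConfig, build_model,
                           load_checkpoint, save_checkpoint)
from oralseg.nn import Tensor

REDUCED = dict(embed_size=24, feature_dim=8, attention_window=(5, 5, 5),
               smamba_state_dim=8)
TINY = dict(embed_size=8, feature_dim=8, attention_window=(3, 3, 3),
            smamba_state_dim=4, num_classes=5)


class TestModelConfig:
    def test_stage_widths_double_from_embed_size(self):
        cfg = ModelConfig()
        assert cfg.stage_widths == (48, 96, 192, 384)

    def test_input_divisibility_is_validated_with_axis_named(self):
        cfg = ModelConfig(**REDUCED)
        with pytest.raises(ConfigError, match="axis 1"):
            cfg.validate_input_shape((64, 48, 64))
        cfg.validate_input_shape((64, 64, 64))
        cfg.validate_input_shape((32, 32, 32))

    def test_invalid_settings_rejected(self):
        with pytest.raises(ConfigError):
            ModelConfig(num_classes=1)
        with pytest.raises(ConfigError):
            ModelConfig(ablation="nope")
        with pytest.raises(ConfigError):
            ModelConfig(embed_size=10, feature_dim=8)


class TestBuildAndShapes:
    def test_seeded_builds_are_identical(self):
        m1 = build_model(ModelConfig(**TINY), seed=5)
        m2 = build_model(ModelConfig(**TINY), seed=5)
        for (k1, p1), (k2, p2) in zip(m1.named_parameters(),
                                      m2.named_parameters()):
            assert k1 == k2
            np.testing.assert_array_equal(p1.data, p2.data)

    def test_different_seeds_differ(self):
        m1 = build_model(ModelConfig(**TINY), seed=5)
        m2 = build_model(ModelConfig(**TINY), seed=6)
        diffs = [not np.array_equal(p1.data, p2.data)
                 for (_, p1), (_, p2) in zip(m1.named_parameters(),
                                             m2.named_parameters())
                 if p1.data.std() > 0]
        assert any(diffs)

    def test_encoder_pyramid_halves_resolution_per_stage(self):
        m = build_model(ModelConfig(**TINY), seed=0)
        x = Tensor(np.zeros((1, 1, 32, 32, 32), dtype=np.float32))
        with nn.no_grad():
            skips = m.encode(x)
        assert [s.shape for s in skips] == [
            (1, 8, 16, 16, 16), (1, 16, 8, 8, 8),
            (1, 32, 4, 4, 4), (1, 64, 2, 2, 2)]

    def test_forward_outputs_class_scores_on_the_input_grid(self, rng):
        m = build_model(ModelConfig(**TINY), seed=0)
        x = Tensor(rng.normal(size=(1, 1, 32, 32, 32)).astype(np.float32))
        with nn.no_grad():
            out = m.forward(x)
        assert out.shape == (1, 5, 32, 32, 32)
        assert out.numpy().min() >= 0.0 and out.numpy().max() <= 1.0
        # softmax head: voxelwise scores sum to one
        np.testing.assert_allclose(out.numpy().sum(axis=1), 1.0, atol=1e-5)

    def test_sigmoid_head_is_available(self, rng):
        m = build_model(ModelConfig(head_activation="sigmoid", **TINY), seed=0)
        x = Tensor(rng.normal(size=(1, 1, 32, 32, 32)).astype(np.float32))
        with nn.no_grad():
            out = m.forward(x).numpy()
        assert out.min() >= 0.0 and out.max() <= 1.0
        assert not np.allclose(out.sum(axis=1), 1.0)

    def test_inference_is_deterministic(self, rng):
        m = build_model(ModelConfig(**TINY), seed=1)
        x = rng.normal(size=(32, 32, 32)).astype(np.float32)
        np.testing.assert_array_equal(m.predict_scores(x),
                                      m.predict_scores(x))

    def test_batch_equivariance(self, rng):
        m = build_model(ModelConfig(**TINY), seed=1)
        a = rng.normal(size=(1, 1, 32, 32, 32)).astype(np.float32)
        b = rng.normal(size=(1, 1, 32, 32, 32)).astype(np.float32)
        with nn.no_grad():
            ab = m.forward(Tensor(np.concatenate([a, b]))).numpy()
            ba = m.forward(Tensor(np.concatenate([b, a]))).numpy()
        np.testing.assert_allclose(ab[0], ba[1], atol=2e-5)
        np.testing.assert_allclose(ab[1], ba[0], atol=2e-5)


class TestAblations:
    def test_component_census_is_consistent(self):
        full = build_model(ModelConfig(ablation="full", **TINY), seed=0)
        swin = build_model(ModelConfig(ablation="swin_only", **TINY), seed=0)
        smamba = build_model(ModelConfig(ablation="smamba_only", **TINY), seed=0)
        cf, cw, cm = (m.parameter_census() for m in (full, swin, smamba))
        # removing a branch removes exactly that branch's parameters
        assert cw["smamba"] == 0 and cm["swin"] == 0
        assert cf["swin"] == cw["swin"]
        assert cf["smamba"] == cm["smamba"]
        # decoder, embedding and head are shared across ablations
        for part in ("decoder", "embed", "head"):
            assert cf[part] == cw[part] == cm[part]
        assert cf["total"] > cw["total"] and cf["total"] > cm["total"]

    def test_ablations_accept_the_same_input(self, rng):
        x = Tensor(rng.normal(size=(1, 1, 32, 32, 32)).astype(np.float32))
        for ab in ("full", "swin_only", "smamba_only"):
            m = build_model(ModelConfig(ablation=ab, **TINY), seed=0)
            with nn.no_grad():
                assert m.forward(x).shape == (1, 5, 32, 32, 32)


class TestSwinProperties:
    def test_constant_input_stays_constant_without_shift(self, rng):
        """With shift disabled and windows dividing every stage grid, window
        attention, MLPs and patch merging are all constant-preserving."""
        cfg = ModelConfig(embed_size=8, feature_dim=8,
                          attention_window=(2, 2, 2), smamba_state_dim=4,
                          num_classes=5, ablation="swin_only",
                          coord_channels=False)
        m = build_model(cfg, seed=2)
        for stage in m.swin_stages:
            for block in stage:
                block.shifted = False
        x = Tensor(np.full((1, 1, 32, 32, 32), 0.7, dtype=np.float32))
        with nn.no_grad():
            skips = m.encode(x)
        for s in skips:
            flat = s.numpy().reshape(s.shape[1], -1) if s.shape[0] == 1 else None
            per_channel = s.numpy().reshape(1, s.shape[1], -1)[0]
            assert np.allclose(per_channel, per_channel[:, :1], atol=1e-4)

    def test_shifted_windows_change_the_features(self, rng):
        cfg = ModelConfig(**TINY, ablation="swin_only")
        m = build_model(cfg, seed=2)
        x = Tensor(rng.normal(size=(1, 1, 32, 32, 32)).astype(np.float32))
        with nn.no_grad():
            base = [s.numpy().copy() for s in m.encode(x)]
        for stage in m.swin_stages:
            for block in stage:
                block.shifted = False
        with nn.no_grad():
            unshifted = [s.numpy() for s in m.encode(x)]
        assert any(not np.allclose(a, b) for a, b in zip(base, unshifted))


class TestSMambaProperties:
    def test_closed_gate_reduces_to_the_conv_path(self, rng):
        from oralseg.model import SMambaBlock
        blk = SMambaBlock(4, 4, False, np.random.default_rng(0))
        blk.gate.bias.data[:] = -40.0   # sigmoid -> 0: scans contribute nothing
        x = Tensor(rng.normal(size=(1, 4, 8, 8, 8)).astype(np.float32))
        with nn.no_grad():
            out = blk(x).numpy()
            conv_only = (blk.conv1(x) + blk.conv3(x)).silu().numpy()
        np.testing.assert_allclose(out, conv_only, atol=1e-5)

    def test_tied_axis_scans_commute_with_axis_transposition(self, rng):
        from oralseg.model import SMambaBlock
        blk = SMambaBlock(3, 4, True, np.random.default_rng(1))
        u = Tensor(rng.normal(size=(1, 3, 4, 4, 4)).astype(np.float32))
        with nn.no_grad():
            s = (blk._scan_axis(u, 0) + blk._scan_axis(u, 1)
                 + blk._scan_axis(u, 2)).numpy()
            ut = Tensor(np.ascontiguousarray(
                u.numpy().transpose(0, 1, 4, 2, 3)))
            st = (blk._scan_axis(ut, 0) + blk._scan_axis(ut, 1)
                  + blk._scan_axis(ut, 2)).numpy()
        np.testing.assert_allclose(st, s.transpose(0, 1, 4, 2, 3), atol=1e-4)

    def test_tied_parameters_are_reported_once(self):
        from oralseg.model import SMambaBlock
        tied = SMambaBlock(4, 4, True, np.random.default_rng(0))
        untied = SMambaBlock(4, 4, False, np.random.default_rng(0))
        n_tied = sum(p.size for _, p in tied.named_parameters())
        n_untied = sum(p.size for _, p in untied.named_parameters())
        assert n_untied > n_tied


class TestGradientFlow:
    @pytest.mark.parametrize("ablation", ["full", "swin_only", "smamba_only"])
    def test_every_parameter_receives_gradient(self, rng, ablation):
        from oralseg.training import dice_ce_loss
        m = build_model(ModelConfig(ablation=ablation, **TINY), seed=0)
        x = Tensor(rng.normal(size=(1, 1, 32, 32, 32)).astype(np.float32))
        t = rng.integers(0, 5, size=(32, 32, 32))
        loss = dice_ce_loss(m.forward_logits(x), t)
        loss.backward()
        dead = [k for k, p in m.named_parameters()
                if p.grad is None or float(np.abs(p.grad).sum()) == 0.0]
        assert dead == []


class TestCheckpoints:
    def test_save_load_round_trip(self, tmp_path, rng):
        from oralseg.label_scheme import default_scheme
        m = build_model(ModelConfig(**TINY), seed=3)
        path = save_checkpoint(m, tmp_path / "ckpt.npz",
                               extra={"note": "test"},
                               scheme_json=default_scheme().to_json())
        m2, sidecar = load_checkpoint(path)
        assert sidecar["extra"]["note"] == "test"
        assert len(sidecar["label_scheme"]) == 36
        x = rng.normal(size=(32, 32, 32)).astype(np.float32)
        np.testing.assert_array_equal(m.predict_scores(x),
                                      m2.predict_scores(x))
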