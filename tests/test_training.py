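import numpy as np
import pytest

from oralseg.model import ModelConfig, build_model
from oralseg.nn import Tensor
from oralseg.phantom import PhantomSpec, generate_phantom
from oralseg.training import (TrainConfig, dice_ce_loss, fit, lr_schedule,
                              split_dataset)

TINY_MODEL = dict(embed_size=8, feature_dim=8, attention_window=(3, 3, 3),
                  smamba_state_dim=4)


class TestSplitDataset:
    def test_study_split_sizes(self):
        tr, va, te = split_dataset(list(range(100)), (0.70, 0.20, 0.10), seed=0)
        assert (len(tr), len(va), len(te)) == (70, 20, 10)

    def test_small_cohort_rounding_with_remainder_to_training(self):
        tr, va, te = split_dataset(list(range(10)), (0.70, 0.20, 0.10), seed=1)
        assert (len(tr), len(va), len(te)) == (7, 2, 1)

    def test_partition_is_disjoint_and_exhaustive(self):
        ids = [f"case{i}" for i in range(23)]
        tr, va, te = split_dataset(ids, (0.70, 0.20, 0.10), seed=3)
        assert set(tr) | set(va) | set(te) == set(ids)
        assert not (set(tr) & set(va) or set(tr) & set(te) or set(va) & set(te))

    def test_same_seed_reproduces_the_partition(self):
        a = split_dataset(list(range(50)), (0.7, 0.2, 0.1), seed=9)
        b = split_dataset(list(range(50)), (0.7, 0.2, 0.1), seed=9)
        assert a == b

    def test_too_few_cases_is_an_error(self):
        with pytest.raises(ValueError):
            split_dataset([1, 2], (0.7, 0.2, 0.1), seed=0)

    def test_fractions_must_sum_to_one(self):
        with pytest.raises(ValueError):
            split_dataset(list(range(10)), (0.5, 0.2, 0.1), seed=0)


class TestDiceCELoss:
    def test_uniform_predictor_cross_entropy_is_log_37(self, rng):
        logits = Tensor(np.zeros((1, 37, 4, 4, 4), dtype=np.float32))
        target = rng.integers(0, 37, size=(4, 4, 4))
        ce_only = dice_ce_loss(logits, target, weights=(0.0, 1.0))
        assert float(ce_only.data) == pytest.approx(np.log(37), abs=1e-6)

    def test_one_hot_correct_prediction_has_zero_dice_term(self, rng):
        target = rng.integers(0, 5, size=(4, 4, 4))
        onehot = np.zeros((1, 5, 4, 4, 4), dtype=np.float32)
        np.put_along_axis(onehot, target[None, None], 1.0, axis=1)
        logits = Tensor(np.log(onehot * (1 - 1e-7) + 1e-7) * 30.0)
        dice_only = dice_ce_loss(logits, target, weights=(1.0, 0.0))
        assert float(dice_only.data) == pytest.approx(0.0, abs=1e-6)

    def test_matches_hand_computed_soft_dice_plus_ce(self, rng):
        """Brute-force oracle on a random 4-cube: per-class soft Dice and
        voxel-mean cross-entropy computed with explicit loops."""
        C = 3
        logits_np = rng.normal(size=(1, C, 4, 4, 4)).astype(np.float32)
        target = rng.integers(0, C, size=(4, 4, 4))
        got = float(dice_ce_loss(Tensor(logits_np), target,
                                 weights=(1.0, 1.0), smooth=1e-5).data)
        # oracle
        z = logits_np[0].astype(np.float64)
        e = np.exp(z - z.max(axis=0))
        p = e / e.sum(axis=0)
        ce = 0.0
        for i in range(4):
            for j in range(4):
                for k in range(4):
                    ce -= np.log(p[target[i, j, k], i, j, k])
        ce /= 64
        dice_sum = 0.0
        for c in range(C):
            t = (target == c).astype(float)
            inter = (p[c] * t).sum()
            dice_sum += (2 * inter + 1e-5) / (p[c].sum() + t.sum() + 1e-5)
        expected = (1 - dice_sum / C) + ce
        assert got == pytest.approx(expected, rel=1e-4)

    def test_loss_is_nonnegative(self, rng):
        for _ in range(5):
            logits = Tensor(rng.normal(size=(1, 4, 4, 4, 4)).astype(np.float32))
            target = rng.integers(0, 4, size=(4, 4, 4))
            assert float(dice_ce_loss(logits, target).data) >= 0.0

    def test_shape_mismatch_is_contract_error(self, rng):
        logits = Tensor(np.zeros((1, 4, 4, 4, 4), dtype=np.float32))
        with pytest.raises(ValueError, match="shape"):
            dice_ce_loss(logits, np.zeros((5, 5, 5), dtype=int))

    def test_target_class_out_of_range_rejected(self):
        logits = Tensor(np.zeros((1, 4, 4, 4, 4), dtype=np.float32))
        with pytest.raises(ValueError, match="class"):
            dice_ce_loss(logits, np.full((4, 4, 4), 7))


class TestLRSchedule:
    CFG = TrainConfig(lr=1e-5, epochs=61, warmup_epochs=10)

    def test_ramp_starts_at_zero(self):
        assert lr_schedule(0, self.CFG) == 0.0

    def test_peak_at_warmup_end(self):
        assert lr_schedule(10, self.CFG) == pytest.approx(1e-5)

    def test_half_peak_at_cosine_midpoint(self):
        # span = 61 - 1 - 10 = 50 epochs; midpoint at epoch 35
        assert lr_schedule(35, self.CFG) == pytest.approx(0.5e-5)

    def test_decays_to_zero_at_the_final_epoch(self):
        assert lr_schedule(60, self.CFG) == pytest.approx(0.0, abs=1e-12)

    def test_monotone_ramp_then_monotone_decay(self):
        lrs = [lr_schedule(e, self.CFG) for e in range(61)]
        assert all(b >= a for a, b in zip(lrs[:10], lrs[1:11]))
        assert all(b <= a for a, b in zip(lrs[10:-1], lrs[11:]))

    def test_epoch_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            lr_schedule(61, self.CFG)


@pytest.fixture(scope="module")
def tiny_cohort():
    return [generate_phantom(PhantomSpec(grid_shape=(32, 32, 32),
                                         spacing_mm=1.2, seed=s))
            for s in (5, 6)]


class TestFit:
    def _cfg(self, **kw):
        base = dict(lr=1e-3, epochs=3, patch=(32, 32, 32), warmup_epochs=1,
                    seed=4, val_every=10, weight_decay=0.0)
        base.update(kw)
        return TrainConfig(**base)

    def test_curves_are_finite_and_full_length(self, tiny_cohort):
        model = build_model(ModelConfig(**TINY_MODEL), seed=0)
        res = fit(model, tiny_cohort, self._cfg())
        assert len(res.curves.train_loss) == 3
        assert len(res.curves.val_dice) == 3
        assert np.isfinite(res.curves.train_loss).all()
        assert np.isfinite(res.curves.val_loss).all()

    def test_fixed_seed_reproduces_the_curves(self, tiny_cohort):
        r1 = fit(build_model(ModelConfig(**TINY_MODEL), seed=0),
                 tiny_cohort, self._cfg())
        r2 = fit(build_model(ModelConfig(**TINY_MODEL), seed=0),
                 tiny_cohort, self._cfg())
        assert r1.curves.train_loss == r2.curves.train_loss
        assert r1.curves.val_dice == r2.curves.val_dice

    def test_resume_reproduces_the_uninterrupted_run(self, tiny_cohort,
                                                     tmp_path):
        cfg = self._cfg(epochs=6, checkpoint_every=3)
        full = fit(build_model(ModelConfig(**TINY_MODEL), seed=0),
                   tiny_cohort, cfg, out_dir=tmp_path / "full")
        # restart from the run's own mid-point checkpoint (epoch 2): the
        # restored weights, optimiser moments and RNG state must reproduce
        # epochs 3..5 bitwise
        resumed = fit(build_model(ModelConfig(**TINY_MODEL), seed=0),
                      tiny_cohort, cfg,
                      resume_from=tmp_path / "full" / "epoch_0002.npz")
        assert resumed.curves.train_loss == full.curves.train_loss
        assert resumed.curves.train_dice == full.curves.train_dice

    def test_empty_cohort_rejected(self):
        with pytest.raises(ValueError):
            fit(build_model(ModelConfig(**TINY_MODEL), seed=0), [],
                self._cfg())

    def test_checkpoints_and_curves_written(self, tiny_cohort, tmp_path):
        cfg = self._cfg(epochs=2, checkpoint_every=1)
        fit(build_model(ModelConfig(**TINY_MODEL), seed=0), tiny_cohort, cfg,
            out_dir=tmp_path)
        assert (tmp_path / "best.npz").exists()
        assert (tmp_path / "last.npz").exists()
        assert (tmp_path / "curves.csv").exists()
        assert (tmp_path / "epoch_0000.npz").exists()

    def test_ablation_arms_see_the_same_data_stream(self, tiny_cohort,
                                                    monkeypatch):
        """With one seed, the patch/augment draws are identical across
        ablation settings."""
        import oralseg.training as T
        seen = {}

        orig = T.sample_patch

        def record(v, lv, patch, seed=None, rng=None):
            out = orig(v, lv, patch, seed=seed, rng=rng)
            seen.setdefault(key, []).append(out[0].data.sum())
            return out

        monkeypatch.setattr(T, "sample_patch", record)
        for key in ("full", "swin_only"):
            fit(build_model(ModelConfig(ablation=key, **TINY_MODEL), seed=0),
                tiny_cohort, self._cfg(epochs=2))
        assert seen["full"] == seen["swin_only"]
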