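import numpy as np
import pytest

from planct import model
from planct.diffeo import folding_fraction, integrate_velocity
from planct.errors import TrainingDivergedError
from planct.losses import LossWeights
from planct.nn import autograd as ag
from planct.phantom import PhantomSpec, make_dataset, make_phantom
from planct.volumes import ScalarVolume, VolumeGrid


def tiny_cfg(**overrides):
    """Smallest config that exercises the full loop (16^3, 3 levels)."""
    params = dict(
        patch_size=16,
        generator=model.GeneratorConfig(levels=3, base_channels=2,
                                        max_channels=8),
        discriminator=model.DiscriminatorConfig(layers=2, base_channels=2,
                                                max_channels=8),
        n_integration_steps=3,
    )
    params.update(overrides)
    return model.desk_train_config(**params)


@pytest.fixture(scope="module")
def tiny_cases():
    grid = VolumeGrid((16, 16, 16), (2.5, 2.5, 2.5))
    return make_dataset(2, base_seed=100, grid=grid)


class TestConfigs:
    def test_patch_divisibility_enforced(self):
        with pytest.raises(ValueError):
            model.TrainConfig(patch_size=48,
                              generator=model.GeneratorConfig(levels=7))

    def test_round_trip_dict(self):
        cfg = model.desk_train_config(epochs=3, seed=9)
        back = model.TrainConfig.from_dict(cfg.to_dict())
        assert back == cfg

    def test_epochs_validated(self):
        with pytest.raises(ValueError):
            model.desk_train_config(epochs=0)


class TestPatchSampling:
    def test_zero_ranges_deterministic_centered_crop(self, phantom_case_48):
        cfg = model.desk_train_config(patch_size=32)
        src1, tgt1, rec = model.sample_training_patch(
            phantom_case_48, cfg, np.random.default_rng(0))
        src2, _, _ = model.sample_training_patch(
            phantom_case_48, cfg, np.random.default_rng(99))
        np.testing.assert_array_equal(src1.values, src2.values)
        assert rec["shift_mm"] == [0.0, 0.0, 0.0]
        assert rec["rotation_deg"] == 0.0

    def test_same_rng_state_identical_patches(self, phantom_case_48):
        cfg = model.desk_train_config(patch_size=32,
                                      shift_range_mm=(-10.0, 10.0),
                                      rotation_range_deg=(-10.0, 10.0))
        a = model.sample_training_patch(phantom_case_48, cfg,
                                        np.random.default_rng(5))
        b = model.sample_training_patch(phantom_case_48, cfg,
                                        np.random.default_rng(5))
        np.testing.assert_array_equal(a[0].values, b[0].values)
        assert a[2] == b[2]

    def test_rotation_preserves_cylinder_symmetric_volume(self):
        # a volume invariant under rotation about z changes only by
        # interpolation error
        grid = VolumeGrid((32, 32, 32), (2.0, 2.0, 2.0))
        x, y, z = grid.coordinates()
        cx = grid.extent_mm[0] / 2.0
        r = np.sqrt((x - cx) ** 2 + (y - cx) ** 2)
        vol = ScalarVolume(grid, 100.0 * np.exp(-r / 20.0) + z)
        cfg = model.desk_train_config(patch_size=32,
                                      rotation_range_deg=(10.0, 10.0))
        patch, _, rec = model.sample_training_patch((vol, vol), cfg,
                                                    np.random.default_rng(0))
        assert rec["rotation_deg"] == pytest.approx(10.0)
        inside = r < 20.0
        assert np.abs(patch.values - vol.values)[inside].max() < 2.0

    def test_volume_smaller_than_patch_rejected(self, phantom_case_48):
        cfg = model.desk_train_config(patch_size=64)
        with pytest.raises(ValueError):
            model.sample_training_patch(phantom_case_48, cfg,
                                        np.random.default_rng(0))


class TestGeneratorForward:
    def test_velocity_field_contract(self, phantom_case_48):
        cfg = model.desk_train_config()
        gen = model.build_generator(cfg.generator, np.random.default_rng(0))
        src, _, _ = model.sample_training_patch(phantom_case_48, cfg,
                                                np.random.default_rng(0))
        from planct.preprocess import normalize_intensity

        v = model.generator_forward(gen, normalize_intensity(src))
        assert v.vectors.shape == src.grid.shape + (3,)
        assert np.all(np.isfinite(v.vectors))


class TestTrain:
    def test_smoke_history_contract(self, tiny_cases):
        cfg = tiny_cfg(epochs=2)
        gen, disc, history = model.train(tiny_cases, cfg)
        assert len(history) == 2 * len(tiny_cases)
        for row in history:
            for key in ("d_loss", "adv", "sim", "fid", "smooth", "total"):
                assert np.isfinite(row[key])

    def test_zero_weights_adversarial_only(self, tiny_cases):
        cfg = tiny_cfg(epochs=1, weights=LossWeights(0.0, 0.0, 0.0))
        _, _, history = model.train(tiny_cases, cfg)
        for row in history:
            assert row["total"] == pytest.approx(row["adv"], rel=1e-5)
            assert "sim" in row and "fid" in row and "smooth" in row

    def test_seeded_training_reproducible(self, tiny_cases):
        cfg = tiny_cfg(epochs=2, seed=3)
        _, _, h1 = model.train(tiny_cases, cfg)
        _, _, h2 = model.train(tiny_cases, cfg)
        assert h1 == h2

    def test_empty_dataset_rejected(self):
        with pytest.raises(ValueError):
            model.train([], tiny_cfg())

    def test_divergence_raises_with_state(self, tiny_cases):
        cfg = tiny_cfg(epochs=1, learning_rate_g=1e12)
        try:
            model.train(tiny_cases * 4, cfg)
        except TrainingDivergedError as exc:
            assert "step" in exc.state
        # divergence is not guaranteed even at an absurd rate; finishing
        # without NaN is acceptable

    def test_end_to_end_gradients_finite(self, tiny_cases):
        # one full objective evaluation produces finite gradients for every
        # generator parameter
        cfg = tiny_cfg(epochs=1)
        gen, _, _ = model.train(tiny_cases, cfg)
        for p in gen.parameters():
            assert np.all(np.isfinite(p.data))


class TestSynthesize:
    def _zeroed_generator(self, cfg):
        gen = model.build_generator(cfg.generator, np.random.default_rng(0))
        gen.head.weight.data[:] = 0.0
        gen.head.bias.data[:] = 0.0
        return gen

    def test_zero_velocity_returns_input_bit_exact(self, phantom_case_48):
        cfg = model.desk_train_config()
        gen = self._zeroed_generator(cfg)
        dct = phantom_case_48.dct
        sct, dvf = model.synthesize(gen, dct, cfg)
        assert np.array_equal(sct.values, dct.values)
        assert np.all(dvf.vectors == 0.0)

    def test_hu_provenance_interpolation_hull(self, phantom_case_48):
        cfg = model.desk_train_config()
        gen = model.build_generator(cfg.generator, np.random.default_rng(4))
        dct = phantom_case_48.dct
        sct, _ = model.synthesize(gen, dct, cfg)
        assert sct.values.max() <= dct.values.max() + 1e-6
        assert sct.values.min() >= dct.values.min() - 1e-6

    def test_folding_free_for_random_generator(self, phantom_case_48):
        cfg = model.desk_train_config()
        gen = model.build_generator(cfg.generator, np.random.default_rng(11))
        _, dvf = model.synthesize(gen, phantom_case_48.dct, cfg)
        assert folding_fraction(dvf) == 0.0

    def test_tiled_inference_covers_larger_volume(self, phantom_case_48):
        cfg = model.desk_train_config(patch_size=32)
        gen = self._zeroed_generator(cfg)
        sct, dvf = model.synthesize(gen, phantom_case_48.dct, cfg)
        assert np.array_equal(sct.values, phantom_case_48.dct.values)

    def test_incompatible_patch_size_rejected(self, phantom_case_48):
        cfg = model.desk_train_config()
        gen = model.build_generator(
            model.GeneratorConfig(levels=6, base_channels=2),
            np.random.default_rng(0))
        with pytest.raises(ValueError):
            model.synthesize(gen, phantom_case_48.dct, cfg)


class TestCheckpoint:
    def test_round_trip(self, tmp_path, tiny_cases):
        cfg = tiny_cfg(epochs=1)
        gen, disc, _ = model.train(tiny_cases, cfg)
        model.save_checkpoint(tmp_path / "ck.npz", gen, disc, cfg,
                              extra={"note": "test"})
        gen2, disc2, cfg2, meta = model.load_checkpoint(tmp_path / "ck.npz")
        assert cfg2 == cfg
        assert meta["note"] == "test"
        for a, b in zip(gen.parameters(), gen2.parameters()):
            np.testing.assert_array_equal(a.data, b.data)


def test_training_loss_path_matches_reference_losses(phantom_case_48):
    """The differentiable loss graph agrees with the numpy loss definitions."""
    from planct.diffeo import VelocityField
    from planct.losses import (ContrastWindow, curvature_regularizer,
                               image_similarity_loss, contrast_fidelity_loss)
    from planct.volumes import warp

    cfg = model.desk_train_config()
    gen = model.build_generator(cfg.generator, np.random.default_rng(2))
    case = phantom_case_48
    src, tgt, _ = model.sample_training_patch(case, cfg,
                                              np.random.default_rng(0))
    spacing = src.grid.spacing
    src_n = model._normalize_array(src.values, cfg.normalization_window)
    v = gen(ag.constant(src_n[np.newaxis].astype(np.float32)))
    u = model._integrate_diff(v, spacing, cfg.n_integration_steps)
    warped = model._warp_diff(
        ag.constant(src.values[np.newaxis].astype(np.float32)), u, spacing)
    sim_graph = model._l1_diff(
        warped, ag.constant(tgt.values[np.newaxis].astype(np.float32))).item()
    smooth_graph = model._curvature_diff(v, spacing).item()

    vf = VelocityField(src.grid,
                       np.moveaxis(v.data.astype(np.float64), 0, -1))
    u_ref = integrate_velocity(vf, cfg.n_integration_steps)
    warped_ref = warp(src, u_ref)
    sim_ref = image_similarity_loss(warped_ref, tgt)
    smooth_ref = curvature_regularizer(vf)

    assert sim_graph == pytest.approx(sim_ref, rel=1e-3)
    assert smooth_graph == pytest.approx(smooth_ref, rel=1e-3, abs=1e-6)
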