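import numpy as np
import pytest

import virtualstain as vs
from virtualstain import nn
from conftest import STUDY_DSPEC, STUDY_GSPEC, STUDY_LR, crop_all, scene_pairs


class TestGenerator:
    def test_bottleneck_size_is_patch_over_2_pow_depth(self):
        gen = vs.build_generator(vs.GeneratorSpec(depth=4, base_filters=4), seed=0)
        x = np.zeros((1, 1, 256, 256))
        feats = [gen.enc0.forward(x, train=False)]
        cur = feats[0]
        for blk in gen.enc_blocks:
            cur = blk.forward(cur, train=False)
        assert cur.shape[2:] == (16, 16)  # 256 / 2**4

    def test_output_in_tanh_range_and_same_size(self):
        rng = np.random.default_rng(0)
        gen = vs.build_generator(vs.GeneratorSpec(in_channels=2, depth=3,
                                                  base_filters=4), seed=1)
        y = gen.forward(rng.normal(size=(2, 2, 32, 32)) * 3, train=True)
        assert y.shape == (2, 1, 32, 32)
        assert y.min() >= -1.0 and y.max() <= 1.0

    def test_build_is_deterministic_given_seed(self):
        spec = vs.GeneratorSpec(depth=3, base_filters=4)
        g1 = vs.build_generator(spec, seed=7)
        g2 = vs.build_generator(spec, seed=7)
        for k, v in g1.params().items():
            np.testing.assert_array_equal(v, g2.params()[k])

    def test_indivisible_patch_size_rejected(self):
        gen = vs.build_generator(vs.GeneratorSpec(depth=3, base_filters=4), seed=0)
        with pytest.raises(vs.SpecError):
            gen.forward(np.zeros((1, 1, 36, 36)))

    def test_generator_gradient_matches_finite_difference(self):
        rng = np.random.default_rng(3)
        gen = vs.build_generator(vs.GeneratorSpec(depth=2, base_filters=4), seed=2)
        x = rng.normal(size=(2, 1, 8, 8)) * 0.5
        t = rng.uniform(-1, 1, size=(2, 1, 8, 8))
        gen.zero_grads()
        out = gen.forward(x, train=True)
        gen.backward(np.sign(out - t) / out.size)
        grads, params = gen.grads(), gen.params()
        for key in ("enc0/W", "final/1/W"):
            i = (0, 0)
            eps = 1e-6
            orig = params[key][i]
            params[key][i] = orig + eps
            lp = np.abs(gen.forward(x, train=True) - t).mean()
            params[key][i] = orig - eps
            lm = np.abs(gen.forward(x, train=True) - t).mean()
            params[key][i] = orig
            assert grads[key][i] == pytest.approx((lp - lm) / (2 * eps),
                                                  rel=1e-4, abs=1e-9)


class TestDiscriminator:
    def test_score_in_open_unit_interval_and_deterministic(self):
        rng = np.random.default_rng(1)
        disc = vs.build_discriminator(vs.DiscriminatorSpec(base_filters=4), 32, seed=3)
        inputs = rng.normal(size=(1, 32, 32))
        cand = rng.normal(size=(32, 32))
        s1 = vs.discriminator_score(disc, inputs, cand)
        s2 = vs.discriminator_score(disc, inputs, cand)
        assert 0.0 < s1 < 1.0
        assert s1 == s2

    def test_score_sensitive_to_candidate(self):
        rng = np.random.default_rng(2)
        disc = vs.build_discriminator(vs.DiscriminatorSpec(base_filters=4), 32, seed=4)
        inputs = rng.normal(size=(1, 32, 32))
        s1 = vs.discriminator_score(disc, inputs, rng.normal(size=(32, 32)))
        s2 = vs.discriminator_score(disc, inputs, rng.normal(size=(32, 32)))
        assert s1 != s2

    def test_shape_mismatch_rejected(self):
        disc = vs.build_discriminator(vs.DiscriminatorSpec(base_filters=4), 32, seed=0)
        with pytest.raises(ValueError):
            vs.discriminator_score(disc, np.zeros((1, 32, 32)), np.zeros((16, 16)))


class TestGeneratorLoss:
    def test_zero_error_gives_zero_mae(self):
        a = np.zeros((4, 4))
        out = vs.generator_loss(a, a, 0.5, 0.0, vs.LossConfig())
        assert out.l_mae == 0.0

    def test_adversarial_term_is_minus_log_score(self):
        out = vs.generator_loss(np.zeros((2, 2)), np.zeros((2, 2)), 0.5, 0.0,
                                vs.LossConfig())
        assert out.l_adv == pytest.approx(np.log(2), abs=1e-12)

    def test_hand_computed_composite_value(self):
        # pred=1, target=0 on 2x2; lambdas (0.99, 0.01, 0.001); D=0.5; |theta|=10
        out = vs.generator_loss(np.ones((2, 2)), np.zeros((2, 2)), 0.5, 10.0,
                                vs.LossConfig(0.99, 0.01, 0.001))
        expected = 0.99 * 1.0 + 0.01 * float(np.log(2)) + 0.001 * 10.0
        assert out.total == pytest.approx(expected, abs=1e-12)
        assert out.total == pytest.approx(1.0069314718, abs=1e-9)

    def test_invalid_score_rejected(self):
        with pytest.raises(ValueError):
            vs.generator_loss(np.zeros((2, 2)), np.zeros((2, 2)), 1.0, 0.0,
                              vs.LossConfig())


def _tiny_training(coupling=1.0, epochs=3, seed=5, lcfg=None):
    samples = scene_pairs(coupling, 6, 400, image_shape=(64, 64))
    tr_s, va_s = vs.split_train_val(samples, 0.2, 7)
    tr = crop_all(tr_s, 32, 6, 1)
    va = crop_all(va_s, 32, 6, 2)
    gspec = vs.GeneratorSpec(**STUDY_GSPEC)
    dspec = vs.DiscriminatorSpec(**STUDY_DSPEC)
    tcfg = vs.TrainConfig(learning_rate=STUDY_LR, batch_size=8,
                          max_epochs=epochs, seed=seed)
    return vs.train(tr, va, gspec, dspec, lcfg=lcfg, tcfg=tcfg)


class TestTraining:
    def test_identity_task_reduces_validation_mae(self):
        # target equals the input channel: a few hundred steps must help
        samples = scene_pairs(1.0, 6, 500, input_channel="puncta",
                              target_channel="puncta", image_shape=(64, 64))
        tr_s, va_s = vs.split_train_val(samples, 0.2, 7)
        tr = crop_all(tr_s, 32, 8, 1)
        va = crop_all(va_s, 32, 8, 2)
        tcfg = vs.TrainConfig(learning_rate=STUDY_LR, batch_size=8,
                              max_epochs=15, seed=5)
        state = vs.train(tr, va, vs.GeneratorSpec(**STUDY_GSPEC),
                         vs.DiscriminatorSpec(**STUDY_DSPEC), tcfg=tcfg)
        assert state.history[-1]["val_l_mae"] < state.history[0]["val_l_mae"]
        assert state.best_val_loss == min(h["val_l"] for h in state.history)

    def test_identical_seeds_identical_history(self):
        h1 = _tiny_training(epochs=2, seed=9).history
        h2 = _tiny_training(epochs=2, seed=9).history
        assert h1 == h2

    def test_best_checkpoint_reproduces_recorded_val_loss(self):
        from virtualstain.cgan_core import _val_losses, pairs_to_arrays
        state = _tiny_training(epochs=4, seed=6)
        samples = scene_pairs(1.0, 6, 400, image_shape=(64, 64))
        _, va_s = vs.split_train_val(samples, 0.2, 7)
        va = crop_all(va_s, 32, 6, 2)
        xv, yv = pairs_to_arrays(va)
        state.restore_best()
        val = _val_losses(state.generator, state.discriminator, xv, yv, state.lcfg)
        assert val.total == pytest.approx(state.best_val_loss, rel=1e-12)

    def test_checkpoint_save_load_round_trip(self, tmp_path):
        state = _tiny_training(epochs=2, seed=8)
        path = str(tmp_path / "ckpt.npz")
        state.save(path)
        loaded = vs.load_checkpoint(path)
        for k, v in state.generator.state().items():
            np.testing.assert_array_equal(v, loaded.generator.state()[k])
        assert loaded.best_val_loss == state.best_val_loss
        assert loaded.history == state.history
        loaded.restore_best()
        rng = np.random.default_rng(0)
        x = rng.uniform(-1, 1, size=(1, 32, 32))
        state.restore_best()
        np.testing.assert_allclose(state.generator.predict(x),
                                   loaded.generator.predict(x), atol=1e-12)

    @pytest.mark.filterwarnings("ignore:overflow", "ignore:invalid value")
    def test_divergent_run_aborts_with_diagnostics(self):
        samples = scene_pairs(1.0, 4, 300, image_shape=(64, 64))
        tr_s, va_s = vs.split_train_val(samples, 0.25, 7)
        tr = crop_all(tr_s, 32, 4, 1)
        va = crop_all(va_s, 32, 4, 2)
        # a step size large enough to overflow activations to non-finite values
        tcfg = vs.TrainConfig(learning_rate=1e200, batch_size=8, max_epochs=5, seed=1)
        with pytest.raises(vs.TrainingDivergedError):
            vs.train(tr, va, vs.GeneratorSpec(**STUDY_GSPEC),
                     vs.DiscriminatorSpec(**STUDY_DSPEC), tcfg=tcfg)

    def test_pure_mae_mode_gradients_match_finite_difference(self):
        """With lambda2 = lambda3 = 0 the composite gradient is the MAE gradient."""
        rng = np.random.default_rng(11)
        gen = vs.build_generator(vs.GeneratorSpec(depth=2, base_filters=4), seed=3)
        x = rng.normal(size=(2, 1, 8, 8)) * 0.5
        t = rng.uniform(-1, 1, size=(2, 1, 8, 8))
        lcfg = vs.LossConfig(0.99, 0.0, 0.0)
        gen.zero_grads()
        out = gen.forward(x, train=True)
        # composite-loss gradient with the adversarial and L1 terms switched off
        gen.backward(lcfg.lambda1 * np.sign(out - t) / out.size)
        key, i = "enc0/W", (1, 3)
        eps = 1e-6
        p = gen.params()[key]
        orig = p[i]
        p[i] = orig + eps
        lp = lcfg.lambda1 * np.abs(gen.forward(x, train=True) - t).mean()
        p[i] = orig - eps
        lm = lcfg.lambda1 * np.abs(gen.forward(x, train=True) - t).mean()
        p[i] = orig
        assert gen.grads()[key][i] == pytest.approx((lp - lm) / (2 * eps),
                                                    rel=1e-4, abs=1e-9)
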