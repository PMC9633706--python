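"""Architecture fingerprints, WGAN-GP losses, penalty oracles, training."""

import numpy as np
import pytest

from roentgan.nn import Dense, Flatten, Sequential
from roentgan import wgan
from roentgan.wgan import (
    CriticSpec,
    GeneratorSpec,
    TrainConfig,
    build_critic,
    build_generator,
    gradient_penalty,
    images_to_tensor,
    load_checkpoint,
    original_gan_loss,
    sample,
    sample_latents,
    save_checkpoint,
    scaled_critic_spec,
    scaled_generator_spec,
    to_uint8,
    train,
    wgan_loss,
)


# -- architecture fingerprints --------------------------------------------

def test_generator_parameter_fingerprint():
    counts = build_generator().count_params()
    assert counts["total"] == 6_304_900
    assert counts["trainable"] == 6_104_194


def test_generator_layerwise_parameter_sums():
    """The printed total decomposes as dense + input BN + three/one conv
    stages + output BN: 5,017,600 + 401,408 + 589,824 + 2*147,456 + 1,152 + 4."""
    gen = build_generator()
    sizes = {}
    for p in gen.params():
        sizes.setdefault(p.name.split(".")[0], 0)
        sizes[p.name.split(".")[0]] += p.size
    assert sizes["g_dense"] == 5_017_600
    assert sizes["g_bn_in"] == 401_408
    assert sizes["g_conv0"] == 589_824
    assert sizes["g_conv1"] == sizes["g_conv2"] == 147_456
    assert sizes["g_conv_out"] == 1_152
    assert sizes["g_bn_out"] == 4
    assert sum(sizes.values()) == 6_304_900


def test_critic_parameter_fingerprint_and_feature_shape():
    critic = build_critic()
    counts = critic.count_params()
    assert counts["total"] == 6_335_861
    assert counts["trainable"] == 6_335_861
    spec = CriticSpec()
    assert spec.feature_shape() == (7, 7, 422)
    assert spec.flat_features == 20_678


def test_generator_output_shape_and_range():
    gen = build_generator()
    out = gen.forward(np.zeros((1, 50), dtype=np.float32))
    assert out.shape == (1, 210, 210, 1)
    assert out.min() >= -1.0 and out.max() <= 1.0
    assert GeneratorSpec().output_size == 210   # 14 * 2^4 - 2*7


def test_critic_scores_are_unbounded_scalars():
    critic = build_critic(scaled_critic_spec())
    x = np.random.default_rng(0).standard_normal((3, 64, 64, 1)).astype(np.float32)
    scores = critic.forward(x)
    assert scores.shape == (3, 1)


# -- losses ----------------------------------------------------------------

def test_wgan_loss_arithmetic_and_antisymmetry():
    assert wgan_loss([1, 1], [1, 1]) == (0.0, -1.0)
    c, g = wgan_loss([2.0], [0.0])
    assert c == pytest.approx(-2.0) and g == pytest.approx(0.0)
    rng = np.random.default_rng(0)
    a, b = rng.standard_normal(5), rng.standard_normal(5)
    assert wgan_loss(a, b)[0] == pytest.approx(-wgan_loss(b, a)[0])
    with pytest.raises(ValueError):
        wgan_loss([], [1.0])


def test_original_gan_loss_documented_variant():
    d_loss, g_obj = original_gan_loss([0.9, 0.8], [0.1, 0.2])
    expected = np.log([0.9, 0.8]).mean() + np.log1p([-0.1, -0.2]).mean()
    assert g_obj == pytest.approx(expected)
    assert d_loss == pytest.approx(-expected)


# -- gradient penalty ------------------------------------------------------

def _linear_critic(w):
    w = np.asarray(w, dtype=np.float32).reshape(-1, 1)
    net = Sequential([Flatten(), Dense(w.shape[0], 1, use_bias=False)])
    net.layers[1].w.value[...] = w
    return net


def test_penalty_zero_for_unit_norm_linear_critic():
    rng = np.random.default_rng(0)
    w = rng.standard_normal(9)
    w /= np.linalg.norm(w)
    critic = _linear_critic(w)
    real = rng.standard_normal((4, 3, 3, 1)).astype(np.float32)
    fake = rng.standard_normal((4, 3, 3, 1)).astype(np.float32)
    assert gradient_penalty(critic, real, fake, 10.0, seed=1) == pytest.approx(
        0.0, abs=1e-6)


def test_penalty_equals_lambda_for_constant_critic():
    critic = _linear_critic(np.zeros(9))
    rng = np.random.default_rng(1)
    real = rng.standard_normal((4, 3, 3, 1)).astype(np.float32)
    fake = rng.standard_normal((4, 3, 3, 1)).astype(np.float32)
    assert gradient_penalty(critic, real, fake, 10.0, seed=2) == pytest.approx(10.0)


def test_penalty_linear_in_lambda_and_nonnegative():
    rng = np.random.default_rng(2)
    critic = _linear_critic(rng.standard_normal(9) * 3.0)
    real = rng.standard_normal((5, 3, 3, 1)).astype(np.float32)
    fake = rng.standard_normal((5, 3, 3, 1)).astype(np.float32)
    p10 = gradient_penalty(critic, real, fake, 10.0, seed=3)
    p5 = gradient_penalty(critic, real, fake, 5.0, seed=3)
    assert p10 == pytest.approx(2 * p5, rel=1e-6)
    assert p5 >= 0.0


def test_penalty_nonnegative_for_nonlinear_critic():
    critic = build_critic(scaled_critic_spec())
    rng = np.random.default_rng(3)
    real = rng.standard_normal((2, 64, 64, 1)).astype(np.float32)
    fake = rng.standard_normal((2, 64, 64, 1)).astype(np.float32)
    assert gradient_penalty(critic, real, fake, 10.0, seed=4) >= 0.0


def test_penalty_shape_mismatch_raises():
    critic = _linear_critic(np.zeros(9))
    with pytest.raises(ValueError):
        gradient_penalty(critic, np.zeros((2, 3, 3, 1)), np.zeros((3, 3, 3, 1)))


# -- sampling --------------------------------------------------------------

def test_sampling_deterministic_under_seed():
    gen = build_generator(scaled_generator_spec(), seed=0)
    a = sample(gen, 5, seed=1)
    b = sample(gen, 5, seed=1)
    np.testing.assert_array_equal(a, b)
    assert a.shape == (5, 64, 64, 1)


def test_latent_sample_mean_close_to_zero():
    n, d = 1000, 50
    z = sample_latents(n, d, seed=0)
    assert np.abs(z.mean(axis=0)).max() < 4.0 / np.sqrt(n)


def test_uint8_export_round_trip_range():
    x = np.array([-1.0, 0.0, 1.0])
    np.testing.assert_array_equal(to_uint8(x), [0, 128, 255])
    imgs = [np.zeros((4, 4), dtype=np.uint8), np.full((4, 4), 255, np.uint8)]
    t = images_to_tensor(imgs)
    assert t.shape == (2, 4, 4, 1)
    assert t.min() == -1.0 and t.max() == 1.0


# -- training --------------------------------------------------------------

def _toy_two_gaussian_images(n=64, size=8, seed=0):
    """Constant-intensity images whose levels follow a two-Gaussian mixture."""
    rng = np.random.default_rng(seed)
    levels = np.concatenate([rng.normal(-0.5, 0.08, n // 2),
                             rng.normal(0.5, 0.08, n - n // 2)])
    return np.clip(levels, -1, 1)[:, None, None, None] * np.ones(
        (1, size, size, 1), dtype=np.float32)


def _toy_nets(size=8, latent=4):
    rng = np.random.default_rng(5)
    from roentgan.nn import ELU, Reshape
    gen = Sequential([Dense(latent, 16, rng=rng, name="tg1"), ELU(1.0),
                      Dense(16, size * size, rng=rng, name="tg2"),
                      Reshape((size, size, 1))], name="toy_gen")
    critic = Sequential([Flatten(), Dense(size * size, 16, rng=rng, name="tc1"),
                         ELU(1.0), Dense(16, 1, rng=rng, name="tc2")],
                        name="toy_critic")
    return gen, critic


def test_training_smoke_two_epochs_saves_checkpoints(phantom_stack_64):
    data = images_to_tensor(phantom_stack_64)
    cfg = TrainConfig(latent_dim=16, epochs=2, batch_size=16, seed=0,
                      critic_steps_per_gen=2)
    res = train(data, cfg, generator_spec=scaled_generator_spec(),
                critic_spec=scaled_critic_spec(), max_steps=8)
    assert len(res.checkpoints) >= 1
    assert all(np.isfinite(res.wasserstein_history))


def test_training_dataset_smaller_than_batch_raises():
    cfg = TrainConfig(latent_dim=4, epochs=1, batch_size=32, seed=0)
    with pytest.raises(ValueError):
        train(np.zeros((8, 8, 8, 1), dtype=np.float32), cfg)


def test_wasserstein_estimate_declines_on_toy_dataset():
    """After a critic warm-up, adversarial updates shrink the critic's
    Wasserstein estimate on a two-Gaussian toy image dataset."""
    data = _toy_two_gaussian_images()
    gen, critic = _toy_nets()
    cfg = TrainConfig(latent_dim=4, epochs=1000, batch_size=16, seed=0,
                      critic_steps_per_gen=1, critic_warmup_steps=60,
                      lr=1e-3, checkpoint_every=10 ** 6)
    res = train(data, cfg, generator=gen, critic=critic, max_steps=140)
    h = np.abs(np.asarray(res.wasserstein_history))
    assert h[-20:].mean() < h[:20].mean()


def test_checkpoint_round_trip_bit_exact(tmp_path, phantom_stack_64):
    data = images_to_tensor(phantom_stack_64)
    cfg = TrainConfig(latent_dim=16, epochs=1, batch_size=16, seed=3,
                      critic_steps_per_gen=2)
    res = train(data, cfg, generator_spec=scaled_generator_spec(),
                critic_spec=scaled_critic_spec(), max_steps=4)
    ck = res.checkpoints[-1]
    path = tmp_path / "ck"
    save_checkpoint(ck, path)
    loaded = load_checkpoint(str(path) + ".npz")
    assert loaded.epoch == ck.epoch

    gen_a = build_generator(scaled_generator_spec())
    gen_a.load_state_dict(ck.generator_state)
    gen_b = build_generator(scaled_generator_spec())
    gen_b.load_state_dict(loaded.generator_state)
    z = sample_latents(3, 16, seed=9)
    np.testing.assert_array_equal(gen_a.forward(z), gen_b.forward(z))


def test_lr_constant_when_decay_zero():
    from roentgan.nn import Adam
    from roentgan.nn.layers import Param
    opt = Adam([Param("p", np.zeros(1))], lr=2e-4, decay=0.0)
    for _ in range(10):
        opt.step()
    assert opt.current_lr() == pytest.approx(2e-4)
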