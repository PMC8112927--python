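"""Training: the residual MSE objective, analytic-vs-numeric gradients,
optimisation behaviour and patch-based volume denoising."""

import numpy as np
import pytest

from ricianet import (ArchConfig, NoiseSpec, TrainConfig,
                      build_parallel_network, denoise_volume, extract_slices,
                      generate_phantom, load_model, residual_mse_loss,
                      rician_corrupt, save_model, train)


def test_loss_is_zero_at_perfect_deviation_prediction(rng):
    noisy = rng.random((3, 4, 4))
    clean = rng.random((3, 4, 4))
    assert residual_mse_loss(noisy, clean, noisy - clean) == 0.0


def test_loss_with_zero_prediction_is_the_noisy_clean_energy(rng):
    noisy = rng.random((3, 4, 4))
    clean = rng.random((3, 4, 4))
    expected = np.mean([(n - c).ravel() @ (n - c).ravel()
                        for n, c in zip(noisy, clean)])
    got = residual_mse_loss(noisy, clean, np.zeros_like(noisy),
                            reduction="per_sample")
    assert got == pytest.approx(expected, rel=1e-12)


def test_loss_toy_value():
    noisy = np.array([[[1.0, 2.0]], [[0.0, 0.0]]])
    clean = np.zeros_like(noisy)
    dev = np.array([[[1.0, 1.0]], [[0.0, 1.0]]])
    assert residual_mse_loss(noisy, clean, dev,
                             reduction="per_sample") == pytest.approx(1.0)
    assert residual_mse_loss(noisy, clean, dev,
                             reduction="per_voxel") == pytest.approx(0.5)


def test_loss_rejects_mismatched_shapes(rng):
    with pytest.raises(ValueError):
        residual_mse_loss(rng.random((2, 4)), rng.random((2, 4)),
                          rng.random((2, 5)))


def _loss(model, x, target):
    dev = model.forward(x, training=False)
    return float(np.sum((dev - target) ** 2))


def test_analytic_gradient_matches_central_differences(tiny_2d_config):
    model = build_parallel_network(tiny_2d_config, init_seed=2)
    for p in model.param_entries():  # float64 for a tight check
        p.value = p.value.astype(np.float64)
        p.grad = np.zeros_like(p.value)
    rng = np.random.default_rng(0)
    x = rng.random((2, 1, 9, 9))
    target = rng.random((2, 1, 9, 9))
    dev = model.forward(x, training=False)
    model.zero_grad()
    gx = model.backward(2.0 * (dev - target))
    eps = 1e-6
    for _ in range(4):
        idx = tuple(rng.integers(0, s) for s in x.shape)
        xp, xm = x.copy(), x.copy()
        xp[idx] += eps
        xm[idx] -= eps
        numeric = (_loss(model, xp, target) - _loss(model, xm, target)) / (2 * eps)
        assert numeric == pytest.approx(gx[idx], rel=1e-4, abs=1e-8)
    params = model.trainable_params()
    for _ in range(6):
        p = params[rng.integers(0, len(params))]
        idx = tuple(rng.integers(0, s) for s in p.value.shape)
        old = p.value[idx]
        p.value[idx] = old + eps
        lp = _loss(model, x, target)
        p.value[idx] = old - eps
        lm = _loss(model, x, target)
        p.value[idx] = old
        numeric = (lp - lm) / (2 * eps)
        assert numeric == pytest.approx(p.grad[idx], rel=1e-4, abs=1e-8)


def _phantom_slice_pairs(seeds, shape=(32, 32, 32), level=9.0):
    noisy_list, clean_list = [], []
    for k, seed in enumerate(seeds):
        phantom = generate_phantom(shape, seed, smooth_sigma=0.8)
        clean = phantom.intensity
        pair = rician_corrupt(clean, NoiseSpec.for_volume(clean, level,
                                                          seed=500 + k))
        for c_sl, n_sl in zip(extract_slices(clean, "coronal"),
                              extract_slices(pair.noisy, "coronal")):
            if (c_sl > 0).mean() > 0.1:
                clean_list.append(c_sl)
                noisy_list.append(n_sl)
    return np.stack(noisy_list), np.stack(clean_list)


def test_zero_learning_rate_leaves_parameters_unchanged(tiny_2d_config):
    noisy, clean = _phantom_slice_pairs([5])
    model = build_parallel_network(tiny_2d_config, init_seed=1)
    before = {k: v.copy() for k, v in model.state_dict().items()}
    cfg = TrainConfig(learning_rate=0.0, batch_size=4, steps=5, seed=0,
                      val_fraction=0.0)
    train(model, noisy, clean, cfg)
    after = model.state_dict()
    for name, value in before.items():
        if "running" in name:
            continue  # BN statistics update regardless of the optimiser
        assert np.array_equal(value, after[name]), name


def test_training_descends(tiny_2d_config):
    noisy, clean = _phantom_slice_pairs([5, 6])
    model = build_parallel_network(tiny_2d_config, init_seed=1)
    cfg = TrainConfig(learning_rate=1e-3, batch_size=4, steps=60, seed=0)
    state = train(model, noisy, clean, cfg)
    losses = state.history["train_loss"]
    assert np.mean(losses[-10:]) < losses[0]


def test_training_is_seed_deterministic(tiny_2d_config):
    noisy, clean = _phantom_slice_pairs([5])
    curves = []
    for _ in range(2):
        model = build_parallel_network(tiny_2d_config, init_seed=1)
        state = train(model, noisy, clean,
                      TrainConfig(batch_size=4, steps=10, seed=9))
        curves.append(state.history["train_loss"])
    assert curves[0] == curves[1]


def test_overfitting_one_patch_drives_the_loss_down():
    cfg = ArchConfig(dim=2, n_modules=3, filters=6, dilation_schedule=(1, 2, 3))
    model = build_parallel_network(cfg, init_seed=4)
    noisy, clean = _phantom_slice_pairs([7])
    noisy, clean = noisy[16:17], clean[16:17]
    tcfg = TrainConfig(learning_rate=1e-3, batch_size=1, steps=400, seed=1,
                       val_fraction=0.0)
    state = train(model, noisy, clean, tcfg)
    losses = state.history["train_loss"]
    assert losses[-1] < 0.01 * losses[0]


def test_empty_patch_source_is_rejected(tiny_2d_config):
    model = build_parallel_network(tiny_2d_config)
    with pytest.raises(ValueError):
        train(model, np.zeros((0, 8, 8)), np.zeros((0, 8, 8)), TrainConfig())


def test_zero_weight_model_denoises_to_identity(tiny_2d_config):
    model = build_parallel_network(tiny_2d_config)
    for p in model.param_entries():
        if not p.name.endswith(("running_mean", "running_var", "gamma")):
            p.value[...] = 0.0
    noisy = np.random.default_rng(0).random((20, 24)).astype(np.float32)
    out = denoise_volume(model, noisy, window=(12, 12), stride=(6, 6))
    assert out.shape == noisy.shape
    assert np.abs(out - noisy).max() < 1e-6


def test_denoise_volume_rejects_dimension_mismatch(tiny_2d_config):
    model = build_parallel_network(tiny_2d_config)
    with pytest.raises(ValueError, match="2-D"):
        denoise_volume(model, np.zeros((8, 8, 8)))
    with pytest.raises(ValueError, match="window"):
        denoise_volume(model, np.zeros((8, 8)), window=(16, 16))


def test_checkpoint_round_trip(tmp_path, tiny_2d_config):
    model = build_parallel_network(tiny_2d_config, init_seed=3)
    x = np.random.default_rng(0).random((1, 1, 12, 12)).astype(np.float32)
    expected = model.forward(x)
    save_model(model, tiny_2d_config, tmp_path / "ckpt.npz")
    restored, cfg = load_model(tmp_path / "ckpt.npz")
    assert cfg == tiny_2d_config
    assert np.array_equal(restored.forward(x), expected)
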