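"""Architecture: dilation schedule, receptive-field analyzers (formula vs a
numeric impulse-propagation oracle), shape preservation, residual identity,
and exact parameter counting against closed-form enumeration."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from ricianet import (ArchConfig, build_parallel_network,
                      cascade_receptive_field, count_parameters,
                      dilation_schedule_default, effective_kernel_extent)
from ricianet.nn import Conv, DSConv


def test_default_schedule_is_the_published_one():
    sched = dilation_schedule_default()
    assert sched == (1, 1, 1, 1, 1, 1, 2, 3, 1, 2, 3, 1, 2, 3, 1, 2, 3, 1)
    assert len(sched) == 18
    assert sum(sched) == 30
    assert sorted(sched) == [1] * 10 + [2] * 4 + [3] * 4


@pytest.mark.parametrize("kernel, rate, extent", [
    (3, 1, 3), (3, 2, 5), (3, 3, 7), (5, 2, 9), (1, 4, 1),
])
def test_effective_kernel_extent(kernel, rate, extent):
    assert effective_kernel_extent(kernel, rate) == extent


def test_effective_kernel_extent_rejects_nonpositive():
    with pytest.raises(ValueError):
        effective_kernel_extent(0, 1)
    with pytest.raises(ValueError):
        effective_kernel_extent(3, 0)


@pytest.mark.parametrize("schedule, expected", [
    (dilation_schedule_default(), 61),
    ([1] * 18, 37),
    ([2] * 18, 73),
    ([3] * 18, 109),
])
def test_cascade_receptive_field_published_values(schedule, expected):
    assert cascade_receptive_field(3, schedule) == expected


def test_cascade_receptive_field_rejects_empty_schedule():
    with pytest.raises(ValueError):
        cascade_receptive_field(3, [])


@given(st.lists(st.integers(1, 4), min_size=1, max_size=10),
       st.integers(0, 9), st.integers(1, 3))
@settings(max_examples=50, deadline=None)
def test_receptive_field_strictly_increases_with_any_rate(schedule, pos, delta):
    base = cascade_receptive_field(3, schedule)
    bumped = list(schedule)
    bumped[pos % len(bumped)] += delta
    grown = cascade_receptive_field(3, bumped)
    assert grown == base + 2 * delta
    assert delta == 0 or grown > base


def test_receptive_field_matches_impulse_propagation_oracle():
    """Propagate an impulse through a bias-free single-conv cascade with
    all-ones kernels and measure the support width directly."""
    schedule = (1, 2, 3, 1)
    size = 41
    x = np.zeros((1, 1, size, size), np.float32)
    x[0, 0, size // 2, size // 2] = 1.0
    for rate in schedule:
        conv = Conv(dim=2, in_channels=1, out_channels=1, kernel=3, rate=rate,
                    bias=False)
        conv.W.value[...] = 1.0
        x = conv.forward(x, training=False)
    rows = np.nonzero(x[0, 0].sum(axis=1))[0]
    measured = rows.max() - rows.min() + 1
    assert measured == cascade_receptive_field(3, schedule)


@pytest.mark.parametrize("dim, size", [(2, 16), (2, 17), (3, 12), (3, 13)])
@pytest.mark.parametrize("fusion", ["inject", "both"])
def test_network_preserves_spatial_shape(dim, size, fusion):
    cfg = ArchConfig(dim=dim, n_modules=3, filters=4,
                     dilation_schedule=(1, 2, 3), fusion=fusion)
    model = build_parallel_network(cfg)
    x = np.random.default_rng(0).random((2, 1) + (size,) * dim,
                                        ).astype(np.float32)
    assert model.forward(x).shape == x.shape


@pytest.mark.parametrize("dim", [2, 3])
def test_zero_weight_network_is_the_identity_denoiser(dim):
    cfg = ArchConfig(dim=dim, n_modules=2, filters=4, dilation_schedule=(1, 2))
    model = build_parallel_network(cfg)
    for p in model.param_entries():
        if not p.name.endswith(("running_mean", "running_var", "gamma")):
            p.value[...] = 0.0
    y = np.random.default_rng(1).random((1, 1) + (10,) * dim).astype(np.float32)
    assert np.array_equal(model.denoise(y), y)


def test_dsconv_parameter_count_vs_standard_conv():
    ds = DSConv(dim=3, in_channels=16, out_channels=16, kernel=3, bias=True)
    assert count_parameters(ds).overall == 720  # (27*16 + 16) + (16*16 + 16)
    std = Conv(dim=3, in_channels=16, out_channels=16, kernel=3, bias=True)
    assert count_parameters(std).overall == 6928  # 27*16*16 + 16


def test_single_conv_parameter_count():
    conv = Conv(dim=2, in_channels=1, out_channels=1, kernel=3, bias=True)
    assert count_parameters(conv).overall == 10


def expected_default_counts(dim: int) -> tuple[int, int]:
    """Closed-form enumeration of the frozen default architecture,
    independent of the builder: (trainable, non_trainable)."""
    k = 3 ** dim
    f, n = 16, 18
    bn_affine, bn_stats = 2 * f, 2 * f

    def conv(ci, co, kk):
        return kk * ci * co + co

    def dsconv(ci, co):
        return (k * ci + ci) + (ci * co + co)

    trainable = non_trainable = 0
    for i in range(n):
        ci = 1 if i == 0 else f
        # DCR: two dilated convs + BN each (+ 1x1 projection on module 1)
        trainable += conv(ci, f, k) + conv(f, f, k) + 2 * bn_affine
        non_trainable += 2 * bn_stats
        if ci != f:
            trainable += conv(ci, f, 1)
        # DSCR: two DSConvs + BN each, DS shortcut without BN
        trainable += dsconv(ci, f) + dsconv(f, f) + dsconv(ci, f) + 2 * bn_affine
        non_trainable += 2 * bn_stats
    trainable += conv(f, 1, k)  # reconstruction head
    return trainable, non_trainable


@pytest.mark.parametrize("dim", [2, 3])
def test_parameter_counter_matches_independent_enumeration(dim):
    model = build_parallel_network(ArchConfig(dim=dim))
    bd = count_parameters(model)
    trainable, non_trainable = expected_default_counts(dim)
    assert bd.trainable == trainable
    assert bd.non_trainable == non_trainable
    assert bd.overall == trainable + non_trainable
    assert sum(c for _, c in bd.per_layer) == bd.overall


def test_2d_and_3d_counts_differ_only_by_the_kernel_volume_factor():
    bd2 = count_parameters(build_parallel_network(ArchConfig(dim=2)))
    bd3 = count_parameters(build_parallel_network(ArchConfig(dim=3)))
    for (name2, c2), (name3, c3) in zip(bd2.per_layer, bd3.per_layer):
        assert name2 == name3
        if c3 != c2:  # spatial kernels: 3^3 vs 3^2 entries
            assert name2.endswith("weight")
            assert c3 == 3 * c2


def test_arch_config_validation():
    with pytest.raises(ValueError):
        ArchConfig(dim=4)
    with pytest.raises(ValueError):
        ArchConfig(kernel=4)
    with pytest.raises(ValueError):
        ArchConfig(n_modules=5)  # schedule required
    with pytest.raises(ValueError):
        ArchConfig(n_modules=2, dilation_schedule=(1, 0))
    with pytest.raises(ValueError):
        ArchConfig(fusion="concat")


def test_arch_config_round_trips_through_dict():
    cfg = ArchConfig(dim=2, n_modules=3, filters=8, dilation_schedule=(1, 2, 3))
    assert ArchConfig.from_dict(cfg.to_dict()) == cfg
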