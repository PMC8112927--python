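"""Architecture description, builders and analyzers.

The default configuration reproduces the published network geometry: a
cascade of 18 dilated-convolution residual (DCR) modules with the mixed
dilation schedule ``1,1,1,1,1,1,2,3,1,2,3,1,2,3,1,2,3,1`` (per-axis receptive
field 61 for kernel 3) in parallel with 18 depthwise-separable-convolution
residual (DSCR) modules, 16 filters each, fused per module by addition, with a
final reconstruction convolution producing the deviation estimate.

Two analyzers accompany the builders: a receptive-field calculator using the
stacked-dilation recurrence ``RF = 1 + (k - 1) * sum(rates)`` (one scheduled
dilated convolution per module), and an exact parameter counter that
distinguishes trainable weights from batch-norm running statistics.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np

from .nn import DCRModule, DSCRModule, ParallelRicianNet

__all__ = [
    "ArchConfig",
    "ParamBreakdown",
    "dilation_schedule_default",
    "effective_kernel_extent",
    "cascade_receptive_field",
    "build_dcr_module",
    "build_dscr_module",
    "build_parallel_network",
    "count_parameters",
]

#: Published dilation-rate schedule of the 18-module global branch.
_DEFAULT_SCHEDULE = (1, 1, 1, 1, 1, 1, 2, 3, 1, 2, 3, 1, 2, 3, 1, 2, 3, 1)


def dilation_schedule_default() -> tuple[int, ...]:
    """Return the 18-element mixed dilation-rate schedule of the global branch."""
    return _DEFAULT_SCHEDULE


@dataclass
class ArchConfig:
    """Structural description of the two-branch denoising network.

    The shipped defaults are the frozen reference configuration: biases on
    every convolution, batch-norm with affine terms and running statistics, a
    1-extent projection on the first DCR skip connection (1 -> 16 channels),
    no batch-norm on the DSCR shortcut, and two dilated convolutions per DCR
    module.
    """

    dim: int = 3
    n_modules: int = 18
    filters: int = 16
    kernel: int = 3
    dilation_schedule: tuple[int, ...] | None = None
    leaky_slope: float = 0.3
    conv_bias: bool = True
    bn_affine_and_stats: bool = True
    shortcut_conv_in_dcr: bool = True
    bn_on_dscr_shortcut: bool = False
    single_dilated_conv_per_module: bool = False
    fusion: str = "inject"

    def __post_init__(self) -> None:
        if self.dim not in (2, 3):
            raise ValueError("dim must be 2 or 3")
        if self.n_modules < 1 or self.filters < 1:
            raise ValueError("n_modules and filters must be positive")
        if self.kernel < 1 or self.kernel % 2 == 0:
            raise ValueError("kernel must be a positive odd integer")
        if self.dilation_schedule is None:
            if self.n_modules == 18:
                self.dilation_schedule = _DEFAULT_SCHEDULE
            else:
                raise ValueError(
                    "dilation_schedule is required when n_modules != 18")
        self.dilation_schedule = tuple(int(r) for r in self.dilation_schedule)
        if len(self.dilation_schedule) != self.n_modules:
            raise ValueError("dilation_schedule length must equal n_modules")
        if any(r < 1 for r in self.dilation_schedule):
            raise ValueError("all dilation rates must be >= 1")
        if not 0.0 < self.leaky_slope < 1.0:
            raise ValueError("leaky_slope must lie in (0, 1)")
        if self.fusion not in ("inject", "both"):
            raise ValueError("fusion must be 'inject' or 'both'")

    def to_dict(self) -> dict:
        d = asdict(self)
        d["dilation_schedule"] = list(self.dilation_schedule)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "ArchConfig":
        d = dict(d)
        if d.get("dilation_schedule") is not None:
            d["dilation_schedule"] = tuple(d["dilation_schedule"])
        return cls(**d)


def effective_kernel_extent(kernel: int, rate: int) -> int:
    """Per-axis extent ``(k - 1)(R - 1) + k`` of one dilated filter.

    The d-dimensional receptive field of a single dilated convolution is this
    value raised to the power d.
    """
    if kernel < 1 or rate < 1:
        raise ValueError("kernel and rate must be positive")
    return (kernel - 1) * (rate - 1) + kernel


def cascade_receptive_field(kernel: int, schedule) -> int:
    """Per-axis receptive field ``1 + (k - 1) * sum(rates)`` of a cascade in
    which each scheduled rate contributes one dilated convolution."""
    schedule = tuple(schedule)
    if not schedule:
        raise ValueError("schedule must be non-empty")
    if kernel < 1 or kernel % 2 == 0:
        raise ValueError("kernel must be a positive odd integer")
    if any(r < 1 for r in schedule):
        raise ValueError("all dilation rates must be >= 1")
    return 1 + (kernel - 1) * int(sum(schedule))


def build_dcr_module(in_channels: int, config: ArchConfig, rate: int,
                     rng: np.random.Generator | None = None) -> DCRModule:
    """Build one dilated-convolution residual module at the given rate."""
    if in_channels < 1:
        raise ValueError("in_channels must be >= 1")
    return DCRModule(config.dim, in_channels, config.filters, config.kernel,
                     rate, config.leaky_slope, config.conv_bias,
                     config.shortcut_conv_in_dcr,
                     config.single_dilated_conv_per_module, rng)


def build_dscr_module(in_channels: int, config: ArchConfig,
                      rng: np.random.Generator | None = None) -> DSCRModule:
    """Build one depthwise-separable-convolution residual module."""
    if in_channels < 1:
        raise ValueError("in_channels must be >= 1")
    return DSCRModule(config.dim, in_channels, config.filters, config.kernel,
                      config.leaky_slope, config.conv_bias,
                      config.bn_on_dscr_shortcut, rng)


def build_parallel_network(config: ArchConfig, init_seed: int = 0) -> ParallelRicianNet:
    """Instantiate the full two-branch denoiser described by ``config``."""
    return ParallelRicianNet(
        dim=config.dim,
        n_modules=config.n_modules,
        filters=config.filters,
        kernel=config.kernel,
        dilation_schedule=config.dilation_schedule,
        slope=config.leaky_slope,
        conv_bias=config.conv_bias,
        shortcut_conv_in_dcr=config.shortcut_conv_in_dcr,
        bn_on_dscr_shortcut=config.bn_on_dscr_shortcut,
        single_dilated_conv_per_module=config.single_dilated_conv_per_module,
        fusion=config.fusion,
        init_seed=init_seed,
    )


@dataclass
class ParamBreakdown:
    """Exact per-weight-array parameter counts with trainability totals."""

    per_layer: list[tuple[str, int]] = field(default_factory=list)
    trainable: int = 0
    non_trainable: int = 0

    @property
    def overall(self) -> int:
        return self.trainable + self.non_trainable

    def check(self) -> None:
        if sum(c for _, c in self.per_layer) != self.overall:
            raise AssertionError("per-layer counts do not sum to the total")


def count_parameters(model) -> ParamBreakdown:
    """Count parameters of any object exposing ``param_entries()``.

    Trainable weights (convolution kernels, biases, batch-norm affine terms)
    and non-trainable batch-norm running statistics are reported separately;
    ``overall`` is their sum.
    """
    bd = ParamBreakdown()
    for p in model.param_entries():
        n = int(p.value.size)
        bd.per_layer.append((p.name, n))
        if p.trainable:
            bd.trainable += n
        else:
            bd.non_trainable += n
    bd.check()
    return bd
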