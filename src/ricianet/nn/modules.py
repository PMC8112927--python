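"""Residual modules and the two-branch denoising network.

The network predicts the Rician noise deviation f(Y; theta) of a magnitude MR
image and reconstructs the clean image as ``X_hat = Y - f(Y; theta)``.  It runs
two cascades in parallel over the same input:

* a global branch of dilated-convolution residual (DCR) modules whose dilation
  schedule widens the receptive field without extra parameters, and
* a local branch of depthwise-separable-convolution residual (DSCR) modules
  that mix per-position channel information cheaply.

After every pair of modules the two feature maps are fused by elementwise
addition and the fused map feeds the next module of *both* branches; a final
convolution (the reconstruction head) collapses the fused features to the
single-channel deviation estimate.
"""

from __future__ import annotations

import numpy as np

from .layers import BatchNorm, Conv, DepthwiseConv, Layer, LeakyReLU, Param

__all__ = ["DSConv", "DCRModule", "DSCRModule", "ParallelRicianNet"]


class DSConv(Layer):
    """Depthwise separable convolution: per-channel spatial filter followed by
    a pointwise (1-extent) cross-channel convolution."""

    def __init__(self, dim: int, in_channels: int, out_channels: int,
                 kernel: int = 3, bias: bool = True,
                 rng: np.random.Generator | None = None, slope: float = 0.3,
                 name: str = "dsconv"):
        self.depthwise = DepthwiseConv(dim, in_channels, kernel, bias=bias,
                                       rng=rng, slope=slope, name=f"{name}.depthwise")
        self.pointwise = Conv(dim, in_channels, out_channels, kernel=1, rate=1,
                              bias=bias, rng=rng, slope=slope,
                              name=f"{name}.pointwise")

    def param_entries(self) -> list[Param]:
        return self.depthwise.param_entries() + self.pointwise.param_entries()

    def forward(self, x: np.ndarray, training: bool) -> np.ndarray:
        return self.pointwise.forward(self.depthwise.forward(x, training), training)

    def backward(self, grad: np.ndarray) -> np.ndarray:
        return self.depthwise.backward(self.pointwise.backward(grad))


class DCRModule(Layer):
    """Dilated-convolution residual module (global-feature branch).

    Main path: dilated conv -> BN -> leaky rectifier, repeated (twice by
    default, once when ``single_conv`` is set), both convolutions at the
    module's scheduled dilation rate.  The module input is added to the main
    path output; when the channel counts differ a 1-extent projection
    convolution aligns them.
    """

    def __init__(self, dim: int, in_channels: int, filters: int, kernel: int,
                 rate: int, slope: float = 0.3, bias: bool = True,
                 shortcut_conv: bool = True, single_conv: bool = False,
                 rng: np.random.Generator | None = None, name: str = "dcr"):
        self.blocks: list[tuple[Conv, BatchNorm, LeakyReLU]] = []
        n_convs = 1 if single_conv else 2
        for i in range(n_convs):
            cin = in_channels if i == 0 else filters
            conv = Conv(dim, cin, filters, kernel=kernel, rate=rate, bias=bias,
                        rng=rng, slope=slope, name=f"{name}.conv{i + 1}")
            bn = BatchNorm(filters, dim, name=f"{name}.bn{i + 1}")
            self.blocks.append((conv, bn, LeakyReLU(slope)))
        self.proj: Conv | None = None
        if in_channels != filters:
            if not shortcut_conv:
                raise ValueError(
                    "channel mismatch on the skip path requires the projection "
                    "convolution (shortcut_conv_in_dcr)")
            self.proj = Conv(dim, in_channels, filters, kernel=1, rate=1,
                             bias=bias, rng=rng, slope=slope,
                             name=f"{name}.shortcut")

    def param_entries(self) -> list[Param]:
        out: list[Param] = []
        for conv, bn, _ in self.blocks:
            out += conv.param_entries() + bn.param_entries()
        if self.proj is not None:
            out += self.proj.param_entries()
        return out

    def forward(self, x: np.ndarray, training: bool) -> np.ndarray:
        h = x
        for conv, bn, act in self.blocks:
            h = act.forward(bn.forward(conv.forward(h, training), training), training)
        skip = x if self.proj is None else self.proj.forward(x, training)
        return h + skip

    def backward(self, grad: np.ndarray) -> np.ndarray:
        g = grad
        for conv, bn, act in reversed(self.blocks):
            g = conv.backward(bn.backward(act.backward(g)))
        if self.proj is None:
            return g + grad
        return g + self.proj.backward(grad)


class DSCRModule(Layer):
    """Depthwise-separable-convolution residual module (local-feature branch).

    Main path: DSConv -> BN -> leaky rectifier -> DSConv -> BN.  Shortcut
    path: one DSConv (optionally followed by BN).  The two paths are added and
    passed through a final leaky rectifier.
    """

    def __init__(self, dim: int, in_channels: int, filters: int, kernel: int,
                 slope: float = 0.3, bias: bool = True,
                 bn_on_shortcut: bool = False,
                 rng: np.random.Generator | None = None, name: str = "dscr"):
        self.ds1 = DSConv(dim, in_channels, filters, kernel, bias, rng, slope,
                          name=f"{name}.ds1")
        self.bn1 = BatchNorm(filters, dim, name=f"{name}.bn1")
        self.act1 = LeakyReLU(slope)
        self.ds2 = DSConv(dim, filters, filters, kernel, bias, rng, slope,
                          name=f"{name}.ds2")
        self.bn2 = BatchNorm(filters, dim, name=f"{name}.bn2")
        self.ds_short = DSConv(dim, in_channels, filters, kernel, bias, rng,
                               slope, name=f"{name}.shortcut")
        self.bn_short = (BatchNorm(filters, dim, name=f"{name}.bn_shortcut")
                         if bn_on_shortcut else None)
        self.act_out = LeakyReLU(slope)

    def param_entries(self) -> list[Param]:
        out = (self.ds1.param_entries() + self.bn1.param_entries()
               + self.ds2.param_entries() + self.bn2.param_entries()
               + self.ds_short.param_entries())
        if self.bn_short is not None:
            out += self.bn_short.param_entries()
        return out

    def forward(self, x: np.ndarray, training: bool) -> np.ndarray:
        h = self.act1.forward(self.bn1.forward(self.ds1.forward(x, training),
                                               training), training)
        h = self.bn2.forward(self.ds2.forward(h, training), training)
        s = self.ds_short.forward(x, training)
        if self.bn_short is not None:
            s = self.bn_short.forward(s, training)
        return self.act_out.forward(h + s, training)

    def backward(self, grad: np.ndarray) -> np.ndarray:
        g = self.act_out.backward(grad)
        gs = g if self.bn_short is None else self.bn_short.backward(g)
        gx = self.ds_short.backward(gs)
        gh = self.ds2.backward(self.bn2.backward(g))
        gx = gx + self.ds1.backward(self.bn1.backward(self.act1.backward(gh)))
        return gx


class ParallelRicianNet:
    """Two-branch residual denoiser with per-module additive fusion.

    Fusion wiring (``fusion``):

    * ``"inject"`` (default): the local branch cascades on its own stream and
      the output of DSCR module i is added into the global trunk after DCR
      module i; the reconstruction head reads the last fused trunk map.  Trunk
      amplitude grows only additively with depth, which keeps deep cascades
      trainable.
    * ``"both"``: the fused map feeds module i+1 of *both* branches.  With
      identity skips in every module this doubles the signal amplitude per
      stage (2^n growth over n modules), so it is kept only as an option.

    ``forward`` returns the predicted deviation map; :meth:`denoise` returns
    ``y - f(y)`` in evaluation mode (batch-norm running statistics).
    """

    def __init__(self, dim: int, n_modules: int, filters: int, kernel: int,
                 dilation_schedule: tuple[int, ...], slope: float = 0.3,
                 conv_bias: bool = True, shortcut_conv_in_dcr: bool = True,
                 bn_on_dscr_shortcut: bool = False,
                 single_dilated_conv_per_module: bool = False,
                 fusion: str = "inject",
                 init_seed: int = 0):
        if len(dilation_schedule) != n_modules:
            raise ValueError("dilation schedule length must equal n_modules")
        if fusion not in ("inject", "both"):
            raise ValueError("fusion must be 'inject' or 'both'")
        self.fusion = fusion
        rng = np.random.default_rng(init_seed)
        self.dim = dim
        self.dcr: list[DCRModule] = []
        self.dscr: list[DSCRModule] = []
        for i, rate in enumerate(dilation_schedule):
            cin = 1 if i == 0 else filters
            self.dcr.append(DCRModule(
                dim, cin, filters, kernel, rate, slope, conv_bias,
                shortcut_conv_in_dcr, single_dilated_conv_per_module,
                rng, name=f"dcr{i + 1:02d}"))
            self.dscr.append(DSCRModule(
                dim, cin, filters, kernel, slope, conv_bias,
                bn_on_dscr_shortcut, rng, name=f"dscr{i + 1:02d}"))
        self.rec = Conv(dim, filters, 1, kernel=kernel, rate=1, bias=conv_bias,
                        rng=rng, slope=slope, name="rec.conv")
        self.rec.W.value *= 0.1  # small deviation head keeps early training stable
        self._n_fused = n_modules

    # -- parameter plumbing ------------------------------------------------
    def param_entries(self) -> list[Param]:
        out: list[Param] = []
        for m in self.dcr:
            out += m.param_entries()
        for m in self.dscr:
            out += m.param_entries()
        out += self.rec.param_entries()
        return out

    def trainable_params(self) -> list[Param]:
        return [p for p in self.param_entries() if p.trainable]

    def zero_grad(self) -> None:
        for p in self.param_entries():
            p.grad[...] = 0.0

    def state_dict(self) -> dict[str, np.ndarray]:
        return {p.name: p.value for p in self.param_entries()}

    def load_state_dict(self, state: dict[str, np.ndarray]) -> None:
        for p in self.param_entries():
            p.value[...] = state[p.name]

    # -- computation -------------------------------------------------------
    def forward(self, y: np.ndarray, training: bool = False) -> np.ndarray:
        """Predict the deviation map for a batch ``(n, 1, *spatial)``."""
        h_dcr = h_dscr = y
        fused = y
        for mg, ml in zip(self.dcr, self.dscr):
            a = mg.forward(h_dcr, training)
            b = ml.forward(h_dscr, training)
            fused = a + b
            if self.fusion == "both":
                h_dcr = h_dscr = fused
            else:
                h_dcr = fused
                h_dscr = b
        return self.rec.forward(fused, training)

    def backward(self, grad: np.ndarray) -> np.ndarray:
        g = self.rec.backward(grad)
        if self.fusion == "both":
            for mg, ml in zip(reversed(self.dcr), reversed(self.dscr)):
                g = mg.backward(g) + ml.backward(g)
            return g
        # inject wiring: DSCR output b_i feeds both the fusion add and the
        # next DSCR module, so its gradient is the trunk gradient plus the
        # input gradient coming back from stage i+1 of the local branch
        g_dscr = np.zeros_like(g)
        for mg, ml in zip(reversed(self.dcr), reversed(self.dscr)):
            g_b = g + g_dscr
            g_dscr = ml.backward(g_b)
            g = mg.backward(g)
        return g + g_dscr

    def denoise(self, y: np.ndarray) -> np.ndarray:
        """Reconstruct the clean image batch as ``y - f(y)`` (eval mode)."""
        return y - self.forward(y, training=False)
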