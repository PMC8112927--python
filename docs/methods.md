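# Methods

## Degradation model

Magnitude images from single-coil acquisition carry independent zero-mean
Gaussian noise of standard deviation sigma in the real and imaginary
channels; the magnitude `Y = sqrt((X + n1)^2 + n2^2)` is Rician with signal
parameter nu = X.  The corruptor draws both channels from one counter-based
Philox stream keyed by the noise seed, so the noise field of a volume does
not depend on patch-extraction order.  Useful closed forms used by the test
suite: at nu = 0 the magnitude is Rayleigh with mean `sigma*sqrt(pi/2)`, and
`E[Y^2] = nu^2 + 2 sigma^2` exactly.  The density is evaluated through the
exponentially scaled Bessel function `i0e` to stay finite at large
`y*nu/sigma^2`.

Percent noise levels follow the BrainWeb convention:
`sigma = (level/100) * reference`, with the reference defaulting to the
maximum of the clean volume.  Whether a given archive's "x% noise" uses the
maximum or a bright-tissue mean as reference is not standardised, so the
reference is an explicit, recorded parameter.

## Network

Both branches see the 1-channel noisy image.  A DCR module is
`dilated conv -> BN -> LeakyReLU(0.3)` twice, both convolutions at the
module's scheduled rate, plus a skip connection (identity, or a 1-extent
projection where the channel count changes, i.e. in module 1).  A DSCR
module is `DSConv -> BN -> LeakyReLU -> DSConv -> BN` with a DSConv shortcut
and a trailing LeakyReLU after the add; a DSConv is a per-channel spatial
filter followed by a pointwise channel mixer, both with biases.  All
convolutions use symmetric zero padding of `(extent-1)/2` per axis, where the
dilated extent is `(k-1)*R + 1`, so every layer preserves the spatial shape.

**Fusion wiring.** The outputs of DCR module i and DSCR module i are added.
Two wirings are implemented (`ArchConfig.fusion`):

* `"inject"` (default): the fused map feeds the next DCR module; the DSCR
  branch cascades on its own stream.  The trunk amplitude then grows at most
  additively with depth.
* `"both"`: the fused map feeds the next module of both branches.  Because
  every module carries an identity skip, the fused signal is roughly twice
  its input (`a + b ≈ 2h`), so amplitude grows like `2^n` over n modules —
  numerically hopeless at 18 modules, and in a 6+6-module experiment at 9%
  noise the network converged to the trivial zero-deviation solution.  The
  wiring is kept as an option for comparison.

The reconstruction head is one convolution (16 -> 1) whose output is the
deviation estimate; the denoised image is `Y - f(Y)`.  With all weights zero
the network is therefore exactly the identity on its input, which the tests
use as the residual-identity contract.

**Receptive-field analyzer vs module internals.** The printed receptive
fields (61 for the mixed schedule; 37/73/109 for uniform rates 1/2/3) follow
`RF = 1 + (k-1)*sum(rates)`, i.e. one scheduled dilated convolution per
module, while the module diagram contains two.  The analyzer implements the
printed arithmetic; the builder follows the diagram by default and offers
`single_dilated_conv_per_module` for the one-conv variant.  The analyzer is
verified against a numeric oracle that propagates an impulse through a
single-conv cascade with all-ones kernels and measures the support width.

**Parameter accounting.** The counter walks every weight array and reports
trainable parameters (convolution kernels, biases, batch-norm gamma/beta)
separately from batch-norm running statistics.  Under the shipped default
3-D configuration the network counts 283,257 trainable + 2,304 statistics =
285,561 parameters (global branch 245,264, local branch 39,864, head 433).
The parameter total printed for this architecture in the literature
(395,405) could not be reproduced by any flag combination of the described
design: with additive fusion the count stays below ~298k under every
bias/BN/shortcut accounting variant we enumerated, adding a per-module 3^3
fusion convolution overshoots to >= 402k, and the gap is not divisible by
the module count, so no uniform per-module layer explains it.  The default
configuration is therefore frozen on fidelity grounds (Keras-convention
accounting: biases on, BN affine + running statistics) and the discrepancy
is reported rather than tuned away.

**Initialisation.** Variance-scaling (fan-in) normal initialisation with the
leaky-rectifier gain, biases zero, the head kernel scaled by 0.1 so early
training starts near the identity map; a single integer seed drives all
initial weights.

## Training

The objective is the residual MSE; the implementation trains on the
per-voxel mean (same minimiser, step sizes independent of patch size) and
exposes the literal per-sample sum form for exact loss-value checks.  Adam
uses beta1 0.9, beta2 0.999, eps 1e-7, learning rate 1e-3 by default.
Batch-norm running statistics use momentum 0.9 — faster-adapting than the
usual 0.99 because the intended trainings are a few hundred steps; inference
always uses the running statistics.  Batch sizes default to 8 in 2-D and 2
in 3-D (memory-driven).  Training is bitwise deterministic for a fixed seed
on one platform; gradients of the full network agree with central
differences to ~1e-9 relative error in float64.

Volume denoising extracts sliding-window patches (with end-aligned extra
windows so non-tiling strides still cover every voxel), predicts the
deviation per patch, and averages overlapping clean-patch predictions;
extraction/reassembly is an exact identity whenever the grid covers the
volume.

## Synthetic phantoms

Three seed-jittered nested ellipsoids (outer CSF shell, GM shell, WM core)
are rasterized into a label grid; class intensities default to
0.25/0.55/0.85 on [0, 1] — well-separated levels so percent noise maps
cleanly — and optional Gaussian smoothing (sigma 0.8 voxels in the shipped
studies) creates partial-volume edges.  The phantoms exercise homogeneous
regions, tissue boundaries and a Rayleigh background, and make per-tissue
masked evaluation exact.  They deliberately do not model MR contrast
physics, bias fields, anatomy-scale texture or spatially varying noise;
results on them bound what the architecture can do on piecewise-smooth
signals and say nothing about generalisation across scanners or anatomies.

## Metrics

PSNR uses `10 log10(max^2 / MSE)` with the reference maximum as default
dynamic range and an infinity sentinel for identical images.  SSIM uses the
standard reference configuration (Gaussian window sigma 1.5 truncated at 11
taps, K1 = 0.01, K2 = 0.03, population moments) via scikit-image; a
hand-rolled sliding-window evaluation of the definition serves as the test
oracle.  Entropy is `-sum p ln p` (natural logarithm) over 256 equal-width
bins on [0, max] by default; binning is an explicit argument since it is a
convention, not a property of the image.  Masked variants restrict PSNR and
entropy to in-mask voxels and average the local SSIM map over in-mask
positions inside the window-radius interior of the mask's bounding box, so a
full mask reproduces the unmasked values exactly.

## Study sizes

The shipped end-to-end study (also the stochastic acceptance exercise) is a
2-D 6 DCR + 6 DSCR network with 8 filters and schedule (1,1,2,3,2,1),
trained 300 Adam steps at batch 8 on the foreground coronal 64x64 slices of
two 64^3 phantoms at 9% noise, then evaluated on a held-out phantom.  These
sizes were chosen so the whole study runs in minutes on one CPU core while
still training a genuine two-branch network; at this scale the held-out PSNR
gain is about +5 dB with a clear entropy drop.

## Known limitations

* No GPU path and no mixed precision; the NumPy backward pass is exact but
  not fast enough for full-scale 3-D training on real archives.
* Single-coil Rician noise only; multi-coil noncentral-chi noise, spatially
  varying sigma maps and noise-level estimation from data are out of scope.
* The published parameter total for this architecture is not reproducible
  from its description (see above); the counter reports what the constructed
  network actually contains.
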