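"""Rician degradation model for magnitude MR images.

A magnitude image acquired from a single coil carries independent zero-mean
Gaussian noise in the real and imaginary channels; the measured magnitude

    Y = sqrt((X + n1)^2 + n2^2),   n1, n2 ~ N(0, sigma^2)

therefore follows a Rician distribution with signal parameter nu = X and scale
sigma.  The deviation delta(Y) = Y - X is the residual a denoising network is
trained to predict.  Noise levels are stated as percentages following the
BrainWeb convention: "p% noise" means sigma = (p / 100) * reference_intensity,
with the reference defaulting to the maximum intensity of the clean volume.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.special import i0e

__all__ = [
    "NoiseSpec",
    "PairedSample",
    "sigma_from_level",
    "rician_corrupt",
    "residual_target",
    "rician_pdf",
]


def sigma_from_level(level_percent: float, reference_intensity: float) -> float:
    """Gaussian channel noise sigma for a percent noise level.

    sigma = (level_percent / 100) * reference_intensity.
    """
    if level_percent < 0:
        raise ValueError("noise level must be non-negative")
    if reference_intensity <= 0:
        raise ValueError("reference intensity must be positive")
    return (level_percent / 100.0) * reference_intensity


@dataclass(frozen=True)
class NoiseSpec:
    """Parameters of one Rician corruption.

    level_percent : noise level as a percentage of the reference intensity.
    reference_intensity : intensity whose fraction defines sigma (typically
        the clean volume's maximum).
    seed : RNG seed; a counter-based Philox stream keyed by it makes the noise
        field independent of evaluation order.
    """

    level_percent: float
    reference_intensity: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        sigma_from_level(self.level_percent, self.reference_intensity)  # validates

    @property
    def sigma(self) -> float:
        return sigma_from_level(self.level_percent, self.reference_intensity)

    @classmethod
    def for_volume(cls, clean: np.ndarray, level_percent: float,
                   seed: int = 0) -> "NoiseSpec":
        """Spec whose reference intensity is the clean volume's maximum."""
        ref = float(np.max(clean))
        if ref <= 0:
            raise ValueError("clean volume must contain positive intensities")
        return cls(level_percent=level_percent, reference_intensity=ref, seed=seed)


@dataclass(frozen=True)
class PairedSample:
    """A clean volume X, its Rician-corrupted version Y, and delta = Y - X."""

    clean: np.ndarray
    noisy: np.ndarray
    residual: np.ndarray
    spec: NoiseSpec | None = None


def rician_corrupt(clean: np.ndarray, spec: NoiseSpec) -> PairedSample:
    """Corrupt a non-negative volume with Rician noise at the given spec.

    Per voxel: ``noisy = sqrt((clean + n1)^2 + n2^2)`` with n1, n2 independent
    N(0, sigma^2) draws from a Philox stream seeded by ``spec.seed``.
    """
    clean = np.asarray(clean)
    if np.any(clean < 0):
        raise ValueError("clean intensities must be non-negative")
    sigma = spec.sigma
    if sigma == 0.0:
        noisy = clean.astype(np.float32, copy=True)
        return PairedSample(clean=clean, noisy=noisy,
                            residual=np.zeros_like(noisy), spec=spec)
    rng = np.random.Generator(np.random.Philox(spec.seed))
    n1 = rng.normal(0.0, sigma, size=clean.shape)
    n2 = rng.normal(0.0, sigma, size=clean.shape)
    noisy = np.hypot(clean + n1, n2).astype(np.float32)
    residual = (noisy - clean).astype(np.float32)
    return PairedSample(clean=clean, noisy=noisy, residual=residual, spec=spec)


def residual_target(noisy: np.ndarray, clean: np.ndarray) -> np.ndarray:
    """Elementwise deviation delta = noisy - clean (the training target)."""
    noisy = np.asarray(noisy)
    clean = np.asarray(clean)
    if noisy.shape != clean.shape:
        raise ValueError("noisy and clean volumes must share a shape")
    return noisy - clean


def rician_pdf(y, nu: float, sigma: float):
    """Rician probability density.

    p(y) = (y / sigma^2) exp(-(y^2 + nu^2) / (2 sigma^2)) I0(y nu / sigma^2)

    evaluated stably via the exponentially scaled Bessel function:
    p(y) = (y / sigma^2) exp(-(y - nu)^2 / (2 sigma^2)) i0e(y nu / sigma^2).
    At nu = 0 this reduces to the Rayleigh density.
    """
    if sigma <= 0:
        raise ValueError("sigma must be positive")
    if nu < 0:
        raise ValueError("nu must be non-negative")
    y = np.asarray(y, dtype=float)
    s2 = sigma * sigma
    out = (y / s2) * np.exp(-((y - nu) ** 2) / (2 * s2)) * i0e(y * nu / s2)
    return np.where(y >= 0, out, 0.0)
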