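"""Denoising quality metrics: PSNR (dB), SSIM, and histogram entropy in nats,
with masked per-tissue variants.

PSNR is ``10 log10(max_val^2 / MSE)`` with an infinity sentinel for identical
images.  SSIM follows the standard reference configuration (Gaussian window,
sigma 1.5, 11 taps per axis, K1 = 0.01, K2 = 0.03) via scikit-image.  Entropy
is ``-sum p ln p`` over an equal-width intensity histogram; lower values after
denoising indicate less residual randomness.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from skimage.metrics import structural_similarity

__all__ = ["MetricsReport", "psnr", "ssim", "entropy", "masked_metrics",
           "evaluate_pair"]

_SSIM_KW = dict(gaussian_weights=True, sigma=1.5, use_sample_covariance=False,
                K1=0.01, K2=0.03)


@dataclass
class MetricsReport:
    psnr: float
    ssim: float | None
    entropy: float
    per_label: dict[int, "MetricsReport"] = field(default_factory=dict)

    def to_dict(self) -> dict:
        d = {"psnr": self.psnr, "ssim": self.ssim, "entropy": self.entropy}
        if self.per_label:
            d["per_label"] = {str(k): v.to_dict() for k, v in self.per_label.items()}
        return d


def _check_shapes(reference: np.ndarray, test: np.ndarray) -> None:
    if reference.shape != test.shape:
        raise ValueError("reference and test volumes must share a shape")


def psnr(reference: np.ndarray, test: np.ndarray,
         max_val: float | None = None) -> float:
    """Peak signal-to-noise ratio in dB; +inf when the images are identical.

    ``max_val`` defaults to the reference volume's maximum intensity.
    """
    reference = np.asarray(reference, dtype=np.float64)
    test = np.asarray(test, dtype=np.float64)
    _check_shapes(reference, test)
    if max_val is None:
        max_val = float(reference.max())
    if max_val <= 0:
        raise ValueError("max_val must be positive")
    mse = float(np.mean((reference - test) ** 2))
    if mse == 0.0:
        return float("inf")
    return 10.0 * np.log10(max_val * max_val / mse)


def ssim(reference: np.ndarray, test: np.ndarray,
         max_val: float | None = None) -> float:
    """Mean structural similarity index over the volume."""
    reference = np.asarray(reference, dtype=np.float64)
    test = np.asarray(test, dtype=np.float64)
    _check_shapes(reference, test)
    if max_val is None:
        max_val = float(reference.max())
    if min(reference.shape) < 11:
        raise ValueError("volume smaller than the 11-tap SSIM window")
    return float(structural_similarity(reference, test, data_range=max_val,
                                       **_SSIM_KW))


def entropy(image: np.ndarray, n_bins: int = 256,
            value_range: tuple[float, float] | None = None) -> float:
    """Histogram entropy -sum p ln p in nats.

    Intensities are binned into ``n_bins`` equal-width bins over
    ``value_range`` (default ``[0, max]``); ``p`` is the bin mass divided by
    the voxel count.  A constant image has zero entropy.
    """
    image = np.asarray(image, dtype=np.float64)
    if n_bins < 1:
        raise ValueError("n_bins must be >= 1")
    if value_range is None:
        value_range = (0.0, float(image.max()))
    low, high = value_range
    if not high > low:
        # a constant all-zero image yields a degenerate default range
        if image.size and np.all(image == image.flat[0]):
            return 0.0
        raise ValueError("value range must satisfy high > low")
    hist, _ = np.histogram(image, bins=n_bins, range=(low, high))
    p = hist[hist > 0] / image.size
    return float(-(p * np.log(p)).sum())


def masked_metrics(reference: np.ndarray, test: np.ndarray, mask: np.ndarray,
                   max_val: float | None = None, n_bins: int = 256
                   ) -> MetricsReport:
    """Metrics restricted to a tissue mask.

    PSNR and entropy are computed over the masked voxels only.  SSIM is
    computed on the bounding box of the mask and averaged over the local SSIM
    map at in-mask positions; ``None`` when the box is smaller than the
    window.
    """
    reference = np.asarray(reference, dtype=np.float64)
    test = np.asarray(test, dtype=np.float64)
    _check_shapes(reference, test)
    mask = np.asarray(mask, dtype=bool)
    if mask.shape != reference.shape:
        raise ValueError("mask shape must match the volumes")
    if not mask.any():
        raise ValueError("mask is empty")
    if max_val is None:
        max_val = float(reference.max())
    rv = reference[mask]
    tv = test[mask]
    mse = float(np.mean((rv - tv) ** 2))
    p = float("inf") if mse == 0.0 else 10.0 * np.log10(max_val**2 / mse)

    hi = float(tv.max())
    e = entropy(tv, n_bins=n_bins, value_range=(0.0, hi) if hi > 0 else None)

    s: float | None = None
    bbox = tuple(slice(int(idx.min()), int(idx.max()) + 1)
                 for idx in np.nonzero(mask))
    ref_c, test_c, mask_c = reference[bbox], test[bbox], mask[bbox]
    if min(ref_c.shape) >= 11:
        _, smap = structural_similarity(ref_c, test_c, data_range=max_val,
                                        full=True, **_SSIM_KW)
        # average over in-mask voxels away from the window-radius border, the
        # same interior the unmasked mean SSIM is taken over
        pad = 5  # radius of the 11-tap window
        interior = tuple(slice(pad, n - pad) for n in smap.shape)
        mask_i = mask_c[interior]
        if mask_i.any():
            s = float(smap[interior][mask_i].mean())
    return MetricsReport(psnr=p, ssim=s, entropy=e)


def evaluate_pair(reference: np.ndarray, test: np.ndarray,
                  labels: np.ndarray | None = None,
                  max_val: float | None = None, n_bins: int = 256
                  ) -> MetricsReport:
    """Whole-volume report, optionally with per-tissue sub-reports."""
    report = MetricsReport(
        psnr=psnr(reference, test, max_val),
        ssim=ssim(reference, test, max_val) if min(np.shape(reference)) >= 11
        else None,
        entropy=entropy(test, n_bins=n_bins),
    )
    if labels is not None:
        for label in np.unique(labels):
            mask = labels == label
            if mask.any():
                report.per_label[int(label)] = masked_metrics(
                    reference, test, mask, max_val, n_bins)
    return report
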