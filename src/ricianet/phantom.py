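"""Deterministic brain-like phantoms with CSF/GM/WM tissue classes.

The generator rasterizes three nested, seed-jittered ellipsoids into a label
grid (0 background, 1 CSF shell, 2 GM shell, 3 WM core) and maps labels to
configured class intensities on a [0, 1] scale.  Optional Gaussian smoothing
of the intensity grid creates partial-volume edges; the label grid is always
returned unsmoothed so tissue masks stay crisp.  Identical (shape, seed,
intensities) inputs reproduce bit-identical phantoms.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

__all__ = [
    "Phantom",
    "DEFAULT_CLASS_INTENSITIES",
    "phantom_geometry",
    "generate_phantom",
    "tissue_mask",
]

#: Default tissue intensities: distinct, well-separated levels in [0, 1].
DEFAULT_CLASS_INTENSITIES = {1: 0.25, 2: 0.55, 3: 0.85}

#: Fraction of the half-extent occupied by the outer (CSF) ellipsoid, and the
#: relative sizes of the GM and WM ellipsoids nested inside it.
_OUTER_FRACTION = 0.42
_SHELL_FRACTIONS = {1: 1.0, 2: 0.80, 3: 0.55}


@dataclass
class Phantom:
    """A clean volume with its tissue segmentation.

    intensity: float32 grid of non-negative intensities (arbitrary units).
    labels: uint8 grid in {0 background, 1 CSF, 2 GM, 3 WM}, same shape.
    spacing: per-axis voxel size in mm.
    """

    intensity: np.ndarray
    labels: np.ndarray
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)
    class_intensities: dict[int, float] = field(
        default_factory=lambda: dict(DEFAULT_CLASS_INTENSITIES))

    def __post_init__(self) -> None:
        if self.intensity.shape != self.labels.shape:
            raise ValueError("intensity and labels must share a shape")


def phantom_geometry(shape: tuple[int, int, int], seed: int
                     ) -> dict[int, tuple[np.ndarray, np.ndarray]]:
    """Seed-jittered ellipsoid (center, semi-axes) per tissue label.

    Exposed separately so the rasterization can be verified independently
    against the same ellipsoid equations.
    """
    rng = np.random.default_rng(seed)
    extent = np.asarray(shape, dtype=float)
    base_center = (extent - 1) / 2.0
    geometry: dict[int, tuple[np.ndarray, np.ndarray]] = {}
    for label in (1, 2, 3):
        jitter_c = rng.uniform(-0.02, 0.02, size=3) * extent
        jitter_a = rng.uniform(-0.04, 0.04, size=3)
        center = base_center + jitter_c
        semiaxes = _OUTER_FRACTION * _SHELL_FRACTIONS[label] * extent * (1.0 + jitter_a)
        geometry[label] = (center, semiaxes)
    return geometry


def _inside(shape, center, semiaxes) -> np.ndarray:
    grids = np.ogrid[tuple(slice(0, s) for s in shape)]
    q = sum(((g - c) / a) ** 2 for g, c, a in zip(grids, center, semiaxes))
    return q <= 1.0


def generate_phantom(shape: tuple[int, int, int], seed: int,
                     class_intensities: dict[int, float] | None = None,
                     smooth_sigma: float = 0.0,
                     spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)
                     ) -> Phantom:
    """Generate a deterministic nested-ellipsoid phantom.

    Parameters
    ----------
    shape : three positive integers, each >= 16.
    seed : integer controlling the ellipsoid jitter (no global RNG is touched).
    class_intensities : map label -> intensity for labels 1..3; defaults to
        0.25 (CSF) < 0.55 (GM) < 0.85 (WM).
    smooth_sigma : standard deviation (voxels) of an optional Gaussian blur of
        the intensity grid, emulating partial-volume edges.  The label grid is
        never smoothed.
    """
    shape = tuple(int(s) for s in shape)
    if len(shape) != 3 or any(s <= 0 for s in shape):
        raise ValueError("shape must be three positive integers")
    if any(s < 16 for s in shape):
        raise ValueError("phantom shape must be at least 16 per axis")
    if smooth_sigma < 0:
        raise ValueError("smooth_sigma must be non-negative")
    intensities = dict(DEFAULT_CLASS_INTENSITIES if class_intensities is None
                       else class_intensities)
    for label in (1, 2, 3):
        if label not in intensities:
            raise ValueError(f"missing class intensity for label {label}")
        if intensities[label] < 0:
            raise ValueError("class intensities must be non-negative")

    labels = np.zeros(shape, dtype=np.uint8)
    for label in (1, 2, 3):  # outer to inner: later labels overwrite
        center, semiaxes = phantom_geometry(shape, seed)[label]
        labels[_inside(shape, center, semiaxes)] = label

    intensity = np.zeros(shape, dtype=np.float32)
    for label in (1, 2, 3):
        intensity[labels == label] = intensities[label]
    if smooth_sigma > 0:
        intensity = ndimage.gaussian_filter(intensity, smooth_sigma).astype(np.float32)
    return Phantom(intensity=intensity, labels=labels,
                   spacing=tuple(float(s) for s in spacing),
                   class_intensities=intensities)


def tissue_mask(phantom: Phantom, label: int) -> np.ndarray:
    """Boolean mask of one tissue class (0 background, 1 CSF, 2 GM, 3 WM)."""
    if label not in (0, 1, 2, 3):
        raise ValueError("label must be one of 0, 1, 2, 3")
    return phantom.labels == label
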