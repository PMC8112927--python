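"""Sliding-window patch extraction, overlap-averaged reassembly, slice
extraction and rotation/mirror augmentation.

Volumes are indexed (x = sagittal, y = coronal, z = axial), 0-based, matching
the canonical NIfTI orientation used by :mod:`ricianet.io`.  Training uses the
plain sliding grid; at inference an extra end-aligned window per axis can be
added so strides that do not tile an axis still cover every voxel.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np

__all__ = [
    "PatchGrid",
    "grid_count",
    "grid_positions",
    "extract_patches",
    "reassemble",
    "augment",
    "extract_slices",
    "stack_slices",
    "PLANE_AXES",
]

PLANE_AXES = {"sagittal": 0, "coronal": 1, "axial": 2}


def grid_count(length: int, window: int, stride: int) -> int:
    """Number of start offsets {0, S, 2S, ...} with last start <= L - W."""
    if window < 1 or stride < 1:
        raise ValueError("window and stride must be positive")
    if length < window:
        raise ValueError("axis length must be at least the window size")
    return (length - window) // stride + 1


def grid_positions(length: int, window: int, stride: int,
                   include_end: bool = False) -> tuple[int, ...]:
    """Sorted start offsets along one axis; ``include_end`` appends an
    end-aligned window when the stride does not tile the axis."""
    n = grid_count(length, window, stride)
    positions = list(range(0, n * stride, stride))
    if include_end and positions[-1] != length - window:
        positions.append(length - window)
    return tuple(positions)


@dataclass(frozen=True)
class PatchGrid:
    """Sliding-window geometry over one volume shape."""

    volume_shape: tuple[int, ...]
    window: tuple[int, ...]
    stride: tuple[int, ...]
    positions: tuple[tuple[int, ...], ...]

    @classmethod
    def build(cls, volume_shape, window, stride,
              include_end: bool = False) -> "PatchGrid":
        volume_shape = tuple(int(s) for s in volume_shape)
        window = tuple(int(w) for w in window)
        stride = tuple(int(s) for s in stride)
        if not len(volume_shape) == len(window) == len(stride):
            raise ValueError("volume shape, window and stride must have the "
                             "same number of axes")
        positions = tuple(
            grid_positions(length, w, s, include_end)
            for length, w, s in zip(volume_shape, window, stride))
        return cls(volume_shape, window, stride, positions)

    @property
    def n_patches(self) -> int:
        return int(np.prod([len(p) for p in self.positions]))

    def starts(self):
        """Row-major iteration over window start corners."""
        return itertools.product(*self.positions)


def extract_patches(volume: np.ndarray, window, stride,
                    include_end: bool = False) -> tuple[np.ndarray, PatchGrid]:
    """Extract sliding-window patches in row-major grid order.

    Returns an array of shape ``(n_patches, *window)`` plus the grid needed to
    reassemble the volume.
    """
    volume = np.asarray(volume)
    grid = PatchGrid.build(volume.shape, window, stride, include_end)
    patches = np.empty((grid.n_patches,) + grid.window, dtype=volume.dtype)
    for i, corner in enumerate(grid.starts()):
        sl = tuple(slice(c, c + w) for c, w in zip(corner, grid.window))
        patches[i] = volume[sl]
    return patches, grid


def reassemble(patches: np.ndarray, grid: PatchGrid) -> np.ndarray:
    """Overlap-averaged reconstruction: each voxel is the arithmetic mean of
    every patch value covering it.  Voxels covered by no window (possible when
    the stride does not tile the axis and ``include_end`` was not used) are
    filled with zero."""
    patches = np.asarray(patches)
    if patches.shape[0] != grid.n_patches:
        raise ValueError(f"expected {grid.n_patches} patches, got {patches.shape[0]}")
    if patches.shape[1:] != grid.window:
        raise ValueError("patch shape does not match the grid window")
    acc = np.zeros(grid.volume_shape, dtype=np.float64)
    count = np.zeros(grid.volume_shape, dtype=np.int32)
    for patch, corner in zip(patches, grid.starts()):
        sl = tuple(slice(c, c + w) for c, w in zip(corner, grid.window))
        acc[sl] += patch
        count[sl] += 1
    covered = count > 0
    acc[covered] /= count[covered]
    return acc.astype(patches.dtype if patches.dtype.kind == "f" else np.float32)


def _rot90(volume: np.ndarray) -> np.ndarray:
    # 90-degree in-plane rotation; for 3-D volumes the axial plane (x, y)
    return np.rot90(volume, k=1, axes=(0, 1))


def _mirror(volume: np.ndarray) -> np.ndarray:
    # reflection along the first (sagittal) axis
    return np.flip(volume, axis=0)


def augment(volume: np.ndarray) -> list[np.ndarray]:
    """Factor-4 augmentation: identity, 90-degree in-plane rotation, mirror,
    mirrored-then-rotated, in that fixed order."""
    volume = np.asarray(volume)
    m = _mirror(volume)
    return [volume.copy(), _rot90(volume), m.copy(), _rot90(m)]


def extract_slices(volume: np.ndarray, plane: str) -> list[np.ndarray]:
    """2-D slices along an anatomical plane in ascending index order.

    ``sagittal`` slices along x, ``coronal`` along y, ``axial`` along z.
    """
    volume = np.asarray(volume)
    if volume.ndim != 3:
        raise ValueError("extract_slices requires a 3-D volume")
    if plane not in PLANE_AXES:
        raise ValueError(f"unknown plane {plane!r}; expected one of "
                         f"{sorted(PLANE_AXES)}")
    axis = PLANE_AXES[plane]
    moved = np.moveaxis(volume, axis, 0)
    return [np.ascontiguousarray(moved[i]) for i in range(moved.shape[0])]


def stack_slices(slices, plane: str) -> np.ndarray:
    """Inverse of :func:`extract_slices`."""
    if plane not in PLANE_AXES:
        raise ValueError(f"unknown plane {plane!r}")
    return np.moveaxis(np.stack(slices, axis=0), 0, PLANE_AXES[plane])
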