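"""Sliding-window patch geometry for volumetric training and inference.

Patch counts follow floor((L - W) / S) + 1 per axis; overlapping predictions
are averaged at reassembly, which is an exact identity when the grid covers
every voxel.
"""

import numpy as np

from ricianet import PatchGrid, extract_patches, grid_count, reassemble

# 64^3 windows with stride 48x48x32 over a 256x256x128 brain volume
grid = PatchGrid.build((256, 256, 128), (64, 64, 64), (48, 48, 32))
print("patches per volume:", grid.n_patches, "->", grid.n_patches * 60,
      "for 60 training volumes")

grid = PatchGrid.build((256, 256, 64), (64, 64, 64), (32, 32, 64))
print("abdominal test volumes:", grid.n_patches, "->", grid.n_patches * 10,
      "for 10 volumes")

# round trip: extract -> overlap-average -> identical volume
volume = np.random.default_rng(0).random((64, 96, 64)).astype(np.float32)
patches, grid = extract_patches(volume, (32, 32, 32), (16, 32, 16))
print("round-trip max abs error:",
      float(np.abs(reassemble(patches, grid) - volume).max()))
print("per-axis counts:",
      [grid_count(s, 32, t) for s, t in zip(volume.shape, (16, 32, 16))])
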