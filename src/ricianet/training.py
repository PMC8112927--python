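"""Residual MSE objective, training loop and patch-based volume denoising.

The network is trained to predict the deviation delta = Y - X; the loss is

    L(theta) = (1/N) sum_i || Y_i - f(Y_i; theta) - X_i ||^2

where the per-sample norm is the sum of squared voxel differences.  For
learning-rate stability the default training reduction divides additionally
by the voxel count (pure per-voxel MSE); both reductions share the same
minimiser.  Optimisation uses Adam (learning rate 1e-3 by default).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .arch import ArchConfig, build_parallel_network
from .nn import Adam, ParallelRicianNet
from .patching import extract_patches, reassemble

__all__ = [
    "TrainConfig",
    "TrainState",
    "residual_mse_loss",
    "train",
    "denoise_volume",
    "save_model",
    "load_model",
]


@dataclass
class TrainConfig:
    learning_rate: float = 1e-3
    optimizer: str = "adam"
    batch_size: int = 8
    steps: int = 300
    seed: int = 0
    val_every: int = 50
    val_fraction: float = 0.1

    def __post_init__(self) -> None:
        if self.learning_rate < 0:
            raise ValueError("learning rate must be non-negative")
        if self.optimizer != "adam":
            raise ValueError("only the adam optimizer is supported")
        if self.batch_size < 1 or self.steps < 1 or self.val_every < 1:
            raise ValueError("batch_size, steps and val_every must be positive")


@dataclass
class TrainState:
    model: ParallelRicianNet
    step: int = 0
    history: dict[str, list] = field(default_factory=lambda: {
        "step": [], "train_loss": [], "val_step": [], "val_loss": []})
    best_val: float = float("inf")
    best_state: dict[str, np.ndarray] | None = None


def residual_mse_loss(noisy_batch: np.ndarray, clean_batch: np.ndarray,
                      predicted_deviation_batch: np.ndarray,
                      reduction: str = "per_voxel") -> float:
    """Residual mean squared error.

    ``per_sample`` returns the literal objective: the mean over samples of the
    *sum* of squared voxel errors.  ``per_voxel`` (default) divides by the
    voxel count as well; both have the same minimiser.
    """
    noisy = np.asarray(noisy_batch, dtype=np.float64)
    clean = np.asarray(clean_batch, dtype=np.float64)
    dev = np.asarray(predicted_deviation_batch, dtype=np.float64)
    if not noisy.shape == clean.shape == dev.shape:
        raise ValueError("noisy, clean and deviation batches must share a shape")
    if noisy.shape[0] < 1:
        raise ValueError("need at least one sample")
    err = (noisy - dev - clean) ** 2
    per_sample = err.reshape(err.shape[0], -1).sum(axis=1)
    if reduction == "per_sample":
        return float(per_sample.mean())
    if reduction == "per_voxel":
        return float(per_sample.mean() / np.prod(err.shape[1:]))
    raise ValueError("reduction must be 'per_sample' or 'per_voxel'")


def _as_batches(arr: np.ndarray) -> np.ndarray:
    # (n, *spatial) -> (n, 1, *spatial) float32
    return np.asarray(arr, dtype=np.float32)[:, None]


def train(model: ParallelRicianNet, noisy_patches: np.ndarray,
          clean_patches: np.ndarray, config: TrainConfig,
          log_fn=None) -> TrainState:
    """Train a deviation predictor on aligned (noisy, clean) patches.

    Patches are ``(n, *spatial)`` arrays; a seeded RNG draws batches with
    replacement.  A validation split (last ``val_fraction`` of the patches) is
    evaluated every ``val_every`` steps and the best-validation weights are
    kept in the returned state.
    """
    noisy = _as_batches(noisy_patches)
    clean = _as_batches(clean_patches)
    if noisy.shape != clean.shape:
        raise ValueError("noisy and clean patch sets must share a shape")
    n = noisy.shape[0]
    if n == 0:
        raise ValueError("empty patch source")
    n_val = int(round(n * config.val_fraction))
    n_train = n - n_val
    if n_train < 1:
        n_train, n_val = n, 0
    rng = np.random.default_rng(config.seed)
    opt = Adam(model.trainable_params(), lr=config.learning_rate)
    state = TrainState(model=model)
    voxels = int(np.prod(noisy.shape[1:]))

    for step in range(1, config.steps + 1):
        idx = rng.integers(0, n_train, size=config.batch_size)
        yb, xb = noisy[idx], clean[idx]
        dev = model.forward(yb, training=True)
        resid = yb - xb
        diff = dev - resid
        loss = float(np.mean(diff.astype(np.float64) ** 2))
        if not np.isfinite(loss):
            raise RuntimeError(f"non-finite training loss at step {step}")
        model.zero_grad()
        model.backward((2.0 / (config.batch_size * voxels)) * diff)
        opt.step()
        state.step = step
        state.history["step"].append(step)
        state.history["train_loss"].append(loss)
        if log_fn is not None:
            log_fn({"event": "train_step", "step": step, "loss": loss})
        if n_val and (step % config.val_every == 0 or step == config.steps):
            vdev = model.forward(noisy[n_train:], training=False)
            vloss = float(np.mean((vdev - (noisy[n_train:] - clean[n_train:]))
                                  .astype(np.float64) ** 2))
            state.history["val_step"].append(step)
            state.history["val_loss"].append(vloss)
            if vloss < state.best_val:
                state.best_val = vloss
                state.best_state = {k: v.copy()
                                    for k, v in model.state_dict().items()}
            if log_fn is not None:
                log_fn({"event": "validation", "step": step, "loss": vloss})
    return state


def denoise_volume(model: ParallelRicianNet, noisy: np.ndarray,
                   window=None, stride=None, batch_size: int = 4) -> np.ndarray:
    """Denoise a full volume (or 2-D image) by patch-wise residual prediction.

    Patches are extracted on the sliding grid (with end-aligned extra windows
    so every voxel is covered), the deviation is predicted per patch, clean
    patches ``Y - f(Y)`` are formed, and overlapping predictions are averaged.
    With ``window=None`` the whole array is processed in one pass.
    """
    noisy = np.asarray(noisy, dtype=np.float32)
    if noisy.ndim != model.dim:
        raise ValueError(f"model is {model.dim}-D but input is {noisy.ndim}-D")
    if window is None:
        out = model.denoise(noisy[None, None])[0, 0]
        if not np.all(np.isfinite(out)):
            raise RuntimeError("non-finite values in the denoised output")
        return out
    window = tuple(int(w) for w in window)
    stride = tuple(int(s) for s in (stride if stride is not None else window))
    if any(n < w for n, w in zip(noisy.shape, window)):
        raise ValueError("volume is smaller than the window")
    patches, grid = extract_patches(noisy, window, stride, include_end=True)
    denoised = np.empty_like(patches)
    for i in range(0, patches.shape[0], batch_size):
        batch = patches[i:i + batch_size][:, None]
        denoised[i:i + batch_size] = model.denoise(batch)[:, 0]
    out = reassemble(denoised, grid).astype(np.float32)
    if not np.all(np.isfinite(out)):
        raise RuntimeError("non-finite values in the denoised output")
    return out


def save_model(model: ParallelRicianNet, config: ArchConfig, path) -> None:
    """Save weights (npz) plus a JSON architecture manifest alongside."""
    path = Path(path)
    np.savez(path, **model.state_dict())
    manifest = path.with_suffix(".json")
    manifest.write_text(json.dumps(config.to_dict(), indent=2))


def load_model(path) -> tuple[ParallelRicianNet, ArchConfig]:
    """Load a checkpoint saved by :func:`save_model`."""
    path = Path(path)
    if path.suffix != ".npz":
        path = path.with_suffix(".npz")
    config = ArchConfig.from_dict(json.loads(path.with_suffix(".json").read_text()))
    model = build_parallel_network(config)
    with np.load(path) as data:
        model.load_state_dict({k: data[k] for k in data.files})
    return model, config
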