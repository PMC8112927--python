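"""NIfTI I/O, run configuration, and the end-to-end pipeline.

Volumes are read with nibabel, reoriented to the closest canonical (RAS)
orientation so that axis 0 is sagittal, axis 1 coronal and axis 2 axial, and
returned as float32.  The pipeline ties the stages together:
phantom -> Rician corruption -> slice/patch extraction -> training ->
denoising -> evaluation, with every randomized stage consuming a named
sub-seed derived from the global seed.
"""

from __future__ import annotations

import csv
import json
import zlib
from dataclasses import dataclass, field, asdict
from pathlib import Path

import nibabel as nib
import numpy as np
import yaml

from . import metrics as metrics_mod
from .arch import ArchConfig, build_parallel_network
from .noise import NoiseSpec, rician_corrupt
from .patching import augment, extract_slices
from .phantom import DEFAULT_CLASS_INTENSITIES, generate_phantom
from .training import TrainConfig, denoise_volume, save_model, train

__all__ = [
    "read_volume",
    "write_volume",
    "RunConfig",
    "load_config",
    "save_config",
    "sub_seed",
    "run_pipeline",
]


def read_volume(path) -> tuple[np.ndarray, dict]:
    """Read a NIfTI volume as float32 in canonical orientation.

    Returns ``(data, meta)`` where meta records the affine after
    canonicalisation and the original orientation string.
    """
    path = Path(path)
    if not path.exists():
        raise IOError(f"no such file: {path}")
    try:
        img = nib.load(str(path))
    except Exception as exc:  # corrupt or unsupported file
        raise IOError(f"could not read NIfTI file {path}: {exc}") from exc
    if len(img.shape) != 3:
        raise ValueError(f"expected a 3-D volume, got {len(img.shape)}-D "
                         f"data in {path}")
    orig_orientation = "".join(nib.aff2axcodes(img.affine))
    img = nib.as_closest_canonical(img)
    data = np.asarray(img.dataobj, dtype=np.float32)
    meta = {
        "affine": img.affine.copy(),
        "original_orientation": orig_orientation,
        "spacing": tuple(float(z) for z in img.header.get_zooms()[:3]),
    }
    return data, meta


def write_volume(path, data: np.ndarray, affine: np.ndarray | None = None,
                 spacing: tuple[float, ...] = (1.0, 1.0, 1.0),
                 dtype=np.float32) -> None:
    """Write a volume as NIfTI-1 (float32 by default); the affine defaults to
    a diagonal matrix encoding the voxel spacing."""
    data = np.asarray(data, dtype=dtype)
    if affine is None:
        affine = np.diag(list(spacing[:3]) + [1.0])
    nib.save(nib.Nifti1Image(data, affine), str(path))


def sub_seed(global_seed: int, name: str) -> int:
    """Deterministic named sub-seed below 2**31."""
    return (int(global_seed) * 2654435761 + zlib.crc32(name.encode())) % (2**31)


# ---------------------------------------------------------------------------
# Run configuration
# ---------------------------------------------------------------------------

@dataclass
class PhantomSection:
    shape: tuple[int, int, int] = (64, 64, 64)
    n_train: int = 2
    n_val: int = 1
    n_test: int = 1
    smooth_sigma: float = 0.8
    class_intensities: dict[int, float] = field(
        default_factory=lambda: dict(DEFAULT_CLASS_INTENSITIES))


@dataclass
class NoiseSection:
    level_percent: float = 9.0
    reference: str | float = "max"


@dataclass
class PatchSection:
    mode: str = "slices2d"        # "slices2d" or "patches3d"
    plane: str = "coronal"
    window: tuple[int, ...] = (32, 32, 32)
    stride: tuple[int, ...] = (16, 16, 16)
    augment: bool = False
    min_foreground: float = 0.05  # drop nearly-empty slices/patches


@dataclass
class EvalSection:
    n_bins: int = 256
    per_tissue: bool = True


@dataclass
class RunConfig:
    phantom: PhantomSection = field(default_factory=PhantomSection)
    noise: NoiseSection = field(default_factory=NoiseSection)
    arch: ArchConfig = field(default_factory=lambda: ArchConfig(
        dim=2, n_modules=6, filters=8,
        dilation_schedule=(1, 1, 2, 3, 2, 1)))
    training: TrainConfig = field(default_factory=TrainConfig)
    evaluation: EvalSection = field(default_factory=EvalSection)
    patching: PatchSection = field(default_factory=PatchSection)
    seed: int = 0
    out_dir: str = "run"
    verbosity: int = 1

    def to_dict(self) -> dict:
        d = asdict(self)
        d["arch"] = self.arch.to_dict()
        return d


_SECTION_TYPES = {
    "phantom": PhantomSection,
    "noise": NoiseSection,
    "patching": PatchSection,
    "training": TrainConfig,
    "evaluation": EvalSection,
}


def _build_section(cls, payload: dict, name: str):
    valid = set(cls.__dataclass_fields__)
    unknown = set(payload) - valid
    if unknown:
        raise ValueError(f"unknown keys in config section '{name}': "
                         f"{sorted(unknown)}")
    kwargs = {}
    for key, value in payload.items():
        if isinstance(value, list):
            value = tuple(value)
        if key == "class_intensities":
            value = {int(k): float(v) for k, v in value.items()}
        kwargs[key] = value
    return cls(**kwargs)


def load_config(path) -> RunConfig:
    """Load a YAML run configuration, validating sections and keys."""
    payload = yaml.safe_load(Path(path).read_text())
    if not isinstance(payload, dict):
        raise ValueError("config file must contain a mapping")
    required = set(_SECTION_TYPES) | {"arch"}
    missing = required - set(payload)
    if missing:
        raise ValueError(f"missing config sections: {sorted(missing)}")
    sections = {name: _build_section(cls, payload.get(name, {}) or {}, name)
                for name, cls in _SECTION_TYPES.items()}
    arch = ArchConfig.from_dict(payload["arch"])
    extras = {k: payload[k] for k in ("seed", "out_dir", "verbosity")
              if k in payload}
    return RunConfig(arch=arch, **sections, **extras)


def save_config(config: RunConfig, path) -> None:
    Path(path).write_text(yaml.safe_dump(config.to_dict(), sort_keys=False))


# ---------------------------------------------------------------------------
# Pipeline
# ---------------------------------------------------------------------------

def _foreground_fraction(image: np.ndarray) -> float:
    return float(np.mean(image > 0))


def _collect_training_pairs(config: RunConfig, phantom_seeds: list[int],
                            noise_tag: str):
    """Clean/noisy 2-D slices or 3-D patches from fresh phantoms."""
    ph = config.phantom
    pt = config.patching
    noisy_items, clean_items = [], []
    for k, pseed in enumerate(phantom_seeds):
        phantom = generate_phantom(ph.shape, pseed,
                                   class_intensities=ph.class_intensities,
                                   smooth_sigma=ph.smooth_sigma)
        clean = phantom.intensity
        ref = (float(clean.max()) if config.noise.reference == "max"
               else float(config.noise.reference))
        spec = NoiseSpec(config.noise.level_percent, ref,
                         seed=sub_seed(config.seed, f"{noise_tag}-{k}"))
        noisy = rician_corrupt(clean, spec).noisy
        if pt.mode == "slices2d":
            for c_sl, n_sl in zip(extract_slices(clean, pt.plane),
                                  extract_slices(noisy, pt.plane)):
                if _foreground_fraction(c_sl) < pt.min_foreground:
                    continue
                if pt.augment:
                    clean_items.extend(augment(c_sl))
                    noisy_items.extend(augment(n_sl))
                else:
                    clean_items.append(c_sl)
                    noisy_items.append(n_sl)
        elif pt.mode == "patches3d":
            from .patching import extract_patches
            c_patches, _ = extract_patches(clean, pt.window, pt.stride)
            n_patches, _ = extract_patches(noisy, pt.window, pt.stride)
            for c_p, n_p in zip(c_patches, n_patches):
                if _foreground_fraction(c_p) < pt.min_foreground:
                    continue
                clean_items.append(c_p)
                noisy_items.append(n_p)
        else:
            raise ValueError(f"unknown patching mode {pt.mode!r}")
    return np.stack(noisy_items), np.stack(clean_items)


def run_pipeline(config: RunConfig) -> dict:
    """Run phantom -> corrupt -> train -> denoise -> evaluate and write all
    artifacts (volumes, checkpoint, metrics CSV/JSON, resolved config, log)
    under ``config.out_dir``.  Returns a summary dictionary."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    log_path = out / "events.jsonl"
    log_file = log_path.open("w")

    def log(event: dict) -> None:
        log_file.write(json.dumps(event) + "\n")

    try:
        save_config(config, out / "config.resolved.yaml")
        ph = config.phantom
        train_seeds = [sub_seed(config.seed, f"phantom-train-{i}")
                       for i in range(ph.n_train + ph.n_val)]
        log({"event": "stage", "name": "data",
             "sub_seeds": {"phantoms": train_seeds}})
        noisy_p, clean_p = _collect_training_pairs(config, train_seeds, "noise-train")
        log({"event": "data", "n_pairs": int(noisy_p.shape[0]),
             "item_shape": list(noisy_p.shape[1:])})

        model = build_parallel_network(config.arch,
                                       init_seed=sub_seed(config.seed, "init"))
        tcfg = TrainConfig(**{**asdict(config.training),
                              "seed": sub_seed(config.seed, "train")})
        state = train(model, noisy_p, clean_p, tcfg, log_fn=log)
        if state.best_state is not None:
            model.load_state_dict(state.best_state)
        save_model(model, config.arch, out / "model.npz")

        # held-out evaluation phantom
        test_seed = sub_seed(config.seed, "phantom-test")
        phantom = generate_phantom(ph.shape, test_seed,
                                   class_intensities=ph.class_intensities,
                                   smooth_sigma=ph.smooth_sigma)
        clean = phantom.intensity
        ref = (float(clean.max()) if config.noise.reference == "max"
               else float(config.noise.reference))
        spec = NoiseSpec(config.noise.level_percent, ref,
                         seed=sub_seed(config.seed, "noise-test"))
        noisy = rician_corrupt(clean, spec).noisy
        write_volume(out / "clean.nii.gz", clean)
        write_volume(out / "noisy.nii.gz", noisy)
        write_volume(out / "labels.nii.gz", phantom.labels, dtype=np.uint8)

        if config.arch.dim == 2:
            plane = config.patching.plane
            den_slices = [denoise_volume(model, s)
                          for s in extract_slices(noisy, plane)]
            from .patching import stack_slices
            denoised = stack_slices(den_slices, plane)
        else:
            denoised = denoise_volume(model, noisy,
                                      window=config.patching.window,
                                      stride=config.patching.stride)
        write_volume(out / "denoised.nii.gz", denoised)

        max_val = float(clean.max())
        labels = phantom.labels if config.evaluation.per_tissue else None
        rep_noisy = metrics_mod.evaluate_pair(clean, noisy, labels, max_val,
                                              config.evaluation.n_bins)
        rep_den = metrics_mod.evaluate_pair(clean, denoised, labels, max_val,
                                            config.evaluation.n_bins)
        results = {"noisy": rep_noisy.to_dict(), "denoised": rep_den.to_dict(),
                   "final_train_loss": state.history["train_loss"][-1],
                   "best_val_loss": state.best_val}
        (out / "metrics.json").write_text(json.dumps(results, indent=2))
        with (out / "metrics.csv").open("w", newline="") as fh:
            writer = csv.writer(fh)
            writer.writerow(["volume", "psnr", "ssim", "entropy"])
            for name, rep in (("noisy", rep_noisy), ("denoised", rep_den)):
                writer.writerow([name, rep.psnr, rep.ssim, rep.entropy])
        log({"event": "done", "psnr_noisy": rep_noisy.psnr,
             "psnr_denoised": rep_den.psnr})
        return results
    finally:
        log_file.close()
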