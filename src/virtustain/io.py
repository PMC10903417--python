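"""Dataset I/O, run configuration, and the end-to-end pipeline.

Conventions (fixed so every artifact in a run is comparable):

* multi-page 16-bit TIFF; bright-field slices in acquisition z-order,
  fluorescence channels ordered droplets, cytoplasm, nuclei;
* intensities are normalised by the fixed constant 65535 (never per-image
  min–max), so a stored value of 65535 maps to exactly 1.0 and intensity
  features remain comparable across images;
* every pipeline run writes a manifest recording the seed, the config and
  its hash, and all produced files.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import asdict
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile
from pydantic import BaseModel, ConfigDict, field_validator

from . import phantom as ph
from .models import (DiscriminatorConfig, GeneratorConfig, build_discriminator,
                     build_generator, save_checkpoint)
from .training import TrainConfig, predict, train_cgan
from .metrics import evaluate_set
from .profiling import ProfilingConfig, SegmentationParams, profile_image
from .stats import build_report

log = logging.getLogger("virtustain")

NORM = 65535.0


class FormatError(ValueError):
    """A TIFF file does not match the declared pairing convention."""


def load_pair(entry: dict, root: str | Path = ".") -> tuple[np.ndarray, np.ndarray]:
    """Load one (bright-field stack, fluorescence target) pair.

    Returns float32 arrays of shapes (n_slices, H, W) and (3, H, W) on the
    [0, 1] scale (divisor 65535).
    """
    root = Path(root)
    bf = tifffile.imread(root / entry["brightfield"])
    fl = tifffile.imread(root / entry["fluorescence"])
    bf = np.atleast_3d(bf) if bf.ndim == 3 else bf[None]
    declared = int(entry.get("n_slices", bf.shape[0]))
    if bf.ndim != 3 or bf.shape[0] != declared:
        raise FormatError(
            f"{entry['brightfield']}: expected {declared} bright-field "
            f"pages, found {bf.shape[0] if bf.ndim == 3 else 1}")
    if fl.ndim != 3 or fl.shape[0] != 3:
        raise FormatError(
            f"{entry['fluorescence']}: expected 3 fluorescence pages")
    for name, arr in ((entry["brightfield"], bf), (entry["fluorescence"], fl)):
        if arr.dtype != np.uint16:
            raise FormatError(f"{name}: expected 16-bit pages, got {arr.dtype}")
    if bf.shape[1:] != fl.shape[1:]:
        raise FormatError("stack and target field sizes differ")
    return (bf.astype(np.float32) / NORM, fl.astype(np.float32) / NORM)


def load_dataset(index_path: str | Path) -> dict:
    """Read a dataset index and load all pairs, keyed by split."""
    index_path = Path(index_path)
    index = json.loads(index_path.read_text())
    root = index_path.parent
    out = {"train": [], "val": [], "entries": index["entries"]}
    for entry in index["entries"]:
        out[entry.get("split", "train")].append(load_pair(entry, root))
    return out


def _validated_section(section: dict, cls) -> dict:
    known = {f.name for f in dataclasses.fields(cls)}
    unknown = set(section) - known
    if unknown:
        raise ValueError(
            f"unknown {cls.__name__} keys: {sorted(unknown)}")
    return section


class RunConfig(BaseModel):
    """Schema-validated configuration of the end-to-end pipeline."""

    model_config = ConfigDict(extra="forbid")

    seed: int = 0
    n_fields: int = 60
    val_fraction: float = 0.2
    phantom: dict = {}
    generator: dict = {}
    discriminator: dict = {}
    train: dict = {}
    profiling: dict = {}
    tile: int = 128
    overlap: int = 32

    @field_validator("phantom")
    @classmethod
    def _v_phantom(cls, v):
        return _validated_section(v, ph.PhantomParams)

    @field_validator("generator")
    @classmethod
    def _v_gen(cls, v):
        return _validated_section(v, GeneratorConfig)

    @field_validator("discriminator")
    @classmethod
    def _v_disc(cls, v):
        return _validated_section(v, DiscriminatorConfig)

    @field_validator("train")
    @classmethod
    def _v_train(cls, v):
        return _validated_section(v, TrainConfig)

    @field_validator("profiling")
    @classmethod
    def _v_prof(cls, v):
        known = {f.name for f in dataclasses.fields(ProfilingConfig)}
        unknown = set(v) - known
        if unknown:
            raise ValueError(f"unknown profiling sections: {sorted(unknown)}")
        return {k: _validated_section(s, SegmentationParams)
                for k, s in v.items()}


def desk_phantom_params(seed: int | None = None) -> ph.PhantomParams:
    """Desk-scale 64-px phantom preset used by the smoke experiments.

    The geometry of the full-scale defaults is shrunk with the field: one
    cell per field with droplet-radius medians 2.5 / 7 px so both size
    populations fit a 64-px field while keeping the bright-field contrast
    hierarchy intact.
    """
    return ph.PhantomParams(
        field_size=(64, 64), n_cells=1, droplets_per_cell=12,
        small_radius_median=2.5, large_radius_median=7.0,
        large_fraction=0.25, nucleus_radius=7.0, cell_radius=26.0,
        cytoplasm_texture_scale=4.0, seed=seed)


def desk_profiling_config() -> ProfilingConfig:
    """Segmentation parameters matched to the 64-px phantom preset."""
    return ProfilingConfig(
        nuclei=SegmentationParams(diameter_range=(8.0, 30.0),
                                  threshold_strategy="adaptive",
                                  adaptive_window=32, declump="shape"),
        cytoplasm=SegmentationParams(diameter_range=(10.0, 60.0),
                                     threshold_strategy="adaptive",
                                     adaptive_window=64, declump="none",
                                     threshold_correction=0.7),
        droplets_small=SegmentationParams(diameter_range=(3.0, 11.0),
                                          threshold_strategy="global",
                                          declump="intensity"),
        droplets_large=SegmentationParams(diameter_range=(11.0, 36.0),
                                          threshold_strategy="global",
                                          declump="intensity",
                                          smoothing_sigma=2.5))


def _profiling_from_config(cfg: RunConfig) -> ProfilingConfig:
    base = desk_profiling_config()
    for section, params in cfg.profiling.items():
        setattr(base, section, SegmentationParams(**params))
    return base


def run_pipeline(config: RunConfig, out_dir: str | Path) -> Path:
    """simulate -> train -> predict -> evaluate -> profile -> report.

    All artifacts land under ``out_dir``; a stage failure aborts with a
    stage-tagged error, preserving prior stage outputs.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    cfg_json = json.dumps(config.model_dump(), sort_keys=True)
    cfg_hash = hashlib.sha256(cfg_json.encode()).hexdigest()[:16]
    log.info("pipeline start: seed=%d config_hash=%s", config.seed, cfg_hash)
    manifest = {"seed": config.seed, "config": config.model_dump(),
                "config_hash": cfg_hash, "outputs": [],
                "versions": {"numpy": np.__version__,
                             "virtustain": _version()}}

    def record(path: Path) -> Path:
        manifest["outputs"].append(str(path.relative_to(out_dir)))
        return path

    stage = "simulate"
    try:
        base = asdict(desk_phantom_params())
        base.update(config.phantom)
        base["seed"] = config.seed
        params = ph.PhantomParams(**base)
        data_dir = out_dir / "data"
        ph.make_dataset(config.n_fields, params, data_dir,
                        val_fraction=config.val_fraction)
        record(data_dir / "index.json")
        log.info("simulated %d fields", config.n_fields)

        stage = "load"
        data = load_dataset(data_dir / "index.json")
        train_pairs, val_pairs = data["train"], data["val"]

        stage = "train"
        n_slices = params.n_slices
        gcfg = GeneratorConfig(**{"in_channels": n_slices, "depth": 3,
                                  "base_width": 8, **config.generator})
        dcfg = DiscriminatorConfig(**{
            "in_channels": n_slices + gcfg.out_channels,
            "depth": 3, "base_width": 8, **config.discriminator})
        tcfg = TrainConfig(**{"epochs": 40, "seed": config.seed,
                              **config.train})
        gen = build_generator(gcfg, seed=config.seed)
        disc = build_discriminator(dcfg, seed=config.seed + 1)
        gen, history = train_cgan(train_pairs, val_pairs, gen, disc, tcfg)
        history.to_csv(record(out_dir / "history.csv"))
        save_checkpoint(gen, out_dir / "generator.npz")
        record(out_dir / "generator.npz")
        record(out_dir / "generator.json")

        stage = "predict"
        preds = [predict(gen, x, tile=config.tile, overlap=config.overlap)
                 for x, _ in val_pairs]
        pred_dir = out_dir / "predictions"
        pred_dir.mkdir(exist_ok=True)
        for i, p in enumerate(preds):
            tifffile.imwrite(record(pred_dir / f"pred_{i:04d}.tif"),
                             np.clip(p * NORM, 0, NORM).astype(np.uint16),
                             photometric="minisblack")

        stage = "evaluate"
        targets = [y for _, y in val_pairs]
        report = evaluate_set(preds, targets)
        report.to_csv(record(out_dir / "metrics.csv"))
        report.to_json(record(out_dir / "metrics.json"))

        stage = "profile"
        prof_cfg = _profiling_from_config(config)
        pred_rows, targ_rows = [], []
        for i, (p, t) in enumerate(zip(preds, targets)):
            _, pf = profile_image(p, prof_cfg, image_id=i)
            _, tf = profile_image(t, prof_cfg, image_id=i)
            pred_rows.append(pf)
            targ_rows.append(tf)
        pred_table = pd.concat(pred_rows, ignore_index=True)
        targ_table = pd.concat(targ_rows, ignore_index=True)
        pred_table.to_csv(record(out_dir / "features_pred.csv"), index=False)
        targ_table.to_csv(record(out_dir / "features_target.csv"), index=False)

        stage = "report"
        comparison = build_report(pred_table, targ_table)
        comparison.to_csv(record(out_dir / "comparison.csv"))
        comparison.to_json(record(out_dir / "comparison.json"))
    except Exception as exc:
        raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc

    (out_dir / "manifest.json").write_text(json.dumps(manifest, indent=2))
    log.info("pipeline done: %d outputs", len(manifest["outputs"]))
    return out_dir


def _version() -> str:
    from importlib.metadata import version, PackageNotFoundError
    try:
        return version("virtustain")
    except PackageNotFoundError:
        return "dev"


__all__ = ["FormatError", "RunConfig", "load_pair", "load_dataset",
           "run_pipeline", "desk_phantom_params", "desk_profiling_config",
           "NORM"]
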