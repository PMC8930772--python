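"""End-to-end pipeline: simulate -> train -> segment -> quantify -> stats.

One master seed fans out to stable per-stage seeds, so any stage can be
rerun independently yet reproducibly.  Every stage writes its outputs
under the run directory and records them (with SHA-256 hashes) in a
manifest; a completed stage is skipped on rerun unless forced.  The
segmentation stage can run either from a trained network checkpoint or
from oracle prediction maps (idealized network output built from the
ground truth), which exercises the identical inference and
quantification code path without the cost of training.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile
import yaml

from . import __version__
from .infer import cluster_instances, match_to_ground_truth, postprocess
from .network import EmbedNet, NetworkSpec
from .quant import ThresholdSweepSpec, summarize_field
from .rois import export_rois
from .scenes import (
    ARCHETYPES,
    Calibration,
    Scene,
    StrainArchetype,
    generate_experiment,
    generate_scene,
    load_scene,
    oracle_prediction_maps,
    save_scene,
)
from .stats import build_experiment_table, holm_sidak, linked_anova, report
from .train import TrainConfig, train

__all__ = [
    "RunConfig",
    "RunManifest",
    "run_pipeline",
    "make_fixtures",
    "stage_seed",
    "bridge_image",
    "three_disk_image",
    "disk_image",
]

log = logging.getLogger("dropseg")

_STAGES = ("simulate", "train", "segment", "quantify", "stats")


@dataclass
class RunConfig:
    seed: int = 0
    out_dir: str = "run"
    archetypes: list[str] = field(default_factory=lambda: ["wt_like", "null_like"])
    n_experiments: int = 3
    fields_per_strain: int = 3
    n_cells: int = 50
    image_shape: tuple[int, int] = (256, 256)
    border_fraction: float = 0.1
    pixel_size_um: float = 0.065
    segmentation: str = "network"  # "network" | "oracle"
    oracle_bandwidth: float = 0.02
    # training
    train_steps: int = 500
    train_scenes: int = 8
    val_scenes: int = 2
    train_cells: int = 10
    train_image: int = 128
    crop_size: int = 128
    batch_size: int = 2
    learning_rate: float = 1e-4
    augment: bool = True
    depth: int = 3
    base_channels: int = 16
    # quantification
    sweep_start: int = 20000
    sweep_stop: int = 2000
    sweep_step: int = 2000
    supersized_threshold: int = 10000
    supersized_area_um2: float = 0.5
    # statistics
    metric: str = "pct_cells_supersized"
    pairs: list[tuple[str, str]] = field(default_factory=list)

    def __post_init__(self) -> None:
        unknown = [a for a in self.archetypes if a not in ARCHETYPES]
        if unknown:
            raise ValueError(f"unknown archetypes {unknown}; available: {sorted(ARCHETYPES)}")
        if self.segmentation not in ("network", "oracle"):
            raise ValueError("segmentation must be 'network' or 'oracle'")
        self.image_shape = tuple(self.image_shape)

    @property
    def calibration(self) -> Calibration:
        return Calibration(pixel_size_um=self.pixel_size_um)

    @property
    def sweep(self) -> ThresholdSweepSpec:
        return ThresholdSweepSpec(
            start=self.sweep_start,
            stop=self.sweep_stop,
            step=self.sweep_step,
            supersized_threshold=self.supersized_threshold,
            supersized_area_um2=self.supersized_area_um2,
        )

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        data.setdefault("pairs", [])
        data["pairs"] = [tuple(p) for p in data["pairs"]]
        return cls(**data)

    def to_yaml(self, path: str | Path) -> None:
        data = dataclasses.asdict(self)
        data["image_shape"] = list(self.image_shape)
        data["pairs"] = [list(p) for p in self.pairs]
        Path(path).write_text(yaml.safe_dump(data, sort_keys=False))


@dataclass
class RunManifest:
    stages: dict[str, dict[str, str]]  # stage -> {relative path: sha256}
    versions: dict[str, str]
    timestamps: dict[str, float]
    log_path: str

    def save(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(dataclasses.asdict(self), indent=1))

    @classmethod
    def load(cls, path: str | Path) -> "RunManifest":
        return cls(**json.loads(Path(path).read_text()))

    def verify(self, root: str | Path) -> bool:
        root = Path(root)
        for files in self.stages.values():
            for rel, digest in files.items():
                p = root / rel
                if not p.exists() or _sha256(p) != digest:
                    return False
        return True


class _JsonLineFormatter(logging.Formatter):
    def format(self, record: logging.LogRecord) -> str:
        return json.dumps(
            {
                "time": self.formatTime(record),
                "level": record.levelname,
                "message": record.getMessage(),
            }
        )


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def stage_seed(master_seed: int, stage: str) -> int:
    """Stable per-stage seed derived from the master seed."""
    tag = int.from_bytes(hashlib.sha256(stage.encode()).digest()[:4], "big")
    return int(np.random.SeedSequence([int(master_seed), tag]).generate_state(1)[0])


def _scene_dirs(cfg: RunConfig) -> list[Path]:
    root = Path(cfg.out_dir) / "scenes"
    return sorted(p for p in root.glob("*") if (p / "scene.json").exists())


# ---------------------------------------------------------------------------
# stages

def stage_simulate(cfg: RunConfig) -> list[Path]:
    out = Path(cfg.out_dir) / "scenes"
    archs = [ARCHETYPES[a] for a in cfg.archetypes]
    scenes = generate_experiment(
        archs,
        cfg.n_experiments,
        cfg.fields_per_strain,
        stage_seed(cfg.seed, "simulate"),
        n_cells=cfg.n_cells,
        image_shape=cfg.image_shape,
        calibration=cfg.calibration,
        border_fraction=cfg.border_fraction,
    )
    paths = []
    for sc in scenes:
        d = out / f"{sc.strain_tag}_e{sc.experiment_id}_f{sc.field_id}"
        save_scene(sc, d)
        paths.append(d)
    log.info("simulate: wrote %d scenes (%d cells each)", len(scenes), cfg.n_cells)
    return paths


def stage_train(cfg: RunConfig) -> Path:
    seed = stage_seed(cfg.seed, "train")
    arch = ARCHETYPES[cfg.archetypes[0]]
    n_total = cfg.train_scenes + cfg.val_scenes
    shape = (cfg.train_image, cfg.train_image)
    scenes = [
        generate_scene(
            arch, cfg.train_cells, shape, cfg.calibration, seed + 1 + i,
            border_fraction=cfg.border_fraction,
        )
        for i in range(n_total)
    ]
    spec = NetworkSpec(depth=cfg.depth, base_channels=cfg.base_channels)
    tcfg = TrainConfig(
        crop_size=cfg.crop_size,
        steps=cfg.train_steps,
        learning_rate=cfg.learning_rate,
        batch_size=cfg.batch_size,
        augment=cfg.augment,
        seed=seed,
    )
    result = train(spec, scenes[: cfg.train_scenes], tcfg, scenes[cfg.train_scenes :])
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    ckpt = out / "checkpoint.npz"
    result.network.save(ckpt, extra={"coord_scale": tcfg.scale})
    result.trace.to_csv(out / "training_log.csv", index=False)
    result.val_trace.to_csv(out / "validation_log.csv", index=False)
    log.info(
        "train: %d steps, final loss %.4f, best val %.4f at step %d",
        cfg.train_steps, result.trace["total"].iloc[-1], result.best_val_loss, result.best_step,
    )
    return ckpt


def stage_segment(cfg: RunConfig) -> pd.DataFrame:
    net = None
    coord_scale = None
    if cfg.segmentation == "network":
        net, extra = EmbedNet.load(Path(cfg.out_dir) / "checkpoint.npz")
        coord_scale = float(extra["coord_scale"])
    rows = []
    for d in _scene_dirs(cfg):
        sc = load_scene(d)
        if net is None:
            maps = oracle_prediction_maps(sc, cfg.oracle_bandwidth)
        else:
            maps = net.predict_maps(sc.brightfield, coord_scale=coord_scale)
        raw = cluster_instances(maps)
        seg = postprocess(raw, sc.shape)
        export_rois(seg, d / "segmentation")
        seg.removals_table().to_csv(d / "segmentation" / "removals.csv", index=False)
        rep = match_to_ground_truth(seg, sc.label_image)
        rows.append(
            {
                "scene": d.name,
                "n_raw": len(raw),
                "n_kept": len(seg.instances),
                "mean_iou": rep.mean_iou,
                "matched": rep.n_matched,
                "merged": rep.n_merged,
                "split": rep.n_split,
                "missed": rep.n_missed,
            }
        )
        log.info("segment: %s -> %d cells (IoU %.3f)", d.name, len(seg.instances), rep.mean_iou)
    metrics = pd.DataFrame(rows)
    metrics.to_csv(Path(cfg.out_dir) / "segmentation_metrics.csv", index=False)
    return metrics


def stage_quantify(cfg: RunConfig) -> pd.DataFrame:
    rows_fields = []
    rows_cells = []
    for d in _scene_dirs(cfg):
        sc = load_scene(d)
        seg_dir = d / "segmentation"
        labels = tifffile.imread(seg_dir / "labels.tif")
        regions = {int(i): labels == i for i in np.unique(labels) if i != 0}
        if not regions:
            log.warning("quantify: %s has no retained cells; skipped", d.name)
            continue
        fs = summarize_field(
            sc.fluorescence,
            regions,
            cfg.sweep,
            cfg.calibration,
            strain_tag=sc.strain_tag,
            experiment_id=sc.experiment_id,
            field_id=sc.field_id,
        )
        cells = fs.cells.copy()
        cells.insert(0, "scene", d.name)
        rows_cells.append(cells)
        rows_fields.append(fs.row())
        log.info(
            "quantify: %s -> %d cells, %.2f LD/cell, %.1f%% supersized",
            d.name, fs.n_cells, fs.mean_ld_per_cell, fs.pct_cells_supersized,
        )
    fields = pd.DataFrame(rows_fields)
    fields.to_csv(Path(cfg.out_dir) / "fields.csv", index=False)
    cells = (
        pd.concat(rows_cells, ignore_index=True) if rows_cells else pd.DataFrame()
    )
    cells.to_csv(Path(cfg.out_dir) / "cells.csv", index=False)
    return fields


def stage_stats(cfg: RunConfig) -> pd.DataFrame:
    if not cfg.pairs:
        raise ValueError("no preselected strain pairs configured for the stats stage")
    fields = pd.read_csv(Path(cfg.out_dir) / "fields.csv")
    table = build_experiment_table(fields, cfg.metric)
    table.to_csv(Path(cfg.out_dir) / "experiment_table.csv", index=False)
    anova = linked_anova(table)
    pd.DataFrame(
        [
            {
                "F": anova.F,
                "p_value": anova.p_value,
                "df_strain": anova.df_strain,
                "df_block": anova.df_block,
                "df_residual": anova.df_residual,
                "ss_strain": anova.ss_strain,
                "ss_block": anova.ss_block,
                "ss_residual": anova.ss_residual,
            }
        ]
    ).to_csv(Path(cfg.out_dir) / "anova.csv", index=False)
    results = holm_sidak(cfg.pairs, table, anova)
    frame = report(results, Path(cfg.out_dir) / "pairwise.csv", anova)
    for r in results:
        log.info(
            "stats: %s vs %s adj. p = %.4g [%s]", r.pair[0], r.pair[1], r.p_adjusted, r.stars
        )
    return frame


_STAGE_FUNCS = {
    "simulate": stage_simulate,
    "train": stage_train,
    "segment": stage_segment,
    "quantify": stage_quantify,
    "stats": stage_stats,
}

_STAGE_OUTPUTS = {
    "simulate": ["scenes"],
    "train": ["checkpoint.npz", "training_log.csv"],
    "segment": ["segmentation_metrics.csv"],
    "quantify": ["fields.csv", "cells.csv"],
    "stats": ["experiment_table.csv", "anova.csv", "pairwise.csv"],
}


def _stage_done(cfg: RunConfig, stage: str) -> bool:
    root = Path(cfg.out_dir)
    if not all((root / rel).exists() for rel in _STAGE_OUTPUTS[stage]):
        return False
    if stage == "simulate":
        return len(_scene_dirs(cfg)) > 0
    if stage == "segment":
        dirs = _scene_dirs(cfg)
        return bool(dirs) and all(
            (d / "segmentation" / "labels.tif").exists() for d in dirs
        )
    return True


def _stage_files(cfg: RunConfig, stage: str) -> dict[str, str]:
    root = Path(cfg.out_dir)
    files: dict[str, str] = {}
    for rel in _STAGE_OUTPUTS[stage]:
        p = root / rel
        if p.is_dir():
            for f in sorted(p.rglob("*")):
                if f.is_file():
                    files[str(f.relative_to(root))] = _sha256(f)
        elif p.exists():
            files[rel] = _sha256(p)
    return files


def run_pipeline(cfg: RunConfig, force: bool = False) -> RunManifest:
    """Execute all stages in order; resume over existing outputs.

    A failing stage halts the run with the stage named; outputs of the
    earlier stages are preserved on disk.
    """
    root = Path(cfg.out_dir)
    root.mkdir(parents=True, exist_ok=True)
    log_path = root / "pipeline.log"
    handler = logging.FileHandler(log_path)
    handler.setFormatter(logging.Formatter("%(asctime)s %(levelname)s %(message)s"))
    jsonl_handler = logging.FileHandler(root / "pipeline.jsonl")
    jsonl_handler.setFormatter(_JsonLineFormatter())
    log.addHandler(handler)
    log.addHandler(jsonl_handler)
    log.setLevel(logging.INFO)
    cfg.to_yaml(root / "config.yaml")
    stages: dict[str, dict[str, str]] = {}
    timestamps: dict[str, float] = {}
    try:
        for stage in _STAGES:
            if stage == "train" and cfg.segmentation == "oracle":
                continue
            if not force and _stage_done(cfg, stage):
                log.info("%s: outputs present, skipping (use force to recompute)", stage)
            else:
                log.info("%s: running", stage)
                try:
                    _STAGE_FUNCS[stage](cfg)
                except Exception as exc:
                    raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc
            stages[stage] = _stage_files(cfg, stage)
            timestamps[stage] = time.time()
        manifest = RunManifest(
            stages=stages,
            versions={"dropseg": __version__, "numpy": np.__version__},
            timestamps=timestamps,
            log_path=str(log_path),
        )
        manifest.save(root / "manifest.json")
        return manifest
    finally:
        for h in (handler, jsonl_handler):
            log.removeHandler(h)
            h.close()


# ---------------------------------------------------------------------------
# canonical fixtures

def disk_image(
    radius: float,
    intensity: float,
    shape: tuple[int, int] = (96, 96),
    background: float = 300.0,
) -> np.ndarray:
    """One centred uniform disk on a clean background (uint16)."""
    h, w = shape
    rr, cc = np.meshgrid(np.arange(h), np.arange(w), indexing="ij")
    img = np.full(shape, background)
    img[(rr - h / 2) ** 2 + (cc - w / 2) ** 2 <= radius**2] = intensity
    return img.astype(np.uint16)


def three_disk_image(shape: tuple[int, int] = (64, 64)) -> np.ndarray:
    """Three disjoint uniform disks of intensity 25,000."""
    img = np.full(shape, 300.0)
    rr, cc = np.meshgrid(np.arange(shape[0]), np.arange(shape[1]), indexing="ij")
    for (r0, c0) in [(16, 16), (16, 46), (46, 30)]:
        img[(rr - r0) ** 2 + (cc - c0) ** 2 <= 5**2] = 25000.0
    return img.astype(np.uint16)


def bridge_image(shape: tuple[int, int] = (64, 64)) -> np.ndarray:
    """Two bright disks (25,000) joined by a 1-px bridge of 6,000.

    At lower thresholds of 8,000 and above the bridge is background and
    two particles are counted; at 6,000 and below the bridge joins them
    into one.
    """
    img = np.full(shape, 300.0)
    rr, cc = np.meshgrid(np.arange(shape[0]), np.arange(shape[1]), indexing="ij")
    img[(rr - 32) ** 2 + (cc - 16) ** 2 <= 5**2] = 25000.0
    img[(rr - 32) ** 2 + (cc - 48) ** 2 <= 5**2] = 25000.0
    img[32, 21:44] = 6000.0
    return img.astype(np.uint16)


def make_fixtures(out_dir: str | Path) -> dict[str, Path]:
    """Write the small canonical test images and an oracle scene."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}
    for name, img in [
        ("three_disks.tif", three_disk_image()),
        ("bridge.tif", bridge_image()),
        ("disk_r25.tif", disk_image(25, 30000, shape=(96, 96))),
        ("disk_r10.tif", disk_image(10, 30000)),
        ("disk_r5.tif", disk_image(5, 30000)),
        ("disk_dim9000.tif", disk_image(25, 9000, shape=(96, 96))),
    ]:
        p = out / name
        tifffile.imwrite(p, img)
        paths[name] = p
    sc = generate_scene(
        ARCHETYPES["bright_sparse"], 6, (128, 128), seed=7,
        border_fraction=0.0, disjoint_droplets=True,
    )
    paths["oracle_scene"] = save_scene(sc, out / "oracle_scene")
    return paths
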