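"""Pipeline-level validation experiments on synthetic data.

These routines exercise the full chain — scene generation,
segmentation (oracle maps or a trained network), threshold-sweep
quantification and the blocked ANOVA — to measure properties that no
single unit can show: type-I error calibration under a null generator,
and direction/power of the strain comparison under distinct archetypes.
Problem sizes default to desk-scale values (small fields, tens of
cells) chosen so a full calibration run completes in minutes on one
CPU; all sizes are parameters.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .infer import cluster_instances, match_to_ground_truth, postprocess
from .network import NetworkSpec
from .quant import FieldSummary, ThresholdSweepSpec, summarize_field
from .scenes import (
    ARCHETYPES,
    Calibration,
    Scene,
    StrainArchetype,
    generate_experiment,
    generate_scene,
    oracle_prediction_maps,
)
from .stats import build_experiment_table, holm_sidak, linked_anova
from .train import TrainConfig, train

__all__ = [
    "field_summaries_for_scenes",
    "type_i_error",
    "phenotype_comparison",
    "phenotype_power",
    "heldout_segmentation_iou",
]


def field_summaries_for_scenes(
    scenes: list[Scene],
    spec: ThresholdSweepSpec | None = None,
    segmentation: str = "ground_truth",
    oracle_bandwidth: float = 0.02,
) -> list[FieldSummary]:
    """Quantify every scene on ground-truth or oracle-segmented regions.

    ``segmentation='oracle'`` runs the real inference path (clustering
    of oracle prediction maps, size/border filters, convex hulls) and
    quantifies on the hull regions, mirroring the deployed pipeline
    without network training.
    """
    out = []
    for sc in scenes:
        if segmentation == "ground_truth":
            regions = {c.instance_id: sc.label_image == c.instance_id for c in sc.cells}
        elif segmentation == "oracle":
            maps = oracle_prediction_maps(sc, oracle_bandwidth)
            seg = postprocess(cluster_instances(maps), sc.shape)
            regions = seg.regions()
        else:
            raise ValueError(f"unknown segmentation mode {segmentation!r}")
        regions = {k: v for k, v in regions.items() if v.any()}
        out.append(
            summarize_field(
                sc.fluorescence,
                regions,
                spec,
                sc.calibration,
                strain_tag=sc.strain_tag,
                experiment_id=sc.experiment_id,
                field_id=sc.field_id,
            )
        )
    return out


def type_i_error(
    n_sets: int = 200,
    seed: int = 0,
    *,
    archetype: str | StrainArchetype = "bright_sparse",
    n_experiments: int = 3,
    fields_per_strain: int = 3,
    n_cells: int = 12,
    image_shape: tuple[int, int] = (160, 160),
    metric: str = "mean_ld_per_cell",
    alpha: float = 0.05,
) -> dict:
    """False-positive rate of the linked ANOVA under a null generator.

    Two pseudo-strains are drawn from the *same* archetype, the full
    generate -> quantify -> ANOVA chain runs, and the fraction of
    simulated experiment sets rejecting at ``alpha`` is returned.  A
    calibrated test should reject in about alpha of the sets.
    """
    arch = ARCHETYPES[archetype] if isinstance(archetype, str) else archetype
    pseudo_a = StrainArchetype(
        "pseudo_a", arch.droplets_per_cell_mean, arch.radius_log_mean,
        arch.radius_log_sd, arch.intensity_range, arch.clustering_prob,
    )
    pseudo_b = StrainArchetype(
        "pseudo_b", arch.droplets_per_cell_mean, arch.radius_log_mean,
        arch.radius_log_sd, arch.intensity_range, arch.clustering_prob,
    )
    rejections = 0
    root = np.random.SeedSequence(seed)
    for child in root.spawn(n_sets):
        set_seed = int(child.generate_state(1)[0])
        scenes = generate_experiment(
            [pseudo_a, pseudo_b],
            n_experiments,
            fields_per_strain,
            set_seed,
            n_cells=n_cells,
            image_shape=image_shape,
            border_fraction=0.0,
        )
        summaries = field_summaries_for_scenes(scenes)
        table = build_experiment_table(summaries, metric)
        if linked_anova(table).p_value < alpha:
            rejections += 1
    return {
        "rate": rejections / n_sets,
        "rejections": rejections,
        "n_sets": n_sets,
        "alpha": alpha,
    }


def phenotype_comparison(
    seed: int,
    *,
    strain_a: str = "wt_like",
    strain_b: str = "null_like",
    n_experiments: int = 3,
    fields_per_strain: int = 3,
    n_cells: int = 30,
    image_shape: tuple[int, int] = (224, 224),
    metric: str = "pct_cells_supersized",
    segmentation: str = "oracle",
) -> dict:
    """One full strain comparison: generate, segment, quantify, test."""
    scenes = generate_experiment(
        [ARCHETYPES[strain_a], ARCHETYPES[strain_b]],
        n_experiments,
        fields_per_strain,
        seed,
        n_cells=n_cells,
        image_shape=image_shape,
        border_fraction=0.05,
    )
    summaries = field_summaries_for_scenes(scenes, segmentation=segmentation)
    table = build_experiment_table(summaries, metric)
    anova = linked_anova(table)
    pw = holm_sidak([(strain_a, strain_b)], table, anova)[0]
    return {
        "mean_a": anova.strain_means[strain_a],
        "mean_b": anova.strain_means[strain_b],
        "anova_p": anova.p_value,
        "adjusted_p": pw.p_adjusted,
        "stars": pw.stars,
    }


def phenotype_power(
    n_seeds: int = 10,
    seed: int = 0,
    **kwargs,
) -> dict:
    """Direction and rejection rate of the strain comparison across seeds."""
    direction_ok = 0
    significant = 0
    runs = []
    root = np.random.SeedSequence(seed)
    for child in root.spawn(n_seeds):
        r = phenotype_comparison(int(child.generate_state(1)[0]), **kwargs)
        runs.append(r)
        if r["mean_b"] > r["mean_a"]:
            direction_ok += 1
        if r["adjusted_p"] < 0.05:
            significant += 1
    return {
        "n_seeds": n_seeds,
        "direction_fraction": direction_ok / n_seeds,
        "significant_fraction": significant / n_seeds,
        "mean_a": float(np.mean([r["mean_a"] for r in runs])),
        "mean_b": float(np.mean([r["mean_b"] for r in runs])),
        "runs": runs,
    }


@dataclass
class SegmentationEvaluation:
    mean_iou: float
    per_scene: list[float]
    n_matched: int
    n_missed: int
    n_merged: int
    final_train_loss: float


def heldout_segmentation_iou(
    seed: int = 0,
    *,
    steps: int = 500,
    n_train: int = 8,
    n_val: int = 2,
    n_cells: int = 10,
    image_size: int = 128,
    crop_size: int = 128,
    archetype: str = "wt_like",
    spec: NetworkSpec | None = None,
) -> SegmentationEvaluation:
    """Train on synthetic scenes and score mean IoU on held-out fields."""
    arch = ARCHETYPES[archetype]
    scenes = [
        generate_scene(
            arch, n_cells, (image_size, image_size), seed=seed * 1000 + i,
            border_fraction=0.1,
        )
        for i in range(n_train + n_val)
    ]
    cfg = TrainConfig(crop_size=crop_size, steps=steps, seed=seed)
    result = train(spec or NetworkSpec(), scenes[:n_train], cfg, scenes[n_train:])
    ious, matched, missed, merged = [], 0, 0, 0
    for sc in scenes[n_train:]:
        maps = result.network.predict_maps(sc.brightfield, coord_scale=cfg.scale)
        seg = postprocess(cluster_instances(maps), sc.shape)
        rep = match_to_ground_truth(seg, sc.label_image)
        ious.append(rep.mean_iou)
        matched += rep.n_matched
        missed += rep.n_missed
        merged += rep.n_merged
    return SegmentationEvaluation(
        mean_iou=float(np.mean(ious)),
        per_scene=ious,
        n_matched=matched,
        n_missed=missed,
        n_merged=merged,
        final_train_loss=float(result.trace["total"].iloc[-1]),
    )
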