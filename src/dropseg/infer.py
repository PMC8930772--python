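"""Instance inference from prediction maps, filtering and validation.

Clustering follows the iterative seed rule: among unassigned foreground
pixels (seed score above the seed threshold) the highest-scoring pixel
becomes the seed of a new instance, and every unassigned foreground
pixel whose Gaussian kernel affinity to the seed's embedding —
exp(-||e_i - e_s||^2 / (2 sigma_s^2)) with sigma_s the bandwidth
predicted at the seed pixel — exceeds the membership threshold joins
the instance.  The loop terminates because each round assigns at least
the seed itself (kernel value 1).  Ties in the seed score break to the
lexicographically smallest (row, col) for determinism.

Postprocessing removes instances smaller than 300 pixels ("falls
below" read as strict <, so exactly 300 px is retained) and instances
touching the image border, then takes convex hulls of the survivors;
downstream droplet counting runs on the hull regions, mirroring an
ImageJ ROI workflow.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.spatial import ConvexHull, QhullError
from skimage.morphology import convex_hull_image

from .maps import PredictionMaps

__all__ = [
    "RawInstance",
    "CellInstance",
    "SegmentationResult",
    "cluster_instances",
    "postprocess",
    "match_to_ground_truth",
    "MatchReport",
]


@dataclass
class RawInstance:
    pixels: np.ndarray  # (n, 2) int array of (row, col)
    seed_pixel: tuple[int, int]
    seed_score: float

    @property
    def area_px(self) -> int:
        return len(self.pixels)

    def mask(self, shape: tuple[int, int]) -> np.ndarray:
        m = np.zeros(shape, dtype=bool)
        m[self.pixels[:, 0], self.pixels[:, 1]] = True
        return m


@dataclass
class CellInstance:
    instance_id: int
    pixels: np.ndarray  # raw cluster pixels, (n, 2)
    area_px: int
    hull_polygon: np.ndarray  # (m, 2) hull vertices, (row, col), CCW
    touches_border: bool
    seed_pixel: tuple[int, int]
    seed_score_at_seed: float
    hull_mask_cache: np.ndarray | None = field(default=None, repr=False)

    def hull_mask(self, shape: tuple[int, int]) -> np.ndarray:
        """Rasterized convex-hull region (the downstream ROI)."""
        if self.hull_mask_cache is None or self.hull_mask_cache.shape != shape:
            m = np.zeros(shape, dtype=bool)
            m[self.pixels[:, 0], self.pixels[:, 1]] = True
            self.hull_mask_cache = convex_hull_image(m)
        return self.hull_mask_cache

    def raw_mask(self, shape: tuple[int, int]) -> np.ndarray:
        m = np.zeros(shape, dtype=bool)
        m[self.pixels[:, 0], self.pixels[:, 1]] = True
        return m


@dataclass
class SegmentationResult:
    instances: list[CellInstance]
    removed: list[tuple[RawInstance, str]]
    image_shape: tuple[int, int]
    params: dict

    def label_image(self) -> np.ndarray:
        """Hull-rendered labels; where hulls overlap the higher id wins."""
        lab = np.zeros(self.image_shape, dtype=np.int32)
        for inst in self.instances:
            lab[inst.hull_mask(self.image_shape)] = inst.instance_id
        return lab

    def regions(self) -> dict[int, np.ndarray]:
        """Hull region mask per instance id (regions may overlap)."""
        return {i.instance_id: i.hull_mask(self.image_shape) for i in self.instances}

    def removals_table(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "seed_row": r.seed_pixel[0],
                    "seed_col": r.seed_pixel[1],
                    "area_px": r.area_px,
                    "reason": reason,
                }
                for r, reason in self.removed
            ],
            columns=["seed_row", "seed_col", "area_px", "reason"],
        )


def cluster_instances(
    maps: PredictionMaps,
    seed_threshold: float = 0.5,
    membership_threshold: float = 0.5,
) -> list[RawInstance]:
    """Iterative seed clustering of foreground pixels into instances."""
    fg = maps.seed > seed_threshold
    if not fg.any():
        return []
    coords = np.argwhere(fg)  # sorted lexicographically by (row, col)
    scores = maps.seed[fg]
    e = maps.embeddings()
    emb = np.stack([e[0][fg], e[1][fg]], axis=1)
    bw = maps.bandwidth[fg]
    unassigned = np.ones(len(coords), dtype=bool)
    instances: list[RawInstance] = []
    log_thresh = -2.0 * np.log(membership_threshold) if membership_threshold > 0 else np.inf
    while unassigned.any():
        idx = np.flatnonzero(unassigned)
        # argmax picks the first maximum, i.e. smallest (row, col) on ties
        s = idx[np.argmax(scores[idx])]
        d2 = ((emb[idx] - emb[s]) ** 2).sum(axis=1)
        if np.isfinite(log_thresh):
            member = d2 < log_thresh * bw[s] ** 2  # exp(-d2/2s^2) > thr
        else:
            member = np.ones(len(idx), dtype=bool)
        member[idx == s] = True  # kernel value exactly 1 at the seed
        chosen = idx[member]
        instances.append(
            RawInstance(
                pixels=coords[chosen],
                seed_pixel=(int(coords[s, 0]), int(coords[s, 1])),
                seed_score=float(scores[s]),
            )
        )
        unassigned[chosen] = False
    return instances


def postprocess(
    raw_instances: list[RawInstance],
    image_shape: tuple[int, int],
    min_area_px: int = 300,
) -> SegmentationResult:
    """Apply the size and border filters and compute convex hulls."""
    h, w = image_shape
    counts = np.zeros(image_shape, dtype=np.int32)
    for r in raw_instances:
        counts[r.pixels[:, 0], r.pixels[:, 1]] += 1
    if (counts > 1).any():
        raise ValueError("input instances overlap; upstream contract violated")
    kept: list[CellInstance] = []
    removed: list[tuple[RawInstance, str]] = []
    next_id = 1
    for r in raw_instances:
        if r.area_px < min_area_px:
            removed.append((r, "small"))
            continue
        rows, cols = r.pixels[:, 0], r.pixels[:, 1]
        if (rows == 0).any() or (rows == h - 1).any() or (cols == 0).any() or (cols == w - 1).any():
            removed.append((r, "border"))
            continue
        kept.append(
            CellInstance(
                instance_id=next_id,
                pixels=r.pixels,
                area_px=r.area_px,
                hull_polygon=_hull_vertices(r.pixels),
                touches_border=False,
                seed_pixel=r.seed_pixel,
                seed_score_at_seed=r.seed_score,
            )
        )
        next_id += 1
    return SegmentationResult(
        instances=kept,
        removed=removed,
        image_shape=image_shape,
        params={"min_area_px": min_area_px},
    )


def _hull_vertices(pixels: np.ndarray) -> np.ndarray:
    """Convex hull vertex list (row, col) of integer pixel centres."""
    pts = np.asarray(pixels, dtype=float)
    try:
        hull = ConvexHull(pts)
        return pts[hull.vertices]
    except QhullError:
        # degenerate (collinear) pixel set: return its extreme points
        order = np.lexsort((pts[:, 1], pts[:, 0]))
        return pts[[order[0], order[-1]]]


@dataclass
class MatchReport:
    table: pd.DataFrame  # per-ground-truth rows
    mean_iou: float
    n_matched: int
    n_merged: int
    n_split: int
    n_missed: int


def match_to_ground_truth(
    result: SegmentationResult,
    label_image: np.ndarray,
    iou_threshold: float = 0.5,
    exclude_filtered_gt: bool = True,
) -> MatchReport:
    """Greedy best-IoU matching of predicted instances to ground truth.

    ``exclude_filtered_gt`` drops ground-truth cells that the pipeline's
    own filters would remove (border-touching or smaller than the
    configured minimum area), so the score reflects segmentation
    quality rather than filter bookkeeping.  mean_iou averages, over the
    evaluated ground-truth cells, the IoU with the matched prediction
    (0 when unmatched).
    """
    label_image = np.asarray(label_image)
    if label_image.shape != result.image_shape:
        raise ValueError("shape mismatch between result and label image")
    h, w = label_image.shape
    min_area = result.params.get("min_area_px", 0)
    gt_masks: dict[int, np.ndarray] = {}
    for gid in np.unique(label_image):
        if gid == 0:
            continue
        m = label_image == gid
        if exclude_filtered_gt:
            if m.sum() < min_area:
                continue
            if m[0].any() or m[-1].any() or m[:, 0].any() or m[:, -1].any():
                continue
        gt_masks[int(gid)] = m
    pred_masks = {i.instance_id: i.raw_mask(result.image_shape) for i in result.instances}

    ious: list[tuple[float, int, int]] = []
    inter: dict[tuple[int, int], int] = {}
    for gid, gm in gt_masks.items():
        for pid, pm in pred_masks.items():
            i = int((gm & pm).sum())
            if i:
                inter[(gid, pid)] = i
                u = int(gm.sum() + pm.sum() - i)
                ious.append((i / u, gid, pid))
    ious.sort(key=lambda t: (-t[0], t[1], t[2]))
    matched_gt: dict[int, tuple[int, float]] = {}
    used_pred: set[int] = set()
    for iou, gid, pid in ious:
        if iou < iou_threshold:
            break
        if gid in matched_gt or pid in used_pred:
            continue
        matched_gt[gid] = (pid, iou)
        used_pred.add(pid)

    # merged: a prediction covering >= half of two or more ground-truth cells
    n_merged = 0
    merged_gt: set[int] = set()
    for pid, pm in pred_masks.items():
        covered = [
            gid
            for gid, gm in gt_masks.items()
            if inter.get((gid, pid), 0) >= 0.5 * gm.sum()
        ]
        if len(covered) >= 2:
            n_merged += 1
            merged_gt.update(covered)
    # split: a ground-truth cell containing >= half of two or more predictions
    n_split = 0
    for gid, gm in gt_masks.items():
        inside = [
            pid
            for pid, pm in pred_masks.items()
            if inter.get((gid, pid), 0) >= 0.5 * pm.sum()
        ]
        if len(inside) >= 2:
            n_split += 1

    rows = []
    for gid in sorted(gt_masks):
        pid, iou = matched_gt.get(gid, (0, 0.0))
        status = "matched" if gid in matched_gt else ("merged" if gid in merged_gt else "missed")
        rows.append({"gt_id": gid, "pred_id": pid, "iou": iou, "status": status})
    table = pd.DataFrame(rows, columns=["gt_id", "pred_id", "iou", "status"])
    n_missed = int((table["status"] == "missed").sum()) if len(table) else 0
    mean_iou = float(table["iou"].mean()) if len(table) else 0.0
    return MatchReport(
        table=table,
        mean_iou=mean_iou,
        n_matched=len(matched_gt),
        n_merged=n_merged,
        n_split=n_split,
        n_missed=n_missed,
    )
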