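"""Training objective and loop for the embedding segmentation network.

For every ground-truth cell, the mean embedding and mean predicted
bandwidth over the cell's pixels define a Gaussian soft mask

    phi_k(i) = exp(-||e_i - e_bar_k||^2 / (2 sigma_bar_k^2)),

which the Dice loss drives to match the cell's binary mask.  The seed
map is regressed (squared error) to the gradient-detached soft-mask
value on cell pixels and to zero on background, so at inference the
seed score of a pixel predicts how well its embedding represents an
instance.  Training crops are randomly flipped and rotated; the
optimizer is Adam.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import autograd as ag
from .autograd import Tensor
from .maps import PredictionMaps
from .network import EmbedNet, NetworkSpec, normalize_image
from .scenes import Scene

__all__ = [
    "TrainConfig",
    "InstanceSoftMask",
    "soft_mask",
    "dice_loss",
    "training_loss",
    "train",
    "TrainResult",
]

_EPS = 1e-7


@dataclass(frozen=True)
class TrainConfig:
    crop_size: int = 128
    steps: int = 500
    learning_rate: float = 1e-4
    batch_size: int = 2
    augment: bool = True
    seed: int = 0
    seed_loss_weight: float = 1.0
    bandwidth_var_weight: float = 0.0  # optional bandwidth-consistency penalty
    eval_every: int = 50
    coord_scale: float = 0.0  # 0 -> crop_size

    def __post_init__(self) -> None:
        if self.learning_rate <= 0:
            raise ValueError("learning_rate must be positive")
        if self.crop_size < 8:
            raise ValueError("crop_size too small")

    @property
    def scale(self) -> float:
        return self.coord_scale or float(self.crop_size)


@dataclass
class InstanceSoftMask:
    cell_id: int
    mean_embedding: np.ndarray  # (2,)
    mean_bandwidth: float
    phi: np.ndarray  # (H, W) in (0, 1]


def soft_mask(maps: PredictionMaps, cell_pixels: np.ndarray, cell_id: int = 0) -> InstanceSoftMask:
    """Grow the Gaussian soft mask of one cell from prediction maps.

    ``cell_pixels`` is a boolean mask (or anything castable to one)
    selecting the cell's ground-truth pixels.
    """
    m = np.asarray(cell_pixels, dtype=bool)
    if m.shape != maps.shape:
        raise ValueError("cell pixel mask shape differs from maps")
    if not m.any():
        raise ValueError("cell pixel set is empty")
    e = maps.embeddings()
    e_bar = np.array([e[0][m].mean(), e[1][m].mean()])
    sigma = float(maps.bandwidth[m].mean())
    d2 = (e[0] - e_bar[0]) ** 2 + (e[1] - e_bar[1]) ** 2
    phi = np.exp(-d2 / (2.0 * sigma**2))
    return InstanceSoftMask(cell_id=cell_id, mean_embedding=e_bar, mean_bandwidth=sigma, phi=phi)


def dice_loss(phi: np.ndarray, target: np.ndarray, eps: float = _EPS) -> float:
    """1 - Dice overlap between a soft mask and a binary target."""
    phi = np.asarray(phi, dtype=np.float64)
    target = np.asarray(target, dtype=np.float64)
    if phi.shape != target.shape:
        raise ValueError("shape mismatch between soft mask and target")
    return float(1.0 - 2.0 * (phi * target).sum() / (phi.sum() + target.sum() + eps))


def _loss_graph(
    seed_t: Tensor,
    bw_t: Tensor,
    off_t: Tensor,
    coords: np.ndarray,
    label_image: np.ndarray,
    seed_weight: float,
    bandwidth_var_weight: float = 0.0,
):
    """Autograd graph of the full training loss for one crop.

    ``seed_t``/``bw_t``: (H, W) tensors; ``off_t``: (2, H, W) tensor;
    ``coords``: (2, H, W) normalized pixel coordinates (constant).
    Returns (total Tensor, dict of float terms).
    """
    e_r = Tensor(coords[0]) + _select0(off_t, 0)
    e_c = Tensor(coords[1]) + _select0(off_t, 1)
    ids = np.unique(label_image)
    ids = ids[ids > 0]
    inst_terms = []
    bw_terms = []
    seed_target = np.zeros(label_image.shape, dtype=np.float32)
    for k in ids:
        m = (label_image == k).astype(np.float32)
        n = float(m.sum())
        mt = Tensor(m)
        inv_n = 1.0 / n
        ebar_r = (e_r * mt).sum() * inv_n
        ebar_c = (e_c * mt).sum() * inv_n
        sbar = (bw_t * mt).sum() * inv_n
        d2 = (e_r - ebar_r) ** 2 + (e_c - ebar_c) ** 2
        phi = ag.exp(d2 * (-0.5) * (sbar**-2.0))
        inter = (phi * mt).sum()
        dice = 1.0 - inter * 2.0 * ((phi.sum() + n + _EPS) ** -1.0)
        inst_terms.append(dice)
        seed_target[m > 0] = phi.data[m > 0]
        if bandwidth_var_weight > 0:
            dev = (bw_t - sbar) * mt
            bw_terms.append((dev * dev).sum() * inv_n)
    if inst_terms:
        instance = inst_terms[0]
        for t in inst_terms[1:]:
            instance = instance + t
        instance = instance * (1.0 / len(inst_terms))
    else:
        instance = Tensor(0.0)
    diff = seed_t - Tensor(seed_target)
    seed_term = (diff * diff).mean()
    total = instance + seed_term * seed_weight
    terms = {
        "instance": float(instance.data),
        "seed": float(seed_term.data),
    }
    if bw_terms:
        bw_pen = bw_terms[0]
        for t in bw_terms[1:]:
            bw_pen = bw_pen + t
        bw_pen = bw_pen * (1.0 / len(bw_terms))
        total = total + bw_pen * bandwidth_var_weight
        terms["bandwidth_var"] = float(bw_pen.data)
    terms["total"] = float(total.data)
    return total, terms


def _select0(x: Tensor, i: int) -> Tensor:
    """Select index i along axis 0 (with gradient scatter)."""
    out = Tensor(x.data[i], x.requires_grad, (x,))

    def bw(g):
        if x.requires_grad:
            full = np.zeros_like(x.data)
            full[i] = g
            x._accumulate(full)

    out._backward = bw
    return out


def training_loss(
    maps: PredictionMaps,
    label_image: np.ndarray,
    seed_weight: float = 1.0,
    bandwidth_var_weight: float = 0.0,
) -> dict[str, float]:
    """Evaluate the training loss on given prediction maps (no network)."""
    h, w = maps.shape
    rr, cc = np.meshgrid(np.arange(h), np.arange(w), indexing="ij")
    coords = np.stack([rr, cc]).astype(np.float32) / maps.coord_scale
    _, terms = _loss_graph(
        Tensor(maps.seed.astype(np.float32)),
        Tensor(maps.bandwidth.astype(np.float32)),
        Tensor(maps.offsets.astype(np.float32)),
        coords,
        np.asarray(label_image),
        seed_weight,
        bandwidth_var_weight,
    )
    if not np.isfinite(terms["total"]):
        raise FloatingPointError("non-finite training loss")
    return terms


@dataclass
class TrainResult:
    network: EmbedNet
    trace: pd.DataFrame
    best_step: int
    best_val_loss: float
    val_trace: pd.DataFrame
    batch_log: list[list[int]] = field(repr=False, default_factory=list)


def _augment(img: np.ndarray, lab: np.ndarray, rng: np.random.Generator):
    k = int(rng.integers(4))
    img, lab = np.rot90(img, k), np.rot90(lab, k)
    if rng.integers(2):
        img, lab = np.flipud(img), np.flipud(lab)
    if rng.integers(2):
        img, lab = np.fliplr(img), np.fliplr(lab)
    return np.ascontiguousarray(img), np.ascontiguousarray(lab)


def _sample_crop(scene: Scene, size: int, rng: np.random.Generator):
    h, w = scene.shape
    if h < size or w < size:
        raise ValueError(f"crop size {size} exceeds scene {h}x{w}")
    r0 = int(rng.integers(h - size + 1)) if h > size else 0
    c0 = int(rng.integers(w - size + 1)) if w > size else 0
    img = normalize_image(scene.brightfield[r0 : r0 + size, c0 : c0 + size])
    lab = scene.label_image[r0 : r0 + size, c0 : c0 + size]
    return img, lab


def _scene_loss(net: EmbedNet, scene: Scene, size: int, coords: np.ndarray, cfg: TrainConfig) -> float:
    """Evaluation loss on a centre crop, eval-mode statistics."""
    h, w = scene.shape
    r0, c0 = (h - size) // 2, (w - size) // 2
    img = normalize_image(scene.brightfield[r0 : r0 + size, c0 : c0 + size])
    lab = scene.label_image[r0 : r0 + size, c0 : c0 + size]
    out = net.forward(Tensor(img[None, None]), training=False)
    seed_t, bw_t, off_t = _split_heads(out)
    total, _ = _loss_graph(
        seed_t, bw_t, off_t, coords, lab, cfg.seed_loss_weight, cfg.bandwidth_var_weight
    )
    return float(total.data)


def _split_heads(out: Tensor) -> tuple[Tensor, Tensor, Tensor]:
    """(1, 4, H, W) raw output -> seed (H,W), bandwidth (H,W), offsets (2,H,W)."""
    sample = _select0(out, 0)  # (4, H, W)
    seed_t = ag.sigmoid(_select0(sample, 0))
    bw_t = ag.softplus(_select0(sample, 1)) + 1e-4
    off_r = _select0(sample, 2)
    off_c = _select0(sample, 3)
    off_t = _stack0(off_r, off_c)
    return seed_t, bw_t, off_t


def _stack0(a: Tensor, b: Tensor) -> Tensor:
    out = Tensor(np.stack([a.data, b.data]), a.requires_grad or b.requires_grad, (a, b))

    def bw(g):
        if a.requires_grad:
            a._accumulate(g[0])
        if b.requires_grad:
            b._accumulate(g[1])

    out._backward = bw
    return out


def train(
    spec: NetworkSpec,
    train_scenes: list[Scene],
    config: TrainConfig,
    val_scenes: list[Scene] | None = None,
) -> TrainResult:
    """Train a network on synthetic scenes; return best-on-validation state.

    Determinism: crop sampling, augmentation and initialization are all
    driven by ``config.seed``; with augmentation off and identical
    seeds, two runs on the same CPU give identical loss traces.
    """
    if not train_scenes:
        raise ValueError("training set is empty")
    rng = np.random.default_rng(config.seed)
    net = EmbedNet(spec, seed=config.seed)
    opt = ag.Adam(net.params(), lr=config.learning_rate)
    size = config.crop_size
    rr, cc = np.meshgrid(np.arange(size), np.arange(size), indexing="ij")
    coords = np.stack([rr, cc]).astype(np.float32) / config.scale

    rows = []
    val_rows = []
    batch_log: list[list[int]] = []
    best_state = net.state_dict()
    best_val = np.inf
    best_step = 0
    for step in range(1, config.steps + 1):
        opt.zero_grad()
        batch_ids = []
        term_acc = {"instance": 0.0, "seed": 0.0, "total": 0.0}
        for _ in range(config.batch_size):
            si = int(rng.integers(len(train_scenes)))
            batch_ids.append(si)
            img, lab = _sample_crop(train_scenes[si], size, rng)
            if config.augment:
                img, lab = _augment(img, lab, rng)
            out = net.forward(Tensor(img[None, None]), training=True)
            seed_t, bw_t, off_t = _split_heads(out)
            total, terms = _loss_graph(
                seed_t, bw_t, off_t, coords, lab,
                config.seed_loss_weight, config.bandwidth_var_weight,
            )
            for k in ("instance", "seed", "total"):
                term_acc[k] += terms[k] / config.batch_size
            if not np.isfinite(terms["total"]):
                raise FloatingPointError(
                    f"non-finite loss at step {step} (batch scenes {batch_ids})"
                )
            # accumulate gradients crop by crop so each graph is freed
            # before the next forward pass (identical to a joint mean)
            (total * (1.0 / config.batch_size)).backward()
        opt.step()
        batch_log.append(batch_ids)
        rows.append({"step": step, **term_acc})
        if val_scenes and (step % config.eval_every == 0 or step == config.steps):
            vloss = float(
                np.mean([_scene_loss(net, s, size, coords, config) for s in val_scenes])
            )
            val_rows.append({"step": step, "val_loss": vloss})
            if vloss < best_val:
                best_val, best_step = vloss, step
                best_state = net.state_dict()
    if val_scenes:
        net.load_state_dict(best_state)
    else:
        best_step, best_val = config.steps, float("nan")
    return TrainResult(
        network=net,
        trace=pd.DataFrame(rows),
        best_step=best_step,
        best_val_loss=best_val,
        val_trace=pd.DataFrame(val_rows, columns=["step", "val_loss"]),
        batch_log=batch_log,
    )
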