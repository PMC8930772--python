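"""Synthetic microscope fields with complete ground truth.

Each field ("scene") pairs a brightfield-like image of non-overlapping
elliptical yeast cells with a fluorescence image in which every cell
carries lipid droplets drawn from a strain archetype.  The generator
keeps the exact ground truth (cell label image and droplet table), so
every downstream stage — embedding segmentation, threshold-sweep
droplet counting, supersized scoring and strain statistics — can be
validated without real micrographs.

Intensity model (16-bit counts):
  * fluorescence: low, noisy background (kept far below the lowest
    counting threshold of 2,000), droplets rendered as hard disks at
    their peak intensity, max-blended, then Gaussian-blurred with a
    small PSF sigma plus read noise;
  * brightfield: mid-grey background, darker cell interior, bright cell
    rim, Gaussian blur and noise.  Only learnability matters, not
    optical realism.

Geometry is deliberately scaled down relative to a 100x acquisition:
cells are drawn with ~10-16 px semi-axes so that a couple of hundred
cells fit in a desk-sized field while still clearing the 300-px
instance-area filter used downstream.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile
from scipy.ndimage import gaussian_filter

from .maps import PredictionMaps

__all__ = [
    "Calibration",
    "CellEllipse",
    "Droplet",
    "Scene",
    "StrainArchetype",
    "ARCHETYPES",
    "generate_scene",
    "generate_experiment",
    "oracle_prediction_maps",
    "sample_droplet_radii_um",
    "save_scene",
    "load_scene",
    "background_mask",
    "PlacementError",
]


class PlacementError(RuntimeError):
    """Raised when non-overlapping cell placement exceeds its retry budget."""


@dataclass(frozen=True)
class Calibration:
    """Pixel-size calibration; intensities are 16-bit counts (0-65535)."""

    pixel_size_um: float = 0.065
    bit_depth: int = 16

    def __post_init__(self) -> None:
        if self.pixel_size_um <= 0:
            raise ValueError("pixel_size_um must be positive")
        if self.bit_depth != 16:
            raise ValueError("only 16-bit images are supported")

    @property
    def max_intensity(self) -> int:
        return (1 << self.bit_depth) - 1

    @property
    def pixel_area_um2(self) -> float:
        return self.pixel_size_um**2


@dataclass
class CellEllipse:
    center: tuple[float, float]  # (row, col), 0-based
    semi_axes: tuple[float, float]  # (a, b), pixels, a >= b
    orientation: float  # radians
    instance_id: int

    def __post_init__(self) -> None:
        a, b = self.semi_axes
        if a <= 0 or b <= 0:
            raise ValueError("semi-axes must be positive")
        if self.instance_id <= 0:
            raise ValueError("instance ids must be positive integers")

    def mask(self, shape: tuple[int, int]) -> np.ndarray:
        """Boolean rasterization clipped to ``shape``."""
        r0, c0 = self.center
        a, b = self.semi_axes
        ct, st = math.cos(self.orientation), math.sin(self.orientation)
        h, w = shape
        rad = int(math.ceil(max(a, b))) + 1
        rlo = min(max(0, int(r0) - rad), h)
        rhi = max(rlo, min(h, int(r0) + rad + 2))
        clo = min(max(0, int(c0) - rad), w)
        chi = max(clo, min(w, int(c0) + rad + 2))
        rr, cc = np.meshgrid(np.arange(rlo, rhi), np.arange(clo, chi), indexing="ij")
        dr, dc = rr - r0, cc - c0
        u = dr * ct + dc * st
        v = -dr * st + dc * ct
        out = np.zeros(shape, dtype=bool)
        out[rlo:rhi, clo:chi] = (u / a) ** 2 + (v / b) ** 2 <= 1.0
        return out


@dataclass
class Droplet:
    owner_cell: int
    center: tuple[float, float]  # (row, col), pixels
    radius_px: float
    peak_intensity: float

    def area_um2(self, calibration: Calibration) -> float:
        return math.pi * self.radius_px**2 * calibration.pixel_area_um2


@dataclass(frozen=True)
class StrainArchetype:
    """Distributional description of one strain's droplet phenotype.

    ``radius_log_mean`` / ``radius_log_sd`` parameterize a log-normal on
    the droplet radius in micrometres; ``clustering_prob`` is the chance
    a droplet is deposited adjacent to an already-placed one (tight
    droplet clusters are the hallmark of seipin-deficient cells).
    """

    name: str
    droplets_per_cell_mean: float
    radius_log_mean: float  # log of radius in um
    radius_log_sd: float
    intensity_range: tuple[float, float]
    clustering_prob: float = 0.0

    def __post_init__(self) -> None:
        lo, hi = self.intensity_range
        if self.droplets_per_cell_mean > 0 and not (2000 < lo <= hi <= 65535):
            raise ValueError("intensity_range must lie within (2000, 65535]")
        if not 0 <= self.clustering_prob <= 1:
            raise ValueError("clustering_prob must be in [0, 1]")
        if self.radius_log_sd < 0:
            raise ValueError("radius_log_sd must be nonnegative")


#: Built-in archetypes.  "wt_like": many small (r << 0.4 um), fairly
#: uniform droplets.  "null_like": few droplets, radii straddling the
#: 0.4-um supersized boundary, strong clustering — the seipin-null
#: phenotype.  "bright_sparse": few, well-separated, uniformly bright
#: droplets with radii >= 2 px, for exact count-recovery checks.
#: "empty": no droplets.
ARCHETYPES: dict[str, StrainArchetype] = {
    "wt_like": StrainArchetype(
        "wt_like", 8.0, math.log(0.13), 0.22, (22000.0, 45000.0), 0.1
    ),
    "null_like": StrainArchetype(
        "null_like", 2.0, math.log(0.45), 0.30, (22000.0, 55000.0), 0.6
    ),
    "bright_sparse": StrainArchetype(
        "bright_sparse", 3.0, math.log(0.18), 0.10, (25000.0, 40000.0), 0.0
    ),
    "empty": StrainArchetype("empty", 0.0, math.log(0.15), 0.1, (22000.0, 30000.0), 0.0),
}


@dataclass
class Scene:
    brightfield: np.ndarray  # uint16 (H, W)
    fluorescence: np.ndarray  # uint16 (H, W)
    label_image: np.ndarray  # int32 (H, W), 0 = background
    cells: list[CellEllipse]
    droplets: list[Droplet]
    calibration: Calibration
    strain_tag: str = ""
    experiment_id: int = 0
    field_id: int = 0
    seed: int = 0

    @property
    def shape(self) -> tuple[int, int]:
        return self.label_image.shape

    @property
    def n_cells(self) -> int:
        return len(self.cells)

    def droplet_table(self) -> pd.DataFrame:
        rows = [
            {
                "owner_cell": d.owner_cell,
                "row": d.center[0],
                "col": d.center[1],
                "radius_px": d.radius_px,
                "peak": d.peak_intensity,
                "area_um2": d.area_um2(self.calibration),
            }
            for d in self.droplets
        ]
        cols = ["owner_cell", "row", "col", "radius_px", "peak", "area_um2"]
        return pd.DataFrame(rows, columns=cols)

    def droplets_per_cell(self) -> dict[int, int]:
        counts = {c.instance_id: 0 for c in self.cells}
        for d in self.droplets:
            counts[d.owner_cell] += 1
        return counts


def sample_droplet_radii_um(
    archetype: StrainArchetype, n: int, rng: np.random.Generator
) -> np.ndarray:
    """Raw log-normal radius draws (um), before any fit-in-cell capping."""
    return np.exp(rng.normal(archetype.radius_log_mean, archetype.radius_log_sd, size=n))


# ---------------------------------------------------------------------------
# scene generation

_BF_BACKGROUND = 30000.0
_BF_INTERIOR = 18000.0
_BF_RIM = 48000.0
_FLUOR_BACKGROUND = 300.0


def _place_cells(
    n_cells: int,
    shape: tuple[int, int],
    rng: np.random.Generator,
    border_fraction: float,
    margin: float = 2.0,
    a_range: tuple[float, float] = (11.0, 16.0),
    b_range: tuple[float, float] = (10.0, 13.0),
) -> list[CellEllipse]:
    h, w = shape
    cells: list[CellEllipse] = []
    occupancy = np.zeros(shape, dtype=bool)
    n_border = int(round(border_fraction * n_cells))
    budget = 300 * n_cells
    attempts = 0
    while len(cells) < n_cells:
        if attempts >= budget:
            raise PlacementError(
                f"could not place {n_cells} non-overlapping cells in a "
                f"{h}x{w} field after {budget} attempts; lower the density"
            )
        attempts += 1
        a = rng.uniform(*a_range)
        b = rng.uniform(*b_range)
        theta = rng.uniform(0.0, math.pi)
        want_border = len(cells) < n_border
        rad = max(a, b)
        if want_border:
            # centre close enough to an edge that the ellipse crosses it
            edge = rng.integers(4)
            if edge == 0:
                r0, c0 = rng.uniform(0, b * 0.5), rng.uniform(rad, w - rad)
            elif edge == 1:
                r0, c0 = rng.uniform(h - b * 0.5, h - 1), rng.uniform(rad, w - rad)
            elif edge == 2:
                r0, c0 = rng.uniform(rad, h - rad), rng.uniform(0, b * 0.5)
            else:
                r0, c0 = rng.uniform(rad, h - rad), rng.uniform(w - b * 0.5, w - 1)
        else:
            lo = rad + margin
            if h - lo <= lo or w - lo <= lo:
                raise PlacementError("image too small for even one interior cell")
            r0 = rng.uniform(lo, h - lo)
            c0 = rng.uniform(lo, w - lo)
        cand = CellEllipse((r0, c0), (a, b), theta, len(cells) + 1)
        # pad the candidate so neighbouring cells keep a gap
        padded = CellEllipse((r0, c0), (a + margin, b + margin), theta, cand.instance_id)
        pm = padded.mask(shape)
        if (pm & occupancy).any():
            continue
        m = cand.mask(shape)
        if not m.any():
            continue
        if want_border and not _touches_border(m):
            continue
        occupancy |= pm
        cells.append(cand)
    return cells


def _touches_border(mask: np.ndarray) -> bool:
    return bool(mask[0].any() or mask[-1].any() or mask[:, 0].any() or mask[:, -1].any())


def _disk_mask(shape, center, radius):
    h, w = shape
    r0, c0 = center
    rad = int(math.ceil(radius)) + 1
    rlo = min(max(0, int(r0) - rad), h)
    rhi = max(rlo, min(h, int(r0) + rad + 2))
    clo = min(max(0, int(c0) - rad), w)
    chi = max(clo, min(w, int(c0) + rad + 2))
    rr, cc = np.meshgrid(np.arange(rlo, rhi), np.arange(clo, chi), indexing="ij")
    out = np.zeros(shape, dtype=bool)
    out[rlo:rhi, clo:chi] = (rr - r0) ** 2 + (cc - c0) ** 2 <= radius**2
    return out


def _sample_droplets(
    cell: CellEllipse,
    archetype: StrainArchetype,
    calibration: Calibration,
    shape: tuple[int, int],
    rng: np.random.Generator,
    disjoint: bool = False,
) -> list[Droplet]:
    n = int(rng.poisson(archetype.droplets_per_cell_mean))
    if n == 0:
        return []
    a, b = cell.semi_axes
    ct, st = math.cos(cell.orientation), math.sin(cell.orientation)
    radii_um = sample_droplet_radii_um(archetype, n, rng)
    radii_px = radii_um / calibration.pixel_size_um
    cap = max(1.0, min(a, b) - 1.5)  # disk must fit inside the cell
    radii_px = np.clip(radii_px, 0.8, cap)
    droplets: list[Droplet] = []
    for r_px in radii_px:
        peak = rng.uniform(*archetype.intensity_range)
        placed = False
        if disjoint:
            # strict mode: require >= 3 px clearance from every other
            # droplet of the cell; discard the draw when impossible, so
            # the droplet table stays exact
            for _ in range(60):
                u = rng.uniform(-1, 1) * (a - r_px - 1.0)
                v = rng.uniform(-1, 1) * (b - r_px - 1.0)
                r0 = cell.center[0] + u * ct - v * st
                c0 = cell.center[1] + u * st + v * ct
                if not _center_fits(cell, (r0, c0), r_px, ct, st):
                    continue
                if all(
                    math.hypot(r0 - d.center[0], c0 - d.center[1])
                    >= r_px + d.radius_px + 3.0
                    for d in droplets
                ):
                    droplets.append(Droplet(cell.instance_id, (r0, c0), float(r_px), peak))
                    break
            continue
        if droplets and rng.uniform() < archetype.clustering_prob:
            # deposit adjacent to an existing droplet (tight cluster)
            for _ in range(20):
                anchor = droplets[rng.integers(len(droplets))]
                ang = rng.uniform(0, 2 * math.pi)
                dist = anchor.radius_px + r_px
                r0 = anchor.center[0] + dist * math.sin(ang)
                c0 = anchor.center[1] + dist * math.cos(ang)
                if _center_fits(cell, (r0, c0), r_px, ct, st):
                    droplets.append(Droplet(cell.instance_id, (r0, c0), float(r_px), peak))
                    placed = True
                    break
        if not placed:
            # rejection-sample a centre, preferring >= 2 px clearance from
            # other droplets of the cell; fall back to overlap (cluster)
            best = None
            for trial in range(60):
                u = rng.uniform(-1, 1) * (a - r_px - 1.0)
                v = rng.uniform(-1, 1) * (b - r_px - 1.0)
                r0 = cell.center[0] + u * ct - v * st
                c0 = cell.center[1] + u * st + v * ct
                if not _center_fits(cell, (r0, c0), r_px, ct, st):
                    continue
                best = (r0, c0)
                if all(
                    math.hypot(r0 - d.center[0], c0 - d.center[1])
                    >= r_px + d.radius_px + 2.0
                    for d in droplets
                ):
                    break
            if best is None:
                # cell too small for this radius at any sampled centre;
                # centre the droplet and let the cap keep it inside
                best = cell.center
            droplets.append(Droplet(cell.instance_id, best, float(r_px), peak))
    return droplets


def _center_fits(cell: CellEllipse, center, r_px, ct, st) -> bool:
    """Whole disk inside the cell ellipse (conservative inscribed check)."""
    dr = center[0] - cell.center[0]
    dc = center[1] - cell.center[1]
    u = dr * ct + dc * st
    v = -dr * st + dc * ct
    a, b = cell.semi_axes
    ae, be = a - r_px, b - r_px
    if ae <= 0 or be <= 0:
        return False
    return (u / ae) ** 2 + (v / be) ** 2 <= 1.0


def generate_scene(
    archetype: StrainArchetype,
    n_cells: int,
    image_shape: tuple[int, int],
    calibration: Calibration | None = None,
    seed: int = 0,
    *,
    border_fraction: float = 0.1,
    psf_sigma: float = 0.8,
    fluor_noise_sd: float = 40.0,
    bf_noise_sd: float = 1200.0,
    disjoint_droplets: bool = False,
    cell_a_range: tuple[float, float] = (11.0, 16.0),
    cell_b_range: tuple[float, float] = (10.0, 13.0),
    strain_tag: str | None = None,
    experiment_id: int = 0,
    field_id: int = 0,
) -> Scene:
    """Render one field for ``archetype`` with exact ground truth.

    Deterministic for a fixed seed.  Raises :class:`PlacementError` when
    ``n_cells`` non-overlapping ellipses cannot be placed.
    """
    if n_cells <= 0:
        raise ValueError("n_cells must be positive")
    calibration = calibration or Calibration()
    rng = np.random.default_rng(seed)
    cells = _place_cells(
        n_cells, image_shape, rng, border_fraction,
        a_range=cell_a_range, b_range=cell_b_range,
    )

    label = np.zeros(image_shape, dtype=np.int32)
    for cell in cells:
        label[cell.mask(image_shape)] = cell.instance_id

    droplets: list[Droplet] = []
    for cell in cells:
        droplets.extend(
            _sample_droplets(cell, archetype, calibration, image_shape, rng, disjoint_droplets)
        )

    # fluorescence: max-blend hard disks, blur, add read noise
    fluor = np.full(image_shape, _FLUOR_BACKGROUND, dtype=np.float64)
    for d in droplets:
        m = _disk_mask(image_shape, d.center, d.radius_px)
        np.maximum(fluor, np.where(m, d.peak_intensity, 0.0), out=fluor)
    fluor = gaussian_filter(fluor, psf_sigma)
    fluor += rng.normal(0.0, fluor_noise_sd, image_shape)
    fluor = np.clip(fluor, 0, calibration.max_intensity).astype(np.uint16)

    # brightfield: dark interior, bright rim
    bf = np.full(image_shape, _BF_BACKGROUND, dtype=np.float64)
    interior = label > 0
    bf[interior] = _BF_INTERIOR
    rim = np.zeros(image_shape, dtype=bool)
    for cell in cells:
        a, b = cell.semi_axes
        outer = cell.mask(image_shape)
        inner = CellEllipse(
            cell.center, (max(a - 2.0, 1.0), max(b - 2.0, 1.0)), cell.orientation, cell.instance_id
        ).mask(image_shape)
        rim |= outer & ~inner
    bf[rim] = _BF_RIM
    bf = gaussian_filter(bf, 1.0)
    bf += rng.normal(0.0, bf_noise_sd, image_shape)
    bf = np.clip(bf, 0, calibration.max_intensity).astype(np.uint16)

    return Scene(
        brightfield=bf,
        fluorescence=fluor,
        label_image=label,
        cells=cells,
        droplets=droplets,
        calibration=calibration,
        strain_tag=strain_tag if strain_tag is not None else archetype.name,
        experiment_id=experiment_id,
        field_id=field_id,
        seed=int(seed),
    )


def scene_seed(master_seed: int, index: int) -> int:
    """Stable, pairwise-distinct per-scene seed derived from a master seed."""
    state = np.random.SeedSequence([int(master_seed), int(index)]).generate_state(2)
    return int(state[0]) * (1 << 31) + int(state[1] >> 1)


def generate_experiment(
    archetypes: list[StrainArchetype],
    n_experiments: int,
    fields_per_strain: int,
    seed: int = 0,
    *,
    n_cells: int = 50,
    image_shape: tuple[int, int] = (256, 256),
    calibration: Calibration | None = None,
    border_fraction: float = 0.1,
) -> list[Scene]:
    """Complete strain x experiment x field design of scenes."""
    if not archetypes:
        raise ValueError("archetype list must not be empty")
    if fields_per_strain < 1:
        raise ValueError("fields_per_strain must be >= 1")
    scenes: list[Scene] = []
    index = 0
    for exp in range(1, n_experiments + 1):
        for arch in archetypes:
            for fld in range(1, fields_per_strain + 1):
                scenes.append(
                    generate_scene(
                        arch,
                        n_cells,
                        image_shape,
                        calibration,
                        scene_seed(seed, index),
                        border_fraction=border_fraction,
                        strain_tag=arch.name,
                        experiment_id=exp,
                        field_id=fld,
                    )
                )
                index += 1
    return scenes


# ---------------------------------------------------------------------------
# oracle maps and helpers

def oracle_prediction_maps(scene: Scene, bandwidth: float = 0.02) -> PredictionMaps:
    """Idealized network output for a scene.

    Embeddings are exactly constant over each cell, equal to the cell's
    pixel-coordinate centroid (normalized); seed score is 1 inside
    cells, 0 outside; the bandwidth map is constant.  Feeding this to
    the clustering stage recovers the ground-truth label image, which
    lets inference be tested without any training.
    """
    if scene.n_cells < 1:
        raise ValueError("scene must contain at least one cell")
    h, w = scene.shape
    scale = float(max(h, w))
    offsets = np.zeros((2, h, w), dtype=np.float64)
    rr, cc = np.meshgrid(np.arange(h), np.arange(w), indexing="ij")
    for cell in scene.cells:
        m = scene.label_image == cell.instance_id
        if not m.any():
            continue
        cen_r = rr[m].mean() / scale
        cen_c = cc[m].mean() / scale
        offsets[0][m] = cen_r - rr[m] / scale
        offsets[1][m] = cen_c - cc[m] / scale
    seed = (scene.label_image > 0).astype(np.float64)
    bw = np.full((h, w), float(bandwidth))
    return PredictionMaps(seed=seed, bandwidth=bw, offsets=offsets, coord_scale=scale)


def background_mask(scene: Scene, clearance_sigmas: float = 3.0, psf_sigma: float = 0.8) -> np.ndarray:
    """Pixels outside every droplet's rendered support (disk + PSF tails)."""
    far = np.ones(scene.shape, dtype=bool)
    pad = clearance_sigmas * psf_sigma + 1.0
    for d in scene.droplets:
        far &= ~_disk_mask(scene.shape, d.center, d.radius_px + pad)
    return far


# ---------------------------------------------------------------------------
# serialization

def save_scene(scene: Scene, out_dir: str | Path) -> Path:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    tifffile.imwrite(out / "brightfield.tif", scene.brightfield)
    tifffile.imwrite(out / "fluorescence.tif", scene.fluorescence)
    tifffile.imwrite(out / "labels.tif", scene.label_image)
    scene.droplet_table().to_csv(out / "droplets.csv", index=False)
    meta = {
        "calibration": asdict(scene.calibration),
        "strain_tag": scene.strain_tag,
        "experiment_id": scene.experiment_id,
        "field_id": scene.field_id,
        "seed": scene.seed,
        "cells": [
            {
                "center": list(c.center),
                "semi_axes": list(c.semi_axes),
                "orientation": c.orientation,
                "instance_id": c.instance_id,
            }
            for c in scene.cells
        ],
    }
    (out / "scene.json").write_text(json.dumps(meta, indent=1))
    return out


def load_scene(in_dir: str | Path) -> Scene:
    p = Path(in_dir)
    meta = json.loads((p / "scene.json").read_text())
    cells = [
        CellEllipse(
            tuple(c["center"]), tuple(c["semi_axes"]), c["orientation"], c["instance_id"]
        )
        for c in meta["cells"]
    ]
    table = pd.read_csv(p / "droplets.csv")
    droplets = [
        Droplet(int(r.owner_cell), (r.row, r.col), r.radius_px, r.peak)
        for r in table.itertuples()
    ]
    return Scene(
        brightfield=tifffile.imread(p / "brightfield.tif"),
        fluorescence=tifffile.imread(p / "fluorescence.tif"),
        label_image=tifffile.imread(p / "labels.tif").astype(np.int32),
        cells=cells,
        droplets=droplets,
        calibration=Calibration(**meta["calibration"]),
        strain_tag=meta["strain_tag"],
        experiment_id=meta["experiment_id"],
        field_id=meta["field_id"],
        seed=meta["seed"],
    )
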