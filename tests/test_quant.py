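"""Threshold-sweep particle counting, max rule and supersized scoring.

Counts on the constructed fixture images are checked against an
independent brute-force flood-fill implemented here (no shared code
with the package's scipy-based path).
"""

import math

import numpy as np
import pytest

from dropseg.pipeline import bridge_image, disk_image, three_disk_image
from dropseg.quant import (
    Calibration,
    ThresholdSweepSpec,
    count_particles,
    summarize_field,
    sweep_cell,
    quantify_scene,
)
from dropseg.scenes import ARCHETYPES, generate_scene


def brute_force_count(image, region, lower, upper=65535):
    """Independent 8-connected component count via explicit flood fill."""
    h, w = image.shape
    fg = {
        (r, c)
        for r in range(h)
        for c in range(w)
        if region[r, c] and lower <= image[r, c] <= upper
    }
    count = 0
    areas = []
    while fg:
        count += 1
        stack = [fg.pop()]
        area = 0
        while stack:
            r, c = stack.pop()
            area += 1
            for dr in (-1, 0, 1):
                for dc in (-1, 0, 1):
                    n = (r + dr, c + dc)
                    if n in fg:
                        fg.remove(n)
                        stack.append(n)
        areas.append(area)
    return count, sorted(areas)


SWEEP = ThresholdSweepSpec()


def test_sweep_threshold_list():
    assert SWEEP.thresholds == list(range(20000, 1999, -2000))
    assert len(SWEEP.thresholds) == 10
    with pytest.raises(ValueError):
        ThresholdSweepSpec(start=2000, stop=20000)
    with pytest.raises(ValueError):
        ThresholdSweepSpec(step=7000)  # does not divide the sweep range


def test_background_only_cell_counts_zero():
    img = np.full((32, 32), 500, dtype=np.uint16)
    region = np.ones((32, 32), bool)
    for t in SWEEP.thresholds:
        n, _ = count_particles(img, region, t)
        assert n == 0


def test_three_disks_counted_at_every_threshold():
    img = three_disk_image()
    region = np.ones(img.shape, bool)
    for t in SWEEP.thresholds:
        n, areas = count_particles(img, region, t)
        bf_n, bf_areas = brute_force_count(img, region, t)
        assert (n, sorted(areas)) == (bf_n, bf_areas)
        assert n == 3


def test_bridge_image_counts_match_bruteforce_per_threshold():
    img = bridge_image()
    region = np.ones(img.shape, bool)
    res = sweep_cell(img, region, SWEEP, Calibration())
    for t in SWEEP.thresholds:
        bf_n, _ = brute_force_count(img, region, t)
        assert res.counts_per_threshold[t] == bf_n
    # two particles while the 6,000 bridge is sub-threshold, one below
    assert [res.counts_per_threshold[t] for t in SWEEP.thresholds] == [
        2, 2, 2, 2, 2, 2, 2, 1, 1, 1,
    ]
    assert res.ld_count == 2


def test_region_restriction_splits_shared_particle():
    """A particle spanning two regions contributes to each region's count."""
    img = np.full((20, 20), 300, dtype=np.uint16)
    img[8:12, 4:16] = 30000
    left = np.zeros((20, 20), bool)
    left[:, :10] = True
    right = ~left
    for reg in (left, right):
        n, _ = count_particles(img, reg, 20000)
        assert n == 1


def test_max_rule_and_mask_nesting_on_random_cells(rng):
    sc = generate_scene(ARCHETYPES["wt_like"], 6, (128, 128), seed=31, border_fraction=0.0)
    for cell in sc.cells:
        region = sc.label_image == cell.instance_id
        res = sweep_cell(sc.fluorescence, region, SWEEP, sc.calibration)
        assert res.ld_count == max(res.counts_per_threshold.values())
        for t in SWEEP.thresholds:
            assert res.ld_count >= res.counts_per_threshold[t]
        # monotone nesting of foreground masks
        prev = None
        for t in SWEEP.thresholds:
            mask = (sc.fluorescence >= t) & region
            if prev is not None:
                assert not (prev & ~mask).any()
            prev = mask


@pytest.mark.parametrize(
    "radius,intensity,expect_super",
    [(25, 30000, True), (10, 30000, True), (5, 30000, False), (25, 9000, False)],
)
def test_supersized_boundary_disks(radius, intensity, expect_super):
    """Area > 0.5 um^2 at the 10,000 threshold flags supersized; a 9,000
    disk is counted in the sweep but can never flag."""
    img = disk_image(radius, intensity, shape=(96, 96))
    region = np.ones(img.shape, bool)
    res = sweep_cell(img, region, SWEEP, Calibration(pixel_size_um=0.065))
    assert res.has_supersized is expect_super
    if intensity == 9000:
        assert res.ld_count == 1  # visible in the sweep below 10,000
        assert res.supersized_particles == 0
    else:
        area_um2 = math.pi * radius**2 * 0.065**2
        assert (area_um2 > 0.5) is expect_super


def test_calibration_linearity_of_areas():
    """Halving the pixel size quarters areas; flags only flip to False."""
    img = disk_image(10, 30000)
    region = np.ones(img.shape, bool)
    base = sweep_cell(img, region, SWEEP, Calibration(pixel_size_um=0.065))
    fine = sweep_cell(img, region, SWEEP, Calibration(pixel_size_um=0.0325))
    _, areas_base = count_particles(img, region, 10000)
    _, areas_fine = count_particles(img, region, 10000)
    np.testing.assert_allclose(
        areas_fine * 0.0325**2, areas_base * 0.065**2 / 4.0
    )
    assert base.has_supersized and not fine.has_supersized


def test_exact_recovery_of_ground_truth_counts():
    sc = generate_scene(
        ARCHETYPES["bright_sparse"], 20, (256, 256), seed=17,
        border_fraction=0.0, disjoint_droplets=True,
    )
    fs = quantify_scene(sc)
    gt = sc.droplets_per_cell()
    measured = dict(zip(fs.cells.cell_id, fs.cells.ld_count))
    assert measured == gt
    assert fs.mean_ld_per_cell == pytest.approx(np.mean(list(gt.values())))


def test_summarize_field_arithmetic_and_errors():
    img = np.full((40, 40), 300, dtype=np.uint16)
    img[5:8, 5:8] = 30000  # one particle in region 1
    regions = {
        1: np.zeros((40, 40), bool),
        2: np.zeros((40, 40), bool),
    }
    regions[1][:20] = True
    regions[2][20:] = True
    fs = summarize_field(img, regions, SWEEP, Calibration())
    assert fs.n_cells == 2
    assert fs.mean_ld_per_cell == pytest.approx(0.5)
    assert fs.pct_cells_supersized == 0.0
    with pytest.raises(ValueError, match="field"):
        summarize_field(img, {}, SWEEP, Calibration())
    with pytest.raises(ValueError):
        count_particles(img, np.zeros((40, 40), bool), 10000)
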