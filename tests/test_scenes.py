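"""Synthetic scene generator: determinism, ground truth, archetypes."""

import math

import numpy as np
import pytest
from scipy import stats as sps

from dropseg.scenes import (
    ARCHETYPES,
    Calibration,
    PlacementError,
    StrainArchetype,
    background_mask,
    generate_experiment,
    generate_scene,
    load_scene,
    oracle_prediction_maps,
    sample_droplet_radii_um,
    save_scene,
    scene_seed,
)


def test_same_seed_is_bit_identical():
    a = generate_scene(ARCHETYPES["wt_like"], 8, (128, 128), seed=5)
    b = generate_scene(ARCHETYPES["wt_like"], 8, (128, 128), seed=5)
    assert np.array_equal(a.brightfield, b.brightfield)
    assert np.array_equal(a.fluorescence, b.fluorescence)
    assert np.array_equal(a.label_image, b.label_image)
    assert a.droplet_table().equals(b.droplet_table())


def test_zero_mean_archetype_gives_empty_droplet_table():
    sc = generate_scene(ARCHETYPES["empty"], 6, (128, 128), seed=1)
    assert len(sc.droplets) == 0
    # fluorescence is background only: everything below the lowest sweep threshold
    assert sc.fluorescence.max() < 2000


def test_cells_disjoint_and_labels_match_ids(small_scene):
    ids = sorted(c.instance_id for c in small_scene.cells)
    assert ids == sorted(np.unique(small_scene.label_image[small_scene.label_image > 0]))
    # disjointness: total labelled area equals the sum of per-cell masks
    total = sum(
        (small_scene.label_image == c.instance_id).sum() for c in small_scene.cells
    )
    assert total == (small_scene.label_image > 0).sum()


def test_ground_truth_conservation(small_scene):
    per_cell = small_scene.droplets_per_cell()
    assert sum(per_cell.values()) == len(small_scene.droplets)
    for d in small_scene.droplets:
        r, c = int(round(d.center[0])), int(round(d.center[1]))
        r = min(max(r, 0), small_scene.shape[0] - 1)
        c = min(max(c, 0), small_scene.shape[1] - 1)
        assert small_scene.label_image[r, c] == d.owner_cell


def test_background_stays_below_lowest_threshold(border_scene):
    far = background_mask(border_scene)
    assert border_scene.fluorescence[far].max() < 2000


def test_border_fraction_produces_border_cells(border_scene):
    lab = border_scene.label_image
    edge_ids = set(lab[0]) | set(lab[-1]) | set(lab[:, 0]) | set(lab[:, -1])
    edge_ids.discard(0)
    assert len(edge_ids) >= 2


def test_placement_failure_names_density():
    with pytest.raises(PlacementError, match="density"):
        generate_scene(ARCHETYPES["empty"], 200, (96, 96), seed=0)
    with pytest.raises(ValueError):
        generate_scene(ARCHETYPES["empty"], 0, (96, 96), seed=0)


def test_archetype_count_means_differ_in_direction():
    """wt-like cells average many more droplets than null-like cells."""
    wt = generate_scene(ARCHETYPES["wt_like"], 50, (400, 400), seed=2)
    null = generate_scene(ARCHETYPES["null_like"], 50, (400, 400), seed=3)
    mean_wt = len(wt.droplets) / 50
    mean_null = len(null.droplets) / 50
    # Poisson sampling error bound: 3*sqrt(mean/n)
    assert mean_wt - 3 * math.sqrt(8 / 50) > mean_null + 3 * math.sqrt(2 / 50)


def test_supersized_radius_frequency_matches_lognormal(rng):
    """Drawn radii cross the 0.5-um^2 area boundary at the analytic rate."""
    arch = ARCHETYPES["null_like"]
    cal = Calibration()
    n = 4000
    radii = sample_droplet_radii_um(arch, n, rng)
    areas = math.pi * radii**2
    observed = float((areas > 0.5).mean())
    r_star = math.sqrt(0.5 / math.pi)
    expected = float(
        sps.norm.sf((math.log(r_star) - arch.radius_log_mean) / arch.radius_log_sd)
    )
    sigma = math.sqrt(expected * (1 - expected) / n)
    assert abs(observed - expected) < 3 * sigma


def test_experiment_design_complete_and_seeds_distinct():
    scenes = generate_experiment(
        [ARCHETYPES["wt_like"], ARCHETYPES["null_like"]], 3, 3, seed=9,
        n_cells=4, image_shape=(96, 96),
    )
    assert len(scenes) == 18
    combos = {}
    for sc in scenes:
        combos.setdefault((sc.strain_tag, sc.experiment_id), 0)
        combos[(sc.strain_tag, sc.experiment_id)] += 1
    assert all(v == 3 for v in combos.values())
    seeds = [sc.seed for sc in scenes]
    assert len(set(seeds)) == len(seeds)
    assert len(set(scene_seed(9, i) for i in range(100))) == 100


def test_generate_experiment_rejects_bad_inputs():
    with pytest.raises(ValueError):
        generate_experiment([], 2, 3, seed=0)
    with pytest.raises(ValueError):
        generate_experiment([ARCHETYPES["empty"]], 2, 0, seed=0)


def test_scene_roundtrip_through_disk(tmp_path, small_scene):
    save_scene(small_scene, tmp_path / "s")
    back = load_scene(tmp_path / "s")
    assert np.array_equal(back.brightfield, small_scene.brightfield)
    assert np.array_equal(back.fluorescence, small_scene.fluorescence)
    assert np.array_equal(back.label_image, small_scene.label_image)
    assert back.strain_tag == small_scene.strain_tag
    assert back.experiment_id == small_scene.experiment_id
    assert back.field_id == small_scene.field_id
    assert len(back.droplets) == len(small_scene.droplets)
    np.testing.assert_allclose(
        back.droplet_table()["area_um2"], small_scene.droplet_table()["area_um2"]
    )


def test_oracle_maps_constant_embeddings(small_scene):
    maps = oracle_prediction_maps(small_scene, bandwidth=0.03)
    e = maps.embeddings()
    h, w = small_scene.shape
    rr, cc = np.meshgrid(np.arange(h), np.arange(w), indexing="ij")
    scale = float(max(h, w))
    for cell in small_scene.cells[:3]:
        m = small_scene.label_image == cell.instance_id
        cen = np.array([rr[m].mean(), cc[m].mean()]) / scale
        np.testing.assert_allclose(e[0][m], cen[0], atol=1e-12)
        np.testing.assert_allclose(e[1][m], cen[1], atol=1e-12)
    assert maps.seed[small_scene.label_image > 0].min() == 1.0
    assert maps.seed[small_scene.label_image == 0].max() == 0.0


def test_oracle_maps_two_cells_differ_by_centroid_distance():
    sc = generate_scene(ARCHETYPES["empty"], 2, (128, 128), seed=3, border_fraction=0.0)
    maps = oracle_prediction_maps(sc)
    e = maps.embeddings()
    vals = []
    for cell in sc.cells:
        m = sc.label_image == cell.instance_id
        vals.append(np.array([e[0][m][0], e[1][m][0]]))
    h, w = sc.shape
    rr, cc = np.meshgrid(np.arange(h), np.arange(w), indexing="ij")
    cents = []
    for cell in sc.cells:
        m = sc.label_image == cell.instance_id
        cents.append(np.array([rr[m].mean(), cc[m].mean()]) / max(h, w))
    np.testing.assert_allclose(
        np.linalg.norm(vals[0] - vals[1]), np.linalg.norm(cents[0] - cents[1]), rtol=1e-12
    )


def test_intensity_range_validation():
    with pytest.raises(ValueError):
        StrainArchetype("bad", 2.0, math.log(0.2), 0.1, (1000.0, 30000.0))
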