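"""Soft-mask growing, Dice loss and the full training objective."""

import math

import numpy as np
import pytest

from dropseg.maps import PredictionMaps
from dropseg.scenes import ARCHETYPES, generate_scene, oracle_prediction_maps
from dropseg.train import dice_loss, soft_mask, training_loss


def _random_maps(rng, h=7, w=7):
    return PredictionMaps(
        seed=rng.uniform(0, 1, (h, w)),
        bandwidth=rng.uniform(0.05, 0.5, (h, w)),
        offsets=rng.normal(0, 0.2, (2, h, w)),
        coord_scale=float(max(h, w)),
    )


def test_soft_mask_matches_bruteforce_per_pixel(rng):
    """phi agrees with an independent pixel-by-pixel evaluation."""
    maps = _random_maps(rng)
    mask = np.zeros((7, 7), bool)
    mask[2:5, 1:4] = True
    sm = soft_mask(maps, mask)
    # brute force: accumulate embeddings pixel by pixel from the raw maps
    es, sigmas = [], []
    for r in range(7):
        for c in range(7):
            if mask[r, c]:
                es.append(
                    [r / 7 + maps.offsets[0, r, c], c / 7 + maps.offsets[1, r, c]]
                )
                sigmas.append(maps.bandwidth[r, c])
    e_bar = np.mean(es, axis=0)
    s_bar = np.mean(sigmas)
    for r in range(7):
        for c in range(7):
            e = [r / 7 + maps.offsets[0, r, c], c / 7 + maps.offsets[1, r, c]]
            d2 = (e[0] - e_bar[0]) ** 2 + (e[1] - e_bar[1]) ** 2
            expected = math.exp(-d2 / (2 * s_bar**2))
            assert sm.phi[r, c] == pytest.approx(expected, rel=1e-12)
    np.testing.assert_allclose(sm.mean_embedding, e_bar)
    assert sm.mean_bandwidth == pytest.approx(s_bar)


def test_soft_mask_is_one_on_constant_embeddings():
    sc = generate_scene(ARCHETYPES["empty"], 1, (64, 64), seed=0, border_fraction=0.0)
    maps = oracle_prediction_maps(sc, bandwidth=0.05)
    m = sc.label_image == 1
    sm = soft_mask(maps, m)
    np.testing.assert_allclose(sm.phi[m], 1.0)


def test_soft_mask_half_value_at_fwhm_radius():
    """phi = 0.5 exactly where the embedding distance is sigma*sqrt(2 ln 2)."""
    h = w = 9
    sigma = 0.1
    offsets = np.zeros((2, h, w))
    maps = PredictionMaps(
        seed=np.ones((h, w)),
        bandwidth=np.full((h, w), sigma),
        offsets=offsets,
        coord_scale=1.0,  # embeddings are raw pixel coordinates
    )
    mask = np.zeros((h, w), bool)
    mask[4, 4] = True
    sm = soft_mask(maps, mask)
    d = sigma * math.sqrt(2 * math.log(2))
    d2map = (np.arange(h)[:, None] - 4.0) ** 2 + (np.arange(w)[None, :] - 4.0) ** 2
    phi_expected = np.exp(-d2map / (2 * sigma**2))
    np.testing.assert_allclose(sm.phi, phi_expected, rtol=1e-12)
    assert math.exp(-(d**2) / (2 * sigma**2)) == pytest.approx(0.5)


def test_soft_mask_rejects_empty_pixel_set(rng):
    with pytest.raises(ValueError):
        soft_mask(_random_maps(rng), np.zeros((7, 7), bool))


def test_dice_loss_identity_disjoint_and_half():
    t = np.zeros((10, 10))
    t[2:6, 2:6] = 1.0  # 16 pixels
    assert dice_loss(t, t) == pytest.approx(0.0, abs=1e-6)
    other = np.zeros((10, 10))
    other[7:9, 7:9] = 1.0
    assert dice_loss(other, t) == pytest.approx(1.0, abs=1e-6)
    # phi equals target on exactly half the target pixels, zero elsewhere:
    # 1 - 2*(n/2)/(n/2 + n) = 1/3
    half = t.copy()
    half[2:4, 2:6] = 0.0
    assert dice_loss(half, t) == pytest.approx(1.0 / 3.0, rel=1e-5)
    with pytest.raises(ValueError):
        dice_loss(np.zeros((3, 3)), np.zeros((4, 4)))


def test_training_loss_near_zero_on_oracle_maps():
    sc = generate_scene(
        ARCHETYPES["empty"], 1, (32, 32), seed=2, border_fraction=0.0,
        cell_a_range=(7.0, 9.0), cell_b_range=(6.0, 8.0),
    )
    maps = oracle_prediction_maps(sc, bandwidth=0.02)
    terms = training_loss(maps, sc.label_image, seed_weight=0.0)
    # only Gaussian tails outside the cell contribute
    assert terms["instance"] < 0.1


def test_training_loss_zero_cells_and_seed_term():
    maps = PredictionMaps(
        seed=np.full((16, 16), 0.3),
        bandwidth=np.ones((16, 16)),
        offsets=np.zeros((2, 16, 16)),
    )
    terms = training_loss(maps, np.zeros((16, 16), int))
    assert terms["instance"] == 0.0
    assert terms["seed"] == pytest.approx(0.09, rel=1e-5)  # (0.3 - 0)^2


def test_training_loss_invariant_to_relabeling(rng):
    sc = generate_scene(ARCHETYPES["empty"], 4, (96, 96), seed=5, border_fraction=0.0)
    maps = _random_maps(rng, 96, 96)
    lab = sc.label_image
    relabeled = np.zeros_like(lab)
    perm = {1: 3, 2: 1, 3: 4, 4: 2}
    for old, new in perm.items():
        relabeled[lab == old] = new
    a = training_loss(maps, lab)
    b = training_loss(maps, relabeled)
    assert a["total"] == pytest.approx(b["total"], rel=1e-6)


def test_training_loss_flip_equivariance(rng):
    """Flipping maps and labels together leaves the loss unchanged."""
    sc = generate_scene(ARCHETYPES["empty"], 3, (96, 96), seed=8, border_fraction=0.0)
    maps = _random_maps(rng, 96, 96)
    a = training_loss(maps, sc.label_image)
    flipped = PredictionMaps(
        seed=maps.seed[::-1].copy(),
        bandwidth=maps.bandwidth[::-1].copy(),
        # row offsets change sign under a vertical flip
        offsets=np.stack([-maps.offsets[0][::-1], maps.offsets[1][::-1]]),
        coord_scale=maps.coord_scale,
    )
    # embeddings of flipped maps are the mirrored embeddings up to a
    # constant (h-1)/scale shift, which cancels in the loss
    b = training_loss(flipped, sc.label_image[::-1].copy())
    assert a["total"] == pytest.approx(b["total"], rel=1e-4)
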