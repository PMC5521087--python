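"""Tests for raster scanning, rotation-averaged scoring, candidate selection
(threshold + local maximum), the pixel-std filter, and binning."""

import numpy as np
import pytest

from empick import network as net, recognition as rec


def _constant_scorer(schedule="tiny8"):
    state = net.init_network(net.SCHEDULES[schedule], seed=0)
    state.out_weights[:] = 0.0
    state.out_bias = 0.0
    return state


# ---------------------------------------------------------------------------
# rotation-averaged box scoring
# ---------------------------------------------------------------------------

def test_score_box_exactly_rotation_invariant(tiny_state, rng):
    box = rng.normal(size=(8, 8))
    base = rec.score_box(box, tiny_state)
    for k in (1, 2, 3):
        assert rec.score_box(np.rot90(box, k), tiny_state) == base


def test_score_box_equals_mean_of_four_forward_passes(tiny_state, rng):
    box = rng.normal(size=(8, 8))
    singles = sorted(net.network_forward(np.rot90(box, k), tiny_state)
                     for k in range(4))
    assert rec.score_box(box, tiny_state) == pytest.approx(
        float(np.mean(singles)), abs=1e-12)


def test_score_box_constant_network(rng):
    state = _constant_scorer()
    assert rec.score_box(rng.normal(size=(8, 8)), state) == 0.5


# ---------------------------------------------------------------------------
# raster scan
# ---------------------------------------------------------------------------

def test_scan_grid_dimensions(rng):
    state = _constant_scorer()
    m = rng.normal(size=(40, 33))
    smap = rec.scan_micrograph(m, state, stride=8)
    assert smap.scores.shape == ((40 - 8) // 8 + 1, (33 - 8) // 8 + 1)
    # stride equal to the free span gives the four corners
    sq = rng.normal(size=(24, 24))
    corners = rec.scan_micrograph(sq, state, stride=16)
    assert corners.scores.shape == (2, 2)


def test_scan_constant_network_gives_constant_map(rng):
    state = _constant_scorer()
    smap = rec.scan_micrograph(rng.normal(size=(32, 32)), state, stride=4)
    assert np.all(smap.scores == 0.5)


def test_scan_matches_score_box_at_each_position(tiny16_state, rng):
    m = rng.normal(size=(40, 40))
    smap = rec.scan_micrograph(m, tiny16_state, stride=8)
    for r in range(smap.scores.shape[0]):
        for c in range(smap.scores.shape[1]):
            x, y = smap.position(r, c)
            single = rec.score_box(m[y : y + 16, x : x + 16], tiny16_state)
            # batched and single-box evaluation agree to roundoff
            assert smap.scores[r, c] == pytest.approx(single, abs=1e-12)


def test_scan_rejects_bad_inputs(tiny_state, rng):
    with pytest.raises(net.ConfigurationError):
        rec.scan_micrograph(rng.normal(size=(32, 32)), tiny_state, stride=0)
    with pytest.raises(ValueError):
        rec.scan_micrograph(rng.normal(size=(4, 4)), tiny_state, stride=2)


# ---------------------------------------------------------------------------
# candidate selection
# ---------------------------------------------------------------------------

def _smap(grid, stride=4, box_side=8):
    return rec.ScoreMap(scores=np.asarray(grid, dtype=float), stride=stride,
                        box_side=box_side)


def test_find_candidates_empty_below_threshold():
    smap = _smap(np.full((5, 5), 0.2))
    assert rec.find_candidates(smap, threshold=0.5, nms_radius=8) == []


def test_find_candidates_single_isolated_peak():
    grid = np.full((5, 5), 0.1)
    grid[2, 3] = 0.9
    out = rec.find_candidates(_smap(grid), threshold=0.5, nms_radius=8)
    assert len(out) == 1
    assert (out[0].x, out[0].y) == (3 * 4, 2 * 4)
    assert out[0].score == 0.9


def test_find_candidates_separation_vs_suppression():
    """Brute-force check on a constructed 5x5 grid: two peaks outside the
    radius both survive; inside the radius only the higher one does."""
    far = np.full((5, 5), 0.1)
    far[0, 0], far[4, 4] = 0.8, 0.9  # Chebyshev distance 16 px at stride 4
    out = rec.find_candidates(_smap(far), threshold=0.5, nms_radius=8)
    assert {(c.x, c.y) for c in out} == {(0, 0), (16, 16)}

    near = np.full((5, 5), 0.1)
    near[2, 2], near[2, 3] = 0.8, 0.9  # 4 px apart
    out = rec.find_candidates(_smap(near), threshold=0.5, nms_radius=8)
    assert [(c.x, c.y) for c in out] == [(12, 8)]


def test_find_candidates_tie_goes_to_raster_first():
    grid = np.full((5, 5), 0.1)
    grid[1, 1] = grid[1, 2] = 0.9  # exact tie within the radius
    out = rec.find_candidates(_smap(grid), threshold=0.5, nms_radius=8)
    assert [(c.x, c.y) for c in out] == [(4, 4)]


def test_candidates_are_verifiable_local_maxima(rng):
    """Every returned candidate beats all neighbors within the radius
    (brute-force re-check on a random score map)."""
    s = rng.uniform(0.0, 1.0, size=(12, 12))
    smap = _smap(s, stride=4)
    out = rec.find_candidates(smap, threshold=0.3, nms_radius=9)
    R = 9 // 4
    for c in out:
        r0, c0 = c.y // 4, c.x // 4
        assert s[r0, c0] >= 0.3
        window = s[max(0, r0 - R) : r0 + R + 1, max(0, c0 - R) : c0 + R + 1]
        assert s[r0, c0] == window.max()


# ---------------------------------------------------------------------------
# pixel-std filter
# ---------------------------------------------------------------------------

def _cands(stds):
    return [rec.Candidate(x=i, y=0, score=0.9, pixel_std=s)
            for i, s in enumerate(stds)]


def test_std_filter_keeps_identical_population():
    out = rec.filter_by_std(_cands([1.5] * 6), k=2.0)
    assert len(out) == 6


def test_std_filter_removes_single_outlier():
    stds = [1.0, 1.01, 0.99, 1.02, 0.98, 1.0, 5.0]
    mu, sigma = np.mean(stds), np.std(stds)
    assert not (mu - 2 * sigma <= 5.0 <= mu + 2 * sigma)  # verified directly
    out = rec.filter_by_std(_cands(stds), k=2.0)
    assert [c.pixel_std for c in out] == stds[:-1]


def test_std_filter_absolute_range_and_degenerate_cases():
    cands = _cands([0.5, 2.0, 9.0])
    assert rec.filter_by_std(cands, abs_range=(0.0, 10.0)) == cands
    assert rec.filter_by_std(cands, abs_range=(1.0, 3.0)) == [cands[1]]
    lone = _cands([7.0])
    assert rec.filter_by_std(lone, k=2.0) == lone  # band undefined -> no-op


# ---------------------------------------------------------------------------
# pick composition
# ---------------------------------------------------------------------------

def test_pick_deterministic_and_in_bounds(tiny16_state, rng):
    m = rng.normal(size=(64, 64))
    a = rec.pick(m, tiny16_state, threshold=0.2, stride=8, std_k=None)
    b = rec.pick(m, tiny16_state, threshold=0.2, stride=8, std_k=None)
    assert [(c.x, c.y, c.score) for c in a] == [(c.x, c.y, c.score) for c in b]
    for c in a:
        assert 0 <= c.x <= 64 - 16 and 0 <= c.y <= 64 - 16


def test_pick_huge_radius_keeps_single_global_max(tiny16_state, rng):
    m = rng.normal(size=(64, 64))
    out = rec.pick(m, tiny16_state, threshold=0.0, stride=8,
                   nms_radius=1000, std_k=None)
    assert len(out) <= 1


def test_pick_equivariant_under_micrograph_rotation(tiny16_state, rng):
    """Picking the 90-degree-rotated micrograph returns the rotated
    candidate set (exact here: the scan grid maps onto itself)."""
    side, box, stride = 48, 16, 8
    m = rng.normal(size=(side, side))
    base = rec.pick(m, tiny16_state, threshold=0.0, stride=stride,
                    nms_radius=stride, std_k=None)
    rot = rec.pick(np.rot90(m), tiny16_state, threshold=0.0, stride=stride,
                   nms_radius=stride, std_k=None)
    # rot90 is counter-clockwise: (x, y) -> (y, side - x - box)
    mapped = {(c.y, side - c.x - box) for c in base}
    assert {(c.x, c.y) for c in rot} == mapped


# ---------------------------------------------------------------------------
# binning
# ---------------------------------------------------------------------------

def test_binning_identity_and_mean_preservation(rng):
    m = rng.normal(size=(16, 20))
    assert np.array_equal(rec.bin_micrograph(m, 1), m)
    binned = rec.bin_micrograph(m, 4)
    assert binned.shape == (4, 5)
    assert binned.mean() == pytest.approx(m.mean(), abs=1e-12)


def test_binning_published_micrograph_size():
    """7420 x 7676 binned 4x gives the 1855 x 1919 working size."""
    m = np.zeros((7420, 7676), dtype=float)
    assert rec.bin_micrograph(m, 4).shape == (1855, 1919)


def test_binning_crops_trailing_pixels_and_validates(rng):
    m = rng.normal(size=(10, 11))
    out = rec.bin_micrograph(m, 4)
    assert out.shape == (2, 2)
    assert out[0, 0] == pytest.approx(m[:4, :4].mean())
    with pytest.raises(net.ConfigurationError):
        rec.bin_micrograph(m, 0)
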