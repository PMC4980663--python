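"""Boundary search: gradient cost, exact shortest path, spline init,
full-scan segmentation contracts."""

import itertools

import numpy as np
import pytest

from octcornea.segmentation import (
    BoundaryTrace,
    SegmentationConfig,
    gradient_cost,
    segment_cornea,
    shortest_path_boundary,
    spline_init_boundary,
)


# ---------------------------------------------------------------------------
# gradient cost
# ---------------------------------------------------------------------------


def test_bright_row_minimum_cost_dark_to_bright():
    img = np.zeros((10, 6))
    img[4] = 100.0
    cost = gradient_cost(img, "dark_to_bright")
    assert np.all(np.argmin(cost, axis=0) == 4)


def test_constant_image_uniform_cost():
    cost = gradient_cost(np.full((8, 5), 37.0), "dark_to_bright")
    assert np.allclose(cost, cost[0, 0])


def test_bright_to_dark_minimum_below_band():
    """On a 10x10 bright-band fixture the bright->dark cost minimum per
    column is the row found by exhaustively scanning signed gradients."""
    rng = np.random.default_rng(0)
    img = rng.normal(0, 1, (10, 10))
    img[3:6] += 80.0  # bright band rows 3..5
    cost = gradient_cost(img, "bright_to_dark")
    # oracle: exhaustive scan for the most negative backward difference
    expected = []
    for c in range(10):
        drops = [img[r, c] - img[r - 1, c] for r in range(1, 10)]
        expected.append(1 + int(np.argmin(drops)))
    expected = np.array(expected)
    assert np.array_equal(np.argmin(cost, axis=0), expected)
    assert np.all(expected >= 5)  # below the bright band


def test_gradient_cost_positive_and_input_checks():
    rng = np.random.default_rng(1)
    assert np.all(gradient_cost(rng.normal(size=(6, 4)), "dark_to_bright") > 0)
    with pytest.raises(ValueError):
        gradient_cost(np.zeros((1, 5)), "dark_to_bright")
    with pytest.raises(ValueError):
        gradient_cost(np.zeros((5, 5)), "sideways")


# ---------------------------------------------------------------------------
# shortest path: exactness vs brute force
# ---------------------------------------------------------------------------


def brute_force_min_cost(cost, max_step, band=None):
    H, W = cost.shape
    best = np.inf
    rows_range = range(H)
    for path in itertools.product(rows_range, repeat=W):
        if band is not None and any(not band[0][j] <= path[j] <= band[1][j] for j in range(W)):
            continue
        if any(abs(path[j + 1] - path[j]) > max_step for j in range(W - 1)):
            continue
        total = sum(cost[path[j], j] for j in range(W))
        best = min(best, total)
    return best


@pytest.mark.parametrize("H,W,max_step", [(4, 4, 1), (5, 5, 1), (6, 6, 2), (6, 5, 0), (3, 6, 2)])
def test_path_optimality_matches_enumeration(H, W, max_step):
    rng = np.random.default_rng(H * 100 + W * 10 + max_step)
    for trial in range(3):
        cost = rng.uniform(0.1, 5.0, (H, W))
        tr = shortest_path_boundary(cost, max_step=max_step)
        got = sum(cost[int(r), j] for j, r in enumerate(tr.rows))
        assert got == pytest.approx(brute_force_min_cost(cost, max_step))


def test_banded_path_matches_banded_enumeration():
    rng = np.random.default_rng(99)
    cost = rng.uniform(0.1, 5.0, (6, 5))
    cost[2] = 0.001  # global optimum row excluded by the band
    lo = np.full(5, 3)
    hi = np.full(5, 5)
    tr = shortest_path_boundary(cost, band=(lo, hi), max_step=1)
    got = sum(cost[int(r), j] for j, r in enumerate(tr.rows))
    assert np.all(tr.rows >= 3)
    assert got == pytest.approx(brute_force_min_cost(cost, 1, band=(lo, hi)))


def test_zero_cost_row_is_unique_optimum():
    cost = np.full((7, 9), 5.0) + 1e-6
    cost[3] = 1e-6
    tr = shortest_path_boundary(cost, max_step=1)
    assert np.all(tr.rows == 3)


def test_infeasible_band_raises():
    cost = np.ones((6, 4))
    lo = np.array([0, 5, 0, 0])
    hi = np.array([0, 5, 0, 0])
    with pytest.raises(ValueError, match="infeasible"):
        shortest_path_boundary(cost, band=(lo, hi), max_step=1)


def test_tie_breaking_is_deterministic_and_prefers_small_steps():
    """On a constant-cost grid every path ties; the documented rule picks
    the flat path through the upper row."""
    cost = np.ones((5, 6))
    tr = shortest_path_boundary(cost, max_step=2)
    assert np.all(tr.rows == 0)


# ---------------------------------------------------------------------------
# spline initialization
# ---------------------------------------------------------------------------


def test_spline_reproduces_line():
    pts = [(0, 10.0), (20, 20.0), (40, 30.0), (60, 40.0), (80, 50.0)]
    tr = spline_init_boundary(pts, 100)
    np.testing.assert_allclose(tr.rows, 10.0 + 0.5 * np.arange(100), atol=1e-8)


def test_spline_tracks_parabola_within_half_row():
    pts = [(c, 0.01 * c**2) for c in (0, 25, 50, 75, 100)]
    tr = spline_init_boundary(pts, 101)
    x = np.arange(101)
    assert np.max(np.abs(tr.rows - 0.01 * x**2)) < 0.5


def test_spline_precondition_errors():
    with pytest.raises(ValueError):
        spline_init_boundary([(10, 5.0)], 50)
    with pytest.raises(ValueError):
        spline_init_boundary([(10, 5.0), (10, 6.0)], 50)


# ---------------------------------------------------------------------------
# full segmentation
# ---------------------------------------------------------------------------


def _rms(a, b, mask):
    d = a[mask] - b[mask]
    return float(np.sqrt(np.mean(d**2)))


@pytest.mark.parametrize("region", ["central", "superior", "inferior"])
def test_noiseless_segmentation_within_one_pixel_rms(noiseless_eye, region):
    gt, scans = noiseless_eye
    scan = scans[region]
    bset = segment_cornea(scan)
    H = scan.geometry.axial_pixels
    for name in (
        "air_epithelium",
        "epithelium_bowman",
        "bowman_stroma",
        "stroma_posterior",
    ):
        truth = scan.truth_rows[name]
        tr = bset.trace(name)
        mask = tr.valid & np.isfinite(truth) & (truth < H - 2)
        assert mask.sum() > 1000
        assert _rms(tr.rows, truth, mask) <= 1.0


def test_seeded_bowman_search_matches_unseeded(noiseless_eye):
    """Seeding the Bowman-stroma search with points on the truth gives the
    same interface as the automatic band."""
    gt, scans = noiseless_eye
    scan = scans["central"]
    truth = scan.truth_rows["bowman_stroma"]
    seeds = [(c, float(truth[c])) for c in (100, 500, 1000, 1500, 1900)]
    auto = segment_cornea(scan)
    seeded = segment_cornea(scan, seeds=seeds)
    both = auto.bowman_stroma.valid & seeded.bowman_stroma.valid
    both[:100] = both[1901:] = False  # beyond the outer seeds the spline
    # extrapolates linearly along a curving interface, by design
    assert _rms(seeded.bowman_stroma.rows, truth, both) <= 1.0
    assert _rms(seeded.bowman_stroma.rows, auto.bowman_stroma.rows, both) < 0.5


def test_manual_corrections_apply_exactly(noiseless_eye):
    gt, scans = noiseless_eye
    scan = scans["central"]
    base = segment_cornea(scan)
    fixed = segment_cornea(scan, corrections=[("bowman_stroma", 100, 200, 2.0)])
    diff = fixed.bowman_stroma.rows - base.bowman_stroma.rows
    np.testing.assert_allclose(diff[100:201], 2.0)
    assert np.all(diff[:100] == 0) and np.all(diff[201:] == 0)
    for name in ("air_epithelium", "epithelium_bowman", "stroma_posterior"):
        np.testing.assert_array_equal(fixed.trace(name).rows, base.trace(name).rows)


def test_crossing_forced_by_correction_is_clipped_and_flagged(noiseless_eye):
    """A correction that pushes the epithelium-Bowman trace above the
    surface violates ordering; violating columns are clipped and flagged."""
    gt, scans = noiseless_eye
    scan = scans["central"]
    bset = segment_cornea(scan, corrections=[("epithelium_bowman", 300, 320, -200.0)])
    sl = slice(300, 321)
    assert np.all(bset.epithelium_bowman.rows[sl] >= bset.air_epithelium.rows[sl])
    assert bset.clipped[sl].all()
    assert not bset.clipped[:300].any()


def test_graceful_degradation_with_noise(noiseless_eye):
    """Segmentation error grows (weakly) with rendering noise but stays
    bounded at the default noise level."""
    from octcornea.synthetic import render_bscan

    gt, scans = noiseless_eye
    rms_by_noise = []
    for noise in (0.0, 12.0, 30.0):
        scan = render_bscan(gt, "central", scans["central"].geometry, seed=8, noise_sd=noise, with_truth=True)
        bset = segment_cornea(scan)
        truth = scan.truth_rows["air_epithelium"]
        mask = bset.air_epithelium.valid & np.isfinite(truth)
        rms_by_noise.append(_rms(bset.air_epithelium.rows, truth, mask))
    assert rms_by_noise[0] <= rms_by_noise[2] + 0.05
    assert rms_by_noise[2] < 2.0


def test_blank_image_rejected():
    from octcornea.synthetic import BScan
    from octcornea.geometry import ScanGeometry

    geom = ScanGeometry(axial_pixels=64, lateral_pixels=64, axial_extent_air_mm=0.1, lateral_extent_mm=0.3)
    scan = BScan(intensity=np.full((64, 64), 20, dtype=np.uint8), region="central", geometry=geom)
    with pytest.raises(ValueError, match="surface"):
        segment_cornea(scan)
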