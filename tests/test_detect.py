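"""Rake edge detection, dedup and per-cell statistics.

The edge state machine is pinned down by an independent brute-force
oracle that recomputes running baselines from scratch on every index.
"""

import itertools

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from optopore import (
    DetectionParams,
    SceneSpec,
    TargetPosition,
    deduplicate_targets,
    estimate_cells_treated,
    find_edges,
    generate_brightfield,
    positions_per_cell,
    rake_detect,
)
from optopore.scene import CellTruth, GroundTruth


# --- independent oracles -------------------------------------------------

def edges_oracle(profile, strength, hysteresis=0.0, kernel=0):
    """Literal application of the threshold+hysteresis rule.

    Baselines are recomputed from scratch as the min/max of the smoothed
    profile since the last event — a different mechanism from the
    incremental state machine in the implementation.
    """
    n = len(profile)
    if kernel:
        sm = [
            sum(profile[max(0, i - kernel) : i + kernel + 1])
            / len(profile[max(0, i - kernel) : i + kernel + 1])
            for i in range(n)
        ]
    else:
        sm = [float(v) for v in profile]
    events = []
    j = 0  # index of last event (baseline segment start)
    last = None
    i = 0
    while i < n:
        seg = sm[j : i + 1]
        x = sm[i]
        if last != "rising" and x - min(seg) >= strength + hysteresis:
            events.append((i, "rising", x - min(seg)))
            j, last = i, "rising"
        elif last != "falling" and max(seg) - x >= strength - hysteresis:
            events.append((i, "falling", max(seg) - x))
            j, last = i, "falling"
        i += 1
    return events


def dedup_oracle(points, min_sep):
    """O(n^2) greedy thinning in input order."""
    kept = []
    for x, y in points:
        if all((x - a) ** 2 + (y - b) ** 2 >= min_sep**2 for a, b in kept):
            kept.append((x, y))
    return kept


def as_events(evs):
    return [(e.index_px, e.polarity, e.strength) for e in evs]


# --- find_edges ----------------------------------------------------------

def test_constant_profile_has_no_edges():
    assert find_edges([7] * 10, 5.0) == []
    assert find_edges(np.full(50, 123.0), 1.0) == []


def test_single_step_rising_edge_example():
    evs = find_edges([10, 10, 10, 100, 100], 50.0, hysteresis=10.0)
    assert as_events(evs) == [(3, "rising", 90.0)]


def test_empty_profile_rejected():
    with pytest.raises(ValueError):
        find_edges([], 5.0)


def test_reversed_step_gives_mirrored_falling_edge():
    """With zero hysteresis, a rising edge at i in p is a falling edge at
    n - i in reversed(p): the first sample beyond the step is reported on
    either side."""
    profile = [10, 10, 10, 100, 100, 100]
    n = len(profile)
    rising = [e.index_px for e in find_edges(profile, 50.0) if e.polarity == "rising"]
    falling_rev = [e.index_px for e in find_edges(profile[::-1], 50.0) if e.polarity == "falling"]
    assert rising and falling_rev
    assert falling_rev == [n - i for i in rising]
    # and the oracle agrees on both orientations
    assert as_events(find_edges(profile[::-1], 50.0)) == edges_oracle(profile[::-1], 50.0)


def test_oracle_equivalence_on_random_profiles(rng):
    for _ in range(300):
        n = rng.integers(2, 30)
        profile = rng.integers(0, 120, size=n).astype(float)
        s = float(rng.integers(5, 60))
        h = float(rng.integers(0, 5)) if s > 5 else 0.0
        k = int(rng.integers(0, 3))
        got = as_events(find_edges(profile, s, h, k))
        expected = edges_oracle(list(profile), s, h, k)
        assert got == pytest.approx(expected)


@settings(derandomize=True, max_examples=200, deadline=None)
@given(
    profile=st.lists(st.sampled_from([0.0, 25.0, 50.0, 75.0]), min_size=2, max_size=20),
    strength=st.sampled_from([20.0, 40.0, 60.0]),
)
def test_edge_events_alternate_and_stay_in_range(profile, strength):
    evs = find_edges(profile, strength)
    for a, b in zip(evs, evs[1:]):
        assert a.polarity != b.polarity
        assert a.index_px < b.index_px
    for e in evs:
        assert 0 <= e.index_px < len(profile)
        assert e.strength >= strength


# --- rake_detect ---------------------------------------------------------

def test_blank_image_yields_no_positions():
    image = np.full((100, 100), 50, dtype=np.uint16)
    assert rake_detect(image, DetectionParams()) == []


def test_image_smaller_than_one_roi_rejected():
    with pytest.raises(ValueError):
        rake_detect(np.zeros((10, 10)), DetectionParams(search_area_size_um=12.0, pixel_size_um=0.5))


def test_positions_lie_on_cell_contours_without_noise():
    spec = SceneSpec(n_cells=15, edge_contrast=50.0, noise_sd=0.0, seed=31)
    image, truth = generate_brightfield(spec)
    params = DetectionParams(search_area_size_um=10.0, min_edge_strength=15.0)
    positions = rake_detect(image, params)
    assert positions
    ring_width_px = 2.0
    for p in positions:
        dists = []
        for c in truth.cells:
            d = np.hypot(p.row_px - c.centroid_row, p.col_px - c.centroid_col)
            r = c.radius_um / spec.pixel_size_um
            # distance from the contour ring [r - ring_width, r]
            dists.append(max(0.0, d - r, (r - ring_width_px) - d))
        assert min(dists) <= 2.0


def test_position_count_monotone_in_edge_strength():
    spec = SceneSpec(n_cells=25, edge_contrast=30.0, noise_sd=4.0, seed=13)
    image, _ = generate_brightfield(spec)
    counts = [
        len(rake_detect(image, DetectionParams(min_edge_strength=s)))
        for s in (5.0, 15.0, 25.0)
    ]
    assert counts[0] >= counts[1] >= counts[2]
    assert counts[0] > counts[2]  # the spread is real, not vacuous


def test_doubling_line_spacing_scans_subset_of_positions():
    spec = SceneSpec(n_cells=25, seed=17)
    image, _ = generate_brightfield(spec)
    base = dict(search_area_size_um=12.0, min_edge_strength=15.0)
    fine = rake_detect(image, DetectionParams(rake_spacing_um=6.0, **base))
    coarse = rake_detect(image, DetectionParams(rake_spacing_um=12.0, **base))
    fine_set = {(p.row_px, p.col_px) for p in fine}
    coarse_set = {(p.row_px, p.col_px) for p in coarse}
    assert coarse_set <= fine_set


def test_per_cell_mean_non_increasing_in_line_spacing():
    spec = SceneSpec(n_cells=20, cell_radius_um=(5.0, 7.0), seed=19)
    image, truth = generate_brightfield(spec)
    means = []
    for spacing in (6.0, 12.0, 18.0):
        params = DetectionParams(search_area_size_um=12.0, rake_spacing_um=spacing, min_edge_strength=15.0)
        positions = rake_detect(image, params)
        means.append(positions_per_cell(positions, truth).mean)
    assert means[0] >= means[1] >= means[2]
    assert means[0] > means[2]


# --- deduplicate_targets -------------------------------------------------

def _pos(x, y):
    return TargetPosition(row_px=int(y * 2), col_px=int(x * 2), x_um=x, y_um=y, rake_line_index=0)


def test_dedup_empty_and_two_close_points():
    assert deduplicate_targets([], 5.0) == []
    a, b = _pos(0.0, 0.0), _pos(1.0, 0.0)
    kept = deduplicate_targets([a, b], 5.0)
    assert kept == [a]
    assert b.status == "removed"
    assert a.status == "pending"


def test_dedup_matches_brute_force_oracle(rng):
    for _ in range(25):
        pts = rng.uniform(0, 50, size=(200, 2))
        positions = [_pos(x, y) for x, y in pts]
        kept = deduplicate_targets(positions, 4.0)
        expected = dedup_oracle([tuple(p) for p in pts], 4.0)
        assert [(p.x_um, p.y_um) for p in kept] == expected


def test_dedup_invariants_and_idempotence(rng):
    pts = rng.uniform(0, 30, size=(150, 2))
    positions = [_pos(x, y) for x, y in pts]
    kept = deduplicate_targets(positions, 3.0)
    xy = np.array([(p.x_um, p.y_um) for p in kept])
    d = np.hypot(xy[:, None, 0] - xy[None, :, 0], xy[:, None, 1] - xy[None, :, 1])
    np.fill_diagonal(d, np.inf)
    assert d.min() >= 3.0
    assert deduplicate_targets(list(kept), 3.0) == kept


# --- positions_per_cell --------------------------------------------------

def _grid_truth(n_cells, width=64):
    """Single-pixel cells on a grid; cell k at (2k // width * 2, (2k) % width)."""
    rows = 2 * ((2 * np.arange(n_cells)) // width) + 1
    cols = (2 * np.arange(n_cells)) % width
    h = rows.max() + 2
    labels = np.zeros((h, width), dtype=np.int32)
    cells = []
    for k in range(n_cells):
        labels[rows[k], cols[k]] = k + 1
        cells.append(
            CellTruth(label=k + 1, centroid_row=float(rows[k]), centroid_col=float(cols[k]),
                      radius_um=0.5, cell_class="intact", true_means={})
        )
    return GroundTruth(cells=cells, label_image=labels)


def make_positions(truth, counts):
    positions = []
    for cell, c in zip(truth.cells, counts):
        for _ in range(c):
            positions.append(
                TargetPosition(row_px=int(cell.centroid_row), col_px=int(cell.centroid_col),
                               x_um=cell.centroid_col * 0.5, y_um=cell.centroid_row * 0.5,
                               rake_line_index=0)
            )
    return positions


def test_no_positions_means_zero_counts():
    truth = _grid_truth(5)
    stats = positions_per_cell([], truth)
    assert stats.mean == 0.0
    assert all(v == 0 for v in stats.counts.values())


def test_hand_built_histogram():
    truth = _grid_truth(3)
    stats = positions_per_cell(make_positions(truth, [2, 1, 0]), truth)
    assert stats.histogram == {0: 1, 1: 1, 2: 1}
    assert stats.mean == 1.0


def test_sampled_counts_give_printed_per_cell_mean():
    """404 positions over 281 cells -> 1.44 positions per cell (2 d.p.)."""
    counts = [2] * 123 + [1] * 158  # 123*2 + 158 = 404 over 281 cells
    truth = _grid_truth(281)
    stats = positions_per_cell(make_positions(truth, counts), truth)
    assert stats.n_unassigned == 0
    assert round(stats.mean, 2) == 1.44


def test_estimate_cells_treated_chain():
    assert estimate_cells_treated(6281, 404 / 281) == 4360
    with pytest.raises(ValueError):
        estimate_cells_treated(100, 0.0)


def test_detection_params_validation():
    with pytest.raises(ValueError):
        DetectionParams(min_edge_strength=0.0)
    with pytest.raises(ValueError):
        DetectionParams(min_edge_strength=10.0, hysteresis=10.0)
    with pytest.raises(ValueError):
        DetectionParams(search_area_size_um=0.5, pixel_size_um=0.5)
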