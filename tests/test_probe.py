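"""Probe geometry: mirrored grids, SD pair enumeration, distance classes,
exclusion rules and the non-boundary ring-peeling selection."""

import math

import numpy as np
import pytest

from platedot.errors import (
    GeometryError,
    InvalidInputError,
    SelectionFailureError,
)
from platedot.probe import (
    apply_exclusions,
    build_probe,
    enumerate_pairs,
    group_by_distance,
    retained,
    select_non_boundary,
)

from conftest import make_measurements


@pytest.mark.parametrize(
    "rows,cols,expected",
    [(7, 8, 56), (3, 4, 12), (1, 1, 1)],
)
def test_build_probe_counts(rows, cols, expected):
    probe = build_probe(rows, cols, 13.0, 14.0, 44.0)
    assert probe.I == probe.J == expected
    assert len(enumerate_pairs(probe)) == expected**2


def test_mirrored_grid_geometry():
    probe = build_probe(3, 4, 13.0, 14.0, 44.0)
    src, det = probe.source_positions, probe.detector_positions
    assert np.allclose(src[:, 0], 0.0)
    assert np.allclose(det[:, 0], 44.0)
    # detector k mirrors source k: same (y, z)
    assert np.allclose(src[:, 1:], det[:, 1:])
    # grid pitches
    assert np.isclose(src[4, 1] - src[0, 1], 13.0)  # next row
    assert np.isclose(src[1, 2] - src[0, 2], 14.0)  # next column


@pytest.mark.parametrize(
    "kwargs",
    [
        dict(n_rows=0, n_cols=4, row_spacing=13, col_spacing=14, plate_separation=44),
        dict(n_rows=3, n_cols=4, row_spacing=-1, col_spacing=14, plate_separation=44),
        dict(n_rows=3, n_cols=4, row_spacing=13, col_spacing=14, plate_separation=0),
    ],
)
def test_invalid_geometry_rejected(kwargs):
    with pytest.raises(GeometryError):
        build_probe(**kwargs)


def test_pair_distances_and_ordering():
    probe = build_probe(3, 4, 13.0, 14.0, 44.0)
    pairs = enumerate_pairs(probe)
    # source-major ordering
    assert [p.key for p in pairs[:4]] == [(1, 1), (1, 2), (1, 3), (1, 4)]
    # mirror pair at the plate separation
    assert math.isclose(pairs[0].distance, 44.0)
    # one row and one column over: sqrt(44^2 + 13^2 + 14^2)
    by_key = {p.key: p for p in pairs}
    assert math.isclose(by_key[(1, 6)].distance, math.sqrt(2301.0))
    # every pair at least a plate separation apart
    assert all(p.distance >= 44.0 for p in pairs)


def test_simulation_layout_below_distance_cutoff(sim_probe):
    pairs = enumerate_pairs(sim_probe)
    longest = max(p.distance for p in pairs)
    assert math.isclose(longest, math.sqrt(1936 + 676 + 1764))
    assert longest < 110.0


@pytest.mark.parametrize(
    "rows,cols,expected_k",
    [(3, 4, 12), (7, 8, 56), (1, 1, 1)],
)
def test_distance_class_count(rows, cols, expected_k):
    probe = build_probe(rows, cols, 13.0, 14.0, 44.0)
    pairs = enumerate_pairs(probe)
    classes = group_by_distance(pairs)
    assert len(classes) == expected_k
    assert sum(len(c) for c in classes) == len(pairs)
    # sorted ascending, partition (disjoint cover)
    d = [c.d_k for c in classes]
    assert d == sorted(d)
    seen = [p.key for c in classes for p in c.members]
    assert len(seen) == len(set(seen)) == len(pairs)


def test_grouping_stable_under_float_jitter(sim_probe):
    pairs = enumerate_pairs(sim_probe)
    baseline = [
        sorted(p.key for p in c.members) for c in group_by_distance(pairs)
    ]
    rng = np.random.default_rng(0)
    for p in pairs:
        p.distance += rng.uniform(-1e-9, 1e-9)
    jittered = [
        sorted(p.key for p in c.members) for c in group_by_distance(pairs)
    ]
    assert baseline == jittered


def test_exclusion_by_distance(full_probe):
    pairs = enumerate_pairs(full_probe)
    flagged = apply_exclusions(pairs, None, 110.0)
    brute = sum(1 for p in pairs if p.distance > 110.0)
    assert brute > 0
    excluded = [p for p in flagged if p.excluded]
    assert len(excluded) == brute
    assert all(p.reason == "over_max_distance" for p in excluded)
    # order preserved
    assert [p.key for p in flagged] == [p.key for p in pairs]
    # corner-to-opposite-corner pair is among them: distance sqrt(17624)
    corner = next(p for p in flagged if p.key == (1, 56))
    assert math.isclose(corner.distance, math.sqrt(17624.0))
    assert corner.excluded


def test_no_exclusions_with_infinite_cutoff(full_probe):
    flagged = apply_exclusions(enumerate_pairs(full_probe), None, math.inf)
    assert not any(p.excluded for p in flagged)


def test_uncovered_source_excludes_all_its_pairs(sim_probe):
    mask = np.ones(sim_probe.I, bool)
    mask[0] = False
    flagged = apply_exclusions(enumerate_pairs(sim_probe), mask)
    uncovered = [p for p in flagged if p.excluded and p.reason == "uncovered"]
    # source 1 and detector 1 (mirrored mask) both drop out
    assert {p.key for p in uncovered} == {
        (1, j) for j in range(1, 13)
    } | {(i, 1) for i in range(1, 13)}


def test_coverage_mask_length_mismatch(sim_probe):
    with pytest.raises(InvalidInputError):
        apply_exclusions(enumerate_pairs(sim_probe), np.ones(5, bool))


def test_partition_after_exclusions(full_probe):
    flagged = apply_exclusions(enumerate_pairs(full_probe), None, 110.0)
    classes = group_by_distance(flagged)
    kept = retained(flagged)
    covered = sorted(p.key for c in classes for p in c.members)
    assert covered == sorted(p.key for p in kept)


def test_distances_symmetric_under_endpoint_exchange(sim_probe):
    pairs = {p.key: p.distance for p in enumerate_pairs(sim_probe)}
    for (i, j), d in pairs.items():
        assert math.isclose(d, pairs[(j, i)])


# ------------------------------------------------------- non-boundary peeling
def _ring_keys(probe):
    """Pairs touching the outermost ring of the (mirrored) grids."""
    ring = set()
    for k in range(1, probe.I + 1):
        r, c = probe.grid_position(k)
        if r in (0, probe.n_rows - 1) or c in (0, probe.n_cols - 1):
            ring.add(k)
    return ring


def test_uniform_classes_need_no_peeling(sim_probe, sim_pairs):
    classes = group_by_distance(sim_pairs)
    ms = make_measurements(sim_pairs, np.ones(len(sim_pairs)))
    result = select_non_boundary(sim_probe, classes, ms, cov_threshold=0.3)
    assert len(result.pairs) == len(sim_pairs)
    assert len(result.report) == 1
    assert result.report[0]["max_cov"] == 0.0


def test_perturbed_ring_is_peeled_in_one_iteration(sim_probe, sim_pairs):
    ring = _ring_keys(sim_probe)
    amps = np.array(
        [
            0.5 if (p.source_index in ring or p.detector_index in ring) else 1.0
            for p in sim_pairs
        ]
    )
    classes = group_by_distance(sim_pairs)
    ms = make_measurements(sim_pairs, amps)
    result = select_non_boundary(sim_probe, classes, ms, cov_threshold=0.3)
    assert len(result.report) == 2  # one peel
    assert result.report[0]["max_cov"] > 0.3
    assert result.report[1]["max_cov"] == 0.0
    # only interior-grid pairs survive
    assert all(
        p.source_index not in ring and p.detector_index not in ring
        for p in result.pairs
    )


def test_unreachable_threshold_raises_selection_failure(sim_probe, sim_pairs):
    rng = np.random.default_rng(7)
    amps = rng.uniform(0.5, 1.5, len(sim_pairs))
    classes = group_by_distance(sim_pairs)
    ms = make_measurements(sim_pairs, amps)
    with pytest.raises(SelectionFailureError) as err:
        select_non_boundary(sim_probe, classes, ms, cov_threshold=0.0)
    # failure carries the CoV history of every peel iteration
    assert len(err.value.report) >= 2
    assert err.value.report[-1]["max_cov"] > 0.0


def test_peeling_reduces_max_cov_for_boundary_perturbations(sim_probe, sim_pairs):
    ring = _ring_keys(sim_probe)
    rng = np.random.default_rng(3)
    amps = np.array(
        [
            (0.6 + 0.2 * rng.random())
            if (p.source_index in ring or p.detector_index in ring)
            else 1.0 + 0.01 * rng.random()
            for p in sim_pairs
        ]
    )
    classes = group_by_distance(sim_pairs)
    ms = make_measurements(sim_pairs, amps)
    with pytest.raises(SelectionFailureError) as err:
        # threshold 0 forces full peeling so the whole CoV trajectory is logged
        select_non_boundary(sim_probe, classes, ms, cov_threshold=0.0)
    covs = [entry["max_cov"] for entry in err.value.report]
    assert covs[1] <= covs[0]
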