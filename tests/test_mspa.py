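"""Structural segmentation: distances, components, holes, the classifier
against the brute-force oracle, and its invariants."""

import numpy as np
import pytest

import oracle_mspa
from conftest import labels_to_names
from fragscape.landscape import MSPA_CLASSES, BinaryLandscape
from fragscape.mspa import (
    MSPAParams,
    class_proportions,
    distance_to_background,
    extract_core,
    find_holes,
    label_components,
    segment,
)
from fragscape.synthetic import generate_fixture


def scape(grid):
    return BinaryLandscape(np.asarray(grid, dtype=bool))


# --- distance transform ----------------------------------------------------


def test_distance_all_background_is_zero():
    assert (distance_to_background(scape(np.zeros((4, 4)))) == 0).all()


def test_distance_single_cell():
    grid = np.zeros((3, 3))
    grid[1, 1] = 1
    assert distance_to_background(scape(grid))[1, 1] == 1.0


def test_distance_square_center_matches_bruteforce():
    grid = np.zeros((13, 13), dtype=bool)
    grid[1:12, 1:12] = True  # 11x11 square with a 1-cell margin
    d = distance_to_background(scape(grid))
    assert d[6, 6] == 6.0
    # exhaustive pairwise minimum over all background cells
    bgs = np.argwhere(~grid)
    for r, c in [(6, 6), (1, 1), (3, 7)]:
        d2 = ((bgs[:, 0] - r) ** 2 + (bgs[:, 1] - c) ** 2).min()
        assert d[r, c] == pytest.approx(np.sqrt(d2))


def test_distance_no_background_is_infinite():
    d = distance_to_background(scape(np.ones((5, 5))))
    assert np.isinf(d).all()


# --- core extraction -------------------------------------------------------


def test_core_of_11x11_square_is_3x3():
    scape_, _ = generate_fixture("solid_square", size=11)
    core = extract_core(scape_, MSPAParams(edge_width=4))
    assert core.sum() == 9


def test_thin_shapes_have_no_core():
    grid = np.zeros((20, 20), dtype=bool)
    grid[5:13, 5:9] = True  # max width 4 <= 2*D per short axis at D=4... use 8x4 strip
    assert extract_core(scape(grid), MSPAParams(edge_width=4)).sum() == 0


def test_unit_edge_width_excludes_only_boundary_ring():
    grid = np.zeros((7, 7), dtype=bool)
    grid[1:6, 1:6] = True
    core = extract_core(scape(grid), MSPAParams(edge_width=1.0))
    # distance is strict, so exactly the distance-1 ring drops out
    assert core.sum() == 9


# --- connected components --------------------------------------------------


def test_diagonal_adjacency_depends_on_connectivity():
    mask = np.array([[1, 0], [0, 1]], dtype=bool)
    assert label_components(mask, 8)[1] == 1
    assert label_components(mask, 4)[1] == 2


def test_empty_mask_has_no_components():
    assert label_components(np.zeros((3, 3), dtype=bool), 8)[1] == 0


@pytest.mark.parametrize("connectivity", [4, 8])
def test_component_count_matches_flood_fill_oracle(connectivity, rng):
    for _ in range(100):
        mask = rng.random((20, 20)) < rng.uniform(0.2, 0.8)
        _, n = label_components(mask, connectivity)
        _, n_oracle = oracle_mspa.flood_fill_label(mask, connectivity)
        assert n == n_oracle


def test_labels_are_raster_scan_ordered():
    mask = np.array([[0, 1, 0, 1], [0, 0, 0, 1], [1, 0, 0, 0]], dtype=bool)
    lab, n = label_components(mask, 4)
    assert n == 3
    assert lab[0, 1] == 1 and lab[0, 3] == 2 and lab[2, 0] == 3


# --- holes -----------------------------------------------------------------


def test_donut_has_one_hole():
    scape_, _ = generate_fixture("donut")
    holes, n = find_holes(scape_, MSPAParams())
    assert n == 1
    # the hole is exactly the enclosed background
    inner = ~scape_.grid.copy()
    inner[0, :] = False
    assert (holes > 0).sum() < (~scape_.grid).sum()


def test_solid_square_has_no_holes():
    scape_, _ = generate_fixture("solid_square")
    assert find_holes(scape_, MSPAParams())[1] == 0


def test_border_touching_background_is_not_a_hole():
    grid = np.ones((6, 6), dtype=bool)
    grid[0:3, 2] = False  # strip reaching the border
    assert find_holes(scape(grid), MSPAParams())[1] == 0


def test_connectivity_duality_on_diagonal_ring():
    # diamond of diagonally-touching cells: encloses a hole only under R=8
    grid = np.zeros((7, 7), dtype=bool)
    for r, c in [(1, 3), (2, 2), (2, 4), (3, 1), (3, 5), (4, 2), (4, 4), (5, 3)]:
        grid[r, c] = True
    assert find_holes(scape(grid), MSPAParams(connectivity=8))[1] == 1
    assert find_holes(scape(grid), MSPAParams(connectivity=4))[1] == 0


# --- segmentation ----------------------------------------------------------


def test_scatter_is_all_islet():
    scape_, _ = generate_fixture("scatter")
    props = class_proportions(segment(scape_))
    assert props["islet"] == 1.0


@pytest.mark.parametrize(
    "name", ["solid_square", "donut", "dumbbell", "ring", "scatter", "two_cores_with_branch"]
)
def test_fixtures_match_ground_truth_and_oracle(name):
    scape_, expected = generate_fixture(name)
    got = segment(scape_).labels
    np.testing.assert_array_equal(got, expected)
    oracle = oracle_mspa.classify(scape_.grid)
    np.testing.assert_array_equal(labels_to_names(got), oracle)


def test_donut_bands_split_into_perforation_and_edge():
    scape_, _ = generate_fixture("donut")
    cmap = segment(scape_)
    counts = cmap.class_counts()
    assert counts["core"] > 0
    assert counts["perforation"] > 0 and counts["edge"] > 0
    assert counts["loop"] == 0 and counts["bridge"] == 0
    # inner band faces the hole
    holes, _ = find_holes(scape_, cmap.params)
    perf = cmap.label_mask("perforation")
    from scipy import ndimage

    near_hole = ndimage.binary_dilation(holes > 0, iterations=5)
    assert (perf & ~near_hole).sum() == 0


def test_dumbbell_corridor_is_bridge_stub_is_branch():
    scape_, _ = generate_fixture("two_cores_with_branch")
    cmap = segment(scape_)
    names = labels_to_names(cmap.labels)
    mid = scape_.n_rows // 2
    corridor_cols = np.flatnonzero(scape_.grid[mid])
    # interior corridor cells between the squares are bridge
    assert "bridge" in set(names[mid])
    # the one-ended stub above the left square is branch
    stub_cells = names[: scape_.n_rows // 2 - 7, :]
    assert set(stub_cells[stub_cells != "background"]) <= {"branch"}
    assert corridor_cols.size > 0


def test_ring_fixture_contains_loop():
    scape_, _ = generate_fixture("ring")
    counts = segment(scape_).class_counts()
    assert counts["loop"] > 0
    assert counts["bridge"] == 0


def test_all_foreground_is_all_core():
    cmap = segment(scape(np.ones((6, 6))))
    assert cmap.class_counts()["core"] == 36


def test_all_background_is_valid():
    cmap = segment(scape(np.zeros((6, 6))))
    assert cmap.foreground_cells == 0
    with pytest.raises(ValueError):
        class_proportions(cmap)


def test_proportions_sum_to_one(rng):
    fg = rng.random((30, 30)) < 0.5
    cmap = segment(BinaryLandscape(fg))
    props = class_proportions(cmap)
    assert sum(props.values()) == pytest.approx(1.0, abs=1e-12)
    per_land = class_proportions(cmap, per="landscape")
    assert sum(per_land.values()) == pytest.approx(1.0, abs=1e-12)


def test_partition_invariant_random_maps(rng):
    for _ in range(25):
        fg = rng.random((25, 25)) < rng.uniform(0.2, 0.8)
        cmap = segment(BinaryLandscape(fg))
        counts = cmap.class_counts()
        assert sum(counts[c] for c in MSPA_CLASSES) == fg.sum()
        assert counts["background"] == (~fg).sum()


def test_islets_only_in_coreless_components(rng):
    for _ in range(10):
        fg = rng.random((30, 30)) < 0.45
        cmap = segment(BinaryLandscape(fg))
        islet = cmap.label_mask("islet")
        core = cmap.label_mask("core")
        comp, n = label_components(fg, 8)
        for k in range(1, n + 1):
            cells = comp == k
            if (islet & cells).any():
                assert not (core & cells).any()
                assert (islet & cells).sum() == cells.sum()


def test_core_monotone_and_islets_grow_with_edge_width(rng):
    widths = [1.0, 2.0, 4.0, 6.0]
    for _ in range(20):
        fg = rng.random((30, 30)) < rng.uniform(0.4, 0.7)
        land = BinaryLandscape(fg)
        cores = [extract_core(land, MSPAParams(edge_width=d)) for d in widths]
        islets = [
            segment(land, MSPAParams(edge_width=d)).class_counts()["islet"] for d in widths
        ]
        for small, big in zip(cores, cores[1:]):
            assert not (big & ~small).any()  # core(D2) subset of core(D1)
        assert all(a <= b for a, b in zip(islets, islets[1:]))


def test_padding_with_background_leaves_counts_unchanged(rng):
    for _ in range(10):
        fg = np.zeros((24, 24), dtype=bool)
        fg[2:22, 2:22] = rng.random((20, 20)) < 0.55  # keep a background margin
        counts = segment(BinaryLandscape(fg)).class_counts()
        padded = np.pad(fg, 5, constant_values=False)
        counts_padded = segment(BinaryLandscape(padded)).class_counts()
        for label in MSPA_CLASSES:
            assert counts[label] == counts_padded[label]


def test_boundary_over_connector_absorbs_short_corridors():
    # corridor shorter than 2D sits inside the boundary band of both cores
    scape_, _ = generate_fixture("dumbbell", corridor=5)
    default = segment(scape_).class_counts()
    flipped = segment(scape_, boundary_over_connector=True).class_counts()
    assert default["bridge"] > 0
    assert flipped["bridge"] < default["bridge"]
    assert flipped["edge"] > default["edge"]


def test_params_validation():
    with pytest.raises(ValueError):
        MSPAParams(edge_width=0)
    with pytest.raises(ValueError):
        MSPAParams(connectivity=6)
    assert MSPAParams(connectivity=8).background_connectivity == 4
    assert MSPAParams(connectivity=4).background_connectivity == 8
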