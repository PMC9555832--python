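"""Lattice geometry: neighborhoods, barrier masks, connected components."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from driftgrid import (
    BarrierMask,
    GridSpec,
    connected_components,
    moore_neighbors,
    parse_barrier_mask,
    render_barrier_mask,
)
from driftgrid.grid import GridError, MaskFormatError, degree_array


class TestMooreNeighbors:
    def test_interior_cell_has_eight_neighbors_in_row_major_order(self):
        grid = GridSpec(32, 32)
        nbrs = moore_neighbors(grid, (10, 10))
        assert nbrs == [
            (9, 9), (9, 10), (9, 11),
            (10, 9), (10, 11),
            (11, 9), (11, 10), (11, 11),
        ]

    @pytest.mark.parametrize(
        "cell,expected",
        [
            ((0, 0), {(0, 1), (1, 0), (1, 1)}),  # corner: 3, truncated at two edges
            ((0, 5), {(0, 4), (0, 6), (1, 4), (1, 5), (1, 6)}),  # edge: 5
        ],
    )
    def test_edge_truncation_no_wraparound(self, cell, expected):
        grid = GridSpec(32, 32)
        assert set(moore_neighbors(grid, cell)) == expected

    def test_out_of_bounds_cell_rejected(self, tiny_grid):
        with pytest.raises(GridError):
            moore_neighbors(tiny_grid, (5, 0))

    @given(
        rows=st.integers(3, 12),
        cols=st.integers(3, 12),
        r=st.integers(0, 11),
        c=st.integers(0, 11),
    )
    @settings(max_examples=60, deadline=None)
    def test_symmetry_and_degree_classes(self, rows, cols, r, c):
        grid = GridSpec(rows, cols)
        cell = (r % rows, c % cols)
        nbrs = moore_neighbors(grid, cell)
        assert len(nbrs) in (3, 5, 8)
        assert cell not in nbrs
        for nb in nbrs:
            assert cell in moore_neighbors(grid, nb)

    def test_degree_array_matches_neighbor_counts(self):
        grid = GridSpec(4, 6)
        deg = degree_array(grid)
        assert deg[0, 0] == 3 and deg[0, 3] == 5 and deg[2, 3] == 8
        assert deg.sum() == sum(len(moore_neighbors(grid, c)) for c in grid.cells())


class TestBarrierMask:
    def test_mutation_only_via_add_remove_with_audit(self, tiny_grid):
        mask = BarrierMask(tiny_grid)
        mask.add([(1, 1), (2, 2)])
        mask.remove([(1, 1)])
        assert mask.barrier_cells == {(2, 2)}
        assert mask.audit_log == [("add", (1, 1)), ("add", (2, 2)), ("remove", (1, 1))]

    def test_out_of_grid_cells_rejected(self, tiny_grid):
        with pytest.raises(GridError):
            BarrierMask(tiny_grid, {(9, 9)})


class TestConnectedComponents:
    def test_empty_mask_is_one_component(self, tiny_grid):
        lab = connected_components(tiny_grid)
        assert lab.n_components == 1
        assert (lab.labels == 0).all()

    def test_full_cross_makes_four_quadrants(self):
        grid = GridSpec(32, 32)
        cells = {(15, c) for c in range(32)} | {(r, 15) for r in range(32)}
        lab = connected_components(grid, BarrierMask(grid, cells))
        assert lab.n_components == 4
        # labels ordered by smallest row-major member: 0 is the quadrant of (0,0)
        assert lab.component_of((0, 0)) == 0
        assert lab.component_of((0, 31)) == 1
        assert lab.component_of((31, 0)) == 2
        assert lab.component_of((31, 31)) == 3
        assert sorted(lab.sizes().values()) == [225, 240, 240, 256]

    def test_corridor_gap_reconnects_halves(self):
        # full barrier column at col 2 of a 5x5, except a gap at (2,2)
        grid = GridSpec(5, 5)
        cells = {(r, 2) for r in range(5)} - {(2, 2)}
        lab = connected_components(grid, BarrierMask(grid, cells))
        assert lab.n_components == 1

    def test_diagonal_gap_leaks(self):
        # Moore adjacency is used for connectivity, so a staggered barrier
        # with only diagonal contact does not separate the grid
        grid = GridSpec(4, 4)
        cells = {(0, 1), (1, 2), (2, 1), (3, 2)}
        lab = connected_components(grid, BarrierMask(grid, cells))
        assert lab.n_components == 1

    def test_partition_covers_every_open_cell_once(self):
        grid = GridSpec(6, 6)
        mask = BarrierMask(grid, {(r, 3) for r in range(6)})
        lab = connected_components(grid, mask)
        open_cells = grid.n_cells - len(mask)
        assert sum(lab.sizes().values()) == open_cells
        assert (lab.labels.ravel() >= 0).sum() == open_cells

    @given(st.data())
    @settings(max_examples=40, deadline=None)
    def test_removing_a_barrier_never_increases_component_count(self, data):
        grid = GridSpec(6, 6)
        cells = data.draw(
            st.sets(
                st.tuples(st.integers(0, 5), st.integers(0, 5)),
                min_size=1,
                max_size=20,
            )
        )
        mask = BarrierMask(grid, set(cells))
        before = connected_components(grid, mask).n_components
        victim = sorted(mask.barrier_cells)[0]
        mask.remove([victim])
        after = connected_components(grid, mask).n_components
        assert after <= before

    def test_component_table_has_expected_columns(self):
        grid = GridSpec(3, 3)
        df = connected_components(grid).to_frame()
        assert list(df.columns) == ["component_id", "row", "col"]
        assert len(df) == 9


class TestMaskText:
    def test_parse_simple_masks(self):
        assert parse_barrier_mask("..\n..").barrier_cells == frozenset()
        assert parse_barrier_mask("#.\n.#").barrier_cells == {(0, 0), (1, 1)}

    @pytest.mark.parametrize(
        "text,match",
        [
            ("..\n...", "line 2"),
            ("..\n.x", "line 2"),
            ("", "empty"),
        ],
    )
    def test_malformed_text_names_the_line(self, text, match):
        with pytest.raises(MaskFormatError, match=match):
            parse_barrier_mask(text)

    def test_dimension_mismatch_rejected(self):
        with pytest.raises(MaskFormatError, match="grid"):
            parse_barrier_mask("..\n..", GridSpec(3, 3))

    @given(
        rows=st.integers(1, 8),
        cols=st.integers(1, 8),
        bits=st.lists(st.booleans(), min_size=64, max_size=64),
    )
    @settings(max_examples=50, deadline=None)
    def test_round_trip_is_identity(self, rows, cols, bits):
        text = "\n".join(
            "".join("#" if bits[(r * cols + c) % 64] else "." for c in range(cols))
            for r in range(rows)
        )
        mask = parse_barrier_mask(text)
        assert render_barrier_mask(mask) == text
        assert parse_barrier_mask(render_barrier_mask(mask)).barrier_cells == mask.barrier_cells
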