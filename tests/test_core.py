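"""The stochastic engine: urn initialization, the death/birth kernel,
forced mutation and barrier-edit semantics."""

from dataclasses import replace

import numpy as np
import pytest

from driftgrid import (
    BARRIER,
    EMPTY,
    OCCUPIED,
    BarrierMask,
    GridSpec,
    SimConfig,
    add_barrier,
    expected_initial_alleles,
    force_mutation,
    hoppe_urn_init,
    occupied_neighbors,
    remove_barrier,
    run_generation,
    run_steps,
    step,
)
from driftgrid.core import ParameterError, StateError, state_from_alleles


def distinct_alleles(state):
    return set(state.allele[state.cell_state == OCCUPIED].tolist())


class TestHoppeUrnInit:
    def test_default_grid_holds_1024_individuals(self, default_config):
        state = hoppe_urn_init(default_config)
        assert state.population_size() == 1024
        assert state.generation == 0

    def test_theta_zero_gives_single_allele(self):
        cfg = SimConfig(grid=GridSpec(6, 6), init_mu=0.0, seed=3)
        state = hoppe_urn_init(cfg)
        assert distinct_alleles(state) == {1}

    def test_barrier_cells_stay_barriers_and_shrink_population(self, small_config):
        mask = BarrierMask(small_config.grid, {(0, 0), (3, 3), (7, 7)})
        state = hoppe_urn_init(small_config, mask)
        assert state.population_size() == 61
        assert state.state_of((3, 3)) == BARRIER

    def test_all_barriers_is_an_error(self):
        grid = GridSpec(2, 2)
        mask = BarrierMask(grid, set(grid.cells()))
        with pytest.raises(StateError, match="barrier"):
            hoppe_urn_init(SimConfig(grid=grid), mask)

    def test_mean_allele_count_matches_ewens_closed_form(self):
        # small-N version of the urn calibration: E[K] = sum theta/(theta+i)
        n_reps, N = 400, 256
        cfg = SimConfig(grid=GridSpec(16, 16), seed=0)
        theta = 2 * N * cfg.init_mu
        ks = []
        for i in range(n_reps):
            state = hoppe_urn_init(replace(cfg, seed=10_000 + i))
            ks.append(len(distinct_alleles(state)))
        ks = np.array(ks, dtype=float)
        expect = expected_initial_alleles(theta, N)
        se = ks.std(ddof=1) / np.sqrt(n_reps)
        assert abs(ks.mean() - expect) < 3 * se

    def test_allele_ids_are_dense_from_one(self, default_config):
        state = hoppe_urn_init(default_config)
        alleles = distinct_alleles(state)
        assert min(alleles) == 1
        assert max(alleles) < state.next_allele_id
        assert state.initial_allele_limit == state.next_allele_id


class TestStepKernel:
    def test_monomorphic_grid_is_invariant_apart_from_clocks(self):
        cfg = SimConfig(grid=GridSpec(4, 4), seed=5)
        state = state_from_alleles(cfg, [7] * 16)
        before = state.allele.copy()
        for _ in range(50):
            step(state, 0.0)
        assert np.array_equal(state.allele, before)
        assert state.step_count == 50

    def test_population_size_conserved_on_full_grid(self):
        cfg = SimConfig(grid=GridSpec(6, 6), seed=8)
        state = hoppe_urn_init(cfg)
        run_steps(state, 5000, 0.0)
        assert state.population_size() == 36

    def test_mu_one_always_creates_new_allele(self):
        cfg = SimConfig(grid=GridSpec(3, 3), seed=2)
        state = state_from_alleles(cfg, [1] * 9)
        start_id = state.next_allele_id
        run_steps(state, 10, 1.0)
        assert state.next_allele_id == start_id + 10

    def test_invalid_mu_rejected(self, small_config):
        state = hoppe_urn_init(small_config)
        with pytest.raises(ParameterError):
            step(state, 1.5)

    def test_batch_kernel_matches_single_step_reference(self):
        # the jit batch path and the pure-Python step() must consume the
        # same RNG stream and produce identical states
        cfg = SimConfig(grid=GridSpec(5, 5), seed=31)
        mask = BarrierMask(cfg.grid, {(2, 2)})
        a = hoppe_urn_init(cfg, mask)
        b = hoppe_urn_init(cfg, mask)
        for _ in range(400):
            step(a, 0.05)
        run_steps(b, 400, 0.05)
        assert np.array_equal(a.allele, b.allele)
        assert np.array_equal(a.cell_state, b.cell_state)
        assert a.next_allele_id == b.next_allele_id
        assert a.noop_count == b.noop_count
        assert a.rng.bit_generator.state == b.rng.bit_generator.state

    def test_isolated_individual_survives_as_noop(self):
        # cell (2,2) walled in: its death event has no parent, so it survives
        grid = GridSpec(5, 5)
        mask_cells = {
            (r, c)
            for r in (1, 2, 3)
            for c in (1, 2, 3)
            if (r, c) != (2, 2)
        }
        cfg = SimConfig(grid=grid, seed=17)
        state = hoppe_urn_init(cfg, BarrierMask(grid, mask_cells))
        marked = state.allele_of((2, 2))
        pop = state.population_size()
        run_steps(state, 2000, 0.0)
        assert state.allele_of((2, 2)) == marked
        assert state.population_size() == pop
        assert state.noop_count > 0

    def test_seeded_runs_are_bit_identical(self, small_config):
        a = hoppe_urn_init(small_config)
        b = hoppe_urn_init(small_config)
        run_steps(a, 1000, 0.01)
        run_steps(b, 1000, 0.01)
        assert np.array_equal(a.allele, b.allele)
        assert a.rng.bit_generator.state == b.rng.bit_generator.state

    def test_generation_batches_equal_stepwise_generations(self, small_config):
        a = hoppe_urn_init(small_config)
        b = hoppe_urn_init(small_config)
        for _ in range(3):
            run_generation(a)
        run_steps(b, 3 * small_config.steps_per_generation, small_config.run_mu)
        assert np.array_equal(a.allele, b.allele)
        assert a.generation == 3 and a.step_count == b.step_count

    def test_monotone_allele_loss_without_mutation(self, small_config):
        state = hoppe_urn_init(small_config)
        seen = distinct_alleles(state)
        for _ in range(30):
            run_generation(state, 0.0)
            now = distinct_alleles(state)
            assert now <= seen
            seen = now


class TestOccupiedNeighbors:
    def test_full_grid_interior_has_eight(self, default_config):
        state = hoppe_urn_init(default_config)
        assert len(occupied_neighbors(state, (10, 10))) == 8

    def test_barrier_ring_leaves_none(self):
        grid = GridSpec(5, 5)
        ring = {(r, c) for r in (1, 2, 3) for c in (1, 2, 3) if (r, c) != (2, 2)}
        state = hoppe_urn_init(SimConfig(grid=grid, seed=1), BarrierMask(grid, ring))
        assert occupied_neighbors(state, (2, 2)) == []

    def test_mixed_barriers_on_3x3_center(self):
        # edge-midpoint neighbors barred: only the four corners remain
        grid = GridSpec(3, 3)
        bars = {(0, 1), (1, 0), (1, 2), (2, 1)}
        state = hoppe_urn_init(SimConfig(grid=grid, seed=1), BarrierMask(grid, bars))
        assert occupied_neighbors(state, (1, 1)) == [(0, 0), (0, 2), (2, 0), (2, 2)]


class TestForcedMutation:
    def test_each_cell_gets_its_own_fresh_allele(self, small_config):
        state = hoppe_urn_init(small_config)
        start = state.next_allele_id
        cells = [(0, 0), (1, 1), (2, 2)]
        force_mutation(state, cells)
        new = [state.allele_of(c) for c in cells]
        assert new == [start, start + 1, start + 2]
        assert state.next_allele_id == start + 3
        assert state.population_size() == 64

    def test_empty_list_is_identity(self, small_config):
        state = hoppe_urn_init(small_config)
        before = state.allele.copy()
        force_mutation(state, [])
        assert np.array_equal(state.allele, before)

    def test_monomorphic_grid_becomes_dimorphic(self):
        cfg = SimConfig(grid=GridSpec(4, 4), seed=9)
        state = state_from_alleles(cfg, [1] * 16)
        force_mutation(state, [(2, 2)])
        assert len(distinct_alleles(state)) == 2

    def test_unoccupied_target_is_an_error(self, small_config):
        state = hoppe_urn_init(small_config)
        add_barrier(state, [(0, 0)])
        with pytest.raises(StateError):
            force_mutation(state, [(0, 0)])


class TestBarrierEdits:
    def test_adding_a_barrier_removes_one_individual(self, default_config):
        state = hoppe_urn_init(default_config)
        add_barrier(state, [(5, 5)])
        assert state.population_size() == 1023
        assert state.state_of((5, 5)) == BARRIER

    def test_removal_does_not_resurrect(self, small_config):
        state = hoppe_urn_init(small_config)
        add_barrier(state, [(4, 4)])
        remove_barrier(state, [(4, 4)])
        assert state.state_of((4, 4)) == EMPTY
        assert state.population_size() == 63

    def test_empty_cell_is_refilled_by_drift(self, small_config):
        state = hoppe_urn_init(small_config)
        add_barrier(state, [(4, 4)])
        remove_barrier(state, [(4, 4)])
        run_steps(state, 5000, 0.0)
        assert state.state_of((4, 4)) == OCCUPIED
        assert state.population_size() == 64

    def test_invalid_edits_rejected(self, small_config):
        state = hoppe_urn_init(small_config)
        add_barrier(state, [(0, 0)])
        with pytest.raises(StateError):
            add_barrier(state, [(0, 0)])
        with pytest.raises(StateError):
            remove_barrier(state, [(1, 1)])

    def test_rejoined_halves_fix_on_one_of_the_two_alleles(self):
        # two fixed halves; removing the wall lets one allele take over
        grid = GridSpec(4, 4)
        wall = {(r, 1) for r in range(4)}
        cfg = SimConfig(grid=grid, seed=21)
        layout = [1 if c == 0 else 2 for (r, c) in grid.cells() if (r, c) not in wall]
        state = state_from_alleles(cfg, layout, BarrierMask(grid, wall))
        remove_barrier(state, sorted(wall))
        run_steps(state, 30_000, 0.0)
        occ = state.allele[state.cell_state == OCCUPIED]
        assert len(set(occ.tolist())) == 1
        assert occ[0] in (1, 2)
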