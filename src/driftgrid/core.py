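"""The stochastic engine: Hoppe-urn initialization and the death/birth kernel.

Model
-----
A finite haploid population occupies a 2-D grid, one individual per cell,
single locus, infinite-alleles mutation (every mutation is an allele never
seen before; no back-mutation).  Dynamics are a spatially explicit Moran
process in its death-birth (voter-model) form: at each event one cell is
chosen uniformly among non-barrier cells; if it holds an individual that
individual dies, leaving the cell momentarily empty; a parent is then chosen
uniformly among the *occupied* Moore neighbors of the cell, and the newborn
carries the parent's allele with probability 1-mu or a brand-new allele with
probability mu.  If the cell has no occupied neighbor the event is a no-op
(an occupied target survives; an empty target stays empty), so population
size changes only through barrier edits, never through drift itself.  A
"generation" is a fixed batch of such events (2000 by default).

The initial population is drawn from Hoppe's urn: individual 1 carries a new
allele; individual i+1 carries a new allele with probability theta/(theta+i)
and otherwise copies a uniformly chosen earlier individual, where
theta = 2*N*mu_init.  This produces Ewens-distributed initial allele
configurations.  Urn outputs are placed on open cells in row-major order.

Reproducibility
---------------
All randomness comes from one ``numpy.random.Generator`` (PCG64) seeded from
``SimConfig.seed``.  Each death/birth event consumes exactly three uniforms,
in the order target -> parent-index -> mutation; the parent and mutation
draws are discarded on no-op events.  This fixed discipline makes the batch
(jit-compiled) path and the single-event reference path stream-identical,
and makes seeded trajectories bit-reproducible.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence

import numpy as np

from .grid import BarrierMask, Coord, GridSpec, moore_neighbors

try:  # jit-compiled batch kernel; the pure-Python path below is semantically identical
    from numba import njit

    _HAVE_NUMBA = True
except ImportError:  # pragma: no cover
    _HAVE_NUMBA = False

    def njit(*args, **kwargs):
        def deco(f):
            return f

        return deco if not (args and callable(args[0])) else args[0]


# cell states (values shared with the jit kernel)
EMPTY = 0
OCCUPIED = 1
BARRIER = 2

DEFAULT_STEPS_PER_GENERATION = 2000
DEFAULT_INIT_MU = 0.001
DEFAULT_RUN_MU = 0.0
DEFAULT_MAX_GENERATIONS = 100_000
GENERATOR_NAME = "PCG64"


class ParameterError(ValueError):
    """Out-of-range simulation parameter."""


class StateError(ValueError):
    """Operation applied to a cell in an incompatible state."""


@dataclass(frozen=True)
class SimConfig:
    """Run parameters.

    Parameters
    ----------
    grid
        Lattice dimensions; default 32 x 32 (1,024 cells).
    init_mu
        Mutation probability used only to set the urn's theta = 2*N*init_mu
        at initialization; default 0.001, giving theta = 2.048 on the full
        default grid and a visually diverse starting population.
    run_mu
        Per-birth mutation probability during the run; default 0 (pure
        drift).
    steps_per_generation
        Death/birth events per generation snapshot; default 2000.
    seed
        Seed for the PCG64 generator.
    max_generations
        Cap on generation loops that run "until fixation"; hitting it is
        reported, not an error.
    """

    grid: GridSpec = field(default_factory=GridSpec)
    init_mu: float = DEFAULT_INIT_MU
    run_mu: float = DEFAULT_RUN_MU
    steps_per_generation: int = DEFAULT_STEPS_PER_GENERATION
    seed: int = 0
    max_generations: int = DEFAULT_MAX_GENERATIONS

    def __post_init__(self) -> None:
        _check_mu(self.init_mu, "init_mu")
        _check_mu(self.run_mu, "run_mu")
        if self.steps_per_generation < 1:
            raise ParameterError("steps_per_generation must be >= 1")
        if self.max_generations < 1:
            raise ParameterError("max_generations must be >= 1")


def _check_mu(mu: float, name: str = "mu") -> None:
    if not (0.0 <= mu <= 1.0):
        raise ParameterError(f"{name} must lie in [0, 1], got {mu}")


@dataclass(frozen=True)
class InitParams:
    """Urn parameters actually used at initialization.

    ``N`` is the number of open (non-barrier) cells at init and
    ``theta = 2 * N * init_mu`` by construction.
    """

    N: int
    theta: float

    @classmethod
    def from_config(cls, config: SimConfig, n_open: int) -> "InitParams":
        return cls(N=n_open, theta=2.0 * n_open * config.init_mu)


def _neighbor_table(grid: GridSpec) -> tuple[np.ndarray, np.ndarray]:
    """Flat-index Moore neighbor table: (n_cells, 8) indices + counts."""
    n = grid.n_cells
    idx = np.zeros((n, 8), dtype=np.int64)
    cnt = np.zeros(n, dtype=np.int64)
    for cell in grid.cells():
        nbrs = moore_neighbors(grid, cell)
        f = grid.flat(cell)
        cnt[f] = len(nbrs)
        for j, nb in enumerate(nbrs):
            idx[f, j] = grid.flat(nb)
    return idx, cnt


_NEIGHBOR_CACHE: dict[tuple[int, int], tuple[np.ndarray, np.ndarray]] = {}


def neighbor_table(grid: GridSpec) -> tuple[np.ndarray, np.ndarray]:
    key = (grid.rows, grid.cols)
    if key not in _NEIGHBOR_CACHE:
        _NEIGHBOR_CACHE[key] = _neighbor_table(grid)
    return _NEIGHBOR_CACHE[key]


@dataclass
class PopulationState:
    """Full mutable state of a running simulation.

    ``cell_state`` is a flat length rows*cols int8 array over
    {EMPTY, OCCUPIED, BARRIER}; ``allele`` holds the allele id of occupied
    cells (meaningless elsewhere).  Allele ids are positive, globally unique
    and never reused: every id ever assigned is < ``next_allele_id``.  Ids
    below ``initial_allele_limit`` were created by the urn ("initial"
    alleles); ids at or above it arose by mutation ("mutant" alleles) — the
    distinction drives the basic/neon palette split downstream.
    """

    config: SimConfig
    cell_state: np.ndarray
    allele: np.ndarray
    next_allele_id: int
    rng: np.random.Generator
    generation: int = 0
    step_count: int = 0
    initial_allele_limit: int = 1
    noop_count: int = 0
    _open_cells: np.ndarray | None = None  # cache, invalidated by barrier edits

    @property
    def grid(self) -> GridSpec:
        return self.config.grid

    def is_occupied(self, cell: Coord) -> bool:
        return self.cell_state[self.grid.flat(cell)] == OCCUPIED

    def state_of(self, cell: Coord) -> int:
        self.grid.require(cell)
        return int(self.cell_state[self.grid.flat(cell)])

    def allele_of(self, cell: Coord) -> int:
        f = self.grid.flat(cell)
        if self.cell_state[f] != OCCUPIED:
            raise StateError(f"cell {cell} holds no individual")
        return int(self.allele[f])

    def population_size(self) -> int:
        return int(np.count_nonzero(self.cell_state == OCCUPIED))

    def open_cells(self) -> np.ndarray:
        """Flat indices of non-barrier cells (death/birth target domain)."""
        if self._open_cells is None:
            self._open_cells = np.flatnonzero(self.cell_state != BARRIER)
        return self._open_cells

    def barrier_mask(self) -> BarrierMask:
        cells = {self.grid.coord(int(f)) for f in np.flatnonzero(self.cell_state == BARRIER)}
        return BarrierMask(self.grid, cells)

    def allele_grid(self) -> np.ndarray:
        """rows x cols allele ids, 0 where not occupied."""
        out = np.where(self.cell_state == OCCUPIED, self.allele, 0)
        return out.reshape(self.grid.rows, self.grid.cols)

    def copy(self) -> "PopulationState":
        return PopulationState(
            config=self.config,
            cell_state=self.cell_state.copy(),
            allele=self.allele.copy(),
            next_allele_id=self.next_allele_id,
            rng=_copy_rng(self.rng),
            generation=self.generation,
            step_count=self.step_count,
            initial_allele_limit=self.initial_allele_limit,
            noop_count=self.noop_count,
            _open_cells=None if self._open_cells is None else self._open_cells.copy(),
        )

    def snapshot(self) -> dict:
        """JSON-ready snapshot {rows, cols, cells:[{row,col,state,allele}]}."""
        names = {EMPTY: "empty", OCCUPIED: "occupied", BARRIER: "barrier"}
        cells = []
        for cell in self.grid.cells():
            f = self.grid.flat(cell)
            st = int(self.cell_state[f])
            entry = {"row": cell[0], "col": cell[1], "state": names[st]}
            if st == OCCUPIED:
                entry["allele"] = int(self.allele[f])
            cells.append(entry)
        return {"rows": self.grid.rows, "cols": self.grid.cols, "cells": cells}


def _copy_rng(rng: np.random.Generator) -> np.random.Generator:
    bg = type(rng.bit_generator)()
    bg.state = rng.bit_generator.state
    return np.random.Generator(bg)


# ---------------------------------------------------------------------------
# initialization
# ---------------------------------------------------------------------------

def hoppe_urn_init(config: SimConfig, mask: BarrierMask | None = None) -> PopulationState:
    """Create the initial population by sequential draws from Hoppe's urn.

    One individual per open (non-barrier) cell, assigned in row-major order.
    Individual 1 always receives a new allele; individual i+1 receives a new
    allele with probability theta/(theta+i), else copies a uniformly chosen
    earlier individual, with theta = 2*N*init_mu and N the number of open
    cells.  Allele ids start at 1.
    """
    grid = config.grid
    if mask is not None and mask.grid != grid:
        raise StateError("barrier mask grid does not match config grid")
    rng = np.random.default_rng(config.seed)

    cell_state = np.full(grid.n_cells, OCCUPIED, dtype=np.int8)
    if mask is not None:
        for cell in mask.barrier_cells:
            cell_state[grid.flat(cell)] = BARRIER
    open_flat = np.flatnonzero(cell_state != BARRIER)
    n = len(open_flat)
    if n == 0:
        raise StateError("every cell is a barrier; cannot initialize a population")

    params = InitParams.from_config(config, n)
    theta = params.theta

    urn = np.zeros(n, dtype=np.int64)
    urn[0] = 1
    next_id = 2
    for i in range(1, n):
        if rng.random() < theta / (theta + i):
            urn[i] = next_id
            next_id += 1
        else:
            j = min(int(rng.random() * i), i - 1)
            urn[i] = urn[j]

    allele = np.zeros(grid.n_cells, dtype=np.int64)
    allele[open_flat] = urn
    return PopulationState(
        config=config,
        cell_state=cell_state,
        allele=allele,
        next_allele_id=next_id,
        rng=rng,
        generation=0,
        step_count=0,
        initial_allele_limit=next_id,
    )


def state_from_alleles(
    config: SimConfig, alleles: Sequence[int], mask: BarrierMask | None = None
) -> PopulationState:
    """Build a fully occupied state with an explicit allele layout.

    *alleles* lists the allele id of each open (non-barrier) cell in
    row-major order — handy for controlled experiments and for checking the
    engine against exact solutions on tiny grids.
    """
    grid = config.grid
    cell_state = np.full(grid.n_cells, OCCUPIED, dtype=np.int8)
    if mask is not None:
        for cell in mask.barrier_cells:
            cell_state[grid.flat(cell)] = BARRIER
    open_flat = np.flatnonzero(cell_state != BARRIER)
    if len(alleles) != len(open_flat):
        raise StateError(
            f"{len(alleles)} alleles given for {len(open_flat)} open cells"
        )
    if any(a < 1 for a in alleles):
        raise StateError("allele ids must be positive")
    allele = np.zeros(grid.n_cells, dtype=np.int64)
    allele[open_flat] = np.asarray(alleles, dtype=np.int64)
    next_id = int(max(alleles)) + 1
    return PopulationState(
        config=config,
        cell_state=cell_state,
        allele=allele,
        next_allele_id=next_id,
        rng=np.random.default_rng(config.seed),
        initial_allele_limit=next_id,
    )


def expected_initial_alleles(theta: float, n: int) -> float:
    """Closed-form mean number of distinct alleles from the urn:
    E[K] = sum_{i=0}^{n-1} theta/(theta+i) (with E[K]=1 at theta=0)."""
    if theta == 0.0:
        return 1.0 if n >= 1 else 0.0
    i = np.arange(n, dtype=float)
    return float(np.sum(theta / (theta + i)))


# ---------------------------------------------------------------------------
# the death/birth kernel
# ---------------------------------------------------------------------------

@njit(cache=True)
def _batch_steps(cell_state, allele, nbr_idx, nbr_cnt, open_cells, u, next_id, mu):
    """Apply ``u.shape[0]`` death/birth events in place; returns
    (next_allele_id, n_noops).  ``u`` holds the pre-drawn uniforms, one
    (target, parent, mutation) triple per event."""
    noops = 0
    n_open = open_cells.shape[0]
    occ = np.empty(8, dtype=np.int64)
    for t in range(u.shape[0]):
        k_t = int(u[t, 0] * n_open)
        if k_t >= n_open:
            k_t = n_open - 1
        target = open_cells[k_t]
        k = 0
        for j in range(nbr_cnt[target]):
            nb = nbr_idx[target, j]
            if cell_state[nb] == OCCUPIED:
                occ[k] = nb
                k += 1
        if k == 0:
            noops += 1
            continue
        k_p = int(u[t, 1] * k)
        if k_p >= k:
            k_p = k - 1
        parent = occ[k_p]
        if u[t, 2] < mu:
            allele[target] = next_id
            next_id += 1
        else:
            allele[target] = allele[parent]
        cell_state[target] = OCCUPIED
    return next_id, noops


def step(state: PopulationState, mu: float | None = None) -> PopulationState:
    """One death/birth event, mutating *state* in place (returned for
    chaining).

    The target is drawn uniformly over non-barrier cells.  An occupied
    target's individual dies (and can never be its own parent, since the
    parent pool is its Moore neighborhood); the newborn copies a uniformly
    chosen occupied neighbor's allele with probability 1-mu or receives a
    fresh unique allele with probability mu.  With no occupied neighbor the
    event is a no-op: an occupied target survives, an empty one stays empty.
    ``step_count`` always advances.
    """
    if mu is None:
        mu = state.config.run_mu
    _check_mu(mu)
    open_cells = state.open_cells()
    if len(open_cells) == 0:
        raise StateError("no non-barrier cells; nothing can die or be born")
    u = state.rng.random(3)
    nbr_idx, nbr_cnt = neighbor_table(state.grid)

    target = int(open_cells[min(int(u[0] * len(open_cells)), len(open_cells) - 1)])
    occ = [int(nb) for nb in nbr_idx[target, : nbr_cnt[target]] if state.cell_state[nb] == OCCUPIED]
    if not occ:
        state.noop_count += 1
    else:
        parent = occ[min(int(u[1] * len(occ)), len(occ) - 1)]
        if u[2] < mu:
            state.allele[target] = state.next_allele_id
            state.next_allele_id += 1
        else:
            state.allele[target] = state.allele[parent]
        state.cell_state[target] = OCCUPIED
    state.step_count += 1
    return state


def run_steps(state: PopulationState, n_steps: int, mu: float | None = None) -> PopulationState:
    """Apply *n_steps* death/birth events via the batch kernel.

    Stream-identical to calling :func:`step` *n_steps* times: the uniforms
    are pre-drawn as an (n_steps, 3) block from the same generator, which
    yields the same values in the same order.
    """
    if mu is None:
        mu = state.config.run_mu
    _check_mu(mu)
    if n_steps < 0:
        raise ParameterError("n_steps must be >= 0")
    if n_steps == 0:
        return state
    open_cells = state.open_cells()
    if len(open_cells) == 0:
        raise StateError("no non-barrier cells; nothing can die or be born")
    nbr_idx, nbr_cnt = neighbor_table(state.grid)
    u = state.rng.random((n_steps, 3))
    state.next_allele_id, noops = _batch_steps(
        state.cell_state, state.allele, nbr_idx, nbr_cnt, open_cells, u, state.next_allele_id, mu
    )
    state.noop_count += int(noops)
    state.step_count += n_steps
    return state


def run_generation(state: PopulationState, mu: float | None = None) -> PopulationState:
    """One generation = ``config.steps_per_generation`` death/birth events;
    advances the generation clock by one."""
    run_steps(state, state.config.steps_per_generation, mu)
    state.generation += 1
    return state


def run_generations(state: PopulationState, n_generations: int, mu: float | None = None) -> PopulationState:
    for _ in range(n_generations):
        run_generation(state, mu)
    return state


# ---------------------------------------------------------------------------
# user edits: forced mutation and barriers
# ---------------------------------------------------------------------------

def force_mutation(state: PopulationState, cells: Sequence[Coord]) -> PopulationState:
    """Give each listed occupied cell its own fresh unique allele.

    k cells receive k new ids, assigned in list order; population size is
    unchanged.  Targeting a barrier or empty cell is an error.
    """
    flats = []
    for cell in cells:
        cell = tuple(cell)
        state.grid.require(cell)
        f = state.grid.flat(cell)
        if state.cell_state[f] != OCCUPIED:
            raise StateError(f"cannot force a mutation on unoccupied cell {cell}")
        flats.append(f)
    for f in flats:
        state.allele[f] = state.next_allele_id
        state.next_allele_id += 1
    return state


def add_barrier(state: PopulationState, cells: Sequence[Coord]) -> PopulationState:
    """Turn cells into barriers; each previously occupied cell loses its
    individual, so population size declines by one per such cell."""
    for cell in cells:
        cell = tuple(cell)
        state.grid.require(cell)
        f = state.grid.flat(cell)
        if state.cell_state[f] == BARRIER:
            raise StateError(f"cell {cell} is already a barrier")
        state.cell_state[f] = BARRIER
    state._open_cells = None
    return state


def remove_barrier(state: PopulationState, cells: Sequence[Coord]) -> PopulationState:
    """Turn barrier cells back into EMPTY cells (not occupied: removal does
    not resurrect anyone).  Empty cells are later filled by ordinary
    death/birth events, because empty targets accept neighbor offspring."""
    for cell in cells:
        cell = tuple(cell)
        state.grid.require(cell)
        f = state.grid.flat(cell)
        if state.cell_state[f] != BARRIER:
            raise StateError(f"cell {cell} is not a barrier")
        state.cell_state[f] = EMPTY
    state._open_cells = None
    return state


# ---------------------------------------------------------------------------
# edit schedules (timed events)
# ---------------------------------------------------------------------------

_EVENT_ACTIONS = {
    "add_barrier": add_barrier,
    "remove_barrier": remove_barrier,
    "force_mutation": force_mutation,
}


@dataclass(frozen=True)
class Event:
    """A scheduled edit, applied at the *start* of ``generation`` (before any
    of that generation's death/birth events)."""

    generation: int
    action: str
    cells: tuple[Coord, ...]

    def __post_init__(self) -> None:
        if self.action not in _EVENT_ACTIONS:
            raise ParameterError(
                f"unknown action {self.action!r}; expected one of {sorted(_EVENT_ACTIONS)}"
            )

    def apply(self, state: PopulationState) -> None:
        _EVENT_ACTIONS[self.action](state, list(self.cells))

    def to_dict(self) -> dict:
        return {
            "generation": self.generation,
            "action": self.action,
            "cells": [list(c) for c in self.cells],
        }

    @classmethod
    def from_dict(cls, d: dict) -> "Event":
        return cls(
            generation=int(d["generation"]),
            action=str(d["action"]),
            cells=tuple(tuple(int(x) for x in c) for c in d["cells"]),
        )


def load_events(path) -> list[Event]:
    with open(path) as fh:
        data = json.load(fh)
    return [Event.from_dict(d) for d in data]


def dump_events(events: Iterable[Event], path) -> None:
    with open(path, "w") as fh:
        json.dump([e.to_dict() for e in events], fh, indent=1)


def apply_due_events(state: PopulationState, events: Sequence[Event]) -> list[Event]:
    """Apply every event scheduled for the state's current generation, in
    list order; returns the events applied."""
    due = [e for e in events if e.generation == state.generation]
    for e in due:
        e.apply(state)
    return due
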