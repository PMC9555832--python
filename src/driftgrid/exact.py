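"""Exact fixation probabilities and absorption times on tiny grids.

For a fully occupied, barrier-free grid with mu=0 the death/birth dynamics
form a finite absorbing Markov chain whose absorbing states are the
monomorphic configurations.  This module builds the one-event transition
matrix by direct enumeration over all allele assignments (A^n states for n
cells and A alleles) — deliberately independent of the simulation kernel —
and solves the standard absorbing-chain equations: with Q the
transient-to-transient block and R the transient-to-absorbing block,

    B = (I - Q)^{-1} R        absorption probabilities,
    t = (I - Q)^{-1} 1        expected events to absorption.

Only practical for a handful of cells (the 4-cell and 3-cell classroom
check grids); the point is an oracle the stochastic engine can be tested
against, plus exact verification of the degree-weighted martingale: under
neutral drift P(allele a fixes) equals a's Moore-degree-weighted frequency.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import product

import numpy as np

from .grid import GridSpec, moore_neighbors


@dataclass(frozen=True)
class ExactFixation:
    """Solution of the absorbing chain for one initial configuration.

    ``fixation_probability`` maps each allele in the initial configuration
    to its probability of ultimately fixing; ``expected_events`` is the mean
    number of death/birth events until absorption (divide by
    steps-per-generation for generations).
    """

    initial: tuple[int, ...]
    fixation_probability: dict[int, float]
    expected_events: float


def _neighbor_lists(grid: GridSpec) -> list[list[int]]:
    return [
        [grid.flat(nb) for nb in moore_neighbors(grid, cell)] for cell in grid.cells()
    ]


def transition_matrix(grid: GridSpec, alleles: tuple[int, ...]) -> tuple[np.ndarray, list[tuple[int, ...]]]:
    """Dense one-event transition matrix over all assignments of *alleles*
    to the grid's cells (row-major cell order).

    One event: target cell uniform over all n cells; new allele at the
    target copies a uniformly chosen Moore neighbor.  States are returned in
    lexicographic order of the allele tuples.
    """
    n = grid.n_cells
    allele_set = sorted(set(alleles))
    states = list(product(allele_set, repeat=n))
    index = {s: i for i, s in enumerate(states)}
    nbrs = _neighbor_lists(grid)
    P = np.zeros((len(states), len(states)))
    for s in states:
        i = index[s]
        for target in range(n):
            deg = len(nbrs[target])
            for p in nbrs[target]:
                s2 = list(s)
                s2[target] = s[p]
                P[i, index[tuple(s2)]] += 1.0 / (n * deg)
    return P, states


def solve_fixation(grid: GridSpec, initial: tuple[int, ...]) -> ExactFixation:
    """Exact fixation probabilities and mean absorption time from *initial*.

    *initial* lists the allele of each cell in row-major order; with mu=0 no
    new allele can appear, so the chain is closed over these alleles.
    """
    if len(initial) != grid.n_cells:
        raise ValueError(
            f"initial configuration has {len(initial)} entries for a {grid.n_cells}-cell grid"
        )
    P, states = transition_matrix(grid, initial)
    allele_set = sorted(set(initial))
    absorbing = [i for i, s in enumerate(states) if len(set(s)) == 1]
    transient = [i for i, s in enumerate(states) if len(set(s)) > 1]
    start = states.index(tuple(initial))

    if start in absorbing:
        return ExactFixation(tuple(initial), {initial[0]: 1.0}, 0.0)

    Q = P[np.ix_(transient, transient)]
    R = P[np.ix_(transient, absorbing)]
    t_index = {i: k for k, i in enumerate(transient)}
    N = np.linalg.inv(np.eye(len(transient)) - Q)
    B = N @ R
    t = N @ np.ones(len(transient))

    row = t_index[start]
    probs = {a: 0.0 for a in allele_set}
    for k, i in enumerate(absorbing):
        probs[states[i][0]] += float(B[row, k])
    return ExactFixation(tuple(initial), probs, float(t[row]))


def degree_weighted_frequency(grid: GridSpec, initial: tuple[int, ...]) -> dict[int, float]:
    """Moore-degree-weighted frequency of each allele: under neutral drift
    this equals the allele's exact fixation probability (the conserved
    martingale of the death-birth voter model)."""
    degs = [len(moore_neighbors(grid, cell)) for cell in grid.cells()]
    total = float(sum(degs))
    out: dict[int, float] = {}
    for a, d in zip(initial, degs):
        out[a] = out.get(a, 0.0) + d / total
    return out
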