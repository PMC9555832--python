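"""Trajectory recording, allele spectra, and fixation detection/studies.

Fixation is evaluated on generation snapshots, not per step — observers see
the grid redrawn once per generation, so a component that becomes
monomorphic mid-generation is reported fixed at the next snapshot.  With
mu > 0 permanent fixation is not guaranteed; the stop rule is then
"first monomorphic snapshot", an approximation since a new mutant can arise
immediately after.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .core import (
    OCCUPIED,
    BARRIER,
    PopulationState,
    SimConfig,
    hoppe_urn_init,
    run_generation,
)
from .grid import BarrierMask, ComponentLabeling, connected_components


class ConsistencyError(ValueError):
    """Component labeling does not match the state's barrier layout."""


def _check_labeling(state: PopulationState, components: ComponentLabeling) -> None:
    lab_barrier = components.labels.ravel() < 0
    state_barrier = state.cell_state == BARRIER
    if not np.array_equal(lab_barrier, state_barrier):
        raise ConsistencyError(
            "component labeling is stale: its barrier cells differ from the state's"
        )


def allele_spectrum(
    state: PopulationState, components: ComponentLabeling
) -> dict[int, dict[int, int]]:
    """Exact allele -> count map per component.

    The number of distinct alleles in a component is the size of its map.
    Empty cells contribute nothing; a fully empty component maps to {}.
    """
    _check_labeling(state, components)
    labels = components.labels.ravel()
    occ = state.cell_state == OCCUPIED
    out: dict[int, dict[int, int]] = {cid: {} for cid in range(components.n_components)}
    for cid in out:
        sel = occ & (labels == cid)
        alleles, counts = np.unique(state.allele[sel], return_counts=True)
        out[cid] = {int(a): int(n) for a, n in zip(alleles, counts)}
    return out


def is_fixed(state: PopulationState, components: ComponentLabeling, component_id: int) -> bool:
    """True iff every occupied cell of the component carries one allele."""
    _check_labeling(state, components)
    sel = (components.labels.ravel() == component_id) & (state.cell_state == OCCUPIED)
    a = state.allele[sel]
    if a.size == 0:
        raise ConsistencyError(f"component {component_id} has no occupied cell; fixation undefined")
    return bool((a == a[0]).all())


def global_fixed(state: PopulationState) -> bool:
    """True iff the pooled population (all components) is monomorphic."""
    a = state.allele[state.cell_state == OCCUPIED]
    return a.size > 0 and bool((a == a[0]).all())


@dataclass
class AlleleTrajectory:
    """Long-format per-generation allele counts and frequencies.

    One record per (generation, component, allele); within each
    (generation, component) group the counts sum to the component's occupied
    cells and the frequencies sum to 1.  Component id -1 is not stored;
    pooled global frequencies are derived on demand by :meth:`pooled`.
    """

    records: list[tuple[int, int, int, int, float]] = field(default_factory=list)

    def record(self, state: PopulationState, components: ComponentLabeling) -> None:
        spectrum = allele_spectrum(state, components)
        gen = state.generation
        for cid in sorted(spectrum):
            counts = spectrum[cid]
            total = sum(counts.values())
            for allele_id in sorted(counts):
                n = counts[allele_id]
                self.records.append((gen, cid, allele_id, n, n / total))

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.records,
            columns=["generation", "component_id", "allele_id", "count", "frequency"],
        )

    def pooled(self) -> pd.DataFrame:
        """Global allele frequencies per generation (all components pooled),
        matching the whole-population frequency graph."""
        df = self.to_frame()
        if df.empty:
            return pd.DataFrame(columns=["generation", "allele_id", "count", "frequency"])
        g = df.groupby(["generation", "allele_id"], as_index=False)["count"].sum()
        totals = g.groupby("generation")["count"].transform("sum")
        g["frequency"] = g["count"] / totals
        return g

    def distinct_allele_counts(self) -> pd.Series:
        """Number of distinct alleles in the pooled population per generation."""
        df = self.to_frame()
        if df.empty:
            return pd.Series(dtype=int)
        return df.groupby("generation")["allele_id"].nunique()

    def __eq__(self, other) -> bool:
        return isinstance(other, AlleleTrajectory) and self.records == other.records


@dataclass(frozen=True)
class ComponentFixation:
    fixed: bool
    fixed_allele_id: int | None
    generations_to_fixation: int | None


@dataclass
class FixationReport:
    """Per-component fixation outcome of a run.

    ``generations_to_fixation`` is the first generation snapshot at which the
    component was monomorphic.  ``cap_hit`` flags a run stopped by
    ``max_generations`` before every component fixed.
    """

    components: dict[int, ComponentFixation]
    global_fixed: bool
    cap_hit: bool = False

    @property
    def all_fixed(self) -> bool:
        return all(c.fixed for c in self.components.values())

    @property
    def final_generation(self) -> int | None:
        gens = [c.generations_to_fixation for c in self.components.values()]
        if any(g is None for g in gens):
            return None
        return max(gens) if gens else None

    def to_dict(self) -> dict:
        return {
            "components": {
                str(cid): {
                    "fixed": c.fixed,
                    "fixed_allele_id": c.fixed_allele_id,
                    "generations_to_fixation": c.generations_to_fixation,
                }
                for cid, c in sorted(self.components.items())
            },
            "global_fixed": self.global_fixed,
            "cap_hit": self.cap_hit,
        }


def _fixation_snapshot(state, components) -> dict[int, ComponentFixation]:
    out = {}
    for cid in range(components.n_components):
        sel = (components.labels.ravel() == cid) & (state.cell_state == OCCUPIED)
        a = state.allele[sel]
        if a.size and (a == a[0]).all():
            out[cid] = ComponentFixation(True, int(a[0]), state.generation)
        else:
            out[cid] = ComponentFixation(False, None, None)
    return out


def run_until_fixation(
    config: SimConfig,
    mask: BarrierMask | None = None,
    mu: float | None = None,
    *,
    state: PopulationState | None = None,
    components: ComponentLabeling | None = None,
    record: bool = True,
    record_initial: bool = True,
    trajectory: AlleleTrajectory | None = None,
) -> tuple[FixationReport, AlleleTrajectory]:
    """Run generations until every component is fixed (or the cap is hit).

    Starts from a fresh Hoppe-urn population unless *state* is given (the
    latter lets callers continue a paused run, e.g. after opening a
    corridor).  mu defaults to ``config.run_mu``; with mu > 0 "fixed" means
    first monomorphic snapshot.  Records one trajectory snapshot per
    generation (including generation 0 of a fresh run) unless
    ``record=False``.
    """
    if state is None:
        state = hoppe_urn_init(config, mask)
    if components is None:
        components = connected_components(config.grid, state.barrier_mask())
    traj = trajectory if trajectory is not None else AlleleTrajectory()

    fixed_at: dict[int, ComponentFixation] = {}
    if record and record_initial:
        traj.record(state, components)

    def note_fixations() -> bool:
        snap = _fixation_snapshot(state, components)
        done = True
        for cid, cf in snap.items():
            if cf.fixed and (cid not in fixed_at or not fixed_at[cid].fixed):
                fixed_at[cid] = cf
            elif cid not in fixed_at:
                fixed_at[cid] = cf
            if not fixed_at[cid].fixed:
                done = False
        return done

    cap_hit = False
    done = note_fixations()
    while not done:
        if state.generation >= config.max_generations:
            cap_hit = True
            break
        run_generation(state, mu)
        if record:
            traj.record(state, components)
        done = note_fixations()

    report = FixationReport(fixed_at, global_fixed(state), cap_hit)
    return report, traj


def replicate_fixation_times(
    config: SimConfig,
    mask: BarrierMask | None = None,
    mu: float | None = None,
    n_reps: int = 1,
    base_seed: int = 0,
) -> list[int | None]:
    """Global fixation generation of *n_reps* independent seeded runs.

    Replicate i runs with seed ``base_seed + i``, so a single replicate
    reproduces :func:`run_until_fixation` at ``seed=base_seed``.  A replicate
    that hits the generation cap contributes ``None``.
    """
    if n_reps < 1:
        raise ValueError("n_reps must be >= 1")
    times: list[int | None] = []
    for i in range(n_reps):
        cfg = replace(config, seed=base_seed + i)
        report, _ = run_until_fixation(cfg, mask, mu, record=False)
        times.append(None if report.cap_hit else report.final_generation)
    return times


def summarize_times(times: list[int | None]) -> dict:
    """Mean / median / IQR of fixation times, ignoring capped replicates."""
    arr = np.array([t for t in times if t is not None], dtype=float)
    if arr.size == 0:
        return {"n": 0, "mean": None, "median": None, "iqr": None, "capped": len(times)}
    q1, q3 = np.percentile(arr, [25, 75])
    return {
        "n": int(arr.size),
        "mean": float(arr.mean()),
        "median": float(np.median(arr)),
        "iqr": float(q3 - q1),
        "capped": len(times) - int(arr.size),
    }


def consensus_monte_carlo(
    config: SimConfig,
    alleles: list[int],
    n_reps: int,
    base_seed: int = 0,
) -> tuple[dict[int, float], float]:
    """Run the engine to consensus *n_reps* times from a fixed allele layout.

    Returns the empirical fixation frequency of each allele and the mean
    number of death/birth events to consensus.  Checks run per event, so the
    event count is exact — meant for tiny grids where it can be compared
    with the absorbing-chain solution.
    """
    from .core import run_steps, state_from_alleles

    wins: dict[int, int] = {int(a): 0 for a in alleles}
    total_events = 0
    for i in range(n_reps):
        cfg = replace(config, seed=base_seed + i)
        state = state_from_alleles(cfg, alleles)
        while not global_fixed(state):
            run_steps(state, 1, 0.0)
        wins[int(state.allele[state.cell_state == OCCUPIED][0])] += 1
        total_events += state.step_count
    return (
        {a: w / n_reps for a, w in wins.items()},
        total_events / n_reps,
    )


def run_until_allele_resolved(
    state: PopulationState,
    allele_id: int,
    mu: float = 0.0,
    check_every: int | None = None,
    max_steps: int = 200_000_000,
) -> bool:
    """Drift until *allele_id* either fixes (True) or is lost (False).

    Used for fixation-probability studies: under neutral drift with mu=0 an
    allele's degree-weighted frequency is a martingale, so its fixation
    probability equals that frequency at time 0.  Checks are batched every
    *check_every* steps (default: the number of open cells).
    """
    from .core import run_steps  # local import to avoid cycle at module load

    if check_every is None:
        check_every = max(1, len(state.open_cells()))
    steps = 0
    while steps < max_steps:
        occ = state.cell_state == OCCUPIED
        k = int(np.count_nonzero(state.allele[occ] == allele_id))
        if k == 0:
            return False
        if k == int(np.count_nonzero(occ)):
            return True
        run_steps(state, check_every, mu)
        steps += check_every
    raise RuntimeError(f"allele {allele_id} unresolved after {max_steps} steps")
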