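"""The four classroom drift activities as scripted, seeded experiments.

Each activity returns a :class:`ScenarioResult` holding, for every
simulation run it performed, the resolved config, initial barrier mask,
timed edit events, the per-generation allele trajectory and fixation
reports.  A result replays bit-identically: :func:`replay` re-executes each
run from nothing but its config + mask + event log + generation count and
produces identical trajectories, because all randomness flows from the
seeded generator and edits/fixation checks consume no random draws.

Geometry defaults (the original classroom instructions gave none): the
barrier cross is a full horizontal line at row 15 and a full vertical line
at column 15 of the 32 x 32 grid, giving four quadrants of roughly equal
size (15x15, 15x16, 16x15, 16x16).  The Activity-2 corridor removes the 3
cells at the vertical barrier's midpoint (rows 14-16 of column 15, which
includes the junction, joining all four quadrants); the Activity-3 corridor
is pre-opened at the midpoint of the vertical barrier's *upper* segment
(rows 7-9), joining only the two upper quadrants so that connected and
isolated subpopulations can be compared.  All of these are parameters.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

from .core import Event, PopulationState, SimConfig, hoppe_urn_init, run_generation
from .grid import (
    BarrierMask,
    ComponentLabeling,
    Coord,
    GridSpec,
    connected_components,
    parse_barrier_mask,
    render_barrier_mask,
)
from .stats import AlleleTrajectory, FixationReport, run_until_fixation


@dataclass
class RunRecord:
    """One simulation run inside a scenario: everything needed to replay it."""

    name: str
    config: SimConfig
    mask_text: str | None
    events: list[Event]
    final_generation: int
    mu: float
    trajectory: AlleleTrajectory
    fixation_by_phase: dict[str, FixationReport] = field(default_factory=dict)


@dataclass
class ScenarioResult:
    scenario_id: str
    seed: int
    runs: list[RunRecord]
    extras: dict = field(default_factory=dict)

    @property
    def event_log(self) -> list[Event]:
        return [e for run in self.runs for e in run.events]


def cross_barrier_mask(
    grid: GridSpec | None = None, barrier_row: int = 15, barrier_col: int = 15
) -> BarrierMask:
    """Full horizontal + full vertical barrier lines (the Activity-2 cross)."""
    grid = grid or GridSpec()
    cells = {(barrier_row, c) for c in range(grid.cols)}
    cells |= {(r, barrier_col) for r in range(grid.rows)}
    return BarrierMask(grid, cells)


def default_corridor(barrier_col: int = 15, center_row: int = 15, length: int = 3) -> list[Coord]:
    """*length* contiguous vertical-barrier cells centered on *center_row*."""
    half = length // 2
    return [(center_row - half + i, barrier_col) for i in range(length)]


def execute_run(
    config: SimConfig,
    mask: BarrierMask | None,
    events: list[Event],
    final_generation: int,
    mu: float | None = None,
) -> tuple[AlleleTrajectory, "PopulationState"]:
    """Deterministic replay engine: urn init, then generations 1..final,
    applying scheduled events (and relabeling components after barrier
    edits) whenever the generation clock matches an event's stamp."""
    state = hoppe_urn_init(config, mask)
    labeling = connected_components(config.grid, state.barrier_mask())
    traj = AlleleTrajectory()
    traj.record(state, labeling)
    while state.generation < final_generation:
        due = [e for e in events if e.generation == state.generation]
        for e in due:
            e.apply(state)
        if any(e.action in ("add_barrier", "remove_barrier") for e in due):
            labeling = connected_components(config.grid, state.barrier_mask())
        run_generation(state, mu)
        traj.record(state, labeling)
    return traj, state


def replay(result: ScenarioResult) -> dict[str, AlleleTrajectory]:
    """Re-execute every run of a scenario from its recorded inputs; the
    returned trajectories are bit-identical to the originals."""
    out = {}
    for run in result.runs:
        mask = parse_barrier_mask(run.mask_text, run.config.grid) if run.mask_text else None
        traj, _ = execute_run(run.config, mask, run.events, run.final_generation, run.mu)
        out[run.name] = traj
    return out


# ---------------------------------------------------------------------------
# Activity 1: unmodified drift to fixation
# ---------------------------------------------------------------------------

def activity1_defaults(seed: int, config: SimConfig | None = None) -> ScenarioResult:
    """Run with default parameters and no barriers until one allele fixes;
    track allele counts, frequencies and generations-to-fixation."""
    config = replace(config or SimConfig(), seed=seed, run_mu=0.0)
    report, traj = run_until_fixation(config, mask=None, mu=0.0)
    run = RunRecord(
        name="main",
        config=config,
        mask_text=None,
        events=[],
        final_generation=report.final_generation
        if report.final_generation is not None
        else config.max_generations,
        mu=0.0,
        trajectory=traj,
        fixation_by_phase={"main": report},
    )
    return ScenarioResult(
        scenario_id="activity1",
        seed=seed,
        runs=[run],
        extras={
            "generations_to_fixation": report.final_generation,
            "cap_hit": report.cap_hit,
        },
    )


# ---------------------------------------------------------------------------
# Activity 2: absolute barriers, then a corridor
# ---------------------------------------------------------------------------

def activity2_absolute_barriers(
    seed: int,
    config: SimConfig | None = None,
    barrier_row: int = 15,
    barrier_col: int = 15,
    corridor: list[Coord] | None = None,
) -> ScenarioResult:
    """Cross barriers isolate four quadrants; run each to fixation, then
    open a corridor through the vertical barrier and run the joined system
    to fixation."""
    config = replace(config or SimConfig(), seed=seed, run_mu=0.0)
    mask = cross_barrier_mask(config.grid, barrier_row, barrier_col)
    if corridor is None:
        corridor = default_corridor(barrier_col, center_row=barrier_row)
    mask_text = render_barrier_mask(mask)

    state = hoppe_urn_init(config, mask.copy())
    labeling1 = connected_components(config.grid, state.barrier_mask())
    traj = AlleleTrajectory()
    report1, _ = run_until_fixation(
        config, mu=0.0, state=state, components=labeling1, trajectory=traj
    )
    events: list[Event] = []
    report2 = None
    if not report1.cap_hit:
        corridor_event = Event(
            generation=state.generation, action="remove_barrier", cells=tuple(corridor)
        )
        corridor_event.apply(state)
        events.append(corridor_event)
        labeling2 = connected_components(config.grid, state.barrier_mask())
        report2, _ = run_until_fixation(
            config,
            mu=0.0,
            state=state,
            components=labeling2,
            trajectory=traj,
            record_initial=False,
        )
    fixation = {"phase1": report1}
    if report2 is not None:
        fixation["phase2"] = report2
    run = RunRecord(
        name="main",
        config=config,
        mask_text=mask_text,
        events=events,
        final_generation=state.generation,
        mu=0.0,
        trajectory=traj,
        fixation_by_phase=fixation,
    )
    extras = {
        "phase1_components": labeling1.n_components,
        "phase1_fixation_generations": {
            cid: cf.generations_to_fixation for cid, cf in report1.components.items()
        },
        "phase1_fixed_alleles": {
            cid: cf.fixed_allele_id for cid, cf in report1.components.items()
        },
        "corridor": [list(c) for c in corridor],
    }
    if report2 is not None:
        extras["phase2_fixation_generation"] = report2.final_generation
        extras["phase2_fixed_alleles"] = {
            cid: cf.fixed_allele_id for cid, cf in report2.components.items()
        }
    return ScenarioResult("activity2", seed, [run], extras)


# ---------------------------------------------------------------------------
# Activity 3: partial barriers — corridor open from the start
# ---------------------------------------------------------------------------

def activity3_partial_barriers(
    seed: int,
    config: SimConfig | None = None,
    barrier_row: int = 15,
    barrier_col: int = 15,
    corridor: list[Coord] | None = None,
) -> ScenarioResult:
    """Cross barriers with a pre-opened corridor, so gene flow between the
    corridor-connected quadrants starts at generation 0; runs to fixation
    and reports connected vs isolated components separately."""
    config = replace(config or SimConfig(), seed=seed, run_mu=0.0)
    if corridor is None:
        # midpoint of the vertical barrier's upper segment: joins the two
        # upper quadrants, leaves the lower two isolated
        corridor = default_corridor(barrier_col, center_row=(barrier_row - 1) // 2)
    mask = cross_barrier_mask(config.grid, barrier_row, barrier_col)
    mask.remove(corridor)
    mask_text = render_barrier_mask(mask)

    labeling = connected_components(config.grid, mask)
    corridor_component = labeling.component_of(corridor[0])
    report, traj = run_until_fixation(config, mask=mask.copy(), mu=0.0)
    run = RunRecord(
        name="main",
        config=config,
        mask_text=mask_text,
        events=[],
        final_generation=report.final_generation
        if report.final_generation is not None
        else config.max_generations,
        mu=0.0,
        trajectory=traj,
        fixation_by_phase={"main": report},
    )
    gens = {cid: cf.generations_to_fixation for cid, cf in report.components.items()}
    return ScenarioResult(
        "activity3",
        seed,
        [run],
        extras={
            "n_components": labeling.n_components,
            "corridor": [list(c) for c in corridor],
            "corridor_component": corridor_component,
            "connected_fixation_generations": {corridor_component: gens[corridor_component]},
            "isolated_fixation_generations": {
                cid: g for cid, g in gens.items() if cid != corridor_component
            },
            "component_sizes": labeling.sizes(),
        },
    )


# ---------------------------------------------------------------------------
# Activity 4: mutation-rate sweep
# ---------------------------------------------------------------------------

def activity4_mutation_rates(
    seed: int,
    mu_values: tuple[float, ...] = (0.0, 0.001, 0.01),
    config: SimConfig | None = None,
    n_generations: int = 200,
) -> ScenarioResult:
    """Fixed-length runs at each mutation rate, recording distinct-allele
    trajectories for a like-for-like comparison of mutation-drift balance."""
    base = config or SimConfig()
    runs = []
    final_counts = {}
    for k, mu in enumerate(mu_values):
        cfg = replace(base, seed=seed + k, run_mu=mu)
        traj, _ = execute_run(cfg, None, [], n_generations, mu)
        runs.append(
            RunRecord(
                name=f"mu={mu}",
                config=cfg,
                mask_text=None,
                events=[],
                final_generation=n_generations,
                mu=mu,
                trajectory=traj,
            )
        )
        counts = traj.distinct_allele_counts()
        final_counts[mu] = int(counts.iloc[-1])
    return ScenarioResult(
        "activity4",
        seed,
        runs,
        extras={"mu_values": list(mu_values), "final_allele_counts": final_counts},
    )


SCENARIOS = {
    "activity1": activity1_defaults,
    "activity2": activity2_absolute_barriers,
    "activity3": activity3_partial_barriers,
    "activity4": activity4_mutation_rates,
}
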