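# Methods

## Model and assumptions

driftgrid simulates neutral evolution of a single haploid locus in a finite
population arranged one-individual-per-cell on a rectangular lattice.  The
dynamics are a spatially explicit Moran process in death-birth (voter-model)
form: population size is constant under drift, generations overlap, and
space enters only through the parent pool — the Moore neighborhood of the
dying cell.  There is no selection, no diploidy, no recombination and no
back-mutation; mutation follows the infinite-alleles model, so every
mutation event creates an allele never seen before and allele identity is
the only heritable state.

Edges are hard: the lattice is not a torus, so corner cells have 3
neighbors, edge cells 5, interior cells 8.  This produces a small,
deliberate edge effect.  One consequence is exact and load-bearing for the
tests: the degree-weighted allele frequency
M(a) = Σ_{cells carrying a} d(cell) / Σ_all d(cell)
is a martingale of the neutral dynamics, hence P(a fixes) = M(a) at time 0
(3/420 for a corner allele on 8 x 8, 1/2 for the middle cell of 1 x 3).

A single adjacency — the 8-cell Moore neighborhood — serves both parent
selection and the connectivity that defines subpopulations.  A barrier line
with a purely diagonal gap therefore leaks alleles; this is a documented
consequence of using one adjacency everywhere, not a bug.

## Event kernel

Per death/birth event: (a) target uniform over non-barrier cells (occupied
*and* empty — this one kernel also recolonizes cells left empty by barrier
removal, with no second process); (b) an occupied target's individual dies
and is excluded from the parent pool by construction (it is not its own
neighbor); (c) parent uniform over occupied Moore neighbors; (d) the
newborn mutates with probability μ applied to the birth only; (e) if no
occupied neighbor exists the event is a no-op — an occupied target
survives, an empty target stays empty — counted in `noop_count` for
transparency.  Consequently population size changes only through barrier
edits (−1 per occupied cell turned barrier; +1 when an empty cell is
refilled after barrier removal), never through drift on a full grid.

## Initialization

Hoppe's urn with θ = 2·N·μ_init, where N is the number of open cells *at
initialization* (pre-placed barriers reduce N, and θ with it).  Individual
1 always receives allele 1; individual i+1 innovates with probability
θ/(θ+i), else copies a uniformly chosen predecessor.  Urn outputs are
placed on open cells in row-major order — the spatial arrangement is a
design choice (the partition structure, not placement, is what Ewens theory
constrains) and is deterministic given the seed.  Allele ids are dense from
1; the counter value at the end of initialization (`initial_allele_limit`)
permanently separates "initial" from "mutant" alleles, which is what the
18-basic/6-neon color assignment keys on.

## Randomness and reproducibility

One PCG64 generator per run, seeded from `SimConfig.seed`.  Each event
consumes exactly three uniforms in fixed order — target, parent-index,
mutation — with the last two discarded on no-ops.  Index draws map a
uniform u to `min(int(u*k), k-1)`.  Because the draw discipline is fixed,
the jit-compiled batch kernel (which pre-draws an (n, 3) block) is
stream-identical to the single-event reference implementation; a test
asserts this, including the final generator state.  Barrier edits, forced
mutations and fixation checks consume no randomness, which is what makes
scenario replay from an event log bit-identical.  Replicate studies use
`base_seed + i`; the acceptance script derives widely separated sub-seeds
via `SeedSequence`.

## Statistics

Trajectories are long-format (generation, component, allele, count,
frequency) with frequencies normalized within each component; pooled global
frequencies are derived by aggregation.  Fixation is evaluated on
generation snapshots, so sub-generation fixation rounds up to the next
snapshot; with μ > 0 the stop rule is "first monomorphic snapshot", an
approximation documented as such.  Loops that run "until fixation" are
capped at `max_generations` (default 100,000); hitting the cap is flagged
in the report, not raised.

The exact solver (`driftgrid.exact`) enumerates the full A^n-state chain
directly from lattice geometry — sharing no code with the engine — and
solves B = (I−Q)⁻¹R and t = (I−Q)⁻¹1 densely.  It is feasible only for a
handful of cells and exists as an independent oracle (2 x 2: 256 states;
1 x 3: 27).

## Scenario geometry

The classroom activities specify no coordinates, so the package fixes
configurable defaults: barrier cross at row 15 / column 15 of the 32 x 32
grid (quadrants 15x15, 15x16, 16x15, 16x16 — "roughly equal"); the
Activity-2 corridor removes the 3 vertical-barrier cells centered on the
cross (rows 14–16 of column 15), which includes the junction and joins all
four quadrants; the Activity-3 corridor sits at the midpoint of the
vertical barrier's upper segment (rows 7–9), joining only the upper
quadrants so connected and isolated subpopulations can be contrasted in one
run.  Activity 4 uses fixed-length 200-generation runs at each μ (default
sweep 0, 0.001, 0.01) so allele-count comparisons are like-for-like.

## Problem sizes used in tests

Unit and property tests run on 2x2–12x12 grids with generations scaled to
2N events, sizes at which every property is already informative.  The
acceptance suite uses the sizes its statistics require: 2,000 urn draws at
N = 1024 (3-standard-error band around the closed form E[K] = Σ θ/(θ+i));
10⁵ Monte-Carlo consensus runs on 2x2 and 1x3 against the exact chain (99%
binomial CIs); 5,000 corner-allele runs on 8x8 against 3/420; 500 + 500
replicates for the Kolmogorov–Smirnov comparison (α = 0.01) of Activity-2
phase-1 quadrant fixation times against independent single-quadrant runs.

For that KS comparison the independent 15x15 run must match the quadrant's
*effective* conditions, and two non-obvious calibrations follow from the
model rather than convenience: (1) its urn uses the full-grid
θ = 2·961·0.001, not 2·225·0.001, because the Ewens partition structure is
sampling-consistent — a 225-cell quadrant of a 961-individual urn is
distributed as a 225-draw urn at the *same* θ; (2) its
`steps_per_generation` is 2000·225/961 ≈ 468, because under the cross each
quadrant receives a binomially thinned share of the 2,000 global events per
generation.  The residual discrepancies (rounding 468.26 to 468; binomial
thinning noise) are far below KS resolution at 500 replicates.

## Synthetic data and what passing tests show

The package generates all of its own data; the generator of record is the
Hoppe urn plus the event kernel at the defaults above (1,024 individuals,
μ_init = 0.001, μ_run = 0, 2000 events/generation).  These defaults emulate
the classroom configuration, not any natural population: real populations
have fluctuating size, non-lattice structure, selection and recurrent
mutation.  Passing tests therefore certify that the simulator implements
the stated neutral model exactly (against closed forms and exact chains),
not that the model describes field data.

## Known limitations

- The exact solver scales as A^n states and is unusable beyond ~6 cells.
- With μ > 0, "fixation" reports are snapshot approximations (see above).
- Whether an individual whose neighborhood is entirely barriers should die
  or survive is not derivable from the model description; driftgrid chooses
  survival (no-op) to keep population accounting exact, and counts such
  events.
- Component labels are recomputed after barrier edits; trajectories spanning
  an edit change component ids at the edit boundary (labels are ordered by
  smallest row-major member for reproducibility).
- The 18 basic / 6 neon color names are a fixed arbitrary palette satisfying
  the cardinalities; only the initial/mutant split and cycling order are
  meaningful.
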