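"""Lattice geometry: Moore neighborhoods, barrier masks, connected components.

The simulation lives on a finite rows x cols grid with *hard* (non-periodic)
edges: cells on edges and corners simply have fewer neighbors, which produces
a small edge effect in the drift dynamics.  Adjacency is the Moore
neighborhood (the up-to-8 cells at Chebyshev distance 1, diagonals included)
and the *same* adjacency is used both for parent selection in the death/birth
kernel and for connectivity of barrier-delimited subpopulations.  A
consequence worth knowing about: a purely diagonal gap in a barrier is
passable, because diagonal neighbors are neighbors.

Coordinates are 0-based ``(row, col)``, row-major; text masks are read with
the top row first.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Iterator

import numpy as np
import pandas as pd
from scipy import ndimage

Coord = tuple[int, int]

#: 8-connected structuring element shared by parent selection and components.
_MOORE_STRUCTURE = np.ones((3, 3), dtype=bool)


class GridError(ValueError):
    """Invalid grid geometry or out-of-bounds coordinate."""


class MaskFormatError(ValueError):
    """Malformed barrier-mask text."""


@dataclass(frozen=True)
class GridSpec:
    """Dimensions of the simulation lattice.

    The classroom default is a 32 x 32 grid holding 1,024 individuals.
    """

    rows: int = 32
    cols: int = 32

    def __post_init__(self) -> None:
        if self.rows < 1 or self.cols < 1:
            raise GridError(f"grid dimensions must be >= 1, got {self.rows}x{self.cols}")

    @property
    def n_cells(self) -> int:
        return self.rows * self.cols

    def contains(self, cell: Coord) -> bool:
        r, c = cell
        return 0 <= r < self.rows and 0 <= c < self.cols

    def require(self, cell: Coord) -> None:
        if not self.contains(cell):
            raise GridError(f"cell {cell} outside {self.rows}x{self.cols} grid")

    def flat(self, cell: Coord) -> int:
        """Row-major flat index of a cell."""
        return cell[0] * self.cols + cell[1]

    def coord(self, flat: int) -> Coord:
        return divmod(flat, self.cols)

    def cells(self) -> Iterator[Coord]:
        """All cells in row-major order."""
        for r in range(self.rows):
            for c in range(self.cols):
                yield (r, c)


def moore_neighbors(grid: GridSpec, cell: Coord) -> list[Coord]:
    """In-bounds Moore neighbors of *cell*, center excluded, no wraparound.

    Order is the row-major scan of the 3x3 block around the cell.  Interior
    cells have 8 neighbors, edge cells 5, corner cells 3.
    """
    grid.require(cell)
    r, c = cell
    out = []
    for dr in (-1, 0, 1):
        for dc in (-1, 0, 1):
            if dr == 0 and dc == 0:
                continue
            rr, cc = r + dr, c + dc
            if 0 <= rr < grid.rows and 0 <= cc < grid.cols:
                out.append((rr, cc))
    return out


def occupied_neighbors(state, cell: Coord) -> list[Coord]:
    """Moore neighbors of *cell* currently holding a live individual.

    Barrier cells are never parents and empty cells cannot serve as a parent
    either, so both are excluded.  ``state`` is a
    :class:`driftgrid.core.PopulationState` (any object with a compatible
    ``grid`` and ``is_occupied``).
    """
    return [nb for nb in moore_neighbors(state.grid, cell) if state.is_occupied(nb)]


@dataclass
class BarrierMask:
    """Set of barrier cells on a grid, mutable only through add/remove.

    Barriers are impassable: they are never selected as parents and never
    die.  Every mutation of the mask is appended to :attr:`audit_log` as
    ``("add"|"remove", cell)`` so an editing session can be replayed.
    """

    grid: GridSpec = field(default_factory=GridSpec)
    _cells: set[Coord] = field(default_factory=set)
    audit_log: list[tuple[str, Coord]] = field(default_factory=list)

    def __post_init__(self) -> None:
        for cell in self._cells:
            self.grid.require(cell)

    @property
    def barrier_cells(self) -> frozenset[Coord]:
        return frozenset(self._cells)

    def __contains__(self, cell: Coord) -> bool:
        return cell in self._cells

    def __len__(self) -> int:
        return len(self._cells)

    def add(self, cells: Iterable[Coord]) -> None:
        for cell in cells:
            cell = tuple(cell)
            self.grid.require(cell)
            if cell not in self._cells:
                self._cells.add(cell)
                self.audit_log.append(("add", cell))

    def remove(self, cells: Iterable[Coord]) -> None:
        for cell in cells:
            cell = tuple(cell)
            self.grid.require(cell)
            if cell in self._cells:
                self._cells.discard(cell)
                self.audit_log.append(("remove", cell))

    def copy(self) -> "BarrierMask":
        return BarrierMask(self.grid, set(self._cells), list(self.audit_log))

    def open_array(self) -> np.ndarray:
        """Boolean rows x cols array, True where the cell is NOT a barrier."""
        arr = np.ones((self.grid.rows, self.grid.cols), dtype=bool)
        for r, c in self._cells:
            arr[r, c] = False
        return arr


@dataclass(frozen=True)
class ComponentLabeling:
    """Partition of non-barrier cells into Moore-connected components.

    ``labels`` is a rows x cols int array; barrier cells carry -1.  Component
    ids are 0..n_components-1, ordered by the smallest row-major flat index of
    any member, so labelings are reproducible across runs.
    """

    grid: GridSpec
    labels: np.ndarray

    @property
    def n_components(self) -> int:
        return int(self.labels.max()) + 1 if self.labels.size and self.labels.max() >= 0 else 0

    def component_of(self, cell: Coord) -> int:
        self.grid.require(cell)
        lab = int(self.labels[cell])
        if lab < 0:
            raise GridError(f"cell {cell} is a barrier cell; it belongs to no component")
        return lab

    def cells_of(self, component_id: int) -> list[Coord]:
        rs, cs = np.nonzero(self.labels == component_id)
        return list(zip(rs.tolist(), cs.tolist()))

    def sizes(self) -> dict[int, int]:
        ids, counts = np.unique(self.labels[self.labels >= 0], return_counts=True)
        return {int(i): int(n) for i, n in zip(ids, counts)}

    def to_frame(self) -> pd.DataFrame:
        """Long-format table with columns component_id,row,col."""
        rs, cs = np.nonzero(self.labels >= 0)
        return pd.DataFrame(
            {
                "component_id": self.labels[rs, cs].astype(int),
                "row": rs.astype(int),
                "col": cs.astype(int),
            }
        ).sort_values(["component_id", "row", "col"], ignore_index=True)


def connected_components(grid: GridSpec, mask: BarrierMask | None = None) -> ComponentLabeling:
    """Label maximal Moore-connected sets of non-barrier cells.

    Uses the same 8-cell adjacency as parent selection, so two
    subpopulations separated by a barrier line with a diagonal gap are a
    single component.
    """
    if mask is None:
        mask = BarrierMask(grid)
    open_arr = mask.open_array()
    raw, n = ndimage.label(open_arr, structure=_MOORE_STRUCTURE)
    labels = np.full((grid.rows, grid.cols), -1, dtype=np.int64)
    if n:
        # relabel so ids follow the smallest row-major member of each component
        flat = raw.ravel()
        order = []
        seen = set()
        for lab in flat:
            if lab > 0 and lab not in seen:
                seen.add(lab)
                order.append(lab)
        remap = {old: new for new, old in enumerate(order)}
        for old, new in remap.items():
            labels[raw == old] = new
    return ComponentLabeling(grid, labels)


BARRIER_CHAR = "#"
OPEN_CHAR = "."


def parse_barrier_mask(text: str, grid: GridSpec | None = None) -> BarrierMask:
    """Parse a text mask: one line per row, '#'=barrier, '.'=open.

    If *grid* is given the text dimensions must match it; otherwise the grid
    is inferred from the text.  Raises :class:`MaskFormatError` naming the
    offending line for ragged lines, unknown characters, or a dimension
    mismatch.
    """
    lines = text.splitlines()
    if not lines:
        raise MaskFormatError("empty mask text")
    width = len(lines[0])
    cells: set[Coord] = set()
    for i, line in enumerate(lines):
        if len(line) != width:
            raise MaskFormatError(
                f"line {i + 1}: expected {width} characters, got {len(line)}"
            )
        for j, ch in enumerate(line):
            if ch == BARRIER_CHAR:
                cells.add((i, j))
            elif ch != OPEN_CHAR:
                raise MaskFormatError(f"line {i + 1}: unknown character {ch!r}")
    inferred = GridSpec(len(lines), width)
    if grid is not None and (grid.rows, grid.cols) != (inferred.rows, inferred.cols):
        raise MaskFormatError(
            f"mask is {inferred.rows}x{inferred.cols} but grid is {grid.rows}x{grid.cols}"
        )
    return BarrierMask(grid or inferred, cells)


def render_barrier_mask(mask: BarrierMask) -> str:
    """Inverse of :func:`parse_barrier_mask`; ``parse(render(m)) == m``."""
    return "\n".join(
        "".join(
            BARRIER_CHAR if (r, c) in mask else OPEN_CHAR
            for c in range(mask.grid.cols)
        )
        for r in range(mask.grid.rows)
    )


def moore_degree(grid: GridSpec, cell: Coord) -> int:
    """Number of Moore neighbors: 3 (corner), 5 (edge) or 8 (interior)."""
    return len(moore_neighbors(grid, cell))


def degree_array(grid: GridSpec) -> np.ndarray:
    """rows x cols array of Moore degrees (geometry only, ignores barriers)."""
    deg = np.empty((grid.rows, grid.cols), dtype=np.int64)
    for r in range(grid.rows):
        for c in range(grid.cols):
            deg[r, c] = len(moore_neighbors(grid, (r, c)))
    return deg
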