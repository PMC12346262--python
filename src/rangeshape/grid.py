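"""Two-resolution grid data model.

The simulation world is a fine lattice of equal-area cells (the resolution at
which ranges are simulated, a 0.25-degree analogue) nested inside a coarse
analysis lattice (a 1-degree analogue): each coarse cell is an ``agg_factor`` x
``agg_factor`` block of fine cells.  Cells are addressed 0-based, row-major;
the coarse parent of fine cell ``(r, c)`` is ``(r // f, c // f)``.

Cells are plain ``(row, col)`` tuples and occupancy sets are Python sets of
such tuples; richness maps are dense numpy arrays wrapped in
:class:`RichnessMap`.  No geographic projection or cell-area weighting is
applied: cells are treated as equal-area.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

Cell = tuple[int, int]

VON_NEUMANN_OFFSETS = ((-1, 0), (1, 0), (0, -1), (0, 1))
MOORE_OFFSETS = VON_NEUMANN_OFFSETS + ((-1, -1), (-1, 1), (1, -1), (1, 1))


@dataclass(frozen=True)
class GridSpec:
    """Dimensions of the fine grid and the fine-to-coarse aggregation factor.

    ``agg_factor`` is the number of fine cells per coarse-cell side; 4 models
    the 0.25-degree -> 1-degree aggregation.  Dimensions must be divisible by
    the factor so that every coarse cell is a full block.
    """

    n_rows: int
    n_cols: int
    agg_factor: int = 1

    def __post_init__(self) -> None:
        if self.n_rows <= 0 or self.n_cols <= 0:
            raise ValueError("grid dimensions must be positive")
        if self.agg_factor <= 0:
            raise ValueError("agg_factor must be positive")
        if self.n_rows % self.agg_factor or self.n_cols % self.agg_factor:
            raise ValueError(
                f"grid dimensions ({self.n_rows}x{self.n_cols}) must be "
                f"divisible by agg_factor={self.agg_factor}"
            )

    @property
    def shape(self) -> tuple[int, int]:
        return (self.n_rows, self.n_cols)

    @property
    def coarse_shape(self) -> tuple[int, int]:
        return (self.n_rows // self.agg_factor, self.n_cols // self.agg_factor)

    def contains(self, cell: Cell) -> bool:
        r, c = cell
        return 0 <= r < self.n_rows and 0 <= c < self.n_cols

    def coarse_parent(self, cell: Cell) -> Cell:
        return (cell[0] // self.agg_factor, cell[1] // self.agg_factor)


@dataclass
class RichnessMap:
    """Per-cell species counts at fine or coarse resolution.

    ``values`` holds integer counts for single realizations and real numbers
    for ensemble averages; missing cells (e.g. all-ocean coarse blocks) are
    NaN, never zero.
    """

    resolution: str  # "fine" | "coarse"
    values: np.ndarray = field(repr=False)

    def __post_init__(self) -> None:
        if self.resolution not in ("fine", "coarse"):
            raise ValueError(f"unknown resolution {self.resolution!r}")
        self.values = np.asarray(self.values, dtype=float)
        with np.errstate(invalid="ignore"):
            if np.nanmin(self.values, initial=0.0) < 0:
                raise ValueError("richness values must be nonnegative")

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape


def neighbors(cell: Cell, spec: GridSpec, scheme: str = "von_neumann") -> set[Cell]:
    """The 4 (von Neumann) or 8 (Moore) cells adjacent to *cell*.

    Truncated at grid edges; never contains *cell* itself.
    """
    if not spec.contains(cell):
        raise ValueError(f"cell {cell} outside {spec.n_rows}x{spec.n_cols} grid")
    if scheme == "von_neumann":
        offsets = VON_NEUMANN_OFFSETS
    elif scheme == "moore":
        offsets = MOORE_OFFSETS
    else:
        raise ValueError(f"unknown neighborhood scheme {scheme!r}")
    r, c = cell
    out = set()
    for dr, dc in offsets:
        nb = (r + dr, c + dc)
        if spec.contains(nb):
            out.add(nb)
    return out


def _check_in_grid(cells, spec: GridSpec) -> None:
    for cell in cells:
        if not spec.contains(cell):
            raise ValueError(f"cell {cell} outside grid {spec.shape}")


def coarse_presence(cells: set[Cell], spec: GridSpec) -> set[Cell]:
    """Coarse cells containing at least one member fine cell."""
    _check_in_grid(cells, spec)
    f = spec.agg_factor
    return {(r // f, c // f) for r, c in cells}


def fine_richness(ranges: list[set[Cell]], spec: GridSpec) -> RichnessMap:
    """Per-fine-cell count of ranges containing the cell.

    The sum over all cells equals the sum of range sizes (each occupied cell
    contributes exactly once per species).
    """
    counts = np.zeros(spec.shape, dtype=float)
    for rng_cells in ranges:
        _check_in_grid(rng_cells, spec)
        for r, c in rng_cells:
            counts[r, c] += 1
    return RichnessMap("fine", counts)


def coarse_total_richness(ranges: list[set[Cell]], spec: GridSpec) -> RichnessMap:
    """Per-coarse-cell count of species with >= 1 occupied fine cell inside."""
    counts = np.zeros(spec.coarse_shape, dtype=float)
    for rng_cells in ranges:
        for r, c in coarse_presence(rng_cells, spec):
            counts[r, c] += 1
    return RichnessMap("coarse", counts)


def aggregate(
    ranges: list[set[Cell]], spec: GridSpec, land_mask: set[Cell]
) -> tuple[RichnessMap, RichnessMap]:
    """Coarse total and mean richness.

    *total*: per coarse cell, the number of species present in the block
    (presence = any occupied fine cell inside).  *mean*: per coarse cell, the
    mean of the fine richness over the LAND fine cells of the block; coarse
    cells with no land fine cells are NaN (missing), not zero.

    For every coarse cell ``total >= mean`` and ``total >= max`` fine richness
    in the block, since each species contributes at most 1 to the total but at
    most 1 to *each* fine cell.
    """
    if not land_mask:
        raise ValueError("land_mask must be nonempty")
    _check_in_grid(land_mask, spec)
    land = np.zeros(spec.shape, dtype=bool)
    for r, c in land_mask:
        land[r, c] = True
    for rng_cells in ranges:
        for cell in rng_cells:
            if not land[cell]:
                raise ValueError(f"range cell {cell} is not on land")

    fine = fine_richness(ranges, spec).values
    total = coarse_total_richness(ranges, spec).values

    f = spec.agg_factor
    cr, cc = spec.coarse_shape
    blocks = fine.reshape(cr, f, cc, f)
    land_blocks = land.reshape(cr, f, cc, f)
    n_land = land_blocks.sum(axis=(1, 3)).astype(float)
    sums = np.where(land_blocks, blocks, 0.0).sum(axis=(1, 3))
    with np.errstate(invalid="ignore", divide="ignore"):
        mean = np.where(n_land > 0, sums / n_land, np.nan)
    return RichnessMap("coarse", total), RichnessMap("coarse", mean)


def land_cellset(land: np.ndarray) -> set[Cell]:
    """Convert a boolean land raster to a cell set."""
    rows, cols = np.nonzero(np.asarray(land, dtype=bool))
    return {(int(r), int(c)) for r, c in zip(rows, cols)}
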