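"""Range patches: Moore-connected components and tiny-patch grouping.

A range *patch* is a maximal set of occupied cells connected through the Moore
(8-cell) neighborhood.  Many empirical ranges carry tiny satellite patches
that are small protrusions of the main range rather than genuinely vicariant
units; such satellites should not receive independent starting positions in
patchy-range simulations.  The grouping algorithm merges, stepwise, any patch
group smaller than ``ps_min`` times the largest group with its nearest group,
provided their distance is below ``d_min`` (defaults: ps_min = 0.10,
d_min = 5 cell distances).

Inter-patch distance is the minimum Chebyshev distance over cell pairs, the
metric consistent with Moore connectivity (distance 1 <=> Moore-adjacent).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from scipy.spatial.distance import cdist

from .grid import Cell, GridSpec

MOORE_STRUCTURE = np.ones((3, 3), dtype=int)

DEFAULT_PS_MIN = 0.10
DEFAULT_D_MIN = 5.0


@dataclass
class PatchSet:
    """Moore-connected components of a range, largest first."""

    parent_range: frozenset
    patches: list[frozenset]

    @property
    def sizes(self) -> list[int]:
        return [len(p) for p in self.patches]

    def __len__(self) -> int:
        return len(self.patches)


@dataclass
class PatchGrouping:
    """A partition of a PatchSet's patches into groups.

    ``groups`` lists, per group, the member patch indices; ``group_cells``
    the union of member cells.
    """

    patch_set: PatchSet
    groups: list[list[int]]
    ps_min: float = DEFAULT_PS_MIN
    d_min: float = DEFAULT_D_MIN

    @property
    def group_cells(self) -> list[frozenset]:
        return [
            frozenset().union(*(self.patch_set.patches[i] for i in g))
            for g in self.groups
        ]

    @property
    def group_sizes(self) -> list[int]:
        return [sum(len(self.patch_set.patches[i]) for i in g) for g in self.groups]

    def __len__(self) -> int:
        return len(self.groups)


def find_patches(range_cells: set[Cell], spec: GridSpec) -> PatchSet:
    """Decompose a range into Moore-connected patches.

    Patches are listed in descending size; ties broken by the smallest
    (row, col) cell of the patch.
    """
    cells = frozenset(range_cells)
    for cell in cells:
        if not spec.contains(cell):
            raise ValueError(f"cell {cell} outside grid {spec.shape}")
    if not cells:
        return PatchSet(cells, [])
    raster = np.zeros(spec.shape, dtype=np.int8)
    for r, c in cells:
        raster[r, c] = 1
    labels, n = ndimage.label(raster, structure=MOORE_STRUCTURE)
    patches: list[frozenset] = []
    for k in range(1, n + 1):
        rows, cols = np.nonzero(labels == k)
        patches.append(frozenset((int(r), int(c)) for r, c in zip(rows, cols)))
    patches.sort(key=lambda p: (-len(p), min(p)))
    return PatchSet(cells, patches)


def patch_distance(p1: set[Cell], p2: set[Cell]) -> float:
    """Minimum Chebyshev distance between any pair of member cells."""
    if not p1 or not p2:
        raise ValueError("patches must be nonempty")
    a = np.array(sorted(p1), dtype=float)
    b = np.array(sorted(p2), dtype=float)
    return float(cdist(a, b, "chebyshev").min())


def group_tiny_patches(
    ps: PatchSet, ps_min: float = DEFAULT_PS_MIN, d_min: float = DEFAULT_D_MIN
) -> PatchGrouping:
    """Merge tiny satellite patches into their nearest neighbor group.

    Iterates until no group smaller than ``ps_min`` x (largest group size)
    lies closer than ``d_min`` to another group.  Both comparisons are strict
    (<).  Deterministic: the smallest mergeable group is processed first;
    nearest-group ties are broken by larger candidate size, then by lowest
    member patch index.  Each merge reduces the group count, so the procedure
    terminates.
    """
    if ps_min <= 0 or d_min <= 0:
        raise ValueError("ps_min and d_min must be strictly positive")
    if not ps.patches:
        return PatchGrouping(ps, [], ps_min, d_min)

    groups: list[list[int]] = [[i] for i in range(len(ps.patches))]

    def gsize(g: list[int]) -> int:
        return sum(len(ps.patches[i]) for i in g)

    def gcells(g: list[int]) -> set[Cell]:
        out: set[Cell] = set()
        for i in g:
            out |= ps.patches[i]
        return out

    while len(groups) > 1:
        sizes = [gsize(g) for g in groups]
        largest = max(sizes)
        # smallest tiny group first; ties by lowest member patch index
        tiny = sorted(
            (i for i, s in enumerate(sizes) if s < ps_min * largest),
            key=lambda i: (sizes[i], min(groups[i])),
        )
        merged = False
        for gi in tiny:
            cells_i = gcells(groups[gi])
            best: tuple[float, int, int, int] | None = None
            for gj in range(len(groups)):
                if gj == gi:
                    continue
                d = patch_distance(cells_i, gcells(groups[gj]))
                key = (d, -sizes[gj], min(groups[gj]), gj)
                if best is None or key < best:
                    best = key
            assert best is not None
            if best[0] < d_min:
                gj = best[3]
                merged_group = sorted(groups[gi] + groups[gj])
                groups = [g for k, g in enumerate(groups) if k not in (gi, gj)]
                groups.append(merged_group)
                merged = True
                break
        if not merged:
            break

    groups.sort(key=lambda g: (-gsize(g), min(g)))
    return PatchGrouping(ps, groups, ps_min, d_min)


def grouping_for_range(
    range_cells: set[Cell],
    spec: GridSpec,
    ps_min: float = DEFAULT_PS_MIN,
    d_min: float = DEFAULT_D_MIN,
) -> PatchGrouping:
    """Convenience: find_patches then group_tiny_patches."""
    return group_tiny_patches(find_patches(range_cells, spec), ps_min, d_min)
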