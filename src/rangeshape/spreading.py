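"""The spreading-dye range simulator.

A simulated range grows from a start cell inside the species' geographic
domain by repeatedly adding one unoccupied von-Neumann neighbor of the
current range, chosen uniformly at random from the frontier, until the number
of in-domain cells reaches the target (the empirical, or standardized, range
size).  Domains may be fragmented: when the frontier holds no suitable cell,
growth *bridges* through traversable but non-suitable land cells; the moment
an unoccupied suitable cell is reached, all bridge cells are deleted.  Bridge
cells never count toward the target and never appear in the result.  Ocean
(non-traversable) cells are a hard boundary that is never entered.

Patchy ranges use one start per empirical patch group, grown sequentially in
descending target size; cells occupied by earlier patches block later
frontiers, so simulated patches never overlap (they may touch and merge into
one Moore component).

Realized size is always ``min(target, number of suitable cells reachable from
the start through traversable cells)`` — growth stops naturally when the
frontier empties, which happens exactly when the reachable component is
exhausted.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .constraints import DomainMask, SpeciesRecord
from .grid import Cell, GridSpec, RichnessMap, coarse_presence, fine_richness
from .patches import PatchGrouping

logger = logging.getLogger(__name__)

_VN = ((-1, 0), (1, 0), (0, -1), (0, 1))


@dataclass
class SpreadConfig:
    """Ensemble settings: repetitions, master seed, scenario flags."""

    n_reps: int = 1000
    seed: int = 0
    patchy: bool = False
    bounded: bool = False

    def __post_init__(self) -> None:
        if self.n_reps < 1:
            raise ValueError("n_reps must be >= 1")


@dataclass
class SimulatedRange:
    """One spreading-dye realization for one species."""

    species_id: str
    cells: frozenset
    bridged: bool = False
    targets: tuple[int, ...] = ()
    resampled_starts: int = 0

    @property
    def realized_size(self) -> int:
        return len(self.cells)


def _grow(
    domain: DomainMask,
    start: Cell,
    target: int,
    rng: np.random.Generator,
    blocked: set[Cell] | None = None,
) -> tuple[set[Cell], bool]:
    """Single spreading-dye growth; returns (in-domain cells, bridged flag)."""
    suitable = domain.suitable
    traversable = domain.traversable
    blocked = blocked or set()

    o_in: set[Cell] = {start}
    o_out: set[Cell] = set()
    f_suit: set[Cell] = set()
    f_bridge: set[Cell] = set()
    bridged = False

    def add_frontier_of(cell: Cell) -> None:
        r, c = cell
        for dr, dc in _VN:
            nb = (r + dr, c + dc)
            if (
                nb in traversable
                and nb not in o_in
                and nb not in o_out
                and nb not in blocked
            ):
                (f_suit if nb in suitable else f_bridge).add(nb)

    def rebuild_frontier() -> None:
        f_suit.clear()
        f_bridge.clear()
        for cell in o_in:
            add_frontier_of(cell)

    add_frontier_of(start)

    while len(o_in) < target:
        if f_suit:
            chosen = _draw(f_suit, rng)
            o_in.add(chosen)
            if o_out:
                # overflow rule: entering the domain purges all bridge cells
                o_out.clear()
                rebuild_frontier()
            else:
                f_suit.discard(chosen)
                f_bridge.discard(chosen)
                add_frontier_of(chosen)
        elif f_bridge:
            bridged = True
            chosen = _draw(f_bridge, rng)
            o_out.add(chosen)
            f_bridge.discard(chosen)
            add_frontier_of(chosen)
        else:
            break  # reachable component exhausted: realized = min(target, reachable)
    return o_in, bridged


def _draw(cells: set[Cell], rng: np.random.Generator) -> Cell:
    ordered = sorted(cells)
    return ordered[int(rng.integers(len(ordered)))]


def spread_single(
    domain: DomainMask, start: Cell, target: int, rng: np.random.Generator
) -> set[Cell]:
    """Grow one coherent range of ``target`` in-domain cells from ``start``."""
    if start not in domain.suitable:
        raise ValueError(f"start {start} not in the suitable domain")
    if target < 1:
        raise ValueError("target must be >= 1")
    cells, _ = _grow(domain, start, target, rng)
    return cells


def _chebyshev_to_set(cell: Cell, cells: set[Cell]) -> float:
    return min(max(abs(cell[0] - r), abs(cell[1] - c)) for r, c in cells)


def spread_multi(
    domain: DomainMask,
    starts_and_targets: list[tuple[Cell, int]],
    rng: np.random.Generator,
    source_groups: list[set[Cell]] | None = None,
) -> tuple[set[Cell], bool, int]:
    """Grow several non-overlapping patches sequentially.

    Patches are grown in descending target size; earlier cells block later
    frontiers.  If a later start is already occupied it is resampled
    uniformly from its source patch group; if the whole group is occupied, a
    fallback start is drawn among unoccupied suitable cells nearest (Chebyshev)
    to the group.  Returns (union of cells, any-bridging flag, resample count).
    """
    for start, target in starts_and_targets:
        if start not in domain.suitable:
            raise ValueError(f"start {start} not in the suitable domain")
        if target < 1:
            raise ValueError("targets must be >= 1")
    if source_groups is not None and len(source_groups) != len(starts_and_targets):
        raise ValueError("source_groups length mismatch")

    order = sorted(
        range(len(starts_and_targets)),
        key=lambda i: (-starts_and_targets[i][1], i),
    )
    occupied: set[Cell] = set()
    bridged = False
    resampled = 0
    for i in order:
        start, target = starts_and_targets[i]
        if start in occupied:
            resampled += 1
            group = source_groups[i] if source_groups is not None else {start}
            free = sorted(set(group) & domain.suitable - occupied)
            if not free:
                # whole group swallowed by earlier patches: nearest free cell
                candidates = sorted(domain.suitable - occupied)
                if not candidates:
                    logger.warning("domain saturated; patch %d skipped", i)
                    continue
                dmin = min(_chebyshev_to_set(c, group) for c in candidates)
                free = [
                    c for c in candidates if _chebyshev_to_set(c, group) == dmin
                ]
            start = free[int(rng.integers(len(free)))]
        cells, b = _grow(domain, start, target, rng, blocked=occupied)
        bridged = bridged or b
        occupied |= cells
    return occupied, bridged, resampled


def simulate_species(
    sp: SpeciesRecord,
    domain: DomainMask,
    grouping: PatchGrouping,
    cfg: SpreadConfig,
    rng: np.random.Generator,
    target_size: int | None = None,
) -> SimulatedRange:
    """One realization for one species under the configured scenario.

    Coherent: one start drawn uniformly from the empirical range, target =
    empirical (or standardized) size.  Patchy: one start per patch group,
    drawn uniformly within the group; per-group targets are the group sizes,
    or the standardized size apportioned proportionally across groups.
    """
    from .standardize import apportion_patches

    size = target_size if target_size is not None else sp.range_size
    if not cfg.patchy or len(grouping) <= 1:
        start = _draw(set(sp.empirical_range), rng)
        cells, bridged = _grow(domain, start, size, rng)
        return SimulatedRange(sp.species_id, frozenset(cells), bridged, (size,))

    group_cells = grouping.group_cells
    group_sizes = grouping.group_sizes
    if target_size is not None:
        targets = apportion_patches(group_sizes, max(target_size, len(group_cells)))
    else:
        targets = list(group_sizes)
    starts = [_draw(set(g), rng) for g in group_cells]
    cells, bridged, resampled = spread_multi(
        domain,
        list(zip(starts, targets)),
        rng,
        source_groups=[set(g) for g in group_cells],
    )
    return SimulatedRange(
        sp.species_id, frozenset(cells), bridged, tuple(targets), resampled
    )


@dataclass
class EnsembleResult:
    """Rep-averaged richness maps plus per-rep bookkeeping."""

    fine_mean: RichnessMap
    coarse_total_mean: RichnessMap
    rep_log: list[dict] = field(default_factory=list)
    n_reps: int = 0


def run_ensemble(
    species: list[SpeciesRecord],
    domains: dict[str, DomainMask],
    groupings: dict[str, PatchGrouping],
    cfg: SpreadConfig,
    spec: GridSpec,
    sizes: dict[str, int] | None = None,
) -> EnsembleResult:
    """Monte-Carlo ensemble over all species.

    Per repetition, one realization is drawn per species; fine richness and
    coarse total richness are averaged across repetitions.  The random stream
    for (rep r, species k) is seeded deterministically from the master seed,
    so ensembles are reproducible and order-independent.
    """
    fine_acc = np.zeros(spec.shape)
    coarse_acc = np.zeros(spec.coarse_shape)
    rep_log: list[dict] = []
    for rep in range(cfg.n_reps):
        realized = 0
        cells_r: list[int] = []
        cells_c: list[int] = []
        coarse_counts = np.zeros(spec.coarse_shape)
        bridged_any = False
        for k, sp in enumerate(species):
            rng = np.random.default_rng([cfg.seed, rep, k])
            size = sizes.get(sp.species_id) if sizes else None
            sim = simulate_species(
                sp, domains[sp.species_id], groupings[sp.species_id], cfg, rng,
                target_size=size,
            )
            realized += sim.realized_size
            bridged_any = bridged_any or sim.bridged
            for r, c in sim.cells:
                cells_r.append(r)
                cells_c.append(c)
            for R, C in coarse_presence(set(sim.cells), spec):
                coarse_counts[R, C] += 1
        np.add.at(fine_acc, (np.array(cells_r, int), np.array(cells_c, int)), 1.0)
        coarse_acc += coarse_counts
        rep_log.append(
            {"rep": rep, "seed": cfg.seed, "realized_total": realized,
             "bridged": bridged_any}
        )
    fine_mean = RichnessMap("fine", fine_acc / cfg.n_reps)
    coarse_mean = RichnessMap("coarse", coarse_acc / cfg.n_reps)
    return EnsembleResult(fine_mean, coarse_mean, rep_log, cfg.n_reps)
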