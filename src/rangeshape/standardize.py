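"""Range-size standardization across biogeographic realms.

To isolate the effect of range *shape* from regional structure in range
*size*, the realm-specific range-size frequency distributions are replaced by
random samples from the global pool of range sizes: for each realm, as many
sizes as the realm has species are drawn without replacement from the global
pool and assigned to the realm's species in rank order (smallest sampled size
to the species with the smallest empirical range, and so on).  Species
spanning several realms receive the mean of their per-realm assignments.  The
draw is repeated many times (default 1000) and each species keeps the average
across repetitions, rounded to a whole number of cells (min 1).

For patchy ranges, a standardized total is apportioned across patch groups
proportionally to the empirical group sizes (largest-remainder rounding), so
standardization never changes the relative size structure within a range.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .constraints import SpeciesRecord
from .grid import Cell


@dataclass
class RealmPartition:
    """Integer realm id per fine cell (land cells only are meaningful)."""

    realm_grid: np.ndarray

    def __post_init__(self) -> None:
        self.realm_grid = np.asarray(self.realm_grid, dtype=int)

    def realms_of(self, cells: frozenset | set) -> frozenset:
        """Realm ids overlapped by a cell set (any-overlap membership)."""
        return frozenset(int(self.realm_grid[r, c]) for r, c in cells)

    @property
    def realm_ids(self) -> list[int]:
        return sorted(int(v) for v in np.unique(self.realm_grid))


@dataclass
class StandardizedSizes:
    """Final per-species standardized target sizes.

    ``raw_means`` keeps the unrounded repetition means (the quantity that is
    averaged in the standardization procedure); ``sizes`` are those means
    rounded to whole cells (min 1), which is what the simulator consumes.
    """

    sizes: dict[str, int]
    n_reps: int
    seed: int
    raw_means: dict[str, float] = None

    def __getitem__(self, species_id: str) -> int:
        return self.sizes[species_id]


def sample_realm_sizes(
    realm_species: list[tuple[str, int]],
    global_pool: list[int],
    rng: np.random.Generator,
) -> dict[str, float]:
    """One standardization draw for one realm.

    Draws ``len(realm_species)`` sizes without replacement from the global
    pool and assigns them in size-rank order: the k-th smallest sampled size
    to the species with the k-th smallest empirical size (ties broken by
    species_id).
    """
    n = len(realm_species)
    if n > len(global_pool):
        raise ValueError("realm has more species than the global pool")
    sample = np.sort(rng.choice(np.asarray(global_pool), size=n, replace=False))
    ranked = sorted(realm_species, key=lambda t: (t[1], t[0]))
    return {sid: float(s) for (sid, _), s in zip(ranked, sample)}


def standardize_sizes(
    species: list[SpeciesRecord],
    partition: RealmPartition,
    n_reps: int = 1000,
    seed: int = 0,
) -> StandardizedSizes:
    """Average rank-order resampled sizes over ``n_reps`` repetitions.

    Per repetition the realms are resampled independently; a multi-realm
    species' repetition value is the mean of its per-realm assignments.  The
    final size is the repetition mean rounded to the nearest integer,
    floored at 1.
    """
    global_pool = [sp.range_size for sp in species]
    realm_members: dict[int, list[tuple[str, int]]] = {}
    for sp in species:
        realms = sp.realms or partition.realms_of(sp.empirical_range)
        for realm in sorted(realms):
            realm_members.setdefault(realm, []).append((sp.species_id, sp.range_size))
    n_realms = {sp.species_id: 0 for sp in species}
    for members in realm_members.values():
        for sid, _ in members:
            n_realms[sid] += 1

    acc = {sp.species_id: 0.0 for sp in species}
    for rep in range(n_reps):
        rep_sum = {sp.species_id: 0.0 for sp in species}
        for realm in sorted(realm_members):
            rng = np.random.default_rng([seed, rep, realm])
            assigned = sample_realm_sizes(realm_members[realm], global_pool, rng)
            for sid, size in assigned.items():
                rep_sum[sid] += size
        for sid in acc:
            acc[sid] += rep_sum[sid] / n_realms[sid]

    raw = {sid: total / n_reps for sid, total in acc.items()}
    final = {sid: max(1, int(round(m))) for sid, m in raw.items()}
    return StandardizedSizes(final, n_reps, seed, raw)


def apportion_patches(group_sizes: list[int], new_total: int) -> list[int]:
    """Split ``new_total`` cells across patch groups proportionally.

    Largest-remainder rounding with a floor of 1 cell per group; conserves the
    total exactly and never inverts the ordering of group sizes.
    """
    if not group_sizes or any(s < 1 for s in group_sizes):
        raise ValueError("group_sizes must be nonempty with all sizes >= 1")
    n = len(group_sizes)
    if new_total < n:
        raise ValueError("new_total must be at least the number of groups")
    total = sum(group_sizes)
    quotas = [new_total * s / total for s in group_sizes]
    out = [int(q) for q in quotas]
    remainders = [q - o for q, o in zip(quotas, out)]
    leftover = new_total - sum(out)
    # hand leftover cells to the largest remainders (ties: larger group, then index)
    order = sorted(range(n), key=lambda i: (-remainders[i], -group_sizes[i], i))
    for i in order[:leftover]:
        out[i] += 1
    # enforce the floor of one cell per group; the donor is the smallest
    # group among those holding the maximum share, so size ordering survives
    while min(out) < 1:
        i = out.index(min(out))
        top = max(out)
        j = min(
            (k for k in range(n) if out[k] == top),
            key=lambda k: (group_sizes[k], k),
        )
        out[i] += 1
        out[j] -= 1
    return out
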