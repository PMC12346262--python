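from collections import Counter

import numpy as np
import pytest

from rangeshape import (
    DomainMask,
    GridSpec,
    SpreadConfig,
    grouping_for_range,
    run_ensemble,
    simulate_species,
    spread_multi,
    spread_single,
)
from rangeshape.constraints import SpeciesRecord
from rangeshape.grid import fine_richness
from rangeshape.patches import find_patches


def _full(rows, cols):
    return {(r, c) for r in range(rows) for c in range(cols)}


class TestSpreadSingle:
    def test_line_never_skips_the_middle(self, line_domain):
        # on A-B-C with target 2, {A,C} is unreachable; uniform start gives
        # {A,B} and {B,C} equal probability
        rng = np.random.default_rng(0)
        counts = Counter()
        starts = sorted(line_domain.suitable)
        for _ in range(4000):
            start = starts[rng.integers(3)]
            counts[frozenset(spread_single(line_domain, start, 2, rng))] += 1
        assert set(counts) == {
            frozenset({(0, 0), (0, 1)}),
            frozenset({(0, 1), (0, 2)}),
        }
        assert abs(counts[frozenset({(0, 0), (0, 1)})] / 4000 - 0.5) < 0.05

    def test_target_one_returns_start(self, line_domain):
        rng = np.random.default_rng(1)
        assert spread_single(line_domain, (0, 1), 1, rng) == {(0, 1)}

    def test_bridging_skips_unsuitable_gap(self):
        # two 1-cell islands separated by a traversable unsuitable cell
        dom = DomainMask("b", {(0, 0), (0, 1), (0, 2)}, {(0, 0), (0, 2)})
        rng = np.random.default_rng(2)
        cells = spread_single(dom, (0, 0), 2, rng)
        assert cells == {(0, 0), (0, 2)}  # bridge cell purged

    def test_ocean_is_never_entered(self):
        # suitable islands separated by non-traversable cells cannot connect
        dom = DomainMask("o", {(0, 0), (0, 2)}, {(0, 0), (0, 2)})
        rng = np.random.default_rng(3)
        cells = spread_single(dom, (0, 0), 2, rng)
        assert cells == {(0, 0)}  # capped at the reachable component

    def test_start_outside_suitable_raises(self, line_domain):
        with pytest.raises(ValueError, match="not in the suitable"):
            spread_single(line_domain, (5, 5), 1, np.random.default_rng(0))

    def test_nonpositive_target_raises(self, line_domain):
        with pytest.raises(ValueError, match="target"):
            spread_single(line_domain, (0, 0), 0, np.random.default_rng(0))


class TestSpreadMulti:
    def test_two_distant_starts_two_patches(self):
        cells_all = _full(12, 12)
        dom = DomainMask("m", cells_all, cells_all)
        rng = np.random.default_rng(4)
        out, bridged, resampled = spread_multi(
            dom, [((1, 1), 5), ((10, 10), 5)], rng
        )
        assert len(out) == 10 and not bridged and resampled == 0
        assert len(find_patches(out, GridSpec(12, 12))) == 2

    def test_single_start_reduces_to_spread_single_in_law(self, line_domain):
        rng1, rng2 = np.random.default_rng(5), np.random.default_rng(5)
        multi, _, _ = spread_multi(line_domain, [((0, 1), 2)], rng1)
        single = spread_single(line_domain, (0, 1), 2, rng2)
        assert multi == single

    def test_capping_in_small_region(self):
        region = {(0, c) for c in range(5)}
        dom = DomainMask("cap", region, region)
        rng = np.random.default_rng(6)
        out, _, _ = spread_multi(dom, [((0, 0), 3), ((0, 4), 3)], rng)
        assert len(out) == 5  # realized total capped at |suitable|


class TestSimulateSpecies:
    def test_coherent_free_range_is_connected(self):
        land = _full(16, 16)
        dom = DomainMask("sp", land, land)
        sp = SpeciesRecord("sp", frozenset({(8, 8)}), (0.0, 1.0))
        grouping = grouping_for_range(set(sp.empirical_range), GridSpec(16, 16))
        cfg = SpreadConfig(n_reps=1, seed=0)
        sim = simulate_species(sp, dom, grouping, cfg, np.random.default_rng(7),
                               target_size=30)
        # von-Neumann-connected implies one Moore patch
        assert len(find_patches(set(sim.cells), GridSpec(16, 16))) == 1
        assert sim.realized_size == 30

    def test_patchy_species_at_most_n_group_components(self):
        land = _full(20, 20)
        dom = DomainMask("sp", land, land)
        emp = {(2, 2), (2, 3), (3, 2)} | {(15, 15), (15, 16), (16, 16)}
        sp = SpeciesRecord("sp", frozenset(emp), (0.0, 1.0))
        grouping = grouping_for_range(emp, GridSpec(20, 20))
        assert len(grouping) == 2
        cfg = SpreadConfig(n_reps=1, seed=0, patchy=True)
        for k in range(20):
            sim = simulate_species(sp, dom, grouping, cfg, np.random.default_rng(k))
            n_comp = len(find_patches(set(sim.cells), GridSpec(20, 20)))
            assert 1 <= n_comp <= 2
            assert sim.realized_size == len(emp)

    def test_domain_smaller_than_target_caps(self):
        region = {(0, c) for c in range(4)}
        dom = DomainMask("sp", region, region)
        sp = SpeciesRecord("sp", frozenset({(0, 0)}), (0.0, 1.0))
        grouping = grouping_for_range(set(sp.empirical_range), GridSpec(1, 4))
        cfg = SpreadConfig(n_reps=1, seed=0)
        sim = simulate_species(sp, dom, grouping, cfg, np.random.default_rng(8),
                               target_size=99)
        assert sim.realized_size == 4


class TestRunEnsemble:
    def _tiny_setup(self):
        spec = GridSpec(8, 8, 4)
        land = _full(8, 8)
        species = [
            SpeciesRecord("a", frozenset({(1, 1)}), (0.0, 1.0)),
            SpeciesRecord("b", frozenset({(6, 6), (6, 7)}), (0.0, 1.0)),
        ]
        domains = {s.species_id: DomainMask(s.species_id, land, land) for s in species}
        groupings = {
            s.species_id: grouping_for_range(set(s.empirical_range), spec)
            for s in species
        }
        return spec, species, domains, groupings

    def test_same_seed_reproduces_maps(self):
        spec, species, domains, groupings = self._tiny_setup()
        cfg = SpreadConfig(n_reps=5, seed=42)
        r1 = run_ensemble(species, domains, groupings, cfg, spec)
        r2 = run_ensemble(species, domains, groupings, cfg, spec)
        assert np.array_equal(r1.fine_mean.values, r2.fine_mean.values)
        assert np.array_equal(r1.coarse_total_mean.values, r2.coarse_total_mean.values)

    def test_fine_sum_conserves_range_sizes(self):
        spec, species, domains, groupings = self._tiny_setup()
        cfg = SpreadConfig(n_reps=7, seed=1)
        res = run_ensemble(species, domains, groupings, cfg, spec)
        assert res.fine_mean.values.sum() == pytest.approx(
            sum(s.range_size for s in species)
        )
        for entry in res.rep_log:
            assert entry["realized_total"] == 3

    def test_single_rep_is_one_joint_realization(self):
        spec, species, domains, groupings = self._tiny_setup()
        cfg = SpreadConfig(n_reps=1, seed=9)
        res = run_ensemble(species, domains, groupings, cfg, spec)
        assert np.all(np.mod(res.fine_mean.values, 1) == 0)


class TestRandomizedInvariants:
    def test_containment_and_realized_size(self):
        # randomized small domains: realized = min(target, reachable suitable),
        # where reachability is BFS through traversable cells (independent
        # oracle for the grower's stopping rule)
        rng = np.random.default_rng(11)
        for case in range(300):
            rows, cols = 6, 6
            all_cells = _full(rows, cols)
            trav = {
                c for c in all_cells if rng.random() < 0.8
            }
            suit = {c for c in trav if rng.random() < 0.6}
            if not suit:
                continue
            start = sorted(suit)[rng.integers(len(suit))]
            target = int(rng.integers(1, 15))
            dom = DomainMask("r", trav, suit)
            out = spread_single(dom, start, target, rng)
            assert out <= suit
            # oracle: flood fill over traversable, count suitable
            seen, stack = {start}, [start]
            while stack:
                r, c = stack.pop()
                for nb in ((r - 1, c), (r + 1, c), (r, c - 1), (r, c + 1)):
                    if nb in trav and nb not in seen:
                        seen.add(nb)
                        stack.append(nb)
            reachable = len(seen & suit)
            assert len(out) == min(target, reachable)

    def test_fine_richness_matches_realizations(self):
        rng = np.random.default_rng(12)
        spec = GridSpec(6, 6)
        all_cells = _full(6, 6)
        dom = DomainMask("r", all_cells, all_cells)
        sims = [
            spread_single(dom, (int(rng.integers(6)), int(rng.integers(6))),
                          int(rng.integers(1, 8)), rng)
            for _ in range(30)
        ]
        m = fine_richness(sims, spec)
        assert m.values.sum() == sum(len(s) for s in sims)
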