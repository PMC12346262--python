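import numpy as np
import pytest
from scipy.stats import skew

from rangeshape import (
    LandscapeSpec,
    ShapeTemplate,
    make_landscape,
    make_shape,
    make_species_pool,
    random_relocate,
    ridge_coarse_masks,
    shape_scale_experiment,
)
from rangeshape.grid import GridSpec
from rangeshape.patches import find_patches


class TestMakeLandscape:
    def test_flat_landscape_has_identical_bands(self):
        ls = make_landscape(LandscapeSpec(kind="flat", n_rows=8, n_cols=8,
                                          agg_factor=4))
        assert np.all(ls.bands.elev_min == ls.bands.elev_min[0, 0])
        assert np.all(ls.bands.elev_max == ls.bands.elev_max[0, 0])

    def test_same_seed_identical_outputs(self):
        a = make_landscape(LandscapeSpec(seed=5))
        b = make_landscape(LandscapeSpec(seed=5))
        assert np.array_equal(a.elevation, b.elevation)
        assert np.array_equal(a.climate.bio1, b.climate.bio1)
        assert np.array_equal(a.realms.realm_grid, b.realms.realm_grid)

    def test_ridge_elevation_peaks_on_axis(self):
        ls = make_landscape(LandscapeSpec(kind="ridge"))
        axis = np.argmax(ls.elevation[0])
        assert ls.elevation[0, axis] == ls.elevation.max()
        assert ls.elevation[0, 0] == 0.0  # lowland far from the axis

    def test_invalid_dims_raise(self):
        with pytest.raises(ValueError, match="divisible"):
            LandscapeSpec(n_rows=65, n_cols=64, agg_factor=4)

    def test_realms_cover_land(self):
        ls = make_landscape(LandscapeSpec())
        assert set(np.unique(ls.realms.realm_grid)) == {1, 2}


class TestMakeSpeciesPool:
    def test_right_skewed_sizes(self, ridge_landscape):
        pool = make_species_pool(ridge_landscape, n_species=60, seed=11)
        sizes = [sp.range_size for sp in pool]
        assert skew(sizes) > 0

    def test_single_cell_species(self, ridge_landscape):
        pool = make_species_pool(
            ridge_landscape, n_species=1, size_distribution=(0.0, 1e-9), seed=0
        )
        assert pool[0].range_size == 1

    def test_range_within_own_elevational_band(self, ridge_landscape, ridge_species):
        for sp in ridge_species:
            ok = ridge_landscape.bands.overlaps(sp.elev_limits)
            for cell in sp.empirical_range:
                assert ok[cell]

    def test_lowland_ranges_more_compact_than_montane(self, ridge_landscape):
        # perimeter-to-area of narrow-band montane ranges exceeds that of
        # wide-band lowland ranges (linearity of ridge-bound stripes)
        def perimeter_to_area(cells):
            per = 0
            for r, c in cells:
                for nb in ((r - 1, c), (r + 1, c), (r, c - 1), (r, c + 1)):
                    if nb not in cells:
                        per += 1
            return per / len(cells)

        flat = make_landscape(LandscapeSpec(kind="flat", seed=3))
        compact = make_species_pool(
            flat, 25, size_distribution=(3.5, 0.3),
            band_widths=(5000.0, 6000.0), seed=4,
        )
        linear = make_species_pool(
            ridge_landscape, 25, size_distribution=(3.5, 0.3),
            band_widths=(200.0, 300.0), montane_fraction=1.0,
            patchy_fraction=0.0, seed=4,
        )
        pa_compact = np.mean([perimeter_to_area(set(s.empirical_range)) for s in compact])
        pa_linear = np.mean([perimeter_to_area(set(s.empirical_range)) for s in linear])
        assert pa_linear > pa_compact


class TestMakeShape:
    def test_single_cell_circle(self):
        assert make_shape(ShapeTemplate("circle", area=1)) == {(0, 0)}

    @pytest.mark.parametrize("kind", ["circle", "ellipse", "patchy"])
    @pytest.mark.parametrize("area", [5, 12, 30])
    def test_exact_area(self, kind, area):
        assert len(make_shape(ShapeTemplate(kind, area=area))) == area

    def test_ellipse_wider_than_tall(self):
        cells = make_shape(ShapeTemplate("ellipse", area=12, aspect=3.0))
        rows = [r for r, _ in cells]
        cols = [c for _, c in cells]
        assert max(cols) - min(cols) > max(rows) - min(rows)

    def test_patchy_has_three_moore_components(self):
        cells = make_shape(ShapeTemplate("patchy", area=12))
        shifted = {(r + 3, c) for r, c in cells}
        assert len(find_patches(shifted, GridSpec(8, 20))) == 3

    def test_ellipse_perimeter_to_area_exceeds_circle(self):
        def p2a(cells):
            per = sum(
                1
                for r, c in cells
                for nb in ((r - 1, c), (r + 1, c), (r, c - 1), (r, c + 1))
                if nb not in cells
            )
            return per / len(cells)

        for area in (12, 20, 40):
            circle = make_shape(ShapeTemplate("circle", area=area))
            ellipse = make_shape(ShapeTemplate("ellipse", area=area, aspect=3.0))
            assert p2a(ellipse) > p2a(circle)


class TestRandomRelocate:
    def test_whole_domain_template_identity(self):
        cells = {(r, c) for r in range(3) for c in range(4)}
        out = random_relocate(cells, (3, 4), np.random.default_rng(0))
        assert out == cells

    def test_single_cell_covers_all_positions(self):
        rng = np.random.default_rng(1)
        seen = set()
        for _ in range(3000):
            seen |= random_relocate({(0, 0)}, (6, 18), rng)
        assert len(seen) == 108

    def test_translation_preserves_shape(self):
        rng = np.random.default_rng(2)
        t = make_shape(ShapeTemplate("patchy", area=12))
        spec = GridSpec(12, 36)
        n0 = len(find_patches({(r + 3, c + 1) for r, c in t}, spec))
        for _ in range(20):
            moved = random_relocate(t, (12, 36), rng)
            assert len(moved) == len(t)
            assert len(find_patches(moved, spec)) == n0

    def test_too_large_template_raises(self):
        with pytest.raises(ValueError, match="fit"):
            random_relocate({(0, 0), (0, 9)}, (3, 5), np.random.default_rng(0))


class TestShapeScaleExperiment:
    def test_occupancy_conserved_and_deterministic(self):
        a = shape_scale_experiment(n_reps=50, seed=7)
        b = shape_scale_experiment(n_reps=50, seed=7)
        for key in a.mean_richness:
            assert np.array_equal(a.mean_richness[key], b.mean_richness[key])
        # at factor 1, mean richness * n cells = n_species * area exactly
        for kind in ("circle", "ellipse", "patchy"):
            assert np.all(a.mean_richness[(kind, 1)] * 108 == 36)


class TestRidgeMasks:
    def test_flank_and_lowland_disjoint(self, ridge_landscape):
        ridge, adj = ridge_coarse_masks(ridge_landscape)
        assert not np.any(ridge & adj)
        assert ridge.any() and adj.any()
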