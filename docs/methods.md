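# Methods

## The spreading-dye growth process

A realization for one species is a random set of fine-grid cells of the
target size, grown inside the species' geographic domain. The state is a
pair (O_in, O_out): in-domain cells and a temporary bridge. At each step the
frontier is the set of unoccupied, traversable cells von-Neumann-adjacent to
O_in ∪ O_out. If the frontier contains suitable cells, one is added to O_in
uniformly at random and the whole bridge O_out is deleted; otherwise one
traversable non-suitable frontier cell is added to O_out. Growth stops when
|O_in| reaches the target, or the frontier empties — which happens exactly
when every suitable cell reachable from the start through traversable cells
is occupied. Hence `realized_size = min(target, reachable suitable)` without
any auxiliary reachability search. Only O_in is returned; bridge cells never
count toward the size and never appear in the result.

Two choices the growth rule leaves open are fixed as follows: selection is
uniform over frontier *cells* (not over occupied cells followed by a random
neighbor), and suitable frontier cells take strict priority over bridging, so
bridging is purely a fallback when no suitable cell is adjacent. Both are
verified against an exhaustive enumeration of the decision tree on small
domains (`tests/test_acceptance.py`), so the sampled distribution over
outcome sets is exactly the one the rule defines.

Patchy ranges are grown sequentially, one sub-range per patch group in
descending target order; cells of earlier sub-ranges block later frontiers,
so sub-ranges never overlap, though they may touch. If a later start cell is
already occupied, it is resampled uniformly from the unoccupied cells of its
source group; if the entire group has been swallowed, a fallback start is
drawn among unoccupied suitable cells at minimal Chebyshev distance from the
group (logged). The fallback keeps the realized total conserved, which the
fine-scale invariance checks rely on.

## Geographic domains

*Free* dispersal: every mainland cell is suitable; the coastline is the only
constraint. *Bounded* dispersal: a cell is suitable when (i) its elevation
band (the min–max terrain span inside the cell) overlaps the species'
elevational limits, closed-interval, and (ii) its climate falls inside both
occupied-climate convex hulls — one in (mean annual temperature, annual
precipitation), one in (temperature seasonality, precipitation seasonality)
— built over the cells of the empirical range. Climate layers are z-scored
(over land) before hull construction so the boundary tolerance
(ε = 1e-9) is comparable across layers; membership is boundary-inclusive via
a distance-within-ε predicate, which also handles degenerate point and
segment hulls from one-cell or collinear climate sets. Empirical-range cells
are force-included in the bounded domain (the dye must be able to start
there); force inclusions are logged on the mask.

## Patches and tiny-patch grouping

Patches are Moore-connected components (scipy.ndimage labeling). Inter-patch
distance is the minimum Chebyshev distance over cell pairs — the metric
consistent with Moore adjacency (distance 1 ⇔ adjacent). Grouping iterates:
any group with total size strictly below `ps_min` × (largest group's size)
merges with its nearest group when their distance is strictly below `d_min`;
the smallest mergeable group goes first, nearest-group ties resolve to the
larger candidate and then the lowest patch index, and the reference "largest
group" is recomputed after every merge. Each merge reduces the group count,
so termination is immediate; the procedure is idempotent. Defaults
`ps_min = 0.10`, `d_min = 5`.

## Range-size standardization

Per repetition and realm, as many sizes as the realm has member species are
drawn without replacement from the global pool of empirical sizes and
assigned in rank order (ties in empirical size break by species id). A
species belongs to every realm its range touches; its repetition value is
the mean over its realms, realms are resampled independently. The final
target size is the repetition mean rounded to a whole cell count (min 1);
the unrounded means are kept alongside. For patchy ranges a standardized
total is split across patch groups by largest-remainder rounding,
proportional to empirical group sizes with a floor of one cell, taking any
floor deficit from the smallest group holding the maximum share — this
conserves the total exactly and never inverts the group-size ordering. When
a standardized size exceeds the bounded domain, the realization is capped at
the domain size.

## Aggregation and analysis

Fine cells aggregate 4 × 4 (configurable) into coarse blocks. Coarse *total*
richness counts species with any presence in the block; coarse *mean*
richness averages fine richness over the land cells of the block, and blocks
without land cells are missing (NaN), not zero. Cells are treated as
equal-area; no projection or latitude weighting is applied. Hotspots are
coarse cells at or above the q-quantile of land richness, using the lower
order statistic (for integer-valued richness this keeps exactly the top
(1−q) share of cells, rounded up, plus ties; q = 0 keeps everything).
Scenario means within hotspots are paired per-cell means with a
percentile bootstrap over cells, the same cell resample applied to every
scenario; in this balanced within-cell design the paired means coincide with
the marginal means of a mixed model with a cell random effect, which the
bootstrap replaces deliberately.

## Synthetic landscapes and species

The generator emulates the *structure* of gridded mountain-bird data, not
any real geography. Ridge landscapes place a north–south ridge whose
elevation decays linearly from a central axis (default peak 3000 m,
half-width 0.1875 × grid width — a steep flank occupying ~40% of the domain,
with the remainder flat lowland); sky-island landscapes use cones at chosen
centers. Climate is primarily elevation-driven — temperature through a lapse
rate of 6.5 °C/km, precipitation with an orographic term — plus weak
regional gradients and Gaussian noise, so occupied-climate hulls generalize
*along* elevational contours rather than truncating them; this is the
configuration that yields linear suitable stripes. Elevation bands are the
point elevation ± 100 m. Realms split the grid into two contiguous halves.

Species sizes are log-normal (default μ = 4.0, σ = 0.8 on the log scale;
median ≈ 55 cells on the 64 × 64 default grid), giving the right-skewed
size-frequency distribution typical of these assemblages. Each species draws
a focal cell (half of them from elevated terrain), an elevational band
(width uniform on 200–1200 m around the focal elevation), and grows its
"empirical" range with the bounded dye inside its own elevational domain —
so lowland species come out compact and montane species linear, and every
range is contained in its own bounded domain by construction. A configurable
fraction (default 0.3) of species with ≥ 12 cells is grown from 2–3
well-separated starts to create genuinely disjunct ranges. The toy
shape-scale randomization uses a 6 × 18 domain, three species of 12 cells,
shapes discretized to the exact requested area (circle; horizontal ellipse,
aspect 3; three round patches separated by two empty columns), uniform
random translation with full containment, and aggregation factors {1, 3, 6}.

What the generator does *not* emulate: real topography and climate fields,
island systems, taxonomic or phylogenetic structure, and spatial
autocorrelation beyond what elevation induces. Passing tests therefore
demonstrate the mechanism — shape effects on richness are absent at the
simulation grain and emerge under aggregation — not any empirical magnitude.

## Problem sizes and numerical choices

The test suite and the acceptance script run the ridge experiment at 64 × 64
cells, 30 species and 100–200 repetitions per scenario, and the toy
randomization at 2000 repetitions; these sizes make the Monte-Carlo noise
small relative to the effects being demonstrated while keeping a full run in
the minutes range on one CPU. Randomness is fully determined by a master
seed; the stream for (scenario, repetition, species) is derived
deterministically, so ensembles are reproducible and order-independent. At
the native grain the toy experiment's per-*cell* mean richness is exactly
equal across shapes (conservation); the per-rep *maximum* differs slightly
between shapes even at the native grain because full-containment placement
constrains wide shapes more than compact ones — an edge effect of the small
domain, which is why the scale-dependence checks use the exact conservation
identity at factor 1 and the coarse statistics at factor 6.

## Known limitations

Equal-area cells (no spherical geometry); two-hull climate envelopes rather
than full niche models; sequential-with-blocking patch growth is one of
several defensible conventions for non-overlapping multi-start growth; the
hotspot comparison reports bootstrap intervals, not mixed-model inference;
rasters are read and written as plain CSV matrices (and long-format CSV for
presences), not GeoTIFF.
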