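"""Shape effects on richness appear only at coarse spatial grain.

Three equal-area shapes (compact circle, horizontal ellipse, three-patch
range) are placed uniformly at random on a 6 x 18 domain, many times over.
Per-cell richness at the native grain is fixed by conservation — every
repetition occupies exactly n_species x area cells — but the maximum coarse
richness climbs with range linearity and patchiness, because elongated and
disjunct ranges intersect more aggregation blocks.
"""

from rangeshape import shape_scale_experiment

res = shape_scale_experiment(n_reps=2000, seed=11)
print(res.summary.to_string(index=False, float_format=lambda v: f"{v:.3f}"))
print(
    "\n-> at agg_factor 1 the mean per-cell richness is identical for every "
    "shape (36 occupied cells out of 108, exactly);\n   at agg_factor 6 "
    "ellipses and patchy ranges overlap in more blocks than circles, so "
    "their mean maximum coarse richness is higher"
)
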