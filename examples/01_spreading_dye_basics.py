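"""Grow single spreading-dye ranges, with and without domain bridging.

The spreading dye grows a range from a start cell by repeatedly adding one
unoccupied von-Neumann neighbor, chosen uniformly at random, until the target
size is reached.  When the suitable domain is fragmented, growth bridges
through traversable but unsuitable land cells and deletes the bridge as soon
as it re-enters the domain.
"""

import numpy as np

from rangeshape import DomainMask, spread_single

rng = np.random.default_rng(0)

# a 1x3 strip A-B-C: with target 2, {A, C} can never occur
strip = {(0, 0), (0, 1), (0, 2)}
dom = DomainMask("strip", traversable=strip, suitable=strip)
counts = {}
for _ in range(2000):
    start = sorted(strip)[rng.integers(3)]
    key = tuple(sorted(spread_single(dom, start, 2, rng)))
    counts[key] = counts.get(key, 0) + 1
print("outcome frequencies on the 1x3 strip (target 2, uniform start):")
for key, n in sorted(counts.items()):
    print(f"  {key}: {n / 2000:.3f}")
print("-> the two adjacent pairs each occur with probability ~0.5; "
      "the disconnected pair {A, C} never does\n")

# bridging: two suitable islands separated by an unsuitable land cell
dom2 = DomainMask("islands", traversable={(0, 0), (0, 1), (0, 2)},
                  suitable={(0, 0), (0, 2)})
cells = spread_single(dom2, (0, 0), 2, rng)
print(f"bridged realization: {sorted(cells)}")
print("-> both islands are occupied; the bridge cell (0, 1) was traversed "
      "but deleted, so it never counts toward the range size")
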