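"""Branch-level tree map of a phantom and its decile profile.

Roots the vessel tree at the umbilical insertion, assigns each branch a
generation level (trunk = 1, bends do not count), and groups the levels
into ten contiguous deciles — the representation used to localise where
along the tree two cohorts differ.
"""

import numpy as np

from vasculocast import get_preset, sample_tree
from vasculocast.treemap import branch_levels, decile_bins, rooted_tree_from_ground_truth

tree = sample_tree(get_preset("normal_arterial"), seed=3)
rooted = rooted_tree_from_ground_truth(tree)
levels = branch_levels(rooted)
deciles = decile_bins(levels)

print(f"{rooted.n_branches} branches over {rooted.n_levels} levels")
print("branches per level:", [int(x) for x in levels])
print("decile counts:     ", [int(x) for x in deciles])
print("conservation check: sum of deciles =", deciles.sum(),
      "= total branches =", rooted.n_branches)
# An 80-level tree would split into ten groups of eight levels each; a
# remainder is front-loaded one level at a time onto the first groups.
assert list(decile_bins(np.ones(80, int))) == [8] * 10
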