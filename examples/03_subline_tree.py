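"""Venn-decompose subline call sets and rebuild the developmental tree.

Four sublines are expanded from single cells of a simulated clone; an SNV
called in several sublines arose on the branch above their common
ancestor, so the carrier subsets reconstruct the division history.
"""

import burstline as bl

cfg = bl.SimConfig(seed=3, generations=6, mu_burst=5.0, mu_background=0.3,
                   n_preexisting=0, burst_window=(1, 3))
mset = bl.simulate_clone(cfg)

# one subline per generation-2 subtree (leaves 0, 16, 32, 48)
leaves = [0, 16, 32, 48]
calls = {f"S{leaf}": {m.site for m in mset if bl.carries(m, leaf, 6)}
         for leaf in leaves}

panel = bl.panel_from_calls(calls)
for subset, snvs in sorted(bl.venn_decompose(panel).items(),
                           key=lambda kv: -len(kv[0])):
    print(f"carried by {sorted(subset)}: {len(snvs)} SNVs")

tree = bl.build_tree(panel)
print("tree:", tree.root.newick())
print("incompatible SNVs:", tree.incompatible)

# SNVs shared by {S0,S16} arose at generation 1 in the ancestor of the
# first half of the clone; subline-specific SNVs arose later and sit at
# low VAF in the parent. A noiseless panel is always conflict-free.
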