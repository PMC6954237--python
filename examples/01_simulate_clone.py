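"""Simulate a clonal expansion with an early hypermutation burst.

A founder cell divides 10 times; divisions 1-4 mutate at 100x the
background rate with a transversion-biased signature. Each mutation's true
VAF in the final clone is 2**-(k+1) for origin generation k.
"""

from collections import Counter

import burstline as bl

cfg = bl.SimConfig(seed=1)
mset = bl.simulate_clone(cfg)

print(f"simulated {len(mset)} mutations "
      f"({sum(m.is_burst for m in mset)} burst, "
      f"{sum(m.generation == 0 for m in mset)} pre-existing)")

by_gen = Counter(m.generation for m in mset)
print("generation -> count, true heterozygous VAF:")
for k in sorted(by_gen):
    m = next(m for m in mset if m.generation == k)
    print(f"  k={k:2d}  n={by_gen[k]:4d}  vaf={bl.true_vaf(m):.4g}")

# The burst generations (1-4) hold far more mutations than the background
# rate alone would place there, and each generation's VAF halves: this VAF
# ladder is what the amplicon deconvolution reads back out.
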