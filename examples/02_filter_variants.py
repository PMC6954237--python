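"""Run the post-call SNV filter chain on a small variant table.

The chain keeps clonal heterozygous calls: depth >= 20, no parental
evidence (alt reads >= 2 in the parent somatic sample excludes), not a
known or sister-shared site, no repeat flank, VAF inside 35-65%
(>= 75% hemizygous).
"""

import pandas as pd

import burstline as bl
from burstline.filters import trace_frame

variants = pd.DataFrame([
    {"chrom": "chr1", "pos": 101, "ref": "C", "alt": "A", "depth": 40,
     "alt_count": 20},                       # clean heterozygous call
    {"chrom": "chr1", "pos": 202, "ref": "T", "alt": "G", "depth": 19,
     "alt_count": 10},                       # too shallow
    {"chrom": "chr1", "pos": 303, "ref": "C", "alt": "T", "depth": 40,
     "alt_count": 8},                        # VAF 0.20: subclonal, rejected
    {"chrom": "chr1", "pos": 404, "ref": "G", "alt": "A", "depth": 60,
     "alt_count": 30},                       # parental-shared (see below)
])
parental = {("chr1", 404): 5}  # 5 alt reads in the parental cells

kept, traces = bl.filter_snvs(variants, parental_obs=parental)
print("kept positions:", list(kept["pos"]))
print(trace_frame(traces).to_string(index=False))

# Only pos 101 survives: the trace shows which stage rejected each other
# call. Note the VAF window is exactly why conventional WGS misses the
# low-VAF burst mutations that the subline approach recovers.
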