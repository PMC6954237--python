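"""Shared fixtures and independent test oracles.

The oracles here deliberately avoid the package's index-arithmetic carrier
representation: the explicit-tree oracle materialises every cell of the
division tree and propagates mutation sets through divisions, and the
filter oracle is a single boolean expression per variant.
"""

from __future__ import annotations

from collections import defaultdict

import numpy as np
import pandas as pd
import pytest

from burstline import LineageMutationSet, SimConfig


@pytest.fixture
def rng():
    return np.random.default_rng(20260929)


@pytest.fixture
def quiet_config():
    """Noise-free config: only pre-existing founder variants."""
    return SimConfig(mu_background=0.0, mu_burst=0.0, n_preexisting=5,
                     seq_error=0.0, seed=11)


# ---------------------------------------------------------------------------
# Explicit division-tree oracle (independent of the // arithmetic)
# ---------------------------------------------------------------------------

def explicit_leaf_mutation_sets(mset: LineageMutationSet, generations: int):
    """Propagate mutation sets through an explicitly materialised tree.

    Generation by generation every cell is duplicated into two daughters
    (preserving order, so daughter indices are 2i and 2i+1), then each
    mutation of that generation is added to the cell it names. Returns the
    list of 2**G per-leaf mutation sets.
    """
    by_gen = defaultdict(list)
    for m in mset:
        by_gen[m.generation].append(m)
    cells = [set(by_gen[0])]
    for k in range(1, generations + 1):
        cells = [set(c) for c in cells for _ in range(2)]
        for m in by_gen[k]:
            cells[m.lineage_index].add(m)
    return cells


def oracle_venn_partition(leaf_sets, subline_leaves, subline_ids):
    """Partition SNVs by exact carrier subset using the explicit leaf sets."""
    partition = defaultdict(set)
    all_muts = set().union(*(leaf_sets[i] for i in subline_leaves))
    for m in all_muts:
        subset = frozenset(sid for sid, leaf in zip(subline_ids, subline_leaves)
                           if m in leaf_sets[leaf])
        partition[subset].add(m.site)
    return dict(partition)


# ---------------------------------------------------------------------------
# Single-expression filter oracles
# ---------------------------------------------------------------------------

def oracle_snv_keep(row, parental_alt, known, sisters) -> bool:
    key = (row["chrom"], row["pos"], row["alt"])
    vaf = row["alt_count"] / row["depth"] if row["depth"] > 0 else 0.0
    hemi = row["chrom_class"] == "hemizygous"
    return (row["depth"] >= 20
            and parental_alt <= 1
            and key not in known
            and not any(key in s for s in sisters)
            and not row["repeat_flag"]
            and ((vaf >= 0.75) if hemi else (0.35 <= vaf <= 0.65)))


def oracle_indel_keep(row, parental_alt, known, sisters) -> bool:
    key = (row["chrom"], row["pos"], row["alt"])
    vaf = row["alt_count"] / row["depth"] if row["depth"] > 0 else 0.0
    hemi = row["chrom_class"] == "hemizygous"
    return (row["depth"] >= 20
            and row["alt_count"] >= 10
            and parental_alt <= 1
            and key not in known
            and not any(key in s for s in sisters)
            and not row["repeat_flag"]
            and ((vaf >= 0.70) if hemi else (0.30 <= vaf <= 0.70)))


def random_variant_table(rng, n=500):
    """Random toy variant table plus exclusion sets for the filter oracle."""
    df = pd.DataFrame({
        "chrom": rng.choice(["chr1", "chrX"], size=n),
        "pos": rng.integers(1, 10_000, size=n),
        "ref": rng.choice(list("ACGT"), size=n),
        "alt": rng.choice(list("ACGT"), size=n),
        "depth": rng.integers(0, 61, size=n),
        "chrom_class": rng.choice(["autosome", "hemizygous"], size=n,
                                  p=[0.8, 0.2]),
        "repeat_flag": rng.random(size=n) < 0.1,
    })
    df["alt_count"] = rng.binomial(df["depth"], rng.uniform(0, 1, size=n))
    keys = list(zip(df["chrom"], df["pos"], df["alt"]))
    known = frozenset(k for k in keys if rng.random() < 0.1)
    sisters = (frozenset(k for k in keys if rng.random() < 0.1),)
    parental = {(c, p): int(rng.poisson(0.5)) for c, p in
                zip(df["chrom"], df["pos"])}
    return df, known, sisters, parental
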