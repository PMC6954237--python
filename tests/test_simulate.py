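"""Lineage simulator: carrier model, Poisson rates, read model, sublines."""

import dataclasses

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import burstline as bl
from burstline.simulate import expected_mutation_count, sample_read_counts

from conftest import explicit_leaf_mutation_sets, oracle_venn_partition


def test_noise_free_config_yields_exactly_the_preexisting_variants(quiet_config):
    mset = bl.simulate_clone(quiet_config)
    assert len(mset) == 5
    assert all(m.generation == 0 for m in mset)
    assert all(bl.true_vaf(m) == 0.5 for m in mset)


@pytest.mark.parametrize("generation,zygosity,expected", [
    (0, "heterozygous", 0.5),
    (0, "hemizygous", 1.0),
    (1, "heterozygous", 0.25),   # the secondary ~20-30% VAF peak
    (3, "heterozygous", 0.0625),
    (3, "hemizygous", 0.125),
])
def test_true_vaf_is_exact_power_of_two(generation, zygosity, expected):
    m = bl.LineageMutation(site=1, ref="C", alt="A", context="ACA",
                           generation=generation, lineage_index=0,
                           is_burst=False, zygosity=zygosity)
    assert bl.true_vaf(m) == expected


def test_burst_mutation_count_matches_poisson_mean():
    """Monte-Carlo mean of burst mutations agrees with sum(2^k mu) over the window."""
    base = bl.SimConfig(generations=6, burst_window=(1, 4), mu_burst=10.0,
                        mu_background=0.1, n_preexisting=0)
    expected_burst = sum(2 ** k * 10.0 for k in range(1, 5))  # 300
    counts = []
    for seed in range(200):
        mset = bl.simulate_clone(dataclasses.replace(base, seed=seed))
        counts.append(sum(m.is_burst for m in mset))
    se = np.sqrt(expected_burst / 200)  # Poisson variance = mean
    assert abs(np.mean(counts) - expected_burst) < 3 * se


def test_deep_expansion_is_tractable_and_on_rate():
    # 20 generations with the same burst parameters: count still ~Poisson(300)
    cfg = bl.SimConfig(generations=20, burst_window=(1, 4), mu_burst=10.0,
                       mu_background=0.01, n_preexisting=0, seed=77)
    mset = bl.simulate_clone(cfg)
    n_burst = sum(m.is_burst for m in mset)
    assert abs(n_burst - 300) < 5 * np.sqrt(300)


def test_config_rejected_when_mutations_would_exceed_genome():
    with pytest.raises(ValueError, match="genome_length"):
        bl.simulate_clone(bl.SimConfig(genome_length=100, mu_burst=50,
                                       mu_background=1.0))


@pytest.mark.parametrize("bad", [
    {"burst_window": (3, 1)},
    {"burst_window": (0, 99)},
    {"mu_burst": 0.1, "mu_background": 0.2},
    {"vaf_floor": 0.7},
])
def test_invalid_configs_rejected(bad):
    with pytest.raises(ValueError):
        bl.SimConfig(**bad)


def test_seed_determinism():
    cfg = bl.SimConfig(seed=123)
    a, b = bl.simulate_clone(cfg), bl.simulate_clone(cfg)
    assert a.to_dataframe().equals(b.to_dataframe())
    oa = bl.sample_reads(a, cfg, "wgs", "parent")
    ob = bl.sample_reads(b, cfg, "wgs", "parent")
    assert oa == ob


def test_sites_unique():
    cfg = bl.SimConfig(seed=2, genome_length=20_000, mu_burst=2.0,
                       mu_background=0.2, n_preexisting=100)
    mset = bl.simulate_clone(cfg)
    sites = [m.site for m in mset]
    assert len(sites) == len(set(sites))
    assert all(1 <= s <= cfg.genome_length for s in sites)


def test_burst_signature_fidelity():
    """>=2000 burst mutations reproduce the burst signature at cosine >= 0.98."""
    cfg = bl.SimConfig(mu_burst=70.0, mu_background=0.0, n_preexisting=0,
                       generations=5, burst_window=(1, 4), seed=8,
                       genome_length=5_000_000)
    mset = bl.simulate_clone(cfg)
    df = mset.to_dataframe()
    assert len(df) >= 2000
    assert bl.cosine(bl.profile(df), cfg.burst_signature) >= 0.98


@settings(derandomize=True, max_examples=40)
@given(st.integers(0, 8), st.integers(0, 8), st.integers(0, 8))
def test_enlarging_burst_window_never_decreases_expected_count(a, w, extra):
    g = 8
    b = min(a + w, g)
    cfg = bl.SimConfig(generations=g, burst_window=(a, b), mu_burst=5.0,
                       mu_background=0.5)
    wider = (max(0, a - extra), min(g, b + extra))
    cfg2 = dataclasses.replace(cfg, burst_window=wider)
    assert expected_mutation_count(cfg2) >= expected_mutation_count(cfg)


# ---------------------------------------------------------------------------
# Carrier arithmetic vs the explicit-tree oracle
# ---------------------------------------------------------------------------

def test_carrier_fraction_matches_explicit_tree_oracle():
    cfg = bl.SimConfig(generations=7, mu_burst=3.0, mu_background=0.3,
                       n_preexisting=10, seed=31, genome_length=100_000)
    mset = bl.simulate_clone(cfg)
    leaf_sets = explicit_leaf_mutation_sets(mset, cfg.generations)
    n_leaves = 2 ** cfg.generations
    for m in mset:
        explicit = sum(m in s for s in leaf_sets)
        assert explicit / n_leaves == 2.0 ** -m.generation
        arithmetic = {i for i in range(n_leaves)
                      if bl.carries(m, i, cfg.generations)}
        assert arithmetic == {i for i, s in enumerate(leaf_sets) if m in s}
        assert arithmetic == set(bl.carrier_leaves(m, cfg.generations))


def test_sample_reads_zero_vaf_zero_error_gives_zero_alt(rng):
    total, alt = sample_read_counts(0.0, 100.0, 0.0, rng, size=500)
    assert (alt == 0).all()


def test_sample_reads_heterozygous_at_deep_coverage(rng):
    total, alt = sample_read_counts(0.5, 1e5, 0.0, rng, size=1)
    sd = np.sqrt(0.25 / total[0])
    assert abs(alt[0] / total[0] - 0.5) < 5 * sd


def test_sub_floor_vaf_indistinguishable_from_background(rng):
    """True 0.05% VAF and pure error both stay under the 0.1% floor."""
    t1, a1 = sample_read_counts(0.0005, 1e5, 3e-4, rng, size=1000)
    t0, a0 = sample_read_counts(0.0, 1e5, 3e-4, rng, size=1000)
    above1 = np.mean(a1 / t1 >= 0.001)
    above0 = np.mean(a0 / t0 >= 0.001)
    assert above1 < 0.05 and above0 < 0.05
    assert abs(above1 - above0) < 0.05


def test_parental_somatic_sample_carries_only_preexisting():
    cfg = bl.SimConfig(seed=4, generations=5, mu_burst=5.0, mu_background=0.2,
                       n_preexisting=20, seq_error=0.0)
    mset = bl.simulate_clone(cfg)
    obs = bl.sample_reads(mset, cfg, "wgs", "parental_somatic")
    by_site = {m.site: m for m in mset}
    for o in obs:
        if by_site[o.site].generation == 0:
            assert o.alt_reads > 0 or o.total_reads < 5  # het at 40x
        else:
            assert o.alt_reads == 0


# ---------------------------------------------------------------------------
# Sublines
# ---------------------------------------------------------------------------

def test_every_preexisting_mutation_present_in_every_subline():
    cfg = bl.SimConfig(seed=6, generations=6, mu_burst=2.0, mu_background=0.1,
                       n_preexisting=8, subline_generations=3)
    mset = bl.simulate_clone(cfg)
    pre = {m.site for m in mset if m.generation == 0}
    for leaf in (0, 17, 63):
        sub = bl.derive_subline(mset, cfg, leaf)
        inherited = {m.site for m in sub if m.generation == 0}
        assert pre <= inherited
        assert all(bl.true_vaf(m) == 0.5 for m in sub
                   if m.generation == 0 and m.zygosity == "heterozygous")


def test_first_division_mutation_carried_by_exactly_one_half():
    cfg = bl.SimConfig(seed=1, generations=6)
    m = bl.LineageMutation(site=9, ref="C", alt="A", context="ACA",
                           generation=1, lineage_index=0, is_burst=True)
    half = 2 ** (cfg.generations - 1)
    assert all(bl.carries(m, i, cfg.generations) for i in range(half))
    assert not any(bl.carries(m, i, cfg.generations)
                   for i in range(half, 2 ** cfg.generations))


def test_subline_venn_partition_matches_brute_force_oracle():
    """Shared/specific decomposition of 4 gen-2 subtree sublines vs the oracle."""
    cfg = bl.SimConfig(seed=13, generations=6, mu_burst=4.0,
                       mu_background=0.4, n_preexisting=10,
                       genome_length=100_000)
    mset = bl.simulate_clone(cfg)
    G = cfg.generations
    leaves = [0, 2 ** (G - 2), 2 * 2 ** (G - 2), 3 * 2 ** (G - 2)]
    ids = ["S0", "S1", "S2", "S3"]
    leaf_sets = explicit_leaf_mutation_sets(mset, G)
    oracle = oracle_venn_partition(leaf_sets, leaves, ids)
    calls = {sid: {m.site for m in mset if bl.carries(m, leaf, G)}
             for sid, leaf in zip(ids, leaves)}
    panel = bl.panel_from_calls(calls)
    venn = {k: set(v) for k, v in bl.venn_decompose(panel).items()}
    assert venn == {k: set(v) for k, v in oracle.items()}


def test_derive_subline_rejects_out_of_range_leaf():
    cfg = bl.SimConfig(seed=1, generations=4)
    mset = bl.simulate_clone(cfg)
    with pytest.raises(ValueError):
        bl.derive_subline(mset, cfg, 2 ** 4)
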