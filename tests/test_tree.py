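"""Venn decomposition, perfect-phylogeny reconstruction, edge timelines."""

import numpy as np
import pandas as pd
import pytest

import burstline as bl
from burstline.tree import SublinePanel, _compatible, build_tree, edge_timeline

from conftest import explicit_leaf_mutation_sets, oracle_venn_partition


def _panel(rows: dict, sublines=("A", "B", "C", "D"), parent_obs=None):
    matrix = pd.DataFrame(
        {s: [bool(int(bits[i])) for bits in rows.values()]
         for i, s in enumerate(sublines)},
        index=list(rows.keys()),
    )
    return SublinePanel(matrix, parent_obs)


def test_venn_decompose_basic_enumeration():
    panel = _panel({"s1": "111", "s2": "110", "s3": "100", "s4": "001"},
                   sublines=("A", "B", "C"))
    venn = bl.venn_decompose(panel)
    assert {frozenset(k): set(v) for k, v in venn.items()} == {
        frozenset("ABC"): {"s1"},
        frozenset("AB"): {"s2"},
        frozenset("A"): {"s3"},
        frozenset("C"): {"s4"},
    }


def test_venn_shared_by_all_class():
    panel = _panel({"s1": "1111", "s2": "1111", "s3": "1000"})
    venn = bl.venn_decompose(panel)
    assert set(venn[frozenset("ABCD")]) == {"s1", "s2"}


def test_venn_requires_two_sublines():
    with pytest.raises(ValueError):
        bl.venn_decompose(_panel({"s1": "1"}, sublines=("A",)))


def test_panel_rejects_all_false_rows():
    with pytest.raises(ValueError, match="no subline"):
        _panel({"s1": "0000"})


def test_venn_invariant_to_row_and_column_permutation(rng):
    rows = {f"s{i}": "".join(rng.choice(["0", "1"], 4)) for i in range(20)}
    rows = {k: v for k, v in rows.items() if "1" in v}
    base = {frozenset(k): set(v)
            for k, v in bl.venn_decompose(_panel(rows)).items()}
    shuffled_keys = list(rows)
    rng.shuffle(shuffled_keys)
    perm_panel = _panel({k: rows[k] for k in shuffled_keys})
    perm_panel.matrix = perm_panel.matrix[["C", "A", "D", "B"]]
    perm = {frozenset(k): set(v)
            for k, v in bl.venn_decompose(perm_panel).items()}
    assert base == perm


def test_textbook_perfect_phylogeny():
    """{1111, 1100, 0011} over (A,B,C,D) gives ((A,B),(C,D)) with SNVs on edges."""
    panel = _panel({"root_snv": "1111", "ab_snv": "1100", "cd_snv": "0011"})
    tree = bl.build_tree(panel)
    assert tree.incompatible == []
    assert tree.clades() == {
        frozenset("ABCD"), frozenset("AB"), frozenset("CD"),
        frozenset("A"), frozenset("B"), frozenset("C"), frozenset("D")}
    by_leaves = {n.leaves: n for n in tree.nodes()}
    assert by_leaves[frozenset("ABCD")].edge_snvs in ([], ["root_snv"])
    assert by_leaves[frozenset("AB")].edge_snvs == ["ab_snv"]
    assert by_leaves[frozenset("CD")].edge_snvs == ["cd_snv"]
    # the founder -> all-sublines root edge carries the clone-wide SNVs
    assert tree.root.newick() == "(((A,B)A|B,(C,D)C|D)all)founder;"


def test_leaf_to_root_union_recovers_subline_callset():
    panel = _panel({"s1": "1111", "s2": "1100", "s3": "1000", "s4": "0011",
                    "s5": "0010"})
    tree = bl.build_tree(panel)
    for leaf in "ABCD":
        union = set()
        for node in tree.nodes():
            if leaf in node.leaves:
                union |= set(node.edge_snvs)
        called = set(panel.matrix.index[panel.matrix[leaf]])
        assert union == called


def test_single_flipped_cell_is_the_snv_flagged_incompatible():
    rows = {f"ab{i}": "1100" for i in range(3)}
    rows |= {f"cd{i}": "0011" for i in range(3)}
    rows["flipped"] = "1110"  # one spurious call in subline C
    tree = bl.build_tree(_panel(rows))
    assert tree.incompatible == ["flipped"]
    assert frozenset("AB") in tree.clades() and frozenset("CD") in tree.clades()


def test_conflict_ties_break_toward_lower_parent_vaf():
    rows = {"x": "1100", "y": "1010"}  # mutually incompatible, degree 1 each
    parent = pd.DataFrame({"total": [100, 100], "alt": [40, 2]},
                          index=["x", "y"])
    tree = bl.build_tree(_panel(rows, parent_obs=parent))
    assert tree.incompatible == ["y"]  # the noisier (low-VAF) call goes first


def _laminar_by_sorting(carrier_sets: list[frozenset]) -> bool:
    """Independent laminarity check: sort by size, each set must be contained
    in (or disjoint from) every larger set."""
    ordered = sorted(carrier_sets, key=len, reverse=True)
    for i, small in enumerate(ordered):
        for big in ordered[:i]:
            if small & big and not small <= big:
                return False
    return True


def test_sorted_containment_equals_pairwise_compatibility(rng):
    """On random matrices the sorted nested/disjoint check agrees with the
    pairwise two-character test (standard perfect-phylogeny property)."""
    sublines = list("ABCDEF")
    agree_seen = conflict_seen = False
    for _ in range(200):
        sets = [frozenset(s for s in sublines if rng.random() < 0.4)
                for _ in range(6)]
        sets = [s for s in sets if s]
        if not sets:
            continue
        pairwise = all(_compatible(a, b)
                       for i, a in enumerate(sets) for b in sets[i + 1:])
        assert pairwise == _laminar_by_sorting(sets)
        agree_seen |= pairwise
        conflict_seen |= not pairwise
    assert agree_seen and conflict_seen  # both branches exercised


def test_noiseless_simulated_panels_recover_true_topology(rng):
    """Reconstructed clades equal the carrier subsets of the division tree."""
    for trial in range(50):
        g = int(rng.integers(4, 9))
        cfg = bl.SimConfig(generations=g, mu_burst=4.0, mu_background=0.5,
                           n_preexisting=5, seed=int(rng.integers(2 ** 31)),
                           genome_length=100_000)
        mset = bl.simulate_clone(cfg)
        n_sub = int(rng.integers(3, 7))
        leaves = sorted(rng.choice(2 ** g, size=n_sub, replace=False).tolist())
        ids = [f"S{l}" for l in leaves]
        calls = {sid: {m.site for m in mset if bl.carries(m, leaf, g)}
                 for sid, leaf in zip(ids, leaves)}
        if not any(calls.values()) or not all(calls.values()):
            continue
        panel = bl.panel_from_calls(calls)
        tree = bl.build_tree(panel)
        assert tree.incompatible == []  # truth is conflict-free
        leaf_sets = explicit_leaf_mutation_sets(mset, g)
        oracle = oracle_venn_partition(leaf_sets, leaves, ids)
        expected_clades = ({frozenset(ids)}
                           | {frozenset({s}) for s in ids}
                           | set(oracle))
        assert tree.clades() == expected_clades


def test_edge_timeline_depth_orders_parent_vaf():
    """Deeper (more shared) edges show higher parent VAF; shared edges are
    WGS-detectable while subline-specific ones are not."""
    parent = pd.DataFrame(
        {"total": [40, 40, 40, 40], "alt": [20, 19, 9, 0]},
        index=["s1", "s2", "ab", "a_only"])
    panel = _panel({"s1": "1111", "s2": "1111", "ab": "1100", "a_only": "1000"})
    meta = pd.DataFrame({"ref": ["C", "T", "T", "C"],
                         "alt": ["T", "C", "G", "A"]},
                        index=["s1", "s2", "ab", "a_only"])
    tree = bl.build_tree(panel)
    table = edge_timeline(tree, parent, meta).set_index("node")
    assert table.loc["all", "mean_parent_vaf"] == pytest.approx(39 / 80)
    assert table.loc["all", "wgs_detected_frac"] == 1.0
    assert table.loc["A|B", "mean_parent_vaf"] == pytest.approx(0.225)
    assert table.loc["A|B", "wgs_detected_frac"] == 0.0
    assert (table.loc["all", "ts"], table.loc["all", "tv"]) == (2, 0)
    assert table.loc["A", "n_snvs"] == 1
    # leaves B, C, D carry no edge SNVs: empty summaries
    for leaf in ("B", "C", "D"):
        row = table.loc[leaf]
        assert row["n_snvs"] == 0 and np.isnan(row["mean_parent_vaf"])


def test_build_tree_requires_two_sublines():
    with pytest.raises(ValueError):
        bl.build_tree(_panel({"s1": "1"}, sublines=("A",)))
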