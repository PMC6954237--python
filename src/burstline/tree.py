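"""Shared/specific decomposition of subline call sets and tree building.

Each SNV called across a panel of single-cell-derived sublines is a binary
character that is absent in the clone founder's germline and, barring call
errors, arose exactly once on the clone's division tree. The carrier sets
of such characters form a laminar family (any two are nested or disjoint),
which is precisely the condition for a rooted perfect phylogeny. The
module partitions SNVs by their exact carrier subset (the Venn view),
builds the developmental tree with SNVs attached to edges, and summarises
per-edge parent-clone VAFs — deeper, more widely shared edges carry older,
higher-VAF mutations.

Conflicting characters (call noise) are removed greedily by conflict
degree, ties broken toward lower parent VAF, before tree construction.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
import pandas as pd

from .filters import FilterPolicy, filter_snvs
from .signatures import is_transition


@dataclass
class SublinePanel:
    """Binary SNV-by-subline presence matrix plus parent-clone read counts.

    ``matrix`` is indexed by SNV id with one boolean column per subline;
    ``parent_obs`` (optional) is indexed by SNV id with columns
    ``total``/``alt`` (parent-clone read counts) and optionally
    ``ref``/``alt_base`` for substitution summaries.
    """

    matrix: pd.DataFrame
    parent_obs: pd.DataFrame | None = None

    def __post_init__(self) -> None:
        self.matrix = self.matrix.astype(bool)
        empty = ~self.matrix.any(axis=1)
        if empty.any():
            bad = list(self.matrix.index[empty][:5])
            raise ValueError(f"SNVs called in no subline: {bad}")

    @property
    def sublines(self) -> list[str]:
        return list(self.matrix.columns)


def venn_decompose(panel: SublinePanel) -> dict[frozenset, list]:
    """Partition SNVs by the exact subset of sublines carrying them.

    Returns {frozenset of subline ids: [snv ids]}. SNVs present in every
    subline form the shared-by-all class; singleton subsets are the
    subline-specific classes.
    """
    if len(panel.sublines) < 2:
        raise ValueError("need at least 2 sublines")
    out: dict[frozenset, list] = {}
    for snv_id, row in panel.matrix.iterrows():
        subset = frozenset(row.index[row])
        out.setdefault(subset, []).append(snv_id)
    return out


@dataclass
class TreeNode:
    """Node of the developmental tree; ``edge_snvs`` hang on the edge above it."""

    name: str
    leaves: frozenset
    edge_snvs: list = field(default_factory=list)
    children: list["TreeNode"] = field(default_factory=list)

    def newick(self) -> str:
        def fmt(node: TreeNode) -> str:
            if not node.children:
                return node.name
            inner = ",".join(fmt(c) for c in sorted(
                node.children, key=lambda n: sorted(n.leaves)))
            return f"({inner}){node.name}"
        return fmt(self) + ";"


@dataclass
class DevelopmentalTree:
    """Rooted tree over sublines with SNV sets assigned to edges."""

    root: TreeNode
    incompatible: list = field(default_factory=list)  # SNV ids removed as conflicting

    def nodes(self) -> list[TreeNode]:
        out, stack = [], [self.root]
        while stack:
            n = stack.pop()
            out.append(n)
            stack.extend(n.children)
        return out

    def clades(self) -> set[frozenset]:
        return {n.leaves for n in self.nodes()}

    def edge_table(self) -> pd.DataFrame:
        rows = [
            {"node": n.name, "n_leaves": len(n.leaves),
             "leaves": ",".join(sorted(map(str, n.leaves))),
             "n_snvs": len(n.edge_snvs),
             "snvs": ";".join(map(str, n.edge_snvs))}
            for n in self.nodes() if n is not self.root
        ]
        return pd.DataFrame(rows)


def _compatible(a: frozenset, b: frozenset) -> bool:
    """Rooted two-character compatibility: nested or disjoint carrier sets."""
    return a <= b or b <= a or not (a & b)


def _conflicting_snvs(panel: SublinePanel) -> list:
    """Greedy minimal-cardinality-style removal set of conflicting SNVs.

    Repeatedly removes the SNV with the highest conflict degree; ties are
    broken toward the lower parent-clone VAF (noisier calls first), then
    lexicographically by id for determinism.
    """
    carriers = {snv: frozenset(row.index[row])
                for snv, row in panel.matrix.iterrows()}
    vaf = {}
    if panel.parent_obs is not None:
        for snv in carriers:
            if snv in panel.parent_obs.index:
                r = panel.parent_obs.loc[snv]
                vaf[snv] = r["alt"] / r["total"] if r["total"] > 0 else 0.0
    conflicts = {snv: set() for snv in carriers}
    for a, b in combinations(carriers, 2):
        if not _compatible(carriers[a], carriers[b]):
            conflicts[a].add(b)
            conflicts[b].add(a)
    removed = []
    while True:
        degrees = {s: len(c) for s, c in conflicts.items() if c}
        if not degrees:
            break
        worst = max(degrees.values())
        candidates = [s for s, d in degrees.items() if d == worst]
        victim = min(candidates, key=lambda s: (vaf.get(s, 0.0), str(s)))
        removed.append(victim)
        for other in conflicts.pop(victim):
            conflicts[other].discard(victim)
    return removed


def build_tree(panel: SublinePanel) -> DevelopmentalTree:
    """Reconstruct the developmental tree from the presence matrix.

    If every pair of carrier sets is nested or disjoint the matrix admits a
    rooted perfect phylogeny, returned with SNVs attached to the edge above
    the clade they define; otherwise a greedy set of conflicting SNVs is
    removed first and reported in ``tree.incompatible``.
    """
    sublines = panel.sublines
    if len(sublines) < 2:
        raise ValueError("need at least 2 sublines")
    incompatible = _conflicting_snvs(panel)
    keep = panel.matrix.drop(index=incompatible)

    # group SNVs by carrier set; laminar family after conflict removal
    by_subset: dict[frozenset, list] = {}
    for snv, row in keep.iterrows():
        by_subset.setdefault(frozenset(row.index[row]), []).append(snv)

    all_leaves = frozenset(sublines)
    root = TreeNode(name="founder", leaves=all_leaves)
    # internal nodes: one per distinct carrier subset (plus the root clade)
    subsets = sorted(by_subset, key=lambda s: (-len(s), sorted(s)))
    if all_leaves in by_subset:
        # clone-wide SNVs: edge from the founder to the clade of all sublines
        clade = TreeNode(name="all", leaves=all_leaves,
                         edge_snvs=list(by_subset[all_leaves]))
        root.children.append(clade)
        attach_root = clade
    else:
        attach_root = root
    placed: dict[frozenset, TreeNode] = {all_leaves: attach_root}
    for subset in subsets:
        if subset == all_leaves:
            continue
        node = TreeNode(name="|".join(sorted(map(str, subset))), leaves=subset,
                        edge_snvs=list(by_subset[subset]))
        # parent = smallest already-placed strict superset (laminar => unique chain)
        parent = min((s for s in placed if subset < s), key=len)
        placed[parent].children.append(node)
        placed[subset] = node
    # leaves: attach each subline under the smallest subset containing it
    for leaf in sublines:
        holder = min((s for s in placed if leaf in s), key=len)
        node = placed[holder]
        if node.leaves == frozenset({leaf}) and not node.children:
            node.name = str(leaf)  # singleton clade is the leaf itself
        else:
            node.children.append(TreeNode(name=str(leaf),
                                          leaves=frozenset({leaf})))
    return DevelopmentalTree(root=root, incompatible=incompatible)


def edge_timeline(
    tree: DevelopmentalTree,
    parent_obs: pd.DataFrame,
    snv_meta: pd.DataFrame | None = None,
    policy: FilterPolicy = FilterPolicy(),
) -> pd.DataFrame:
    """Per-edge summary: SNV count, mean parent-clone VAF, ts/tv, WGS yield.

    ``parent_obs`` is indexed by SNV id with ``total``/``alt`` parent read
    counts; ``snv_meta`` (optional, same index) provides ``ref``/``alt``
    base columns for the transition/transversion split. The
    ``wgs_detected_frac`` column reports the fraction of each edge's SNVs
    a conventional WGS filter chain (depth + 35-65% VAF window) would keep
    from the parent-clone counts — the shared edges are recovered, the
    shallow subline-specific ones largely are not.
    """
    rows = []
    for node in tree.nodes():
        if node is tree.root:
            continue
        snvs = node.edge_snvs
        row = {"node": node.name, "n_leaves": len(node.leaves),
               "n_snvs": len(snvs), "mean_parent_vaf": np.nan,
               "ts": 0, "tv": 0, "wgs_detected_frac": np.nan}
        if snvs:
            obs = parent_obs.loc[[s for s in snvs if s in parent_obs.index]]
            if len(obs):
                vafs = obs["alt"] / obs["total"].where(obs["total"] > 0)
                row["mean_parent_vaf"] = float(vafs.mean())
                table = pd.DataFrame({
                    "pos": obs.index, "alt": "N",
                    "depth": obs["total"].astype(int),
                    "alt_count": obs["alt"].astype(int),
                })
                kept, _ = filter_snvs(table, policy)
                row["wgs_detected_frac"] = len(kept) / len(obs)
            if snv_meta is not None:
                meta = snv_meta.loc[[s for s in snvs if s in snv_meta.index]]
                ts = int(sum(is_transition(r, a)
                             for r, a in zip(meta["ref"], meta["alt"])))
                row["ts"], row["tv"] = ts, len(meta) - ts
        rows.append(row)
    return pd.DataFrame(rows)


def panel_from_calls(calls: dict[str, set], parent_obs: pd.DataFrame | None = None
                     ) -> SublinePanel:
    """Build a panel from per-subline call sets ({subline id: set of SNV ids})."""
    all_snvs = sorted(set().union(*calls.values()))
    matrix = pd.DataFrame(
        {sub: [snv in snvs for snv in all_snvs] for sub, snvs in calls.items()},
        index=all_snvs,
    )
    return SublinePanel(matrix=matrix, parent_obs=parent_obs)
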