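"""End-to-end driver: simulate -> filter -> tree -> timeline -> signatures.

Mirrors the study's conceptual flow on synthetic data: expand a clone with
an early hypermutation window, establish single-cell sublines, call each
subline's clonal SNVs through the WGS filter chain, decompose shared vs
subline-specific SNVs and rebuild the developmental tree, measure each
SNV's parent-clone VAF by ultra-deep amplicon counts, classify groups and
estimate origin generations, test burst vs continuous accumulation, and
profile the 96-class signatures per stage. Every stage's outputs are
written to the run directory and recorded in a manifest; re-running with
the same seed reproduces identical files.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .filters import FilterPolicy, filter_snvs, trace_frame
from .signatures import (SignatureProfile, StageBounds, background_signature,
                         signature_17_like, signature_18_like, stage_profiles,
                         tstv)
from .simulate import (LineageMutationSet, SimConfig, derive_subline,
                       observations_to_frame, sample_reads, simulate_clone,
                       write_vcf)
from .timing import (GroupCall, burst_test, classify_group, estimate_vaf,
                     observable_generations)
from .tree import SublinePanel, build_tree, edge_timeline, panel_from_calls, venn_decompose


@dataclass(frozen=True)
class PipelineConfig:
    sim: SimConfig = field(default_factory=SimConfig)
    n_sublines: int = 4
    filter_policy: FilterPolicy = field(default_factory=FilterPolicy)
    stage_bounds: StageBounds = field(default_factory=StageBounds)
    group1_min: float = 0.01
    group2_max: float = 0.01
    w_max: int = 6
    skip_tree: bool = False
    skip_signature: bool = False


@dataclass
class RunManifest:
    config_hash: str
    seed: int
    version: str
    stages: dict = field(default_factory=dict)  # stage -> {files, counts}

    def to_json(self) -> str:
        return json.dumps(dataclasses.asdict(self), indent=2, sort_keys=True)


def _config_hash(config: PipelineConfig) -> str:
    from .simulate import config_to_dict
    d = dataclasses.asdict(config)
    d["sim"] = config_to_dict(config.sim)
    for k in ("known_sites", "sister_clones"):
        d["filter_policy"][k] = sorted(map(str, d["filter_policy"][k]))
    blob = json.dumps(d, sort_keys=True, default=str).encode()
    return hashlib.sha256(blob).hexdigest()[:16]


def choose_subline_leaves(generations: int, n_sublines: int) -> list[int]:
    """Evenly spaced final-generation cells, one per 2**ceil(log2 n) subtree."""
    n_leaves = 2 ** generations
    if n_sublines > n_leaves:
        raise ValueError("more sublines than final cells")
    step = n_leaves // n_sublines
    return [i * step for i in range(n_sublines)]


def call_subline_snvs(
    sub_mset: LineageMutationSet,
    config: SimConfig,
    policy: FilterPolicy,
    parental_lookup: dict,
    rng: np.random.Generator,
) -> tuple[set, pd.DataFrame]:
    """Call a subline's clonal SNVs from its WGS counts via the filter chain."""
    obs = sample_reads(sub_mset, sub_mset.config, assay="wgs",
                       sample="parent", rng=rng)
    by_site = {m.site: m for m in sub_mset}
    table = pd.DataFrame({
        "chrom": "sim1",
        "pos": [o.site for o in obs],
        "ref": [by_site[o.site].ref for o in obs],
        "alt": [by_site[o.site].alt for o in obs],
        "depth": [o.total_reads for o in obs],
        "alt_count": [o.alt_reads for o in obs],
        "chrom_class": ["hemizygous" if by_site[o.site].zygosity == "hemizygous"
                        else "autosome" for o in obs],
    })
    kept, traces = filter_snvs(table, policy, parental_lookup)
    return set(kept["pos"]), trace_frame(traces)


def run_pipeline(config: PipelineConfig, out_dir) -> RunManifest:
    """Run every stage on a simulated clone and write a run report.

    Returns the manifest; raises on any stage failure (the CLI maps that
    to a non-zero exit naming the stage).
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    sim = config.sim
    manifest = RunManifest(config_hash=_config_hash(config), seed=sim.seed,
                           version=__version__)
    rng = np.random.default_rng(np.random.SeedSequence([sim.seed, 7_001]))

    # --- simulate ---------------------------------------------------------
    mset = simulate_clone(sim)
    truth_vcf = out / "truth.vcf"
    write_vcf(mset, truth_vcf)
    by_site = {m.site: m for m in mset}
    manifest.stages["simulate"] = {
        "files": [str(truth_vcf)],
        "counts": {"mutations": len(mset),
                   "burst": sum(m.is_burst for m in mset),
                   "preexisting": sum(m.generation == 0 for m in mset)},
    }

    # --- parental somatic WGS (pre-existing exclusion) --------------------
    parental_obs = sample_reads(mset, sim, assay="wgs",
                                sample="parental_somatic", rng=rng)
    parental_lookup = {("sim1", o.site): o.alt_reads for o in parental_obs}

    # --- sublines: derive, sequence, call ---------------------------------
    leaves = choose_subline_leaves(sim.generations, config.n_sublines)
    calls: dict[str, set] = {}
    for leaf in leaves:
        sub = derive_subline(mset, sim, leaf)
        called, _ = call_subline_snvs(sub, sim, config.filter_policy,
                                      parental_lookup, rng)
        calls[f"S{leaf}"] = called
    discovered = sorted(set().union(*calls.values()))
    manifest.stages["sublines"] = {
        "files": [],
        "counts": {f"S{leaf}": len(calls[f"S{leaf}"]) for leaf in leaves}
        | {"discovered": len(discovered)},
    }

    # --- parent amplicon VAFs --------------------------------------------
    parent_sites = {m.site for m in mset}
    extra = [s for s in discovered if s not in parent_sites]
    amp_obs = sample_reads(mset, sim, assay="amplicon", sample="parent",
                           rng=rng, extra_sites=extra)
    amp_by_site = {o.site: o for o in amp_obs}
    amp_tsv = out / "parent_amplicon.tsv"
    observations_to_frame(amp_obs).to_csv(amp_tsv, sep="\t", index=False)

    # --- venn + developmental tree ----------------------------------------
    if not config.skip_tree:
        parent_counts = pd.DataFrame(
            {"total": [amp_by_site[s].total_reads for s in discovered],
             "alt": [amp_by_site[s].alt_reads for s in discovered]},
            index=discovered)
        panel = panel_from_calls(calls, parent_counts)
        venn = venn_decompose(panel)
        tree = build_tree(panel)
        snv_meta = pd.DataFrame(
            {"ref": [by_site[s].ref if s in by_site else "N" for s in discovered],
             "alt": [by_site[s].alt if s in by_site else "N" for s in discovered]},
            index=discovered)
        edges = edge_timeline(tree, parent_counts, snv_meta,
                              config.filter_policy)
        panel_tsv, tree_nwk, edges_tsv = (out / "panel.tsv", out / "tree.nwk",
                                          out / "edges.tsv")
        panel.matrix.to_csv(panel_tsv, sep="\t")
        tree_nwk.write_text(tree.root.newick() + "\n")
        edges.to_csv(edges_tsv, sep="\t", index=False)
        manifest.stages["tree"] = {
            "files": [str(panel_tsv), str(tree_nwk), str(edges_tsv)],
            "counts": {"venn_subsets": len(venn),
                       "incompatible": len(tree.incompatible)},
        }

    # --- timing: groups, origin generations, burst test -------------------
    de_novo = [s for s in discovered
               if parental_lookup.get(("sim1", s), 0) < 2]
    group_calls: list[GroupCall] = []
    timeline_rows = []
    for s in de_novo:
        est = estimate_vaf(amp_by_site[s], sim.vaf_floor)
        m = by_site.get(s)
        call = classify_group(est, m.ref if m else None, m.alt if m else None,
                              config.group1_min, config.group2_max)
        group_calls.append(call)
        timeline_rows.append({
            "site": s, "vaf": est.vaf, "ci_low": est.ci_low,
            "ci_high": est.ci_high, "censored": est.censored,
            "group": call.group, "substitution": call.substitution or "",
            "k_hat": call.k_hat if call.k_hat is not None else "",
            "true_generation": m.generation if m else "",
        })
    g_max = min(observable_generations(sim.vaf_floor), sim.generations)
    result = burst_test(group_calls, g_max, w_max=config.w_max)
    timeline_tsv = out / "timeline.tsv"
    pd.DataFrame(timeline_rows).to_csv(timeline_tsv, sep="\t", index=False)
    verdict_json = out / "verdict.json"
    verdict_json.write_text(json.dumps({
        "verdict": result.verdict,
        "delta_aic": result.delta_aic,
        "burst_window": list(result.burst_window) if result.burst_window else None,
        "mu_continuous": result.mu_continuous,
        "mu_burst": result.mu_burst,
        "mu_outside": result.mu_outside,
        "generation_counts": list(result.counts),
    }, indent=2) + "\n")
    manifest.stages["timeline"] = {
        "files": [str(timeline_tsv), str(verdict_json)],
        "counts": {"de_novo": len(de_novo),
                   "group_I": sum(c.group == "I" for c in group_calls),
                   "group_II": sum(c.group == "II" for c in group_calls),
                   "censored": sum(c.group == "censored" for c in group_calls),
                   "verdict": result.verdict},
    }

    # --- stage-wise signature profiles -------------------------------------
    if not config.skip_signature:
        # profile everything with known context: discovered + the clone-wide set
        snvs = mset.to_dataframe()
        amp_total = np.array([amp_by_site[m.site].total_reads for m in mset])
        amp_alt = np.array([amp_by_site[m.site].alt_reads for m in mset])
        snvs["vaf"] = np.where(amp_total > 0, amp_alt / np.maximum(amp_total, 1), 0.0)
        snvs["parental_alt"] = [parental_lookup.get(("sim1", m.site), 0)
                                for m in mset]
        refs = [signature_17_like(), signature_18_like(), background_signature()]
        profiles, table = stage_profiles(snvs, refs, config.stage_bounds)
        stage_csv = out / "stage_cosine.csv"
        table.to_csv(stage_csv)
        ratio, ts, tv = tstv(snvs)
        manifest.stages["signature"] = {
            "files": [str(stage_csv)],
            "counts": {"stages": list(profiles),
                       "tv_ts_ratio": None if np.isnan(ratio) else
                       ("inf" if np.isinf(ratio) else round(ratio, 3)),
                       "ts": ts, "tv": tv},
        }

    # --- summary + manifest -------------------------------------------------
    summary = out / "summary.txt"
    with open(summary, "w") as fh:
        fh.write(f"burstline run (seed {sim.seed})\n")
        for stage, info in manifest.stages.items():
            fh.write(f"[{stage}] {json.dumps(info['counts'], default=str)}\n")
    manifest_path = out / "manifest.json"
    manifest_path.write_text(manifest.to_json() + "\n")
    return manifest
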