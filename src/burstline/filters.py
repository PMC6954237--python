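"""Post-call SNV and INDEL filter chains.

Pure functions over variant tables that reproduce the published exclusion
rules applied after base-level calling: minimum depth, parental sharing,
known-variant (dbSNP-style) sites, sister-clone sharing, repeat-flanked
sites, and a clonal-heterozygous VAF window (35-65% on autosomes, >=75%
hemizygous for SNVs; depth >=20 and alt count >=10 with a 30-70% window,
>=70% hemizygous, for INDELs). Every per-variant decision is recorded in a
trace; the verdict is the conjunction of all stages.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

SNV_REQUIRED = ("depth", "alt_count")
SNV_STAGES = ("depth", "parental", "known", "sister", "repeat", "vaf_window")
INDEL_STAGES = ("depth", "min_count", "parental", "known", "sister", "repeat",
                "vaf_window")


@dataclass(frozen=True)
class FilterPolicy:
    """Thresholds of the SNV and INDEL filter chains."""

    min_depth: int = 20
    snv_vaf_window: tuple[float, float] = (0.35, 0.65)
    snv_hemizygous_min: float = 0.75
    indel_min_depth: int = 20
    indel_min_count: int = 10
    indel_vaf_window: tuple[float, float] = (0.30, 0.70)
    indel_hemizygous_min: float = 0.70
    parental_max_alt: int = 1      # exclude when parental alt reads >= 2
    known_sites: frozenset = frozenset()        # {(chrom, pos, alt), ...}
    sister_clones: tuple = ()                   # per-sister sets of (chrom, pos, alt)

    def __post_init__(self) -> None:
        for lo, hi in (self.snv_vaf_window, self.indel_vaf_window):
            if not (0 <= lo <= hi <= 1):
                raise ValueError("VAF windows must lie within [0, 1]")
        if min(self.min_depth, self.indel_min_depth, self.indel_min_count,
               self.parental_max_alt) < 0:
            raise ValueError("count thresholds must be >= 0")


@dataclass
class FilterTrace:
    """Ordered per-stage decisions for one variant."""

    variant_id: object
    stages: list[tuple[str, bool]] = field(default_factory=list)
    verdict: str = "pass"  # "pass" | "fail" | "error"
    error: str | None = None

    def record(self, name: str, passed: bool) -> None:
        self.stages.append((name, bool(passed)))
        if not passed:
            self.verdict = "fail"

    @property
    def failed_stages(self) -> list[str]:
        return [name for name, ok in self.stages if not ok]


def _variant_key(row: pd.Series) -> tuple:
    return (row.get("chrom", "sim1"), row["pos"], row["alt"])


def _parental_alt_lookup(parental_obs) -> dict:
    """Accept a DataFrame (chrom?/pos/alt?/alt_count or alt) or a dict."""
    if parental_obs is None:
        return {}
    if isinstance(parental_obs, dict):
        return dict(parental_obs)
    df = parental_obs
    count_col = "alt_count" if "alt_count" in df.columns else "alt"
    lookup = {}
    for _, row in df.iterrows():
        key = (row.get("chrom", "sim1"), row["pos"])
        lookup[key] = int(row[count_col])
    return lookup


def _run_chain(variants: pd.DataFrame, policy: FilterPolicy, parental_obs,
               *, indel: bool) -> tuple[pd.DataFrame, list[FilterTrace]]:
    min_depth = policy.indel_min_depth if indel else policy.min_depth
    window = policy.indel_vaf_window if indel else policy.snv_vaf_window
    hemi_min = policy.indel_hemizygous_min if indel else policy.snv_hemizygous_min
    parental = _parental_alt_lookup(parental_obs)
    sisters = [set(s) for s in policy.sister_clones]

    traces: list[FilterTrace] = []
    keep_mask = []
    for idx, row in variants.iterrows():
        trace = FilterTrace(variant_id=idx)
        traces.append(trace)
        missing = [c for c in ("pos", "alt", *SNV_REQUIRED) if c not in row
                   or pd.isna(row[c])]
        if missing:
            trace.verdict = "error"
            trace.error = f"missing required field(s): {', '.join(missing)}"
            keep_mask.append(False)
            continue
        depth, alt_count = int(row["depth"]), int(row["alt_count"])
        key3 = _variant_key(row)
        key2 = key3[:2]
        hemizygous = str(row.get("chrom_class", "autosome")) == "hemizygous"
        vaf = alt_count / depth if depth > 0 else 0.0

        trace.record("depth", depth >= min_depth)
        if indel:
            trace.record("min_count", alt_count >= policy.indel_min_count)
        trace.record("parental",
                     parental.get(key2, 0) <= policy.parental_max_alt)
        trace.record("known", key3 not in policy.known_sites)
        trace.record("sister", not any(key3 in s for s in sisters))
        trace.record("repeat", not bool(row.get("repeat_flag", False)))
        if hemizygous:
            trace.record("vaf_window", vaf >= hemi_min)
        else:
            trace.record("vaf_window", window[0] <= vaf <= window[1])
        keep_mask.append(trace.verdict == "pass")
    kept = variants.loc[keep_mask] if len(variants) else variants
    return kept, traces


def filter_snvs(variants: pd.DataFrame, policy: FilterPolicy = FilterPolicy(),
                parental_obs=None) -> tuple[pd.DataFrame, list[FilterTrace]]:
    """Apply the SNV chain: depth -> parental -> known -> sister -> repeat -> VAF.

    ``variants`` needs columns pos, alt, depth, alt_count; optional chrom,
    chrom_class ("autosome"/"hemizygous"), repeat_flag. ``parental_obs``
    maps (chrom, pos) to parental alt read counts (dict or DataFrame).
    Variants with missing required fields get an "error" verdict in the
    trace and are not kept, never silently dropped.
    """
    return _run_chain(variants, policy, parental_obs, indel=False)


def filter_indels(variants: pd.DataFrame, policy: FilterPolicy = FilterPolicy(),
                  parental_obs=None) -> tuple[pd.DataFrame, list[FilterTrace]]:
    """Apply the INDEL chain (adds the minimum alt-count stage and INDEL windows)."""
    return _run_chain(variants, policy, parental_obs, indel=True)


def trace_frame(traces: list[FilterTrace]) -> pd.DataFrame:
    """Flatten traces to a tidy per-variant table (one column per stage)."""
    rows = []
    for t in traces:
        row = {"variant_id": t.variant_id, "verdict": t.verdict,
               "error": t.error or ""}
        for name, ok in t.stages:
            row[name] = ok
        rows.append(row)
    return pd.DataFrame(rows)


def repeat_flag_from_sequence(sequence: str, pos: int, flank: int = 5) -> bool:
    """Flag a site whose flanks look homopolymeric or simple-repeat-like.

    ``pos`` is 1-based within ``sequence``. A site is flagged when the
    +-``flank`` bp neighbourhood contains a homopolymer run of length >= 5
    or >= 3 tandem copies of a 1-2 bp unit. Used when actual sequence is
    available; otherwise supply a precomputed ``repeat_flag`` column.
    """
    lo = max(0, pos - 1 - flank)
    hi = min(len(sequence), pos + flank)
    window = sequence[lo:hi].upper()
    run, best = 1, 1
    for a, b in zip(window, window[1:]):
        run = run + 1 if a == b else 1
        best = max(best, run)
    if best >= 5:
        return True
    for unit in (1, 2):
        for start in range(len(window) - 3 * unit + 1):
            u = window[start:start + unit]
            if unit == 2 and u[0] == u[1]:
                continue
            if window[start:start + 3 * unit] == u * 3:
                return True
    return False
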