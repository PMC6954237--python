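"""Clonal-expansion simulator with a transient early hypermutation window.

The clone grows as a complete binary division tree: the founder is
generation 0 and after G synchronous divisions there are 2**G cells. Each
division of each cell acquires a Poisson number of new point mutations; the
per-division rate is ``mu_burst`` inside the burst window (modelling the
transient checkpoint-deficient divisions early in reprogramming) and
``mu_background`` outside it. A mutation arising at generation k in cell i
is carried by exactly the 2**(G-k) descendant leaves of that cell, so its
carrier fraction is 2**-k and its true heterozygous VAF is 2**-(k+1): the
founder's own pre-existing variants sit at 50% VAF, first-division
mutations at 25%, and so on.

Mutations are indexed by ``(generation, lineage_index)`` instead of an
explicit cell tree, which keeps G = 20+ tractable; for small G the leaf
set of a mutation can still be enumerated exactly. Read counts for WGS and
ultra-deep amplicon assays are drawn Poisson/binomial with a uniform
miscall probability spread over the three non-reference bases.
"""

from __future__ import annotations

import dataclasses
import json
import zlib
from dataclasses import dataclass, field
from fractions import Fraction
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .signatures import (
    BASES,
    CLASS_LABELS,
    SignatureProfile,
    background_signature,
    revcomp,
    signature_17_like,
)

_ZYGOSITIES = ("heterozygous", "hemizygous")


@dataclass(frozen=True)
class SimConfig:
    """Parameters of one simulated clonal expansion.

    Defaults model the study conditions: a ~10-division clone whose first
    few divisions (window [1, 4], the days-2-3 checkpoint-deficient phase)
    mutate at 100x the background rate with a transversion-biased
    (Sig17-like) signature, on top of transition-biased background
    mutagenesis; founder carries 200 pre-existing heterozygous variants;
    WGS at ~40x, amplicons at ~1e5 reads with a 0.1% VAF detection floor.
    """

    genome_length: int = 1_000_000
    generations: int = 10
    burst_window: tuple[int, int] = (1, 4)
    mu_background: float = 0.2
    mu_burst: float = 20.0
    n_preexisting: int = 200
    burst_signature: SignatureProfile = field(default_factory=signature_17_like)
    background_signature: SignatureProfile = field(default_factory=background_signature)
    wgs_depth: float = 40.0
    amplicon_reads: float = 100_000.0
    seq_error: float = 3e-4
    vaf_floor: float = 0.001
    seed: int = 0
    sex_chromosome_fraction: float = 0.0
    subline_generations: int = 14  # single-cell subline expansion (~14-16 days)

    def __post_init__(self) -> None:
        k1, k2 = self.burst_window
        if not (0 <= k1 <= k2 <= self.generations):
            raise ValueError(f"burst_window {self.burst_window} must satisfy "
                             f"0 <= k1 <= k2 <= G={self.generations}")
        if not (self.mu_burst >= self.mu_background >= 0):
            raise ValueError("require mu_burst >= mu_background >= 0")
        if not (0 < self.vaf_floor < 0.5):
            raise ValueError("vaf_floor must lie in (0, 0.5)")
        if not (0 <= self.sex_chromosome_fraction <= 1):
            raise ValueError("sex_chromosome_fraction must lie in [0, 1]")
        if not (0 <= self.seq_error < 0.5):
            raise ValueError("seq_error must lie in [0, 0.5)")
        if self.genome_length <= 0 or self.generations < 0:
            raise ValueError("genome_length and generations must be positive")


@dataclass(frozen=True)
class LineageMutation:
    """One mutation tagged with its origin cell on the division tree."""

    site: int                # 1-based position on the virtual contig
    ref: str
    alt: str
    context: str             # 3-mer centred on the site, middle base == ref
    generation: int          # k; 0 = pre-existing in the founder
    lineage_index: int       # carrying cell at generation k, in [0, 2**k)
    is_burst: bool
    zygosity: str = "heterozygous"

    def __post_init__(self) -> None:
        if self.generation < 0:
            raise ValueError("generation must be >= 0")
        if not (0 <= self.lineage_index < 2 ** self.generation):
            raise ValueError(
                f"lineage_index {self.lineage_index} out of [0, 2^{self.generation})")
        if self.zygosity not in _ZYGOSITIES:
            raise ValueError(f"unknown zygosity {self.zygosity!r}")


@dataclass
class LineageMutationSet:
    """A simulated clone's ground-truth mutation catalogue."""

    mutations: list[LineageMutation]
    config: SimConfig

    def __len__(self) -> int:
        return len(self.mutations)

    def __iter__(self):
        return iter(self.mutations)

    def to_dataframe(self) -> pd.DataFrame:
        rows = [dataclasses.asdict(m) for m in self.mutations]
        cols = ["site", "ref", "alt", "context", "generation",
                "lineage_index", "is_burst", "zygosity"]
        return pd.DataFrame(rows, columns=cols)


@dataclass(frozen=True)
class ReadObservation:
    """Read counts for one site in one sample/assay."""

    site: int
    total_reads: int
    alt_reads: int
    assay: str               # "wgs" | "amplicon"
    sample: str              # "parent" | "parental_somatic" | subline id

    def __post_init__(self) -> None:
        if not (0 <= self.alt_reads <= self.total_reads):
            raise ValueError("require 0 <= alt_reads <= total_reads")


def true_vaf(m: LineageMutation) -> float:
    """Exact allele frequency of a mutation in the final clone.

    A generation-k mutation is carried by a 2**-k fraction of cells; on an
    autosome (heterozygous) that is a 2**-(k+1) allele fraction, on a
    hemizygous sex-chromosome site 2**-k. Powers of two are exact in
    binary floating point, so the result is exact.
    """
    f = Fraction(1, 2 ** m.generation)
    if m.zygosity == "heterozygous":
        f /= 2
    return float(f)


def expected_mutation_count(config: SimConfig) -> float:
    """Closed-form expected number of de novo + pre-existing mutations."""
    k1, k2 = config.burst_window
    total = float(config.n_preexisting)
    for k in range(1, config.generations + 1):
        mu = config.mu_burst if k1 <= k <= k2 else config.mu_background
        total += 2 ** k * mu
    return total


def _draw_sites(rng: np.random.Generator, n: int, genome_length: int,
                taken: set[int]) -> np.ndarray:
    """Draw n unique 1-based sites not already in `taken` (resample collisions)."""
    if n == 0:
        return np.empty(0, dtype=np.int64)
    sites: list[int] = []
    seen = set(taken)
    while len(sites) < n:
        for s in rng.integers(1, genome_length + 1, size=2 * (n - len(sites))):
            s = int(s)
            if s not in seen:
                seen.add(s)
                sites.append(s)
                if len(sites) == n:
                    break
    return np.asarray(sites, dtype=np.int64)


def _draw_mutations(
    rng: np.random.Generator,
    n: int,
    generation: int,
    is_burst: bool,
    signature: SignatureProfile,
    config: SimConfig,
    taken: set[int],
) -> list[LineageMutation]:
    """Materialise n mutations at one generation with signature-drawn classes."""
    if n == 0:
        return []
    sites = _draw_sites(rng, n, config.genome_length, taken)
    taken.update(int(s) for s in sites)
    classes = rng.choice(96, size=n, p=signature.weights)
    lineages = rng.integers(0, 2 ** generation, size=n)
    flip = rng.random(n) < 0.5  # record on the purine strand half the time
    hemi = rng.random(n) < config.sex_chromosome_fraction
    out = []
    for site, ci, li, fl, hz in zip(sites, classes, lineages, flip, hemi):
        lab = CLASS_LABELS[ci]
        ref, alt = lab[2], lab[4]
        context = lab[0] + lab[2] + lab[6]
        if fl:
            ref, alt, context = revcomp(ref), revcomp(alt), revcomp(context)
        out.append(LineageMutation(
            site=int(site), ref=ref, alt=alt, context=context,
            generation=generation, lineage_index=int(li),
            is_burst=bool(is_burst),
            zygosity="hemizygous" if hz else "heterozygous",
        ))
    return out


def simulate_clone(config: SimConfig,
                   rng: np.random.Generator | None = None) -> LineageMutationSet:
    """Simulate one clonal expansion under the burst/background model.

    Per generation k in [1, G] the number of new mutations is
    Poisson(2**k * mu_k); each gets a uniform carrying cell. Pre-existing
    founder variants are generation 0 and draw their classes from the
    background signature. All sites are unique (infinite-sites; collisions
    resampled). Deterministic for a given config.seed when rng is None.
    """
    if expected_mutation_count(config) > config.genome_length:
        raise ValueError("expected mutation count exceeds genome_length; "
                         "infinite-sites model would be violated")
    if rng is None:
        rng = np.random.default_rng(config.seed)
    taken: set[int] = set()
    muts = _draw_mutations(rng, config.n_preexisting, 0, False,
                           config.background_signature, config, taken)
    k1, k2 = config.burst_window
    for k in range(1, config.generations + 1):
        in_burst = k1 <= k <= k2
        mu = config.mu_burst if in_burst else config.mu_background
        n_k = int(rng.poisson(2 ** k * mu))
        muts.extend(_draw_mutations(rng, n_k, k, in_burst,
                                    config.burst_signature if in_burst
                                    else config.background_signature,
                                    config, taken))
    return LineageMutationSet(muts, config)


# ---------------------------------------------------------------------------
# Carrier arithmetic and sublines
# ---------------------------------------------------------------------------

def carries(m: LineageMutation, leaf_index: int, generations: int) -> bool:
    """Whether final-generation cell `leaf_index` descends from m's origin cell."""
    if not (0 <= leaf_index < 2 ** generations):
        raise ValueError(f"leaf_index {leaf_index} out of [0, 2^{generations})")
    return leaf_index // 2 ** (generations - m.generation) == m.lineage_index


def carrier_leaves(m: LineageMutation, generations: int) -> range:
    """The contiguous block of final-generation cells carrying m."""
    width = 2 ** (generations - m.generation)
    return range(m.lineage_index * width, (m.lineage_index + 1) * width)


def derive_subline(
    mset: LineageMutationSet,
    config: SimConfig,
    leaf_index: int,
    subline_generations: int | None = None,
    rng: np.random.Generator | None = None,
) -> LineageMutationSet:
    """Expand one final-generation cell into a single-cell subline.

    The subline founder carries exactly the parent-clone mutations present
    in that cell — all now clonal in the subline (generation 0, VAF 0.5) —
    and the subline then accrues its own background mutations over
    ``subline_generations`` divisions at ``mu_background``.
    """
    G = config.generations
    if not (0 <= leaf_index < 2 ** G):
        raise ValueError(f"leaf_index {leaf_index} out of [0, 2^{G})")
    if subline_generations is None:
        subline_generations = config.subline_generations
    if rng is None:
        rng = np.random.default_rng(
            np.random.SeedSequence([config.seed, 1 + leaf_index]))
    inherited = [
        dataclasses.replace(m, generation=0, lineage_index=0)
        for m in mset if carries(m, leaf_index, G)
    ]
    sub_config = dataclasses.replace(
        config, generations=subline_generations,
        burst_window=(0, 0), mu_burst=config.mu_background)
    taken = {m.site for m in mset}
    muts = list(inherited)
    for k in range(1, subline_generations + 1):
        n_k = int(rng.poisson(2 ** k * config.mu_background))
        muts.extend(_draw_mutations(rng, n_k, k, False,
                                    config.background_signature, sub_config, taken))
    return LineageMutationSet(muts, sub_config)


# ---------------------------------------------------------------------------
# Read sampling
# ---------------------------------------------------------------------------

def sample_read_counts(
    vaf: np.ndarray | float,
    depth: float,
    seq_error: float,
    rng: np.random.Generator,
    size: int | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Draw (total, alt) read counts at sites with true allele frequency `vaf`.

    total ~ Poisson(depth); alt ~ Binomial(total, v*(1-e) + (1-v)*e/3) —
    a miscall lands on a specific wrong base a third of the time.
    """
    v = np.atleast_1d(np.asarray(vaf, dtype=float))
    if size is not None and v.size == 1:
        v = np.full(size, v[0])
    p = v * (1 - seq_error) + (1 - v) * seq_error / 3
    total = rng.poisson(depth, size=v.shape)
    alt = rng.binomial(total, p)
    return total, alt


def _vaf_in_sample(m: LineageMutation, sample: str, config: SimConfig) -> float:
    if sample == "parent":
        return true_vaf(m)
    if sample == "parental_somatic":
        # pre-existing variants came in with the founder's somatic genome
        if m.generation == 0 and not m.is_burst:
            return 1.0 if m.zygosity == "hemizygous" else 0.5
        return 0.0
    if sample.startswith("subline:"):
        leaf = int(sample.split(":", 1)[1])
        if carries(m, leaf, config.generations):
            return 1.0 if m.zygosity == "hemizygous" else 0.5
        return 0.0
    raise ValueError(f"unknown sample {sample!r}")


def sample_reads(
    mset: LineageMutationSet,
    config: SimConfig,
    assay: str,
    sample: str = "parent",
    rng: np.random.Generator | None = None,
    extra_sites: Sequence[int] = (),
) -> list[ReadObservation]:
    """Emit read-count observations for every mutation site in one sample.

    ``extra_sites`` adds non-mutated positions (true VAF 0), useful for
    error-only background. ``assay`` selects wgs_depth or amplicon_reads.
    """
    if assay == "wgs":
        depth = config.wgs_depth
    elif assay == "amplicon":
        depth = config.amplicon_reads
    else:
        raise ValueError(f"assay must be 'wgs' or 'amplicon', got {assay!r}")
    if rng is None:
        tag = zlib.crc32(f"{assay}:{sample}".encode()) % 2**31
        rng = np.random.default_rng(np.random.SeedSequence([config.seed, tag]))
    sites = [m.site for m in mset] + list(extra_sites)
    vafs = np.array([_vaf_in_sample(m, sample, config) for m in mset]
                    + [0.0] * len(extra_sites))
    total, alt = sample_read_counts(vafs, depth, config.seq_error, rng)
    return [
        ReadObservation(site=int(s), total_reads=int(t), alt_reads=int(a),
                        assay=assay, sample=sample)
        for s, t, a in zip(sites, total, alt)
    ]


def observations_to_frame(obs: Iterable[ReadObservation]) -> pd.DataFrame:
    return pd.DataFrame(
        [(o.site, o.sample, o.assay, o.total_reads, o.alt_reads) for o in obs],
        columns=["site", "sample", "assay", "total", "alt"],
    )


# ---------------------------------------------------------------------------
# File output (VCF v4.2 + TSV) and config (de)serialisation
# ---------------------------------------------------------------------------

_VCF_HEADER = """\
##fileformat=VCFv4.2
##source=burstline
##contig=<ID=sim1,length={length}>
##INFO=<ID=GT_GEN,Number=1,Type=Integer,Description="Generation at which the mutation arose (0 = pre-existing)">
##INFO=<ID=LINEAGE,Number=1,Type=Integer,Description="Carrying cell index at the origin generation">
##INFO=<ID=BURST,Number=0,Type=Flag,Description="Arose inside the hypermutation window">
##INFO=<ID=CONTEXT,Number=1,Type=String,Description="Trinucleotide context centred on the site">
##INFO=<ID=ZYG,Number=1,Type=String,Description="heterozygous or hemizygous">
#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO
"""


def write_vcf(mset: LineageMutationSet, path) -> None:
    """Write the ground-truth catalogue as a plain-text VCF v4.2."""
    with open(path, "w", newline="\n") as fh:
        fh.write(_VCF_HEADER.format(length=mset.config.genome_length))
        for m in sorted(mset.mutations, key=lambda m: m.site):
            info = (f"GT_GEN={m.generation};LINEAGE={m.lineage_index}"
                    + (";BURST" if m.is_burst else "")
                    + f";CONTEXT={m.context};ZYG={m.zygosity}")
            fh.write(f"sim1\t{m.site}\t.\t{m.ref}\t{m.alt}\t.\tPASS\t{info}\n")


def write_read_counts(obs: Iterable[ReadObservation], path) -> None:
    observations_to_frame(obs).to_csv(path, sep="\t", index=False)


def config_to_dict(config: SimConfig) -> dict:
    d = dataclasses.asdict(config)
    d["burst_window"] = list(config.burst_window)
    d["burst_signature"] = config.burst_signature.label
    d["background_signature"] = config.background_signature.label
    return d


def save_config(config: SimConfig, path) -> None:
    with open(path, "w") as fh:
        json.dump(config_to_dict(config), fh, indent=2)


def load_config(path) -> SimConfig:
    """Load a SimConfig from flat JSON (or TOML when the suffix is .toml)."""
    p = str(path)
    if p.endswith(".toml"):
        import tomllib
        with open(path, "rb") as fh:
            d = tomllib.load(fh)
    else:
        with open(path) as fh:
            d = json.load(fh)
    return config_from_dict(d)


_NAMED_SIGNATURES = {
    "Sig17-like (synthetic)": signature_17_like,
    "Sig18-like (synthetic)": None,  # filled lazily below
    "background (synthetic)": background_signature,
    "sig17": signature_17_like,
    "background": background_signature,
}


def config_from_dict(d: dict) -> SimConfig:
    from .signatures import signature_18_like
    _NAMED_SIGNATURES["Sig18-like (synthetic)"] = signature_18_like
    _NAMED_SIGNATURES["sig18"] = signature_18_like
    d = dict(d)
    if "burst_window" in d:
        d["burst_window"] = tuple(d["burst_window"])
    for key in ("burst_signature", "background_signature"):
        if isinstance(d.get(key), str):
            builder = _NAMED_SIGNATURES.get(d[key])
            if builder is None:
                raise ValueError(f"unknown signature name {d[key]!r}")
            d[key] = builder()
    return SimConfig(**d)
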