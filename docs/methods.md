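# Methods

## The carrier model

burstline models a clone growing from a single founder cell by `G`
synchronous binary divisions with no cell death or selection: after
generation `k` there are `2^k` cells, and the final population holds
`2^G`. A point mutation arising in one cell at generation `k` is inherited
by all of that cell's descendants and by nothing else, so it is carried by
exactly a `2^-k` fraction of final cells. On an autosome the mutation sits
on one of two homologous chromosomes, giving a true variant allele
frequency (VAF)

    vaf(k) = 2^-(k+1)        (heterozygous; 2^-k for hemizygous sites).

Pre-existing founder variants (`k = 0`) therefore sit at exactly 50% VAF —
present in every cell of the clone — first-division mutations at 25%, and
each later generation halves again. This VAF ladder is the entire basis of
the timing analysis: a deep-enough allele-frequency measurement dates a
mutation's origin division.

Mutations are stored as `(generation k, lineage_index i)` pairs rather
than on an explicit cell tree; cell `j` of the final generation carries
the mutation iff `floor(j / 2^(G-k)) == i`. This makes `G = 20+`
expansions cheap while remaining exactly equivalent to explicit leaf
enumeration, which the tests re-derive independently for `G <= 12` by
materialising every cell and propagating mutation sets through divisions.

## The mutation process

Each division of each cell acquires `Poisson(mu)` new mutations, so
generation `k` contributes `Poisson(2^k * mu_k)` mutations in total, each
assigned a uniformly random carrying cell. The per-division rate is
`mu_burst` inside a configurable window of generations (the transient
hypermutation phase early in reprogramming, when the G1/S checkpoint is
down) and `mu_background` outside it. Burst and background mutations draw
their trinucleotide class from separate 96-class signatures — by default
a transversion-dominated profile concentrated on T>G at NTT contexts for
the burst and a transition-dominated profile for the background, so the
two mutational regimes are distinguishable downstream.

Sites are drawn uniformly without replacement from a virtual contig
(infinite-sites; collisions are resampled, and a configuration whose
expected mutation count exceeds the contig length is rejected).
Coordinates are 1-based and fully closed, matching VCF.

Key defaults (all overridable in `SimConfig`):

| parameter | default | rationale |
|---|---|---|
| `generations` | 10 | clone growth to colony pick at realistic scale |
| `burst_window` | [1, 4] | the checkpoint-deficient days correspond to the first few divisions; the exact division count is not observable, so this is a modelling choice |
| `mu_burst` / `mu_background` | 20 / 0.2 per division | 100x rate contrast; yields ~600 burst mutations and a ~1200-mutation clone, in the range reported for deeply sequenced reprogrammed clones |
| `n_preexisting` | 200 | heterozygous founder variants at 50% VAF |
| `wgs_depth` | 40x | standard single-run WGS coverage |
| `amplicon_reads` | 1e5 | ultra-deep amplicon redundancy per SNV |
| `seq_error` | 3e-4 per base | makes the 0.1% detection floor binding |
| `vaf_floor` | 0.001 | below it, signal is indistinguishable from miscalls |
| `subline_generations` | 14 | single-cell subline expansion (~2 weeks) |

## Read model

At a site with sample allele frequency `v`, total coverage is
`Poisson(depth)` and alternate reads are `Binomial(total, p)` with

    p = v (1 - e) + (1 - v) e / 3,

where `e` is the per-base miscall rate, spread uniformly over the three
non-reference bases. With `e = 3e-4` an unmutated site shows a mean
apparent VAF of `1e-4`; a true 0.05% variant shows ~0.06%, which at `1e5`
reads cannot be separated from the floor — this is why estimates under
0.1% are censored rather than interpreted.

## Filter chains

`filter_snvs` and `filter_indels` reproduce the published post-call
exclusion rules as pure functions over call tables: depth >= 20; exclusion
when the parental somatic sample shows >= 2 alternate reads; known-variant
(dbSNP-style) sites; sites shared with sister clones from the same
experiment; repeat-flanked sites (homopolymer run >= 5 or >= 3 tandem
copies of a 1-2 bp unit within +-5 bp, when sequence is available;
otherwise a caller-supplied mask column); and finally the clonal VAF
window — 35-65% on autosomes and >= 75% hemizygous for SNVs, with an
additional alternate-count >= 10 stage and a 30-70% window (>= 70%
hemizygous) for INDELs. Stages are conjunctive, so the verdict is
order-independent; the trace records every stage's decision in a fixed
order (exclusion lists before the VAF window). A variant missing a
required field receives an explicit error verdict, never a silent drop.
Upstream caller quality metrics (base quality, alignment windows) are
assumed already applied; this module filters call tables, not reads.

## Subline panels and the developmental tree

SNVs called across single-cell-derived sublines are binary characters
that are absent in the founder's germline and arise once on the division
tree, so conflict-free carrier sets form a laminar family — any two are
nested or disjoint — which is exactly the rooted perfect-phylogeny
condition. `venn_decompose` partitions SNVs by exact carrier subset;
`build_tree` checks pairwise compatibility, removes conflicting SNVs
greedily (highest conflict degree first, ties broken toward the lower
parent-clone VAF so the noisier call is sacrificed, then lexicographically
for determinism), and assembles the laminar family into a rooted tree
with each SNV set attached to the edge above the clade it defines.
Clone-wide SNVs hang on the edge from the founder to the common ancestor
of all sublines. The greedy rule is this package's choice: the source
analyses do not describe how call discordance was resolved.

`edge_timeline` summarises each edge with its SNV count, mean parent-clone
VAF, transition/transversion counts, and the fraction of its SNVs a
conventional WGS filter chain would keep from parent-clone counts —
making quantitative the observation that shared (old, high-VAF) SNVs are
recoverable by ordinary WGS while subline-specific ones are not.

## VAF timing and the burst test

`estimate_vaf` is the alt/total fraction with a Wilson 95% interval
(via statsmodels); estimates under the floor are censored and never
grouped or dated. `classify_group` splits non-censored SNVs at 1% VAF
into group I (>= 1%, the reprogramming-associated class) and group II
(< 1%, spontaneous culture mutations); an alternative two-threshold mode
(5%/1%) reproduces the narrower textual definition of group I with an
explicit intermediate band. 50%-VAF SNVs stay in group I, flagged
clone-wide — whether they are de novo or pre-existing is not decidable
from the clone alone, which is why the pipeline removes
parental-evidenced SNVs before timing. The origin generation is the
rounded inversion of the carrier model,

    k_hat = max(0, round(log2(1 / (2 vaf)))),

an estimator this package defines (the carrier model makes it the obvious
one); at `1e5` reads the binomial noise moves `log2(1/(2 vaf))` by far
less than the 0.5 rounding margin for every observable generation.

`burst_test` bins non-censored SNVs by `k_hat` over generations
`0..g_max`, where `g_max = floor(log2(1/(2 * floor)))` is the deepest
generation whose VAF clears the detection floor (8 at the 0.1% floor):
deeper generations are censored, and including them in the fit would
spuriously favour a burst. Two Poisson models are compared:

- continuous: counts `c_k ~ Poisson(mu * 2^k)`, one free rate;
- burst: rate `mu_b` inside a window `[a, b]` and `mu_0` outside, every
  window of width `<= w_max` (default 6 divisions — a "limited number"
  of divisions) scanned, maximum-likelihood rates in closed form.

Because the window endpoints are chosen by the scan, they are charged as
parameters: the burst model carries 4 (two rates, two endpoints) against
the continuous model's 1, and the verdict is "burst" when
`AIC_continuous - AIC_burst > 4`. Charging only the two rates makes the
scan's selection gain look like evidence and inflates false bursts on
continuous data beyond the tolerated rate; the changepoint-style
accounting keeps the test calibrated while leaving the decisive
likelihood gaps of genuine bursts (hundreds of log-units) untouched.
With the full range as window the burst likelihood equals the continuous
one exactly (the models nest). Fewer than 10 usable calls yields
"inconclusive" rather than an exception.

## Signature profiling

Substitutions are folded onto the pyrimidine strand and indexed by
(substitution, 5' base, 3' base) into the standard 96 classes; the 192
raw (ref, alt, flank) combinations map two-to-one onto them. Profiles are
normalised class counts; comparison is cosine similarity, symmetric and
scale-invariant on non-negative vectors. `stage_profiles` partitions a
variant table into pre-existing (stage 1: parental alternate reads >= 2),
clone-wide (VAF 35-65%), early de novo (stage 2: 1-25% VAF) and
prolonged-culture (stage 3: < 1%) sets and reports each stage's cosine
against a reference set. Stage boundaries follow the figure-caption
convention (1-25% / < 1%); both are configurable. The bundled references
are synthetic constructions — a T>G-at-NTT-concentrated profile, a
C>A-dominated profile, and a transition-biased background — not
catalogue signatures; user CSVs in COSMIC v2 layout are supported. The
judgement "signature present" is formalised as the argmax cosine match,
a choice this package makes explicit since the original comparison was
visual. No exposure decomposition (NNLS/NMF) is performed: profiles are
compared, not refit.

## What the generator does and does not emulate

The simulator reproduces the features the inference depends on: the
binary-tree VAF ladder, a rate burst confined to early divisions with a
distinct signature, Poisson/binomial sequencing noise with a uniform
miscall rate, the amplicon detection floor, and subline derivation with
ongoing background mutagenesis. It does not model cell death or selection
(carrier fractions are exact powers of two, where real colonies show
spread), copy-number changes (VAF is never CN-corrected), mapping or
alignment artefacts, PCR jackpot errors in amplicons (miscalls are
independent per read), colony merging, or sequence-context-dependent
error rates. Passing tests therefore demonstrate that the inference
machinery is correct under its stated model, not that the model captures
every property of real sequencing data.

## Numerical and degenerate-input choices

- Powers of two up to the supported generation counts are exact in
  binary floating point, so `true_vaf` is exact, not approximate.
- Poisson log-likelihoods use `gammaln`; a zero rate is compatible only
  with a zero count (`0 * log 0 = 0`), else `-inf`.
- `tstv` returns infinity when transversions exist without transitions,
  and NaN for an empty table.
- Empty variant sets cannot be profiled (error), a burst test on fewer
  than 10 calls is "inconclusive", zero-depth sites cannot yield a VAF
  estimate (error), and an all-zero vector has no cosine (error).
- All randomness flows from a single integer seed through
  `numpy.random.Generator` with fixed derivation tags per assay/sample,
  so a run is byte-reproducible; test problem sizes (50 oracle
  simulations at `G <= 12`, 100 + 100 clones for the recovery study,
  1000 censoring replicates) are the package's chosen verification
  scales.
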