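# burstline

Tools for timing the acquisition of point mutations in clonally expanding
reprogrammed cells (iPSC/ntESC clones), where a transient loss of the G1/S
checkpoint early in reprogramming produces a burst of transversion-biased
mutations confined to a few cell divisions.

The package is aimed at people analysing variant-allele-frequency (VAF)
data from clonal cell populations: it provides

- **`simulate`** — a ground-truthed clonal-expansion simulator: a founder
  cell divides `G` times; each division acquires `Poisson(mu)` mutations,
  with `mu` elevated 100-fold inside an early burst window and drawn from
  a distinct 96-class mutational signature; WGS (~40x) and ultra-deep
  amplicon (~1e5 reads) counts are emitted with a realistic error model;
- **`filters`** — the post-call SNV/INDEL exclusion chains (depth >= 20,
  parental sharing, known sites, sister clones, repeat flanks, VAF
  windows 35-65% / 30-70%) as pure, traced functions over call tables;
- **`tree`** — shared/specific decomposition of single-cell subline call
  sets and rooted perfect-phylogeny reconstruction of the developmental
  tree, with SNVs assigned to edges;
- **`timing`** — VAF estimation with censoring at the 0.1% detection
  floor, group I/II classification, origin-generation estimation, and a
  burst-vs-continuous Poisson model comparison;
- **`signatures`** — 96-class trinucleotide profiling, ts/tv summaries,
  stage-wise decomposition and cosine comparison to reference signatures.

## The model in brief

On a complete binary division tree a mutation arising at generation `k`
is carried by a `2^-k` fraction of final cells, so its heterozygous VAF is

    vaf(k) = 2^-(k+1)

— 50% for founder variants, 25% for first-division mutations, and so on.
Ultra-deep amplicon counts read this ladder back out:
`k_hat = round(log2(1/(2 vaf)))` dates each SNV, and the per-generation
counts `c_k` are compared between a one-rate model
`c_k ~ Poisson(mu 2^k)` and a two-rate model with an elevated rate inside
a scanned window `[a, b]`. A clone is called "burst" when the window
model beats the continuous one by more than 4 AIC units (the window
endpoints are charged as parameters). Details and all defaults are in
[docs/methods.md](docs/methods.md).

## Worked example

```python
import burstline as bl
from burstline.timing import observable_generations

cfg = bl.SimConfig(seed=1)              # burst in divisions 1-4, ratio 100
mset = bl.simulate_clone(cfg)
amplicon = bl.sample_reads(mset, cfg, "amplicon", "parent")
parental = {o.site: o.alt_reads
            for o in bl.sample_reads(mset, cfg, "wgs", "parental_somatic")}

calls = [bl.classify_group(bl.estimate_vaf(o, cfg.vaf_floor))
         for o in amplicon if parental[o.site] < 2]   # de novo only
res = bl.burst_test(calls, min(observable_generations(cfg.vaf_floor),
                               cfg.generations))
print([ (c.group, c.k_hat) for c in calls[:2] ])
print(res.verdict, res.burst_window, round(res.delta_aic, 1))
```

prints

```
[('I', 1), ('I', 1)]
burst (1, 4) 2776.8
```

The simulated clone carried 1237 mutations (590 burst, 200 pre-existing
at 50% VAF). After excluding parental-evidenced SNVs, the amplicon VAFs
split into 599 group I (>= 1% VAF, the reprogramming-associated class),
174 group II (< 1%, spontaneous culture mutations) and 264 censored
(< 0.1%, indistinguishable from sequencing error). The per-generation
counts concentrate in divisions 1-4, and the model comparison recovers
exactly the simulated burst window with an overwhelming AIC margin —
the mutations arose transiently, not continuously.

The `examples/` directory holds one short script per capability
(simulation, filtering, subline trees, timing, stage-wise signatures,
and the end-to-end pipeline); each prints what it computes and says what
the numbers mean. The same flow is available from the shell:

```sh
burstline run --seed 17 --out demo_run/
burstline defaults          # every threshold the package applies
```

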