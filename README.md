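# rangesim

Spatially explicit, forward-time simulation of **range contraction** and its
demographic and population-genetic consequences.

Species ranges rarely just get smaller — they contract in distinct spatial
patterns: **shrinkage** (periphery collapses onto the core), **amputation**
(an extinction front advances from one edge) and **fragmentation** (the
range loses continuity, leaving disjunct patches).  `rangesim` is an
individual-based model of a generalist species on a continuous 20 x 20
landscape that makes these patterns comparable: each removes the same area
(22% per event, four events 100 timesteps apart, ~88% total) and causes the
same population decline, so any differences in genetic outcomes are caused
by the *geometry* of the contraction, not by population size.

The package is aimed at conservation-genetics and spatial population
genetics researchers who want a tested, scriptable desk-scale version of
this experimental design.

## Model in brief

Individuals are diploid, hermaphroditic but self-incompatible, live in
continuous space with overlapping generations, and interact through a
Gaussian kernel with maximum `m = 1/(2 pi sigma^2)` truncated at `3 sigma`
(mate choice and competition alike).  Each timestep every individual mates
at most once as focal parent (Poisson(`lambda = 1/L`) offspring), newborns
disperse once by Normal(0, `sigma`) displacements with absorbing range
boundaries, and everyone survives with probability

    W_i = h_i / (1 + rho * C_i),        rho = lambda / ((1 + lambda) K)

where `h_i` is bilinearly interpolated habitat fitness (1.0, dropping to
0.1 in contracted cells), and `C_i` is the kernel-weighted neighbour load,
edge-corrected by the exact circle–rectangle intersection area.  At these
defaults the uncontracted population equilibrates at density `K = 5` per
cell with mean age `L = 4`.

Genomes are infinite-sites (default desk profile: 1e7 bp with ~10 new
mutations and ~1 crossover per gamete, the same per-gamete means as the
full-scale 1e9 bp profile), seeded by founder-diversity injection at a
target pairwise diversity theta.  The full pedigree is recorded for
Wright's relatedness (`F_r = (r - n)/n` over a 50-individual sample), and
genome segments are label-tracked so the geographic positions of a sampled
individual's ancestors — weighted by genomic contribution — can be mapped
at past time slices.

Downstream statistics: individual heterozygosity, group nucleotide
diversity pi, pairwise divergence pi12, `F_ST = 1 - 2(pi1+pi2)/(pi1+2
pi12+pi2)`, Shapiro–Wilk, pairwise Holm-adjusted rank-sum tests, and OLS
trend fits.  See `docs/methods.md` for the full account.

## Worked example

Run one desk-scale fragmentation replicate and summarise its diversity
decline:

```python
from rangesim import SimParams, run_replicate
from rangesim.pipeline import _snapshot_diversity

res = run_replicate("fragmentation", SimParams(), seed=11)
print(f"final N = {res.final_n}")
print(_snapshot_diversity(res)[["label", "t", "mean_het", "rel_het"]]
      .round(4).to_string(index=False))
```

prints

```
final N = 152
       label    t  mean_het  rel_het
         pre  350    0.0009   1.0000
post_event_1  450    0.0009   0.9560
post_event_2  550    0.0008   0.9048
post_event_3  650    0.0008   0.8848
post_event_4  750    0.0007   0.7700
       final 1100    0.0003   0.3740
```

Read: the population fell from ~1900 to 152 individuals (a ~92% decline for
88% area loss), and mean individual heterozygosity (`mean_het`, per site)
eroded to 37% of the replicate's own pre-contraction baseline by 400
timesteps after the last event — fragmentation's hallmark >50% diversity
loss, driven by drift inside the four isolated remnant patches.  The same
replicate's patch-pair `F_ST` values (via `rangesim.pipeline._region_fst`)
all exceed 0.5, while shrinkage run the same way loses almost no diversity
and shows no isolation by distance.

The CLI wraps the same machinery:

```bash
rangesim simulate --config my_run.yaml       # one replicate, full outputs
rangesim experiment --config my_run.yaml     # scenario x replicate grid
rangesim analyze runs/out                    # recompute stats from written files
rangesim report runs/out --plots             # summary tables / figures
```

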