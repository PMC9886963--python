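# Methods

`rangesim` simulates a generalist, hermaphroditic but self-incompatible
species in continuous two-dimensional space and follows the demographic and
population-genetic consequences of three geometries of range contraction:
**shrinkage** (periphery collapses onto the core), **amputation** (an
extinction front sweeps in from one edge) and **fragmentation** (the range
loses continuity and only disjunct patches survive).  This note documents
the model, its parameters, the numerical choices, and what the synthetic
experiments can and cannot show.

## Landscape and contraction

The range is a rectangle of `nx x ny` unit cells (default 20 x 20, one
distance unit per cell side).  Each cell carries a habitat-fitness value
`h`: 1.0 before contraction, 0.1 after a cell has been contracted.  `h` is
read at continuous coordinates by bilinear interpolation between the four
surrounding cell centers (clamped beyond the outermost centers), so habitat
edges are smooth ramps one cell wide rather than cliffs.

A contraction schedule removes 22% of the cells per event in four events
100 timesteps apart, for ~88% cumulative loss (352/400 cells exactly).
Only the area fractions and the qualitative geometry are fundamental; the
exact cell sets are fixed, versioned conventions:

* shrinkage removes rectangular peripheral rings (cells ranked by
  `max(|ix-cx|/nx, |iy-cy|/(0.75 ny))`), leaving the centered 8 x 6 block;
* amputation sweeps row-major from the top edge down, leaving a strip on
  the bottom edge;
* fragmentation first removes a central cross — severing the range into
  quadrants at the very first event — and then erodes the quadrants down to
  four corner patches (two of 16 cells, two of 8).

A `random_fragmentation` variant draws the removed cells uniformly without
replacement from a seeded generator.  Schedules serialize to YAML and a
mask file can override any geometry.

## Demography

Timesteps are discrete with overlapping generations.  Interactions (mate
choice and competition alike) use a Gaussian kernel with maximum
`m = 1/(2 pi sigma^2)` truncated to zero at `3 sigma`.  Per timestep:

1. a scheduled contraction event, if any, is applied;
2. every living individual acts once as focal parent: it draws one mate
   within `3 sigma` with probability proportional to the kernel (none
   available: no offspring), then a Poisson(`lambda = 1/L`) number of
   offspring;
3. each newborn disperses once, by independent Normal(0, `sigma`)
   displacements per axis; the boundary is absorbing — dispersing outside
   the range is death;
4. everyone (adults and newborns) survives independently with probability
   `W`; the competition load `C_i` is the kernel-weighted sum over
   neighbours within `3 sigma`, multiplied by `pi R^2 / A_i`, where `A_i`
   is the exact area of the interaction disc clipped to the range rectangle
   (individuals near an edge meet their neighbours in less occupiable
   space);
5. survivors that existed at the start of the step age by one timestep.

Survival couples competition and habitat through the spatial competition
constant `rho = lambda / ((1 + lambda) K)`.  Two couplings are implemented:

* `scaled` (default): `W = h / (1 + rho C)`;
* `printed`: `W = 1 / (1 + rho C / h)`.

The default treats habitat quality as a multiplicative survival scaling,
the way a habitat map normally enters nonWF spatial models.  The choice is
consequential: with the `printed` coupling, contracted habitat equilibrates
at a residual density of about `K h` per cell (0.5/cell), so the total
decline saturates near 79% and the contracted matrix keeps carrying genes
between remnant patches.  With the multiplicative coupling, contracted
cells empty within a few timesteps, the population tracks the remaining
habitable area (86–92% decline for the 88% loss), and remnant patches are
genuinely isolated — which is the regime the downstream analyses describe.

With the default parameters (`K = 5` per cell, `L = 4`, `sigma = 0.5`),
the uncontracted equilibrium is analytically transparent: stationarity
requires `(1 + lambda) W = 1`, i.e. `W = 0.8`, which the competition
constant places at density `K` per cell with stationary mean age
`W/(1-W) = L`.  Simulations sit ~5% below `K x n_cells` because the
absorbing boundary removes some dispersers.  Newborns do not age in their
birth step; aging them would shift the stationary mean age to `L + 1`.

`sigma` is a single scale for competition, mating and dispersal.  Its
value is a free design choice: 0.5 cell sides keeps a Wright
neighbourhood of ~15–20 individuals (strong isolation by distance, which
the differentiation analyses require) while leaving mate finding
essentially certain at equilibrium density.  Declines are insensitive to
`sigma` in the 0.3–0.5 range (scanned during design).

## Genetics

Genomes are diploid, infinite-sites: a haplotype is a sorted array of
continuous mutation positions on `[0, G)`.  A gamete draws
Poisson(`rec x G`) crossovers uniform on the genome, alternates between the
parent's haplotypes from a random start, and adds Poisson(`mu x G`) new
mutations.  The desk-scale profile (`G = 1e7`, `mu = 1e-6`, `rec = 1e-7`)
preserves the full-scale per-gamete means — ~10 new mutations and ~1
crossover — at 1% of the bookkeeping cost; this invariance is unit-tested.
The full-scale profile (`G = 1e9`, `mu = 1e-8`, `rec = 1e-9`) is available
in configuration.

Runs start demographically, not from a coalescent.  Standing variation is
seeded by **founder-diversity injection** 250 timesteps before the first
contraction: every haplotype receives mutations drawn from a common pool of
segregating sites whose copy numbers follow the neutral frequency spectrum
(P(k copies) ∝ 1/k), with the site count set by Watterson's relation so the
expected pairwise difference per site equals `founder_theta` (default 1e-3,
a typical vertebrate-to-invertebrate diversity; verified to calibrate
within Monte-Carlo error).  For populations above 1000 haplotypes, founders
draw lineages with replacement from a 1000-sequence pool (theta inflated by
`1/(1 - 1/pool)` to compensate lineage coincidence) — the natural picture
of founders drawn from a large ancestral population.  The 250-timestep lead
(~60 generations) lets isolation-by-distance structure form before
treatment: the range core accumulates higher individual heterozygosity than
the edges, which is what differentiates shrinkage (core remnant) from
amputation (edge remnant).  Absolute diversity levels are a configuration
choice and carry no meaning on their own; all diversity outcomes are
relative to the same replicate's own pre-contraction mean.

A consequence of injecting at a fixed lead rather than burning in for
thousands of generations: mean individual heterozygosity settles mildly
downward (order 10%) after injection while local mating structure forms.
The pre-contraction baseline is sampled 200 timesteps after injection,
when the fast part of that settling has happened; the no-contraction
control in the test suite bounds the residual drift.

## Pedigree relatedness

The full pedigree (parents, birth/death timesteps, birth location) is
recorded.  Kinship is Malecot's coefficient by recursive pedigree
traversal, truncated at `max_depth` generations (default 10), with the
non-inbred convention on the diagonal (relatedness matrix diagonal 1, as
implied by the summary statistic `F_r = (r - n)/n`, which is zero for n
mutually unrelated individuals).  The full recursion with inbreeding
(`Phi(x,x) = (1 + F_x)/2`) is available and is what the gene-dropping
oracle in the test suite checks against.

The per-timestep `F_r` series samples 50 individuals every 10 timesteps.
It uses its own truncation depth, default 3: once the whole population is
interrelated, the depth-10 pair closure contains millions of ancestor
pairs and costs seconds per evaluation, whereas close-kin relatedness
(depth ≤ 3, what pedigree-id-based engines effectively report) captures
the same post-contraction rise at negligible cost.  Both depths are
configuration knobs.

## Spatial ancestry

Each haplotype carries, per *anchor* timestep, a breakpoint/label list
recording which anchor-time haplotype every genome interval descends from;
gametes splice these lists along with the mutation arrays, and the lists
always tile the genome (checked in tests), so the genomic contributions of
slice-time ancestors to any descendant sum to one.  Anchors are placed 50
timesteps before the first event and 50 after the last; four random
descendants are sampled 100 timesteps after the last event, and their
ancestry clouds (ancestor location x genomic fraction) are reported at both
slices.  Anchoring at a slice rather than carrying tree sequences bounds
memory and matches the two slices the analysis actually uses; stale layers
are dropped at re-anchoring.

## Sampling and statistics

Per scenario and replicate: 100 random individuals 50 timesteps after each
event, plus the pre-contraction baseline (first event − 50) and a final
sample 400 timesteps after the last event; 50 individuals per named remnant
region at the final timestep (shrinkage: four corner blocks + center;
amputation: four segments along the strip; fragmentation: the four
patches), each compared against an "ancient" pre-contraction group.
Regions smaller than 50 individuals contribute everyone and the shortfall
is logged — with `K = 5` the remnant holds only ~240 individuals, so some
shortfall is structural, not an error.

Nucleotide diversity uses site-frequency counting over all C(2n, 2)
haplotype pairs (a between-individual-only variant is a flag); divergence
`pi12` averages cross-group haplotype pairs; differentiation is
`F_ST = 1 - 2(pi1 + pi2)/(pi1 + 2 pi12 + pi2)`.  The *diversity decline*
statistic is the mean individual heterozygosity of a sample relative to the
pre-contraction mean.  This matters for fragmentation: pooled group pi over
diverged patches is nearly conserved under drift (differences move from
within to between patches), so only within-individual diversity can show
the >50% fragmentation loss; both quantities are reported.

Group comparisons use the unpaired rank-sum (Mann-Whitney) test — the
groups are different individuals at different times — with Holm adjustment
over the pairwise family; the paired signed-rank variant and other
adjustment methods are switches.  Shapiro-Wilk is provided to justify the
nonparametric choice.  Trends (relatedness, ages) are ordinary least
squares on timestep.

## Scale profiles and problem sizes

The desk-scale profile used by the tests and the acceptance script runs a
400-timestep demographic burn-in (first event at t = 400, injection at
t = 150), four events at 100-timestep intervals, and 400 post-run
timesteps (1100 total), with four replicates per scenario; one replicate
takes on the order of a minute.  The full-scale profile (20,000-timestep
burn-in, 1e9 bp, 10 replicates) is stored in configuration for cluster
use.  All randomness derives from a single master seed through named
substreams (per scenario/replicate; simulation vs sampling within a run),
and identical configurations and seeds reproduce outputs bit for bit.

Two desk-scale behaviours worth knowing when comparing against
full-equilibrium expectations.  First, with `mu = 1e-6` the uncontracted
population's mutation-drift equilibrium diversity (4 N mu ~ 8e-3) exceeds
the injected theta, so control diversity drifts gently upward — measured
post-contraction declines are therefore conservative.  Second, per-timestep
maximum age behaves as an extreme order statistic (~ln N / −ln s): the
order-of-magnitude population drop outweighs the survival increase, so max
age tends to fall after contraction even while mean age rises; only
fragmentation's tiny, competition-relaxed patches end with a higher
maximum.  Likewise, at `sigma = 0.5` the shrinkage core remnant spans
several dispersal scales, so its region groups retain a weak (F_ST < 0.13)
but statistically detectable distance pattern.

## Known limitations

* No selection, separate sexes, Allee effects, adult movement, habitat
  preference or age-specific vital rates — deliberately outside the model.
* Founder injection approximates mutation-drift equilibrium: the site
  frequency spectrum is exact only in expectation, spatial genetic
  structure is only ~60 generations old at treatment, and absolute pi is a
  configuration choice.  Relative declines and orderings are the meaningful
  outputs.
* VCF export rounds continuous positions to integer base pairs; colliding
  sites are merged, so statistics recomputed from VCF agree with in-memory
  values only up to those rare merges.
* Region sampling rectangles and contraction cell sets are conventions
  (documented above), not reconstructions of the original study's exact
  geometry; the random-fragmentation variant exists to show the qualitative
  conclusions do not depend on the fragmentation mask.
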