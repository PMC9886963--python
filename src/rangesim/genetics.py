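"""Diploid genomes, pedigree relatedness, and founder-ancestry tracking.

Genomes are infinite-sites: a haplotype is a sorted array of mutation
positions, continuous on ``[0, genome_length)``, so recurrent mutation is
impossible and two haplotypes share a position only by descent.  Gametes are
formed by splicing the parent's two haplotypes at Poisson(rec * G) uniform
crossover points and adding Poisson(mu * G) new mutations.

Because runs start from a demographic (not coalescent) burn-in, standing
variation is seeded by *founder-diversity injection*: every haplotype in the
population receives mutations drawn from a common pool of segregating sites
whose copy numbers follow the neutral equilibrium frequency spectrum
(P(k copies) proportional to 1/k), calibrated so the expected pairwise
difference per site equals a target theta.

Ancestry is tracked as genome *segments*: each haplotype carries, per anchor
timestep, a breakpoint/label list recording which anchor-time haplotype every
part of the genome descends from.  Segment lists always tile the genome, so
genomic contributions of ancestors sum to one.

Pedigree relatedness is Wright's coefficient r = 2 * Malecot kinship,
computed by depth-truncated recursion over the recorded pedigree with the
non-inbred founder convention (diagonal relatedness 1).
"""

from __future__ import annotations

import math

import numpy as np
import pandas as pd

__all__ = [
    "Haplotype",
    "PedigreeLog",
    "gamete",
    "make_gamete",
    "inject_founder_diversity",
    "founder_mutation_sets",
    "self_segments",
    "segments_tile",
    "kinship",
    "relatedness",
    "relatedness_matrix",
    "avg_sampled_relatedness",
    "ancestry_contributions",
]


class Haplotype:
    """One haploid genome: sorted mutation positions plus ancestry layers.

    ``muts`` is a sorted float array of mutation positions (treated as
    immutable; gametes share parent arrays when no crossover occurs).
    ``layers`` maps an anchor timestep to ``(breakpoints, labels)`` where
    ``breakpoints`` starts at 0.0 and ``labels[i]`` is the anchor-time
    haplotype id owning ``[breakpoints[i], breakpoints[i+1])``.
    """

    __slots__ = ("muts", "layers")

    def __init__(self, muts: np.ndarray, layers: dict | None = None):
        self.muts = muts
        self.layers = layers if layers is not None else {}

    def __len__(self) -> int:
        return len(self.muts)

    def segments(self, anchor_time: int):
        return self.layers[anchor_time]


def self_segments(individual_id: int, params):
    """Fresh single-segment layers labelling a diploid's two haplotypes.

    Haplotype labels are ``2*id`` and ``2*id + 1``; a label maps back to its
    carrier individual as ``label // 2``.
    """
    bps = np.zeros(1)
    return (
        (bps, np.array([2 * individual_id], dtype=np.int64)),
        (bps.copy(), np.array([2 * individual_id + 1], dtype=np.int64)),
    )


def segments_tile(layer, genome_length: float) -> bool:
    """True when a (breakpoints, labels) layer exactly tiles the genome."""
    bps, labels = layer
    if len(bps) != len(labels) or len(bps) == 0:
        return False
    if bps[0] != 0.0 or bps[-1] >= genome_length:
        return False
    return bool(np.all(np.diff(bps) > 0))


# ---------------------------------------------------------------------------
# gamete formation


def _splice_positions(a: np.ndarray, b: np.ndarray, cross: np.ndarray, start: int) -> np.ndarray:
    """Alternate sorted position arrays a/b between crossover points."""
    bounds = np.concatenate([[0.0], cross])
    ia = np.searchsorted(a, cross)
    ib = np.searchsorted(b, cross)
    ia = np.concatenate([[0], ia, [len(a)]])
    ib = np.concatenate([[0], ib, [len(b)]])
    pieces = []
    for k in range(len(bounds)):
        if (k + start) % 2 == 0:
            pieces.append(a[ia[k] : ia[k + 1]])
        else:
            pieces.append(b[ib[k] : ib[k + 1]])
    return np.concatenate(pieces)


def _splice_segments(layer_a, layer_b, cross: np.ndarray, start: int, genome_length: float):
    """Splice two (breakpoints, labels) layers at the crossover points."""
    bounds = np.concatenate([[0.0], cross, [genome_length]])
    out_bps, out_labs = [], []
    for k in range(len(bounds) - 1):
        lo, hi = bounds[k], bounds[k + 1]
        sbps, slab = layer_a if (k + start) % 2 == 0 else layer_b
        i0 = np.searchsorted(sbps, lo, side="right") - 1
        i1 = np.searchsorted(sbps, hi, side="left")
        out_bps.append(np.concatenate([[lo], sbps[i0 + 1 : i1]]))
        out_labs.append(slab[i0:i1])
    return np.concatenate(out_bps), np.concatenate(out_labs)


def gamete(hap_a: Haplotype, hap_b: Haplotype, params, rng) -> Haplotype:
    """Form one gamete from a parent's two haplotypes.

    Draws Poisson(rec * G) crossovers uniform on the genome, alternates
    copying between the haplotypes from a random starting one, splices both
    the mutation sets and every ancestry layer, then adds Poisson(mu * G)
    new unique mutations.
    """
    G = float(params.genome_length)
    n_bp = int(rng.poisson(params.rec * G))
    n_mut = int(rng.poisson(params.mu * G))
    start = int(rng.integers(0, 2))
    if n_bp == 0:
        src = hap_a if start == 0 else hap_b
        muts = src.muts
        layers = dict(src.layers)
    else:
        cross = np.sort(rng.random(n_bp) * G)
        muts = _splice_positions(hap_a.muts, hap_b.muts, cross, start)
        layers = {
            at: _splice_segments(hap_a.layers[at], hap_b.layers[at], cross, start, G)
            for at in hap_a.layers
        }
    if n_mut:
        new = np.sort(rng.random(n_mut) * G)
        muts = np.insert(muts, np.searchsorted(muts, new), new)
    return Haplotype(muts, layers)


def make_gamete(parent, params, rng) -> Haplotype:
    """Gamete from an Individual carrying a (Haplotype, Haplotype) genome."""
    if parent.genome is None or len(parent.genome) != 2:
        raise ValueError("parent has no diploid genome")
    return gamete(parent.genome[0], parent.genome[1], params, rng)


# ---------------------------------------------------------------------------
# founder diversity


def _pool_mutation_sets(M: int, theta_per_site: float, genome_length: float, rng):
    """Mutation sets for M distinct haplotypes at pairwise diversity theta.

    Segregating sites are drawn from the neutral frequency spectrum
    (P(k copies) proportional to 1/k over k = 1..M-1); the site count is
    theta * G * a(M-1) (Watterson's relation), so the expected per-site
    difference between two random haplotypes equals theta.  Carriers of each
    site are realized as independent Bernoulli(k/M) draws per haplotype
    (copy numbers Binomial around the spectrum draw); the M/(M-1) factor
    compensates E[2c(M-c)] = M(M-1) p(1-p) exactly.
    """
    ks = np.arange(1, M)
    pk = (1.0 / ks) / np.sum(1.0 / ks)
    a_m = float(np.sum(1.0 / ks))
    n_sites = int(round(theta_per_site * genome_length * a_m * M / (M - 1)))
    copies = rng.choice(ks, size=n_sites, p=pk)
    positions = rng.random(n_sites) * genome_length
    site_chunks, hap_chunks = [], []
    batch = max(1, 20_000_000 // M)
    for lo in range(0, n_sites, batch):
        p = (copies[lo : lo + batch] / M)[:, None]
        hit_site, hit_hap = np.nonzero(rng.random((len(p), M)) < p)
        site_chunks.append(positions[lo + hit_site])
        hap_chunks.append(hit_hap)
    pos_rep = np.concatenate(site_chunks)
    hap_idx = np.concatenate(hap_chunks).astype(np.int64)
    order = np.argsort(hap_idx, kind="stable")
    hap_idx, pos_rep = hap_idx[order], pos_rep[order]
    splits = np.searchsorted(hap_idx, np.arange(1, M))
    return [np.sort(chunk) for chunk in np.split(pos_rep, splits)]


#: largest number of distinct founder lineage haplotypes built at injection
MAX_FOUNDER_POOL = 1000


def founder_mutation_sets(n_haplotypes: int, theta_per_site: float, genome_length: float,
                          rng, pool_size: int | None = None):
    """Mutation sets for founder haplotypes at pairwise diversity ``theta``.

    For populations larger than ``pool_size`` diploids-worth of haplotypes,
    founders are assigned lineages drawn (with replacement, uniformly) from
    a pool of ``pool_size`` distinct haplotype sequences -- the natural
    picture of founders sampled from a large equilibrium source population,
    and far cheaper than materialising thousands of distinct genomes.  The
    pool itself carries neutral-spectrum variation at a slightly inflated
    theta so that two random *founders* (which coincide in lineage with
    probability 1/pool) differ at rate ``theta`` per site.  Returns a list
    of sorted position arrays, one per haplotype; arrays are shared between
    founders of the same lineage and must be treated as immutable.
    """
    M = int(n_haplotypes)
    if M < 2:
        raise ValueError("need at least 2 founder haplotypes")
    if theta_per_site < 0:
        raise ValueError("theta_per_site must be non-negative")
    if theta_per_site == 0:
        return [np.empty(0) for _ in range(M)]
    pool = min(M, MAX_FOUNDER_POOL if pool_size is None else int(pool_size))
    if pool < M:
        target = theta_per_site / (1.0 - 1.0 / pool)
        sets = _pool_mutation_sets(pool, target, genome_length, rng)
        picks = rng.integers(0, pool, size=M)
        return [sets[p] for p in picks]
    return _pool_mutation_sets(M, theta_per_site, genome_length, rng)


def inject_founder_diversity(population, theta_per_site: float, params, rng):
    """Seed standing variation into the current population.

    ``population`` may be an integer (number of diploids; returns a flat
    list of 2N mutation arrays, the engine's fast path) or a sequence of
    Individuals, which get ``genome`` assigned in place (each haplotype a
    single self-referential ancestry segment anchored at time 0) and are
    returned.
    """
    if theta_per_site < 0:
        raise ValueError("theta_per_site must be non-negative")
    if isinstance(population, (int, np.integer)):
        return founder_mutation_sets(2 * int(population), theta_per_site,
                                     float(params.genome_length), rng)
    inds = list(population)
    sets = founder_mutation_sets(2 * len(inds), theta_per_site,
                                 float(params.genome_length), rng)
    for k, ind in enumerate(inds):
        segs = self_segments(ind.id, params)
        ind.genome = (
            Haplotype(sets[2 * k], {0: segs[0]}),
            Haplotype(sets[2 * k + 1], {0: segs[1]}),
        )
    return inds


# ---------------------------------------------------------------------------
# pedigree


class PedigreeLog:
    """Append-only pedigree: id -> parents, birth/death timesteps, birth place.

    Ids are dense non-negative integers in creation order; founders have
    parent ids -1.  Death timestep is -1 while alive.
    """

    def __init__(self):
        self.parent1: list = []
        self.parent2: list = []
        self.birth: list = []
        self.death: list = []
        self.bx: list = []
        self.by: list = []

    def __len__(self) -> int:
        return len(self.parent1)

    def add(self, p1: int, p2: int, birth_t: int, x: float, y: float) -> int:
        new_id = len(self.parent1)
        if max(p1, p2) >= new_id:
            raise ValueError("parents must precede offspring in the pedigree")
        self.parent1.append(int(p1))
        self.parent2.append(int(p2))
        self.birth.append(int(birth_t))
        self.death.append(-1)
        self.bx.append(float(x))
        self.by.append(float(y))
        return new_id

    def set_death(self, ind_id: int, t: int) -> None:
        self.death[ind_id] = int(t)

    def parents(self, ind_id: int):
        return self.parent1[ind_id], self.parent2[ind_id]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "id": np.arange(len(self), dtype=np.int64),
                "parent1": self.parent1,
                "parent2": self.parent2,
                "birth": self.birth,
                "death": self.death,
                "x": self.bx,
                "y": self.by,
            }
        )

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "PedigreeLog":
        ped = cls()
        for row in df.sort_values("id").itertuples():
            ped.add(int(row.parent1), int(row.parent2), int(row.birth), float(row.x), float(row.y))
            ped.set_death(int(row.id), int(row.death))
        return ped


def _closure(ids, ped: PedigreeLog, max_depth: int) -> dict:
    """Sub-pedigree of all ancestors within ``max_depth`` generations.

    Individuals first reached at exactly ``max_depth`` are treated as
    unrelated, non-inbred founders (parents None).
    """
    sub: dict = {}
    frontier = set(int(i) for i in ids)
    for depth in range(max_depth + 1):
        nxt: set = set()
        for i in frontier:
            if i in sub:
                continue
            if depth == max_depth:
                sub[i] = (None, None)
                continue
            p1, p2 = ped.parents(i)
            sub[i] = (p1 if p1 >= 0 else None, p2 if p2 >= 0 else None)
            for p in sub[i]:
                if p is not None and p not in sub:
                    nxt.add(p)
        frontier = nxt
        if not frontier:
            break
    return sub


def _phi(a, b, sub: dict, birth, memo: dict, inbreeding: bool = False) -> float:
    if a is None or b is None:
        return 0.0
    if a == b:
        if not inbreeding:
            return 0.5  # non-inbred convention
        pa, pb = sub[a]
        return 0.5 * (1.0 + _phi(pa, pb, sub, birth, memo, True))
    key = (a, b) if a < b else (b, a)
    if key in memo:
        return memo[key]
    # recurse on the younger individual (a parent is always older)
    if birth[a] < birth[b]:
        a, b = b, a
    pa, pb = sub[a]
    val = 0.5 * (
        _phi(pa, b, sub, birth, memo, inbreeding)
        + _phi(pb, b, sub, birth, memo, inbreeding)
    )
    memo[key] = val
    return val


def kinship(a: int, b: int, pedigree: PedigreeLog, max_depth: int = 10,
            include_inbreeding: bool = False) -> float:
    """Malecot kinship Phi by pedigree recursion truncated at ``max_depth``.

    Individuals beyond the depth horizon are treated as unrelated and
    non-inbred.  By default Phi(a, a) = 0.5 (the non-inbred diagonal
    convention used by the F_r statistic); with ``include_inbreeding`` the
    full recursion Phi(x, x) = (1 + F_x)/2 is used, which is what a
    gene-dropping experiment on the same pedigree measures.
    """
    n = len(pedigree)
    for i in (a, b):
        if not (0 <= i < n):
            raise ValueError(f"unknown individual id {i}")
    sub = _closure([a, b], pedigree, max_depth)
    return _phi(int(a), int(b), sub, pedigree.birth, {}, include_inbreeding)


def relatedness(a: int, b: int, pedigree: PedigreeLog, max_depth: int = 10) -> float:
    """Wright's relatedness r = 2 Phi off-diagonal, 1 on the diagonal."""
    if a == b:
        return 1.0
    return 2.0 * kinship(a, b, pedigree, max_depth)


def relatedness_matrix(ids, pedigree: PedigreeLog, max_depth: int = 10) -> np.ndarray:
    """n x n relatedness matrix for a sample (diagonal 1), shared-cache recursion."""
    ids = [int(i) for i in ids]
    n = len(pedigree)
    for i in ids:
        if not (0 <= i < n):
            raise ValueError(f"unknown individual id {i}")
    sub = _closure(ids, pedigree, max_depth)
    memo: dict = {}
    k = len(ids)
    out = np.ones((k, k))
    for i in range(k):
        for j in range(i + 1, k):
            out[i, j] = out[j, i] = 2.0 * _phi(ids[i], ids[j], sub, pedigree.birth, memo)
    return out


def avg_sampled_relatedness(sample, pedigree: PedigreeLog, max_depth: int = 10) -> float:
    """Average sampled relatedness F_r = (r - n) / n.

    ``r`` is the sum of the n x n relatedness matrix (diagonal 1) over a
    sample of n >= 2 individuals; mutually unrelated samples give F_r = 0.
    """
    ids = list(sample)
    if len(ids) < 2:
        raise ValueError("relatedness sample must contain at least 2 individuals")
    mat = relatedness_matrix(ids, pedigree, max_depth)
    n = len(ids)
    return float((mat.sum() - n) / n)


# ---------------------------------------------------------------------------
# spatial ancestry


def ancestry_contributions(haplotypes, slice_time: int, genome_length: float) -> dict:
    """Genomic contribution of each slice-time ancestor to a descendant.

    ``haplotypes`` is the descendant's (Haplotype, Haplotype); both must
    carry an ancestry layer anchored at ``slice_time``.  Returns a dict
    mapping ancestor individual id -> fraction of the descendant's two
    haplotypes (by genome length) carried by that individual at the slice.
    Fractions sum to 1.
    """
    out: dict = {}
    for hap in haplotypes:
        if slice_time not in hap.layers:
            raise ValueError(f"ancestry tracking has no anchor at timestep {slice_time}")
        bps, labels = hap.layers[slice_time]
        lengths = np.diff(np.append(bps, genome_length))
        for lab, ln in zip(labels, lengths):
            anc = int(lab) // 2
            out[anc] = out.get(anc, 0.0) + float(ln)
    return {anc: ln / (2.0 * genome_length) for anc, ln in out.items()}
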