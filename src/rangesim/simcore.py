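"""Per-timestep engine: competition, mating, reproduction, dispersal, survival.

The model is an individual-based, continuous-space, overlapping-generations
simulation of a generalist species.  Each timestep, in fixed order:

1. any scheduled contraction event is applied to the habitat grid;
2. every living individual attempts mate choice once as the focal parent
   (hermaphroditic, self-incompatible) and draws a Poisson(lambda = 1/L)
   number of offspring with the chosen mate;
3. newborns disperse once, by an independent Normal(0, sigma) displacement
   per axis; the range boundary is absorbing (dispersing outside kills);
4. every individual, old and new, survives with probability W(C_i, h_i);
5. survivors that existed at the start of the step age by one timestep;
6. observables are recorded (N, mean/max age, mean lifetime offspring,
   periodic pedigree-relatedness samples).

Both mate choice and competition use a truncated Gaussian interaction kernel
with maximum m = 1/(2 pi sigma^2) and hard cutoff at 3 sigma.  The
competition load C_i is the kernel-weighted sum over neighbours, scaled by
pi R^2 / A_i where A_i is the area of the 3 sigma interaction disc clipped to
the range rectangle (edge correction: individuals near an edge experience
their neighbours concentrated into less occupiable space).

Survival couples competition and habitat quality h.  Two couplings are
provided (see ``fitness``):

* ``"scaled"`` (default): W = h / (1 + rho C) -- habitat quality scales
  survival multiplicatively, so contracted habitat (h = 0.1) cannot sustain
  a population and the post-contraction population tracks the remaining
  habitable area.
* ``"printed"``: W = 1 / (1 + rho C / h) -- habitat quality relaxes the
  competition term only; contracted habitat then retains a residual density
  of about K h per cell.

rho = lambda / ((1 + lambda) K) is the spatial competition constant; with it
the uncontracted equilibrium sits at density K per cell with per-timestep
survival L/(1+L) and stationary mean age L.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

from .landscape import ContractionSchedule, FitnessGrid
from . import genetics as gen

__all__ = [
    "SimParams",
    "Individual",
    "SamplingPlan",
    "SampleGroup",
    "SimResult",
    "kernel_max",
    "interaction_strength",
    "clipped_interaction_area",
    "competition_load",
    "fitness",
    "choose_mate",
    "reproduce",
    "disperse",
    "run",
]


# ---------------------------------------------------------------------------
# parameters


@dataclass(frozen=True)
class SimParams:
    """Model parameters.

    sigma
        Interaction/dispersal scale in distance units (cell sides).  Used
        for competition, mate choice and natal dispersal alike.
    K
        Per-cell carrying capacity.
    L
        Mean age in timesteps; fecundity is lambda = 1/L offspring per focal
        mating per timestep.
    genome_length, mu, rec
        Haploid genome size (bp) and per-bp per-gamete mutation and
        recombination rates.  Defaults are the scaled profile (1e7 bp with
        rates chosen to preserve ~10 new mutations and ~1 crossover per
        gamete).
    burn_in
        Timesteps of demographic burn-in before the first contraction event.
    post_run
        Timesteps simulated after the final contraction event.
    founder_theta
        Target per-site pairwise diversity injected into the founders when
        genetics activates.
    genetics_lead
        Timesteps before the first contraction at which genomes, pedigree
        relatedness sampling and ancestry tracking are switched on.
    habitat_mode
        ``"scaled"`` or ``"printed"``; see module docstring.
    """

    sigma: float = 0.5
    K: float = 5.0
    L: float = 4.0
    genome_length: int = 10_000_000
    mu: float = 1e-6
    rec: float = 1e-7
    burn_in: int = 400
    post_run: int = 400
    founder_theta: float = 1e-3
    genetics_lead: int = 250
    kinship_depth: int = 10
    relatedness_depth: int = 3
    relatedness_cadence: int = 10
    relatedness_sample: int = 50
    habitat_mode: str = "scaled"

    def __post_init__(self) -> None:
        if self.sigma <= 0:
            raise ValueError("sigma must be positive")
        if self.K <= 0 or self.L <= 0:
            raise ValueError("K and L must be positive")
        if min(self.mu, self.rec) < 0 or self.genome_length <= 0:
            raise ValueError("genome_length must be positive and rates non-negative")
        if self.habitat_mode not in ("scaled", "printed"):
            raise ValueError(f"unknown habitat_mode {self.habitat_mode!r}")

    @property
    def lambda_fec(self) -> float:
        return 1.0 / self.L

    @property
    def rho(self) -> float:
        lam = self.lambda_fec
        return lam / ((1.0 + lam) * self.K)

    @property
    def interaction_radius(self) -> float:
        return 3.0 * self.sigma


# ---------------------------------------------------------------------------
# kernel, edge correction, fitness


def kernel_max(sigma: float) -> float:
    """Kernel value at distance zero, m = 1/(2 pi sigma^2)."""
    if sigma <= 0:
        raise ValueError("sigma must be positive")
    return 1.0 / (2.0 * math.pi * sigma * sigma)


def interaction_strength(d, sigma: float):
    """Truncated Gaussian interaction kernel.

    m exp(-d^2 / (2 sigma^2)) for d < 3 sigma, exactly 0 at and beyond the
    3 sigma cutoff.  Accepts scalars or arrays; rejects negative distances.
    """
    da = np.asarray(d, dtype=float)
    if np.any(da < 0):
        raise ValueError("distance must be non-negative")
    m = kernel_max(sigma)
    out = np.where(da < 3.0 * sigma, m * np.exp(-(da * da) / (2.0 * sigma * sigma)), 0.0)
    return float(out) if np.isscalar(d) else out


def _segment_area(d: np.ndarray, r: float) -> np.ndarray:
    """Area of the circular segment beyond a chord at distance d (d >= 0)."""
    d = np.minimum(d, r)
    return r * r * np.arccos(d / r) - d * np.sqrt(np.maximum(r * r - d * d, 0.0))


def _corner_area(dx: np.ndarray, dy: np.ndarray, r: float) -> np.ndarray:
    """Area of disc(0, r) intersected with the quadrant {x > dx, y > dy}.

    dx, dy >= 0; zero when the corner lies outside the disc.  Closed form via
    F(x) = (x sqrt(r^2-x^2) + r^2 asin(x/r)) / 2, the antiderivative of
    sqrt(r^2 - x^2).
    """
    dx = np.minimum(np.maximum(dx, 0.0), r)
    dy = np.minimum(np.maximum(dy, 0.0), r)
    inside = dx * dx + dy * dy < r * r
    xhi = np.sqrt(np.maximum(r * r - dy * dy, 0.0))

    def F(x):
        x = np.clip(x, -r, r)
        return 0.5 * (x * np.sqrt(np.maximum(r * r - x * x, 0.0)) + r * r * np.arcsin(x / r))

    area = (F(xhi) - F(dx)) - dy * (xhi - dx)
    return np.where(inside, np.maximum(area, 0.0), 0.0)


def clipped_interaction_area(x, y, radius: float, range_rect) -> float | np.ndarray:
    """Exact area of disc((x, y), radius) intersected with the range rectangle.

    ``range_rect`` is (x0, y0, x1, y1).  Computed by inclusion-exclusion:
    full disc minus the four edge segments plus the four corner overlaps, so
    it is exact for any radius.  Vectorized over x, y.
    """
    x0, y0, x1, y1 = map(float, range_rect)
    if x1 <= x0 or y1 <= y0:
        raise ValueError("degenerate range rectangle")
    if radius <= 0:
        raise ValueError("radius must be positive")
    xa = np.asarray(x, dtype=float)
    ya = np.asarray(y, dtype=float)
    if np.any(xa < x0) or np.any(xa > x1) or np.any(ya < y0) or np.any(ya > y1):
        raise ValueError("point outside the range rectangle")
    r = float(radius)
    dl, dr = xa - x0, x1 - xa
    db, dt = ya - y0, y1 - ya
    area = np.pi * r * r
    for d in (dl, dr, db, dt):
        area = area - np.where(d < r, _segment_area(d, r), 0.0)
    for dxe, dye in ((dl, db), (dl, dt), (dr, db), (dr, dt)):
        area = area + _corner_area(dxe, dye, r)
    return float(area) if np.isscalar(x) else area


def fitness(C, h, params: SimParams):
    """Per-timestep survival probability from competition load and habitat.

    ``"scaled"`` mode (default): W = h / (1 + rho C).
    ``"printed"`` mode: W = 1 / (1 + rho C / h).
    Clamped to [0, 1]; rejects h <= 0 and C < 0.
    """
    Ca = np.asarray(C, dtype=float)
    ha = np.asarray(h, dtype=float)
    if np.any(ha <= 0):
        raise ValueError("habitat fitness h must be positive")
    if np.any(Ca < 0):
        raise ValueError("competition load must be non-negative")
    if params.habitat_mode == "printed":
        w = 1.0 / (1.0 + params.rho * Ca / ha)
    else:
        w = ha / (1.0 + params.rho * Ca)
    w = np.clip(w, 0.0, 1.0)
    return float(w) if np.isscalar(C) and np.isscalar(h) else w


# ---------------------------------------------------------------------------
# individual-level reference operations
#
# The engine below is a vectorized equivalent of these; they define the
# per-individual semantics and are what unit tests exercise directly.


@dataclass
class Individual:
    """A diploid, aged, pedigree-linked individual at a continuous position."""

    id: int
    x: float
    y: float
    age: int = 0
    parent_ids: tuple | None = None
    offspring_count: int = 0
    genome: tuple | None = None  # pair of genetics.Haplotype
    alive: bool = True
    birth_timestep: int = 0

    @property
    def pos(self) -> tuple:
        return (self.x, self.y)


def competition_load(focal: Individual, population, params: SimParams, range_rect) -> float:
    """Edge-corrected competition load C_i on the focal individual.

    Kernel-weighted sum over all other individuals within 3 sigma, scaled by
    (full disc area) / (disc area clipped to the range rectangle).
    """
    R = params.interaction_radius
    total = 0.0
    for other in population:
        if other is focal or not other.alive:
            continue
        d = math.hypot(other.x - focal.x, other.y - focal.y)
        if d < R:
            total += interaction_strength(d, params.sigma)
    if total == 0.0:
        return 0.0
    area = clipped_interaction_area(focal.x, focal.y, R, range_rect)
    return total * (math.pi * R * R) / area


def choose_mate(focal: Individual, population, params: SimParams, rng) -> Individual | None:
    """Draw one mate within 3 sigma with probability proportional to the kernel.

    Returns None when no other living individual is in interaction range
    (no offspring this timestep).
    """
    R = params.interaction_radius
    cands, weights = [], []
    for other in population:
        if other is focal or not other.alive:
            continue
        d = math.hypot(other.x - focal.x, other.y - focal.y)
        if d < R:
            cands.append(other)
            weights.append(interaction_strength(d, params.sigma))
    if not cands:
        return None
    w = np.asarray(weights)
    return cands[rng.choice(len(cands), p=w / w.sum())]


def reproduce(focal: Individual, mate: Individual, params: SimParams, rng,
              id_start: int = 0, timestep: int = 0) -> list:
    """Poisson(1/L) offspring at the focal's position (pre-dispersal).

    Increments both parents' lifetime offspring tallies.  Self-mating is
    rejected (the species is self-incompatible).
    """
    if mate is focal or mate.id == focal.id:
        raise ValueError("self-incompatible: focal cannot mate with itself")
    if not (focal.alive and mate.alive):
        raise ValueError("both parents must be alive")
    n = int(rng.poisson(params.lambda_fec))
    kids = [
        Individual(
            id=id_start + k,
            x=focal.x,
            y=focal.y,
            age=0,
            parent_ids=(focal.id, mate.id),
            birth_timestep=timestep,
        )
        for k in range(n)
    ]
    focal.offspring_count += n
    mate.offspring_count += n
    return kids


def disperse(offspring: Individual, params: SimParams, range_rect, rng) -> Individual | None:
    """Natal dispersal: Normal(0, sigma) displacement per axis, absorbing edges.

    Returns the individual at its settled position, or None when it crossed
    the range boundary (a boundary death).  Only age-0 individuals disperse.
    """
    if offspring.age != 0:
        raise ValueError("only newborn (age 0) individuals disperse")
    x0, y0, x1, y1 = range_rect
    dx, dy = rng.normal(0.0, params.sigma, size=2)
    nx, ny = offspring.x + dx, offspring.y + dy
    if not (x0 <= nx <= x1 and y0 <= ny <= y1):
        return None
    offspring.x, offspring.y = float(nx), float(ny)
    return offspring


# ---------------------------------------------------------------------------
# sampling plan and results


@dataclass
class SamplingPlan:
    """What to record during a run, and when.

    All times are end-of-timestep.  ``snapshots`` maps a label to
    ``(timestep, sample_size)`` -- random individuals whose genotypes are
    kept for diversity analysis.  ``region_groups`` are named rectangles
    sampled at ``region_time``.  ``anchor_times`` re-anchor ancestry-segment
    labels to the individuals alive at that time; ``descendant_time`` samples
    ``n_descendants`` individuals whose ancestry clouds are computed against
    every anchor.  ``inject_time`` activates genomes (founder diversity).
    """

    inject_time: int | None = None
    snapshots: dict = field(default_factory=dict)
    region_time: int | None = None
    region_groups: dict = field(default_factory=dict)
    region_n: int = 50
    anchor_times: tuple = ()
    descendant_time: int | None = None
    n_descendants: int = 4
    relatedness_start: int | None = None


@dataclass
class SampleGroup:
    """A sampled group: ids, positions and haplotype pairs at one timestep."""

    label: str
    timestep: int
    ids: np.ndarray
    x: np.ndarray
    y: np.ndarray
    haplotypes: list  # list of (Haplotype, Haplotype) per individual
    requested_n: int = 0

    @property
    def n(self) -> int:
        return len(self.ids)

    @property
    def shortfall(self) -> int:
        return max(0, self.requested_n - self.n)


@dataclass
class SimResult:
    """Output of one replicate run."""

    params: SimParams
    schedule: ContractionSchedule
    seed: int
    timeseries: pd.DataFrame
    samples: dict
    region_samples: dict
    pedigree: "gen.PedigreeLog"
    anchors: dict  # anchor time -> {"ids": array, "x": array, "y": array}
    descendants: list  # list of (id, x, y, (hapA, hapB))
    extinct: bool
    extinct_at: int | None
    final_n: int
    final_population: pd.DataFrame | None = None


# ---------------------------------------------------------------------------
# vectorized engine internals


def _segmented_weighted_choice(i_sorted, w_sorted, starts, counts, u):
    """For each segment of (i_sorted, w_sorted), pick one index ~ weights.

    ``starts``/``counts`` delimit segments (one per focal with candidates);
    ``u`` is one uniform draw per segment.  Returns positions into the
    sorted arrays.
    """
    cw = np.cumsum(w_sorted)
    base = np.where(starts > 0, cw[starts - 1], 0.0)
    totals = cw[starts + counts - 1] - base
    targets = base + u * totals
    pick = np.searchsorted(cw, targets, side="left")
    return np.clip(pick, starts, starts + counts - 1)


def _pair_kernel_sums(pos: np.ndarray, sigma: float, n_out: int) -> np.ndarray:
    """Kernel-weighted neighbour sums (excluding self) for all points."""
    R = 3.0 * sigma
    m = kernel_max(sigma)
    tree = cKDTree(pos)
    pairs = tree.query_pairs(r=R, output_type="ndarray")
    sums = np.zeros(n_out)
    if len(pairs):
        d2 = np.sum((pos[pairs[:, 0]] - pos[pairs[:, 1]]) ** 2, axis=1)
        w = m * np.exp(-d2 / (2.0 * sigma * sigma))
        sums += np.bincount(pairs[:, 0], weights=w, minlength=n_out)
        sums += np.bincount(pairs[:, 1], weights=w, minlength=n_out)
    return sums


class _Engine:
    """Mutable state of one run (struct-of-arrays over living individuals)."""

    def __init__(self, params: SimParams, schedule: ContractionSchedule,
                 grid: FitnessGrid, seed: int, plan: SamplingPlan):
        self.params = params
        self.schedule = schedule
        self.grid = grid
        self.plan = plan
        self.seed = seed
        ss = np.random.SeedSequence(seed)
        sim_ss, samp_ss = ss.spawn(2)
        self.rng = np.random.default_rng(sim_ss)
        self.rng_sample = np.random.default_rng(samp_ss)
        self.rect = (0.0, 0.0, grid.width, grid.height)
        self.pedigree = gen.PedigreeLog()
        self.genetics_on = False

        # founders: uniform positions at carrying capacity, age 0
        n0 = int(round(params.K * grid.n_cells))
        self.x = self.rng.uniform(0.0, grid.width, n0)
        self.y = self.rng.uniform(0.0, grid.height, n0)
        self.age = np.zeros(n0, dtype=np.int64)
        self.noff = np.zeros(n0, dtype=np.int64)
        self.ids = np.array(
            [self.pedigree.add(-1, -1, 0, xx, yy) for xx, yy in zip(self.x, self.y)],
            dtype=np.int64,
        )
        self.haps: list = [None] * n0
        self.records: list = []
        self.samples: dict = {}
        self.region_samples: dict = {}
        self.anchors: dict = {}
        self.descendants: list = []
        self.extinct = False
        self.extinct_at: int | None = None

    # -- per-step phases ------------------------------------------------

    def n_alive(self) -> int:
        return len(self.ids)

    def _reproduction(self, t: int):
        """Mate choice + Poisson births for every living focal individual.

        Returns arrays describing surviving (post-dispersal) newborns and the
        number of boundary deaths.
        """
        p = self.params
        n = self.n_alive()
        empty = (np.empty(0, dtype=np.intp), np.empty(0, dtype=np.intp),
                 np.empty(0), np.empty(0), 0)
        if n < 2:
            return empty
        pos = np.column_stack([self.x, self.y])
        R = p.interaction_radius
        tree = cKDTree(pos)
        pairs = tree.query_pairs(r=R, output_type="ndarray")
        # each individual is focal exactly once; candidates are neighbours < 3 sigma
        i = np.concatenate([pairs[:, 0], pairs[:, 1]])
        j = np.concatenate([pairs[:, 1], pairs[:, 0]])
        d2 = np.sum((pos[pairs[:, 0]] - pos[pairs[:, 1]]) ** 2, axis=1)
        w = np.exp(-d2 / (2.0 * p.sigma * p.sigma))  # kernel max cancels
        w = np.concatenate([w, w])
        order = np.argsort(i, kind="stable")
        i_s, j_s, w_s = i[order], j[order], w[order]
        counts = np.bincount(i_s, minlength=n)
        has_cand = counts > 0
        starts = np.concatenate([[0], np.cumsum(counts)])[:-1]

        # one uniform per focal, one Poisson per focal (drawn for all to keep
        # the stream layout independent of neighbourhood structure)
        u = self.rng.random(n)
        n_off_all = self.rng.poisson(p.lambda_fec, size=n)
        focal_idx = np.nonzero(has_cand)[0]
        picks = _segmented_weighted_choice(
            i_s, w_s, starts[focal_idx], counts[focal_idx], u[focal_idx]
        )
        mate_of = np.full(n, -1, dtype=np.intp)
        mate_of[focal_idx] = j_s[picks]
        n_off = np.where(has_cand, n_off_all, 0)

        parents_f = np.repeat(np.arange(n), n_off)
        if len(parents_f) == 0:
            return empty
        parents_m = mate_of[parents_f]
        bx = self.x[parents_f] + self.rng.normal(0.0, p.sigma, len(parents_f))
        by = self.y[parents_f] + self.rng.normal(0.0, p.sigma, len(parents_f))
        inside = (bx >= 0) & (bx <= self.rect[2]) & (by >= 0) & (by <= self.rect[3])
        boundary_deaths = int(len(parents_f) - inside.sum())
        # lifetime tallies count all offspring produced, boundary deaths included
        self.noff += np.bincount(parents_f, minlength=n)
        self.noff += np.bincount(parents_m, minlength=n)
        return parents_f[inside], parents_m[inside], bx[inside], by[inside], boundary_deaths

    def _make_newborns(self, t, pf, pm, bx, by):
        """Create ids, pedigree entries and (if active) genomes for newborns."""
        kid_ids = np.empty(len(pf), dtype=np.int64)
        kid_haps = []
        for k in range(len(pf)):
            fi, mi = pf[k], pm[k]
            kid_ids[k] = self.pedigree.add(self.ids[fi], self.ids[mi], t, bx[k], by[k])
            if self.genetics_on:
                ha = gen.gamete(self.haps[fi][0], self.haps[fi][1], self.params, self.rng)
                hb = gen.gamete(self.haps[mi][0], self.haps[mi][1], self.params, self.rng)
                kid_haps.append((ha, hb))
            else:
                kid_haps.append(None)
        return kid_ids, kid_haps

    def _survival(self, t, bx, by):
        """Competition + habitat survival over adults and newborns jointly."""
        p = self.params
        n_a, n_b = self.n_alive(), len(bx)
        ax = np.concatenate([self.x, bx])
        ay = np.concatenate([self.y, by])
        total = n_a + n_b
        if total == 0:
            return np.empty(0, dtype=bool)
        pos = np.column_stack([ax, ay])
        C_raw = _pair_kernel_sums(pos, p.sigma, total)
        R = p.interaction_radius
        full = math.pi * R * R
        # edge correction only matters within R of a boundary
        near = (
            (ax < R) | (ax > self.rect[2] - R) | (ay < R) | (ay > self.rect[3] - R)
        )
        factor = np.ones(total)
        if near.any():
            areas = clipped_interaction_area(ax[near], ay[near], R, self.rect)
            factor[near] = full / areas
        C = C_raw * factor
        h = self.grid.fitness_at_unchecked(ax, ay)
        W = fitness(C, h, p)
        return self.rng.random(total) < W

    def step(self, t: int):
        """Execute one timestep; returns the observable record."""
        # (1) contraction
        cells = self.schedule.cells_at(t)
        if cells is not None:
            self.grid = self.grid.with_cells(cells, 0.1)
        # (2) reproduction, (3) dispersal
        pf, pm, bx, by, boundary_deaths = self._reproduction(t)
        kid_ids, kid_haps = self._make_newborns(t, pf, pm, bx, by)
        births = len(kid_ids)
        # (4) survival of everyone
        survive = self._survival(t, bx, by)
        n_a = self.n_alive()
        sa, sb = survive[:n_a], survive[n_a:]
        dead_ids = np.concatenate([self.ids[~sa], kid_ids[~sb]])
        for did in dead_ids:
            self.pedigree.set_death(int(did), t)
        # (5) aging: only individuals that existed at step start
        new_age = np.concatenate([self.age[sa] + 1, np.zeros(int(sb.sum()), dtype=np.int64)])
        self.ids = np.concatenate([self.ids[sa], kid_ids[sb]])
        self.x = np.concatenate([self.x[sa], bx[sb]])
        self.y = np.concatenate([self.y[sa], by[sb]])
        self.noff = np.concatenate([self.noff[sa], np.zeros(int(sb.sum()), dtype=np.int64)])
        self.age = new_age
        self.haps = [h for h, s in zip(self.haps, sa) if s] + [
            h for h, s in zip(kid_haps, sb) if s
        ]
        # (6) observables
        n = self.n_alive()
        rec = {
            "t": t,
            "n": n,
            "births": births,
            "boundary_deaths": boundary_deaths,
            "mean_age": float(self.age.mean()) if n else np.nan,
            "max_age": int(self.age.max()) if n else 0,
            "mean_offspring": float(self.noff.mean()) if n else np.nan,
            "fr": np.nan,
        }
        plan, p = self.plan, self.params
        if (
            plan.relatedness_start is not None
            and t >= plan.relatedness_start
            and (t - plan.relatedness_start) % p.relatedness_cadence == 0
            and n >= 2
        ):
            k = min(p.relatedness_sample, n)
            sel = self.rng_sample.choice(n, size=k, replace=False)
            # the per-timestep F_r series uses a shallow close-kin truncation
            # (cost grows explosively with depth once the population is
            # fully interrelated); kinship_depth remains available for
            # one-off deep queries
            rec["fr"] = gen.avg_sampled_relatedness(
                self.ids[sel], self.pedigree, max_depth=p.relatedness_depth
            )
        self.records.append(rec)
        return rec

    # -- scheduled actions at end of step -------------------------------

    def _activate_genetics(self, t: int):
        haps = gen.inject_founder_diversity(
            self.n_alive(), self.params.founder_theta, self.params, self.rng
        )
        self.haps = [
            (gen.Haplotype(haps[2 * k], {t: gen.self_segments(int(i), self.params)[0]}),
             gen.Haplotype(haps[2 * k + 1], {t: gen.self_segments(int(i), self.params)[1]}))
            for k, i in enumerate(self.ids)
        ]
        self.genetics_on = True

    def _anchor(self, t: int):
        """Re-anchor ancestry labels to the individuals alive right now.

        Earlier layers are kept only if they are themselves planned anchors
        (the founder layer from injection is dropped at the first re-anchor;
        it has served its purpose of seeding the segment bookkeeping).
        """
        keep = set(self.plan.anchor_times)
        for k, i in enumerate(self.ids):
            segs = gen.self_segments(int(i), self.params)
            ha, hb = self.haps[k]
            ha.layers = {a: v for a, v in ha.layers.items() if a in keep} | {t: segs[0]}
            hb.layers = {a: v for a, v in hb.layers.items() if a in keep} | {t: segs[1]}
        self.anchors[t] = {"ids": self.ids.copy(), "x": self.x.copy(), "y": self.y.copy()}

    def _snapshot(self, label: str, t: int, size: int):
        k = min(size, self.n_alive())
        sel = self.rng_sample.choice(self.n_alive(), size=k, replace=False)
        self.samples[label] = SampleGroup(
            label, t, self.ids[sel].copy(), self.x[sel].copy(), self.y[sel].copy(),
            [self.haps[s] for s in sel], requested_n=size,
        )

    def _sample_regions(self, t: int):
        for name, (rx0, ry0, rx1, ry1) in self.plan.region_groups.items():
            mask = (self.x >= rx0) & (self.x < rx1) & (self.y >= ry0) & (self.y < ry1)
            idx = np.nonzero(mask)[0]
            k = min(self.plan.region_n, len(idx))
            sel = self.rng_sample.choice(idx, size=k, replace=False) if k else idx[:0]
            self.region_samples[name] = SampleGroup(
                name, t, self.ids[sel].copy(), self.x[sel].copy(), self.y[sel].copy(),
                [self.haps[s] for s in sel], requested_n=self.plan.region_n,
            )

    def _sample_descendants(self, t: int):
        k = min(self.plan.n_descendants, self.n_alive())
        sel = self.rng_sample.choice(self.n_alive(), size=k, replace=False)
        self.descendants = [
            (int(self.ids[s]), float(self.x[s]), float(self.y[s]), self.haps[s]) for s in sel
        ]

    def end_of_step(self, t: int):
        plan = self.plan
        if plan.inject_time is not None and t == plan.inject_time and not self.extinct:
            self._activate_genetics(t)
        if self.genetics_on and t in plan.anchor_times:
            self._anchor(t)
        if self.genetics_on:
            for label, (st, size) in plan.snapshots.items():
                if st == t:
                    self._snapshot(label, t, size)
        if plan.region_time == t and self.genetics_on:
            self._sample_regions(t)
        if plan.descendant_time == t and self.genetics_on:
            self._sample_descendants(t)


def total_steps(params: SimParams, schedule: ContractionSchedule) -> int:
    """Last simulated timestep: final event (or burn-in end) + post_run."""
    final = schedule.final_event_time
    if final is None:
        final = params.burn_in
    return final + params.post_run


def run(
    params: SimParams,
    schedule: ContractionSchedule,
    grid: FitnessGrid,
    seed: int,
    plan: SamplingPlan | None = None,
) -> SimResult:
    """Run one replicate: burn-in, contraction events, post-run.

    Timesteps are 1-based; scheduled times in ``schedule`` and ``plan`` refer
    to the end of that timestep.  Fully reproducible from ``seed`` (one
    master SeedSequence spawns separate simulation and sampling streams).
    If the population goes extinct the run terminates early with the flag
    set and all partial outputs preserved.
    """
    if schedule.nx != grid.nx or schedule.ny != grid.ny:
        raise ValueError("schedule and grid dimensions disagree")
    if plan is None:
        plan = SamplingPlan()
    first = schedule.first_event_time
    if plan.inject_time is not None and first is not None and plan.inject_time >= first:
        raise ValueError("genetics must activate before the first contraction event")
    eng = _Engine(params, schedule, grid, seed, plan)
    T = total_steps(params, schedule)
    for t in range(1, T + 1):
        rec = eng.step(t)
        if rec["n"] == 0:
            eng.extinct = True
            eng.extinct_at = t
            break
        eng.end_of_step(t)
    ts = pd.DataFrame(eng.records)
    p1 = np.asarray(eng.pedigree.parent1, dtype=np.int64)
    p2 = np.asarray(eng.pedigree.parent2, dtype=np.int64)
    final_pop = pd.DataFrame(
        {
            "id": eng.ids,
            "x": eng.x,
            "y": eng.y,
            "age": eng.age,
            "parent1": p1[eng.ids] if len(eng.ids) else np.empty(0, dtype=np.int64),
            "parent2": p2[eng.ids] if len(eng.ids) else np.empty(0, dtype=np.int64),
            "offspring": eng.noff,
        }
    )
    return SimResult(
        params=params,
        schedule=schedule,
        seed=seed,
        timeseries=ts,
        samples=eng.samples,
        region_samples=eng.region_samples,
        pedigree=eng.pedigree,
        anchors=eng.anchors,
        descendants=eng.descendants,
        extinct=eng.extinct,
        extinct_at=eng.extinct_at,
        final_n=int(ts["n"].iloc[-1]) if len(ts) else 0,
        final_population=final_pop,
    )
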