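"""Habitat landscape: the fitness grid and range-contraction schedules.

The range is a continuous rectangle tiled by ``nx x ny`` unit cells, each
carrying a habitat-fitness value ``h`` in (0, 1].  Before a contraction every
cell has ``h = 1.0``; a contraction event drops a set of cells to
``h = 0.1``.  Fitness is read at continuous coordinates by bilinear
interpolation between the four surrounding cell *centers* (cell ``(ix, iy)``
has its center at ``(ix + 0.5, iy + 0.5)``), so the transition between good
and contracted habitat is smooth rather than stepped.

Three deterministic contraction geometries are provided, plus a seeded random
one:

* ``shrinkage`` -- peripheral rings are removed around a shrinking centered
  rectangle; the final remnant on a 20x20 grid is the centered 8x6 block.
* ``amputation`` -- a row-major sweep from the top edge downward (an
  advancing extinction front); the remnant hugs the bottom edge.
* ``fragmentation`` -- the central cross is removed first, severing the range
  into quadrants, which are then eroded down to four corner patches (two of
  16 cells, two of 8).
* ``random_fragmentation`` -- cells drawn uniformly without replacement from
  a seeded generator.

Cell indices are 0-based ``(ix, iy)`` with the origin at the lower-left
corner and 1 distance unit per cell side.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import yaml

__all__ = [
    "FitnessGrid",
    "ContractionSchedule",
    "build_grid",
    "habitat_fitness_at",
    "make_schedule",
    "apply_contraction",
    "PATTERNS",
]

PATTERNS = ("shrinkage", "amputation", "fragmentation", "random_fragmentation", "none")

#: habitat fitness assigned to contracted cells
CONTRACTED_FITNESS = 0.1


class OutOfRangeError(ValueError):
    """Raised when a coordinate falls outside the range rectangle."""


@dataclass(frozen=True)
class FitnessGrid:
    """Cell-valued habitat fitness over a continuous rectangular range.

    ``values[ix, iy]`` is the fitness of cell ``(ix, iy)``; the continuous
    extent is ``[0, nx] x [0, ny]`` distance units (1 unit per cell side).
    """

    nx: int
    ny: int
    values: np.ndarray

    def __post_init__(self) -> None:
        if self.nx < 2 or self.ny < 2:
            raise ValueError(f"grid dimensions must be >= 2, got {self.nx}x{self.ny}")
        v = np.asarray(self.values, dtype=float)
        if v.shape != (self.nx, self.ny):
            raise ValueError(f"values shape {v.shape} != ({self.nx}, {self.ny})")
        if np.any(v <= 0) or np.any(v > 1):
            raise ValueError("cell fitness values must lie in (0, 1]")
        object.__setattr__(self, "values", v)

    @property
    def width(self) -> float:
        return float(self.nx)

    @property
    def height(self) -> float:
        return float(self.ny)

    @property
    def n_cells(self) -> int:
        return self.nx * self.ny

    def fitness_at(self, x, y):
        """Bilinearly interpolated habitat fitness at continuous coordinates.

        Accepts scalars or arrays.  Raises :class:`OutOfRangeError` for
        coordinates outside the range rectangle.  Beyond the outermost cell
        centers the value is clamped (constant extrapolation), so the result
        is always bounded by the surrounding cell values and is exact at cell
        centers.
        """
        xa = np.asarray(x, dtype=float)
        ya = np.asarray(y, dtype=float)
        if np.any(xa < 0) or np.any(xa > self.nx) or np.any(ya < 0) or np.any(ya > self.ny):
            raise OutOfRangeError("coordinate outside the range rectangle")
        out = self.fitness_at_unchecked(xa, ya)
        if np.isscalar(x) or (xa.ndim == 0 and np.isscalar(y)):
            return float(out)
        return out

    def fitness_at_unchecked(self, xa: np.ndarray, ya: np.ndarray) -> np.ndarray:
        """Vectorized bilinear interpolation without bounds checking."""
        u = np.clip(xa - 0.5, 0.0, self.nx - 1.0)
        v = np.clip(ya - 0.5, 0.0, self.ny - 1.0)
        i0 = np.minimum(u.astype(np.intp), self.nx - 2)
        j0 = np.minimum(v.astype(np.intp), self.ny - 2)
        fx = u - i0
        fy = v - j0
        g = self.values
        return (
            g[i0, j0] * (1 - fx) * (1 - fy)
            + g[i0 + 1, j0] * fx * (1 - fy)
            + g[i0, j0 + 1] * (1 - fx) * fy
            + g[i0 + 1, j0 + 1] * fx * fy
        )

    def with_cells(self, cells, value: float) -> "FitnessGrid":
        """Return a new grid with ``cells`` set to ``value``."""
        new = self.values.copy()
        for ix, iy in cells:
            if not (0 <= ix < self.nx and 0 <= iy < self.ny):
                raise ValueError(f"cell index ({ix}, {iy}) outside {self.nx}x{self.ny} grid")
            new[ix, iy] = value
        return FitnessGrid(self.nx, self.ny, new)

    def to_tsv(self, path) -> None:
        """Plain-text matrix snapshot: rows are y from top to bottom."""
        np.savetxt(path, self.values.T[::-1], fmt="%.3f", delimiter="\t")

    @classmethod
    def from_tsv(cls, path) -> "FitnessGrid":
        mat = np.loadtxt(path, delimiter="\t", ndmin=2)
        return cls(mat.shape[1], mat.shape[0], mat[::-1].T)


def build_grid(nx: int, ny: int, init_fitness: float = 1.0) -> FitnessGrid:
    """Build a uniform habitat grid (default: pristine range, all cells 1.0)."""
    if nx < 2 or ny < 2:
        raise ValueError(f"grid dimensions must be >= 2, got {nx}x{ny}")
    if not (0 < init_fitness <= 1):
        raise ValueError(f"init_fitness must be in (0, 1], got {init_fitness}")
    return FitnessGrid(nx, ny, np.full((nx, ny), float(init_fitness)))


def habitat_fitness_at(grid: FitnessGrid, x: float, y: float) -> float:
    """Habitat fitness at a continuous point (bilinear; see FitnessGrid.fitness_at)."""
    return grid.fitness_at(x, y)


def apply_contraction(grid: FitnessGrid, event, value: float = CONTRACTED_FITNESS) -> FitnessGrid:
    """Apply one contraction event: listed cells drop to ``value`` (default 0.1)."""
    return grid.with_cells(event, value)


@dataclass(frozen=True)
class ContractionSchedule:
    """Timed, disjoint cell sets whose fitness drops to 0.1.

    ``events`` is an ordered list of ``(timestep, frozenset of (ix, iy))``;
    events are strictly increasing in time and pairwise disjoint in cells.
    """

    pattern: str
    nx: int
    ny: int
    events: tuple = field(default_factory=tuple)
    frac_per_event: float = 0.22
    interval: int = 100
    start: int = 0

    def __post_init__(self) -> None:
        if self.pattern not in PATTERNS:
            raise ValueError(f"unknown contraction pattern {self.pattern!r}")
        times = [t for t, _ in self.events]
        if any(t2 <= t1 for t1, t2 in zip(times, times[1:])):
            raise ValueError("event timesteps must be strictly increasing")
        seen: set = set()
        for _, cells in self.events:
            if seen & set(cells):
                raise ValueError("event cell sets must be disjoint")
            seen |= set(cells)

    @property
    def n_events(self) -> int:
        return len(self.events)

    @property
    def first_event_time(self):
        return self.events[0][0] if self.events else None

    @property
    def final_event_time(self):
        return self.events[-1][0] if self.events else None

    def cells_at(self, t: int):
        """Cells of the event scheduled exactly at timestep ``t`` (or None)."""
        for et, cells in self.events:
            if et == t:
                return cells
        return None

    def cumulative_cells(self, k: int | None = None) -> frozenset:
        """Union of the first ``k`` events' cells (all events if ``k`` is None)."""
        k = self.n_events if k is None else k
        out: set = set()
        for _, cells in self.events[:k]:
            out |= set(cells)
        return frozenset(out)

    def removed_fraction(self, k: int | None = None) -> float:
        return len(self.cumulative_cells(k)) / (self.nx * self.ny)

    def remnant_cells(self) -> frozenset:
        """Cells never contracted by this schedule."""
        gone = self.cumulative_cells()
        return frozenset(
            (ix, iy) for ix in range(self.nx) for iy in range(self.ny) if (ix, iy) not in gone
        )

    # -- serialization --------------------------------------------------

    def to_dict(self) -> dict:
        return {
            "pattern": self.pattern,
            "nx": self.nx,
            "ny": self.ny,
            "frac_per_event": self.frac_per_event,
            "interval": self.interval,
            "start": self.start,
            "events": [[int(t), sorted([int(a), int(b)] for a, b in cells)] for t, cells in self.events],
        }

    @classmethod
    def from_dict(cls, d: dict) -> "ContractionSchedule":
        events = tuple(
            (int(t), frozenset((int(a), int(b)) for a, b in cells)) for t, cells in d["events"]
        )
        return cls(
            pattern=d["pattern"],
            nx=int(d["nx"]),
            ny=int(d["ny"]),
            events=events,
            frac_per_event=float(d.get("frac_per_event", 0.22)),
            interval=int(d.get("interval", 100)),
            start=int(d.get("start", 0)),
        )

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh)

    @classmethod
    def from_yaml(cls, path) -> "ContractionSchedule":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))


# ---------------------------------------------------------------------------
# deterministic removal orders for the named geometries


def _shrinkage_order(nx: int, ny: int) -> list:
    # Rectangular "rings": distance from center scaled so the remnant keeps a
    # 4:3 footprint (on 20x20 the final 48 cells are the centered 8x6 block).
    cx, cy = (nx - 1) / 2.0, (ny - 1) / 2.0
    cells = [(ix, iy) for ix in range(nx) for iy in range(ny)]
    key = lambda c: (-max(abs(c[0] - cx) / nx, abs(c[1] - cy) / (0.75 * ny)), c[0], c[1])
    return sorted(cells, key=key)


def _amputation_order(nx: int, ny: int) -> list:
    # Row-major sweep from the top edge downward.
    return [(ix, iy) for iy in range(ny - 1, -1, -1) for ix in range(nx)]


def _fragmentation_patches(nx: int, ny: int) -> dict:
    """The four remnant corner patches (two of 16 cells, two of 8)."""
    return {
        "topleft": frozenset((ix, iy) for ix in range(4) for iy in range(ny - 4, ny)),
        "topright": frozenset((ix, iy) for ix in range(nx - 4, nx) for iy in range(ny - 2, ny)),
        "bottomleft": frozenset((ix, iy) for ix in range(2) for iy in range(4)),
        "bottomright": frozenset((ix, iy) for ix in range(nx - 4, nx) for iy in range(4)),
    }


def _fragmentation_order(nx: int, ny: int) -> list:
    # Central cross first (severs connectivity between quadrants at the first
    # event), then erode outward; the corner patches are never removed.
    keep: set = set()
    for patch in _fragmentation_patches(nx, ny).values():
        keep |= patch
    cx, cy = (nx - 1) / 2.0, (ny - 1) / 2.0
    cells = [(ix, iy) for ix in range(nx) for iy in range(ny) if (ix, iy) not in keep]
    key = lambda c: (min(abs(c[0] - cx), abs(c[1] - cy)), c[0], c[1])
    return sorted(cells, key=key)


def make_schedule(
    pattern: str,
    nx: int = 20,
    ny: int = 20,
    n_events: int = 4,
    frac_per_event: float = 0.22,
    interval: int = 100,
    start: int = 0,
    seed: int | None = None,
) -> ContractionSchedule:
    """Build a contraction schedule for one of the named geometries.

    ``n_events`` events of ``round(frac_per_event * nx * ny)`` cells each
    (whole-cell rounding distributed across events), ``interval`` timesteps
    apart, starting at ``start``.  The deterministic patterns ignore ``seed``;
    ``random_fragmentation`` draws cells uniformly without replacement from
    ``numpy.random.default_rng(seed)``.
    """
    if pattern not in PATTERNS:
        raise ValueError(f"unknown contraction pattern {pattern!r}; choose from {PATTERNS}")
    if n_events < 0 or frac_per_event < 0:
        raise ValueError("n_events and frac_per_event must be non-negative")
    if n_events * frac_per_event > 1.0 + 1e-12:
        raise ValueError(
            f"cannot remove {n_events} x {frac_per_event:.2f} = "
            f"{n_events * frac_per_event:.2f} > 100% of the range"
        )
    if pattern == "none" or n_events == 0:
        return ContractionSchedule(pattern, nx, ny, (), frac_per_event, interval, start)

    total = round(n_events * frac_per_event * nx * ny)
    if pattern == "random_fragmentation":
        rng = np.random.default_rng(seed)
        flat = rng.choice(nx * ny, size=total, replace=False)
        order = [(int(f) // ny, int(f) % ny) for f in flat]
    elif pattern == "shrinkage":
        order = _shrinkage_order(nx, ny)[:total]
    elif pattern == "amputation":
        order = _amputation_order(nx, ny)[:total]
    else:  # fragmentation
        order = _fragmentation_order(nx, ny)
        if len(order) < total:
            raise ValueError(
                "fragmentation schedule would remove the remnant corner patches; "
                "lower n_events * frac_per_event"
            )
        order = order[:total]

    # distribute whole cells as evenly as possible across events
    base, extra = divmod(total, n_events)
    events = []
    pos = 0
    for k in range(n_events):
        n_k = base + (1 if k < extra else 0)
        events.append((start + k * interval, frozenset(order[pos : pos + n_k])))
        pos += n_k
    return ContractionSchedule(pattern, nx, ny, tuple(events), frac_per_event, interval, start)
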