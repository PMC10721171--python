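"""Spatial grid of farm cells: tessellation, crops, pesticides, rotation, edges.

The landscape is an ``xdim x ydim`` grid of cells.  Each cell belongs to a
farm; each farm holds exactly one crop type and one pesticide type at a
time.  Crops and pesticides rotate independently on fixed clocks, amounts
are reset farm-wide on every rotation event, and crop amounts can grow
between rotations.  Pest movement off the grid is resolved by one of four
edge behaviours: torus wrap, reflection, sticking to the boundary, or leaky
removal.

Coordinates are 0-based ``(x, y)`` with ``x`` the column index; grids are
stored as arrays indexed ``[x, y]``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "Landscape",
    "RotationPolicy",
    "splitline_farms",
    "load_terrain",
    "init_assignments",
    "rotate",
    "rotate_assignments",
    "grow_crops",
    "resolve_edge",
    "resolve_edges",
]

EDGE_MODES = ("leaky", "reflect", "sticky", "torus")

#: Sentinel returned by :func:`resolve_edge` when a leaky edge removes a pest.
REMOVED = None

MAX_TYPES = 10  # at most 10 crop types and 10 pesticide types


@dataclass
class Landscape:
    """Grid state: farm ids plus current crop/pesticide types and amounts."""

    farm_id: np.ndarray          # (xdim, ydim) int, values 1..farms
    crop_type: np.ndarray        # (xdim, ydim) int, values 1..crop_number
    pesticide_type: np.ndarray   # (xdim, ydim) int, values 1..pesticide_number
    crop_amount: np.ndarray      # (xdim, ydim) float >= 0
    pesticide_amount: np.ndarray  # (xdim, ydim) float >= 0
    land_edge: str = "torus"

    def __post_init__(self) -> None:
        if self.land_edge not in EDGE_MODES:
            raise ValueError(f"land_edge must be one of {EDGE_MODES}")
        shape = self.farm_id.shape
        for name in ("crop_type", "pesticide_type", "crop_amount", "pesticide_amount"):
            if getattr(self, name).shape != shape:
                raise ValueError(f"{name} shape {getattr(self, name).shape} != {shape}")

    @property
    def xdim(self) -> int:
        return self.farm_id.shape[0]

    @property
    def ydim(self) -> int:
        return self.farm_id.shape[1]

    @property
    def farms(self) -> int:
        return int(self.farm_id.max())

    @classmethod
    def build(
        cls,
        farm_id: np.ndarray,
        crop_assign: np.ndarray,
        pesticide_assign: np.ndarray,
        crop_per_cell: float,
        pesticide_per_cell: float,
        land_edge: str = "torus",
    ) -> "Landscape":
        """Assemble a landscape from a farm grid and per-farm type vectors."""
        farm_id = np.asarray(farm_id, dtype=int)
        crop_type = np.asarray(crop_assign, dtype=int)[farm_id - 1]
        pest_type = np.asarray(pesticide_assign, dtype=int)[farm_id - 1]
        return cls(
            farm_id=farm_id,
            crop_type=crop_type,
            pesticide_type=pest_type,
            crop_amount=np.full(farm_id.shape, float(crop_per_cell)),
            pesticide_amount=np.full(farm_id.shape, float(pesticide_per_cell)),
            land_edge=land_edge,
        )

    def apply_crop_assignments(self, assign: np.ndarray, per_cell: float) -> None:
        """Set every farm's crop type from ``assign`` and reset all amounts."""
        self.crop_type = np.asarray(assign, dtype=int)[self.farm_id - 1]
        self.crop_amount = np.full(self.farm_id.shape, float(per_cell))

    def apply_pesticide_assignments(self, assign: np.ndarray, per_cell: float) -> None:
        self.pesticide_type = np.asarray(assign, dtype=int)[self.farm_id - 1]
        self.pesticide_amount = np.full(self.farm_id.shape, float(per_cell))

    def as_array(self) -> np.ndarray:
        """Layered (5, xdim, ydim) array: farm, crop type, crop amount,
        pesticide type, pesticide amount."""
        return np.stack(
            [
                self.farm_id.astype(float),
                self.crop_type.astype(float),
                self.crop_amount,
                self.pesticide_type.astype(float),
                self.pesticide_amount,
            ]
        )


@dataclass
class RotationPolicy:
    """How and when one resource (crop or pesticide) rotates across farms.

    ``mode`` is 1 (none), 2 (random switch to another type), 3 (cycle in
    numeric order), or a right-stochastic transition matrix.  ``period`` is
    the number of time steps between rotation events (0 disables them);
    ``per_cell_reset`` is the amount placed on every cell at each event.
    """

    mode: int | np.ndarray
    period: int
    per_cell_reset: float
    n_types: int

    def __post_init__(self) -> None:
        if not isinstance(self.mode, (int, np.integer)):
            m = np.asarray(self.mode, dtype=float)
            if m.ndim != 2 or m.shape != (self.n_types, self.n_types):
                raise ValueError(
                    f"transition matrix must be {self.n_types} x {self.n_types}"
                )
            if np.any(m < 0) or not np.allclose(m.sum(axis=1), 1.0):
                raise ValueError("transition matrix rows must be non-negative and sum to 1")
            self.mode = m
        elif self.mode not in (1, 2, 3):
            raise ValueError("integer rotation mode must be 1, 2, or 3")

    def due(self, t: int) -> bool:
        """Whether a rotation event happens at the start of step ``t``."""
        return self.period > 0 and t >= 1 and t % self.period == 0


def splitline_farms(
    xdim: int, ydim: int, farms: int, rng: np.random.Generator
) -> np.ndarray:
    """Partition the grid into ``farms`` contiguous rectangles of roughly
    equal area by recursive splitting.

    Each split divides a rectangle's farm quota in two and cuts along the
    longer dimension at a line proportional to the quota split, jittered a
    few percent, so areas stay within a factor ~2 of each other.
    """
    if farms < 1:
        raise ValueError("farms must be >= 1")
    if farms > xdim * ydim:
        raise ValueError(f"cannot fit {farms} farms on {xdim}x{ydim} cells")
    grid = np.zeros((xdim, ydim), dtype=int)
    next_id = [1]

    def split(x0: int, x1: int, y0: int, y1: int, count: int) -> None:
        if count == 1:
            grid[x0:x1, y0:y1] = next_id[0]
            next_id[0] += 1
            return
        k1 = count // 2
        k2 = count - k1
        w, h = x1 - x0, y1 - y0
        along_x = w >= h
        n = w if along_x else h
        other = h if along_x else w
        frac = k1 / count + rng.uniform(-0.04, 0.04)
        cut = int(round(n * frac))
        # each side needs enough cells for its quota
        lo = max(1, -(-k1 // other))          # ceil(k1 / other)
        hi = n - max(1, -(-k2 // other))
        cut = min(max(cut, lo), hi)
        if along_x:
            split(x0, x0 + cut, y0, y1, k1)
            split(x0 + cut, x1, y0, y1, k2)
        else:
            split(x0, x1, y0, y0 + cut, k1)
            split(x0, x1, y0 + cut, y1, k2)

    split(0, xdim, 0, ydim, farms)
    return grid


def load_terrain(matrix, farms: int) -> np.ndarray:
    """Validate a custom farm-id grid: integers 1..farms, every id present.

    Farm cells need not be contiguous.
    """
    grid = np.asarray(matrix)
    if grid.ndim != 2:
        raise ValueError("terrain must be a 2-D matrix")
    if not np.issubdtype(grid.dtype, np.integer):
        as_int = grid.astype(int)
        if not np.array_equal(as_int, grid):
            raise ValueError("terrain entries must be integers")
        grid = as_int
    present = np.unique(grid)
    if present.min() < 1 or present.max() > farms:
        raise ValueError(f"terrain values must lie in 1..{farms}")
    missing = set(range(1, farms + 1)) - set(int(v) for v in present)
    if missing:
        raise ValueError(f"terrain is missing farm ids: {sorted(missing)}")
    return grid.copy()


def init_assignments(
    farms: int, n_types: int, init, rng: np.random.Generator
) -> np.ndarray:
    """Initial per-farm type vector: uniform random or user-specified."""
    if n_types < 1 or n_types > MAX_TYPES:
        raise ValueError(f"number of types must be in 1..{MAX_TYPES}")
    if isinstance(init, str):
        if init != "random":
            raise ValueError(f"unknown init mode {init!r}")
        return rng.integers(1, n_types + 1, size=farms)
    vec = np.asarray(init, dtype=int)
    if vec.shape != (farms,):
        raise ValueError(f"init vector must have length {farms}")
    if vec.min() < 1 or vec.max() > n_types:
        raise ValueError(f"init types must lie in 1..{n_types}")
    return vec.copy()


def rotate_assignments(
    assignments: np.ndarray, mode, n_types: int, rng: np.random.Generator
) -> np.ndarray:
    """One rotation event applied to a per-farm type vector.

    Mode 1 leaves types unchanged; mode 2 draws uniformly among the *other*
    types; mode 3 cycles in numeric order; a transition matrix draws each
    farm's next type from the row of its current type.
    """
    cur = np.asarray(assignments, dtype=int)
    if isinstance(mode, (int, np.integer)):
        if mode == 1:
            return cur.copy()
        if mode == 3:
            return (cur % n_types) + 1
        if mode == 2:
            if n_types == 1:
                return cur.copy()
            # uniform over the other n_types - 1 types
            shift = rng.integers(1, n_types, size=cur.size)
            return ((cur - 1 + shift) % n_types) + 1
        raise ValueError("integer rotation mode must be 1, 2, or 3")
    m = np.asarray(mode, dtype=float)
    if m.shape != (n_types, n_types) or np.any(m < 0) or not np.allclose(
        m.sum(axis=1), 1.0
    ):
        raise ValueError("transition matrix rows must be stochastic")
    out = np.empty_like(cur)
    for i, t in enumerate(cur):
        out[i] = rng.choice(n_types, p=m[t - 1]) + 1
    return out


def rotate(
    assignments: np.ndarray, policy: RotationPolicy, rng: np.random.Generator
) -> np.ndarray:
    return rotate_assignments(assignments, policy.mode, policy.n_types, rng)


def grow_crops(
    landscape: Landscape, crop_growth: float, crop_growth_type: str
) -> Landscape:
    """Per-step crop growth between rotations: proportional or incremental."""
    if crop_growth < 0:
        raise ValueError("crop_growth must be >= 0")
    if crop_growth_type == "proportion":
        landscape.crop_amount = landscape.crop_amount * (1.0 + crop_growth)
    elif crop_growth_type == "increment":
        landscape.crop_amount = landscape.crop_amount + crop_growth
    else:
        raise ValueError("crop_growth_type must be 'proportion' or 'increment'")
    return landscape


def _reflect(coord: np.ndarray, dim: int) -> np.ndarray:
    """Mirror about the grid walls (period 2*dim triangle wave)."""
    p = np.mod(coord, 2 * dim)
    return np.where(p >= dim, 2 * dim - 1 - p, p)


def resolve_edges(
    xs: np.ndarray, ys: np.ndarray, xdim: int, ydim: int, mode: str
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Vectorised edge resolution for candidate coordinates.

    Returns resolved (xs, ys, keep) where ``keep`` is False for pests that
    leave a leaky landscape.
    """
    xs = np.asarray(xs, dtype=np.int64)
    ys = np.asarray(ys, dtype=np.int64)
    keep = np.ones(xs.shape, dtype=bool)
    if mode == "torus":
        xs, ys = np.mod(xs, xdim), np.mod(ys, ydim)
    elif mode == "sticky":
        xs, ys = np.clip(xs, 0, xdim - 1), np.clip(ys, 0, ydim - 1)
    elif mode == "reflect":
        xs, ys = _reflect(xs, xdim), _reflect(ys, ydim)
    elif mode == "leaky":
        keep = (xs >= 0) & (xs < xdim) & (ys >= 0) & (ys < ydim)
    else:
        raise ValueError(f"unknown edge mode {mode!r}")
    return xs, ys, keep


def resolve_edge(x: int, y: int, landscape: Landscape):
    """Scalar edge resolution; returns (x, y) or ``REMOVED`` for leaky exits."""
    xs, ys, keep = resolve_edges(
        np.array([x]), np.array([y]), landscape.xdim, landscape.ydim, landscape.land_edge
    )
    if not keep[0]:
        return REMOVED
    return int(xs[0]), int(ys[0])
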