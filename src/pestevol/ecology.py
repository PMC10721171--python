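"""Pest ecology: the per-time-step schedule of an individual-based simulation.

Each time step executes, in order: landscape change (rotation clocks and
crop growth), pest aging and metabolism, feeding, pesticide uptake,
movement bouts, reproduction, mortality, and immigration, then records one
row of population statistics.  Feeding, pesticide uptake, movement and
reproduction are each gated by an inclusive age window, so the schedule
order need not match the event order experienced by any focal pest.

The population is stored as a struct-of-arrays (:class:`Population`) so
every sub-step is vectorised; sequential semantics that matter (pests
feeding in random order from a depletable cell) are preserved exactly via a
shuffled, per-cell cumulative-consumption computation.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .config import SimConfig
from .genome import GenomeLayout, batch_traits, mutable_positions
from .landscape import Landscape, RotationPolicy, resolve_edges, rotate, grow_crops
from .network import Network

__all__ = [
    "Population",
    "Pest",
    "SimState",
    "init_population",
    "feed_step",
    "pesticide_step",
    "movement_step",
    "reproduction_step",
    "metabolism_step",
    "mortality_step",
    "immigration_step",
    "run_time_step",
]

SEX_ASEXUAL, SEX_MONOECIOUS, SEX_FEMALE, SEX_MALE = 0, 1, 2, 3
SEX_NAMES = {0: "asexual", 1: "monoecious", 2: "female", 3: "male"}


@dataclass
class Pest:
    """Single-individual view of a population row (convenience accessor)."""

    id: int
    age: int
    sex: str
    position: tuple[int, int]
    food_eaten: np.ndarray
    pesticide_taken: np.ndarray
    traits: np.ndarray
    haplotypes: np.ndarray


class Population:
    """Struct-of-arrays container for all living pests."""

    def __init__(
        self,
        layout: GenomeLayout,
        ploidy: int,
        n_crops: int,
        n_pesticides: int,
        n_traits: int,
    ):
        self.layout = layout
        self.ploidy = ploidy
        self.ids = np.empty(0, dtype=np.int64)
        self.age = np.empty(0, dtype=np.int64)
        self.sex = np.empty(0, dtype=np.int8)
        self.x = np.empty(0, dtype=np.int64)
        self.y = np.empty(0, dtype=np.int64)
        self.food = np.empty((0, n_crops))
        self.pesticide = np.empty((0, n_pesticides))
        self.traits = np.empty((0, n_traits))
        self.haps = np.empty((0, ploidy, layout.length))
        # per-step consumption budgets (reset each step)
        self.step_food_used = np.empty(0)
        self.step_pesticide_used = np.empty(0)

    _ARRAYS = (
        "ids", "age", "sex", "x", "y", "food", "pesticide", "traits", "haps",
        "step_food_used", "step_pesticide_used",
    )

    @property
    def size(self) -> int:
        return self.ids.size

    def keep(self, mask: np.ndarray) -> None:
        """Drop every pest where ``mask`` is False."""
        for name in self._ARRAYS:
            setattr(self, name, getattr(self, name)[mask])

    def append(self, **arrays) -> None:
        n = arrays["ids"].size
        arrays.setdefault("step_food_used", np.zeros(n))
        arrays.setdefault("step_pesticide_used", np.zeros(n))
        for name in self._ARRAYS:
            cur = getattr(self, name)
            setattr(self, name, np.concatenate([cur, arrays[name]]))

    def pest(self, i: int) -> Pest:
        return Pest(
            id=int(self.ids[i]),
            age=int(self.age[i]),
            sex=SEX_NAMES[int(self.sex[i])],
            position=(int(self.x[i]), int(self.y[i])),
            food_eaten=self.food[i].copy(),
            pesticide_taken=self.pesticide[i].copy(),
            traits=self.traits[i].copy(),
            haplotypes=self.haps[i].copy(),
        )


@dataclass
class SimState:
    """Mutable simulation state threaded through the per-step functions."""

    cfg: SimConfig
    network: Network
    landscape: Landscape
    pop: Population
    rng: np.random.Generator
    crop_policy: RotationPolicy
    pesticide_policy: RotationPolicy
    crop_assign: np.ndarray
    pesticide_assign: np.ndarray
    t: int = 0
    next_id: int = 0
    deaths_this_step: int = 0
    stats_rows: list = field(default_factory=list)
    _pop_before_mortality: int = 0

    @property
    def trait_means(self) -> np.ndarray:
        return self.cfg.resolved_trait_means(self.network.traits)


def _ploidy(cfg: SimConfig) -> int:
    return 1 if cfg.repro == "asexual" else 2


def _draw_pests(
    n: int, cfg: SimConfig, network: Network, landscape: Landscape,
    rng: np.random.Generator, start_id: int,
) -> dict:
    """Arrays for ``n`` freshly initialised pests (founders or immigrants)."""
    layout = GenomeLayout(network.loci, network.traits, network.layers)
    ploidy = _ploidy(cfg)
    x = rng.integers(0, landscape.xdim, size=n)
    y = rng.integers(0, landscape.ydim, size=n)
    if cfg.rand_age:
        age = rng.integers(0, cfg.max_age + 1, size=n)
    else:
        age = np.zeros(n, dtype=np.int64)
    if cfg.repro == "asexual":
        sex = np.full(n, SEX_ASEXUAL, dtype=np.int8)
    elif cfg.repro == "sexual":
        sex = np.full(n, SEX_MONOECIOUS, dtype=np.int8)
    else:
        sex = np.where(rng.random(n) < 0.5, SEX_FEMALE, SEX_MALE).astype(np.int8)
    net_vals = network.to_flat()
    loci_scale = 1.0
    if ploidy == 2 and cfg.founder_variance_preserving:
        loci_scale = 1.0 / np.sqrt(2.0)
    haps = np.empty((n, ploidy, layout.length))
    for h in range(ploidy):
        haps[:, h, : layout.loci] = loci_scale * rng.standard_normal((n, layout.loci))
        haps[:, h, layout.loci:] = net_vals
    traits = batch_traits(haps, layout, cfg.resolved_trait_means(network.traits))
    return dict(
        ids=np.arange(start_id, start_id + n, dtype=np.int64),
        age=age.astype(np.int64),
        sex=sex,
        x=x.astype(np.int64),
        y=y.astype(np.int64),
        food=np.zeros((n, cfg.crop_number)),
        pesticide=np.zeros((n, cfg.pesticide_number)),
        traits=traits,
        haps=haps,
    )


def init_population(
    cfg: SimConfig, network: Network, landscape: Landscape, rng: np.random.Generator
) -> Population:
    """N0 pests at uniform random cells, ages per ``rand_age``, genomes founded
    on the mined network with fresh N(0,1) loci."""
    cfg.check_traits(network.traits)
    layout = GenomeLayout(network.loci, network.traits, network.layers)
    pop = Population(
        layout, _ploidy(cfg), cfg.crop_number, cfg.pesticide_number, network.traits
    )
    pop.append(**_draw_pests(cfg.N0, cfg, network, landscape, rng, start_id=0))
    return pop


def _in_window(age: np.ndarray, window: tuple[int, int]) -> np.ndarray:
    lo, hi = window
    return (age >= lo) & (age <= hi)


def _grouped_sequential_consume(
    supply_flat: np.ndarray, cells: np.ndarray, allowed: np.ndarray
) -> np.ndarray:
    """Intake for pests consuming sequentially from depletable cells.

    ``cells``/``allowed`` are ordered (earlier pests eat first within a
    cell).  Returns per-pest intake and decrements ``supply_flat`` in place.
    Equivalent to a per-pest loop: each takes min(allowed, remaining).
    """
    order = np.argsort(cells, kind="stable")
    c = cells[order]
    a = allowed[order]
    cum = np.cumsum(a)
    first = np.ones(c.size, dtype=bool)
    first[1:] = c[1:] != c[:-1]
    base_at_first = np.where(first, cum - a, -np.inf)
    base = np.maximum.accumulate(base_at_first)  # cum is non-decreasing
    taken_before = (cum - a) - base
    intake_sorted = np.clip(supply_flat[c] - taken_before, 0.0, a)
    np.subtract.at(supply_flat, c, intake_sorted)
    intake = np.empty_like(intake_sorted)
    intake[order] = intake_sorted
    return intake


def feed_step(state: SimState, pest_rows: np.ndarray | None = None) -> None:
    """Pests of feeding age consume crop from their cell in random order.

    Intake is capped both by the cell's remaining crop and by the pest's
    per-step consumption ability (shared across the main feed and any
    feeding done while moving).
    """
    cfg, pop, ls = state.cfg, state.pop, state.landscape
    if pest_rows is None:
        pest_rows = np.flatnonzero(_in_window(pop.age, cfg.age_window("feed")))
    if pest_rows.size == 0:
        return
    order = state.rng.permutation(pest_rows)
    cells = pop.x[order] * ls.ydim + pop.y[order]
    ctype = ls.crop_type.ravel()[cells]  # 1-based
    abilities = cfg.consume_abilities("food_consume", pop.traits[order])
    allowed = abilities[np.arange(order.size), ctype - 1]
    allowed = np.maximum(allowed - pop.step_food_used[order], 0.0)
    supply = ls.crop_amount.ravel()
    intake = _grouped_sequential_consume(supply, cells, allowed)
    ls.crop_amount = supply.reshape(ls.crop_amount.shape)
    np.add.at(pop.food, (order, ctype - 1), intake)
    pop.step_food_used[order] += intake


def pesticide_step(state: SimState, pest_rows: np.ndarray | None = None) -> None:
    """Pests of feeding age take up the pesticide on their cell.

    Works like feeding except cell amounts are never depleted, so every
    pest on a cell has the same opportunity.  Negative bound traits give a
    zero uptake ability (threshold trait).
    """
    cfg, pop, ls = state.cfg, state.pop, state.landscape
    if pest_rows is None:
        pest_rows = np.flatnonzero(_in_window(pop.age, cfg.age_window("feed")))
    if pest_rows.size == 0:
        return
    cells = pop.x[pest_rows] * ls.ydim + pop.y[pest_rows]
    ptype = ls.pesticide_type.ravel()[cells]
    abilities = cfg.consume_abilities("pesticide_consume", pop.traits[pest_rows])
    allowed = abilities[np.arange(pest_rows.size), ptype - 1]
    allowed = np.maximum(allowed - pop.step_pesticide_used[pest_rows], 0.0)
    uptake = np.minimum(allowed, ls.pesticide_amount.ravel()[cells])
    np.add.at(pop.pesticide, (pest_rows, ptype - 1), uptake)
    pop.step_pesticide_used[pest_rows] += uptake


def movement_step(state: SimState) -> None:
    """Pests of moving age relocate over one or more bouts.

    Each bout sends a pest to a uniformly drawn cell within Chebyshev
    radius ``move_distance`` (possibly its own cell); edges are resolved by
    the landscape's edge rule (leaky edges remove the pest).  Bouts are
    processed in a fresh random order across pests, and pests may feed and
    take up pesticide on arrival if the corresponding flags are set.
    """
    cfg, pop, ls = state.cfg, state.pop, state.landscape
    movers = np.flatnonzero(_in_window(pop.age, cfg.age_window("move")))
    if movers.size == 0:
        return
    bouts = cfg.param_values("movement_bouts", pop.traits[movers]).astype(np.int64)
    max_bouts = int(bouts.max()) if bouts.size else 0
    feed_ok = _in_window(pop.age, cfg.age_window("feed"))
    for bout in range(max_bouts):
        active = movers[bouts > bout]
        if active.size == 0:
            break
        active = state.rng.permutation(active)
        dist = cfg.param_values("move_distance", pop.traits[active]).astype(np.int64)
        dx = state.rng.integers(-dist, dist + 1)
        dy = state.rng.integers(-dist, dist + 1)
        nx, ny, kept = resolve_edges(
            pop.x[active] + dx, pop.y[active] + dy, ls.xdim, ls.ydim, ls.land_edge
        )
        pop.x[active] = nx
        pop.y[active] = ny
        if not kept.all():
            removed = active[~kept]
            alive = np.ones(pop.size, dtype=bool)
            alive[removed] = False
            # re-index movers/bouts into the compacted population
            new_index = np.cumsum(alive) - 1
            still = alive[movers]
            movers = new_index[movers[still]]
            bouts = bouts[still]
            pop.keep(alive)
            feed_ok = _in_window(pop.age, cfg.age_window("feed"))
            active = new_index[active[kept]]
        if cfg.feed_while_moving:
            rows = active[feed_ok[active]]
            if rows.size:
                feed_step(state, pest_rows=rows)
        if cfg.pesticide_while_moving:
            rows = active[feed_ok[active]]
            if rows.size:
                pesticide_step(state, pest_rows=rows)


def _chebyshev_within(
    mx, my, fx, fy, dist, xdim: int, ydim: int, torus: bool
) -> np.ndarray:
    """Mask over candidate mates (fx, fy) within Chebyshev ``dist`` of (mx, my)."""
    dxa = np.abs(fx - mx)
    dya = np.abs(fy - my)
    if torus:
        dxa = np.minimum(dxa, xdim - dxa)
        dya = np.minimum(dya, ydim - dya)
    return np.maximum(dxa, dya) <= dist


def reproduction_step(state: SimState) -> dict | None:
    """Produce, and append, this step's offspring cohort.

    Mothers are asexual, monoecious, or female pests of reproductive age
    whose pesticide intake is within the reproductive tolerance.  Offspring
    number is Poisson(lambda) or floor(total food / food_needed_repr).
    Sexual modes need >= 1 eligible mate within ``mating_distance``
    (Chebyshev; the raffle for each offspring's sire is fair across mates).
    Offspring are placed on the mother's cell at age 0; if the cohort
    exceeds ``K_on_birth`` > 0, random offspring are removed to capacity.
    """
    cfg, pop, rng = state.cfg, state.pop, state.rng
    repro_ok = _in_window(pop.age, cfg.age_window("reproduce"))
    tol = cfg.param_values("pesticide_tolerated_repr", pop.traits)
    tol_ok = pop.pesticide.sum(axis=1) <= tol
    mother_mask = repro_ok & tol_ok & np.isin(pop.sex, (SEX_ASEXUAL, SEX_MONOECIOUS, SEX_FEMALE))
    mothers = np.flatnonzero(mother_mask)
    if mothers.size == 0:
        return None

    if cfg.reproduction_type == "lambda":
        lam = cfg.param_values("lambda_value", pop.traits[mothers])
        counts = rng.poisson(lam)
    else:
        needed = cfg.param_values("food_needed_repr", pop.traits[mothers])
        total_food = pop.food[mothers].sum(axis=1)
        with np.errstate(divide="ignore", invalid="ignore"):
            counts = np.where(
                needed > 0, np.floor(total_food / needed), 0.0
            ).astype(np.int64)
        counts = np.maximum(counts, 0)

    sires = np.full(mothers.size, -1, dtype=np.int64)
    if cfg.repro in ("sexual", "biparental"):
        mate_mask = (
            _in_window(pop.age, cfg.age_window("reproduce"))
            & tol_ok
            & np.isin(pop.sex, (SEX_MONOECIOUS, SEX_MALE))
        )
        mates = np.flatnonzero(mate_mask)
        mdist = cfg.param_values("mating_distance", pop.traits[mothers]).astype(np.int64)
        torus = state.landscape.land_edge == "torus"
        for k, m in enumerate(mothers):
            if counts[k] == 0:
                continue
            cand = mates
            near = _chebyshev_within(
                pop.x[m], pop.y[m], pop.x[cand], pop.y[cand], mdist[k],
                state.landscape.xdim, state.landscape.ydim, torus,
            )
            cand = cand[near]
            if not cfg.selfing:
                cand = cand[cand != m]
            if cand.size == 0:
                counts[k] = 0  # no mate in range: zero offspring, not an error
            else:
                sires[k] = -2  # defer per-offspring raffle below
        # per-offspring fair raffle among each mother's eligible mates
        off_mother = np.repeat(np.arange(mothers.size), counts)
        off_sire = np.empty(off_mother.size, dtype=np.int64)
        pos = 0
        for k, m in enumerate(mothers):
            c = int(counts[k])
            if c == 0:
                continue
            cand = mates
            near = _chebyshev_within(
                pop.x[m], pop.y[m], pop.x[cand], pop.y[cand], mdist[k],
                state.landscape.xdim, state.landscape.ydim, torus,
            )
            cand = cand[near]
            if not cfg.selfing:
                cand = cand[cand != m]
            off_sire[pos : pos + c] = rng.choice(cand, size=c, replace=True)
            pos += c
    else:
        off_mother = np.repeat(np.arange(mothers.size), counts)
        off_sire = None

    n_off = off_mother.size
    if n_off == 0:
        return None
    mother_rows = mothers[off_mother]

    G = pop.layout.length
    if cfg.repro == "asexual":
        haps = pop.haps[mother_rows].copy()
    else:
        mh = pop.haps[mother_rows]
        fh = pop.haps[off_sire]
        swap_m = rng.random((n_off, G)) < cfg.crossover_pr
        swap_f = rng.random((n_off, G)) < cfg.crossover_pr
        g_m = np.where(swap_m, mh[:, 1], mh[:, 0])
        g_f = np.where(swap_f, fh[:, 1], fh[:, 0])
        haps = np.stack([g_m, g_f], axis=1)
    if cfg.mutation_pr > 0:
        allowed = mutable_positions(pop.layout, cfg.net_mu_layers, cfg.net_mu_dir)
        hit = (rng.random(haps.shape) < cfg.mutation_pr) & allowed
        if hit.any():
            fresh = rng.standard_normal(haps.shape)
            if cfg.mutation_type == 0:
                haps[hit] = fresh[hit]
            else:
                haps[hit] += fresh[hit]

    # birth carrying capacity: thin the cohort uniformly at random
    keep_idx = np.arange(n_off)
    if 0 < cfg.K_on_birth < n_off:
        keep_idx = rng.choice(n_off, size=cfg.K_on_birth, replace=False)
        keep_idx.sort()
        haps = haps[keep_idx]
        mother_rows = mother_rows[keep_idx]
        n_off = keep_idx.size

    traits = batch_traits(haps, pop.layout, state.trait_means)
    if cfg.repro == "asexual":
        sex = np.full(n_off, SEX_ASEXUAL, dtype=np.int8)
    elif cfg.repro == "sexual":
        sex = np.full(n_off, SEX_MONOECIOUS, dtype=np.int8)
    else:
        sex = np.where(rng.random(n_off) < 0.5, SEX_FEMALE, SEX_MALE).astype(np.int8)
    offspring = dict(
        ids=np.arange(state.next_id, state.next_id + n_off, dtype=np.int64),
        age=np.zeros(n_off, dtype=np.int64),
        sex=sex,
        x=pop.x[mother_rows].copy(),
        y=pop.y[mother_rows].copy(),
        food=np.zeros((n_off, cfg.crop_number)),
        pesticide=np.zeros((n_off, cfg.pesticide_number)),
        traits=traits,
        haps=haps,
    )
    state.next_id += n_off
    pop.append(**offspring)
    return offspring


def metabolism_step(state: SimState) -> None:
    """Pests of metabolising age lose ``metabolism`` from their food stores,
    floored at zero (drawn proportionally across crop types)."""
    cfg, pop = state.cfg, state.pop
    rows = np.flatnonzero(_in_window(pop.age, cfg.age_window("metabolism")))
    if rows.size == 0:
        return
    m = cfg.param_values("metabolism", pop.traits[rows])
    total = pop.food[rows].sum(axis=1)
    new_total = np.maximum(total - m, 0.0)
    with np.errstate(divide="ignore", invalid="ignore"):
        factor = np.where(total > 0, new_total / total, 0.0)
    pop.food[rows] *= factor[:, None]


def mortality_step(state: SimState) -> None:
    """Remove pests that exceeded max age, exceeded the pesticide survival
    tolerance at or past the threshold age, or failed the one-off food
    checkpoint at the end of their feeding window."""
    cfg, pop = state.cfg, state.pop
    if pop.size == 0:
        state.deaths_this_step = 0
        return
    dead = pop.age > cfg.max_age
    tol = cfg.param_values("pesticide_tolerated_surv", pop.traits)
    dead |= (pop.age >= cfg.age_pesticide_threshold) & (pop.pesticide.sum(axis=1) > tol)
    needed = cfg.param_values("food_needed_surv", pop.traits)
    _, feed_hi = cfg.age_window("feed")
    dead |= (pop.age == feed_hi) & (pop.food.sum(axis=1) < needed)
    state.deaths_this_step = int(dead.sum())
    pop.keep(~dead)


def immigration_step(state: SimState) -> None:
    """Append Poisson(immigration_rate) immigrants, initialised exactly like
    founders: the founding network's values, fresh N(0,1) loci, random cell."""
    cfg = state.cfg
    if cfg.immigration_rate <= 0:
        return
    n = int(state.rng.poisson(cfg.immigration_rate))
    if n == 0:
        return
    arrs = _draw_pests(n, cfg, state.network, state.landscape, state.rng, state.next_id)
    state.next_id += n
    state.pop.append(**arrs)


def _stats_row(state: SimState) -> dict:
    cfg, pop = state.cfg, state.pop
    n = pop.size
    row = {"time_step": state.t, "population_size": n}
    row["mean_age"] = float(pop.age.mean()) if n else np.nan
    n_f = int(np.sum(pop.sex == SEX_FEMALE))
    n_m = int(np.sum(pop.sex == SEX_MALE))
    row["sex_ratio"] = n_f / (n_f + n_m) if (n_f + n_m) else np.nan
    for j in range(cfg.crop_number):
        row[f"mean_food_consumed_{j + 1}"] = float(pop.food[:, j].mean()) if n else np.nan
    for j in range(cfg.pesticide_number):
        row[f"mean_pesticide_consumed_{j + 1}"] = (
            float(pop.pesticide[:, j].mean()) if n else np.nan
        )
    denom = state._pop_before_mortality
    row["mortality_rate"] = state.deaths_this_step / denom if denom else 0.0
    for j in range(state.network.traits):
        row[f"mean_trait_{j + 1}"] = float(pop.traits[:, j].mean()) if n else np.nan
    return row


def run_time_step(state: SimState) -> None:
    """Advance the simulation by one full time step and record statistics."""
    cfg, ls, rng = state.cfg, state.landscape, state.rng
    state.t += 1
    state.deaths_this_step = 0

    # landscape change: rotation clocks are independent; amounts reset on a
    # rotation event, and crops grow on non-rotation steps
    if state.crop_policy.due(state.t):
        state.crop_assign = rotate(state.crop_assign, state.crop_policy, rng)
        ls.apply_crop_assignments(state.crop_assign, cfg.crop_per_cell)
    elif cfg.crop_growth > 0:
        grow_crops(ls, cfg.crop_growth, cfg.crop_growth_type)
    if state.pesticide_policy.due(state.t):
        state.pesticide_assign = rotate(state.pesticide_assign, state.pesticide_policy, rng)
        ls.apply_pesticide_assignments(state.pesticide_assign, cfg.pesticide_per_cell)

    # aging and metabolism
    state.pop.age += 1
    state.pop.step_food_used[:] = 0.0
    state.pop.step_pesticide_used[:] = 0.0
    metabolism_step(state)

    feed_step(state)
    pesticide_step(state)
    movement_step(state)
    reproduction_step(state)
    state._pop_before_mortality = state.pop.size
    mortality_step(state)
    immigration_step(state)
    state.stats_rows.append(_stats_row(state))
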