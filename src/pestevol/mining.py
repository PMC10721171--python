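"""Covariance mining: an evolutionary algorithm over genotype->phenotype networks.

The miner evolves a population of candidate networks until one maps
standard-normal loci onto traits whose covariance matrix matches a
user-supplied target (the G-matrix) to within a stress criterion.  Network
stress is the natural log of the mean squared element-wise deviation between
the network's estimated trait covariance and the target; lower is fitter.

The algorithm per iteration: mutate network values, cross values over
between paired networks, estimate each network's trait covariance from a
fresh sample of simulated individuals, then fill the next generation by
tournament selection on stress.  The lowest-stress network ever seen is
tracked and returned.  Because a single sampling-based evaluation of a
network is noisy, a candidate record is only accepted (and termination only
declared) after the candidate's stress is confirmed on a second, larger
fresh sample; this guards against terminating on a lucky draw.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .network import (
    Network,
    STRESS_FLOOR,
    expected_covariance,
    estimate_covariance,
    stress,
)

__all__ = [
    "MiningConfig",
    "MiningResult",
    "GMatrixMiner",
    "mine_gmatrix",
    "stress_test",
    "mutate_network",
    "crossover_networks",
    "tournament_select",
]


@dataclass
class MiningConfig:
    """Hyper-parameters for the covariance-mining evolutionary algorithm.

    Parameters
    ----------
    gmatrix : (T, T) array
        Target trait covariance matrix (symmetric, positive diagonal).
    loci : int
        Number of loci L feeding the network.
    layers : int
        Number of T x T internal layer maps.
    npsize : int
        Number of networks in the evolving population.
    max_gen : int
        Iteration cap.
    term_cri : float
        Terminate once the confirmed best stress is at or below this value.
    indivs : int
        Sample size used to estimate each network's trait covariance.
    mutation_rate : float
        Per-value probability of perturbation each iteration.
    mutation_sd : float
        Standard deviation of the additive normal perturbation.
    crossover_rate : float
        Per-pair probability that a shuffled pair of networks attempts
        crossover.
    swap_pr : float
        Per-element swap probability within a crossing-over pair.
    tournament_size : int
        Networks drawn (with replacement) per tournament; the lowest-stress
        entrant wins.
    confirm_factor : int
        Multiplier on ``indivs`` for the confirmation re-evaluation of a
        candidate best network.
    """

    gmatrix: np.ndarray = field(default=None)  # type: ignore[assignment]
    loci: int = 3
    layers: int = 2
    npsize: int = 400
    max_gen: int = 1000
    term_cri: float = -6.0
    indivs: int = 1000
    mutation_rate: float = 0.1
    mutation_sd: float = 0.1
    crossover_rate: float = 0.1
    swap_pr: float = 0.5
    tournament_size: int = 4
    confirm_factor: int = 10
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.gmatrix is None:
            raise ValueError("gmatrix is required")
        self.gmatrix = np.asarray(self.gmatrix, dtype=float)
        g = self.gmatrix
        if g.ndim != 2 or g.shape[0] != g.shape[1] or g.shape[0] < 2:
            raise ValueError("gmatrix must be a square T x T matrix with T >= 2")
        if not np.allclose(g, g.T):
            raise ValueError("gmatrix must be symmetric")
        if np.any(np.diag(g) <= 0):
            raise ValueError("gmatrix diagonal (trait variances) must be positive")
        if self.loci < 1 or self.layers < 1:
            raise ValueError("need loci >= 1 and layers >= 1")
        if self.npsize < 2:
            raise ValueError("npsize must be >= 2")
        if self.indivs < 2:
            raise ValueError("indivs must be >= 2")
        for name in ("mutation_rate", "crossover_rate", "swap_pr"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")

    @property
    def traits(self) -> int:
        return self.gmatrix.shape[0]

    @property
    def genome_size(self) -> int:
        T = self.traits
        return self.loci * T + self.layers * T * T


@dataclass
class MiningResult:
    """Outcome of a mining run.

    Attributes
    ----------
    best_network : Network
        Lowest confirmed-stress network seen over the whole run.
    achieved_covariance : ndarray
        Exact (expected) trait covariance of the best network, ``M.T @ M``.
    estimated_covariance : ndarray
        Fresh sampling-based covariance estimate of the best network made
        once at the end of the run.
    final_stress : float
        Stress of ``estimated_covariance`` against the target.
    expected_stress : float
        Stress of ``achieved_covariance`` against the target (noise-free).
    generations_run : int
        Iterations executed.
    converged : bool
        Whether the termination criterion was met before ``max_gen``.
    stress_trajectory : ndarray
        Confirmed best-ever stress after each iteration (non-increasing).
    """

    best_network: Network
    achieved_covariance: np.ndarray
    estimated_covariance: np.ndarray
    final_stress: float
    expected_stress: float
    generations_run: int
    converged: bool
    stress_trajectory: np.ndarray
    config: MiningConfig

    def summary(self) -> str:
        g = self.config.gmatrix
        lines = [
            "Covariance mining result",
            "=" * 40,
            f"loci: {self.config.loci}   layers: {self.config.layers}   "
            f"traits: {self.config.traits}",
            f"generations run: {self.generations_run}"
            f"   converged: {self.converged}",
            f"final stress (fresh sample): {self.final_stress:.4f}",
            f"expected stress (noise-free): {self.expected_stress:.4f}",
            "target covariance:",
            np.array2string(g, precision=7),
            "achieved (expected) covariance:",
            np.array2string(self.achieved_covariance, precision=7),
        ]
        return "\n".join(lines)


def mutate_network(network: Network, rate: float, rng: np.random.Generator,
                   sd: float = 1.0) -> Network:
    """Perturb each stored value independently with probability ``rate``.

    A perturbation adds a draw from N(0, sd^2) to the current value.
    """
    if not 0.0 <= rate <= 1.0:
        raise ValueError("rate must be in [0, 1]")
    flat = network.to_flat()
    mask = rng.random(flat.size) < rate
    flat = flat + mask * rng.normal(0.0, sd, flat.size)
    return Network.from_flat(flat, network.loci, network.traits, network.layers)


def crossover_networks(
    a: Network, b: Network, pr: float, rng: np.random.Generator
) -> tuple[Network, Network]:
    """Exchange values between two networks element-wise with probability ``pr``.

    The multiset of values across the pair is conserved.
    """
    if (a.loci, a.traits, a.layers) != (b.loci, b.traits, b.layers):
        raise ValueError("networks must share dimensions to cross over")
    if not 0.0 <= pr <= 1.0:
        raise ValueError("pr must be in [0, 1]")
    fa, fb = a.to_flat(), b.to_flat()
    swap = rng.random(fa.size) < pr
    na = np.where(swap, fb, fa)
    nb = np.where(swap, fa, fb)
    dims = (a.loci, a.traits, a.layers)
    return Network.from_flat(na, *dims), Network.from_flat(nb, *dims)


def tournament_select(
    population: list[Network],
    stresses,
    npsize: int,
    tournament_size: int,
    rng: np.random.Generator,
) -> list[Network]:
    """Select ``npsize`` networks, each the lowest-stress member of a random
    tournament drawn with replacement.  Ties break to the first index drawn."""
    if len(population) == 0:
        raise ValueError("population must be non-empty")
    stresses = np.asarray(stresses, dtype=float)
    if stresses.size != len(population):
        raise ValueError("population and stresses must have the same length")
    idx = _tournament_indices(stresses, npsize, tournament_size, rng)
    return [population[i].copy() for i in idx]


def _tournament_indices(
    stresses: np.ndarray, npsize: int, tournament_size: int, rng: np.random.Generator
) -> np.ndarray:
    entrants = rng.integers(0, stresses.size, size=(npsize, tournament_size))
    winners_col = np.argmin(stresses[entrants], axis=1)
    return entrants[np.arange(npsize), winners_col]


def _composite_maps(pop: np.ndarray, L: int, T: int, layers: int) -> np.ndarray:
    """Composite L x T map per network for a (npsize, genome) value array."""
    n = pop.shape[0]
    M = pop[:, : L * T].reshape(n, L, T)
    off = L * T
    for _ in range(layers):
        B = pop[:, off : off + T * T].reshape(n, T, T)
        M = M @ B
        off += T * T
    return M


def _batched_stress(
    pop: np.ndarray, cfg: MiningConfig, rng: np.random.Generator
) -> np.ndarray:
    """Estimate stress for every network from fresh N(0,1) loci samples."""
    L, T = cfg.loci, cfg.traits
    M = _composite_maps(pop, L, T, cfg.layers)
    z = rng.standard_normal((pop.shape[0], cfg.indivs, L))
    x = z @ M
    xc = x - x.mean(axis=1, keepdims=True)
    covs = np.einsum("nit,niu->ntu", xc, xc) / (cfg.indivs - 1)
    msd = np.mean((covs - cfg.gmatrix) ** 2, axis=(1, 2))
    return np.log(np.maximum(msd, STRESS_FLOOR))


class GMatrixMiner:
    """Evolutionary search for a network matching a target trait covariance.

    Examples
    --------
    >>> miner = GMatrixMiner([[1.0, -0.4], [-0.4, 1.0]], loci=3, layers=2)
    >>> result = miner.fit(seed=1)          # doctest: +SKIP
    >>> print(result.summary())             # doctest: +SKIP
    """

    def __init__(self, gmatrix, loci: int = 3, layers: int = 2, **kwargs):
        self.config = MiningConfig(gmatrix=gmatrix, loci=loci, layers=layers, **kwargs)

    def fit(self, seed: int | None = None,
            rng: np.random.Generator | None = None) -> MiningResult:
        """Run the evolutionary algorithm and return the best network found."""
        cfg = self.config
        if rng is None:
            rng = np.random.default_rng(cfg.seed if seed is None else seed)
        L, T, layers = cfg.loci, cfg.traits, cfg.layers
        G = cfg.genome_size
        dims = (L, T, layers)

        pop = rng.standard_normal((cfg.npsize, G))

        best_vals: np.ndarray | None = None
        best_stress = np.inf
        trajectory: list[float] = []
        gen = 0
        converged = False
        n_confirm = cfg.indivs * cfg.confirm_factor

        while gen < cfg.max_gen:
            gen += 1
            # mutation: additive normal perturbation per value
            if cfg.mutation_rate > 0:
                mask = rng.random(pop.shape) < cfg.mutation_rate
                pop = pop + mask * rng.normal(0.0, cfg.mutation_sd, pop.shape)
            # crossover between shuffled pairs
            if cfg.crossover_rate > 0:
                perm = rng.permutation(cfg.npsize)
                half = cfg.npsize // 2
                a_idx, b_idx = perm[:half], perm[half : 2 * half]
                attempt = rng.random(half) < cfg.crossover_rate
                if attempt.any():
                    ai, bi = a_idx[attempt], b_idx[attempt]
                    swap = rng.random((ai.size, G)) < cfg.swap_pr
                    va, vb = pop[ai].copy(), pop[bi].copy()
                    pop[ai] = np.where(swap, vb, va)
                    pop[bi] = np.where(swap, va, vb)
            # evaluate on a fresh sample of individuals
            stresses = _batched_stress(pop, cfg, rng)
            # candidate best-ever: confirm on a larger fresh sample before
            # accepting the record or terminating
            cand = int(np.argmin(stresses))
            if stresses[cand] < best_stress:
                net = Network.from_flat(pop[cand], *dims)
                confirmed = stress(
                    estimate_covariance(net, n_confirm, rng), cfg.gmatrix
                )
                if confirmed < best_stress:
                    best_stress = confirmed
                    best_vals = pop[cand].copy()
            trajectory.append(best_stress)
            if best_stress <= cfg.term_cri:
                converged = True
                break
            pop = pop[_tournament_indices(stresses, cfg.npsize, cfg.tournament_size, rng)]

        assert best_vals is not None
        best = Network.from_flat(best_vals, *dims)
        est_cov = estimate_covariance(best, cfg.indivs, rng)
        achieved = expected_covariance(best)
        return MiningResult(
            best_network=best,
            achieved_covariance=achieved,
            estimated_covariance=est_cov,
            final_stress=stress(est_cov, cfg.gmatrix),
            expected_stress=stress(achieved, cfg.gmatrix),
            generations_run=gen,
            converged=converged,
            stress_trajectory=np.asarray(trajectory),
            config=cfg,
        )


def mine_gmatrix(cfg: MiningConfig | None = None, **kwargs) -> MiningResult:
    """Functional entry point: mine a network for a target covariance matrix.

    Accepts either a prebuilt :class:`MiningConfig` or its keyword fields.
    """
    if cfg is None:
        cfg = MiningConfig(**kwargs)
    elif kwargs:
        raise TypeError("pass either a MiningConfig or keyword fields, not both")
    miner = GMatrixMiner.__new__(GMatrixMiner)
    miner.config = cfg
    return miner.fit()


def stress_test(
    network: Network,
    gmatrix: np.ndarray,
    reps: int,
    indivs: int,
    rng: np.random.Generator,
) -> np.ndarray:
    """Repeatedly re-estimate a network's stress with fresh loci samples.

    Returns ``reps`` independent stress values, useful for judging how robust
    a mined network's fit is to the individuals used to evaluate it.
    """
    if reps < 1:
        raise ValueError("reps must be >= 1")
    return np.array(
        [stress(estimate_covariance(network, indivs, rng), gmatrix) for _ in range(reps)]
    )
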