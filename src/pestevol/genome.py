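"""Individual genomes: loci plus inherited network values.

A genome stores one (haploid) or two (diploid) flat haplotypes, each the
concatenation of ``L`` locus values, the ``L x T`` loci-to-first-layer block
(row-major), and ``layers`` successive ``T x T`` layer maps (row-major).
Traits are computed by feeding the locus values through the network encoded
in the same genome; for diploids, allele values are summed at homologous
loci and network values are averaged across the two haplotypes so that
haploid and diploid founders drawn from the same mined network share the
same trait scale.

Inheritance supports clonal copying (asexual), and gamete formation with
per-position crossover plus mutation whose reach into the network is
constrained by ``net_mu_layers`` / ``net_mu_dir``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .network import Network, compute_traits

__all__ = [
    "GenomeLayout",
    "Genome",
    "TraitBinding",
    "mutable_positions",
    "traits_of",
    "make_gamete",
    "mutate_genome",
    "inherit",
    "batch_traits",
]


@dataclass(frozen=True)
class GenomeLayout:
    """Shape of a flattened genome: L loci, T traits, ``layers`` layer maps."""

    loci: int
    traits: int
    layers: int

    @property
    def network_length(self) -> int:
        return self.loci * self.traits + self.layers * self.traits**2

    @property
    def length(self) -> int:
        return self.loci + self.network_length

    def network_blocks(self) -> list[slice]:
        """Slices of the 1 + layers network-value blocks, loci side first."""
        L, T = self.loci, self.traits
        blocks = [slice(L, L + L * T)]
        off = L + L * T
        for _ in range(self.layers):
            blocks.append(slice(off, off + T * T))
            off += T * T
        return blocks


def mutable_positions(
    layout: GenomeLayout, net_mu_layers: int, net_mu_dir: int
) -> np.ndarray:
    """Boolean mask over genome positions that are allowed to mutate.

    Loci always may; of the ``1 + layers`` network blocks, the first
    ``net_mu_layers`` counted from the loci side (``net_mu_dir = 1``) or from
    the trait side (``net_mu_dir = 0``) may.
    """
    n_blocks = 1 + layout.layers
    if not 0 <= net_mu_layers <= n_blocks:
        raise ValueError(f"net_mu_layers must be in [0, {n_blocks}]")
    if net_mu_dir not in (0, 1):
        raise ValueError("net_mu_dir must be 0 or 1")
    mask = np.zeros(layout.length, dtype=bool)
    mask[: layout.loci] = True
    blocks = layout.network_blocks()
    chosen = blocks[:net_mu_layers] if net_mu_dir == 1 else blocks[n_blocks - net_mu_layers:]
    for sl in chosen:
        mask[sl] = True
    return mask


@dataclass
class Genome:
    """Per-individual genetic store: 1 or 2 flat haplotypes plus their layout."""

    layout: GenomeLayout
    haplotypes: np.ndarray  # shape (ploidy, length)

    def __post_init__(self) -> None:
        self.haplotypes = np.atleast_2d(np.asarray(self.haplotypes, dtype=float))
        if self.haplotypes.shape[0] not in (1, 2):
            raise ValueError("ploidy must be 1 or 2")
        if self.haplotypes.shape[1] != self.layout.length:
            raise ValueError(
                f"haplotype length {self.haplotypes.shape[1]} != layout length "
                f"{self.layout.length}"
            )

    @property
    def ploidy(self) -> int:
        return self.haplotypes.shape[0]

    @classmethod
    def from_network(
        cls,
        network: Network,
        ploidy: int,
        rng: np.random.Generator,
        loci_values: np.ndarray | None = None,
    ) -> "Genome":
        """Found a genome on a mined network: fresh N(0,1) loci (independent
        per haplotype) carrying the network's values on every haplotype."""
        layout = GenomeLayout(network.loci, network.traits, network.layers)
        net_vals = network.to_flat()
        haps = np.empty((ploidy, layout.length))
        for h in range(ploidy):
            loci = (
                rng.standard_normal(layout.loci)
                if loci_values is None
                else np.asarray(loci_values, dtype=float)
            )
            haps[h] = np.concatenate([loci, net_vals])
        return cls(layout, haps)

    def copy(self) -> "Genome":
        return Genome(self.layout, self.haplotypes.copy())


@dataclass(frozen=True)
class TraitBinding:
    """Substitution of evolving trait ``trait_index`` (1-based, as in "Tj")
    for the ecology parameter ``parameter_name``."""

    parameter_name: str
    trait_index: int

    def __post_init__(self) -> None:
        if self.trait_index < 1:
            raise ValueError("trait_index is 1-based and must be >= 1")


def traits_of(genome: Genome, trait_means: np.ndarray | None = None) -> np.ndarray:
    """Trait vector of an individual from its own genome.

    Haploids feed their loci through their haplotype's network; diploids sum
    allele values at homologous loci and average network values across
    haplotypes.  ``trait_means`` is added element-wise to the network output.
    """
    lay = genome.layout
    L = lay.loci
    if genome.ploidy == 1:
        loci = genome.haplotypes[0, :L]
        net_vals = genome.haplotypes[0, L:]
    else:
        loci = genome.haplotypes[0, :L] + genome.haplotypes[1, :L]
        net_vals = 0.5 * (genome.haplotypes[0, L:] + genome.haplotypes[1, L:])
    net = Network.from_flat(net_vals, L, lay.traits, lay.layers)
    out = compute_traits(net, loci)
    if trait_means is not None:
        out = out + np.asarray(trait_means, dtype=float)
    return out


def make_gamete(
    genome: Genome, crossover_pr: float, rng: np.random.Generator
) -> np.ndarray:
    """One recombinant haplotype from a diploid genome.

    At each position independently the two haplotype values swap with
    probability ``crossover_pr`` (complete recombination at 0.5); the gamete
    is haplotype 1 after swapping.
    """
    if genome.ploidy != 2:
        raise ValueError("gametes require a diploid genome")
    if not 0.0 <= crossover_pr <= 0.5:
        raise ValueError("crossover_pr must be in [0, 0.5]")
    swap = rng.random(genome.layout.length) < crossover_pr
    return np.where(swap, genome.haplotypes[1], genome.haplotypes[0])


def mutate_genome(
    genome: Genome,
    mutation_pr: float,
    mutation_type: int,
    net_mu_layers: int,
    net_mu_dir: int,
    rng: np.random.Generator,
) -> Genome:
    """Mutate each permitted genome value independently with ``mutation_pr``.

    The new value is a standard-normal draw that replaces the old value
    (``mutation_type = 0``) or is added to it (``mutation_type = 1``).  Only
    loci and the network blocks selected by ``net_mu_layers``/``net_mu_dir``
    may change; each haplotype mutates independently.
    """
    if mutation_type not in (0, 1):
        raise ValueError("mutation_type must be 0 (replace) or 1 (add)")
    if not 0.0 <= mutation_pr <= 1.0:
        raise ValueError("mutation_pr must be in [0, 1]")
    allowed = mutable_positions(genome.layout, net_mu_layers, net_mu_dir)
    haps = genome.haplotypes.copy()
    hit = (rng.random(haps.shape) < mutation_pr) & allowed
    if hit.any():
        fresh = rng.standard_normal(haps.shape)
        if mutation_type == 0:
            haps[hit] = fresh[hit]
        else:
            haps[hit] += fresh[hit]
    return Genome(genome.layout, haps)


def inherit(
    mother: Genome,
    father: Genome | None,
    repro_mode: str,
    crossover_pr: float,
    mutation_pr: float,
    mutation_type: int,
    net_mu_layers: int,
    net_mu_dir: int,
    rng: np.random.Generator,
) -> Genome:
    """Build an offspring genome from its parent(s).

    Asexual offspring receive a full copy of the parent genome; sexual and
    biparental offspring receive one recombinant gamete from each parent.
    Mutation is applied after recombination.
    """
    if repro_mode == "asexual":
        child = mother.copy()
    elif repro_mode in ("sexual", "biparental"):
        if father is None:
            raise ValueError(f"{repro_mode} reproduction requires a father")
        if father.layout != mother.layout:
            raise ValueError("parental genome layouts differ")
        g1 = make_gamete(mother, crossover_pr, rng)
        g2 = make_gamete(father, crossover_pr, rng)
        child = Genome(mother.layout, np.stack([g1, g2]))
    else:
        raise ValueError(f"unknown reproduction mode {repro_mode!r}")
    if mutation_pr > 0:
        child = mutate_genome(
            child, mutation_pr, mutation_type, net_mu_layers, net_mu_dir, rng
        )
    return child


def batch_traits(
    haplotypes: np.ndarray, layout: GenomeLayout, trait_means: np.ndarray
) -> np.ndarray:
    """Trait vectors for N individuals at once.

    ``haplotypes`` has shape (N, ploidy, length).  Semantics match
    :func:`traits_of`: diploid loci summed, network values averaged.
    """
    haps = np.asarray(haplotypes, dtype=float)
    n, ploidy, _ = haps.shape
    L, T = layout.loci, layout.traits
    if ploidy == 1:
        loci = haps[:, 0, :L]
        net = haps[:, 0, L:]
    else:
        loci = haps[:, 0, :L] + haps[:, 1, :L]
        net = 0.5 * (haps[:, 0, L:] + haps[:, 1, L:])
    A = net[:, : L * T].reshape(n, L, T)
    out = np.einsum("nl,nlt->nt", loci, A)
    off = L * T
    for _ in range(layout.layers):
        B = net[:, off : off + T * T].reshape(n, T, T)
        out = np.einsum("nt,ntu->nu", out, B)
        off += T * T
    return out + np.asarray(trait_means, dtype=float)
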