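"""Genotype->phenotype networks: layered linear maps from loci to traits.

A network maps a row vector of ``L`` locus values through one ``L x T``
matrix and then ``layers`` successive ``T x T`` matrices to produce ``T``
trait values.  Locus values are drawn from a standard normal distribution,
so the trait covariance implied by a network has the closed form ``M.T @ M``
where ``M`` is the composite ``L x T`` map.  Networks are the unit of
selection in the covariance-mining evolutionary algorithm and, flattened,
become part of every simulated individual's genome.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "Network",
    "compute_traits",
    "expected_covariance",
    "estimate_covariance",
    "stress",
    "save_network",
    "load_network",
]

#: Floor applied to the mean squared deviation before taking its log, so the
#: stress of a perfect match is finite rather than -inf.
STRESS_FLOOR = 1e-300


@dataclass
class Network:
    """A layered linear genotype->phenotype map.

    Parameters
    ----------
    loci_to_layer1 : ndarray of shape (L, T)
        Effects of each locus on the first layer of internal nodes.
    layer_maps : list of ndarray of shape (T, T)
        Transitions between successive internal layers; the last matrix maps
        the final internal layer onto the traits themselves.
    """

    loci_to_layer1: np.ndarray
    layer_maps: list[np.ndarray] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.loci_to_layer1 = np.asarray(self.loci_to_layer1, dtype=float)
        self.layer_maps = [np.asarray(m, dtype=float) for m in self.layer_maps]
        if self.loci_to_layer1.ndim != 2:
            raise ValueError("loci_to_layer1 must be a 2-D (L x T) matrix")
        L, T = self.loci_to_layer1.shape
        if L < 1 or T < 2:
            raise ValueError(f"need L >= 1 and T >= 2, got L={L}, T={T}")
        if len(self.layer_maps) < 1:
            raise ValueError("need at least one T x T layer map")
        for m in self.layer_maps:
            if m.shape != (T, T):
                raise ValueError(f"layer map shape {m.shape} != ({T}, {T})")
        arrays = [self.loci_to_layer1, *self.layer_maps]
        if not all(np.all(np.isfinite(a)) for a in arrays):
            raise ValueError("network values must all be finite")

    @property
    def loci(self) -> int:
        return self.loci_to_layer1.shape[0]

    @property
    def traits(self) -> int:
        return self.loci_to_layer1.shape[1]

    @property
    def layers(self) -> int:
        return len(self.layer_maps)

    def composite(self) -> np.ndarray:
        """The composite L x T map (product of all matrices in order)."""
        M = self.loci_to_layer1
        for m in self.layer_maps:
            M = M @ m
        return M

    def to_flat(self) -> np.ndarray:
        """Flatten to the canonical genome order: loci->layer1 block row-major,
        then each layer map row-major in order."""
        return np.concatenate(
            [self.loci_to_layer1.ravel()] + [m.ravel() for m in self.layer_maps]
        )

    @classmethod
    def from_flat(cls, values: np.ndarray, loci: int, traits: int, layers: int) -> "Network":
        """Rebuild a network from its canonical flat representation."""
        values = np.asarray(values, dtype=float)
        expect = loci * traits + layers * traits * traits
        if values.size != expect:
            raise ValueError(f"expected {expect} network values, got {values.size}")
        a = values[: loci * traits].reshape(loci, traits)
        maps = []
        off = loci * traits
        for _ in range(layers):
            maps.append(values[off : off + traits * traits].reshape(traits, traits))
            off += traits * traits
        return cls(a, maps)

    def copy(self) -> "Network":
        return Network(self.loci_to_layer1.copy(), [m.copy() for m in self.layer_maps])


def compute_traits(network: Network, loci_values: np.ndarray) -> np.ndarray:
    """Propagate a row vector of locus values through the network.

    Traits are the summed effects of all preceding nodes, i.e. the row vector
    right-multiplied by each matrix in order.
    """
    v = np.asarray(loci_values, dtype=float).ravel()
    if v.size != network.loci:
        raise ValueError(f"expected {network.loci} loci values, got {v.size}")
    out = v @ network.loci_to_layer1
    for m in network.layer_maps:
        out = out @ m
    return out


def expected_covariance(network: Network) -> np.ndarray:
    """Exact trait covariance for loci ~ N(0, I): ``M.T @ M`` with M composite."""
    M = network.composite()
    return M.T @ M


def estimate_covariance(
    network: Network, indivs: int, rng: np.random.Generator
) -> np.ndarray:
    """Sample trait covariance from ``indivs`` individuals with N(0,1) loci."""
    if indivs < 2:
        raise ValueError("indivs must be >= 2 to estimate a covariance")
    loci = rng.standard_normal((int(indivs), network.loci))
    traits = loci @ network.composite()
    return np.cov(traits, rowvar=False)


def stress(estimated: np.ndarray, gmatrix: np.ndarray, floor: float = STRESS_FLOOR) -> float:
    """Logged mean squared deviation between a covariance estimate and a target.

    Natural log; the mean squared deviation is floored at ``floor`` so a
    perfect match yields a finite (very negative) stress.
    """
    estimated = np.asarray(estimated, dtype=float)
    gmatrix = np.asarray(gmatrix, dtype=float)
    if estimated.shape != gmatrix.shape:
        raise ValueError(f"shape mismatch: {estimated.shape} vs {gmatrix.shape}")
    msd = float(np.mean((estimated - gmatrix) ** 2))
    return float(np.log(max(msd, floor)))


def save_network(network: Network, path) -> None:
    """Write a network as plain text: header ``L T layers`` then the flat values."""
    header = f"{network.loci} {network.traits} {network.layers}"
    vals = network.to_flat()
    with open(path, "w") as fh:
        fh.write(header + "\n")
        fh.write(" ".join(repr(float(v)) for v in vals) + "\n")


def load_network(path) -> Network:
    """Read a network written by :func:`save_network`."""
    if hasattr(path, "read"):
        fh = path
        text = fh.read()
    else:
        with open(path) as fh:
            text = fh.read()
    lines = text.strip().splitlines()
    if not lines:
        raise ValueError("empty network file")
    L, T, layers = (int(x) for x in lines[0].split())
    vals = np.loadtxt(io.StringIO("\n".join(lines[1:])), dtype=float).ravel()
    return Network.from_flat(vals, L, T, layers)
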