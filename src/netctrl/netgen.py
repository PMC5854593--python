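"""Synthetic directed-network generators.

Provides the topology families used throughout the package for validating
the matching and control machinery: Erdos-Renyi digraphs, a directed
preferential-attachment (BA-style) variant, directed configuration models
with Chi-squared / Weibull / Gamma degree laws, and the three elementary
control topologies (stem, circle, dilation).  Every generator is fully
determined by its :class:`GeneratorSpec` including the seed, so the same
spec always yields a byte-identical edge set.
"""

from __future__ import annotations

from dataclasses import dataclass

import networkx as nx
import numpy as np
from scipy import special, stats

from .graph_core import DirectedNetwork

__all__ = [
    "GeneratorSpec",
    "generate",
    "make_stem",
    "make_circle",
    "make_dilation",
]

_FAMILIES = ("er", "ba", "chi2", "weibull", "gamma", "stem", "circle", "dilation")

# shape defaults for the configuration-model degree laws; each law is
# rescaled so the continuous distribution has mean mu before discretisation
_DEFAULT_SHAPE = {"chi2": 2.0, "weibull": 1.5, "gamma": 2.0}


@dataclass(frozen=True)
class GeneratorSpec:
    """Reproducible description of one synthetic network.

    Parameters
    ----------
    family:
        One of ``er``, ``ba``, ``chi2``, ``weibull``, ``gamma``, ``stem``,
        ``circle``, ``dilation``.
    n:
        Node count (for ``dilation`` it is ignored in favour of the three
        segment lengths).
    mu:
        Target mean degree L/N; required for ``er`` and the configuration
        families.
    m:
        Out-edges per new node for the ``ba`` family.
    shape:
        Degree-law shape parameter (chi2 degrees of freedom, Weibull or
        Gamma shape); family-specific default when None.
    trunk, branch_a, branch_b:
        Segment lengths of the ``dilation`` topology.
    seed:
        Integer seed; fully determines the output.
    """

    family: str
    n: int = 1
    mu: float | None = None
    m: int = 2
    shape: float | None = None
    trunk: int = 1
    branch_a: int = 1
    branch_b: int = 1
    seed: int = 0

    def __post_init__(self):
        if self.family not in _FAMILIES:
            raise ValueError(f"unknown family {self.family!r}")
        if self.n < 1:
            raise ValueError("n must be >= 1")
        if self.mu is not None and self.mu < 0:
            raise ValueError("mu must be >= 0")


def generate(spec: GeneratorSpec) -> DirectedNetwork:
    """Generate the network described by ``spec`` (deterministic in seed)."""
    if spec.family == "stem":
        return make_stem(spec.n)
    if spec.family == "circle":
        return make_circle(spec.n)
    if spec.family == "dilation":
        return make_dilation(spec.trunk, spec.branch_a, spec.branch_b)
    if spec.family == "er":
        return _erdos_renyi(spec)
    if spec.family == "ba":
        return _preferential_attachment(spec)
    return _configuration(spec)


# -- elementary topologies ----------------------------------------------


def make_stem(n: int) -> DirectedNetwork:
    """Directed path 1 -> 2 -> ... -> n (n >= 1)."""
    if n < 1:
        raise ValueError("stem length must be >= 1")
    return DirectedNetwork.from_edges(
        ((str(i), str(i + 1)) for i in range(1, n)),
        nodes=(str(i) for i in range(1, n + 1)),
    )


def make_circle(n: int) -> DirectedNetwork:
    """Stem of n nodes closed by the extra edge n -> 1 (n = 1 is a self-loop)."""
    if n < 1:
        raise ValueError("circle length must be >= 1")
    net = make_stem(n)
    net.add_edge(str(n), "1")
    return net


def make_dilation(trunk: int, branch_a: int, branch_b: int) -> DirectedNetwork:
    """A trunk stem whose last node feeds two disjoint branch stems.

    The last trunk node has out-degree 2 (a dilation point: more outgoing
    branches than incoming ones, which inflates the number of required
    control inputs).  Nodes are numbered trunk first, then branch A, then
    branch B.
    """
    for name, val in (("trunk", trunk), ("branch_a", branch_a), ("branch_b", branch_b)):
        if val < 1:
            raise ValueError(f"{name} must be >= 1")
    net = make_stem(trunk)
    start_a = trunk + 1
    start_b = trunk + branch_a + 1
    for start, length in ((start_a, branch_a), (start_b, branch_b)):
        for i in range(length):
            net.add_node(str(start + i))
        net.add_edge(str(trunk), str(start))
        for i in range(start, start + length - 1):
            net.add_edge(str(i), str(i + 1))
    return net


# -- random families -----------------------------------------------------


def _relabel(g: nx.DiGraph) -> DirectedNetwork:
    """Map integer networkx labels 0..n-1 to this package's '1'..'n'."""
    net = DirectedNetwork()
    for u in sorted(g.nodes):
        net.add_node(str(u + 1))
    for u, v in sorted(g.edges()):
        net.add_edge(str(u + 1), str(v + 1))
    return net


def _erdos_renyi(spec: GeneratorSpec) -> DirectedNetwork:
    if spec.mu is None:
        raise ValueError("er family requires mu")
    n = spec.n
    if n == 1 or spec.mu == 0:
        return DirectedNetwork.from_edges((), nodes=(str(i + 1) for i in range(n)))
    p = min(spec.mu / (n - 1), 1.0)
    g = nx.gnp_random_graph(n, p, seed=int(spec.seed), directed=True)
    return _relabel(g)


def _preferential_attachment(spec: GeneratorSpec) -> DirectedNetwork:
    """Directed BA-style growth: each new node sends ``m`` out-edges to
    distinct existing nodes chosen with probability proportional to
    in-degree + 1."""
    rng = np.random.default_rng(spec.seed)
    n, m = spec.n, max(1, spec.m)
    net = DirectedNetwork.from_edges((), nodes=(str(i) for i in range(1, n + 1)))
    indeg = np.zeros(n)
    for new in range(1, n):
        k = min(m, new)
        weights = indeg[:new] + 1.0
        targets = rng.choice(new, size=k, replace=False, p=weights / weights.sum())
        for t in sorted(targets):
            net.add_edge(str(new + 1), str(t + 1))
            indeg[t] += 1
    return net


def _mean_one_sample(family: str, shape: float, size: int, rng) -> np.ndarray:
    """Draw from the named law rescaled to mean 1."""
    if family == "chi2":
        return stats.chi2.rvs(shape, size=size, random_state=rng) / shape
    if family == "weibull":
        mean = special.gamma(1.0 + 1.0 / shape)
        return stats.weibull_min.rvs(shape, size=size, random_state=rng) / mean
    if family == "gamma":
        return stats.gamma.rvs(shape, size=size, random_state=rng) / shape
    raise ValueError(family)


def _configuration(spec: GeneratorSpec) -> DirectedNetwork:
    """Directed configuration model with the requested heavy-tailed degree
    law for both in- and out-degrees, in/out sums balanced by random unit
    increments, parallel edges collapsed."""
    if spec.mu is None:
        raise ValueError(f"{spec.family} family requires mu")
    rng = np.random.default_rng(spec.seed)
    shape = spec.shape if spec.shape is not None else _DEFAULT_SHAPE[spec.family]
    n = spec.n
    din = np.rint(spec.mu * _mean_one_sample(spec.family, shape, n, rng)).astype(int)
    dout = np.rint(spec.mu * _mean_one_sample(spec.family, shape, n, rng)).astype(int)
    din = np.clip(din, 0, n - 1)
    dout = np.clip(dout, 0, n - 1)
    # balance the stub counts with random unit increments on the light side
    while din.sum() != dout.sum():
        side = din if din.sum() < dout.sum() else dout
        i = int(rng.integers(n))
        if side[i] < n - 1:
            side[i] += 1
    g = nx.directed_configuration_model(
        din.tolist(), dout.tolist(), seed=int(rng.integers(2**31))
    )
    return _relabel(nx.DiGraph(g))
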