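"""Local-game matching (LM), control-path extraction and an exact
maximum-matching oracle.

LM is a distributed protocol that approximates maximum matching using only
local topology: in synchronous rounds every node that still lacks a matched
child sends a *child request* to its unmatched child neighbour with the
lowest u-input degree, and every node lacking a matched parent sends a
*parent request* to its unmatched parent neighbour with the lowest u-output
degree.  Only a mutual pair of requests fixes a parent-child match; the
matched parent then drops all its other outgoing links and the matched
child all its other incoming links.  Ties among minimum-degree candidates
are either skipped for this round (with waiting probability ``omega``) or
broken uniformly at random.  The fixed matches decompose the node set into
directed control paths (DCPs, open chains whose head is a driver node that
must receive an external control input) and circled control paths (CCPs,
closed loops that can be tapped onto any existing input).

The exact oracle computes a true maximum matching on the bipartite
out-copy/in-copy representation (Hopcroft-Karp), giving the minimum driver
count ``N_D = max(N - |matching|, 1)`` for comparison with the local
protocol's ``N_D^LM``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import networkx as nx
import numpy as np
from networkx.algorithms import bipartite

from .graph_core import DirectedNetwork

__all__ = [
    "ControlPath",
    "LMResult",
    "MMResult",
    "lm_match",
    "required_inputs",
    "mm_exact",
    "driver_degree_histogram",
    "total_variation",
]


@dataclass(frozen=True)
class ControlPath:
    """An ordered node sequence tagged DCP (open) or CCP (closed).

    ``length`` counts *nodes*; on closed layouts (e.g. inputs on a circle)
    the package separately measures segments in *edges* — both conventions
    are used in the field and each is applied where it belongs.
    """

    kind: str  # "DCP" | "CCP"
    nodes: tuple

    def __post_init__(self):
        if self.kind not in ("DCP", "CCP"):
            raise ValueError("kind must be 'DCP' or 'CCP'")
        if not self.nodes:
            raise ValueError("a control path has at least one node")

    @property
    def length(self) -> int:
        return len(self.nodes)


@dataclass
class LMResult:
    """Outcome of one local-game matching run."""

    parent_of: dict  # node -> its matched parent
    child_of: dict  # node -> its matched child
    dcps: list = field(default_factory=list)
    ccps: list = field(default_factory=list)
    drivers: frozenset = frozenset()
    rounds: int = 0
    omega: float = 0.0
    seed: int = 0

    @property
    def n_driver(self) -> int:
        """N_D^LM: the number of DCPs, i.e. of required driver nodes."""
        return len(self.dcps)

    def to_dict(self) -> dict:
        return {
            "parent_of": dict(sorted(self.parent_of.items())),
            "child_of": dict(sorted(self.child_of.items())),
            "dcps": [list(p.nodes) for p in self.dcps],
            "ccps": [list(p.nodes) for p in self.ccps],
            "drivers": sorted(self.drivers),
            "n_driver": self.n_driver,
            "rounds": self.rounds,
            "omega": self.omega,
            "seed": self.seed,
        }


@dataclass(frozen=True)
class MMResult:
    """Exact maximum-matching result on the bipartite representation."""

    matching: frozenset  # matched (u, v) edges
    n_driver: int
    drivers: frozenset  # one unmatched-node set realizing N_D

    def to_dict(self) -> dict:
        return {
            "matching": sorted(self.matching),
            "n_driver": self.n_driver,
            "drivers": sorted(self.drivers),
        }


def lm_match(
    net: DirectedNetwork,
    omega: float = 0.0,
    seed: int = 0,
    max_rounds: int | None = None,
) -> LMResult:
    """Run the local matching game and extract control paths.

    Rounds are synchronous: requests are computed from the state at the
    start of the round and exchanged simultaneously, and u-degrees are
    recomputed between rounds.  The waiting decision is taken per tie
    event.  Nodes are visited in network order and tie candidates sorted,
    so the run is fully reproducible given ``(net, omega, seed)``.
    """
    if not 0.0 <= omega <= 1.0:
        raise ValueError("omega must be a probability")
    order = list(net.nodes)
    if not order:
        return LMResult({}, {}, omega=omega, seed=seed)
    rng = np.random.default_rng(seed)

    succ = {u: set(net.successors(u)) for u in order}
    pred = {u: set(net.predecessors(u)) for u in order}
    child_of: dict = {}
    parent_of: dict = {}
    rounds = 0
    if max_rounds is None:
        max_rounds = 1000 + 10 * len(order)

    while rounds < max_rounds:
        # u-degrees from the state at the start of the round
        u_in = {x: sum(1 for p in pred[x] if p not in child_of) for x in order}
        u_out = {x: sum(1 for c in succ[x] if c not in parent_of) for x in order}

        stochastic = False

        def pick(cands, key):
            nonlocal stochastic
            best = min(key[c] for c in cands)
            ties = sorted(c for c in cands if key[c] == best)
            if len(ties) == 1:
                return ties[0]
            if omega >= 1.0:
                return None  # always wait on ties
            stochastic = True
            if omega > 0.0 and rng.random() < omega:
                return None  # wait this round
            return ties[int(rng.integers(len(ties)))]

        child_req: dict = {}
        parent_req: dict = {}
        for x in order:
            if x not in child_of:
                cands = [c for c in succ[x] if c not in parent_of]
                if cands:
                    chosen = pick(cands, u_in)
                    if chosen is not None:
                        child_req[x] = chosen
            if x not in parent_of:
                cands = [p for p in pred[x] if p not in child_of]
                if cands:
                    chosen = pick(cands, u_out)
                    if chosen is not None:
                        parent_req[x] = chosen

        if not child_req and not parent_req:
            break
        rounds += 1

        matches = [
            (p, c) for p, c in child_req.items() if parent_req.get(c) == p
        ]
        for p, c in matches:
            child_of[p] = c
            parent_of[c] = p
        for p, c in matches:
            # the matched parent drops its other outgoing links, the
            # matched child its other incoming links
            for other in list(succ[p]):
                if other != c:
                    succ[p].discard(other)
                    pred[other].discard(p)
            for other in list(pred[c]):
                if other != p:
                    pred[c].discard(other)
                    succ[other].discard(c)

        if not matches and not stochastic:
            # deterministic round with no progress: a fixed point
            break

    dcps, ccps = _extract_paths(order, parent_of, child_of)
    drivers = frozenset(p.nodes[0] for p in dcps)
    return LMResult(
        parent_of=parent_of,
        child_of=child_of,
        dcps=dcps,
        ccps=ccps,
        drivers=drivers,
        rounds=rounds,
        omega=omega,
        seed=seed,
    )


def _extract_paths(order, parent_of, child_of):
    """Decompose the match maps into DCPs (open chains) and CCPs (loops)."""
    pos = {u: i for i, u in enumerate(order)}
    visited = set()
    dcps = []
    for head in order:
        if head in parent_of:
            continue
        path = [head]
        visited.add(head)
        x = head
        while x in child_of:
            x = child_of[x]
            path.append(x)
            visited.add(x)
        dcps.append(ControlPath("DCP", tuple(path)))
    ccps = []
    for start in order:
        if start in visited:
            continue
        cycle = [start]
        visited.add(start)
        x = child_of[start]
        while x != start:
            cycle.append(x)
            visited.add(x)
            x = child_of[x]
        # canonical rotation: begin at the smallest node position
        k = min(range(len(cycle)), key=lambda i: pos[cycle[i]])
        cycle = cycle[k:] + cycle[:k]
        ccps.append(ControlPath("CCP", tuple(cycle)))
    return dcps, ccps


def required_inputs(res: LMResult) -> int:
    """Number of independent external control inputs the matching needs.

    Equals the number of DCPs; a non-empty network made only of CCPs still
    needs one existing input to hook the circles onto, and the empty
    network needs none.
    """
    if res.dcps:
        return len(res.dcps)
    return 1 if res.ccps else 0


def mm_exact(net: DirectedNetwork) -> MMResult:
    """Exact maximum matching via Hopcroft-Karp on out-/in-copies.

    Each node is split into an out-copy and an in-copy; a matched bipartite
    edge selects the directed edge between the originals, so no two matched
    edges share a start or an end node.
    """
    if net.n_nodes == 0:
        return MMResult(frozenset(), 0, frozenset())
    # integer labels: out-copy of node i is i, its in-copy is n + i.
    # (string labels would make the algorithm's internal set iteration,
    # hence the returned matching realization, depend on interpreter
    # hash randomization)
    n = net.n_nodes
    idx = net.node_index()
    names = net.nodes
    g = nx.Graph()
    g.add_nodes_from(range(n), bipartite=0)
    g.add_nodes_from(range(n, 2 * n), bipartite=1)
    for u, v, _ in net.edges():
        g.add_edge(idx[u], n + idx[v])
    matching = bipartite.hopcroft_karp_matching(g, top_nodes=set(range(n)))
    matched = frozenset(
        (names[key], names[val - n]) for key, val in matching.items() if key < n
    )
    n_driver = max(n - len(matched), 1)
    unmatched = [u for u in names if n + idx[u] not in matching]
    if unmatched:
        drivers = frozenset(unmatched)
    else:
        # perfect matching: every node sits on a circle, one input suffices
        drivers = frozenset([net.nodes[0]])
    return MMResult(matched, n_driver, drivers)


def driver_degree_histogram(res, net: DirectedNetwork):
    """Normalized in-/out-degree distributions of the driver nodes.

    Accepts either an :class:`LMResult` or an :class:`MMResult`; returns a
    pair of ``{degree: fraction}`` dicts (empty when there are no drivers).
    """
    drivers = sorted(res.drivers)
    if not drivers:
        return {}, {}
    n = len(drivers)
    hist_in: dict = {}
    hist_out: dict = {}
    for u in drivers:
        hist_in[net.in_degree(u)] = hist_in.get(net.in_degree(u), 0) + 1
        hist_out[net.out_degree(u)] = hist_out.get(net.out_degree(u), 0) + 1
    return (
        {k: v / n for k, v in sorted(hist_in.items())},
        {k: v / n for k, v in sorted(hist_out.items())},
    )


def total_variation(p: dict, q: dict) -> float:
    """Total-variation distance between two discrete distributions."""
    support = set(p) | set(q)
    return 0.5 * sum(abs(p.get(k, 0.0) - q.get(k, 0.0)) for k in support)
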