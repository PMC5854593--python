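"""Min-max allocation of extra control inputs over control paths.

Given the control paths produced by the matching stage and a budget of
``m0`` additional inputs beyond the mandatory one-per-DCP, the allocator
solves

    min over (n_1..n_k)   max_i  L_i / (1 + n_i)
    subject to            sum_i n_i = m0,   0 <= n_i <= m0

where ``L_i`` is the node count of path *i*.  The longest resulting
control path is ``max_i ceil(L_i / (1 + n_i))``.  Splitting paths evenly
matters because minimum control energy grows roughly factorially with the
longest stretch of nodes any single input has to steer, so shaving the
longest path dominates every other consideration.

The allocation is solved greedily — repeatedly grant one input to the path
with the current largest ratio, ties toward the lowest path index.  An
exchange argument makes this optimal for the min-max objective; the test
suite additionally verifies it against exhaustive enumeration.  Ratios are
compared as exact fractions so ties are never an artefact of rounding.

CCPs need no input of their own; each is assigned to a control path
(largest CCP first, onto the currently shortest effective path) and simply
lengthens it.  When only CCPs exist a single virtual path hosts the one
mandatory input.
"""

from __future__ import annotations

import heapq
from dataclasses import dataclass
from fractions import Fraction

import numpy as np

from .graph_core import DirectedNetwork
from .matching import ControlPath, LMResult, mm_exact

__all__ = [
    "InputAllocation",
    "ControlPlan",
    "allocate_inputs",
    "assign_ccps",
    "input_positions",
    "place_control_nodes",
    "build_B",
    "ram_select",
    "plan_control",
]


@dataclass(frozen=True)
class InputAllocation:
    """Solution of the min-max input allocation."""

    lengths: tuple  # path lengths L_i in nodes
    m0: int  # extra inputs distributed
    n: tuple  # extra inputs per path, sum(n) == m0
    objective: float  # max_i L_i / (1 + n_i)
    longest: int  # max_i ceil(L_i / (1 + n_i))


def allocate_inputs(lengths, m0: int) -> InputAllocation:
    """Distribute ``m0`` extra inputs to minimize the longest path ratio."""
    lengths = tuple(int(x) for x in lengths)
    if any(x < 1 for x in lengths):
        raise ValueError("path lengths must be >= 1")
    if m0 < 0:
        raise ValueError("m0 must be >= 0")
    if not lengths:
        if m0 > 0:
            raise ValueError("cannot allocate inputs without control paths")
        return InputAllocation((), 0, (), 0.0, 0)
    # greedy: always feed the currently worst path; exact fractions keep
    # tie-breaking deterministic (lowest index first)
    heap = [(Fraction(-length, 1), i, 0) for i, length in enumerate(lengths)]
    heapq.heapify(heap)
    for _ in range(m0):
        _, i, ni = heapq.heappop(heap)
        ni += 1
        heapq.heappush(heap, (Fraction(-lengths[i], 1 + ni), i, ni))
    n = [0] * len(lengths)
    for _, i, ni in heap:
        n[i] = ni
    objective = max(Fraction(length, 1 + ni) for length, ni in zip(lengths, n))
    longest = max(-(-length // (1 + ni)) for length, ni in zip(lengths, n))
    return InputAllocation(lengths, m0, tuple(n), float(objective), longest)


def _assign(dcp_paths, ccp_paths):
    """Assign each CCP to a path, largest CCP onto the currently shortest
    effective path.  Returns one list of pieces per composite path; the
    first piece is the hosting DCP (or the largest CCP when no DCP
    exists) and later pieces are the CCPs folded onto it."""
    if dcp_paths:
        composites = [[tuple(p)] for p in dcp_paths]
    elif ccp_paths:
        ccp_paths = sorted(ccp_paths, key=len, reverse=True)
        composites = [[tuple(ccp_paths[0])]]
        ccp_paths = ccp_paths[1:]
    else:
        return []

    def total(pieces):
        return sum(len(p) for p in pieces)

    for ccp in sorted(ccp_paths, key=len, reverse=True):
        k = min(range(len(composites)), key=lambda i: total(composites[i]))
        composites[k].append(tuple(ccp))
    return composites


def assign_ccps(dcp_lengths, ccp_lengths):
    """Merged effective path lengths after CCP assignment.

    Operates on lengths only; placeholder node labels stand in for the
    actual path members.
    """
    dcps = [tuple(range(length)) for length in dcp_lengths]
    ccps = [tuple(range(length)) for length in ccp_lengths]
    return [sum(len(p) for p in pieces) for pieces in _assign(dcps, ccps)]


def input_positions(length: int, k: int):
    """1-based positions of ``k`` inputs along a path of ``length`` nodes.

    Input j (0-based) attaches at node floor(j * length / k) + 1, which
    splits the path into segments whose node counts differ by at most one;
    the first input always sits at the path head (the driver node).
    """
    if not 1 <= k <= length:
        raise ValueError("need 1 <= k <= path length")
    return [j * length // k + 1 for j in range(k)]


def place_control_nodes(path: ControlPath, k: int):
    """Node identifiers receiving the ``k`` inputs assigned to ``path``."""
    return [path.nodes[p - 1] for p in input_positions(path.length, k)]


def build_B(net: DirectedNetwork, control_nodes) -> np.ndarray:
    """Unit-column input matrix for the given control nodes.

    Column m is the indicator of control node m's row, so B^T B = I_M by
    construction (each network node connects to at most one input).
    """
    idx = net.node_index()
    control_nodes = [str(u) for u in control_nodes]
    if len(set(control_nodes)) != len(control_nodes):
        raise ValueError("control nodes must be distinct")
    b = np.zeros((net.n_nodes, len(control_nodes)))
    for m, u in enumerate(control_nodes):
        if u not in idx:
            raise ValueError(f"unknown node {u!r}")
        b[idx[u], m] = 1.0
    return b


def ram_select(net: DirectedNetwork, m: int, seed: int = 0):
    """Random-allocation baseline: one maximum-matching driver set plus
    ``m - N_D`` uniformly chosen distinct non-driver nodes."""
    if m > net.n_nodes:
        raise ValueError("cannot select more control nodes than nodes")
    mm = mm_exact(net)
    idx = net.node_index()
    drivers = sorted(mm.drivers, key=idx.get)
    if m < len(drivers):
        raise ValueError(f"need at least N_D = {len(drivers)} control nodes")
    pool = sorted((u for u in net.nodes if u not in mm.drivers), key=idx.get)
    rng = np.random.default_rng(seed)
    extra = rng.choice(len(pool), size=m - len(drivers), replace=False)
    chosen = drivers + [pool[i] for i in sorted(extra)]
    return sorted(chosen, key=idx.get)


@dataclass(frozen=True)
class ControlPlan:
    """Full allocation plan: composite paths, per-path inputs, control nodes."""

    paths: tuple  # composite node tuples (DCP + assigned CCP nodes)
    allocation: InputAllocation
    control_nodes: tuple

    @property
    def m_total(self) -> int:
        return len(self.control_nodes)


def _place_on_pieces(pieces, k: int):
    """Distribute ``k`` inputs over the pieces of one composite path.

    The hosting piece always keeps the mandatory head input (the driver
    node); remaining inputs go greedily to the piece whose worst
    within-piece stretch ``len/assigned`` is currently largest, pieces
    without any input first (their nodes are only reachable the long way
    round through the hook-up, the worst case numerically).  Within a
    piece the inputs sit at evenly spaced positions.
    """
    counts = [0] * len(pieces)
    counts[0] = 1
    for _ in range(k - 1):
        best = max(
            range(len(pieces)),
            key=lambda i: (
                counts[i] == 0,
                Fraction(len(pieces[i]), max(counts[i], 1)),
                -i,
            ),
        )
        counts[best] += 1
    nodes = []
    for piece, c in zip(pieces, counts):
        if c > 0:
            nodes.extend(piece[p - 1] for p in input_positions(len(piece), c))
    return nodes


def plan_control(res: LMResult, m0: int) -> ControlPlan:
    """Turn a matching result plus ``m0`` extra inputs into a control plan.

    CCPs are first folded onto effective paths, the min-max allocator
    splits the budget over the merged path lengths, and each path's
    ``1 + n_i`` inputs are spread over its pieces so every stretch of
    nodes between consecutive inputs stays as short as possible.  The
    total number of control nodes is the number of required inputs plus
    ``m0``.
    """
    composites = _assign(
        [p.nodes for p in res.dcps], [p.nodes for p in res.ccps]
    )
    lengths = [sum(len(p) for p in pieces) for pieces in composites]
    alloc = allocate_inputs(lengths, m0)
    control_nodes = []
    for pieces, ni in zip(composites, alloc.n):
        control_nodes.extend(_place_on_pieces(pieces, 1 + ni))
    paths = tuple(tuple(n for p in pieces for n in p) for pieces in composites)
    return ControlPlan(paths, alloc, tuple(control_nodes))
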