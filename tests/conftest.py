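"""Shared fixtures and independent oracles for the test suite.

The oracles here deliberately avoid the package's own code paths: the
allocation oracle enumerates every composition of the input budget, the
matching oracle tries every subset of edges, and the Gramian oracle uses
adaptive quadrature instead of the block-exponential construction.
"""

from fractions import Fraction
from itertools import combinations

import numpy as np
import pytest
from scipy.integrate import quad_vec
from scipy.linalg import expm

from netctrl import DirectedNetwork, make_circle, make_stem


@pytest.fixture
def stem5():
    return make_stem(5)


@pytest.fixture
def circle3():
    return make_circle(3)


@pytest.fixture
def star4():
    """Star 1 -> {2, 3, 4}: a dilation forcing three driver nodes."""
    return DirectedNetwork.from_edges([("1", "2"), ("1", "3"), ("1", "4")])


# -- oracles -------------------------------------------------------------


def brute_force_allocation(lengths, m0):
    """Exhaustive min-max value over all compositions of m0 into the paths."""
    k = len(lengths)

    def compositions(total, parts):
        if parts == 1:
            yield (total,)
            return
        for first in range(total + 1):
            for rest in compositions(total - first, parts - 1):
                yield (first,) + rest

    best = None
    for n in compositions(m0, k):
        val = max(Fraction(length, 1 + ni) for length, ni in zip(lengths, n))
        if best is None or val < best:
            best = val
    return best


def brute_force_mm_size(net):
    """Maximum matching size by trying every subset of edges (tiny nets)."""
    edges = [(u, v) for u, v, _ in net.edges()]
    best = 0
    for r in range(len(edges), 0, -1):
        if r <= best:
            break
        for sub in combinations(edges, r):
            starts = [e[0] for e in sub]
            ends = [e[1] for e in sub]
            if len(set(starts)) == r and len(set(ends)) == r:
                best = max(best, r)
                break
    return best


def quadrature_gramian(a, b, t_f):
    """Adaptive-quadrature reference for the controllability Gramian."""
    val, _ = quad_vec(
        lambda t: expm(a * t) @ b @ b.T @ expm(a * t).T,
        0.0,
        t_f,
        epsabs=1e-13,
        epsrel=1e-13,
    )
    return val


def random_stable_matrix(n, rng, margin=1.0):
    """Random dense matrix shifted to have spectral abscissa -margin."""
    a = rng.standard_normal((n, n))
    shift = np.max(np.linalg.eigvals(a).real) + margin
    return a - shift * np.eye(n)
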