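"""Scaled-down simulation studies combining the matching, allocation and
energy layers.

These are the package's validation experiments: how close the local
matching protocol gets to the exact maximum-matching optimum, whether the
two methods pick statistically similar driver nodes, and whether min-max
input allocation beats random allocation on control cost.  All of them are
deterministic given their seed and sized to finish on a laptop.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from . import netgen
from .energy import LTISystem, expected_cost
from .matching import (
    LMResult,
    driver_degree_histogram,
    lm_match,
    mm_exact,
    total_variation,
)
from .mlcp import build_B, plan_control, ram_select

__all__ = [
    "validate_lm_result",
    "lm_mm_comparison",
    "driver_histogram_distance",
    "driver_fraction_curve",
    "mlcp_vs_ram",
]


def validate_lm_result(res: LMResult, net) -> None:
    """Raise AssertionError unless the matching result is structurally valid.

    Checks: the match maps are mutually consistent, every match is an
    original edge, each node has at most one matched parent/child, and the
    DCPs/CCPs together partition the node set.
    """
    for p, c in res.child_of.items():
        assert res.parent_of.get(c) == p, "parent/child maps inconsistent"
        assert net.has_edge(p, c), f"match {p}->{c} is not a network edge"
    for c, p in res.parent_of.items():
        assert res.child_of.get(p) == c, "parent/child maps inconsistent"
    covered = []
    for path in res.dcps + res.ccps:
        covered.extend(path.nodes)
        pairs = list(zip(path.nodes, path.nodes[1:]))
        if path.kind == "CCP":
            pairs.append((path.nodes[-1], path.nodes[0]))
        for a, b in pairs:
            assert res.child_of.get(a) == b, "path not made of fixed matches"
        if path.kind == "DCP":
            assert path.nodes[0] not in res.parent_of, "DCP head has a parent"
            assert path.nodes[-1] not in res.child_of, "DCP tail has a child"
    assert len(covered) == len(set(covered)) == net.n_nodes, (
        "control paths do not partition the node set"
    )
    assert res.drivers == frozenset(p.nodes[0] for p in res.dcps)


def lm_mm_comparison(
    n_graphs: int = 100,
    n: int = 500,
    mus=(1, 2, 3, 4, 5, 6, 7, 8),
    families=("er", "ba"),
    omega: float = 0.0,
    seed: int = 0,
    validate: bool = True,
) -> pd.DataFrame:
    """Driver counts of the local protocol versus the exact optimum.

    Draws ``n_graphs`` networks cycling through families and mean degrees,
    runs both methods, and returns one row per graph with ``nd_lm``,
    ``nd_mm`` and their ratio.  With ``validate=True`` each matching result
    is also checked for structural validity.
    """
    rng = np.random.default_rng(seed)
    rows = []
    for g in range(n_graphs):
        family = families[g % len(families)]
        mu = float(mus[(g // len(families)) % len(mus)])
        s = int(rng.integers(2**31))
        if family == "ba":
            m = max(1, int(round(mu)))
            spec = netgen.GeneratorSpec("ba", n=n, m=m, seed=s)
        else:
            spec = netgen.GeneratorSpec(family, n=n, mu=mu, seed=s)
        net = netgen.generate(spec)
        res = lm_match(net, omega=omega, seed=int(rng.integers(2**31)))
        if validate:
            validate_lm_result(res, net)
        mm = mm_exact(net)
        rows.append(
            {
                "family": family,
                "mu": mu,
                "seed": s,
                "rounds": res.rounds,
                "nd_lm": res.n_driver,
                "nd_mm": mm.n_driver,
                "ratio": res.n_driver / mm.n_driver,
            }
        )
    return pd.DataFrame(rows)


def driver_histogram_distance(
    n: int = 1000,
    mu: float = 6.0,
    n_seeds: int = 5,
    omega: float = 0.0,
    seed: int = 0,
) -> dict:
    """Total-variation distance between LM and MM driver degree statistics.

    Pools driver in-/out-degrees over ``n_seeds`` Erdos-Renyi draws for
    each method and compares the pooled distributions.
    """
    rng = np.random.default_rng(seed)
    pool: dict = {("lm", "in"): [], ("lm", "out"): [], ("mm", "in"): [], ("mm", "out"): []}
    for _ in range(n_seeds):
        s = int(rng.integers(2**31))
        net = netgen.generate(netgen.GeneratorSpec("er", n=n, mu=mu, seed=s))
        res = lm_match(net, omega=omega, seed=int(rng.integers(2**31)))
        mm = mm_exact(net)
        for label, result in (("lm", res), ("mm", mm)):
            for u in result.drivers:
                pool[(label, "in")].append(net.in_degree(u))
                pool[(label, "out")].append(net.out_degree(u))

    def norm(vals):
        total = len(vals)
        out: dict = {}
        for v in vals:
            out[v] = out.get(v, 0) + 1
        return {k: c / total for k, c in out.items()}

    return {
        "tv_in": total_variation(norm(pool[("lm", "in")]), norm(pool[("mm", "in")])),
        "tv_out": total_variation(norm(pool[("lm", "out")]), norm(pool[("mm", "out")])),
        "n_lm_drivers": len(pool[("lm", "in")]),
        "n_mm_drivers": len(pool[("mm", "in")]),
    }


def driver_fraction_curve(
    family: str = "er",
    n: int = 2000,
    mus=(1, 2, 3, 4, 5, 6, 7, 8),
    seed: int = 0,
) -> pd.DataFrame:
    """Driver-node fraction versus mean degree for one topology family."""
    rng = np.random.default_rng(seed)
    rows = []
    for mu in mus:
        s = int(rng.integers(2**31))
        if family == "ba":
            spec = netgen.GeneratorSpec("ba", n=n, m=max(1, int(round(mu))), seed=s)
        else:
            spec = netgen.GeneratorSpec(family, n=n, mu=float(mu), seed=s)
        net = netgen.generate(spec)
        res = lm_match(net, seed=int(rng.integers(2**31)))
        mm = mm_exact(net)
        rows.append(
            {
                "family": family,
                "mu": float(mu),
                "frac_lm": res.n_driver / n,
                "frac_mm": mm.n_driver / n,
            }
        )
    return pd.DataFrame(rows)


def mlcp_vs_ram(
    n: int = 100,
    mu: float = 2.0,
    m0: int = 10,
    n_seeds: int = 50,
    t_f: float = 1.0,
    seed: int = 0,
) -> pd.DataFrame:
    """Control cost of min-max allocation versus random allocation.

    For each seed, draw an Erdos-Renyi network, run the local matching,
    fold CCPs, allocate ``m0`` extra inputs by the min-max rule and place
    them evenly (MLCP); as the baseline, take one exact maximum-matching
    driver set plus uniformly random extra nodes with the same total input
    count (RAM).  Both input matrices are evaluated with the same expected
    cost functional; numerically singular Gramians are floored identically
    for the two methods so the comparison stays fair.
    """
    import warnings as _warnings

    from .energy import ControllabilityWarning

    rng = np.random.default_rng(seed)
    rows = []
    for _ in range(n_seeds):
        s = int(rng.integers(2**31))
        net = netgen.generate(netgen.GeneratorSpec("er", n=n, mu=mu, seed=s))
        res = lm_match(net, seed=int(rng.integers(2**31)))
        plan = plan_control(res, m0)
        m_total = plan.m_total
        sys = LTISystem(net.adjacency_matrix(), t_f=t_f)
        ram_nodes = ram_select(net, m_total, seed=int(rng.integers(2**31)))
        with _warnings.catch_warnings():
            _warnings.simplefilter("ignore", ControllabilityWarning)
            cost_mlcp = expected_cost(
                sys, build_B(net, plan.control_nodes), clip_singular=True
            )
            cost_ram = expected_cost(
                sys, build_B(net, ram_nodes), clip_singular=True
            )
        rows.append(
            {
                "seed": s,
                "m_total": m_total,
                "longest": plan.allocation.longest,
                "cost_mlcp": cost_mlcp,
                "cost_ram": cost_ram,
                "mlcp_wins": cost_mlcp <= cost_ram,
            }
        )
    return pd.DataFrame(rows)
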