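"""Local-game matching protocol, path extraction, and the exact oracle."""

import numpy as np
import pytest

from netctrl import (
    DirectedNetwork,
    GeneratorSpec,
    driver_degree_histogram,
    generate,
    lm_match,
    make_circle,
    make_stem,
    mm_exact,
    required_inputs,
)
from netctrl.experiments import validate_lm_result
from netctrl.matching import total_variation

from conftest import brute_force_mm_size


class TestLMElementary:
    def test_stem_forms_one_dcp(self, stem5):
        res = lm_match(stem5)
        assert [p.nodes for p in res.dcps] == [("1", "2", "3", "4", "5")]
        assert res.ccps == [] and res.drivers == frozenset(["1"])
        assert res.n_driver == 1 and required_inputs(res) == 1
        assert res.rounds == 1  # every request is forced and mutual

    def test_circle_forms_one_ccp(self, circle3):
        res = lm_match(circle3)
        assert res.dcps == [] and len(res.ccps) == 1
        assert res.ccps[0].nodes == ("1", "2", "3")
        assert res.drivers == frozenset()
        assert required_inputs(res) == 1  # circles tap an existing input

    def test_isolated_nodes_are_singleton_drivers(self):
        net = DirectedNetwork.from_edges([], nodes=["a", "b", "c"])
        res = lm_match(net)
        assert len(res.dcps) == 3 and all(p.length == 1 for p in res.dcps)
        assert res.drivers == frozenset(["a", "b", "c"])

    def test_self_loop_self_matches(self):
        res = lm_match(make_circle(1))
        assert res.ccps[0].nodes == ("1",) and res.drivers == frozenset()

    def test_empty_network(self):
        res = lm_match(DirectedNetwork())
        assert res.dcps == [] and res.ccps == [] and required_inputs(res) == 0

    def test_star_strands_two_leaves(self, star4):
        res = lm_match(star4, seed=3)
        assert res.n_driver == 3  # centre path head plus two stranded leaves

    def test_determinism_and_omega_validation(self, star4):
        a = lm_match(star4, omega=0.25, seed=9)
        b = lm_match(star4, omega=0.25, seed=9)
        assert a.to_dict() == b.to_dict()
        with pytest.raises(ValueError):
            lm_match(star4, omega=1.5)

    def test_omega_one_waits_forever_on_pure_ties(self, star4):
        # with omega = 1 the centre never resolves its three-way tie, so
        # no match can form and every node ends up on its own path
        res = lm_match(star4, omega=1.0)
        assert res.n_driver == 4


class TestExactMaximumMatching:
    @pytest.mark.parametrize(
        "maker,size,n_driver",
        [(lambda: make_stem(5), 4, 1), (lambda: make_circle(3), 3, 1)],
    )
    def test_elementary(self, maker, size, n_driver):
        res = mm_exact(maker())
        assert len(res.matching) == size and res.n_driver == n_driver

    def test_star(self, star4):
        res = mm_exact(star4)
        assert len(res.matching) == 1 and res.n_driver == 3
        assert len(res.drivers) == 3

    def test_perfect_matching_still_needs_one_driver(self, circle3):
        res = mm_exact(circle3)
        assert res.n_driver == 1 and len(res.drivers) == 1

    @pytest.mark.parametrize("seed", range(8))
    def test_matches_exhaustive_search_on_small_graphs(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(2, 6))
        edges = {
            (str(rng.integers(1, n + 1)), str(rng.integers(1, n + 1)))
            for _ in range(rng.integers(1, 9))
        }
        net = DirectedNetwork.from_edges(edges, nodes=[str(i) for i in range(1, n + 1)])
        assert len(mm_exact(net).matching) == brute_force_mm_size(net)


class TestProtocolProperties:
    @pytest.mark.parametrize("family,mu,seed", [
        ("er", 2.0, 0), ("er", 5.0, 1), ("er", 8.0, 2),
        ("ba", 3.0, 3), ("chi2", 4.0, 4),
    ])
    def test_paths_partition_nodes_and_dominance(self, family, mu, seed):
        kw = {"m": int(mu)} if family == "ba" else {"mu": mu}
        net = generate(GeneratorSpec(family, n=200, seed=seed, **kw))
        res = lm_match(net, seed=seed)
        validate_lm_result(res, net)  # partition + match validity
        nd_mm = mm_exact(net).n_driver
        assert max(res.n_driver, 1) >= nd_mm  # LM cannot beat the optimum

    def test_excess_drivers_stay_a_small_node_fraction(self):
        """The local protocol's driver excess over the exact optimum is a
        few percent of N even where the optimum itself is tiny."""
        rng = np.random.default_rng(5)
        excess = []
        for mu in (2.0, 4.0, 6.0):
            for _ in range(3):
                net = generate(
                    GeneratorSpec("er", n=300, mu=mu, seed=int(rng.integers(2**31)))
                )
                res = lm_match(net, seed=int(rng.integers(2**31)))
                excess.append((res.n_driver - mm_exact(net).n_driver) / 300)
        assert np.mean(excess) < 0.05

    def test_round_count_grows_slowly(self):
        rounds = {}
        for n in (250, 500):
            net = generate(GeneratorSpec("er", n=n, mu=3.0, seed=n))
            rounds[n] = lm_match(net, seed=1).rounds
        assert rounds[500] <= 2 * rounds[250] + 10


class TestDriverHistograms:
    def test_stem_driver_has_zero_in_degree(self, stem5):
        hin, hout = driver_degree_histogram(lm_match(stem5), stem5)
        assert hin == {0: 1.0} and hout == {1: 1.0}

    def test_star_mm_drivers_are_leaves(self, star4):
        hin, _ = driver_degree_histogram(mm_exact(star4), star4)
        assert hin.get(1, 0.0) >= 2 / 3  # stranded leaves dominate

    def test_empty_driver_set(self, circle3):
        assert driver_degree_histogram(lm_match(circle3), circle3) == ({}, {})

    def test_total_variation(self):
        assert total_variation({0: 1.0}, {0: 1.0}) == 0.0
        assert total_variation({0: 1.0}, {1: 1.0}) == 1.0
        assert total_variation({0: 0.5, 1: 0.5}, {0: 1.0}) == pytest.approx(0.5)
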