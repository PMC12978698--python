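"""Network pruning, three-step neighborhoods and hypergeometric DDG calls."""

import math

import numpy as np
import pandas as pd
import pytest

from ddgnet.datatypes import GeneDAG
from ddgnet.ddg import (
    call_ddgs,
    filter_neighborhoods,
    hypergeom_enrichment,
    hypergeom_upper_tail,
    prune_network,
    three_step_neighborhood,
)
from ddgnet.ddg import test_network_boundaries as network_boundary_records


def _dag(nodes, edges):
    return GeneDAG("c", "m", nodes, edges)


class TestPrune:
    def test_isolated_node_removed(self):
        out = prune_network(_dag(["a", "b", "c"], [("a", "b"), ("b", "a2")][0:1]))
        assert "c" not in out.nodes

    def test_path_single_pass_keeps_middle(self):
        out = prune_network(_dag(["a", "b", "c"], [("a", "b"), ("b", "c")]))
        assert out.nodes == ["b"]
        out2 = prune_network(_dag(["a", "b", "c"], [("a", "b"), ("b", "c")]),
                             iterate=True)
        assert out2.nodes == []

    def test_diamond_unchanged(self):
        edges = [("a", "b"), ("a", "c"), ("b", "d"), ("c", "d")]
        out = prune_network(_dag(list("abcd"), edges))
        assert sorted(out.nodes) == list("abcd")
        assert sorted(out.edges) == sorted(edges)


class TestNeighborhood:
    def test_isolated_focal(self):
        assert three_step_neighborhood(_dag(["a", "b"], []), "a") == {"a"}

    def test_chain_depth_three(self):
        edges = [("a", "b"), ("b", "c"), ("c", "d"), ("d", "e")]
        hood = three_step_neighborhood(_dag(list("abcde"), edges), "a")
        assert hood == {"a", "b", "c", "d"}

    def test_out_mode_on_collider(self):
        dag = _dag(["x", "y", "z"], [("x", "z"), ("y", "z")])
        assert three_step_neighborhood(dag, "z", mode="out") == {"z"}
        assert three_step_neighborhood(dag, "z", mode="in") == {"x", "y", "z"}
        assert three_step_neighborhood(dag, "z", mode="all") == {"x", "y", "z"}

    def test_absent_focal_raises(self):
        with pytest.raises(KeyError):
            three_step_neighborhood(_dag(["a"], []), "q")


class TestSizeFilter:
    def test_equal_sizes_none_retained(self):
        hoods = {f"g{i}": {"a", "b", "c", "d"} for i in range(4)}
        assert filter_neighborhoods(hoods) == {}

    def test_arithmetic_example(self):
        hoods = {"a": set("xy"), "b": set("xy"), "c": set("xy"),
                 "d": set("abcdefghij")}
        kept = filter_neighborhoods(hoods)
        assert list(kept) == ["d"]

    def test_single_neighborhood_rejected(self):
        with pytest.raises(ValueError):
            filter_neighborhoods({"a": {"a"}})


class TestHypergeom:
    def test_zero_overlap_gives_one(self):
        assert hypergeom_upper_tail(0, 5, 15, 6) == 1.0

    def test_matches_enumeration_small_case(self):
        m, n, k = 5, 15, 6
        expect = sum(
            math.comb(m, x) * math.comb(n, k - x) for x in range(3, min(m, k) + 1)
        ) / math.comb(m + n, k)
        assert np.isclose(hypergeom_upper_tail(3, m, n, k), expect, rtol=1e-12)

    def test_monotone_in_overlap(self):
        ps = [hypergeom_upper_tail(ov, 8, 20, 10) for ov in range(0, 9)]
        assert all(a >= b for a, b in zip(ps, ps[1:]))

    def test_enrichment_uses_overlap_minus_one_upper_tail(self):
        from scipy.stats import hypergeom as hg

        rec = hypergeom_enrichment(
            "f", members={"f", "a", "b", "c", "d", "e"},
            dynamic_set={"a", "b", "c", "q", "r"},
            network_genes={"f", "a", "b", "c", "d", "e", "q", "r"} | set("stuvwxyz"),
            population_mode="network",
        )
        assert rec["overlap"] == 3
        m, n, k = rec["m"], rec["n"], rec["k"]
        assert np.isclose(rec["p"], float(hg.sf(3 - 1, m + n, m, k)), rtol=1e-12)

    def test_literal_mode_matches_printed_recipe(self):
        rec = hypergeom_enrichment(
            "f", members={"f", "a"}, dynamic_set={"a", "b", "c"},
            n_neighborhoods=30, population_mode="literal",
        )
        assert rec["m"] == 3 and rec["n"] == 27 and rec["k"] == 2

    def test_infeasible_population_floored_or_raises(self):
        # union population smaller than the draw is floored to k - overlap
        rec = hypergeom_enrichment(
            "f", members=set("abcdef"), dynamic_set=set("ab"),
            union_genes=set("abcdef"), population_mode="union",
        )
        assert rec["n"] >= rec["k"] - rec["overlap"]


class TestCallDDGs:
    def test_single_enrichment_passthrough(self):
        calls = call_ddgs([{"focal_gene": "a", "cluster_label": "c",
                            "boundary_label": "b", "p": 0.01, "k": 5,
                            "overlap": 3, "m": 5, "n": 20, "module_id": "m",
                            "population_mode": "network"}])
        assert calls["p_adj"].iloc[0] == pytest.approx(0.01)
        assert bool(calls["is_ddg"].iloc[0])

    def test_no_dynamic_genes_no_calls(self):
        dag = _dag(list("abcdefgh"),
                   [("a", "b"), ("a", "c"), ("b", "d"), ("c", "d"),
                    ("d", "e"), ("e", "f"), ("f", "g"), ("g", "h")])
        records = network_boundary_records(dag, {"B": set()})
        calls = call_ddgs(records)
        assert len(calls) == 0 or not calls["is_ddg"].any()

    def test_invariant_to_gene_order(self):
        rng = np.random.default_rng(0)
        nodes = [f"g{i}" for i in range(16)]
        edges = [(nodes[i], nodes[i + 1]) for i in range(11)]
        edges += [(nodes[0], nodes[5]), (nodes[2], nodes[7]), (nodes[4], nodes[9])]
        edges += [(nodes[2], nodes[j]) for j in range(12, 16)]  # hub at g2
        dyn = {"g1", "g2", "g3"}
        a = call_ddgs(network_boundary_records(_dag(nodes, edges), {"B": dyn}))
        perm = list(rng.permutation(nodes))
        b = call_ddgs(network_boundary_records(_dag(perm, edges), {"B": dyn}))
        key = ["focal_gene", "boundary_label"]
        pd.testing.assert_frame_equal(
            a.sort_values(key).reset_index(drop=True)[["focal_gene", "p", "p_adj"]],
            b.sort_values(key).reset_index(drop=True)[["focal_gene", "p", "p_adj"]],
        )


def test_planted_driver_recovered_in_learned_network():
    """One seed of the driver-network experiment end to end (the 20-seed
    recovery-rate check lives in the acceptance suite)."""
    from ddgnet.bayesnet import learn_network
    from ddgnet.sim import simulate_driver_network

    expr, truth = simulate_driver_network(seed=0)
    dag = learn_network(expr, cluster_label="LMP", module_id="M1")
    calls = call_ddgs(network_boundary_records(
        dag, {"LMP_to_OBP": set(truth["dynamic_genes"])}, population_mode="network",
    ))
    drv = calls[calls["focal_gene"] == truth["driver"]]
    assert len(drv) == 1
    assert bool(drv["is_ddg"].iloc[0])
    assert drv["p"].iloc[0] <= calls["p"].min() + 1e-15
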