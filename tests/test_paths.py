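"""Thresholded metrics, path enumeration, layers, convergence/divergence."""

import math

import numpy as np
import pytest

from _oracles import dfs_paths, random_annotated_graph
from sezconn.errors import SezconnError
from sezconn.model import ConnectomeGraph
from sezconn.paths import (PathQuery, assign_layers, common_interneurons,
                           convergence_divergence, enumerate_paths,
                           fraction_neurons_connected,
                           percent_synaptic_connections, ranking_index,
                           threshold_graph)


def _graph(weights):
    return ConnectomeGraph(weights=weights)


ANN = {
    "S1": "sensory", "S2": "sensory", "S3": "sensory",
    "I1": "interneuron", "I2": "interneuron", "I3": "interneuron",
    "O": "motor", "M": "MBON",
}


class TestPercentAndRanking:
    def test_percent_outgoing(self):
        g = _graph({("A", "B"): 3, ("A", "C"): 1})
        assert percent_synaptic_connections(g, "A", {"B"}, "outgoing") == 75.0

    def test_all_partners_is_100(self):
        g = _graph({("A", "B"): 3, ("A", "C"): 1})
        assert percent_synaptic_connections(g, "A", {"B", "C"}, "outgoing") == 100.0

    def test_partition_sums_to_100(self, rng):
        g, _ = random_annotated_graph(rng, n_max=25)
        node = next(n for n in sorted(g.nodes, key=str) if g.out_weight(n) > 0)
        partners = sorted(g.successors(node), key=str)
        half = len(partners) // 2 or 1
        blocks = [set(partners[:half]), set(partners[half:])]
        total = sum(percent_synaptic_connections(g, node, b, "outgoing")
                    for b in blocks if b)
        assert total == pytest.approx(100.0)

    def test_zero_direction_flagged_nan(self):
        g = _graph({("A", "B"): 1})
        assert math.isnan(percent_synaptic_connections(g, "A", {"B"}, "incoming"))

    def test_ranking_index_examples(self):
        g = _graph({("X", "B"): 10, ("A", "B"): 5})
        assert ranking_index(g, "A", "B") == 0.5
        assert ranking_index(g, "X", "B") == 1.0

    def test_ranking_index_argmax_unique(self, rng):
        g, _ = random_annotated_graph(rng, n_max=25)
        tgt = next(n for n in sorted(g.nodes, key=str) if g.in_weight(n) > 0)
        incoming = g.predecessors(tgt)
        best = max(incoming.values())
        for src, w in incoming.items():
            ri = ranking_index(g, src, tgt)
            assert ri == pytest.approx(w / best)
            assert (ri == 1.0) == (w == best)

    def test_ranking_errors(self):
        g = _graph({("A", "B"): 1})
        with pytest.raises(SezconnError):
            ranking_index(g, "B", "A")  # A has no inputs
        with pytest.raises(SezconnError):
            ranking_index(g, "X", "B")  # no such edge


class TestThresholdGraph:
    def test_filters_below_threshold(self):
        g = _graph({("a", "b"): 1, ("b", "c"): 2, ("c", "d"): 3})
        t = threshold_graph(g, 2)
        assert {(s, d) for s, d, _ in t.edges()} == {("b", "c"), ("c", "d")}
        assert t.nodes == g.nodes  # nodes retained

    def test_t1_is_identity(self, rng):
        g, _ = random_annotated_graph(rng, n_max=20)
        assert threshold_graph(g, 1) == g

    def test_anti_monotone_in_threshold(self, rng):
        g, _ = random_annotated_graph(rng, n_max=30)
        prev = None
        for t in (1, 2, 3, 4, 5, 6):
            edges = {(s, d) for s, d, _ in threshold_graph(g, t).edges()}
            if prev is not None:
                assert edges <= prev
            prev = edges


class TestEnumeratePaths:
    def test_chain_gives_one_2hop(self):
        g = _graph({("S1", "I1"): 2, ("I1", "O"): 2})
        ps = enumerate_paths(g, PathQuery({"S1"}, "O"), ANN)
        assert [p.nodes for p in ps.paths] == [("S1", "I1", "O")]
        assert ps.by_hops(1) == []

    def test_threshold_prunes_path(self):
        g = _graph({("S1", "I1"): 2, ("I1", "O"): 1})
        ps = enumerate_paths(g, PathQuery({"S1"}, "O", threshold=2), ANN)
        assert len(ps) == 0

    def test_sensory_never_intermediate(self):
        g = _graph({("S1", "S2"): 5, ("S2", "O"): 5})
        ps = enumerate_paths(g, PathQuery({"S1", "S2"}, "O"), ANN)
        assert [p.nodes for p in ps.paths] == [("S2", "O")]

    def test_3hop_structure_and_weights(self):
        g = _graph({("S1", "I1"): 3, ("I1", "I2"): 4, ("I2", "O"): 5})
        ps = enumerate_paths(g, PathQuery({"S1"}, "O"), ANN)
        (p,) = ps.paths
        assert p.nodes == ("S1", "I1", "I2", "O")
        assert p.weights == (3, 4, 5)
        assert p.interneurons == ("I1", "I2")

    def test_target_in_sources_rejected(self):
        with pytest.raises(SezconnError):
            PathQuery({"O"}, "O")

    def test_no_repeated_nodes(self):
        g = _graph({("S1", "I1"): 2, ("I1", "I1"): 9, ("I1", "O"): 2})
        ps = enumerate_paths(g, PathQuery({"S1"}, "O"), ANN)
        for p in ps.paths:
            assert len(set(p.nodes)) == len(p.nodes)

    def test_matches_exhaustive_dfs_on_random_graphs(self, rng):
        for _ in range(40):
            g, cmap = random_annotated_graph(rng, n_max=30)
            sensory = sorted(n for n, c in cmap.items() if c == "sensory")
            target = sorted(n for n, c in cmap.items() if c == "motor")[0]
            t = int(rng.integers(1, 4))
            query = PathQuery(frozenset(sensory), target, threshold=t, max_hops=3)
            got = {p.nodes for p in enumerate_paths(g, query, cmap).paths}
            want = dfs_paths(g, sensory, target, t, 3, cmap)
            assert got == want

    def test_unrestricted_3hop_is_superset(self, rng):
        for _ in range(10):
            g, cmap = random_annotated_graph(rng, n_max=25)
            sensory = sorted(n for n, c in cmap.items() if c == "sensory")
            target = sorted(n for n, c in cmap.items() if c == "motor")[0]
            query = PathQuery(frozenset(sensory), target, threshold=2)
            restricted = {p.nodes for p in enumerate_paths(g, query, cmap).paths}
            free = {p.nodes for p in
                    enumerate_paths(g, query, cmap, restrict_3hop=False).paths}
            assert restricted <= free

    def test_raising_threshold_never_adds_paths(self, rng):
        g, cmap = random_annotated_graph(rng, n_max=30)
        sensory = sorted(n for n, c in cmap.items() if c == "sensory")
        target = sorted(n for n, c in cmap.items() if c == "motor")[0]
        prev = None
        for t in (1, 2, 3, 4):
            got = {p.nodes for p in enumerate_paths(
                g, PathQuery(frozenset(sensory), target, threshold=t), cmap).paths}
            if prev is not None:
                assert got <= prev
            prev = got


class TestLayers:
    def test_direct_interneuron_is_l2(self):
        g = _graph({("S1", "I1"): 2, ("I1", "O"): 2})
        layers = assign_layers(g, {"S1", "S2", "S3"}, "O", 2, ANN)
        assert layers.layer("I1") == "L2"

    def test_l3b_without_sensory_input(self):
        g = _graph({("S1", "I1"): 1, ("I1", "I2"): 2, ("I2", "O"): 2,
                    ("S1", "I2"): 2})
        layers = assign_layers(g, {"S1", "S2", "S3"}, "O", 2, ANN)
        assert layers.layer("I2") == "L2"
        assert layers.layer("I1") == "L3b"  # sensory edge below threshold

    def test_l3a_with_sensory_input(self):
        g = _graph({("S1", "I2"): 2, ("I2", "O"): 2, ("I1", "I2"): 2,
                    ("S2", "I1"): 2})
        layers = assign_layers(g, {"S1", "S2", "S3"}, "O", 2, ANN)
        assert layers.layer("I1") == "L3a"

    def test_l1_sources_and_output_labelled(self):
        g = _graph({("S1", "O"): 2, ("S2", "O"): 1})
        layers = assign_layers(g, {"S1", "S2"}, "O", 2, ANN)
        assert layers.layer("S1") == "L1-source"
        assert layers.layer("S2") == ""
        assert layers.layer("O") == "output"

    def test_partition_properties_on_random_graphs(self, rng):
        for _ in range(20):
            g, cmap = random_annotated_graph(rng, n_max=30)
            sensory = {n for n, c in cmap.items() if c == "sensory"}
            target = sorted(n for n, c in cmap.items() if c == "motor")[0]
            layers = assign_layers(g, sensory, target, 2, cmap)
            l2, l3a, l3b = (layers.members(k) for k in ("L2", "L3a", "L3b"))
            assert not (l3a & l3b)
            assert not (l2 & (l3a | l3b))
            # every L2 member is on >= 1 valid 2-hop path
            ps = enumerate_paths(g, PathQuery(frozenset(sensory), target, 2), cmap)
            on_2hop = {p.nodes[1] for p in ps.by_hops(2)}
            assert l2 == on_2hop
            # set-algebra oracle for L3
            tg = threshold_graph(g, 2)
            u1 = {p for p in tg.predecessors(target)
                  if cmap[p] not in ("sensory", "motor", "neurosecretory",
                                     "serotonergic") and p != target}
            expect_l3 = set()
            for i2 in u1:
                for i1 in tg.predecessors(i2):
                    if i1 != i2 and i1 not in l2 and i1 != target and \
                            cmap[i1] not in ("sensory", "motor", "neurosecretory",
                                             "serotonergic"):
                        expect_l3.add(i1)
            assert (l3a | l3b) == expect_l3
            for i in expect_l3:
                has_sens = any(s in sensory for s in tg.predecessors(i))
                assert (i in l3a) == has_sens


class TestConvergenceDivergence:
    def test_two_sources_one_interneuron(self):
        g = _graph({("S1", "I1"): 2, ("S2", "I1"): 2, ("I1", "O"): 2})
        ps = enumerate_paths(g, PathQuery({"S1", "S2"}, "O"), ANN)
        rep = convergence_divergence(ps)
        assert rep.degree == {"I1": 2}
        assert rep.divergence == {"S1": 1, "S2": 1}

    def test_one_source_three_routes(self):
        g = _graph({("S1", "I1"): 2, ("S1", "I2"): 2, ("S1", "I3"): 2,
                    ("I1", "O"): 2, ("I2", "O"): 2, ("I3", "O"): 2})
        ps = enumerate_paths(g, PathQuery({"S1"}, "O"), ANN)
        rep = convergence_divergence(ps)
        assert rep.divergence == {"S1": 3}

    def test_degree_sum_equals_distinct_pairs(self, rng):
        g, cmap = random_annotated_graph(rng, n_max=30)
        sensory = sorted(n for n, c in cmap.items() if c == "sensory")
        target = sorted(n for n, c in cmap.items() if c == "motor")[0]
        ps = enumerate_paths(g, PathQuery(frozenset(sensory), target, 2), cmap)
        rep = convergence_divergence(ps)
        pairs = {(p.source, p.nodes[1]) for p in ps.by_hops(2)}
        assert sum(rep.degree.values()) == len(pairs)
        assert sum(rep.divergence.values()) == len(pairs)


class TestCommonInterneurons:
    def test_reported_at_threshold(self):
        g = _graph({("M", "I1"): 2, ("I1", "O"): 2})
        table = common_interneurons(g, ANN, {"M"}, {"O"}, threshold=2)
        assert list(table["interneuron"]) == ["I1"]

    def test_below_threshold_not_reported(self):
        g = _graph({("M", "I1"): 1, ("I1", "O"): 2})
        table = common_interneurons(g, ANN, {"M"}, {"O"}, threshold=2)
        assert table.empty

    def test_double_filter_oracle(self, rng):
        for _ in range(10):
            g, cmap = random_annotated_graph(rng, n_max=25)
            ups = {n for n, c in cmap.items() if c == "PN"}
            outs = {n for n, c in cmap.items() if c == "motor"}
            if not ups or not outs:
                continue
            table = common_interneurons(g, cmap, ups, outs, threshold=2)
            got = set(zip(table["interneuron"], table["output"]))
            tg = threshold_graph(g, 2)
            want = {
                (i, o)
                for o in outs
                for i in tg.predecessors(o)
                if i not in ups and i not in outs
                and any(m in ups for m in tg.predecessors(i))
            }
            assert got == want


class TestFractionConnected:
    ASSIGN = {f"s{i}": "ACa" for i in range(10)}

    def test_nine_of_ten_monosynaptic(self):
        weights = {(f"s{i}", "O"): 2 for i in range(9)}
        weights[("s9", "X")] = 2
        g = _graph(weights)
        ann = {**{f"s{i}": "sensory" for i in range(10)}, "O": "motor",
               "X": "interneuron"}
        out = fraction_neurons_connected(self.ASSIGN, g, "monosynaptic-to-outputs",
                                         threshold=2, annotations=ann)
        assert out["ACa"] == pytest.approx(90.0)

    def test_threshold_above_all_weights_gives_zero(self):
        g = _graph({(f"s{i}", "O"): 1 for i in range(10)})
        ann = {**{f"s{i}": "sensory" for i in range(10)}, "O": "motor"}
        out = fraction_neurons_connected(self.ASSIGN, g, "monosynaptic-to-outputs",
                                         threshold=2, annotations=ann)
        assert out["ACa"] == 0.0

    def test_intra_compartment_either_direction(self):
        assign = {"a": 1, "b": 1, "c": 1}
        g = _graph({("a", "b"): 2})
        out = fraction_neurons_connected(assign, g, "intra-compartment-sensory",
                                         threshold=2)
        assert out[1] == pytest.approx(100.0 * 2 / 3)  # a and b qualify, c not

    def test_per_member_scan_oracle(self, rng):
        g, cmap = random_annotated_graph(rng, n_max=25)
        sensory = sorted(n for n, c in cmap.items() if c == "sensory")
        assign = {n: int(rng.integers(2)) for n in sensory}
        out = fraction_neurons_connected(assign, g, "monosynaptic-to-outputs",
                                         threshold=2, annotations=cmap)
        tg = threshold_graph(g, 2)
        outputs = {n for n, c in cmap.items()
                   if c in ("motor", "neurosecretory", "serotonergic")}
        for comp, pct in out.items():
            members = [n for n, c in assign.items() if c == comp]
            hit = sum(any(p in outputs for p in tg.successors(m)) for m in members)
            assert pct == pytest.approx(100.0 * hit / len(members))
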