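"""Synthetic-data generators: determinism, planted structure, invariants."""

from scipy.stats import ks_2samp

from sezconn.io import write_swc
from sezconn.model import build_graph, validate_skeleton
from sezconn.paths import PathQuery, assign_layers, enumerate_paths
from sezconn.simulate import (CircuitSpec, CompartmentSpec, SkeletonSpec,
                              generate_compartment_dataset,
                              generate_reflex_connectome, generate_skeletons)
from sezconn.synapses import (SynapseSimParams, clouds_from_connectors,
                              synapse_similarity)


def _swc_bytes(neurons):
    chunks = []
    for n in neurons:
        lines = ["# id type x y z radius parent"]
        for nd in n.skeleton:
            p = nd.position
            parent = -1 if nd.parent_id is None else nd.parent_id
            lines.append(f"{nd.node_id} {nd.structure} {p[0]:.17g} {p[1]:.17g} "
                         f"{p[2]:.17g} {nd.radius:.17g} {parent}")
        chunks.append("\n".join(lines))
    return "\n".join(chunks)


class TestSkeletons:
    def test_same_seed_is_byte_identical(self, tmp_path):
        spec = SkeletonSpec(n_neurons=3, n_nodes=30, branch_prob=0.2)
        a = generate_skeletons(spec, seed=11)
        b = generate_skeletons(spec, seed=11)
        f1, f2 = tmp_path / "a.swc", tmp_path / "b.swc"
        write_swc(f1, a[0].skeleton)
        write_swc(f2, b[0].skeleton)
        assert f1.read_bytes() == f2.read_bytes()
        assert _swc_bytes(a) == _swc_bytes(b)

    def test_zero_branch_prob_gives_chains(self):
        spec = SkeletonSpec(n_neurons=2, n_nodes=25, branch_prob=0.0)
        for neuron in generate_skeletons(spec, seed=3):
            children = {}
            for nd in neuron.skeleton:
                if nd.parent_id is not None:
                    children[nd.parent_id] = children.get(nd.parent_id, 0) + 1
            assert all(c == 1 for c in children.values())

    def test_node_count_and_validity(self):
        spec = SkeletonSpec(n_neurons=4, n_nodes=37, branch_prob=0.3)
        for neuron in generate_skeletons(spec, seed=5):
            assert len(neuron.skeleton) == 37
            assert validate_skeleton(neuron).valid


class TestCompartmentDataset:
    def test_planted_structure_recovered_by_similarity(self):
        from sklearn.metrics import adjusted_rand_score

        from sezconn.clustering import (average_linkage, cut_dendrogram,
                                        similarity_to_distance)
        from sezconn.synapses import synapse_similarity_matrix

        spec = CompartmentSpec(k=7, centroid_sep_nm=20000.0, spread_nm=1000.0,
                               neurons_per_cluster=4)
        bundle, planted = generate_compartment_dataset(spec, seed=42)
        clouds = clouds_from_connectors(bundle.connectors,
                                        neuron_ids=list(planted))
        matrix = synapse_similarity_matrix(clouds, SynapseSimParams())
        labels, dist = similarity_to_distance(matrix)
        assignment = cut_dendrogram(average_linkage(dist, labels), 0.06)
        assert assignment.n_clusters == 7
        found = [assignment.mapping[n] for n in labels]
        want = [planted[n] for n in labels]
        assert adjusted_rand_score(want, found) == 1.0

    def test_k1_all_similarities_above_half(self):
        spec = CompartmentSpec(k=1, spread_nm=1000.0, neurons_per_cluster=5)
        bundle, planted = generate_compartment_dataset(spec, seed=7)
        clouds = clouds_from_connectors(bundle.connectors, neuron_ids=list(planted))
        ids = sorted(clouds)
        for a in ids:
            for b in ids:
                if a != b:
                    assert synapse_similarity(clouds[a], clouds[b],
                                              SynapseSimParams()) > 0.5

    def test_huge_spread_erases_cluster_structure(self):
        """With spread >> separation, intra- and inter-cluster similarity
        distributions become statistically indistinguishable."""
        spec = CompartmentSpec(k=2, centroid_sep_nm=20000.0, spread_nm=1e9,
                               neurons_per_cluster=8)
        bundle, planted = generate_compartment_dataset(spec, seed=1)
        clouds = clouds_from_connectors(bundle.connectors, neuron_ids=list(planted))
        ids = sorted(clouds)
        intra, inter = [], []
        for i, a in enumerate(ids):
            for b in ids[i + 1:]:
                s = synapse_similarity(clouds[a], clouds[b], SynapseSimParams())
                (intra if planted[a] == planted[b] else inter).append(s)
        assert ks_2samp(intra, inter).pvalue > 0.01

    def test_bundle_determinism_and_validity(self):
        spec = CompartmentSpec(k=3, neurons_per_cluster=3)
        b1, l1 = generate_compartment_dataset(spec, seed=9)
        b2, l2 = generate_compartment_dataset(spec, seed=9)
        assert l1 == l2
        g1, g2 = build_graph(b1.connectors), build_graph(b2.connectors)
        assert g1 == g2
        assert b1.provenance["min_centroid_separation_nm"] == 20000.0
        assert not b1.unresolved_connector_neurons()


class TestReflexConnectome:
    def test_no_l2_l3_wiring_means_only_1hop(self):
        spec = CircuitSpec(p_l2=0.0, p_l3=0.0, p_mono=0.5, seed=4)
        bundle, truth = generate_reflex_connectome(spec)
        graph = build_graph(bundle.connectors)
        ann = bundle.annotations
        sensory = sorted(ann.index[ann["class"] == "sensory"])
        for o, t in truth["per_output"].items():
            assert t["paths"][2] == set() and t["paths"][3] == set()
            ps = enumerate_paths(graph, PathQuery(frozenset(sensory), o, 2), ann)
            assert all(p.hops == 1 for p in ps.paths)
            layers = assign_layers(graph, sensory, o, 2, ann)
            assert layers.members("L2") == set()
            assert layers.members("L3a") | layers.members("L3b") == set()

    def test_p_mono_zero_no_monosynaptic_fraction(self):
        from sezconn.paths import fraction_neurons_connected

        spec = CircuitSpec(p_mono=0.0, seed=8)
        bundle, truth = generate_reflex_connectome(spec)
        assert truth["l1_edges"] == set()
        graph = build_graph(bundle.connectors)
        ann = bundle.annotations
        sensory = sorted(ann.index[ann["class"] == "sensory"])
        assign = {s: "all" for s in sensory}
        out = fraction_neurons_connected(assign, graph, "monosynaptic-to-outputs",
                                         threshold=1, annotations=ann)
        assert out["all"] == 0.0

    def test_planted_inventory_recovered(self):
        for seed in range(5):
            spec = CircuitSpec(seed=seed)
            bundle, truth = generate_reflex_connectome(spec)
            graph = build_graph(bundle.connectors)
            ann = bundle.annotations
            sensory = sorted(ann.index[ann["class"] == "sensory"])
            for o, t in truth["per_output"].items():
                ps = enumerate_paths(graph, PathQuery(frozenset(sensory), o, 2), ann)
                for h in (1, 2, 3):
                    assert {p.nodes for p in ps.by_hops(h)} == t["paths"][h]
                layers = assign_layers(graph, sensory, o, 2, ann)
                assert layers.members("L2") == t["L2"]
                assert layers.members("L3a") == t["L3a"]
                assert layers.members("L3b") == t["L3b"]

    def test_connector_conservation(self):
        bundle, _ = generate_reflex_connectome(CircuitSpec(seed=2))
        g = build_graph(bundle.connectors)
        assert g.total_weight() == sum(len(c.posts) for c in bundle.connectors)
        assert max(len(c.posts) for c in bundle.connectors) <= 3
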