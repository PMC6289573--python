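"""Thresholded connectivity metrics and multi-hop layered path analysis.

Monosynaptic (1-hop) reflex connections run directly from sensory neurons to
output neurons (motor, neurosecretory, serotonergic). Polysynaptic routes add
one (2-hop) or two (3-hop) interneurons. All analyses apply a per-edge
synapse-count threshold (default 2); paths are simple (no repeated neurons)
and intermediates are never sensory or output-class neurons. Layers classify
the interneurons around one output: L2 are directly presynaptic to it and
reachable from a source in one hop; L3 sit one step further upstream and are
split into L3a (receive monosynaptic sensory input at threshold) and L3b
(do not).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import pandas as pd

from .errors import SezconnError
from .model import DEFAULT_OUTPUT_CLASSES, ConnectomeGraph, class_map


@dataclass(frozen=True)
class PathQuery:
    """Sources, one target, per-edge synapse threshold, and max hop count."""

    sources: frozenset
    target: object
    threshold: int = 2
    max_hops: int = 3

    def __post_init__(self):
        object.__setattr__(self, "sources", frozenset(self.sources))
        if self.threshold < 1:
            raise SezconnError("threshold must be >= 1")
        if not 1 <= self.max_hops <= 3:
            raise SezconnError("max_hops must be 1, 2 or 3")
        if self.target in self.sources:
            raise SezconnError("target must not be one of the sources")


@dataclass(frozen=True)
class Path:
    """One source -> ... -> target route with its per-edge synapse counts."""

    nodes: tuple
    weights: tuple

    def __post_init__(self):
        if len(self.weights) != len(self.nodes) - 1:
            raise SezconnError("need one weight per edge")

    @property
    def hops(self) -> int:
        return len(self.nodes) - 1

    @property
    def source(self):
        return self.nodes[0]

    @property
    def target(self):
        return self.nodes[-1]

    @property
    def interneurons(self) -> tuple:
        return self.nodes[1:-1]


@dataclass
class PathSet:
    """All valid paths for one query, grouped on demand by hop count."""

    query: PathQuery
    paths: list = field(default_factory=list)

    def by_hops(self, h: int) -> list:
        return [p for p in self.paths if p.hops == h]

    def __len__(self) -> int:
        return len(self.paths)


@dataclass
class LayerAssignment:
    """neuron id -> layer in {L1-source, L2, L3a, L3b, output}."""

    mapping: dict
    target: object
    threshold: int

    def layer(self, neuron) -> str:
        return self.mapping.get(neuron, "")

    def members(self, layer: str) -> set:
        return {n for n, lab in self.mapping.items() if lab == layer}


@dataclass
class ConvergenceReport:
    """2-hop route sharing around one target.

    degree: interneuron -> number of distinct sources routing through it.
    divergence: source -> number of distinct interneuron routes it uses.
    """

    target: object
    degree: dict
    divergence: dict


# ---------------------------------------------------------------------------


def percent_synaptic_connections(graph: ConnectomeGraph, neuron, partner_set,
                                 direction: str) -> float:
    """Percentage of a neuron's in- or outgoing synaptic connections with a partner set.

    Polyadic expansion counts each postsynaptic site. Returns NaN when the
    neuron has no connections in the requested direction.
    """
    if neuron not in graph:
        raise SezconnError(f"neuron {neuron!r} not in graph")
    if direction not in ("incoming", "outgoing"):
        raise SezconnError("direction must be 'incoming' or 'outgoing'")
    partners = (
        graph.predecessors(neuron) if direction == "incoming"
        else graph.successors(neuron)
    )
    total = sum(partners.values())
    if total == 0:
        return float("nan")
    hit = sum(w for p, w in partners.items() if p in set(partner_set))
    return 100.0 * hit / total


def ranking_index(graph: ConnectomeGraph, src, tgt) -> float:
    """Synapse count of src->tgt relative to the target's strongest input.

    1.0 marks the strongest of all incoming connections of the target.
    """
    incoming = graph.predecessors(tgt)
    if not incoming:
        raise SezconnError(f"neuron {tgt!r} has no incoming connections")
    w = incoming.get(src)
    if not w:
        raise SezconnError(f"no edge {src!r}->{tgt!r}")
    return w / max(incoming.values())


def threshold_graph(graph: ConnectomeGraph, t: int) -> ConnectomeGraph:
    """Drop edges below t synapses; all nodes are retained."""
    if t < 1:
        raise SezconnError("threshold must be >= 1")
    g = ConnectomeGraph(metadata=graph.metadata)
    for n in graph.nodes:
        g.add_node(n)
    for src, dst, w in graph.edges():
        if w >= t:
            g.add_edge(src, dst, w)
    return g


def _interneuron_test(cmap, query_sources, target, output_classes):
    def is_inter(n):
        c = cmap.get(n)
        return (
            c is not None
            and c != "sensory"
            and c not in output_classes
            and n not in query_sources
            and n != target
        )

    return is_inter


def enumerate_paths(graph: ConnectomeGraph, query: PathQuery, annotations,
                    restrict_3hop: bool = True,
                    output_classes=DEFAULT_OUTPUT_CLASSES) -> PathSet:
    """Enumerate all threshold-valid 1/2/3-hop paths from sources to the target.

    Every edge must carry >= query.threshold synapses; intermediates must be
    interneuron-class (neither sensory nor output-class) and paths never
    repeat a neuron. 3-hop paths run source -> I1 -> I2 -> target with I2 in
    the target's direct-upstream interneuron set; because the threshold
    applies per edge, the ``restrict_3hop`` frontier restriction is implied
    by path validity (disabling it cannot remove paths).
    """
    cmap = class_map(annotations)
    g = threshold_graph(graph, query.threshold)
    is_inter = _interneuron_test(cmap, query.sources, query.target, output_classes)
    tgt = query.target
    sources = sorted(query.sources, key=str)
    paths = []

    for s in sources:
        w = g.weight(s, tgt)
        if w and s != tgt:
            paths.append(Path((s, tgt), (w,)))

    u1 = sorted((p for p in g.predecessors(tgt) if is_inter(p)), key=str)
    if query.max_hops >= 2:
        for i in u1:
            w_it = g.weight(i, tgt)
            for s in sources:
                w_si = g.weight(s, i)
                if w_si:
                    paths.append(Path((s, i, tgt), (w_si, w_it)))
    if query.max_hops >= 3:
        frontier = u1 if restrict_3hop else [
            p for p in sorted(g.predecessors(tgt), key=str) if is_inter(p)
        ]
        for i2 in frontier:
            w_2t = g.weight(i2, tgt)
            for i1 in sorted(g.predecessors(i2), key=str):
                if i1 == i2 or not is_inter(i1):
                    continue
                w_12 = g.weight(i1, i2)
                for s in sources:
                    w_s1 = g.weight(s, i1)
                    if w_s1:
                        paths.append(Path((s, i1, i2, tgt), (w_s1, w_12, w_2t)))
    return PathSet(query, paths)


def assign_layers(graph: ConnectomeGraph, sensory_set, target, threshold: int,
                  annotations, output_classes=DEFAULT_OUTPUT_CLASSES) -> LayerAssignment:
    """Classify neurons around one output into L1-source/L2/L3a/L3b/output.

    L2: interneurons directly presynaptic to the target (>= threshold) that
    also receive >= threshold synapses from a sensory source (i.e. appear on
    a valid 2-hop path). L3: interneurons feeding a direct-upstream
    interneuron of the target (>= threshold) that are not L2; L3a receive
    monosynaptic sensory input at threshold, L3b do not. L1-source: sensory
    neurons with a direct >= threshold edge onto the target.
    """
    cmap = class_map(annotations)
    sensory_set = set(sensory_set)
    g = threshold_graph(graph, threshold)
    is_inter = _interneuron_test(cmap, sensory_set, target, output_classes)

    u1 = {p for p in g.predecessors(target) if is_inter(p)}
    has_sensory_input = lambda n: any(s in sensory_set for s in g.predecessors(n))
    l2 = {i for i in u1 if has_sensory_input(i)}
    l3 = set()
    for i2 in u1:
        for i1 in g.predecessors(i2):
            if i1 != i2 and is_inter(i1) and i1 not in l2:
                l3.add(i1)
    l3a = {i for i in l3 if has_sensory_input(i)}
    l3b = l3 - l3a

    mapping = {target: "output"}
    for s in sensory_set:
        if g.weight(s, target) > 0:
            mapping[s] = "L1-source"
    for i in l2:
        mapping[i] = "L2"
    for i in l3a:
        mapping[i] = "L3a"
    for i in l3b:
        mapping[i] = "L3b"
    return LayerAssignment(mapping, target, threshold)


def convergence_divergence(pathset: PathSet) -> ConvergenceReport:
    """Degree (sources per interneuron) and divergence (routes per source) on 2-hop paths."""
    pairs = {(p.source, p.nodes[1]) for p in pathset.by_hops(2)}
    degree: dict = {}
    divergence: dict = {}
    for s, i in pairs:
        degree[i] = degree.get(i, 0) + 1
        divergence[s] = divergence.get(s, 0) + 1
    return ConvergenceReport(pathset.query.target, degree, divergence)


def common_interneurons(graph: ConnectomeGraph, annotations, upstream_set,
                        output_set, threshold: int = 2,
                        output_classes=DEFAULT_OUTPUT_CLASSES) -> pd.DataFrame:
    """Interneurons bridging an upstream group (e.g. MBONs) to output neurons.

    Reports one row per (interneuron, output) pair where some upstream member
    contacts the interneuron at >= threshold and the interneuron contacts the
    output at >= threshold; each row carries the interneuron's layer with
    respect to that output (sensory set taken from the class annotations).
    """
    upstream_set = set(upstream_set)
    output_set = set(output_set)
    if upstream_set & output_set:
        raise SezconnError("upstream and output sets must be disjoint")
    cmap = class_map(annotations)
    sensory = {n for n, c in cmap.items() if c == "sensory"}
    g = threshold_graph(graph, threshold)
    rows = []
    layer_cache: dict = {}
    for out in sorted(output_set, key=str):
        for i in sorted(g.predecessors(out), key=str):
            if i in upstream_set or i in output_set:
                continue
            ups = sorted(
                (m for m in g.predecessors(i) if m in upstream_set), key=str
            )
            if not ups:
                continue
            if out not in layer_cache:
                layer_cache[out] = assign_layers(
                    graph, sensory, out, threshold, annotations, output_classes
                )
            rows.append(
                {
                    "interneuron": i,
                    "output": out,
                    "n_upstream": len(ups),
                    "upstream": ",".join(str(u) for u in ups),
                    "layer": layer_cache[out].layer(i),
                }
            )
    return pd.DataFrame(rows, columns=["interneuron", "output", "n_upstream",
                                       "upstream", "layer"])


def fraction_neurons_connected(assignment, graph: ConnectomeGraph, relation: str,
                               threshold: int = 2, annotations=None,
                               output_classes=DEFAULT_OUTPUT_CLASSES) -> dict:
    """Per-compartment percentage of members with at least one qualifying edge.

    relation "monosynaptic-to-outputs": a member qualifies if it contacts any
    output-class neuron at >= threshold (requires annotations). relation
    "intra-compartment-sensory": a member qualifies if it has a >= threshold
    edge (either direction) with another member of its own compartment.
    Empty compartments are reported as NaN.
    """
    if relation not in ("monosynaptic-to-outputs", "intra-compartment-sensory"):
        raise SezconnError(f"unknown relation {relation!r}")
    mapping = assignment.mapping if hasattr(assignment, "mapping") else dict(assignment)
    g = threshold_graph(graph, threshold)
    members: dict = {}
    for nid, comp in mapping.items():
        members.setdefault(comp, []).append(nid)
    if relation == "monosynaptic-to-outputs":
        if annotations is None:
            raise SezconnError("annotations required for monosynaptic-to-outputs")
        cmap = class_map(annotations)
        outputs = {n for n, c in cmap.items() if c in output_classes}
    result = {}
    for comp, group in sorted(members.items(), key=lambda kv: str(kv[0])):
        if not group:
            result[comp] = float("nan")
            continue
        count = 0
        gset = set(group)
        for m in group:
            if m not in g:
                continue
            if relation == "monosynaptic-to-outputs":
                ok = any(p in outputs for p in g.successors(m))
            else:
                ok = any(p in gset for p in g.successors(m) if p != m) or any(
                    p in gset for p in g.predecessors(m) if p != m
                )
            count += bool(ok)
        result[comp] = 100.0 * count / len(group)
    return result
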