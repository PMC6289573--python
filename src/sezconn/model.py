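"""Core domain types for neuron-level connectomes built from polyadic synapses.

An EM-reconstructed chemical synapse ("connector") has one presynaptic site
and one or more postsynaptic sites. Following the convention used for
percentage-of-connections analyses, every postsynaptic neurite counts as one
synaptic connection, so a connector with m postsynaptic sites contributes m
units of edge weight to the directed neuron-level graph.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from .errors import SezconnError

#: Closed vocabulary of neuron classes.
CLASS_VOCAB = frozenset(
    {"sensory", "interneuron", "motor", "neurosecretory", "serotonergic", "MBON", "PN"}
)

#: Classes treated as circuit outputs in path/layer analyses (overridable per call).
DEFAULT_OUTPUT_CLASSES = frozenset({"motor", "neurosecretory", "serotonergic"})


@dataclass(frozen=True)
class SkeletonNode:
    """One treenode of a neuron skeleton; positions in nm."""

    node_id: int
    parent_id: Optional[int]  # None marks the root
    position: np.ndarray  # (3,) nm
    radius: float = -1.0
    structure: int = 0  # SWC structure id, preserved for round-trips

    def __post_init__(self):
        pos = np.asarray(self.position, dtype=float)
        if pos.shape != (3,) or not np.all(np.isfinite(pos)):
            raise SezconnError(
                f"node {self.node_id}: position must be a finite 3-vector"
            )
        object.__setattr__(self, "position", pos)


@dataclass
class Neuron:
    """A reconstructed neuron: identity, annotations, and skeleton tree."""

    neuron_id: object
    name: str = ""
    annotations: dict = field(default_factory=dict)
    skeleton: list = field(default_factory=list)  # list[SkeletonNode]

    def node_positions(self) -> np.ndarray:
        if not self.skeleton:
            return np.empty((0, 3))
        return np.vstack([n.position for n in self.skeleton])


@dataclass(frozen=True)
class Connector:
    """One polyadic synapse: a presynaptic site and >=1 postsynaptic sites.

    ``pre`` and each element of ``posts`` are ``(neuron_id, position_nm)``
    pairs; positions are 3-vectors in nm.
    """

    connector_id: object
    pre: tuple  # (neuron_id, (3,) position nm)
    posts: tuple  # tuple of (neuron_id, (3,) position nm), len >= 1

    def __post_init__(self):
        if len(self.posts) < 1:
            raise SezconnError(
                f"connector {self.connector_id}: posts must be non-empty"
            )


@dataclass
class SkeletonValidationReport:
    """Structural check of a skeleton: root count, cycles, orphans."""

    neuron_id: object
    n_nodes: int
    n_roots: int
    cycle_nodes: list
    orphan_nodes: list
    connected: bool

    @property
    def valid(self) -> bool:
        return (
            self.n_roots == 1
            and not self.cycle_nodes
            and not self.orphan_nodes
            and self.connected
        )


class ConnectomeGraph:
    """Directed neuron-level graph weighted by synaptic-connection counts.

    Edge weight (A, B) is the number of postsynaptic sites of B on connectors
    whose presynaptic neuron is A (polyadic expansion). Weights are positive
    integers; self-loops are retained if present in the connector data but are
    excluded from similarity scoring and never traversed by path enumeration.
    """

    def __init__(self, weights=None, nodes=(), metadata=None):
        self._succ: dict = {}
        self._pred: dict = {}
        self.metadata = dict(metadata or {})
        for n in nodes:
            self.add_node(n)
        if weights:
            for (src, dst), w in weights.items():
                self.add_edge(src, dst, w)

    # -- construction -----------------------------------------------------
    def add_node(self, n) -> None:
        self._succ.setdefault(n, {})
        self._pred.setdefault(n, {})

    def add_edge(self, src, dst, w=1) -> None:
        if w <= 0 or int(w) != w:
            raise SezconnError(f"edge {src}->{dst}: weight must be a positive integer")
        self.add_node(src)
        self.add_node(dst)
        self._succ[src][dst] = self._succ[src].get(dst, 0) + int(w)
        self._pred[dst][src] = self._pred[dst].get(src, 0) + int(w)

    # -- queries -----------------------------------------------------------
    @property
    def nodes(self) -> set:
        return set(self._succ)

    def weight(self, src, dst) -> int:
        return self._succ.get(src, {}).get(dst, 0)

    def successors(self, n) -> dict:
        return dict(self._succ.get(n, {}))

    def predecessors(self, n) -> dict:
        return dict(self._pred.get(n, {}))

    def edges(self):
        for src in self._succ:
            for dst, w in self._succ[src].items():
                yield src, dst, w

    def total_weight(self) -> int:
        return sum(w for _, _, w in self.edges())

    def out_weight(self, n) -> int:
        return sum(self._succ.get(n, {}).values())

    def in_weight(self, n) -> int:
        return sum(self._pred.get(n, {}).values())

    def __contains__(self, n) -> bool:
        return n in self._succ

    def __eq__(self, other) -> bool:
        if not isinstance(other, ConnectomeGraph):
            return NotImplemented
        return self._succ == other._succ and self.nodes == other.nodes

    def copy(self) -> "ConnectomeGraph":
        g = ConnectomeGraph(metadata=self.metadata)
        for n in self._succ:
            g.add_node(n)
        for src, dst, w in self.edges():
            g.add_edge(src, dst, w)
        return g

    def to_networkx(self):
        import networkx as nx

        g = nx.DiGraph(**self.metadata)
        g.add_nodes_from(sorted(self._succ, key=str))
        for src, dst, w in self.edges():
            g.add_edge(src, dst, weight=w)
        return g


# ---------------------------------------------------------------------------
# operations


def validate_skeleton(neuron: Neuron) -> SkeletonValidationReport:
    """Check that a skeleton is a single rooted tree.

    The report lists the root count, nodes on parent-pointer cycles, and
    orphan nodes (parent id absent from the node table). A skeleton is valid
    iff it has exactly one root, no cycles, no orphans, and every node's
    parent chain reaches that root.
    """
    nodes = neuron.skeleton
    if not nodes:
        raise SezconnError(f"neuron {neuron.neuron_id}: empty skeleton")
    ids = {n.node_id for n in nodes}
    if len(ids) != len(nodes):
        raise SezconnError(f"neuron {neuron.neuron_id}: duplicate node ids")
    parent = {n.node_id: n.parent_id for n in nodes}
    roots = [i for i, p in parent.items() if p is None]
    orphans = [i for i, p in parent.items() if p is not None and p not in ids]

    # Walk parent chains with memoised colouring to find cycles.
    state: dict = {}  # node -> "root" | "cycle" | "orphan"
    cycle_nodes = []
    for start in parent:
        if start in state:
            continue
        chain = []
        cur = start
        while True:
            if cur in state:
                outcome = state[cur]
                break
            chain.append(cur)
            p = parent[cur]
            if p is None:
                outcome = "root"
                break
            if p not in ids:
                outcome = "orphan"
                break
            if p in chain:
                outcome = "cycle"
                break
            cur = p
        for c in chain:
            state[c] = outcome
        if outcome == "cycle":
            cycle_nodes.extend(chain)

    connected = (
        len(roots) == 1
        and not orphans
        and all(state[i] == "root" for i in parent)
    )
    return SkeletonValidationReport(
        neuron_id=neuron.neuron_id,
        n_nodes=len(nodes),
        n_roots=len(roots),
        cycle_nodes=sorted(set(cycle_nodes), key=str),
        orphan_nodes=sorted(orphans, key=str),
        connected=connected,
    )


def build_graph(connectors: Iterable[Connector], metadata=None) -> ConnectomeGraph:
    """Expand a polyadic connector table into a directed weighted graph.

    Every postsynaptic site contributes one unit of weight to the edge from
    the connector's presynaptic neuron, so total edge weight equals the total
    post-site count of the table (conservation).
    """
    graph = ConnectomeGraph(metadata=metadata)
    seen = set()
    for c in connectors:
        if c.connector_id in seen:
            raise SezconnError(f"duplicate connector id {c.connector_id!r}")
        seen.add(c.connector_id)
        if not c.posts:
            raise SezconnError(f"connector {c.connector_id!r} has no postsynaptic sites")
        pre_id = c.pre[0]
        for post_id, _pos in c.posts:
            graph.add_edge(pre_id, post_id, 1)
    return graph


def class_map(annotations) -> dict:
    """Coerce annotations (mapping or DataFrame with a 'class' column) to id->class."""
    if isinstance(annotations, pd.DataFrame):
        if "class" not in annotations.columns:
            raise SezconnError("annotation table lacks a 'class' column")
        return annotations["class"].to_dict()
    return dict(annotations)


def class_to_class_summary(graph: ConnectomeGraph, annotations):
    """Synapse counts and per-source-class fractions for ordered class pairs.

    Returns ``(counts, fractions)`` DataFrames indexed by source class with
    target classes as columns. Counts partition the total edge weight;
    fractions in each row with at least one outgoing synapse sum to 1.
    """
    cmap = class_map(annotations)
    missing = sorted((n for n in graph.nodes if n not in cmap), key=str)
    if missing:
        raise SezconnError(f"unannotated node(s): {missing[:5]}")
    tallies: dict = {}
    for src, dst, w in graph.edges():
        key = (cmap[src], cmap[dst])
        tallies[key] = tallies.get(key, 0) + w
    classes = sorted({c for pair in tallies for c in pair} | set())
    counts = pd.DataFrame(0, index=classes, columns=classes, dtype=int)
    for (cs, cd), w in tallies.items():
        counts.loc[cs, cd] = w
    row_sums = counts.sum(axis=1)
    fractions = counts.div(row_sums.where(row_sums > 0), axis=0)
    return counts, fractions
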