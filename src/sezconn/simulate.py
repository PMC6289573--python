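"""Seeded generators for synthetic skeletons, compartment datasets, and reflex circuits.

These emulate the statistical structure the analyses assume: spatially
clustered per-compartment synapse clouds (for similarity clustering) and a
layered sensory -> interneuron -> output wiring motif with polyadic synapses
(for path/layer analysis). Ground-truth labels and path inventories are
computed at generation time with plain loops, independent of the analysis
modules, so recovery can be scored end to end. All generators are fully
deterministic given their seed.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import SezconnError
from .io import DatasetBundle
from .model import Connector, Neuron, SkeletonNode, build_graph, validate_skeleton

_ORIGINS = ("enteric", "pharyngeal", "internal")
_NERVES = ("AN", "MxN", "PaN", "NSN")


@dataclass(frozen=True)
class SkeletonSpec:
    """Biased-random-walk tree parameters (lengths in nm)."""

    n_neurons: int = 5
    n_nodes: int = 40
    step_nm: float = 1000.0
    branch_prob: float = 0.08
    direction_bias: float = 0.7
    origin_spread_nm: float = 20000.0

    def __post_init__(self):
        if self.n_neurons < 1 or self.n_nodes < 2:
            raise SezconnError("need >=1 neuron with >=2 nodes")
        if not 0.0 <= self.branch_prob <= 1.0:
            raise SezconnError("branch_prob must lie in [0, 1]")
        if self.step_nm <= 0:
            raise SezconnError("step_nm must be > 0")


@dataclass(frozen=True)
class CompartmentSpec:
    """Planted synapse-cloud clusters (K compartments, isotropic Gaussian clouds)."""

    k: int = 7
    centroid_sep_nm: float = 20000.0
    spread_nm: float = 1000.0
    neurons_per_cluster: int = 5
    synapses_per_neuron: tuple = (10, 20)  # inclusive integer range

    def __post_init__(self):
        if self.k < 1:
            raise SezconnError("k must be >= 1")
        if self.spread_nm <= 0 or self.centroid_sep_nm <= 0:
            raise SezconnError("spread and separation must be > 0")
        lo, hi = self.synapses_per_neuron
        if lo < 1 or hi < lo:
            raise SezconnError("synapses_per_neuron must be a range with lo >= 1")


@dataclass(frozen=True)
class CircuitSpec:
    """Layered reflex-circuit wiring probabilities and weight distribution."""

    n_sensory: int = 12
    n_inter: int = 15
    n_output: int = 3
    p_mono: float = 0.25  # direct sensory -> output edge probability
    p_l2: float = 0.20  # interneuron -> output edge probability
    p_l3: float = 0.12  # interneuron -> interneuron edge probability
    p_sensory_inter: float = 0.25  # sensory -> interneuron edge probability
    weight_geom_p: float = 0.45  # geometric synapse-count parameter (min 1)
    fanout_max: int = 3  # max postsynaptic sites per connector
    threshold: int = 2  # threshold at which ground truth is computed
    seed: int = 0

    def __post_init__(self):
        for p in (self.p_mono, self.p_l2, self.p_l3, self.p_sensory_inter):
            if not 0.0 <= p <= 1.0:
                raise SezconnError("probabilities must lie in [0, 1]")
        if min(self.n_sensory, self.n_inter, self.n_output) < 1:
            raise SezconnError("all neuron counts must be >= 1")
        if not 0.0 < self.weight_geom_p <= 1.0:
            raise SezconnError("weight_geom_p must lie in (0, 1]")
        if self.fanout_max < 1 or self.threshold < 1:
            raise SezconnError("fanout_max and threshold must be >= 1")


# ---------------------------------------------------------------------------
# skeletons


def _unit(v: np.ndarray) -> np.ndarray:
    n = np.linalg.norm(v)
    return v / n if n > 0 else np.array([1.0, 0.0, 0.0])


def _random_unit(rng) -> np.ndarray:
    return _unit(rng.normal(size=3))


def generate_skeletons(spec: SkeletonSpec, seed: int) -> list:
    """Random branched skeleton trees via a biased random walk.

    Each tip advances by step_nm along a direction blended between its
    heading and a fresh random direction; with probability branch_prob the
    current node also spawns a second tip. branch_prob = 0 yields unbranched
    chains. Exactly n_nodes nodes are produced per neuron.
    """
    rng = np.random.default_rng(seed)
    neurons = []
    for idx in range(spec.n_neurons):
        root_pos = rng.normal(scale=spec.origin_spread_nm, size=3)
        nodes = [SkeletonNode(1, None, root_pos)]
        tips = [(1, _random_unit(rng))]
        next_id = 2
        while len(nodes) < spec.n_nodes:
            tip_idx = int(rng.integers(len(tips)))
            parent_id, heading = tips[tip_idx]
            direction = _unit(
                spec.direction_bias * heading
                + (1.0 - spec.direction_bias) * _random_unit(rng)
            )
            parent_pos = nodes[parent_id - 1].position
            nodes.append(
                SkeletonNode(next_id, parent_id, parent_pos + spec.step_nm * direction)
            )
            tips[tip_idx] = (next_id, direction)
            if rng.random() < spec.branch_prob and len(nodes) < spec.n_nodes:
                tips.append((parent_id, _random_unit(rng)))
            next_id += 1
        neuron = Neuron(neuron_id=f"sk{idx}", name=f"sk{idx}", skeleton=nodes)
        report = validate_skeleton(neuron)
        if not report.valid:
            raise SezconnError("generator produced an invalid skeleton")
        neurons.append(neuron)
    return neurons


def _chain_skeleton(origin: np.ndarray, n_nodes: int = 3,
                    step: float = 1000.0) -> list:
    """Minimal straight-chain skeleton anchored at a point."""
    nodes = [SkeletonNode(1, None, np.asarray(origin, dtype=float))]
    for i in range(2, n_nodes + 1):
        nodes.append(
            SkeletonNode(i, i - 1, origin + np.array([step * (i - 1), 0.0, 0.0]))
        )
    return nodes


# ---------------------------------------------------------------------------
# compartment dataset


def _grid_centroids(k: int, sep: float) -> np.ndarray:
    """K centroids on a cubic lattice with pairwise distance >= sep."""
    side = int(np.ceil(k ** (1.0 / 3.0)))
    pts = list(itertools.product(range(side + 1), repeat=3))[:k]
    if len(pts) < k:
        raise SezconnError("could not place centroids")
    return np.asarray(pts, dtype=float) * sep


def generate_compartment_dataset(spec: CompartmentSpec, seed: int):
    """Planted-compartment dataset: per-neuron Gaussian synapse clouds.

    Each of K compartments gets a lattice centroid (pairwise separation >=
    centroid_sep_nm, recorded in provenance); each sensory neuron of the
    compartment places its presynaptic sites isotropically around that
    centroid with st. dev. spread_nm. Every site becomes one connector onto a
    shared relay interneuron (postsynaptic site jittered <= 200 nm). Returns
    (DatasetBundle, planted_labels).
    """
    rng = np.random.default_rng(seed)
    centroids = _grid_centroids(spec.k, spec.centroid_sep_nm)
    neurons: dict = {}
    connectors = []
    ann_rows = []
    labels = {}
    cid_counter = itertools.count(1)
    relays = [f"relay{r}" for r in range(max(2, spec.k // 2))]
    lo, hi = spec.synapses_per_neuron

    for c in range(spec.k):
        for m in range(spec.neurons_per_cluster):
            nid = f"s{c}_{m}"
            labels[nid] = c
            n_syn = int(rng.integers(lo, hi + 1))
            sites = rng.normal(loc=centroids[c], scale=spec.spread_nm,
                               size=(n_syn, 3))
            for s in range(n_syn):
                relay = relays[(c + m + s) % len(relays)]
                jitter = rng.normal(size=3)
                jitter = jitter / np.linalg.norm(jitter) * rng.uniform(0.0, 200.0)
                connectors.append(
                    Connector(
                        next(cid_counter),
                        (nid, sites[s].copy()),
                        ((relay, sites[s] + jitter),),
                    )
                )
            neurons[nid] = Neuron(
                neuron_id=nid, name=nid,
                skeleton=_chain_skeleton(centroids[c] + rng.normal(scale=spec.spread_nm, size=3)),
            )
            ann_rows.append(
                {
                    "neuron_id": nid,
                    "name": nid,
                    "class": "sensory",
                    "nerve": _NERVES[c % len(_NERVES)],
                    "bundle": f"bundle{c % 3}",
                    "origin": _ORIGINS[c % len(_ORIGINS)],
                    "side": "left" if m % 2 == 0 else "right",
                }
            )
    for r, relay in enumerate(relays):
        neurons[relay] = Neuron(
            neuron_id=relay, name=relay,
            skeleton=_chain_skeleton(np.array([0.0, 0.0, -(r + 1) * 5000.0])),
        )
        ann_rows.append(
            {
                "neuron_id": relay,
                "name": relay,
                "class": "interneuron",
                "nerve": "",
                "bundle": "",
                "origin": "",
                "side": "left",
            }
        )
    annotations = pd.DataFrame(ann_rows).set_index("neuron_id")
    bundle = DatasetBundle(
        neurons=neurons,
        connectors=connectors,
        annotations=annotations,
        provenance={
            "generator": "compartments",
            "seed": int(seed),
            "k": spec.k,
            "min_centroid_separation_nm": float(spec.centroid_sep_nm),
            "spread_nm": float(spec.spread_nm),
            "unit_scale_to_nm": 1.0,
        },
    )
    _validate_bundle(bundle)
    return bundle, labels


# ---------------------------------------------------------------------------
# reflex connectome


def generate_reflex_connectome(spec: CircuitSpec):
    """Layered sensory/interneuron/output circuit with polyadic connectors.

    Edges are sampled independently per ordered pair: sensory->output with
    p_mono, sensory->interneuron with p_sensory_inter, interneuron->output
    with p_l2, interneuron->interneuron with p_l3. Synapse counts are
    geometric (min 1), then materialized as connectors whose polyadic fan-out
    is uniform on 1..fanout_max. Ground-truth L1 edges, per-output
    L2/L3a/L3b memberships and the full valid 1/2/3-hop path inventory at
    ``spec.threshold`` are computed with plain loops at generation time.
    Returns (DatasetBundle, truth dict).
    """
    rng = np.random.default_rng(spec.seed)
    sensory = [f"S{i}" for i in range(spec.n_sensory)]
    inter = [f"I{i}" for i in range(spec.n_inter)]
    outputs = [f"O{i}" for i in range(spec.n_output)]
    out_classes = ("motor", "neurosecretory", "serotonergic")

    weights: dict = {}

    def sample_edges(srcs, dsts, p):
        for a in srcs:
            for b in dsts:
                if a != b and rng.random() < p:
                    weights[(a, b)] = int(rng.geometric(spec.weight_geom_p))

    sample_edges(sensory, outputs, spec.p_mono)
    sample_edges(sensory, inter, spec.p_sensory_inter)
    sample_edges(inter, outputs, spec.p_l2)
    sample_edges(inter, inter, spec.p_l3)

    # neuron home positions in a 100 um box
    all_ids = sensory + inter + outputs
    home = {n: rng.uniform(-50000.0, 50000.0, size=3) for n in all_ids}

    connectors = []
    cid_counter = itertools.count(1)
    for a in all_ids:
        demand = []
        for b in sorted(d for (s, d) in weights if s == a):
            demand.extend([b] * weights[(a, b)])
        rng.shuffle(demand)
        pos = 0
        while pos < len(demand):
            fanout = int(rng.integers(1, spec.fanout_max + 1))
            chunk = demand[pos:pos + fanout]
            pos += len(chunk)
            cpos = home[a] + rng.normal(scale=2000.0, size=3)
            posts = []
            for b in chunk:
                jitter = rng.normal(size=3)
                jitter = jitter / np.linalg.norm(jitter) * rng.uniform(0.0, 200.0)
                posts.append((b, cpos + jitter))
            connectors.append(Connector(next(cid_counter), (a, cpos.copy()), tuple(posts)))

    neurons = {
        n: Neuron(neuron_id=n, name=n, skeleton=_chain_skeleton(home[n]))
        for n in all_ids
    }
    ann_rows = []
    for n in sensory:
        ann_rows.append({"neuron_id": n, "name": n, "class": "sensory",
                         "nerve": _NERVES[int(n[1:]) % len(_NERVES)], "bundle": "b0",
                         "origin": _ORIGINS[int(n[1:]) % len(_ORIGINS)],
                         "side": "left"})
    for n in inter:
        ann_rows.append({"neuron_id": n, "name": n, "class": "interneuron",
                         "nerve": "", "bundle": "", "origin": "", "side": "left"})
    for k, n in enumerate(outputs):
        ann_rows.append({"neuron_id": n, "name": n,
                         "class": out_classes[k % len(out_classes)],
                         "nerve": "", "bundle": "", "origin": "", "side": "left"})
    annotations = pd.DataFrame(ann_rows).set_index("neuron_id")

    truth = _circuit_truth(weights, sensory, inter, outputs, spec.threshold)
    bundle = DatasetBundle(
        neurons=neurons,
        connectors=connectors,
        annotations=annotations,
        provenance={
            "generator": "reflex_connectome",
            "seed": int(spec.seed),
            "threshold": spec.threshold,
            "unit_scale_to_nm": 1.0,
        },
    )
    _validate_bundle(bundle)
    # conservation: materialized connectors must reproduce the sampled weights
    g = build_graph(bundle.connectors)
    for (a, b), w in weights.items():
        if g.weight(a, b) != w:
            raise SezconnError("connector materialization lost synapses")
    return bundle, truth


def _circuit_truth(weights, sensory, inter, outputs, t):
    """Generation-time bookkeeping: layer memberships and path inventory.

    Written as direct loops over the sampled weight table, independent of the
    analysis modules.
    """

    def w(a, b):
        return weights.get((a, b), 0)

    truth = {"l1_edges": set(), "per_output": {}}
    for s in sensory:
        for o in outputs:
            if w(s, o) >= t:
                truth["l1_edges"].add((s, o))
    for o in outputs:
        u1 = [i for i in inter if w(i, o) >= t]
        l2 = {i for i in u1 if any(w(s, i) >= t for s in sensory)}
        l3 = set()
        for i2 in u1:
            for i1 in inter:
                if i1 != i2 and w(i1, i2) >= t and i1 not in l2:
                    l3.add(i1)
        l3a = {i for i in l3 if any(w(s, i) >= t for s in sensory)}
        l3b = l3 - l3a
        paths = {1: set(), 2: set(), 3: set()}
        for s in sensory:
            if w(s, o) >= t:
                paths[1].add((s, o))
            for i in u1:
                if w(s, i) >= t:
                    paths[2].add((s, i, o))
            for i2 in u1:
                for i1 in inter:
                    if i1 != i2 and w(i1, i2) >= t and w(s, i1) >= t:
                        paths[3].add((s, i1, i2, o))
        truth["per_output"][o] = {
            "U1": set(u1),
            "L2": l2,
            "L3a": l3a,
            "L3b": l3b,
            "paths": paths,
        }
    return truth


def _validate_bundle(bundle: DatasetBundle) -> None:
    """Generated data must satisfy the core-model invariants."""
    for neuron in bundle.neurons.values():
        if neuron.skeleton and not validate_skeleton(neuron).valid:
            raise SezconnError(f"invalid generated skeleton {neuron.neuron_id}")
    g = build_graph(bundle.connectors)
    n_posts = sum(len(c.posts) for c in bundle.connectors)
    if g.total_weight() != n_posts:
        raise SezconnError("edge weight does not match post-site count")
    unresolved = bundle.unresolved_connector_neurons()
    if unresolved:
        raise SezconnError(f"connector references unknown neurons: {sorted(unresolved)[:5]}")
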