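"""Normalized connectivity similarity between neurons' synaptic partner vectors.

For two neurons i and j with adjacency rows/columns A_i., A_j., each shared
or unshared partner k contributes

    f(A_ik, A_jk) = min(A_ik, A_jk) - C1 * max(A_ik, A_jk) * exp(-C2 * min(A_ik, A_jk))

so matched strong connections score positively and one-sided connections are
punished in proportion to their strength. The summed score is normalized to
its minimal (-C1 * M) and maximal (M) achievable values, M = sum_k max(A_ik,
A_jk), giving a value in [0, 1]. Self-connections and the direct i<->j
connections are excluded; a pair with no remaining partners is undefined
(NaN). Defaults: C1 = 0.5, C2 = 1.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

from .clustering import SimilarityMatrix
from .errors import SezconnError
from .model import ConnectomeGraph

import numpy as np

DIRECTIONS = ("both", "in", "out")


@dataclass
class PartnerVector:
    """Synaptic partner counts of one neuron, split by direction."""

    neuron_id: object
    incoming: dict = field(default_factory=dict)  # partner -> count
    outgoing: dict = field(default_factory=dict)

    def __post_init__(self):
        for d in (self.incoming, self.outgoing):
            d.pop(self.neuron_id, None)  # no self-entries
            for k, v in d.items():
                if v < 0 or int(v) != v:
                    raise SezconnError(
                        f"partner count {self.neuron_id}->{k} must be a "
                        "non-negative integer"
                    )


@dataclass(frozen=True)
class ConnSimParams:
    """C1 weights the penalty for one-sided partners; C2 its decay with matched strength."""

    C1: float = 0.5
    C2: float = 1.0

    def __post_init__(self):
        if not 0.0 <= self.C1 <= 1.0:
            raise SezconnError("C1 must lie in [0, 1]")
        if self.C2 < 0:
            raise SezconnError("C2 must be >= 0")


def partner_vectors_from_graph(graph: ConnectomeGraph) -> dict:
    """One PartnerVector per graph node (self-loops dropped)."""
    return {
        n: PartnerVector(n, incoming=graph.predecessors(n), outgoing=graph.successors(n))
        for n in sorted(graph.nodes, key=str)
    }


def pair_term(a: int, b: int, params: ConnSimParams = ConnSimParams()) -> float:
    """Contribution of one partner: min - C1 * max * exp(-C2 * min)."""
    if a < 0 or b < 0:
        raise SezconnError("partner counts must be non-negative")
    lo, hi = (a, b) if a <= b else (b, a)
    return lo - params.C1 * hi * math.exp(-params.C2 * lo)


def connectivity_similarity(i: PartnerVector, j: PartnerVector,
                            params: ConnSimParams = ConnSimParams(),
                            direction: str = "both") -> float:
    """Normalized partner-vector similarity in [0, 1]; NaN if undefined.

    Partners are taken from the union of both vectors (tagged by direction
    when direction="both"); entries for i and j themselves are ignored. If no
    partner remains the score is undefined and NaN is returned.
    """
    if direction not in DIRECTIONS:
        raise SezconnError(f"unknown direction {direction!r}")
    if i.neuron_id == j.neuron_id:
        raise SezconnError("connectivity similarity of a neuron with itself is undefined")
    excluded = {i.neuron_id, j.neuron_id}

    def universe(attr):
        keys = set(getattr(i, attr)) | set(getattr(j, attr))
        return sorted((k for k in keys if k not in excluded), key=str)

    blocks = []
    if direction in ("both", "in"):
        blocks.append("incoming")
    if direction in ("both", "out"):
        blocks.append("outgoing")

    raw = 0.0
    max_sum = 0.0
    for attr in blocks:
        vi = getattr(i, attr)
        vj = getattr(j, attr)
        for k in universe(attr):
            a = vi.get(k, 0)
            b = vj.get(k, 0)
            if a == 0 and b == 0:
                continue
            raw += pair_term(a, b, params)
            max_sum += max(a, b)
    if max_sum == 0:
        return float("nan")
    return (raw + params.C1 * max_sum) / ((1.0 + params.C1) * max_sum)


def connectivity_similarity_matrix(graph: ConnectomeGraph,
                                   params: ConnSimParams = ConnSimParams(),
                                   direction: str = "both",
                                   labels=None) -> SimilarityMatrix:
    """All-pairs normalized connectivity similarity over graph nodes.

    The matrix is symmetric by construction; undefined pairs are NaN and the
    diagonal is fixed at 1.
    """
    vectors = partner_vectors_from_graph(graph)
    if labels is None:
        labels = sorted(graph.nodes, key=str)
    labels = list(labels)
    if len(labels) < 2:
        raise SezconnError("need at least 2 neurons")
    n = len(labels)
    m = np.ones((n, n))
    for a in range(n):
        for b in range(a + 1, n):
            s = connectivity_similarity(vectors[labels[a]], vectors[labels[b]],
                                        params, direction)
            m[a, b] = m[b, a] = s
    return SimilarityMatrix(labels, m, symmetric=True)
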