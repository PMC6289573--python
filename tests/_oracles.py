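"""Independent brute-force oracles used only by the tests.

Every oracle here re-derives a quantity with plain loops / O(n^2) scans,
deliberately avoiding the spatial indexes and library calls the package
itself uses, so implementation and check stay on separate routes.
"""

from __future__ import annotations

import math

import numpy as np


# ---------------------------------------------------------------------------
# morphology: brute-force nearest neighbour score


def brute_morphology_score(query_points, query_tangents, target_points,
                           target_tangents, sigma):
    terms = []
    for i in range(len(query_points)):
        best_d2, best_j = math.inf, -1
        for j in range(len(target_points)):
            d2 = float(np.sum((query_points[i] - target_points[j]) ** 2))
            if d2 < best_d2:  # strict < keeps the lowest index on ties
                best_d2, best_j = d2, j
        dot = abs(float(np.dot(query_tangents[i], target_tangents[best_j])))
        terms.append(min(dot, 1.0) * math.exp(-best_d2 / (2.0 * sigma ** 2)))
    return sum(terms) / len(terms)


# ---------------------------------------------------------------------------
# synapse similarity: per-site loops


def brute_synapse_similarity(pos_i, pol_i, pos_j, pol_j, sigma, omega,
                             unmatched="zero"):
    def density(positions, pols, idx):
        c = 0
        for m in range(len(positions)):
            if pols[m] == pols[idx] and np.linalg.norm(
                positions[m] - positions[idx]
            ) <= omega:
                c += 1
        return c

    terms = []
    for s in range(len(pos_i)):
        same = [k for k in range(len(pos_j)) if pol_j[k] == pol_i[s]]
        if not same:
            if unmatched == "zero":
                terms.append(0.0)
            continue
        best_d, best_k = math.inf, -1
        for k in same:
            d = float(np.linalg.norm(pos_i[s] - pos_j[k]))
            if d < best_d:
                best_d, best_k = d, k
        n_is = density(pos_i, pol_i, s)
        n_jk = density(pos_j, pol_j, best_k)
        terms.append(
            math.exp(-best_d ** 2 / (2.0 * sigma ** 2))
            * math.exp(-abs(n_is - n_jk) / (n_is + n_jk))
        )
    return sum(terms) / len(terms)


# ---------------------------------------------------------------------------
# connectivity: independent re-derivation


def brute_connectivity_similarity(in_i, out_i, in_j, out_j, i_id, j_id, c1, c2):
    raw = 0.0
    max_sum = 0.0
    for vi, vj in ((in_i, in_j), (out_i, out_j)):
        for k in sorted(set(vi) | set(vj), key=str):
            if k in (i_id, j_id):
                continue
            a, b = vi.get(k, 0), vj.get(k, 0)
            if a == 0 and b == 0:
                continue
            raw += min(a, b) - c1 * max(a, b) * math.exp(-c2 * min(a, b))
            max_sum += max(a, b)
    if max_sum == 0:
        return float("nan")
    return (raw + c1 * max_sum) / ((1 + c1) * max_sum)


# ---------------------------------------------------------------------------
# naive UPGMA -> cophenetic distance matrix


def naive_upgma_cophenetic(dist):
    """O(n^3) average-linkage; ties broken by lexicographically smallest pair."""
    dist = np.asarray(dist, dtype=float)
    n = dist.shape[0]
    members = {i: [i] for i in range(n)}
    d = {}
    for i in range(n):
        for j in range(i + 1, n):
            d[(i, j)] = dist[i, j]
    coph = np.zeros((n, n))
    next_id = n
    while len(members) > 1:
        # smallest distance; ties -> smallest (min leaf of a, min leaf of b)
        best = None
        for (a, b), val in d.items():
            key = (val, min(members[a]), min(members[b]))
            if best is None or key < best[0]:
                best = (key, a, b)
        (_val, _ma, _mb), a, b = best
        h = d[(a, b)]
        for i in members[a]:
            for j in members[b]:
                coph[i, j] = coph[j, i] = h
        merged = members[a] + members[b]
        na, nb = len(members[a]), len(members[b])
        new_d = {}
        for c in members:
            if c in (a, b):
                continue
            da = d[tuple(sorted((a, c)))]
            db = d[tuple(sorted((b, c)))]
            new_d[c] = (na * da + nb * db) / (na + nb)
        del members[a], members[b]
        d = {k: v for k, v in d.items() if a not in k and b not in k}
        for c, val in new_d.items():
            d[tuple(sorted((next_id, c)))] = val
        members[next_id] = merged
        next_id += 1
    return coph


# ---------------------------------------------------------------------------
# exhaustive DFS path enumeration


def dfs_paths(graph, sources, target, threshold, max_hops, cmap,
              output_classes=frozenset({"motor", "neurosecretory", "serotonergic"})):
    """All simple threshold-valid paths source -> interneurons... -> target."""
    adj = {
        u: {v: w for v, w in graph.successors(u).items() if w >= threshold and v != u}
        for u in graph.nodes
    }
    sources = set(sources)

    def is_inter(node):
        c = cmap.get(node)
        return (
            c is not None
            and c != "sensory"
            and c not in output_classes
            and node not in sources
            and node != target
        )

    found = set()

    def rec(node, path):
        for nxt in adj.get(node, {}):
            if nxt == target:
                found.add(tuple(path) + (target,))
            elif is_inter(nxt) and nxt not in path and len(path) < max_hops:
                rec(nxt, path + [nxt])

    for s in sorted(sources, key=str):
        if s != target:
            rec(s, [s])
    return found


# ---------------------------------------------------------------------------
# random annotated test graphs


def random_annotated_graph(rng, n_max=50, edge_prob=0.08, w_max=5):
    """Random directed weighted graph with class annotations for path tests."""
    from sezconn.model import ConnectomeGraph

    n = int(rng.integers(8, n_max + 1))
    ids = [f"n{i}" for i in range(n)]
    classes = ["sensory", "interneuron", "interneuron", "motor",
               "neurosecretory", "sensory", "interneuron", "PN"]
    cmap = {nid: classes[int(rng.integers(len(classes)))] for nid in ids}
    # guarantee the roles the queries need
    cmap[ids[0]] = "sensory"
    cmap[ids[1]] = "sensory"
    cmap[ids[-1]] = "motor"
    g = ConnectomeGraph()
    for nid in ids:
        g.add_node(nid)
    for a in ids:
        for b in ids:
            if a != b and rng.random() < edge_prob:
                g.add_edge(a, b, int(rng.integers(1, w_max + 1)))
    return g, cmap
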