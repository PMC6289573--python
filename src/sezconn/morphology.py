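"""Dotprops conversion and the Gaussian x |dot| morphology similarity score.

A skeleton is converted to "dotprops": resampled 3-D points, each with a unit
tangent vector fitted as the first principal direction of its k nearest
points. The similarity of a query neuron Q to a target neuron T is

    S(Q, T) = (1/n) * sum_i |q_i . t_j| * exp(-d_ij^2 / (2 sigma^2))

where j is the nearest target point to query point i, d_ij their distance,
q_i and t_j the unit tangents, and sigma (default 2 um) sets how close points
must be to count as similar. Tangent sign is arbitrary, hence the absolute
dot product. The raw score is asymmetric; clustering consumes the
symmetrized mean.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial import cKDTree

from ._spatial import nearest_lowest_index
from .clustering import SimilarityMatrix
from .errors import SezconnError
from .model import Neuron, validate_skeleton


@dataclass
class DotProps:
    """Point cloud with unit tangent vectors derived from a skeleton."""

    points: np.ndarray  # (n, 3) nm
    tangents: np.ndarray  # (n, 3) unit vectors
    k_neighbors: int
    source_neuron: object = None

    def __post_init__(self):
        self.points = np.atleast_2d(np.asarray(self.points, dtype=float))
        self.tangents = np.atleast_2d(np.asarray(self.tangents, dtype=float))
        if self.points.shape[0] < 1 or self.points.shape != self.tangents.shape:
            raise SezconnError("dotprops need >=1 point with matching tangents")
        if not np.all(np.isfinite(self.points)):
            raise SezconnError("dotprops points must be finite")
        norms = np.linalg.norm(self.tangents, axis=1)
        if np.any(np.abs(norms - 1.0) > 1e-9):
            raise SezconnError("tangent vectors must be unit length")

    @property
    def n(self) -> int:
        return self.points.shape[0]


@dataclass(frozen=True)
class MorphScoreParams:
    """sigma (nm) of the Gaussian distance kernel; default 2000 nm (2 um)."""

    sigma: float = 2000.0

    def __post_init__(self):
        if self.sigma <= 0:
            raise SezconnError("sigma must be > 0")


def _slab_paths(neuron: Neuron):
    """Decompose the skeleton into unbranched root/branch-to-branch/leaf runs."""
    nodes = {nd.node_id: nd for nd in neuron.skeleton}
    children: dict = {nid: [] for nid in nodes}
    root = None
    for nd in neuron.skeleton:
        if nd.parent_id is None:
            root = nd.node_id
        else:
            children[nd.parent_id].append(nd.node_id)
    for lst in children.values():
        lst.sort()
    starts = [root] + sorted(
        nid for nid, ch in children.items() if len(ch) >= 2 and nid != root
    )
    slabs = []
    for start in starts:
        for child in children[start]:
            slab = [start, child]
            cur = child
            while len(children[cur]) == 1:
                cur = children[cur][0]
                slab.append(cur)
            slabs.append([nodes[i].position for i in slab])
    return slabs


def _resample_polyline(points: np.ndarray, spacing: float) -> np.ndarray:
    """Evenly resample a polyline at ~spacing intervals, endpoints included."""
    points = np.asarray(points, dtype=float)
    seg = np.linalg.norm(np.diff(points, axis=0), axis=1)
    arc = np.concatenate([[0.0], np.cumsum(seg)])
    total = arc[-1]
    if total == 0:
        return points[:1]
    n_out = max(2, int(round(total / spacing)) + 1)
    s = np.linspace(0.0, total, n_out)
    return np.column_stack([np.interp(s, arc, points[:, d]) for d in range(3)])


def to_dotprops(neuron: Neuron, spacing: float = 1000.0, k: int = 5) -> DotProps:
    """Resample a skeleton and fit local tangents.

    Points are placed at ~``spacing`` nm intervals along each unbranched run
    of the skeleton; the tangent at each point is the first principal
    direction of its k nearest resampled points (sign is arbitrary and fixed
    deterministically).
    """
    if spacing <= 0:
        raise SezconnError("spacing must be > 0")
    if k < 2:
        raise SezconnError("k must be >= 2")
    report = validate_skeleton(neuron)
    if not report.valid:
        raise SezconnError(f"neuron {neuron.neuron_id}: invalid skeleton")
    if len(neuron.skeleton) < 2:
        raise SezconnError(
            f"neuron {neuron.neuron_id}: cannot derive a tangent from a "
            "single-node skeleton"
        )
    pts = []
    seen = set()
    for slab in _slab_paths(neuron):
        for p in _resample_polyline(np.asarray(slab), spacing):
            key = (float(p[0]), float(p[1]), float(p[2]))
            if key not in seen:
                seen.add(key)
                pts.append(p)
    points = np.asarray(pts)
    n = points.shape[0]
    k_eff = min(k, n)
    tree = cKDTree(points)
    _, idx = tree.query(points, k=k_eff)
    idx = np.atleast_2d(idx)
    tangents = np.empty_like(points)
    for i in range(n):
        nb = points[idx[i]]
        centred = nb - nb.mean(axis=0)
        cov = centred.T @ centred
        w, v = np.linalg.eigh(cov)
        t = v[:, -1]
        # fix the arbitrary sign deterministically
        for comp in t:
            if comp != 0:
                if comp < 0:
                    t = -t
                break
        nrm = np.linalg.norm(t)
        tangents[i] = t / nrm if nrm > 0 else np.array([1.0, 0.0, 0.0])
    return DotProps(points, tangents, k_neighbors=k, source_neuron=neuron.neuron_id)


def morphology_score(query: DotProps, target: DotProps,
                     params: MorphScoreParams = MorphScoreParams()) -> float:
    """Mean Gaussian-weighted absolute tangent alignment of query vs target.

    For each query point the nearest target point is found (ties to the
    lowest index); each term |q_i . t_j| * exp(-d^2 / 2 sigma^2) lies in
    [0, 1], as does their mean. Asymmetric in general.
    """
    if query.n == 0 or target.n == 0:
        raise SezconnError("cannot score empty dotprops")
    dist, j = nearest_lowest_index(target.points, query.points)
    dots = np.abs(np.einsum("ij,ij->i", query.tangents, target.tangents[j]))
    terms = np.clip(dots, 0.0, 1.0) * np.exp(-(dist ** 2) / (2.0 * params.sigma ** 2))
    return float(np.mean(terms))


def morphology_score_matrix(dotprops_list, params: MorphScoreParams = MorphScoreParams(),
                            symmetrize: bool = True) -> SimilarityMatrix:
    """All-pairs morphology scores; diagonal fixed at 1."""
    if len(dotprops_list) < 2:
        raise SezconnError("need at least 2 dotprops")
    n = len(dotprops_list)
    m = np.ones((n, n))
    for i in range(n):
        for j in range(n):
            if i != j:
                m[i, j] = morphology_score(dotprops_list[i], dotprops_list[j], params)
    if symmetrize:
        m = (m + m.T) / 2.0
    labels = [
        dp.source_neuron if dp.source_neuron is not None else i
        for i, dp in enumerate(dotprops_list)
    ]
    return SimilarityMatrix(labels, m, symmetric=symmetrize)
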