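"""Average-linkage clustering of similarity matrices and compartment summaries.

Sensory compartments are defined by hierarchically clustering a pairwise
similarity matrix (synapse placement, morphology, or connectivity) with
average linkage (UPGMA) and cutting the dendrogram at a fixed similarity
score. The default conversion from similarity s in [0, 1] to distance is
d = 1 - s, so a cut "at score c" stops merging where the mean inter-cluster
similarity falls below c (merges strictly below height 1 - c are applied).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import linkage
from scipy.spatial.distance import squareform

from .errors import SezconnError
from .model import class_map


@dataclass
class SimilarityMatrix:
    """Square pairwise-similarity matrix with neuron-id labels.

    Values lie in [0, 1]; undefined pairs are NaN. The diagonal is 1 by
    convention.
    """

    labels: list
    values: np.ndarray
    symmetric: bool = False

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        n = len(self.labels)
        if self.values.shape != (n, n):
            raise SezconnError(
                f"similarity matrix shape {self.values.shape} does not match "
                f"{n} labels"
            )
        finite = self.values[np.isfinite(self.values)]
        if finite.size and (finite.min() < -1e-12 or finite.max() > 1 + 1e-12):
            raise SezconnError("similarity values must lie in [0, 1]")

    def symmetrized(self) -> "SimilarityMatrix":
        vals = (self.values + self.values.T) / 2.0
        return SimilarityMatrix(list(self.labels), vals, symmetric=True)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.labels, columns=self.labels)

    @classmethod
    def from_frame(cls, df: pd.DataFrame, symmetric=None) -> "SimilarityMatrix":
        vals = df.to_numpy(dtype=float)
        if symmetric is None:
            symmetric = bool(np.allclose(vals, vals.T, equal_nan=True))
        return cls(list(df.index), vals, symmetric=symmetric)


@dataclass
class Dendrogram:
    """UPGMA merge tree: scipy linkage matrix plus leaf labels."""

    linkage: np.ndarray  # (n-1, 4) scipy linkage matrix; may be empty for n=1
    labels: list

    def __post_init__(self):
        self.linkage = np.asarray(self.linkage, dtype=float).reshape(-1, 4)
        n = len(self.labels)
        if n >= 2 and self.linkage.shape[0] != n - 1:
            raise SezconnError("linkage must have n-1 merges for n leaves")
        heights = self.linkage[:, 2]
        if heights.size and np.any(np.diff(heights) < -1e-12):
            raise SezconnError("merge heights must be non-decreasing")


@dataclass
class ClusterAssignment:
    """Flat clustering: neuron id -> integer cluster label (1..K).

    Labels are canonical: clusters are numbered by their smallest member id,
    so the assignment is invariant to leaf input order.
    """

    mapping: dict
    score_cut: float
    convention: str = "one-minus"

    @property
    def n_clusters(self) -> int:
        return len(set(self.mapping.values()))

    def members(self) -> dict:
        out: dict = {}
        for nid, lab in self.mapping.items():
            out.setdefault(lab, []).append(nid)
        return {lab: sorted(v, key=str) for lab, v in out.items()}


def similarity_to_distance(matrix: SimilarityMatrix, symmetrize: bool = False,
                           convention: str = "one-minus"):
    """Convert a similarity matrix to a distance matrix.

    Default convention is d = 1 - s (diagonal 0). The alternative "neg"
    convention uses d = -s. Missing (NaN) similarities map to the maximal
    distance with a warning. Asymmetric input is an error unless
    ``symmetrize`` is set, in which case the elementwise mean is used.
    """
    if convention not in ("one-minus", "neg"):
        raise SezconnError(f"unknown distance convention {convention!r}")
    vals = matrix.values
    if not np.allclose(vals, vals.T, equal_nan=True, atol=1e-12):
        if not symmetrize:
            raise SezconnError(
                "asymmetric similarity matrix: pass symmetrize=True to use the "
                "elementwise mean"
            )
        vals = (vals + vals.T) / 2.0
    if np.isnan(vals).any():
        warnings.warn(
            "missing similarity values replaced by maximal distance",
            stacklevel=2,
        )
    if convention == "one-minus":
        dist = 1.0 - vals
        dist[np.isnan(dist)] = 1.0
    else:
        dist = -vals
        dist[np.isnan(dist)] = 0.0  # s=0 is the minimal similarity
    np.fill_diagonal(dist, 0.0 if convention == "one-minus" else -1.0)
    return list(matrix.labels), dist


def average_linkage(dist: np.ndarray, labels) -> Dendrogram:
    """UPGMA merge tree of a square distance matrix."""
    labels = list(labels)
    dist = np.asarray(dist, dtype=float)
    if len(labels) < 2:
        raise SezconnError("clustering requires at least 2 items")
    if dist.shape != (len(labels), len(labels)):
        raise SezconnError("distance matrix shape does not match labels")
    condensed = squareform(dist, checks=False)
    z = linkage(condensed, method="average")
    return Dendrogram(z, labels)


def cut_dendrogram(dendrogram: Dendrogram, score_cut: float,
                   convention: str = "one-minus") -> ClusterAssignment:
    """Cut a dendrogram at a similarity score.

    With the default d = 1 - s convention the cut height is h = 1 - score_cut
    and clusters are the merge subtrees strictly below h. score_cut = 1 yields
    singletons; score_cut = 0 applies every merge below the maximal distance.
    """
    if not 0.0 <= score_cut <= 1.0:
        raise SezconnError("score_cut must lie in [0, 1]")
    h = (1.0 - score_cut) if convention == "one-minus" else -score_cut
    n = len(dendrogram.labels)
    # union-find over leaves; merge rows of the linkage with height < h
    parent = list(range(n))

    def find(x):
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    rep = {i: i for i in range(n)}  # cluster id -> one leaf inside it
    for m, (a, b, height, _size) in enumerate(dendrogram.linkage):
        a, b = int(a), int(b)
        rep[n + m] = rep[a]
        if height < h:
            parent[find(rep[a])] = find(rep[b])

    groups: dict = {}
    for i, lab in enumerate(dendrogram.labels):
        groups.setdefault(find(i), []).append(lab)
    ordered = sorted(groups.values(), key=lambda g: str(min(g, key=str)))
    mapping = {}
    for k, members in enumerate(ordered, start=1):
        for lab in members:
            mapping[lab] = k
    return ClusterAssignment(mapping, score_cut, convention)


def compartment_composition(assignment: ClusterAssignment, annotations,
                            by: str) -> pd.DataFrame:
    """Percentage composition of each cluster over an annotation attribute.

    ``by`` is one of the annotation columns (e.g. origin, bundle, nerve).
    Each cluster row sums to 100.
    """
    if isinstance(annotations, pd.DataFrame):
        if by not in annotations.columns:
            raise SezconnError(f"annotation table lacks a {by!r} column")
        attr = annotations[by].to_dict()
    else:
        attr = {nid: ann[by] for nid, ann in dict(annotations).items()}
    missing = sorted((n for n in assignment.mapping if n not in attr), key=str)
    if missing:
        raise SezconnError(f"missing {by!r} annotation for neuron(s): {missing[:5]}")
    df = pd.DataFrame(
        {
            "cluster": [assignment.mapping[n] for n in assignment.mapping],
            by: [attr[n] for n in assignment.mapping],
        }
    )
    table = pd.crosstab(df["cluster"], df[by], normalize="index") * 100.0
    return table
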