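"""Nearest-neighbour search with deterministic tie handling.

Built on scipy's cKDTree; exact-distance ties are resolved to the lowest
target-point index so scores are reproducible on degenerate inputs
(duplicated points, symmetric fixtures).
"""

from __future__ import annotations

import numpy as np
from scipy.spatial import cKDTree


def nearest_lowest_index(target_points: np.ndarray, query_points: np.ndarray):
    """Return (distances, indices) of each query's nearest target point.

    Ties at exactly equal distance go to the lowest target index.
    """
    target_points = np.asarray(target_points, dtype=float)
    query_points = np.asarray(query_points, dtype=float)
    tree = cKDTree(target_points)
    dist, idx = tree.query(query_points)
    # query_ball_point at radius == min distance returns exactly the tied set
    balls = tree.query_ball_point(query_points, dist, return_sorted=True)
    idx = np.array(
        [b[0] if len(b) else i for b, i in zip(balls, np.atleast_1d(idx))],
        dtype=int,
    )
    return np.atleast_1d(dist), idx


def counts_within(points: np.ndarray, queries: np.ndarray, radius: float) -> np.ndarray:
    """Number of ``points`` within ``radius`` (inclusive) of each query point."""
    tree = cKDTree(np.asarray(points, dtype=float))
    balls = tree.query_ball_point(np.asarray(queries, dtype=float), radius)
    return np.array([len(b) for b in balls], dtype=int)
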