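"""Synapse-placement similarity: the score whose clustering defines compartments.

Each neuron is reduced to its cloud of synaptic sites (presynaptic and
postsynaptic, in nm). For every site s of neuron i, the nearest site k of
neuron j with the same polarity is found and scored

    f(is, jk) = exp(-d_sk^2 / (2 sigma^2)) * exp(-|n_is - n_jk| / (n_is + n_jk))

where n_is and n_jk count same-polarity sites of i (resp. j) within radius
omega of s (resp. k), inclusive of the site itself. The density factor
penalises placing a lone synapse next to a dense cluster even when the
distance is small. The overall score of i against j is the mean of f over
all sites s of i; sites with no same-polarity counterpart in j contribute 0
(configurable). Defaults: sigma = omega = 2000 nm.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from ._spatial import counts_within, nearest_lowest_index
from .clustering import SimilarityMatrix
from .errors import SezconnError

POLARITIES = ("pre", "post")


@dataclass
class SynapseCloud:
    """All synaptic sites of one neuron with their polarity."""

    neuron_id: object
    positions: np.ndarray  # (n, 3) nm
    polarities: np.ndarray  # (n,) str in {"pre", "post"}

    def __post_init__(self):
        self.positions = np.atleast_2d(np.asarray(self.positions, dtype=float))
        self.polarities = np.asarray(self.polarities, dtype=object)
        if self.positions.shape[0] != self.polarities.shape[0]:
            raise SezconnError("positions and polarities length mismatch")
        if not np.all(np.isfinite(self.positions)):
            raise SezconnError("synapse positions must be finite")
        bad = set(self.polarities) - set(POLARITIES)
        if bad:
            raise SezconnError(f"unknown polarity value(s): {sorted(bad)}")

    @property
    def n(self) -> int:
        return self.positions.shape[0]

    def sites(self, polarity: str) -> np.ndarray:
        return self.positions[self.polarities == polarity]


@dataclass(frozen=True)
class SynapseSimParams:
    """sigma: Gaussian distance scale (nm); omega: density radius (nm)."""

    sigma: float = 2000.0
    omega: float = 2000.0

    def __post_init__(self):
        if self.sigma <= 0 or self.omega <= 0:
            raise SezconnError("sigma and omega must be > 0")


def clouds_from_connectors(connectors, neuron_ids=None) -> dict:
    """Extract per-neuron synapse clouds from a connector table.

    The presynaptic neuron gets a 'pre' site at the connector's presynaptic
    position; each postsynaptic neuron gets a 'post' site at its own position.
    """
    acc: dict = {}
    for c in connectors:
        pre_id, pre_pos = c.pre
        acc.setdefault(pre_id, []).append((pre_pos, "pre"))
        for post_id, post_pos in c.posts:
            acc.setdefault(post_id, []).append((post_pos, "post"))
    if neuron_ids is not None:
        wanted = set(neuron_ids)
        acc = {nid: v for nid, v in acc.items() if nid in wanted}
    clouds = {}
    for nid, sites in acc.items():
        clouds[nid] = SynapseCloud(
            nid,
            np.array([p for p, _ in sites], dtype=float),
            np.array([pol for _, pol in sites], dtype=object),
        )
    return clouds


def local_density(cloud: SynapseCloud, site_index: int, omega: float) -> int:
    """Same-polarity sites of the cloud within omega of the given site.

    Inclusive of the site itself, so the count is always >= 1.
    """
    if not 0 <= site_index < cloud.n:
        raise SezconnError("site index out of range")
    pol = cloud.polarities[site_index]
    same = cloud.positions[cloud.polarities == pol]
    d = np.linalg.norm(same - cloud.positions[site_index], axis=1)
    return int(np.sum(d <= omega))


def synapse_similarity(i: SynapseCloud, j: SynapseCloud,
                       params: SynapseSimParams = SynapseSimParams(),
                       unmatched: str = "zero") -> float:
    """Mean per-site placement similarity of cloud i against cloud j.

    ``unmatched`` controls sites of i whose polarity is absent from j:
    "zero" (default) scores them 0; "skip" drops them from the mean.
    Asymmetric in general; score(i, i) == 1 exactly.
    """
    if unmatched not in ("zero", "skip"):
        raise SezconnError(f"unknown unmatched policy {unmatched!r}")
    if i.n == 0 or j.n == 0:
        raise SezconnError("cannot score an empty synapse cloud")
    i_pols = {p for p in i.polarities}
    if not any(np.any(j.polarities == p) for p in i_pols):
        raise SezconnError(
            f"cloud {j.neuron_id} has no site matching any polarity of "
            f"cloud {i.neuron_id}"
        )
    terms = []
    for pol in POLARITIES:
        si = i.sites(pol)
        if si.shape[0] == 0:
            continue
        sj = j.sites(pol)
        if sj.shape[0] == 0:
            if unmatched == "zero":
                terms.extend([0.0] * si.shape[0])
            continue
        dist, k = nearest_lowest_index(sj, si)
        n_is = counts_within(si, si, params.omega)
        n_jk = counts_within(sj, sj[k], params.omega)
        f = np.exp(-(dist ** 2) / (2.0 * params.sigma ** 2)) * np.exp(
            -np.abs(n_is - n_jk) / (n_is + n_jk)
        )
        terms.extend(f.tolist())
    if not terms:
        raise SezconnError("no scorable sites under the 'skip' policy")
    return float(np.mean(terms))


def synapse_similarity_matrix(clouds, params: SynapseSimParams = SynapseSimParams(),
                              symmetrize: bool = True,
                              unmatched: str = "zero") -> SimilarityMatrix:
    """All-pairs synapse similarity; diagonal fixed at 1.

    ``clouds`` is a sequence of SynapseCloud or a mapping id -> SynapseCloud
    (iterated in sorted-id order for determinism).
    """
    if isinstance(clouds, dict):
        cloud_list = [clouds[k] for k in sorted(clouds, key=str)]
    else:
        cloud_list = list(clouds)
    if len(cloud_list) < 2:
        raise SezconnError("need at least 2 synapse clouds")
    n = len(cloud_list)
    m = np.ones((n, n))
    for a in range(n):
        for b in range(n):
            if a != b:
                m[a, b] = synapse_similarity(
                    cloud_list[a], cloud_list[b], params, unmatched=unmatched
                )
    if symmetrize:
        m = (m + m.T) / 2.0
    labels = [c.neuron_id for c in cloud_list]
    return SimilarityMatrix(labels, m, symmetric=symmetrize)
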