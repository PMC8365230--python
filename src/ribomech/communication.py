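"""Markov-chain communication analysis: hitting/commute times and paths.

A binary contact affinity matrix defines a random walk whose transition
probability from node i to node j is a_ij/d_i (d_i = Σ_j a_ij).  Hitting
times H(j|i) — expected steps from i until first arrival at j — are obtained
by direct linear solves of the first-step equations; commute times
C(i, j) = H(j|i) + H(i|j) are symmetric and metric on connected graphs.
Sensor→effector communication pathways are minimum-total-weight paths on the
contact graph with commute-time edge weights, with deterministic
lexicographic tie-breaking and per-edge usage counts.
"""

from __future__ import annotations

import heapq
import logging
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import scipy.linalg

from .enm import contact_pairs
from .structures import CoarseGrainedStructure, StructureError

logger = logging.getLogger(__name__)

__all__ = [
    "CommunicationError",
    "CommunicationModel",
    "PathSet",
    "affinity_from_contacts",
    "hitting_commute",
    "extract_paths",
]


class CommunicationError(StructureError):
    pass


@dataclass
class CommunicationModel:
    """Affinity matrix, random-walk transition matrix and time matrices.

    ``transition`` is column-stochastic: M[i, j] = a_ij/d_j is the
    probability of stepping j → i.  ``hitting[i, j]`` = H(j|i), the expected
    number of steps from i to first reach j; ``commute`` is its
    symmetrisation.
    """

    affinity: np.ndarray
    degree: np.ndarray
    transition: np.ndarray
    hitting: np.ndarray
    commute: np.ndarray


@dataclass
class PathSet:
    """Shortest communication paths and per-edge usage counts."""

    paths: list[tuple[int, list[int] | None]] = field(default_factory=list)
    edge_usage: dict[tuple[int, int], int] = field(default_factory=dict)

    @property
    def found(self) -> list[list[int]]:
        return [p for _, p in self.paths if p is not None]

    @property
    def n_paths(self) -> int:
        return len(self.found)


def affinity_from_contacts(
    s: CoarseGrainedStructure, cutoff: float = 15.0
) -> np.ndarray:
    """Binary contact affinity: a_ij = 1 for i ≠ j within the cutoff.

    A coarse-grained surrogate for atom-contact counts; the cutoff defaults
    to the elastic-network cutoff so the random walk runs on the same
    topology as the mechanics.
    """
    n = len(s)
    if n < 2:
        raise CommunicationError("need at least 2 nodes")
    a = np.zeros((n, n))
    for i, j in contact_pairs(s.coords, cutoff):
        a[i, j] = a[j, i] = 1.0
    isolated = np.flatnonzero(a.sum(axis=1) == 0)
    for i in isolated:
        logger.warning("isolated node %r at cutoff %.1f Å", s.nodes[i], cutoff)
    return a


def _check_connected(a: np.ndarray) -> None:
    g = nx.from_numpy_array(a)
    if not nx.is_connected(g):
        comps = sorted((len(c) for c in nx.connected_components(g)), reverse=True)
        raise CommunicationError(
            f"affinity graph disconnected (component sizes {comps}); "
            "hitting times are undefined across components"
        )


def hitting_commute(a: np.ndarray) -> CommunicationModel:
    """Hitting- and commute-time matrices of the contact random walk.

    For each target j the first-step equations
    ``h_i = 1 + Σ_{k≠j} T_ik h_k`` (T_ik = a_ik/d_i) are solved directly:
    ``(I − T_{−j,−j}) h = 1``.  H(j|j) = 0; C(i, j) = H(j|i) + H(i|j).
    """
    a = np.asarray(a, dtype=float)
    n = a.shape[0]
    if a.shape != (n, n) or not np.allclose(a, a.T):
        raise CommunicationError("affinity must be square symmetric")
    if np.any(a < 0) or np.any(np.diag(a) != 0):
        raise CommunicationError("affinity must be ≥ 0 with zero diagonal")
    _check_connected(a)
    d = a.sum(axis=1)
    t = a / d[:, None]                      # row-stochastic walk matrix
    transition = t.T                        # column-stochastic convention
    hitting = np.zeros((n, n))
    ones = np.ones(n - 1)
    idx = np.arange(n)
    for j in range(n):
        keep = idx != j
        sub = np.eye(n - 1) - t[np.ix_(keep, keep)]
        try:
            h = scipy.linalg.solve(sub, ones)
        except scipy.linalg.LinAlgError as exc:  # pragma: no cover - guarded above
            raise CommunicationError(f"singular system for target {j}") from exc
        hitting[keep, j] = h
    commute = hitting + hitting.T
    return CommunicationModel(a, d, transition, hitting, commute)


def _lex_dijkstra(
    adj: dict[int, list[tuple[int, float]]], source: int, sink: int
) -> list[int] | None:
    """Shortest path, ties broken by lexicographically smallest node sequence."""
    best: dict[int, tuple[float, tuple[int, ...]]] = {}
    heap: list[tuple[float, tuple[int, ...]]] = [(0.0, (source,))]
    while heap:
        dist, path = heapq.heappop(heap)
        v = path[-1]
        if v in best and best[v] <= (dist, path):
            continue
        best[v] = (dist, path)
        if v == sink:
            return list(path)
        for w, wlen in adj[v]:
            cand = (dist + wlen, path + (w,))
            if w not in best or cand < best[w]:
                heapq.heappush(heap, cand)
    return None


def extract_paths(
    model: CommunicationModel,
    network: nx.Graph,
    sources,
    sinks,
    weighting: str = "commute",
) -> PathSet:
    """One minimum-weight communication path per (source, sink) pair.

    Edge weights on the contact network: ``commute`` uses C(i, j),
    ``hitting`` the symmetrised (H(j|i)+H(i|j))/2, ``unit`` hop count.
    Ties are broken by the lexicographically smallest node sequence, so path
    sets are reproducible.  Unreachable sinks yield a per-pair ``None``
    record rather than an error.  ``edge_usage`` counts, per undirected
    edge, how many returned paths traverse it.
    """
    sources = sorted(int(v) for v in sources)
    sinks = sorted(int(v) for v in sinks)
    if set(sources) & set(sinks):
        raise CommunicationError("sources and sinks must be disjoint")
    for v in sources + sinks:
        if v not in network:
            raise CommunicationError(f"node {v} not in network")

    if weighting == "commute":
        def wfun(i, j): return model.commute[i, j]
    elif weighting == "hitting":
        def wfun(i, j): return 0.5 * (model.hitting[i, j] + model.hitting[j, i])
    elif weighting == "unit":
        def wfun(i, j): return 1.0
    else:
        raise CommunicationError(f"unknown weighting {weighting!r}")

    adj: dict[int, list[tuple[int, float]]] = {v: [] for v in network.nodes}
    for i, j in network.edges:
        w = float(wfun(i, j))
        adj[i].append((j, w))
        adj[j].append((i, w))
    for v in adj:
        adj[v].sort()

    result = PathSet()
    pair_id = 0
    for src in sources:
        for snk in sinks:
            path = _lex_dijkstra(adj, src, snk)
            result.paths.append((pair_id, path))
            pair_id += 1
            if path is None:
                logger.warning("no path from %d to %d", src, snk)
                continue
            for u, v in zip(path[:-1], path[1:]):
                e = (u, v) if u < v else (v, u)
                result.edge_usage[e] = result.edge_usage.get(e, 0) + 1
    return result
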