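"""Residue interaction networks and centrality comparison.

Nodes mirror the coarse-grained structure; edges join residue pairs within a
contact cutoff (default 8 Å) with weight 1/distance, so closer contacts are
stronger.  Shortest-path measures use the edge *length* (= distance), making
tight contacts short hops.  Bound-vs-unbound comparisons report per-node
centrality deltas and edge gain/loss.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import networkx as nx
import numpy as np
import pandas as pd

from .enm import contact_pairs
from .structures import ChainMap, CoarseGrainedStructure, StructureError

logger = logging.getLogger(__name__)

__all__ = [
    "NetworkError",
    "build_rin",
    "centralities",
    "top_fraction",
    "compare_networks",
    "write_edge_list",
]


class NetworkError(StructureError):
    pass


def build_rin(
    s: CoarseGrainedStructure,
    contact_cutoff: float = 8.0,
    exclude_bonded: bool = False,
) -> nx.Graph:
    """Residue interaction network of a coarse-grained structure.

    Edge for every node pair at distance ≤ ``contact_cutoff``; attributes
    ``weight`` = 1/distance (interaction strength) and ``length`` = distance
    (shortest-path metric).  ``exclude_bonded`` drops sequence neighbours
    (same chain, |Δresidue_number| = 1).
    """
    if len(s) < 2:
        raise NetworkError("need at least 2 nodes")
    g = nx.Graph()
    g.add_nodes_from(range(len(s)))
    coords = s.coords
    for i, j in contact_pairs(coords, contact_cutoff):
        i, j = int(i), int(j)
        ni, nj = s.nodes[i], s.nodes[j]
        if exclude_bonded and ni.chain_id == nj.chain_id and \
                abs(ni.residue_number - nj.residue_number) == 1:
            continue
        dist = float(np.linalg.norm(coords[i] - coords[j]))
        if dist <= 0:
            raise NetworkError(f"coincident nodes {ni!r} and {nj!r}")
        g.add_edge(i, j, weight=1.0 / dist, length=dist)
    return g


def centralities(g: nx.Graph) -> pd.DataFrame:
    """Degree, betweenness and closeness centrality per node.

    Degree counts incident edges; betweenness and closeness use shortest
    paths with the edge ``length`` metric.  Closeness is
    ``(n_reachable − 1)/Σ lengths``, rescaled by component size on
    disconnected graphs (the Wasserman–Faust correction), which is logged.
    """
    if g.number_of_nodes() == 0:
        raise NetworkError("empty graph")
    if not nx.is_connected(g):
        logger.warning(
            "graph disconnected (%d components); closeness normalised per component",
            nx.number_connected_components(g),
        )
    deg = dict(g.degree())
    btw = nx.betweenness_centrality(g, weight="length", normalized=True)
    cls = nx.closeness_centrality(g, distance="length", wf_improved=True)
    return pd.DataFrame(
        {
            "degree": [deg[v] for v in g.nodes],
            "betweenness": [btw[v] for v in g.nodes],
            "closeness": [cls[v] for v in g.nodes],
        },
        index=list(g.nodes),
    )


def top_fraction(
    table: pd.DataFrame,
    s: CoarseGrainedStructure,
    measure: str,
    fraction: float = 0.10,
) -> list[int]:
    """The ⌈fraction·N⌉ nodes with the highest value of ``measure``.

    Ties at the boundary are broken deterministically by ascending
    (chain_id, residue_number, icode); a tie crossing the boundary is logged.
    """
    if measure not in table.columns:
        raise NetworkError(f"unknown measure {measure!r}; have {list(table.columns)}")
    if not 0 < fraction <= 1:
        raise NetworkError("fraction must be in (0, 1]")
    k = math.ceil(fraction * len(table))
    order = sorted(
        table.index,
        key=lambda v: (-table.at[v, measure], s.nodes[v].chain_id,
                       s.nodes[v].residue_number, s.nodes[v].icode),
    )
    if len(order) > k and table.at[order[k - 1], measure] == table.at[order[k], measure]:
        logger.warning("top_fraction: tie at the %s boundary broken by residue order", measure)
    return order[:k]


def compare_networks(
    g_unbound: nx.Graph,
    g_bound: nx.Graph,
    cmap: ChainMap,
) -> tuple[pd.DataFrame, dict]:
    """Per-node centrality deltas (bound − unbound) and edge gain/loss.

    Only paired nodes are compared.  Returns a DataFrame indexed by the
    unbound node index with Δdegree/Δbetweenness/Δcloseness columns, and a
    summary dict with edge counts and the number of edges gained/lost among
    paired nodes.
    """
    if not cmap.pairs:
        raise NetworkError("chain map has no paired nodes")
    tab_u = centralities(g_unbound)
    tab_b = centralities(g_bound)
    ia, ib = cmap.index_a, cmap.index_b
    delta = pd.DataFrame(
        {
            f"delta_{m}": tab_b.loc[ib, m].to_numpy() - tab_u.loc[ia, m].to_numpy()
            for m in ("degree", "betweenness", "closeness")
        },
        index=ia,
    )
    b_of_a = dict(cmap.pairs)
    edges_u = {tuple(sorted(e)) for e in g_unbound.edges}
    mapped_u = {
        tuple(sorted((b_of_a[i], b_of_a[j])))
        for i, j in edges_u if i in b_of_a and j in b_of_a
    }
    edges_b = {tuple(sorted(e)) for e in g_bound.edges}
    summary = {
        "edges_unbound": g_unbound.number_of_edges(),
        "edges_bound": g_bound.number_of_edges(),
        "edge_count_delta": g_bound.number_of_edges() - g_unbound.number_of_edges(),
        "edges_gained": len(edges_b - mapped_u),
        "edges_lost": len(mapped_u - edges_b),
    }
    return delta, summary


def write_edge_list(g: nx.Graph, s: CoarseGrainedStructure, path) -> None:
    """TSV edge list (node ids as chain:resnum) for external graph viewers."""
    def label(v: int) -> str:
        n = s.nodes[v]
        return f"{n.chain_id}:{n.residue_number}{n.icode}"

    rows = [
        (label(i), label(j), g.edges[i, j]["weight"]) for i, j in sorted(g.edges)
    ]
    pd.DataFrame(rows, columns=["node_i", "node_j", "weight"]).to_csv(
        path, sep="\t", index=False
    )
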