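"""Network communities of DC genes and gene-set over-representation.

DC genes and their directly connected neighbors are grouped into
communities by fast-greedy modularity maximization (Clauset-Newman-Moore
agglomeration).  Each community can then be tested for over-representation
of user-supplied gene sets (GMT format) with a one-sided hypergeometric
tail, Benjamini-Hochberg adjusted across sets within each community.
The enrichment universe defaults to all tested genes — conditioning on
what the selection step could have picked.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import networkx as nx
import numpy as np
import pandas as pd
from scipy.stats import hypergeom
from statsmodels.stats.multitest import multipletests

logger = logging.getLogger("dnlc")


def build_dc_subgraph(dc_genes, net: nx.Graph) -> nx.Graph:
    """Induced subgraph on DC genes plus all their direct neighbors.

    A DC gene without any edge is kept as a (flagged) singleton so it is
    not silently lost from the community report.
    """
    dc = [g for g in dc_genes if g in net]
    if not dc:
        raise ValueError(
            "no DC genes present in the network; review the lfdr threshold"
        )
    nodes = set(dc)
    for g in dc:
        nodes.update(net.neighbors(g))
    sub = net.subgraph(nodes).copy()
    singletons = [n for n in sub.nodes if sub.degree(n) == 0]
    if singletons:
        logger.info("%d DC gene(s) have no network edges (singleton communities)", len(singletons))
    return sub


@dataclass
class CommunitySet:
    """A modularity-maximizing partition of the DC subgraph.

    ``communities`` are disjoint frozensets covering every node of
    ``subgraph``; ``modularity`` is Q = sum_c (e_c/m - (d_c/2m)^2), the
    within-community edge fraction minus its degree-based expectation.
    """

    communities: list[frozenset]
    modularity: float
    subgraph: nx.Graph

    def membership(self) -> dict[str, int]:
        return {n: k for k, comm in enumerate(self.communities) for n in comm}


def detect_communities(subgraph: nx.Graph) -> CommunitySet:
    """Fast-greedy modularity communities of the DC subgraph.

    Agglomerative merging of the community pair with the best modularity
    gain until no merge improves Q.  An edgeless graph yields one
    singleton community per node with modularity 0.  Deterministic for a
    fixed input graph.
    """
    if subgraph.number_of_nodes() == 0:
        raise ValueError("empty subgraph")
    if subgraph.number_of_edges() == 0:
        comms = [frozenset([n]) for n in sorted(subgraph.nodes)]
        return CommunitySet(communities=comms, modularity=0.0, subgraph=subgraph)
    raw = nx.community.greedy_modularity_communities(subgraph)
    comms = sorted((frozenset(c) for c in raw), key=lambda c: (-len(c), sorted(c)))
    q = nx.community.modularity(subgraph, comms)
    return CommunitySet(communities=comms, modularity=float(q), subgraph=subgraph)


def enrich_communities(
    communities: CommunitySet,
    gene_sets: dict[str, set[str]],
    universe,
) -> pd.DataFrame:
    """Hypergeometric over-representation of gene sets in each community.

    For a community with ``n`` genes in the ``U``-gene universe and a set
    with ``K`` universe members, ``k`` of them in the community, the
    p-value is the exact upper tail P(X >= k) of Hypergeometric(U, K, n).
    BH adjustment is applied within each community across sets.

    Returns a DataFrame with columns community, gene_set, overlap,
    set_size, community_size, universe_size, p_value, p_adjusted.
    """
    universe = set(universe)
    # community members outside the universe (e.g. untestable neighbors)
    # are not counted in the overlap; n below is the testable size.
    if not gene_sets:
        logger.warning("empty gene-set collection; no enrichment computed")
        return pd.DataFrame(
            columns=[
                "community", "gene_set", "overlap", "set_size",
                "community_size", "universe_size", "p_value", "p_adjusted",
            ]
        )
    U = len(universe)
    rows = []
    for ci, comm in enumerate(communities.communities):
        testable = set(comm) & universe
        n = len(testable)
        pvals = []
        for name, members in gene_sets.items():
            inset = members & universe
            K = len(inset)
            k = len(testable & inset)
            p = float(hypergeom.sf(k - 1, U, K, n)) if K > 0 else 1.0
            pvals.append(min(p, 1.0))
            rows.append(
                {
                    "community": ci,
                    "gene_set": name,
                    "overlap": k,
                    "set_size": K,
                    "community_size": n,
                    "universe_size": U,
                    "p_value": min(p, 1.0),
                }
            )
        adj = multipletests(pvals, method="fdr_bh")[1]
        for j, a in enumerate(adj):
            rows[len(rows) - len(pvals) + j]["p_adjusted"] = float(a)
    return pd.DataFrame(rows)


def community_table(communities: CommunitySet, dc_sign: dict[str, int] | None = None) -> pd.DataFrame:
    """Long-format membership table (gene, community, dc_sign).

    ``dc_sign`` maps DC genes to +1/-1 by the sign of their association
    statistic; neighbors that are not DC genes get 0.
    """
    dc_sign = dc_sign or {}
    rows = [
        {"gene_id": g, "community": k, "dc_sign": dc_sign.get(g, 0)}
        for k, comm in enumerate(communities.communities)
        for g in sorted(comm)
    ]
    return pd.DataFrame(rows, columns=["gene_id", "community", "dc_sign"])
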