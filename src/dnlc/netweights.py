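"""Truncated network distances and row-normalized neighborhood weights.

Local Moran's I needs, for each gene ``i``, a weight ``w_ij`` over the
genes in its network vicinity.  Weights are assigned by a truncated
Gaussian kernel of the shortest-path (hop) distance,

    w_raw(d) = (1 / sqrt(2*pi)) * exp(-d^2 / 2)   for d <= radius,
    w_raw(d) = 0                                  for d >  radius,

and then row-normalized so that ``sum_{j != i} w_ij = 1`` for every gene
with at least one in-radius neighbor.  The ``1/sqrt(2*pi)`` constant
cancels in the normalization but is kept so the raw kernel is the
Gaussian density.  The default radius is 2 hops.
"""

from __future__ import annotations

from dataclasses import dataclass

import networkx as nx
import numpy as np
import scipy.sparse as sp

GAUSS_CONST = 1.0 / np.sqrt(2.0 * np.pi)


def truncated_distances(
    net: nx.Graph, radius: int = 2
) -> dict[str, dict[str, int]]:
    """Hop distances from every node to nodes within ``radius`` hops.

    Returns ``{node: {neighbor: distance}}`` with the node itself
    excluded and nodes beyond ``radius`` absent.  An isolated node maps
    to an empty dict.
    """
    if radius < 1:
        raise ValueError("radius must be >= 1")
    out: dict[str, dict[str, int]] = {}
    for node in net.nodes:
        dists = nx.single_source_shortest_path_length(net, node, cutoff=radius)
        dists.pop(node, None)
        out[node] = dists
    return out


def raw_kernel(d: np.ndarray | float, radius: int = 2) -> np.ndarray | float:
    """Truncated Gaussian kernel of hop distance (zero beyond ``radius``)."""
    d = np.asarray(d, dtype=float)
    return np.where(d <= radius, GAUSS_CONST * np.exp(-(d**2) / 2.0), 0.0)


@dataclass
class NeighborhoodWeights:
    """Row-normalized neighborhood weights for a fixed gene ordering.

    Attributes
    ----------
    gene_ids : list of str
        Row/column ordering of ``matrix``.
    matrix : scipy.sparse.csr_matrix
        ``p x p`` matrix with ``matrix[i, j] = w_ij``; each non-empty row
        sums to 1.  The diagonal is zero.
    radius : int
        Hop cutoff used to build the weights.
    isolated : ndarray of bool
        True for genes with no neighbor within ``radius`` hops (empty row).
    """

    gene_ids: list[str]
    matrix: sp.csr_matrix
    radius: int
    isolated: np.ndarray

    def row(self, gene: str) -> dict[str, float]:
        """Weights of ``gene`` as a ``{neighbor: weight}`` map."""
        i = self.gene_ids.index(gene)
        sl = self.matrix[i]
        return {self.gene_ids[j]: v for j, v in zip(sl.indices, sl.data)}


def compute_weights(
    distances: dict[str, dict[str, int]],
    gene_order: list[str] | None = None,
    radius: int = 2,
) -> NeighborhoodWeights:
    """Turn truncated distances into row-normalized neighborhood weights.

    Genes whose distance map is empty keep an all-zero row and are
    flagged in ``isolated``; their Local Moran's I is defined as 0
    downstream.
    """
    gene_ids = list(gene_order) if gene_order is not None else list(distances)
    index = {g: i for i, g in enumerate(gene_ids)}
    rows: list[int] = []
    cols: list[int] = []
    vals: list[float] = []
    isolated = np.zeros(len(gene_ids), dtype=bool)
    for g in gene_ids:
        dmap = distances[g]
        if not dmap:
            isolated[index[g]] = True
            continue
        neigh = [n for n in dmap if n in index and dmap[n] <= radius]
        if not neigh:
            isolated[index[g]] = True
            continue
        raw = np.array([raw_kernel(dmap[n], radius) for n in neigh], dtype=float)
        w = raw / raw.sum()
        rows.extend([index[g]] * len(neigh))
        cols.extend(index[n] for n in neigh)
        vals.extend(w)
    matrix = sp.csr_matrix(
        (vals, (rows, cols)), shape=(len(gene_ids), len(gene_ids))
    )
    return NeighborhoodWeights(
        gene_ids=gene_ids, matrix=matrix, radius=radius, isolated=isolated
    )


def network_weights(
    net: nx.Graph, radius: int = 2, gene_order: list[str] | None = None
) -> NeighborhoodWeights:
    """Convenience: truncated BFS distances followed by weight normalization."""
    order = gene_order if gene_order is not None else list(net.nodes)
    return compute_weights(truncated_distances(net, radius), order, radius)
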