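"""Normal-score transformation and Local Moran's I on a gene network.

For gene ``i`` in sample ``k`` the Local Moran's I (LMI) score is

    I_{i,k} = (z_{i,k} - zbar_k) / sigma_k^2 * sum_{j != i} w_ij (z_{j,k} - zbar_k)

where ``z`` is the normal-score-transformed expression, ``zbar_k`` and
``sigma_k^2`` are the mean and population variance of expression across
all genes in sample ``k``, and ``w_ij`` are the row-normalized
neighborhood weights (see :mod:`dnlc.netweights`).  A large positive
I means the gene and its network vicinity are consistently high or
consistently low in that sample; a large negative I marks a spatial
outlier.  The LMI matrix has exactly the shape of the expression matrix.

Conventions (the population variance, moments including gene ``i``
itself, and van der Waerden normal scores ``r/(N+1)``) are chosen so
that, per sample, ``sum_i I_{i,k} = p * I_global,k`` holds exactly for
row-normalized weights, matching standard Local Moran's I usage.

Both plain functions on genes x samples DataFrames and sklearn-style
transformers on samples x genes arrays are provided; the transformers
are thin orientation adapters over the same math.
"""

from __future__ import annotations

import networkx as nx
import numpy as np
import pandas as pd
from scipy.stats import norm, rankdata
from sklearn.base import BaseEstimator, TransformerMixin
from sklearn.utils.validation import check_array, check_is_fitted

from .netweights import NeighborhoodWeights, network_weights


def normal_score_transform(expr: pd.DataFrame) -> pd.DataFrame:
    """Replace each gene row by van der Waerden normal scores.

    Within each row, values are ranked (average ranks for ties) and
    mapped to ``Phi^{-1}(r / (N + 1))``.  Rank order is preserved and
    any strictly monotone transform of a row yields the same scores.

    Raises
    ------
    ValueError
        If a row is constant (fewer than two distinct values).
    """
    values = expr.to_numpy(dtype=float)
    n = values.shape[1]
    if n < 2:
        raise ValueError("normal score transform needs at least two samples")
    constant = np.all(values == values[:, :1], axis=1)
    if constant.any():
        gene = expr.index[np.flatnonzero(constant)[0]]
        raise ValueError(f"gene {gene!r} has constant expression; cannot rank-transform")
    ranks = rankdata(values, axis=1, method="average")
    scores = norm.ppf(ranks / (n + 1))
    return pd.DataFrame(scores, index=expr.index, columns=expr.columns)


def compute_lmi(expr: pd.DataFrame, weights: NeighborhoodWeights) -> pd.DataFrame:
    """Local Moran's I for every gene in every sample.

    ``expr`` must already be normal-score transformed and its index must
    equal ``weights.gene_ids`` (same order).  Genes flagged isolated in
    ``weights`` (no in-radius neighbor) get I = 0 in every sample.
    """
    if list(expr.index) != list(weights.gene_ids):
        raise ValueError("expression gene ids do not match weight gene ids")
    z = expr.to_numpy(dtype=float)
    p = z.shape[0]
    zbar = z.mean(axis=0)
    var = z.var(axis=0)  # population variance (divide by p)
    if np.any(var == 0):
        sample = expr.columns[int(np.flatnonzero(var == 0)[0])]
        raise ValueError(f"sample {sample!r} has zero expression variance across genes")
    centered = z - zbar
    lag = weights.matrix @ centered
    lmi = centered * lag / var
    lmi[weights.isolated, :] = 0.0
    if not np.all(np.isfinite(lmi)):
        raise ValueError("non-finite LMI values computed")
    return pd.DataFrame(lmi, index=expr.index, columns=expr.columns)


def lmi_pipeline(
    expr: pd.DataFrame, net: nx.Graph, radius: int = 2
) -> tuple[pd.DataFrame, NeighborhoodWeights]:
    """Normal-score transform then LMI, building weights from ``net``."""
    weights = network_weights(net, radius=radius, gene_order=list(expr.index))
    scores = normal_score_transform(expr)
    return compute_lmi(scores, weights), weights


class NormalScoreTransformer(TransformerMixin, BaseEstimator):
    """Rank-based inverse normal transformation, applied per feature.

    Operates on samples x features arrays (sklearn orientation); each
    feature column is replaced by ``Phi^{-1}(rank / (n_samples + 1))``
    with average ranks for ties.  Stateless apart from input validation.
    """

    def fit(self, X, y=None):
        X = check_array(X, dtype=float)
        self.n_features_in_ = X.shape[1]
        return self

    def transform(self, X):
        check_is_fitted(self, "n_features_in_")
        X = check_array(X, dtype=float)
        if X.shape[1] != self.n_features_in_:
            raise ValueError("feature count changed between fit and transform")
        frame = pd.DataFrame(X.T)
        return normal_score_transform(frame).to_numpy().T


class LocalMoranTransformer(TransformerMixin, BaseEstimator):
    """Map expression profiles to Local Moran's I profiles on a network.

    Parameters
    ----------
    graph : networkx.Graph
        Gene network; node labels must match the feature names of ``X``
        (DataFrame columns) or, for plain arrays, ``gene_ids``.
    radius : int, default=2
        Hop cutoff for the neighborhood weights.
    gene_ids : list of str, optional
        Feature names for plain-array input; defaults to the graph's
        node order.
    normal_scores : bool, default=True
        Apply the normal-score transform before computing LMI.  Set to
        False if ``X`` is already rank-normalized.

    Attributes
    ----------
    weights_ : NeighborhoodWeights
        Row-normalized truncated-Gaussian weights for the aligned genes.
    feature_names_in_ : ndarray of str
        Gene identifiers in column order.
    """

    def __init__(self, graph=None, radius: int = 2, gene_ids=None, normal_scores: bool = True):
        self.graph = graph
        self.radius = radius
        self.gene_ids = gene_ids
        self.normal_scores = normal_scores

    def _resolve_genes(self, X) -> list[str]:
        if isinstance(X, pd.DataFrame):
            return [str(c) for c in X.columns]
        if self.gene_ids is not None:
            return [str(g) for g in self.gene_ids]
        return [str(n) for n in self.graph.nodes]

    def fit(self, X, y=None):
        if self.graph is None:
            raise ValueError("a gene network graph is required")
        genes = self._resolve_genes(X)
        X_arr = check_array(X, dtype=float)
        if X_arr.shape[1] != len(genes):
            raise ValueError("number of features does not match gene identifiers")
        node_set = {str(n) for n in self.graph.nodes}
        missing = [g for g in genes if g not in node_set]
        if missing:
            raise ValueError(f"genes absent from network: {missing[:5]}")
        self.feature_names_in_ = np.asarray(genes, dtype=object)
        self.n_features_in_ = len(genes)
        self.weights_ = network_weights(self.graph, radius=self.radius, gene_order=genes)
        return self

    def transform(self, X):
        check_is_fitted(self, "weights_")
        X_arr = check_array(X, dtype=float)
        if X_arr.shape[1] != self.n_features_in_:
            raise ValueError("feature count changed between fit and transform")
        expr = pd.DataFrame(X_arr.T, index=list(self.feature_names_in_))
        if self.normal_scores:
            expr = normal_score_transform(expr)
        return compute_lmi(expr, self.weights_).to_numpy().T
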