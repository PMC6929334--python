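"""Readers, writers and input alignment for DNLC analyses.

Expression matrices are handled as :class:`pandas.DataFrame` objects with
genes in the rows (index) and samples in the columns, matching the usual
genes x samples layout of expression files.  Networks are
:class:`networkx.Graph` objects.  Clinical information is carried by
:class:`ClinicalTable`, which holds the outcome vector (continuous, binary
or survival time/event pairs) together with an optional confounder block.

Gene and sample identifiers are opaque strings; no identifier mapping is
attempted.  All readers validate their input and raise ``ValueError`` with
the offending identifier or cell location rather than silently coercing.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, replace
from pathlib import Path

import networkx as nx
import numpy as np
import pandas as pd

logger = logging.getLogger("dnlc")

OUTCOME_TYPES = ("continuous", "binary", "survival")

ASSOCIATION_COLUMNS = ["gene_id", "estimate", "statistic", "lfdr", "is_dc"]


# ---------------------------------------------------------------------------
# Clinical table
# ---------------------------------------------------------------------------


@dataclass
class ClinicalTable:
    """Clinical outcome and confounders for a cohort of samples.

    Parameters
    ----------
    sample_ids : list of str
        Ordered sample identifiers.
    outcome_type : {"continuous", "binary", "survival"}
        Nature of the outcome; decides the regression family downstream.
    outcome : ndarray
        Shape ``(N,)`` for continuous/binary outcomes; shape ``(N, 2)``
        with columns ``(time, event)`` for survival outcomes.
    confounders : DataFrame
        ``N x m`` block of additional covariates (``m`` may be zero).
        Categorical columns are one-hot encoded at model-fit time.
    """

    sample_ids: list[str]
    outcome_type: str
    outcome: np.ndarray
    confounders: pd.DataFrame = field(default_factory=pd.DataFrame)

    def __post_init__(self) -> None:
        if self.outcome_type not in OUTCOME_TYPES:
            raise ValueError(
                f"unknown outcome type {self.outcome_type!r}; "
                f"expected one of {OUTCOME_TYPES}"
            )
        self.sample_ids = [str(s) for s in self.sample_ids]
        n = len(self.sample_ids)
        self.outcome = np.asarray(self.outcome, dtype=float)
        if self.outcome_type == "survival":
            if self.outcome.shape != (n, 2):
                raise ValueError("survival outcome must be an (N, 2) time/event array")
            if np.any(self.outcome[:, 0] <= 0):
                raise ValueError("survival times must be positive")
            if not set(np.unique(self.outcome[:, 1])) <= {0.0, 1.0}:
                raise ValueError("event indicator must be 0/1")
        else:
            if self.outcome.shape != (n,):
                raise ValueError("outcome must be a length-N vector")
        if self.outcome_type == "binary":
            levels = set(np.unique(self.outcome))
            if not levels <= {0.0, 1.0}:
                raise ValueError("binary outcome must be coded 0/1")
            if len(levels) < 2:
                raise ValueError("binary outcome must contain both classes")
        if len(self.confounders) not in (0, n):
            raise ValueError("confounder rows must match the sample count")
        if len(self.confounders) == n:
            self.confounders = self.confounders.set_axis(self.sample_ids, axis=0)
        else:
            self.confounders = pd.DataFrame(index=self.sample_ids)

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    def subset(self, sample_ids: list[str]) -> "ClinicalTable":
        """Restrict and reorder to ``sample_ids`` (all must be present)."""
        pos = {s: i for i, s in enumerate(self.sample_ids)}
        missing = [s for s in sample_ids if s not in pos]
        if missing:
            raise KeyError(f"samples not in clinical table: {missing[:5]}")
        idx = [pos[s] for s in sample_ids]
        return ClinicalTable(
            sample_ids=list(sample_ids),
            outcome_type=self.outcome_type,
            outcome=self.outcome[idx],
            confounders=self.confounders.iloc[idx],
        )


def _map_binary(values: pd.Series) -> np.ndarray:
    """Map a two-level outcome column onto {0, 1}.

    Accepts numeric 0/1, the strings "0"/"1", or any two distinct labels,
    which are mapped by sorted order (first level -> 0).  The mapping is
    logged so the direction of effects is unambiguous.
    """
    labels = sorted(values.astype(str).unique())
    if len(labels) != 2:
        raise ValueError(
            f"binary outcome must have exactly two levels, found {labels}"
        )
    if labels == ["0", "1"]:
        mapping = {"0": 0.0, "1": 1.0}
    else:
        mapping = {labels[0]: 0.0, labels[1]: 1.0}
        logger.info("binary outcome mapping: %r -> 0, %r -> 1", labels[0], labels[1])
    return values.astype(str).map(mapping).to_numpy(dtype=float)


def read_clinical(
    path: str | Path,
    outcome_col: str,
    outcome_type: str,
    *,
    time_col: str | None = None,
    event_col: str | None = None,
    confounder_cols: list[str] | None = None,
    delimiter: str = "\t",
) -> ClinicalTable:
    """Read a clinical table (first column = sample id, header row)."""
    df = pd.read_csv(path, sep=delimiter, index_col=0)
    df.index = df.index.astype(str)
    if df.index.duplicated().any():
        dups = df.index[df.index.duplicated()].unique().tolist()
        raise ValueError(f"duplicate sample ids in clinical table: {dups}")
    if outcome_type == "survival":
        if time_col is None or event_col is None:
            raise ValueError("survival outcome requires time_col and event_col")
        for col in (time_col, event_col):
            if col not in df.columns:
                raise ValueError(f"column {col!r} not found in clinical table")
        outcome = df[[time_col, event_col]].to_numpy(dtype=float)
    else:
        if outcome_col not in df.columns:
            raise ValueError(f"column {outcome_col!r} not found in clinical table")
        if outcome_type == "binary":
            outcome = _map_binary(df[outcome_col])
        else:
            outcome = pd.to_numeric(df[outcome_col]).to_numpy(dtype=float)
    conf = df[list(confounder_cols)] if confounder_cols else pd.DataFrame(index=df.index)
    return ClinicalTable(
        sample_ids=df.index.tolist(),
        outcome_type=outcome_type,
        outcome=outcome,
        confounders=conf,
    )


# ---------------------------------------------------------------------------
# Expression matrices
# ---------------------------------------------------------------------------


def read_expression(path: str | Path, delimiter: str = "\t") -> pd.DataFrame:
    """Read a genes x samples expression matrix.

    Layout: header row of sample ids, first column of gene ids, numeric
    body.  Duplicate gene or sample ids and any non-numeric or missing
    cell are hard errors (the downstream statistics have no missing-data
    contract; impute upstream if needed).
    """
    df = pd.read_csv(path, sep=delimiter, index_col=0, dtype=str)
    df.index = df.index.astype(str)
    if df.index.duplicated().any():
        dups = df.index[df.index.duplicated()].unique().tolist()
        raise ValueError(f"duplicate gene ids in expression matrix: {dups}")
    if pd.Index(df.columns).duplicated().any():
        dups = pd.Index(df.columns)[pd.Index(df.columns).duplicated()].unique().tolist()
        raise ValueError(f"duplicate sample ids in expression matrix: {dups}")
    def parse_cell(value):
        # builtin float() is correctly rounded; pandas' fast parser is not
        try:
            return float(value)
        except (TypeError, ValueError):
            return np.nan

    out = pd.DataFrame(index=df.index, columns=df.columns, dtype=float)
    for col in df.columns:
        converted = df[col].map(parse_cell)
        bad = converted.isna()
        if bad.any():
            gene = df.index[bad.to_numpy()][0]
            raise ValueError(
                f"non-numeric or missing expression value at gene {gene!r}, "
                f"sample {col!r}"
            )
        out[col] = converted.to_numpy(dtype=float)
    return out


def write_expression(expr: pd.DataFrame, path: str | Path, delimiter: str = "\t") -> None:
    """Write a genes x samples matrix; floats keep shortest-round-trip precision."""
    expr.to_csv(path, sep=delimiter, index_label="gene_id")


# ---------------------------------------------------------------------------
# Networks
# ---------------------------------------------------------------------------

NETWORK_FORMATS = ("edgelist", "sif", "graphml")


def _add_edge_checked(graph: nx.Graph, u: str, v: str, counters: dict) -> None:
    if u == v:
        counters["self_loops"] += 1
        return
    if graph.has_edge(u, v):
        counters["duplicates"] += 1
        return
    graph.add_edge(u, v)


def read_network(path: str | Path, fmt: str = "edgelist") -> nx.Graph:
    """Read an undirected gene network.

    Formats: ``edgelist`` (whitespace-separated pairs), ``sif``
    (``node1 relation node2 [node3 ...]``; the relation is ignored) and
    ``graphml``.  Self-loops and duplicate edges are dropped with a
    logged count; the result is always a simple undirected graph.
    """
    if fmt not in NETWORK_FORMATS:
        raise ValueError(f"unknown network format {fmt!r}; expected {NETWORK_FORMATS}")
    path = Path(path)
    counters = {"self_loops": 0, "duplicates": 0}
    graph: nx.Graph = nx.Graph()
    if fmt == "graphml":
        raw = nx.read_graphml(path)
        graph.add_nodes_from(str(n) for n in raw.nodes)
        for u, v in raw.edges():
            _add_edge_checked(graph, str(u), str(v), counters)
    else:
        lines = [ln.strip() for ln in path.read_text().splitlines()]
        lines = [ln for ln in lines if ln and not ln.startswith("#")]
        if not lines:
            raise ValueError(f"network file {path} is empty")
        for ln in lines:
            parts = ln.split()
            if fmt == "edgelist":
                if len(parts) < 2:
                    raise ValueError(f"malformed edge list line: {ln!r}")
                _add_edge_checked(graph, parts[0], parts[1], counters)
            else:  # sif: source relation target [target ...]
                if len(parts) == 1:
                    graph.add_node(parts[0])
                    continue
                if len(parts) < 3:
                    raise ValueError(f"malformed SIF line: {ln!r}")
                for target in parts[2:]:
                    _add_edge_checked(graph, parts[0], target, counters)
    if graph.number_of_nodes() == 0:
        raise ValueError(f"network file {path} contains no nodes")
    if counters["self_loops"] or counters["duplicates"]:
        logger.warning(
            "network %s: dropped %d self-loop(s) and %d duplicate edge(s)",
            path,
            counters["self_loops"],
            counters["duplicates"],
        )
    return graph


def export_graph(graph: nx.Graph, path: str | Path, fmt: str = "graphml") -> None:
    """Write a network as GraphML or a whitespace edge list."""
    if fmt == "graphml":
        nx.write_graphml(graph, path)
    elif fmt == "edgelist":
        with open(path, "w") as fh:
            for u, v in graph.edges():
                fh.write(f"{u} {v}\n")
    else:
        raise ValueError(f"unknown export format {fmt!r}")


# ---------------------------------------------------------------------------
# Gene sets (GMT)
# ---------------------------------------------------------------------------


def read_gmt(path: str | Path) -> dict[str, set[str]]:
    """Read a GMT gene-set collection: name, description, tab-separated members."""
    sets: dict[str, set[str]] = {}
    for ln in Path(path).read_text().splitlines():
        if not ln.strip():
            continue
        parts = ln.rstrip("\n").split("\t")
        if len(parts) < 3:
            raise ValueError(f"malformed GMT line (need name, description, members): {ln!r}")
        name = parts[0]
        if name in sets:
            raise ValueError(f"duplicate gene-set name in GMT: {name!r}")
        sets[name] = {g for g in parts[2:] if g}
    return sets


# ---------------------------------------------------------------------------
# Alignment
# ---------------------------------------------------------------------------


def align_inputs(
    expr: pd.DataFrame,
    net: nx.Graph,
    clin: ClinicalTable | None = None,
) -> tuple[pd.DataFrame, nx.Graph, ClinicalTable | None]:
    """Restrict expression, network and clinical table to common ids.

    Genes are intersected between the expression index and the network
    node set (unmatched genes/nodes are eliminated); samples are
    restricted to those present in both the expression matrix and the
    clinical table, in expression-matrix order.  Idempotent.
    """
    expr_genes = expr.index
    net_nodes = set(str(n) for n in net.nodes)
    keep_genes = [g for g in expr_genes if g in net_nodes]
    if not keep_genes:
        raise ValueError("no genes shared between expression matrix and network")
    dropped_expr = len(expr_genes) - len(keep_genes)
    dropped_net = len(net_nodes) - len(keep_genes)
    if dropped_expr or dropped_net:
        logger.info(
            "alignment dropped %d expression gene(s) and %d network node(s)",
            dropped_expr,
            dropped_net,
        )
    expr_out = expr.loc[keep_genes]
    net_out = net.subgraph(keep_genes).copy()

    clin_out = clin
    if clin is not None:
        clin_samples = set(clin.sample_ids)
        keep_samples = [s for s in expr.columns if s in clin_samples]
        if not keep_samples:
            raise ValueError("no samples shared between expression matrix and clinical table")
        dropped_samples = (len(expr.columns) - len(keep_samples)) + (
            len(clin.sample_ids) - len(keep_samples)
        )
        if dropped_samples:
            logger.info("alignment dropped %d sample(s)", dropped_samples)
        expr_out = expr_out[keep_samples]
        clin_out = clin.subset(keep_samples)
    return expr_out, net_out, clin_out


# ---------------------------------------------------------------------------
# Association table I/O
# ---------------------------------------------------------------------------


def write_association_table(table: pd.DataFrame, path: str | Path) -> None:
    """Write an association table as TSV (gene_id, estimate, statistic, lfdr, is_dc)."""
    missing = [c for c in ASSOCIATION_COLUMNS if c not in table.columns]
    if missing:
        raise ValueError(f"association table missing columns: {missing}")
    table[ASSOCIATION_COLUMNS].to_csv(path, sep="\t", index=False)


def read_association_table(path: str | Path) -> pd.DataFrame:
    table = pd.read_csv(
        path,
        sep="\t",
        float_precision="round_trip",
        dtype={"gene_id": str, "estimate": float, "statistic": float, "lfdr": float, "is_dc": bool},
    )
    missing = [c for c in ASSOCIATION_COLUMNS if c not in table.columns]
    if missing:
        raise ValueError(f"association table missing columns: {missing}")
    return table


def write_lfdr_fit(fit, path: str | Path) -> None:
    """Serialize an LfdrFit (null parameters and density grid) to JSON."""
    with open(path, "w") as fh:
        json.dump(fit.to_dict(), fh, indent=1)
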