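"""Sparse unweighted gene coexpression networks from correlation rank rules.

Two genes are linked when at least one of two conditions holds on their
Pearson correlation r and mutual correlation ranks:

  rule 1:  r > r_low  (default 0.3) and either gene is among the other's
           k_low (default 3) most-correlated genes;
  rule 2:  r > r_high (default 0.7) and either gene is among the other's
           k_high (default 50) most-correlated genes.

The "top-k of the other" membership is taken in either direction, which makes
both rules symmetric, and the resulting graph is simple, undirected and
unweighted, stored as a binary adjacency matrix. Ranking uses the signed
correlation descending ("most correlated" read literally; an absolute-value
variant is available); genes tied with the k-th ranked gene all count as
within the top k so the result never depends on gene order.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, asdict

import networkx as nx
import numpy as np
import pandas as pd

from .expression import ExpressionMatrix

logger = logging.getLogger(__name__)

__all__ = ["NetworkParams", "CoexprNetwork", "pearson_matrix", "build_network",
           "network_from_correlation"]


@dataclass(frozen=True)
class NetworkParams:
    r_low: float = 0.3
    k_low: int = 3
    r_high: float = 0.7
    k_high: int = 50
    absolute_corr: bool = False

    def validate(self) -> None:
        if not -1.0 < self.r_low <= self.r_high < 1.0:
            raise ValueError("need -1 < r_low <= r_high < 1")
        if not 1 <= self.k_low <= self.k_high:
            raise ValueError("need 1 <= k_low <= k_high")


@dataclass
class CoexprNetwork:
    """Binary symmetric adjacency over an ordered gene list."""

    genes: list[str]
    adjacency: np.ndarray = field(repr=False)
    params: NetworkParams | None = None

    def __post_init__(self) -> None:
        a = self.adjacency
        m = len(self.genes)
        if a.shape != (m, m):
            raise ValueError("adjacency shape does not match gene list")
        if not np.array_equal(a, a.T):
            raise ValueError("adjacency must be symmetric")
        if np.any(np.diag(a) != 0):
            raise ValueError("adjacency diagonal must be zero")
        if not np.isin(a, (0, 1)).all():
            raise ValueError("adjacency entries must be 0/1")
        self._index = {g: i for i, g in enumerate(self.genes)}

    @property
    def n_genes(self) -> int:
        return len(self.genes)

    @property
    def n_edges(self) -> int:
        return int(self.adjacency.sum()) // 2

    def degree(self, gene: str) -> int:
        return int(self.adjacency[self._index[gene]].sum())

    def degrees(self) -> pd.Series:
        return pd.Series(self.adjacency.sum(axis=1), index=self.genes)

    def neighborhood(self, gene: str) -> set[str]:
        """Genes directly adjacent to ``gene`` (never includes ``gene``)."""
        if gene not in self._index:
            raise KeyError(f"unknown gene {gene!r}")
        row = self.adjacency[self._index[gene]]
        return {self.genes[j] for j in np.flatnonzero(row)}

    def isolated_genes(self) -> list[str]:
        return [g for g, d in zip(self.genes, self.adjacency.sum(axis=1)) if d == 0]

    def to_networkx(self) -> nx.Graph:
        g = nx.Graph()
        g.add_nodes_from(self.genes)
        iu, ju = np.nonzero(np.triu(self.adjacency, k=1))
        g.add_edges_from((self.genes[i], self.genes[j]) for i, j in zip(iu, ju))
        return g

    # -- I/O -----------------------------------------------------------------

    def to_edge_list(self, path, node_list_path=None) -> None:
        """Two-column tab-delimited edges; optional node-list sidecar keeps
        isolated genes recoverable."""
        with open(path, "w") as fh:
            iu, ju = np.nonzero(np.triu(self.adjacency, k=1))
            for i, j in zip(iu, ju):
                fh.write(f"{self.genes[i]}\t{self.genes[j]}\n")
        if node_list_path is not None:
            with open(node_list_path, "w") as fh:
                fh.write("\n".join(self.genes) + "\n")

    def to_graphml(self, path) -> None:
        nx.write_graphml(self.to_networkx(), path)

    @classmethod
    def from_edge_list(cls, path, node_list_path=None,
                       params: NetworkParams | None = None) -> "CoexprNetwork":
        edges = []
        with open(path) as fh:
            for line in fh:
                parts = line.split()
                if parts:
                    edges.append((parts[0], parts[1]))
        if node_list_path is not None:
            with open(node_list_path) as fh:
                genes = [ln.strip() for ln in fh if ln.strip()]
        else:
            genes = sorted({g for e in edges for g in e})
        index = {g: i for i, g in enumerate(genes)}
        adj = np.zeros((len(genes), len(genes)), dtype=np.uint8)
        for u, v in edges:
            if u != v:
                adj[index[u], index[v]] = adj[index[v], index[u]] = 1
        return cls(genes, adj, params)

    @classmethod
    def from_networkx(cls, graph: nx.Graph,
                      genes: list[str] | None = None) -> "CoexprNetwork":
        if genes is None:
            genes = sorted(graph.nodes())
        adj = np.zeros((len(genes), len(genes)), dtype=np.uint8)
        index = {g: i for i, g in enumerate(genes)}
        for u, v in graph.edges():
            if u != v:
                adj[index[u], index[v]] = adj[index[v], index[u]] = 1
        return cls(genes, adj)


def pearson_matrix(expr: ExpressionMatrix) -> pd.DataFrame:
    """Gene-gene Pearson correlation matrix.

    Requires >= 3 samples; errors naming any zero-variance gene, for which the
    coefficient is undefined.
    """
    values = expr.data.to_numpy(dtype=float)
    if values.shape[1] < 3:
        raise ValueError("need at least 3 samples to correlate")
    sd = values.std(axis=1)
    if np.any(sd == 0.0):
        bad = [g for g, s in zip(expr.genes, sd) if s == 0.0]
        raise ValueError("zero-variance gene(s): " + ", ".join(bad))
    corr = np.corrcoef(values)
    np.fill_diagonal(corr, 1.0)
    return pd.DataFrame(np.clip(corr, -1.0, 1.0), index=expr.genes, columns=expr.genes)


def _topk_mask(score: np.ndarray, k: int) -> np.ndarray:
    """Boolean matrix: entry (i, j) true iff j is within i's top-k scores.

    Ties with the k-th ranked value are all included, so membership does not
    depend on gene order. The diagonal (self) is excluded beforehand by the
    caller setting it to -inf.
    """
    m = score.shape[0]
    if k >= m - 1:
        return np.isfinite(score)
    # k-th largest per row (0-based index k-1 after sorting descending)
    kth = np.partition(score, -k, axis=1)[:, -k]
    return score >= kth[:, None]


def network_from_correlation(corr: pd.DataFrame,
                             params: NetworkParams | None = None) -> CoexprNetwork:
    """Apply the two linkage rules to a precomputed correlation matrix."""
    params = params or NetworkParams()
    params.validate()
    genes = list(corr.index)
    r = corr.to_numpy(dtype=float).copy()
    score = np.abs(r) if params.absolute_corr else r.copy()
    np.fill_diagonal(score, -np.inf)
    np.fill_diagonal(r, 0.0)

    top_low = _topk_mask(score, params.k_low)
    top_high = _topk_mask(score, params.k_high)
    passes = np.abs(r) if params.absolute_corr else r

    rule1 = (passes > params.r_low) & (top_low | top_low.T)
    rule2 = (passes > params.r_high) & (top_high | top_high.T)
    adj = (rule1 | rule2)
    adj &= adj.T  # thresholds are symmetric already; belt and braces
    np.fill_diagonal(adj, False)

    net = CoexprNetwork(genes, adj.astype(np.uint8), params)
    isolated = net.isolated_genes()
    if isolated:
        logger.warning("coexpression network has %d isolated node(s): %s%s",
                       len(isolated), ", ".join(isolated[:10]),
                       "..." if len(isolated) > 10 else "")
    return net


def build_network(expr: ExpressionMatrix, gene_subset=None,
                  params: NetworkParams | None = None) -> CoexprNetwork:
    """Coexpression network over ``gene_subset`` using all samples of ``expr``.

    Both sample groups of the region (control and affected) contribute to the
    correlations unless the matrix was subset beforehand.
    """
    if gene_subset is not None:
        subset = set(gene_subset)
        if not subset:
            raise ValueError("gene_subset is empty")
        missing = subset - set(expr.genes)
        if missing:
            raise ValueError(f"gene_subset not in matrix: {sorted(missing)[:5]}")
        expr = expr.subset_genes(subset)
    return network_from_correlation(pearson_matrix(expr), params)


def params_to_dict(params: NetworkParams) -> dict:
    return asdict(params)
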