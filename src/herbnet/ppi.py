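"""Multi-source PPI assembly, centrality, and hub-target extraction.

Interaction sources (e.g. BioGRID-, KEGG- or EndoNet-style edge lists)
are merged into one simple undirected graph: unordered-pair deduplication
across sources, self-loops dropped, per-edge provenance retained.

Two node-importance measures are computed: raw degree (incident edge
count) and eigenvector centrality — the principal eigenvector of the
adjacency matrix, obtained by power iteration on the largest connected
component and L2-normalized; nodes outside that component score 0.
Hub targets are query nodes falling in the top percentile of BOTH
measures.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from math import ceil
from pathlib import Path

import networkx as nx
import numpy as np
import pandas as pd
import scipy.sparse as sp

logger = logging.getLogger(__name__)


class ParseError(ValueError):
    pass


class ConvergenceError(RuntimeError):
    pass


def read_edge_list(path: str | Path, source: str | None = None) -> list[tuple[str, str, str]]:
    """Read a per-source edge TSV with columns node_a, node_b[, source]."""
    path = Path(path)
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    for col in ("node_a", "node_b"):
        if col not in df.columns:
            raise ParseError(f"{path}: missing column {col!r}")
    tag = source or path.stem
    out = []
    for i, row in df.iterrows():
        a, b = row["node_a"].strip(), row["node_b"].strip()
        if not a or not b:
            raise ParseError(f"{path}: line {i + 2}: empty node id")
        out.append((a, b, row.get("source", "") or tag))
    return out


def merge_sources(edge_lists: list[list[tuple[str, str, str]]]) -> nx.Graph:
    """Union of tagged edge lists as a simple undirected graph.

    (a, b) and (b, a) collapse to one edge; self-loops are dropped (and
    counted in the log); directed records are implicitly symmetrized.
    Merging is order-independent.
    """
    g = nx.Graph()
    n_loops = 0
    for edges in edge_lists:
        for a, b, src in edges:
            if a == b:
                n_loops += 1
                continue
            if g.has_edge(a, b):
                g.edges[a, b]["sources"].add(src)
            else:
                g.add_edge(a, b, sources={src})
    if n_loops:
        logger.warning("merge_sources: dropped %d self-loop record(s)", n_loops)
    return g


@dataclass
class CentralityReport:
    """Per-node degree and eigenvector scores plus percentile thresholds."""

    nodes: list[str]
    degree: dict[str, int]
    eigenvector: dict[str, float]
    n_iterations: int
    residual: float

    def frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "node": self.nodes,
                "degree": [self.degree[n] for n in self.nodes],
                "eigenvector": [self.eigenvector[n] for n in self.nodes],
            }
        )


def _power_iteration(
    adj: sp.spmatrix, tol: float, max_iter: int
) -> tuple[np.ndarray, int, float]:
    n = adj.shape[0]
    x = np.full(n, 1.0 / np.sqrt(n))
    for it in range(1, max_iter + 1):
        # iterate on (A + I): same principal eigenvector, but strictly
        # dominant eigenvalue even on bipartite graphs (spectrum ±λ1)
        y = adj @ x + x
        norm = np.linalg.norm(y)
        if norm == 0:
            raise ConvergenceError("adjacency annihilated the iterate")
        y /= norm
        resid = np.linalg.norm(y - x)
        x = y
        if resid < tol:
            return x, it, resid
    raise ConvergenceError(
        f"power iteration did not converge in {max_iter} steps (residual {resid:.2e})"
    )


def centrality(
    network: nx.Graph, tol: float = 1e-10, max_iter: int = 10_000
) -> CentralityReport:
    """Degree and eigenvector centrality for every node.

    Eigenvector scores are computed on the largest connected component
    (nodes elsewhere score 0) and L2-normalized.  Convergence: successive
    normalized iterates within ``tol`` in L2.
    """
    if network.number_of_edges() == 0:
        raise ValueError("network has no edges")
    nodes = list(network.nodes)
    degree = {n: int(d) for n, d in network.degree()}
    lcc = max(nx.connected_components(network), key=len)
    sub_nodes = [n for n in nodes if n in lcc]
    adj = nx.to_scipy_sparse_array(network.subgraph(sub_nodes), nodelist=sub_nodes, dtype=float)
    vec, n_iter, resid = _power_iteration(adj, tol, max_iter)
    vec = np.abs(vec)  # Perron vector is non-negative; fix sign
    eigenvector = {n: 0.0 for n in nodes}
    eigenvector.update(dict(zip(sub_nodes, vec)))
    return CentralityReport(nodes, degree, eigenvector, n_iter, resid)


def percentile_thresholds(
    report: CentralityReport, fractions: tuple[float, ...] = (0.01, 0.05, 0.10)
) -> pd.DataFrame:
    """Minimum score attained within the top ⌈f·|V|⌉ nodes, per measure.

    Ties at the threshold keep all tied nodes, so a "top f" set may exceed
    ⌈f·|V|⌉ members.
    """
    nv = len(report.nodes)
    rows = []
    for f in fractions:
        k = ceil(f * nv)
        deg_sorted = sorted(report.degree.values(), reverse=True)
        eig_sorted = sorted(report.eigenvector.values(), reverse=True)
        rows.append(
            {
                "fraction": f,
                "degree_threshold": deg_sorted[k - 1],
                "eigenvector_threshold": eig_sorted[k - 1],
            }
        )
    return pd.DataFrame(rows)


def top_nodes(report: CentralityReport, measure: str, fraction: float) -> set[str]:
    """Nodes with score ≥ the top-``fraction`` threshold for ``measure``."""
    scores = getattr(report, measure)
    k = ceil(fraction * len(report.nodes))
    thr = sorted(scores.values(), reverse=True)[k - 1]
    return {n for n, s in scores.items() if s >= thr}


@dataclass
class HubSet:
    query_targets: set[str]
    hubs: set[str]
    fraction: float


def extract_hubs(
    report: CentralityReport, query_targets: set[str], fraction: float = 0.01
) -> HubSet:
    """Query targets in the top-``fraction`` of BOTH degree and eigenvector
    centrality.  Query ids absent from the network are logged and skipped."""
    known = set(report.nodes)
    unknown = set(query_targets) - known
    if unknown:
        logger.warning("extract_hubs: %d query id(s) not in network: %s",
                       len(unknown), sorted(unknown)[:10])
    targets = set(query_targets) & known
    hubs = (
        targets
        & top_nodes(report, "degree", fraction)
        & top_nodes(report, "eigenvector", fraction)
    )
    return HubSet(targets, hubs, fraction)


def write_ppi(g: nx.Graph, graphml_path: str | Path | None = None,
              edges_tsv: str | Path | None = None) -> None:
    if graphml_path is not None:
        h = nx.Graph()
        h.add_nodes_from(g.nodes)
        for u, v, d in g.edges(data=True):
            h.add_edge(u, v, sources=",".join(sorted(d.get("sources", set()))))
        nx.write_graphml(h, graphml_path)
    if edges_tsv is not None:
        pd.DataFrame(
            [{"node_a": u, "node_b": v,
              "sources": ",".join(sorted(d.get("sources", set())))}
             for u, v, d in g.edges(data=True)]
        ).to_csv(edges_tsv, sep="\t", index=False)
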