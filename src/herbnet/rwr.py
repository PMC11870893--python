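"""Random walk with restart over a heterogeneous compound–target–disease
network.

A walker starts on the seed nodes (therapeutic targets), follows an edge
to a uniformly random neighbour with probability 1 − r, and restarts at
the seed distribution with probability r.  The stationary distribution

    p = r · (I − (1 − r) · W)⁻¹ · p₀

(with W the column-normalized adjacency) scores every node's proximity
to the seeds; disease nodes ranked by this score are the prioritization
output.  The fixed point is computed iteratively,

    p ← (1 − r) · W · p + r · p₀,

which converges geometrically at rate ≤ (1 − r).  Columns of isolated
("dangling") nodes are redirected to p₀ so that probability mass is
conserved exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import networkx as nx
import numpy as np
import pandas as pd
import scipy.sparse as sp

NODE_TYPES = ("protein", "compound", "disease")

#: which node-type pairs an edge may join (undirected)
ALLOWED_EDGE_TYPES = {
    frozenset({"protein"}): "ppi",
    frozenset({"protein", "compound"}): "compound-target",
    frozenset({"protein", "disease"}): "target-disease",
}


class ConvergenceError(RuntimeError):
    pass


class HeterogeneousNetwork:
    """Typed undirected weighted graph over proteins, compounds, diseases."""

    def __init__(self) -> None:
        self.graph = nx.Graph()

    def add_node(self, node: str, node_type: str) -> None:
        if node_type not in NODE_TYPES:
            raise ValueError(f"unknown node type {node_type!r}")
        self.graph.add_node(node, node_type=node_type)

    def add_edge(self, u: str, v: str, weight: float = 1.0) -> None:
        if weight <= 0:
            raise ValueError("edge weights must be positive")
        tu = self.graph.nodes[u]["node_type"]
        tv = self.graph.nodes[v]["node_type"]
        pair = frozenset({tu, tv})
        if pair not in ALLOWED_EDGE_TYPES:
            raise ValueError(f"edges between {tu} and {tv} are not allowed")
        self.graph.add_edge(u, v, weight=weight, edge_type=ALLOWED_EDGE_TYPES[pair])

    @property
    def nodes(self) -> list[str]:
        return list(self.graph.nodes)

    def nodes_of_type(self, node_type: str) -> list[str]:
        return [n for n, t in self.graph.nodes(data="node_type") if t == node_type]

    @classmethod
    def from_files(cls, nodes_tsv: str | Path, edges_tsv: str | Path) -> "HeterogeneousNetwork":
        net = cls()
        nodes = pd.read_csv(nodes_tsv, sep="\t", dtype=str)
        for _, row in nodes.iterrows():
            net.add_node(row["node"], row["node_type"])
        edges = pd.read_csv(edges_tsv, sep="\t", dtype={"weight": float}).astype({"node_a": str, "node_b": str})
        for _, row in edges.iterrows():
            net.add_edge(row["node_a"], row["node_b"], float(row.get("weight", 1.0)))
        return net

    def to_files(self, nodes_tsv: str | Path, edges_tsv: str | Path) -> None:
        pd.DataFrame(
            [{"node": n, "node_type": t} for n, t in self.graph.nodes(data="node_type")]
        ).to_csv(nodes_tsv, sep="\t", index=False)
        pd.DataFrame(
            [{"node_a": u, "node_b": v, "weight": d["weight"], "edge_type": d["edge_type"]}
             for u, v, d in self.graph.edges(data=True)]
        ).to_csv(edges_tsv, sep="\t", index=False)


def seed_vector(network: HeterogeneousNetwork, seeds: list[str]) -> np.ndarray:
    """Uniform restart distribution over the given seed nodes."""
    nodes = network.nodes
    idx = {n: i for i, n in enumerate(nodes)}
    unknown = [s for s in seeds if s not in idx]
    if unknown:
        raise KeyError(f"seed node(s) not in network: {unknown[:10]}")
    if not seeds:
        raise ValueError("empty seed list")
    p0 = np.zeros(len(nodes))
    for s in seeds:
        p0[idx[s]] += 1.0
    return p0 / p0.sum()


@dataclass
class RWRScores:
    nodes: list[str]
    scores: np.ndarray
    restart: float
    n_iterations: int
    residual: float
    by_node: dict[str, float] = field(init=False)

    def __post_init__(self) -> None:
        self.by_node = dict(zip(self.nodes, self.scores))


def _column_normalized(graph: nx.Graph, nodes: list[str]) -> tuple[sp.spmatrix, np.ndarray]:
    adj = nx.to_scipy_sparse_array(graph, nodelist=nodes, weight="weight", dtype=float)
    col_sums = np.asarray(adj.sum(axis=0)).ravel()
    dangling = col_sums == 0
    inv = np.zeros_like(col_sums)
    inv[~dangling] = 1.0 / col_sums[~dangling]
    w = adj @ sp.diags(inv)
    return w.tocsr(), dangling


def rwr(
    network: HeterogeneousNetwork,
    p0: np.ndarray,
    restart: float = 0.7,
    tol: float = 1e-10,
    max_iter: int = 10_000,
) -> RWRScores:
    """Stationary RWR distribution for restart probability ``restart``.

    Iterates p ← (1−r)(W p + dangling-mass · p₀) + r p₀ until the L1
    change drops below ``tol``.  With r = 1 the result is p₀ itself.
    """
    if not (0 < restart <= 1):
        raise ValueError("restart must be in (0, 1]")
    nodes = network.nodes
    p0 = np.asarray(p0, dtype=float)
    if p0.shape != (len(nodes),):
        raise ValueError("seed vector length must match node count")
    if (p0 < 0).any() or not np.isclose(p0.sum(), 1.0):
        raise ValueError("seed vector must be a probability distribution")
    if restart == 1.0:
        return RWRScores(nodes, p0.copy(), restart, 0, 0.0)
    w, dangling = _column_normalized(network.graph, nodes)
    r = restart
    p = p0.copy()
    for it in range(1, max_iter + 1):
        dangling_mass = p[dangling].sum()
        p_new = (1 - r) * (w @ p + dangling_mass * p0) + r * p0
        resid = float(np.abs(p_new - p).sum())
        p = p_new
        if resid < tol:
            return RWRScores(nodes, p, restart, it, resid)
    raise ConvergenceError(
        f"RWR did not converge in {max_iter} iterations (residual {resid:.2e})"
    )


def rwr_direct(network: HeterogeneousNetwork, p0: np.ndarray, restart: float) -> np.ndarray:
    """Closed-form solve p = r(I − (1−r)W̃)⁻¹p₀ with dangling columns
    redirected to p₀.  Dense; intended for small networks and testing."""
    nodes = network.nodes
    w, dangling = _column_normalized(network.graph, nodes)
    w = w.toarray()
    w[:, dangling] += p0[:, None] @ np.ones((1, dangling.sum()))
    n = len(nodes)
    return restart * np.linalg.solve(np.eye(n) - (1 - restart) * w, p0)


def rank_diseases(scores: RWRScores, network: HeterogeneousNetwork) -> pd.DataFrame:
    """Disease nodes sorted by descending RWR score; ties broken
    lexicographically and flagged in the ``tied`` column."""
    diseases = network.nodes_of_type("disease")
    rows = [{"disease": d, "score": scores.by_node[d]} for d in diseases]
    df = pd.DataFrame(rows, columns=["disease", "score"])
    if df.empty:
        return df.assign(rank=pd.Series(dtype=int), tied=pd.Series(dtype=bool))
    df = df.sort_values(["score", "disease"], ascending=[False, True]).reset_index(drop=True)
    df["rank"] = np.arange(1, len(df) + 1)
    df["tied"] = df.duplicated("score", keep=False)
    return df


def write_scores(scores: RWRScores, path: str | Path, tol: float = 1e-10) -> None:
    with open(path, "w") as fh:
        fh.write(f"# restart={scores.restart} tol={tol} "
                 f"iterations={scores.n_iterations} residual={scores.residual:.3e}\n")
        pd.DataFrame({"node": scores.nodes, "score": scores.scores}).to_csv(
            fh, sep="\t", index=False
        )
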