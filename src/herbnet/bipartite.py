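"""Disease–material bipartite network and radar-chart tables.

Every surviving association rule becomes one edge between its disease and
its material, weighted by lift (the specificity of the association) and
annotated with confidence.  Node degree then reads off how broadly a
material is used, or how many materials a disease is treated with.

Radar tables summarize one disease's rules: per-material confidence and
lift plus standardized columns for comparison on a common scale.
"""

from __future__ import annotations

from pathlib import Path

import networkx as nx
import numpy as np
import pandas as pd

from .mining import AssociationRule


class DiseaseNotFoundError(KeyError):
    pass


def build_rule_network(rules: list[AssociationRule]) -> nx.Graph:
    """One node per distinct label, one edge per rule.

    Node attributes: ``kind`` ("disease"/"material") and ``degree``.
    Edge attributes: ``lift`` (weight) and ``confidence``.
    """
    if not rules:
        raise ValueError("no rules to build a network from")
    g = nx.Graph()
    for r in rules:
        g.add_node(r.antecedent, kind="disease")
        g.add_node(r.consequent, kind="material")
        g.add_edge(r.antecedent, r.consequent, lift=r.lift, confidence=r.confidence,
                   weight=r.lift)
    for node, deg in g.degree():
        g.nodes[node]["degree"] = deg
    return g


def is_bipartite_by_kind(g: nx.Graph) -> bool:
    """Check no edge joins two nodes of the same kind (a 2-coloring by the
    ``kind`` attribute)."""
    return all(g.nodes[u]["kind"] != g.nodes[v]["kind"] for u, v in g.edges)


def _standardize(x: np.ndarray, scheme: str) -> np.ndarray:
    if scheme == "zscore":
        sd = x.std(ddof=0)
        if sd == 0:
            return np.zeros_like(x)
        return (x - x.mean()) / sd
    if scheme == "minmax":
        span = x.max() - x.min()
        if span == 0:
            return np.zeros_like(x)
        return (x - x.min()) / span
    raise ValueError(f"unknown standardization scheme {scheme!r}")


def radar_table(
    rules: list[AssociationRule], disease: str, scheme: str = "zscore"
) -> pd.DataFrame:
    """Per-material confidence/lift table for one disease, with
    standardized columns.

    ``scheme``: "zscore" (default; within-table mean 0, sd 1) or "minmax".
    With a single material (zero variance) standardized values are 0.
    Rows sorted by descending confidence.
    """
    sel = [r for r in rules if r.antecedent == disease]
    if not sel:
        raise DiseaseNotFoundError(disease)
    df = pd.DataFrame(
        {
            "material": [r.consequent for r in sel],
            "confidence": [r.confidence for r in sel],
            "lift": [r.lift for r in sel],
        }
    )
    df["standardized_confidence"] = _standardize(df["confidence"].to_numpy(float), scheme)
    df["standardized_lift"] = _standardize(df["lift"].to_numpy(float), scheme)
    df = df.sort_values(
        ["confidence", "lift", "material"], ascending=[False, False, True]
    ).reset_index(drop=True)
    df.attrs["disease"] = disease
    df.attrs["standardization"] = scheme
    return df


def write_network(g: nx.Graph, graphml_path: str | Path | None = None,
                  nodes_tsv: str | Path | None = None,
                  edges_tsv: str | Path | None = None) -> None:
    if graphml_path is not None:
        nx.write_graphml(g, graphml_path)
    if nodes_tsv is not None:
        pd.DataFrame(
            [{"node": n, **attrs} for n, attrs in g.nodes(data=True)]
        ).to_csv(nodes_tsv, sep="\t", index=False)
    if edges_tsv is not None:
        pd.DataFrame(
            [{"disease": u if g.nodes[u]["kind"] == "disease" else v,
              "material": v if g.nodes[u]["kind"] == "disease" else u,
              "lift": d["lift"], "confidence": d["confidence"]}
             for u, v, d in g.edges(data=True)]
        ).to_csv(edges_tsv, sep="\t", index=False)
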