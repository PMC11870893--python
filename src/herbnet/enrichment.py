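"""Hypergeometric over-representation analysis against GMT gene-set
libraries, with Benjamini–Hochberg FDR adjustment.

For a query of n genes drawn from a universe of N, a term of K members
and an observed overlap of k, the raw p-value is the upper hypergeometric
tail P(X ≥ k) — the chance of at least k overlaps if the query were a
uniform random draw.  Adjusted p-values come from the BH step-up
procedure across all terms in the library; terms with adjusted p ≤ α
(default 0.05) are called significantly enriched.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

import pandas as pd
from scipy.stats import hypergeom
from statsmodels.stats.multitest import multipletests

logger = logging.getLogger(__name__)


class GMTFormatError(ValueError):
    pass


@dataclass
class GeneSetLibrary:
    """Named gene sets plus the background universe.

    By default the universe is the union of all set members; pass an
    explicit background list to override.
    """

    sets: dict[str, frozenset[str]]
    universe: frozenset[str]

    @classmethod
    def from_sets(
        cls, sets: dict[str, frozenset[str]], universe: set[str] | None = None
    ) -> "GeneSetLibrary":
        if universe is None:
            universe = set().union(*sets.values()) if sets else set()
        return cls({k: frozenset(v) for k, v in sets.items()}, frozenset(universe))


def read_gmt(path: str | Path, universe: set[str] | None = None) -> GeneSetLibrary:
    """Parse a GMT file (set name, description, members…).

    Duplicate members within a set are collapsed; empty sets are skipped
    with a warning; a duplicated set name is a format error.
    """
    sets: dict[str, frozenset[str]] = {}
    for lineno, line in enumerate(Path(path).read_text().splitlines(), start=1):
        if not line.strip():
            continue
        fields = line.rstrip("\n").split("\t")
        if len(fields) < 2:
            raise GMTFormatError(f"{path}: line {lineno}: expected name, description, members")
        name = fields[0].strip()
        members = frozenset(g.strip() for g in fields[2:] if g.strip())
        if name in sets:
            raise GMTFormatError(f"{path}: line {lineno}: duplicate set name {name!r}")
        if not members:
            logger.warning("%s: line %d: empty set %r skipped", path, lineno, name)
            continue
        sets[name] = members
    return GeneSetLibrary.from_sets(sets, universe)


def write_gmt(library: GeneSetLibrary, path: str | Path) -> None:
    with open(path, "w") as fh:
        for name, members in library.sets.items():
            fh.write("\t".join([name, ""] + sorted(members)) + "\n")


@dataclass(frozen=True)
class EnrichmentResult:
    term: str
    k_overlap: int
    set_size: int
    query_size: int
    universe_size: int
    p_value: float
    adjusted_p: float


def ora(query: list[str] | set[str], library: GeneSetLibrary) -> list[EnrichmentResult]:
    """Over-representation of ``query`` in every set of ``library``.

    Query ids outside the universe are logged and dropped.  Results are
    BH-adjusted across all terms and sorted by (adjusted p, raw p, term).
    """
    query = set(query)
    if not query:
        raise ValueError("empty query")
    mapped = query & library.universe
    unmapped = query - library.universe
    if unmapped:
        logger.info("ora: %d query id(s) not in universe (dropped)", len(unmapped))
    if not mapped:
        raise ValueError("no query gene maps to the library universe")
    n_universe = len(library.universe)
    n_query = len(mapped)
    names, pvals, overlaps, sizes = [], [], [], []
    for name, members in library.sets.items():
        k = len(mapped & members)
        big_k = len(members)
        # upper tail P(X >= k) = sf(k-1)
        p = float(hypergeom.sf(k - 1, n_universe, big_k, n_query))
        names.append(name)
        pvals.append(min(p, 1.0))
        overlaps.append(k)
        sizes.append(big_k)
    _, adjusted, _, _ = multipletests(pvals, method="fdr_bh")
    results = [
        EnrichmentResult(nm, k, K, n_query, n_universe, p, float(adj))
        for nm, k, K, p, adj in zip(names, overlaps, sizes, pvals, adjusted)
    ]
    results.sort(key=lambda r: (r.adjusted_p, r.p_value, r.term))
    return results


def filter_significant(
    results: list[EnrichmentResult], alpha: float = 0.05
) -> list[EnrichmentResult]:
    """Keep results with adjusted p ≤ alpha (inclusive)."""
    return [r for r in results if r.adjusted_p <= alpha]


def results_to_frame(results: list[EnrichmentResult]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "term": r.term,
                "k": r.k_overlap,
                "K": r.set_size,
                "n": r.query_size,
                "N": r.universe_size,
                "p": r.p_value,
                "adj_p": r.adjusted_p,
            }
            for r in results
        ]
    )


def write_results(results: list[EnrichmentResult], path: str | Path) -> None:
    results_to_frame(results).to_csv(path, sep="\t", index=False)
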