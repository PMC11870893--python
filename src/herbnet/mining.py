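"""Apriori frequent-itemset mining and disease ⇒ material association rules.

For a rule X ⇒ Y over N transactions,

    support(X ⇒ Y)    = |X ∧ Y| / N
    confidence(X ⇒ Y) = |X ∧ Y| / |X|
    lift(X ⇒ Y)       = confidence / (|Y| / N)

A lift of 1 means antecedent and consequent are statistically independent;
lift > 1 marks a positive association — in this setting, a material that is
specifically used against that disease rather than broadly prescribed.

Rules are restricted to single-disease antecedents and single-material
consequents (itemsets of size ≤ 2): that is the form every reported
disease–material association takes.  Transactions are sets — presence or
absence only, never dosage.
"""

from __future__ import annotations

from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal
from itertools import combinations
from pathlib import Path

import numpy as np
import pandas as pd

from .prescriptions import BinaryMatrix


class EmptyInputError(ValueError):
    """The transaction matrix has no rows."""


class UndefinedMetricError(ValueError):
    """Metrics are undefined for items never observed (zero marginals)."""


def round_half_up(x: float, ndigits: int = 2) -> float:
    """Round-half-up at ``ndigits`` decimals (report formatting; internal
    values stay full precision)."""
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(float(x))).quantize(q, rounding=ROUND_HALF_UP))


@dataclass(frozen=True)
class MiningConfig:
    """Thresholds and rule shape for the miner.

    ``min_support`` is a fraction of transactions (default 0.003, i.e.
    0.3%); ``min_confidence`` a fraction of antecedent transactions
    (default 0.10).  A rule survives only if it meets or exceeds both.
    """

    min_support: float = 0.003
    min_confidence: float = 0.10
    max_rule_length: int = 2

    def __post_init__(self) -> None:
        if not (0 < self.min_support <= 1):
            raise ValueError("min_support must be in (0, 1]")
        if not (0 < self.min_confidence <= 1):
            raise ValueError("min_confidence must be in (0, 1]")
        if self.max_rule_length < 2:
            raise ValueError("max_rule_length must be ≥ 2")


@dataclass(frozen=True)
class FrequentItemset:
    items: frozenset[str]
    count: int
    support: float


@dataclass(frozen=True)
class AssociationRule:
    """One disease ⇒ material rule with its co-occurrence counts."""

    antecedent: str  # disease
    consequent: str  # material
    n_both: int
    n_ante: int
    n_cons: int
    n_total: int
    support: float
    confidence: float
    lift: float

    def as_dict(self) -> dict:
        return {
            "disease": self.antecedent,
            "material": self.consequent,
            "n_both": self.n_both,
            "n_disease": self.n_ante,
            "n_material": self.n_cons,
            "N": self.n_total,
            "support_pct": round_half_up(100 * self.support),
            "confidence_pct": round_half_up(100 * self.confidence),
            "lift": round_half_up(self.lift),
        }


def compute_metrics(
    n_both: int, n_ante: int, n_cons: int, n_total: int
) -> tuple[float, float, float]:
    """Support, confidence and lift from raw co-occurrence counts."""
    if n_ante <= 0 or n_cons <= 0:
        raise UndefinedMetricError(
            "antecedent/consequent never observed; metrics undefined"
        )
    if not (0 <= n_both <= min(n_ante, n_cons) <= n_total):
        raise ValueError(
            f"inconsistent counts: n_both={n_both}, n_ante={n_ante}, "
            f"n_cons={n_cons}, N={n_total}"
        )
    support = n_both / n_total
    confidence = n_both / n_ante
    lift = confidence / (n_cons / n_total)
    return support, confidence, lift


def apriori(matrix: BinaryMatrix, config: MiningConfig | None = None) -> list[FrequentItemset]:
    """Level-wise frequent-itemset search with downward-closure pruning.

    Returns exactly the itemsets of size ≤ ``max_rule_length`` whose
    support is ≥ ``min_support``.  A size-k candidate is only counted if
    all its (k−1)-subsets are frequent.
    """
    config = config or MiningConfig()
    n = matrix.values.shape[0]
    if n == 0:
        raise EmptyInputError("transaction matrix is empty")
    min_count = config.min_support * n

    cols = matrix.values.astype(bool)
    labels = matrix.column_labels
    counts1 = cols.sum(axis=0)

    out: list[FrequentItemset] = []
    frequent_prev: list[tuple[int, ...]] = []
    for j in range(len(labels)):
        if counts1[j] >= min_count:
            out.append(
                FrequentItemset(frozenset([labels[j]]), int(counts1[j]), counts1[j] / n)
            )
            frequent_prev.append((j,))

    k = 2
    while k <= config.max_rule_length and frequent_prev:
        frequent_k: list[tuple[int, ...]] = []
        if k == 2:
            # every pair of frequent singletons is a valid candidate;
            # count all pairs at once via the Gram matrix
            idx = np.array([t[0] for t in frequent_prev])
            sub = cols[:, idx].astype(np.int32)
            gram = sub.T @ sub
            ai, bi = np.nonzero(np.triu(gram >= min_count, k=1))
            for a, b in zip(ai, bi):
                ja, jb = int(idx[a]), int(idx[b])
                c = int(gram[a, b])
                frequent_k.append(tuple(sorted((ja, jb))))
                out.append(
                    FrequentItemset(frozenset((labels[ja], labels[jb])), c, c / n)
                )
            frequent_k.sort()
        else:
            frequent_set = set(frequent_prev)
            candidates: set[tuple[int, ...]] = set()
            # join step: merge (k-1)-sets sharing a (k-2)-prefix
            for a, b in combinations(sorted(frequent_prev), 2):
                if a[:-1] == b[:-1]:
                    cand = tuple(sorted(set(a) | {b[-1]}))
                    # prune: every (k-1)-subset must be frequent
                    if all(
                        tuple(x for x in cand if x != drop) in frequent_set
                        for drop in cand
                    ):
                        candidates.add(cand)
            for cand in sorted(candidates):
                mask = cols[:, cand[0]]
                for j in cand[1:]:
                    mask = mask & cols[:, j]
                c = int(mask.sum())
                if c >= min_count:
                    frequent_k.append(cand)
                    out.append(
                        FrequentItemset(frozenset(labels[j] for j in cand), c, c / n)
                    )
        frequent_prev = frequent_k
        k += 1
    return out


def generate_rules(
    itemsets: list[FrequentItemset],
    matrix: BinaryMatrix,
    config: MiningConfig | None = None,
) -> list[AssociationRule]:
    """Turn frequent {disease, material} pairs into disease ⇒ material rules.

    Keeps rules with confidence ≥ ``min_confidence``; sorted by disease,
    then descending confidence, descending lift, and material label.
    """
    config = config or MiningConfig()
    n = matrix.values.shape[0]
    kind = dict(zip(matrix.column_labels, matrix.column_kinds))
    counts = {
        next(iter(s.items)): s.count for s in itemsets if len(s.items) == 1
    }
    rules: list[AssociationRule] = []
    for s in itemsets:
        if len(s.items) != 2:
            continue
        a, b = s.items
        if kind[a] == "disease" and kind[b] == "material":
            disease, material = a, b
        elif kind[b] == "disease" and kind[a] == "material":
            disease, material = b, a
        else:
            continue  # disease–disease or material–material pair
        n_ante, n_cons = counts[disease], counts[material]
        support, confidence, lift = compute_metrics(s.count, n_ante, n_cons, n)
        if confidence >= config.min_confidence:
            rules.append(
                AssociationRule(
                    disease, material, s.count, n_ante, n_cons, n,
                    support, confidence, lift,
                )
            )
    rules.sort(key=lambda r: (r.antecedent, -r.confidence, -r.lift, r.consequent))
    return rules


def filter_rules(
    rules: list[AssociationRule], config: MiningConfig | None = None
) -> list[AssociationRule]:
    """Keep rules with support ≥ min_support AND confidence ≥ min_confidence
    (thresholds are inclusive); input order preserved."""
    config = config or MiningConfig()
    return [
        r
        for r in rules
        if r.support >= config.min_support and r.confidence >= config.min_confidence
    ]


def mine_rules(
    matrix: BinaryMatrix, config: MiningConfig | None = None
) -> list[AssociationRule]:
    """Full mining pass: apriori → rule generation → threshold filter."""
    config = config or MiningConfig()
    itemsets = apriori(matrix, config)
    return filter_rules(generate_rules(itemsets, matrix, config), config)


def rules_to_frame(rules: list[AssociationRule]) -> pd.DataFrame:
    return pd.DataFrame([r.as_dict() for r in rules])


def write_rules(rules: list[AssociationRule], path: str | Path) -> None:
    """TSV export mirroring the reported rule tables, plus raw counts."""
    rules_to_frame(rules).to_csv(path, sep="\t", index=False)


def read_rules(path: str | Path) -> list[AssociationRule]:
    df = pd.read_csv(path, sep="\t")
    out = []
    for _, row in df.iterrows():
        s, c, l = compute_metrics(
            int(row["n_both"]), int(row["n_disease"]), int(row["n_material"]), int(row["N"])
        )
        out.append(
            AssociationRule(
                str(row["disease"]), str(row["material"]),
                int(row["n_both"]), int(row["n_disease"]), int(row["n_material"]),
                int(row["N"]), s, c, l,
            )
        )
    return out
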