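"""Synthetic study-scale inputs with known ground truth.

No machine-readable raw data accompanies the study this pipeline
emulates: prescriptions were curated by hand and the interaction
networks come from licensed sources.  Everything the pipeline consumes
is therefore generated here, deterministically, with planted structure
the tests can assert against:

* prescription databases in which chosen disease⇒material rules are
  realized with *exact* co-occurrence counts (never expected values);
* integer count reconstruction from printed (support%, confidence%,
  lift) triples, so published rule metrics become generator inputs;
* scale-free PPI graphs with planted super-hubs;
* heterogeneous compound–target–disease networks with a known
  seed-proximity ordering of the diseases;
* GMT gene-set libraries with one planted enriched set.

Every generator is a pure function of its configuration and seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import networkx as nx
import numpy as np

from .enrichment import GeneSetLibrary
from .mining import round_half_up
from .prescriptions import Prescription, TransactionDB
from .rwr import HeterogeneousNetwork

#: study-scale defaults: 505 prescriptions over 106 diseases and 567
#: medicinal materials
STUDY_N_TRANSACTIONS = 505
STUDY_N_DISEASES = 106
STUDY_N_MATERIALS = 567


class InfeasibleReconstructionError(ValueError):
    """Printed metrics admit no consistent integer counts."""


class InfeasiblePlantingError(ValueError):
    """Planted rules cannot be jointly realized in N transactions."""


@dataclass(frozen=True)
class PlantedRule:
    """Ground truth for one disease⇒material association.

    ``n_both`` transactions contain both labels, ``n_ante`` the disease
    in total, ``n_cons`` the material in total.
    """

    disease: str
    material: str
    n_both: int
    n_ante: int
    n_cons: int

    def __post_init__(self) -> None:
        if not (1 <= self.n_both <= min(self.n_ante, self.n_cons)):
            raise InfeasiblePlantingError(
                f"rule {self.disease}⇒{self.material}: n_both={self.n_both} "
                f"exceeds min(n_ante={self.n_ante}, n_cons={self.n_cons})"
            )


@dataclass
class GeneratorConfig:
    """Configuration for :func:`synth_prescriptions`.

    ``noise_rate`` is the mean number of extra background materials per
    transaction (Poisson); the default of 2.0 makes transactions look like
    multicomponent prescriptions (≈3 materials each) rather than minimal
    pairs.  One disease per transaction by default, matching the form of
    the published rules.
    """

    n_transactions: int = STUDY_N_TRANSACTIONS
    n_diseases: int = STUDY_N_DISEASES
    n_materials: int = STUDY_N_MATERIALS
    planted_rules: list[PlantedRule] = field(default_factory=list)
    noise_rate: float = 2.0
    seed: int = 0


def reconstruct_counts(
    n_total: int, support_pct: float, confidence_pct: float, lift: float
) -> tuple[int, int, int]:
    """Back-solve integer counts from a printed (support%, confidence%,
    lift) triple.

    Rounding is half-up, applied sequentially: n_both from support, then
    n_ante from confidence, then n_cons from lift.  The counts are then
    checked by recomputing all three metrics at 2 dp; any deviation
    beyond 0.005 raises :class:`InfeasibleReconstructionError`.
    """
    if n_total < 1 or support_pct <= 0 or confidence_pct <= 0 or lift <= 0:
        raise ValueError("N and all metrics must be positive")
    n_both = int(round_half_up(support_pct / 100 * n_total, 0))
    n_ante = int(round_half_up(n_both / (confidence_pct / 100), 0))
    n_cons = int(round_half_up((confidence_pct / lift) / 100 * n_total, 0))
    if not (1 <= n_both <= min(n_ante, n_cons)) or max(n_ante, n_cons) > n_total:
        raise InfeasibleReconstructionError(
            f"counts ({n_both}, {n_ante}, {n_cons}) not realizable in N={n_total}"
        )
    support2 = round_half_up(100 * n_both / n_total)
    confidence2 = round_half_up(100 * n_both / n_ante)
    lift2 = round_half_up((n_both / n_ante) / (n_cons / n_total))
    deviations = {
        "support_pct": abs(support2 - round_half_up(support_pct)),
        "confidence_pct": abs(confidence2 - round_half_up(confidence_pct)),
        "lift": abs(lift2 - round_half_up(lift)),
    }
    bad = {k: v for k, v in deviations.items() if v > 0.005}
    if bad:
        raise InfeasibleReconstructionError(
            f"recomputed metrics deviate from inputs beyond 2 dp: {bad} "
            f"(counts {n_both}, {n_ante}, {n_cons})"
        )
    return n_both, n_ante, n_cons


def _disease_blocks(rules: list[PlantedRule], n_transactions: int) -> dict[str, int]:
    """Per-disease transaction budget (n_ante), checked for consistency."""
    blocks: dict[str, int] = {}
    for r in rules:
        if r.disease in blocks and blocks[r.disease] != r.n_ante:
            raise InfeasiblePlantingError(
                f"disease {r.disease!r}: conflicting n_ante values "
                f"({blocks[r.disease]} vs {r.n_ante})"
            )
        blocks[r.disease] = r.n_ante
    if sum(blocks.values()) > n_transactions:
        raise InfeasiblePlantingError(
            f"planted diseases need {sum(blocks.values())} transactions, "
            f"only {n_transactions} available"
        )
    return blocks


def synth_prescriptions(config: GeneratorConfig) -> TransactionDB:
    """Generate a prescription database realizing the planted rules with
    exact counts.

    Layout: each planted disease owns a contiguous block of n_ante
    transactions (one disease per transaction); each of its rules places
    the material in the first n_both transactions of the block.  Material
    shortfalls to reach n_cons are placed outside that disease's block.
    Remaining transactions carry background diseases; background
    materials are spread round-robin (so the whole catalog is used) plus
    Poisson(noise_rate) extras.
    """
    rng = np.random.default_rng(config.seed)
    n = config.n_transactions
    rules = config.planted_rules
    blocks = _disease_blocks(rules, n)

    planted_diseases = list(blocks)
    planted_materials = sorted({r.material for r in rules})
    n_bg_diseases = config.n_diseases - len(planted_diseases)
    n_bg_materials = config.n_materials - len(planted_materials)
    if n_bg_diseases < 0 or n_bg_materials < 0:
        raise InfeasiblePlantingError("catalog sizes smaller than planted label sets")
    bg_diseases = [f"disease_{i:03d}" for i in range(n_bg_diseases)]
    bg_materials = [f"material_{i:03d}" for i in range(n_bg_materials)]

    diseases_per_tx: list[set[str]] = [set() for _ in range(n)]
    materials_per_tx: list[set[str]] = [set() for _ in range(n)]

    # planted disease blocks
    start = 0
    block_range: dict[str, range] = {}
    for d in planted_diseases:
        block_range[d] = range(start, start + blocks[d])
        for t in block_range[d]:
            diseases_per_tx[t].add(d)
        start += blocks[d]
    background_tx = list(range(start, n))

    # planted co-occurrences: first n_both transactions of the block
    for r in rules:
        for t in list(block_range[r.disease])[: r.n_both]:
            materials_per_tx[t].add(r.material)

    # top up each material to its global n_cons outside conflicting blocks
    totals: dict[str, int] = {}
    rules_by_material: dict[str, list[PlantedRule]] = {}
    for r in rules:
        rules_by_material.setdefault(r.material, []).append(r)
    for material, mrules in rules_by_material.items():
        n_cons = {r.n_cons for r in mrules}
        if len(n_cons) > 1:
            raise InfeasiblePlantingError(
                f"material {material!r}: conflicting n_cons values {sorted(n_cons)}"
            )
        placed = sum(r.n_both for r in mrules)
        deficit = n_cons.pop() - placed
        if deficit < 0:
            raise InfeasiblePlantingError(
                f"material {material!r}: planted co-occurrences exceed n_cons"
            )
        forbidden = {r.disease for r in mrules}
        candidates = background_tx + [
            t for d in planted_diseases if d not in forbidden for t in block_range[d]
        ]
        free = [t for t in candidates if material not in materials_per_tx[t]]
        if deficit > len(free):
            raise InfeasiblePlantingError(
                f"material {material!r}: cannot place {deficit} extra occurrence(s)"
            )
        for t in free[:deficit]:
            materials_per_tx[t].add(material)
        totals[material] = placed + deficit

    # background diseases cycled over the leftover transactions
    for i, t in enumerate(background_tx):
        if bg_diseases:
            diseases_per_tx[t].add(bg_diseases[i % len(bg_diseases)])
        else:
            diseases_per_tx[t].add(planted_diseases[i % len(planted_diseases)])

    # round-robin coverage so every background material occurs at least once
    if bg_materials:
        for j, m in enumerate(bg_materials):
            materials_per_tx[j % n].add(m)
        # Poisson extras at the noise rate
        if config.noise_rate > 0:
            extras = rng.poisson(config.noise_rate, size=n)
            for t in range(n):
                for m in rng.choice(len(bg_materials), size=min(extras[t], len(bg_materials)), replace=False):
                    materials_per_tx[t].add(bg_materials[m])

    # every transaction needs ≥1 material
    for t in range(n):
        if not materials_per_tx[t]:
            materials_per_tx[t].add(bg_materials[t % len(bg_materials)] if bg_materials
                                    else planted_materials[t % len(planted_materials)])

    prescriptions = [
        Prescription(f"rx{t + 1:04d}", frozenset(diseases_per_tx[t]), frozenset(materials_per_tx[t]))
        for t in range(n)
    ]
    return TransactionDB(prescriptions)


def synth_ppi(
    n_nodes: int = 2000,
    attachment: int = 3,
    n_super_hubs: int = 5,
    hub_wiring_fraction: float = 0.3,
    seed: int = 0,
) -> tuple[nx.Graph, list[str]]:
    """Scale-free PPI stand-in with planted super-hubs.

    A Barabási–Albert graph of ``n_nodes`` proteins; ``n_super_hubs``
    extra nodes are each wired to a ``hub_wiring_fraction`` random sample
    of the proteins so they land in the top 1% of both degree and
    eigenvector centrality.  Returns (graph, planted hub ids).
    """
    if not (1 <= attachment < n_nodes):
        raise ValueError("need n_nodes > attachment ≥ 1")
    rng = np.random.default_rng(seed)
    base = nx.barabasi_albert_graph(n_nodes, attachment, seed=int(rng.integers(2**31)))
    g = nx.relabel_nodes(base, {i: f"G{i:05d}" for i in base.nodes})
    hubs = [f"HUB{i:02d}" for i in range(n_super_hubs)]
    k = max(1, int(hub_wiring_fraction * n_nodes))
    protein_ids = sorted(g.nodes)
    for h in hubs:
        targets = rng.choice(len(protein_ids), size=k, replace=False)
        for t in targets:
            g.add_edge(h, protein_ids[t])
    nx.set_edge_attributes(g, {e: {"sources": {"synthetic"}} for e in g.edges})
    return g, hubs


def synth_heterogeneous(
    ppi: nx.Graph,
    n_compounds: int = 10,
    n_diseases: int = 8,
    n_seed_targets: int = 20,
    compound_degree: int = 5,
    seed: int = 0,
) -> tuple[HeterogeneousNetwork, list[str], list[str]]:
    """Layer compounds and diseases onto a protein graph.

    Disease ``D01`` attaches to all ``n_seed_targets`` seed proteins,
    ``D02`` to a strict prefix of them, and so on (nested subsets), so
    that the RWR ranking from those seeds is provably D01 > D02 > … .
    The last disease gets no edges at all (a reachability control).
    Returns (network, seed target ids, diseases in ground-truth order).
    """
    if n_diseases < 2:
        raise ValueError("need at least 2 diseases")
    rng = np.random.default_rng(seed)
    net = HeterogeneousNetwork()
    proteins = sorted(ppi.nodes)
    for p in proteins:
        net.add_node(p, "protein")
    for u, v in ppi.edges:
        net.add_edge(u, v)

    seeds = [proteins[i] for i in rng.choice(len(proteins), size=n_seed_targets, replace=False)]
    for c in range(n_compounds):
        cid = f"C{c:03d}"
        net.add_node(cid, "compound")
        for t in rng.choice(len(proteins), size=compound_degree, replace=False):
            net.add_edge(cid, proteins[t])

    diseases = [f"D{i:02d}" for i in range(1, n_diseases + 1)]
    # nested prefixes of the seed list, strictly shrinking; last disease isolated
    sizes = np.linspace(n_seed_targets, 1, n_diseases - 1).round().astype(int)
    sizes = np.maximum.accumulate(sizes[::-1])[::-1]  # enforce monotone non-increasing
    prev = None
    for d, size in zip(diseases[:-1], sizes):
        size = int(size)
        if prev is not None and size >= prev:
            size = prev - 1
        if size < 1:
            raise ValueError("too many diseases for the number of seed targets")
        net.add_node(d, "disease")
        for s in seeds[:size]:
            net.add_edge(d, s)
        prev = size
    net.add_node(diseases[-1], "disease")  # deliberately unreachable
    return net, seeds, diseases


def synth_gmt(
    universe_size: int = 200,
    n_sets: int = 20,
    set_size: tuple[int, int] = (10, 40),
    query_size: int = 25,
    planted_overlap: int = 15,
    seed: int = 0,
) -> tuple[GeneSetLibrary, list[str], str]:
    """GMT library with one planted enriched set.

    The emitted query shares exactly ``planted_overlap`` genes with the
    planted set; the other sets are uniform random draws.  Returns
    (library, query, planted set name).
    """
    if planted_overlap > min(query_size, set_size[1]):
        raise ValueError("planted overlap larger than query or set size")
    rng = np.random.default_rng(seed)
    genes = [f"g{i:04d}" for i in range(universe_size)]
    planted_size = max(set_size[0], planted_overlap)
    perm = rng.permutation(universe_size)
    planted = [genes[i] for i in perm[:planted_size]]
    query = planted[:planted_overlap] + [
        genes[i] for i in perm[planted_size : planted_size + (query_size - planted_overlap)]
    ]
    sets = {"PLANTED_SET": frozenset(planted)}
    for s in range(n_sets - 1):
        size = int(rng.integers(set_size[0], set_size[1] + 1))
        members = rng.choice(universe_size, size=size, replace=False)
        sets[f"RANDOM_SET_{s:02d}"] = frozenset(genes[i] for i in members)
    library = GeneSetLibrary.from_sets(sets, universe=set(genes))
    return library, query, "PLANTED_SET"
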