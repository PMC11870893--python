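# Methods

## Transaction model and rule mining

A prescription is a set-valued transaction: ≥1 disease label and ≥1
material label, the two namespaces disjoint. Quantities and dosages are
never modeled — the binary matrix records presence only. Labels are
trimmed and internal whitespace collapsed, but case is preserved
(botanical binomials and authority strings are case-sensitive by
convention). Multi-valued TSV cells use ";" as the delimiter so that
authority strings containing commas ("Calpurnia aurea (Ait.) Benth.")
round-trip.

Mining is classic level-wise apriori. Size-1 counts come from column
sums; size-2 counts from the Gram matrix of the frequent columns (every
pair of frequent singletons is a candidate at k = 2); deeper levels —
off by default, `max_rule_length = 2` — use prefix-join candidate
generation with subset pruning. Rules are restricted to one disease
antecedent ⇒ one material consequent, the only form the published rule
tables contain. Metrics follow the standard definitions
(support = n_both/N, confidence = n_both/n_ante,
lift = confidence/(n_cons/N)); thresholds are inclusive (≥).

Threshold defaults are min support 0.003 and min confidence 0.10. The
source analysis states its thresholds as "0.3 and 10%"; read as a
support of 0.30 it would exclude every published rule (their supports
are 0.40–1.58%), so 0.3 *percent* is the only consistent reading. Both
values are configurable.

Reported percentages are rendered at 2 decimals with round-half-up
(`decimal.Decimal`), matching the published tables; internal values stay
full precision. Sort order for rule output — disease, then descending
confidence, descending lift, material label — is a tie-break convention
of this package; the source tables specify none.

The disease-frequency filter (`filter_diseases`, default
`min_prescriptions = 3`) implements the stated exclusion of diseases
with too few prescriptions; the original cutoff is unpublished, so the
default is this package's choice and is logged with every removal.

## Count reconstruction

`reconstruct_counts` inverts the three metric equations at N = 505:
n_both = round(support·N), then n_ante = round(n_both/confidence), then
n_cons = round(confidence/lift·N), each rounded half-up in that
sequence. The counts are accepted only if recomputing all three metrics
reproduces the printed values at 2 dp; otherwise the row is reported
infeasible, never silently adjusted. All 91 published rule rows pass
this check row-by-row. Rows are *not* jointly realizable: a material
shared between diseases is printed with inconsistent implied marginals
(e.g. one shared material implies n_cons = 23 under one disease and 6
under another), because each row was evidently computed independently.
Reconstruction therefore always targets one row = one database.

## Synthetic prescriptions

The generator's defaults are the study conditions: 505 transactions,
106 diseases, 567 materials, one disease per transaction (the rule form
of the published table). Planted rules are realized exactly: each
planted disease owns a contiguous block of n_ante transactions, the
material occupies the first n_both of them, and the remaining
n_cons − n_both occurrences are placed outside that disease's block
(background transactions first). Conflicting plants — a disease with
two different n_ante values, a shared material with inconsistent
n_cons, or blocks exceeding N — raise an infeasibility error listing
the conflict.

Background transactions cycle through the unused disease labels;
background materials are spread round-robin so the whole catalog is
exercised, plus Poisson-distributed extras at `noise_rate` (default
2.0 per transaction, making transactions look like multicomponent
prescriptions of ~3 materials rather than minimal pairs). All
randomness flows from one `numpy` generator seeded from the config, so
reruns are byte-identical.

What the generator does *not* emulate: real botanical vocabularies,
correlated material co-usage (materials that travel together in
practice), multi-disease prescriptions (available but off by default),
and curation noise such as synonym variants. Passing tests demonstrate
the pipeline's arithmetic and recovery behavior, not robustness to
real-world label noise.

## PPI centrality and hubs

Sources merge as unordered pairs into a simple undirected graph;
self-loops are dropped (logged), and per-edge source provenance is kept.
"Degree centrality" is the raw incident-edge count, not the normalized
variant — the published percentile thresholds (243/101/67 on a
17,358-node graph) are only sensible as raw counts.

Eigenvector centrality is the principal eigenvector of the adjacency
matrix, computed by power iteration on the largest connected component
and L2-normalized; nodes outside that component score 0. The iteration
runs on A + I: the shift leaves the eigenvector unchanged but makes the
dominant eigenvalue strictly dominant on bipartite(-ish) graphs, whose
±λ₁ pairs would otherwise prevent convergence. Convergence is successive
normalized iterates within `tol` (default 1e-10, max 10,000 iterations);
non-convergence raises with the residual.

Top-percentile membership uses ⌈f·|V|⌉ ranked descending with ties
included, so a top-1% set can exceed 1% of nodes. Hubs = query targets
in the top-f sets of *both* measures; the hub set is monotone in f.

## Random walk with restart

The walker moves to a uniformly random neighbor (column-normalized
adjacency; edge weights supported) with probability 1 − r and restarts
at the seed distribution with probability r. Dangling columns redirect
to the seed distribution, which preserves total probability exactly (the
score vector sums to 1 at every iteration). Convergence is L1 change
< 1e-10 (geometric rate ≤ 1 − r); r = 1 short-circuits to the seed
vector. Default r = 0.7, the common network-propagation choice — the
source analysis does not state its restart parameter, so rankings on
real data are reproducible in form, not value. A dense closed-form
solver (`rwr_direct`) exists for small networks and serves as the
independent oracle in tests. Type-stratified transition weighting is
deliberately not implemented beyond per-edge weights; nothing in the
source defines one.

Disease ranking sorts disease-type nodes by descending score, breaking
ties lexicographically and flagging them.

## Enrichment

Standard over-representation analysis: raw p = hypergeometric upper
tail P(X ≥ k) (`scipy.stats.hypergeom.sf`), BH adjustment across all
library terms (`statsmodels`), significance at adjusted p ≤ 0.05
inclusive. The universe defaults to the union of library members and is
configurable to an explicit background. The external enrichment service
the source analysis called (with an unexplained "cut-off of 0.5") is
not reproduced; hypergeometric + BH is the computation its reported
"adjusted P ≤ 0.05" results imply.

## Radar standardization

The published radar charts show "standardized values" without a
formula. Default here: within-table z-scores (mean 0, sd 1 across the
disease's materials); min–max scaling to [0, 1] is available via
`scheme="minmax"`; zero-variance columns standardize to 0. The scheme
used is recorded in the table metadata.

## Problem sizes and numerical choices

Tests and the acceptance script run everything at the sizes the methods
were designed for: rule mining at the full 505 × 673 study scale;
oracle-equivalence sweeps on 500 random databases of ≤ 80 transactions
and ≤ 15 items (exhaustive enumeration stays trivially cheap there);
RWR vs dense linear solve on ≤ 30-node networks; eigenvector centrality
vs dense eigendecomposition on ≤ 50-node graphs, with planted-hub
recovery at 2,000 nodes; the permutation check of the hypergeometric
tail uses 200,000 label permutations on a 200-gene universe. These
sizes make every independent oracle exact or tightly bounded while
keeping a full run fast.

## Known limitations

- Joint realization of a full published rule table in one database is
  impossible in general (inconsistent shared-material marginals, see
  above); the generator detects and refuses such conflicts rather than
  approximating.
- Apriori is in-memory and quadratic in frequent singletons at k = 2 —
  ample at study scale, not engineered for millions of transactions.
- Eigenvector centrality on a graph whose largest component is a
  single edge is degenerate (both nodes score 1/√2); callers should not
  interpret centrality on near-empty graphs.
- Identifier mapping (gene symbol ↔ Entrez, botanical synonymy) is out
  of scope; inputs are taken as given.
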