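# herbnet

Association-rule mining and network pharmacology for multicomponent
traditional-medicine prescriptions.

Traditional healing systems — Ethiopian herbal medicine being the
motivating case — treat diseases with multicomponent prescriptions that
vary across practitioners and regions. Given a corpus of prescriptions,
each recording the disease treated and the medicinal materials
combined, `herbnet` identifies which materials are *consistently* and
*specifically* associated with which diseases, and carries the analysis
on into molecular networks: which protein targets of a material's
phytochemicals are network hubs, which diseases lie closest to those
targets, and which pathways the targets are enriched in.

It is a library first (see `examples/`), with a thin `herbnet` CLI for
shell-driven runs.

## The computations

**Rule mining.** Each prescription is one transaction over disjoint
disease and material item namespaces, encoded in a binary
presence/absence matrix. Apriori level-wise search (with
downward-closure pruning) finds frequent itemsets; each frequent
{disease, material} pair becomes a rule X ⇒ Y scored by

- support(X ⇒ Y) = |X ∧ Y| / N,
- confidence(X ⇒ Y) = |X ∧ Y| / |X|,
- lift(X ⇒ Y) = confidence / (|Y| / N),

with defaults min support 0.3% and min confidence 10% (both inclusive).
Lift 1 is statistical independence; high lift with modest confidence
marks a material *specific* to a disease, high confidence with low lift
a broadly used material.

**Networks.** Surviving rules form a bipartite disease–material graph
(edge weight = lift); per-disease radar tables report confidence, lift
and within-table standardized values. Multi-source PPI edge lists merge
into one simple graph; hub targets are query genes in the top 1% of
*both* raw degree and eigenvector centrality (power iteration on the
largest component, L2-normalized). A random walk with restart
(p ← (1−r)·W·p + r·p₀, column-normalized W, default r = 0.7) ranks
disease nodes of a heterogeneous compound–target–disease network by
proximity to therapeutic-target seeds. Over-representation of a target
list in GMT gene-set libraries uses the hypergeometric upper tail with
Benjamini–Hochberg adjustment (significant at adjusted p ≤ 0.05).

**Synthetic data.** No machine-readable raw data accompanies the study
this package emulates, so `herbnet.synthetic` generates every input at
study scale (505 prescriptions, 106 diseases, 567 materials; ~2,000-node
scale-free PPI graphs; heterogeneous networks; GMT libraries) with
*planted, exact* ground truth — including `reconstruct_counts`, which
back-solves published (support %, confidence %, lift) triples into the
integer co-occurrence counts that generated them.

## Worked example

```sh
python examples/mine_rules.py
```

```
database: 505 prescriptions, 106 diseases, 567 materials
8 rule(s) above thresholds (support ≥ 0.3%, confidence ≥ 10%)

wound => Rumex abyssinicus Jacq.
  counts: both=7, disease=39, material=17, N=505
  support    = 1.39 %
  confidence = 17.95 %
  lift       = 5.33
```

Seven of 505 prescriptions pair the disease with the material; 17.95%
of wound prescriptions include *Rumex abyssinicus* Jacq., 5.33× the
rate expected if the two were independent — a strong, specific
association. The other examples cover count reconstruction from
published tables, radar tables, PPI hub extraction, RWR disease
prioritization and enrichment.

CLI equivalents:

```sh
herbnet simulate prescriptions --seed 1 --out-dir sim/
herbnet mine --input sim/prescriptions.tsv --out rules.tsv
herbnet run --seed 1 --out-dir full_run/     # whole pipeline, synthetic inputs
```

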