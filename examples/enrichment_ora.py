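"""Over-representation analysis of a gene list against a GMT library.

Generates a 200-gene universe with 20 gene sets, one of which shares 15
of the query's 25 genes (far above the ~3 expected by chance).  The
hypergeometric upper-tail test with Benjamini–Hochberg adjustment calls
exactly that planted set significant: its adjusted p is many orders of
magnitude below 0.05, while the random sets stay near 1.
"""

from herbnet import filter_significant, ora, results_to_frame, synth_gmt

library, query, planted = synth_gmt(
    universe_size=200, n_sets=20, query_size=25, planted_overlap=15, seed=11
)
print(f"library: {len(library.sets)} sets over a {len(library.universe)}-gene universe")
print(f"query: {len(query)} genes; planted enriched set: {planted}\n")

results = ora(query, library)
print(results_to_frame(results).head(5).to_string(index=False))

significant = filter_significant(results, alpha=0.05)
print(f"\nsignificant at adjusted p <= 0.05: {[r.term for r in significant]}")
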