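"""Rank diseases by random-walk-with-restart proximity to seed targets.

Builds a heterogeneous compound–target–disease network on top of a
300-protein graph.  Diseases are wired to nested subsets of 20 seed
targets (D01 to all of them, each later disease to fewer; the last one
to none), so the proximity ordering is known in advance.  RWR from the
seed targets (restart 0.7) recovers that ordering; the isolated disease
scores exactly 0 because the walker can never reach it.
"""

from herbnet import rank_diseases, rwr, seed_vector, synth_heterogeneous, synth_ppi

ppi, _ = synth_ppi(n_nodes=300, seed=7)
network, seeds, truth = synth_heterogeneous(ppi, n_diseases=6, n_seed_targets=20, seed=7)
print(f"network: {len(network.nodes)} nodes "
      f"({len(network.nodes_of_type('protein'))} proteins, "
      f"{len(network.nodes_of_type('compound'))} compounds, "
      f"{len(network.nodes_of_type('disease'))} diseases)")
print(f"seeds: {len(seeds)} therapeutic targets; expected order: {truth}")

scores = rwr(network, seed_vector(network, seeds), restart=0.7)
print(f"converged in {scores.n_iterations} iterations "
      f"(residual {scores.residual:.1e}, total probability {scores.scores.sum():.12f})\n")

ranking = rank_diseases(scores, network)
print(ranking.to_string(index=False))
print("\nhigher score = closer to the therapeutic-target seeds;"
      " the zero-score disease is unreachable from them.")
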