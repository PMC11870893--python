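"""Bipartite rule network and radar-style summary tables.

Builds association rules for two diseases sharing one material,
assembles the disease–material bipartite network (edges weighted by
lift), and prints a radar table for one disease: per-material confidence
and lift plus within-table z-scores, the standardized columns a radar
chart would display.  A material with standardized lift well above its
standardized confidence is specific to the disease; the reverse pattern
marks a broadly used material.
"""

from herbnet import (
    build_rule_network,
    compute_metrics,
    radar_table,
    reconstruct_counts,
)
from herbnet.mining import AssociationRule

# leprosy rules as printed: (material, support %, confidence %, lift)
leprosy_rows = [
    ("Plumbago zeylanica L.", 0.99, 33.33, 5.26),
    ("Withania somnifera (L.) Dunal", 0.59, 20.00, 5.05),
    ("Sylvicapra grimmia", 0.40, 13.33, 16.83),
    ("Maesa lanceolata Forssk.", 0.40, 13.33, 22.44),
    ("Ranunculus multifidus Forssk.", 0.40, 13.33, 22.44),
]

rules = []
for material, s, c, l in leprosy_rows:
    counts = reconstruct_counts(505, s, c, l)
    metrics = compute_metrics(*counts, 505)
    rules.append(AssociationRule("Leprosy", material, *counts, 505, *metrics))

g = build_rule_network(rules)
print(f"bipartite network: {g.number_of_nodes()} nodes, {g.number_of_edges()} edges")

table = radar_table(rules, "Leprosy")
print("\nradar table for Leprosy (z-score standardization):")
print(table.to_string(index=False, float_format=lambda x: f"{x:8.3f}"))
print("\nhigh standardized lift + low standardized confidence ⇒ leprosy-specific material;")
print("the reverse ⇒ a material also used against many other conditions.")
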