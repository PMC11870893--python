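"""Back-solve printed rule metrics into integer counts and verify them.

Published rule tables report (support %, confidence %, lift) at two
decimals over N = 505 prescriptions.  These three numbers pin down the
integer co-occurrence counts: n_both from support, n_ante from
confidence, n_cons from lift.  The example reconstructs the counts for
four reported rules, realizes each in its own synthetic database, runs
the miner, and shows the printed triple coming back out unchanged.
"""

from herbnet import (
    GeneratorConfig,
    PlantedRule,
    encode_matrix,
    mine_rules,
    reconstruct_counts,
    round_half_up,
    synth_prescriptions,
)

published = [
    ("Wound", "Rumex abyssinicus Jacq.", 1.39, 17.95, 5.33),
    ("Rabies", "Cucumis ficifolius A. Rich.", 1.39, 43.75, 4.80),
    ("Menorrhagia", "Protea gaguedi Gmel.", 0.40, 14.29, 36.07),
    ("Leprosy", "Maesa lanceolata Forssk.", 0.40, 13.33, 22.44),
]

for disease, material, s, c, l in published:
    counts = reconstruct_counts(505, s, c, l)
    db = synth_prescriptions(
        GeneratorConfig(planted_rules=[PlantedRule(disease, material, *counts)], seed=0)
    )
    hit = next(
        r for r in mine_rules(encode_matrix(db))
        if (r.antecedent, r.consequent) == (disease, material)
    )
    print(f"{disease} => {material}")
    print(f"  printed  : support {s} %, confidence {c} %, lift {l}")
    print(f"  counts   : n_both={counts[0]}, n_disease={counts[1]}, n_material={counts[2]}")
    print(f"  re-mined : support {round_half_up(100 * hit.support)} %, "
          f"confidence {round_half_up(100 * hit.confidence)} %, "
          f"lift {round_half_up(hit.lift)}\n")
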