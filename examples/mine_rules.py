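"""Mine disease ⇒ material association rules from a prescription database.

Builds a synthetic 505-prescription database in which the association
wound ⇒ Rumex abyssinicus Jacq. is planted with exact co-occurrence
counts (7 joint, 39 wound, 17 material occurrences), runs the apriori
miner, and prints the recovered rule.  Support is the fraction of all
prescriptions containing both labels, confidence the fraction of wound
prescriptions that include the material, and lift the confidence over
the material's marginal rate — lift 5.33 means the material appears 5.3×
more often in wound prescriptions than chance would predict.
"""

from herbnet import (
    GeneratorConfig,
    PlantedRule,
    encode_matrix,
    mine_rules,
    round_half_up,
    synth_prescriptions,
)

rule = PlantedRule("wound", "Rumex abyssinicus Jacq.", n_both=7, n_ante=39, n_cons=17)
db = synth_prescriptions(GeneratorConfig(planted_rules=[rule], seed=1))
print(f"database: {len(db)} prescriptions, "
      f"{len(db.disease_catalog)} diseases, {len(db.material_catalog)} materials")

rules = mine_rules(encode_matrix(db))
print(f"{len(rules)} rule(s) above thresholds (support ≥ 0.3%, confidence ≥ 10%)")

hit = next(r for r in rules if r.antecedent == "wound")
print(f"\n{hit.antecedent} => {hit.consequent}")
print(f"  counts: both={hit.n_both}, disease={hit.n_ante}, material={hit.n_cons}, N={hit.n_total}")
print(f"  support    = {round_half_up(100 * hit.support)} %")
print(f"  confidence = {round_half_up(100 * hit.confidence)} %")
print(f"  lift       = {round_half_up(hit.lift)}")
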