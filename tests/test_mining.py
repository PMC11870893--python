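"""Apriori, rule metrics, and threshold filtering against brute-force
enumeration and the published rule values."""

import numpy as np
import pytest

from herbnet import (
    AssociationRule,
    MiningConfig,
    Prescription,
    TransactionDB,
    apriori,
    compute_metrics,
    encode_matrix,
    filter_rules,
    generate_rules,
    mine_rules,
    round_half_up,
)
from herbnet.mining import EmptyInputError, UndefinedMetricError
from herbnet.synthetic import GeneratorConfig, PlantedRule, synth_prescriptions

from conftest import brute_force_itemsets, brute_force_rules, random_db


class TestComputeMetrics:
    @pytest.mark.parametrize(
        "counts, expected",
        [
            # published rules, counts back-solved from the printed triples
            ((7, 39, 17, 505), (1.39, 17.95, 5.33)),   # wound ⇒ R. abyssinicus
            ((7, 16, 46, 505), (1.39, 43.75, 4.80)),   # rabies ⇒ C. ficifolius
            ((2, 14, 2, 505), (0.40, 14.29, 36.07)),   # menorrhagia ⇒ P. gaguedi
            ((2, 18, 2, 505), (0.40, 11.11, 28.06)),   # aphrodisiacs ⇒ Habenaria
            ((3, 27, 8, 505), (0.59, 11.11, 7.01)),    # mental ⇒ T. foenum-graecum
        ],
    )
    def test_published_metric_triples(self, counts, expected):
        support, confidence, lift = compute_metrics(*counts)
        assert round_half_up(100 * support) == expected[0]
        assert round_half_up(100 * confidence) == expected[1]
        assert round_half_up(lift) == expected[2]

    def test_universal_consequent_gives_unit_confidence_and_lift(self):
        for k in (1, 5, 20):
            _, confidence, lift = compute_metrics(k, k, 100, 100)
            assert confidence == 1.0
            assert lift == 1.0

    def test_unseen_item_is_undefined(self):
        with pytest.raises(UndefinedMetricError):
            compute_metrics(0, 0, 5, 10)

    def test_metric_identities_on_random_counts(self, rng):
        for _ in range(200):
            n = int(rng.integers(2, 200))
            n_a = int(rng.integers(1, n + 1))
            n_c = int(rng.integers(1, n + 1))
            n_b = int(rng.integers(0, min(n_a, n_c) + 1))
            s, c, l = compute_metrics(n_b, n_a, n_c, n)
            assert l * (n_c / n) == pytest.approx(c)
            assert s <= c + 1e-12
            assert s <= n_c / n + 1e-12


class TestApriori:
    def test_universal_item_has_support_one(self):
        db = TransactionDB(
            [
                Prescription(f"p{i}", frozenset({"d"}), frozenset({"A"}))
                for i in range(5)
            ]
        )
        itemsets = apriori(encode_matrix(db), MiningConfig(min_support=0.5))
        singletons = {frozenset(["A"]): s for s in itemsets if s.items == {"A"}}
        assert singletons[frozenset(["A"])].support == 1.0

    def test_empty_matrix_rejected(self):
        from herbnet.prescriptions import BinaryMatrix

        m = BinaryMatrix(np.zeros((0, 2)), [], ["d1", "m1"], ["disease", "material"])
        with pytest.raises(EmptyInputError):
            apriori(m)

    def test_matches_exhaustive_enumeration(self, rng):
        for _ in range(20):
            db = random_db(rng, int(rng.integers(5, 40)), 4, 6)
            config = MiningConfig(min_support=0.1, min_confidence=0.01)
            got = {s.items: s.count for s in apriori(encode_matrix(db), config)}
            expected = brute_force_itemsets(db, 0.1)
            assert got == expected

    def test_downward_closure(self, rng):
        db = random_db(rng, 50, 5, 8)
        config = MiningConfig(min_support=0.15)
        itemsets = apriori(encode_matrix(db), config)
        supports = {s.items: s.support for s in itemsets}
        for s in itemsets:
            if len(s.items) == 2:
                for item in s.items:
                    assert frozenset([item]) in supports
                    assert supports[frozenset([item])] >= s.support


class TestGenerateRules:
    def test_full_confidence_when_consequent_always_present(self):
        db = TransactionDB(
            [
                Prescription("p1", frozenset({"d"}), frozenset({"A"})),
                Prescription("p2", frozenset({"d"}), frozenset({"A", "B"})),
                Prescription("p3", frozenset({"x"}), frozenset({"A"})),
            ]
        )
        m = encode_matrix(db)
        config = MiningConfig(min_support=0.01, min_confidence=0.01)
        rules = generate_rules(apriori(m, config), m, config)
        rule = next(r for r in rules if r.antecedent == "d" and r.consequent == "A")
        assert rule.confidence == 1.0

    def test_independence_gives_lift_near_one(self, rng):
        # disease and material drawn independently at fixed rates
        n = 4000
        prescriptions = []
        for t in range(n):
            ds = {"d"} if rng.random() < 0.5 else {"other"}
            ms = {"M"} if rng.random() < 0.5 else {"m_alt"}
            prescriptions.append(Prescription(f"p{t}", frozenset(ds), frozenset(ms)))
        m = encode_matrix(TransactionDB(prescriptions))
        config = MiningConfig(min_support=0.01, min_confidence=0.01)
        rules = generate_rules(apriori(m, config), m, config)
        rule = next(r for r in rules if r.antecedent == "d" and r.consequent == "M")
        assert rule.lift == pytest.approx(1.0, abs=0.1)

    def test_rule_output_identical_to_brute_force(self, rng):
        for _ in range(20):
            db = random_db(rng, int(rng.integers(10, 60)), 3, 5)
            config = MiningConfig(min_support=0.05, min_confidence=0.10)
            got = {
                (r.antecedent, r.consequent): (r.n_both, r.n_ante, r.n_cons)
                for r in mine_rules(encode_matrix(db), config)
            }
            assert got == brute_force_rules(db, 0.05, 0.10)

    def test_sorted_by_disease_then_descending_confidence(self, rng):
        db = random_db(rng, 50, 4, 8)
        config = MiningConfig(min_support=0.02, min_confidence=0.02)
        rules = mine_rules(encode_matrix(db), config)
        keys = [(r.antecedent, -r.confidence, -r.lift, r.consequent) for r in rules]
        assert keys == sorted(keys)


class TestFilterRules:
    def _rule(self, n_both, n_ante, n_cons, n=100):
        s, c, l = compute_metrics(n_both, n_ante, n_cons, n)
        return AssociationRule("d", "m", n_both, n_ante, n_cons, n, s, c, l)

    def test_support_exactly_at_threshold_is_kept(self):
        rule = self._rule(5, 10, 20, 100)  # support 0.05
        assert filter_rules([rule], MiningConfig(min_support=0.05, min_confidence=0.1)) == [rule]

    def test_confidence_below_threshold_dropped(self):
        rule = self._rule(9, 100, 20, 100)  # confidence 0.09
        assert filter_rules([rule], MiningConfig(min_support=0.01, min_confidence=0.10)) == []

    def test_matches_brute_force_predicate_scan(self, rng):
        rules = []
        for _ in range(100):
            n = 200
            n_a = int(rng.integers(1, n))
            n_c = int(rng.integers(1, n))
            n_b = int(rng.integers(1, min(n_a, n_c) + 1))
            rules.append(self._rule(n_b, n_a, n_c, n))
        config = MiningConfig(min_support=0.02, min_confidence=0.25)
        expected = [
            r for r in rules
            if r.support >= 0.02 and r.confidence >= 0.25
        ]
        assert filter_rules(rules, config) == expected


class TestPlantedRecovery:
    def test_planted_rule_recovered_with_exact_counts(self):
        rule = PlantedRule("wound", "Rumex abyssinicus Jacq.", 7, 39, 17)
        db = synth_prescriptions(GeneratorConfig(planted_rules=[rule], seed=7))
        mined = mine_rules(encode_matrix(db))
        hit = next(
            r for r in mined
            if r.antecedent == "wound" and r.consequent == "Rumex abyssinicus Jacq."
        )
        assert (hit.n_both, hit.n_ante, hit.n_cons, hit.n_total) == (7, 39, 17, 505)
        assert round_half_up(100 * hit.support) == 1.39
        assert round_half_up(100 * hit.confidence) == 17.95
        assert round_half_up(hit.lift) == 5.33
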