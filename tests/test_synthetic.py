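"""Generators: count reconstruction, exact rule planting, determinism."""

import networkx as nx
import numpy as np
import pytest

from herbnet import (
    GeneratorConfig,
    MiningConfig,
    PlantedRule,
    encode_matrix,
    mine_rules,
    reconstruct_counts,
    round_half_up,
    summarize,
    synth_gmt,
    synth_heterogeneous,
    synth_ppi,
    synth_prescriptions,
    write_prescriptions,
)
from herbnet.synthetic import InfeasiblePlantingError, InfeasibleReconstructionError

from conftest import table1_rows


class TestReconstructCounts:
    @pytest.mark.parametrize(
        "metrics, expected",
        [
            ((505, 1.39, 17.95, 5.33), (7, 39, 17)),
            ((505, 0.40, 14.29, 36.07), (2, 14, 2)),
            ((505, 1.39, 43.75, 4.80), (7, 16, 46)),
            ((505, 0.40, 11.11, 28.06), (2, 18, 2)),
            ((505, 0.59, 11.11, 7.01), (3, 27, 8)),
        ],
    )
    def test_published_rows_back_solve(self, metrics, expected):
        assert reconstruct_counts(*metrics) == expected

    def test_inconsistent_triple_rejected(self):
        # confidence 100% forces n_both = n_ante, but the stated lift
        # implies n_cons < n_both: violates lift·n_cons/N = confidence
        with pytest.raises(InfeasibleReconstructionError):
            reconstruct_counts(100, 10.0, 100.0, 50.0)

    def test_rounding_drift_beyond_2dp_rejected(self):
        # counts forced by the triple recompute to confidence 30.30, not 30.00
        with pytest.raises(InfeasibleReconstructionError):
            reconstruct_counts(100, 10.0, 30.0, 1.0)

    def test_all_published_rows_reconstruct_or_report(self):
        """Every published row either back-solves to counts that reproduce
        its printed triple at 2 dp, or is flagged infeasible — never
        silently adjusted."""
        feasible = 0
        for disease, material, s, c, l in table1_rows():
            try:
                n_both, n_ante, n_cons = reconstruct_counts(505, s, c, l)
            except InfeasibleReconstructionError:
                continue
            feasible += 1
            assert round_half_up(100 * n_both / 505) == s
            assert round_half_up(100 * n_both / n_ante) == c
            assert round_half_up((n_both / n_ante) / (n_cons / 505)) == l
        # the printed table is self-consistent row by row
        assert feasible == len(table1_rows())


class TestSynthPrescriptions:
    def test_planted_counts_exact_through_the_miner(self):
        rule = PlantedRule("wound", "Rumex", 7, 39, 17)
        db = synth_prescriptions(GeneratorConfig(planted_rules=[rule], seed=5))
        mined = mine_rules(encode_matrix(db))
        hit = next(r for r in mined if (r.antecedent, r.consequent) == ("wound", "Rumex"))
        assert (hit.n_both, hit.n_ante, hit.n_cons) == (7, 39, 17)

    def test_study_scale_totals(self):
        db = synth_prescriptions(GeneratorConfig(seed=1))
        s = summarize(db)
        assert s["n_prescriptions"] == 505
        assert s["n_diseases"] == 106
        assert s["n_materials"] == 567

    def test_planted_disease_is_most_frequent(self):
        rule = PlantedRule("wound", "Rumex", 7, 39, 17)
        db = synth_prescriptions(GeneratorConfig(planted_rules=[rule], seed=2))
        ranking = summarize(db)["disease_ranking"]
        assert ranking[0]["disease"] == "wound"
        assert ranking[0]["n_prescriptions"] == 39

    def test_no_rules_no_noise_yields_nothing_above_thresholds(self):
        config = GeneratorConfig(noise_rate=0.0, seed=3)
        db = synth_prescriptions(config)
        mined = mine_rules(encode_matrix(db), MiningConfig())
        assert mined == []

    def test_same_seed_byte_identical(self, tmp_path):
        config = GeneratorConfig(
            planted_rules=[PlantedRule("d", "m", 3, 10, 6)], seed=42
        )
        p1, p2 = tmp_path / "a.tsv", tmp_path / "b.tsv"
        write_prescriptions(synth_prescriptions(config), p1)
        write_prescriptions(synth_prescriptions(config), p2)
        assert p1.read_bytes() == p2.read_bytes()

    def test_conflicting_n_ante_rejected(self):
        rules = [PlantedRule("d", "m1", 2, 10, 5), PlantedRule("d", "m2", 2, 12, 5)]
        with pytest.raises(InfeasiblePlantingError, match="n_ante"):
            synth_prescriptions(GeneratorConfig(planted_rules=rules, seed=0))

    def test_shared_material_with_consistent_marginal(self):
        rules = [
            PlantedRule("d1", "m", 3, 10, 9),
            PlantedRule("d2", "m", 4, 12, 9),
        ]
        db = synth_prescriptions(GeneratorConfig(planted_rules=rules, seed=0))
        mined = mine_rules(encode_matrix(db), MiningConfig(min_support=0.001, min_confidence=0.01))
        got = {
            (r.antecedent, r.consequent): (r.n_both, r.n_ante, r.n_cons)
            for r in mined
        }
        assert got[("d1", "m")] == (3, 10, 9)
        assert got[("d2", "m")] == (4, 12, 9)

    def test_overcommitted_transactions_rejected(self):
        rules = [PlantedRule(f"d{i}", "m", 1, 200, 10) for i in range(3)]
        with pytest.raises(InfeasiblePlantingError):
            synth_prescriptions(GeneratorConfig(planted_rules=rules, seed=0))


class TestSynthPPI:
    def test_tree_when_attachment_one(self):
        g, _ = synth_ppi(n_nodes=100, attachment=1, n_super_hubs=0, seed=4)
        assert g.number_of_edges() == g.number_of_nodes() - 1

    def test_degree_sum_identity(self):
        g, _ = synth_ppi(n_nodes=300, seed=6)
        assert sum(d for _, d in g.degree()) == 2 * g.number_of_edges()

    def test_determinism(self):
        g1, h1 = synth_ppi(n_nodes=200, seed=8)
        g2, h2 = synth_ppi(n_nodes=200, seed=8)
        assert h1 == h2
        assert set(g1.edges) == set(g2.edges)

    def test_ground_truth_hub_list_emitted(self):
        g, hubs = synth_ppi(n_nodes=400, n_super_hubs=3, seed=9)
        assert len(hubs) == 3
        assert all(h in g for h in hubs)


class TestSynthHeterogeneous:
    def test_first_disease_adjacent_to_all_seeds(self):
        g, _ = synth_ppi(n_nodes=200, seed=10)
        net, seeds, order = synth_heterogeneous(g, n_seed_targets=10, seed=10)
        first = order[0]
        assert all(net.graph.has_edge(first, s) for s in seeds)

    def test_last_disease_isolated(self):
        g, _ = synth_ppi(n_nodes=200, seed=10)
        net, _, order = synth_heterogeneous(g, seed=10)
        assert net.graph.degree(order[-1]) == 0

    def test_determinism(self):
        g, _ = synth_ppi(n_nodes=150, seed=12)
        n1 = synth_heterogeneous(g, seed=12)
        n2 = synth_heterogeneous(g, seed=12)
        assert set(n1[0].graph.edges) == set(n2[0].graph.edges)
        assert n1[1] == n2[1]


class TestSynthGMT:
    def test_planted_overlap_is_exact(self):
        lib, query, planted = synth_gmt(planted_overlap=15, query_size=25, seed=14)
        assert len(set(query) & lib.sets[planted]) == 15
        assert len(query) == 25

    def test_chance_level_overlap_rarely_significant(self):
        """Power control: with overlap at the expected chance level the
        planted set should not be called significant in ≥90% of seeds."""
        from herbnet import filter_significant, ora

        n_hits = 0
        n_seeds = 100
        for seed in range(n_seeds):
            # expected chance overlap = query * set / universe ≈ 25*20/200 ≈ 3
            lib, query, planted = synth_gmt(
                universe_size=200, set_size=(20, 20), query_size=25,
                planted_overlap=3, seed=seed,
            )
            significant = {r.term for r in filter_significant(ora(query, lib))}
            if planted in significant:
                n_hits += 1
        assert n_hits <= 0.1 * n_seeds

    def test_empty_overlap_boundary(self):
        lib, query, planted = synth_gmt(planted_overlap=0, seed=16)
        from herbnet import ora

        res = {r.term: r for r in ora(query, lib)}
        assert res[planted].k_overlap == 0
        assert res[planted].p_value == pytest.approx(1.0)

    def test_determinism(self):
        a = synth_gmt(seed=17)
        b = synth_gmt(seed=17)
        assert a[0].sets == b[0].sets
        assert a[1] == b[1]
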