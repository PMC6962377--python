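"""Interaction scoring: substitutions, classification, node scores, aggregation."""

import numpy as np
import pandas as pd
import pytest

from mechanomir.interaction import (
    PATHWAY_GROUPS,
    RuleConfigError,
    SubstitutionRule,
    aggregate,
    apply_substitutions,
    build_interaction_matrix,
    classify_pathway,
    compare_groups,
    consolidate_exports,
    count_intersections,
    export_heatmaps,
    score_node,
)
from mechanomir.synthetic import generate_pathway_db

from conftest import make_matrix_from_values


class TestSubstitutions:
    def test_default_rules_map_reported_ids(self):
        out = apply_substitutions(["mir-548-AJ2", "mir-181-A1-HG", "mir-999"])
        assert out == ["hsa-mir-548aj", "hsa-mir-181a", "mir-999"]

    def test_conflicting_rules_rejected(self):
        rules = [
            SubstitutionRule("x", "a", "host_gene"),
            SubstitutionRule("x", "b", "host_gene"),
        ]
        with pytest.raises(RuleConfigError):
            apply_substitutions(["x"], rules)

    def test_unknown_reason_rejected(self):
        with pytest.raises(RuleConfigError):
            SubstitutionRule("x", "y", "typo")


class TestClassifyPathway:
    @pytest.mark.parametrize(
        "name,group",
        [
            ("cell projection morphogenesis", "Motility"),
            ("Apoptotic Process", "Apoptosis"),
            ("zzz unmatched zzz", "Miscellaneous"),
            ("pathways in cancer", "Cancer"),
            ("ATM Signaling Network in Development and Disease", "Canonical"),
            ("Mismatch repair", "DNA Repair"),
            ("Cell Cycle Checkpoints", "Cell Cycle"),
        ],
    )
    def test_keyword_rules(self, name, group):
        assert classify_pathway(name) == group

    def test_total_and_stable(self):
        rng = np.random.default_rng(0)
        names = ["".join(chr(97 + c) for c in rng.integers(0, 26, 12))
                 for _ in range(50)]
        first = [classify_pathway(n) for n in names]
        second = [classify_pathway(n) for n in names]
        assert first == second
        assert all(g in PATHWAY_GROUPS for g in first)


class TestScoreNode:
    def test_hand_enumerated_example(self, toy_de_map):
        node = score_node({"A", "B", "C", "D"}, 0.01, toy_de_map)
        assert node.percent_overlap == 50.0
        assert node.cumulative_abs_fc == pytest.approx(5.5)
        assert node.intersects

    def test_no_de_targets(self):
        node = score_node({"X", "Y"}, 0.01, {"A": 3.0})
        assert node.percent_overlap == 0.0
        assert node.cumulative_abs_fc == 0.0
        assert node.n_de_targets == 0

    def test_all_targets_de(self):
        node = score_node({"A", "B"}, 0.2, {"A": 2.1, "B": -4.0})
        assert node.percent_overlap == 100.0
        assert not node.intersects  # enrichment p >= 0.05

    def test_empty_targets_rejected(self):
        with pytest.raises(ValueError):
            score_node(set(), 0.01, {})

    def test_matches_brute_force_oracle_on_synthetic_db(self):
        """Every node of a full synthetic DB agrees with an independent
        set-arithmetic recomputation."""
        de_map = {f"GENE{i:05d}": (-1) ** i * (2.1 + i % 5) for i in range(0, 200, 3)}
        db = generate_pathway_db(4, ["m1", "m2", "m3"], 12, seed=13)
        matrix = build_interaction_matrix(db.exports, de_map)
        assert len(matrix.nodes) == len(db.exports)  # no duplicates here
        by_key = {(r.mirna, r.pathway): r for r in matrix.nodes.itertuples()}
        for row in db.exports.itertuples():
            # oracle: plain python, no shared code
            hits = [t for t in row.targets if t in de_map]
            exp_overlap = 100.0 * len(hits) / len(row.targets)
            exp_cum = sum(abs(de_map[t]) for t in hits)
            got = by_key[(row.mirna, row.pathway)]
            assert got.percent_overlap == pytest.approx(exp_overlap)
            assert got.cumulative_abs_fc == pytest.approx(exp_cum)
            assert got.intersects == (row.enrichment_p < 0.05)
            assert got.group == db.truth_groups[row.pathway]


class TestConsolidation:
    def test_duplicate_pathway_merged(self):
        rows = pd.DataFrame([
            {"mirna": "m", "pathway": "p", "database": "KEGG",
             "enrichment_p": 0.02, "targets": frozenset({"A", "B"})},
            {"mirna": "m", "pathway": "p", "database": "Reactome",
             "enrichment_p": 0.005, "targets": frozenset({"B", "C"})},
        ])
        out = consolidate_exports(rows)
        assert len(out) == 1
        rec = out.iloc[0]
        assert rec["targets"] == frozenset({"A", "B", "C"})
        assert rec["enrichment_p"] == 0.005
        assert rec["database"] == "KEGG;Reactome"

    def test_consolidation_order_invariance(self, toy_exports, toy_de_map):
        m1 = build_interaction_matrix(toy_exports, toy_de_map)
        m2 = build_interaction_matrix(
            toy_exports.sample(frac=1.0, random_state=1), toy_de_map
        )
        a1 = aggregate(m1, "pathway_group", "percent_overlap")
        a2 = aggregate(m2, "pathway_group", "percent_overlap")
        pd.testing.assert_frame_equal(a1, a2)


class TestMatrixAndCounts:
    def test_toy_matrix_shape_and_counts(self, toy_exports, toy_de_map):
        matrix = build_interaction_matrix(toy_exports, toy_de_map)
        assert len(matrix.nodes) == 6
        assert count_intersections(matrix, "cell projection morphogenesis") == 3
        assert count_intersections(matrix, "pathways in cancer") == 0
        with pytest.raises(KeyError):
            count_intersections(matrix, "no such pathway")

    def test_intersection_count_by_enumeration(self):
        db = generate_pathway_db(2, [f"m{i}" for i in range(5)], 6, seed=3)
        matrix = build_interaction_matrix(db.exports, {})
        for pathway in matrix.pathway_order:
            expected = sum(
                1 for r in db.exports.itertuples()
                if r.pathway == pathway and r.enrichment_p < 0.05
            )
            assert count_intersections(matrix, pathway) == expected


class TestAggregate:
    def test_simple_mean(self):
        matrix = make_matrix_from_values({"Cancer": [0.0, 50.0]})
        agg = aggregate(matrix, "pathway_group", "percent_overlap")
        assert agg.set_index("pathway_group").loc["Cancer", "mean"] == 25.0

    def test_empty_groups_reported_with_zero_n(self):
        matrix = make_matrix_from_values({"Cancer": [10.0, 20.0]})
        agg = aggregate(matrix, "pathway_group", "cumulative_abs_fc").set_index(
            "pathway_group"
        )
        assert set(agg.index) == set(PATHWAY_GROUPS)
        assert agg.loc["Motility", "n"] == 0
        assert np.isnan(agg.loc["Motility", "mean"])

    def test_construction_contrast_between_groups(self):
        """High-FC/low-overlap Motility vs the reverse in Cancer shows up in
        the group means with the expected ordering."""
        rng = np.random.default_rng(7)
        de_map = {f"G{i}": 12.0 for i in range(10)}  # big |FC|
        de_map |= {f"g{i}": 2.1 for i in range(90)}  # small |FC|
        rows = []
        for i in range(6):
            # Motility: few targets DE, but the big-FC ones
            rows.append({"mirna": f"m{i}", "pathway": "cell projection morphogenesis",
                         "database": "GO-BP", "enrichment_p": 0.01,
                         "targets": frozenset({f"G{i}", "x1", "x2", "x3", "x4"})})
            # Cancer: most targets DE, small FC
            rows.append({"mirna": f"m{i}", "pathway": "pathways in cancer",
                         "database": "KEGG", "enrichment_p": 0.01,
                         "targets": frozenset({f"g{i}", f"g{i+10}", f"g{i+20}",
                                               f"g{i+30}", "x1"})})
        matrix = build_interaction_matrix(pd.DataFrame(rows), de_map)
        ov = aggregate(matrix, "pathway_group", "percent_overlap").set_index(
            "pathway_group"
        )
        fc = aggregate(matrix, "pathway_group", "cumulative_abs_fc").set_index(
            "pathway_group"
        )
        assert fc.loc["Motility", "mean"] > fc.loc["Cancer", "mean"]
        assert ov.loc["Motility", "mean"] < ov.loc["Cancer", "mean"]

    def test_relevance_grouping_requires_annotation(self, toy_exports, toy_de_map):
        matrix = build_interaction_matrix(toy_exports, toy_de_map)
        with pytest.raises(ValueError, match="relevance"):
            aggregate(matrix, "relevance_group", "percent_overlap")


class TestCompareGroups:
    def test_separated_groups_significant(self):
        rng = np.random.default_rng(1)
        matrix = make_matrix_from_values({
            "Cancer": list(rng.normal(10, 1, 8)),
            "Motility": list(rng.normal(60, 1, 8)),
        })
        res = compare_groups(matrix, "pathway_group", "percent_overlap")
        assert res.anova_p < 0.05
        assert res.tukey["reject"].all()
        assert res.letters["Cancer"] != res.letters["Motility"]

    def test_identical_groups_skipped(self):
        matrix = make_matrix_from_values(
            {"Cancer": [5.0, 5.0], "Motility": [5.0, 5.0], "Apoptosis": [5.0, 5.0]}
        )
        res = compare_groups(matrix, "pathway_group", "percent_overlap")
        assert res.skipped is not None

    def test_type_one_error_rate_near_nominal(self):
        """Two groups from the same distribution: significant in <= 10% of
        seeded simulations at alpha = 0.05."""
        rng = np.random.default_rng(42)
        false_pos = 0
        n_runs = 100
        for _ in range(n_runs):
            matrix = make_matrix_from_values({
                "Cancer": list(rng.normal(10, 3, 10)),
                "Motility": list(rng.normal(10, 3, 10)),
            })
            res = compare_groups(matrix, "pathway_group", "percent_overlap")
            if res.anova_p < 0.05:
                false_pos += 1
        assert false_pos <= 0.10 * n_runs

    def test_three_identical_distributions_all_ns(self):
        rng = np.random.default_rng(5)
        matrix = make_matrix_from_values({
            g: list(rng.normal(20, 4, 10)) for g in ("Cancer", "Motility", "Apoptosis")
        })
        res = compare_groups(matrix, "pathway_group", "percent_overlap")
        letters = set(res.letters.values())
        assert len(letters) == 1  # all share one letter


class TestHeatmaps:
    def test_three_files_with_expected_shape(self, tmp_path, toy_exports, toy_de_map):
        db = generate_pathway_db(1, ["m1", "m2", "m3"], 4, seed=2)
        matrix = build_interaction_matrix(db.exports, toy_de_map)
        paths = export_heatmaps(matrix, tmp_path)
        assert set(paths) == {"intersections", "percent_overlap", "cumulative_abs_fc"}
        for metric, path in paths.items():
            df = pd.read_csv(path, sep="\t", index_col=0)
            assert df.shape == (3, 7)

    def test_round_trip_bit_exact(self, tmp_path, toy_exports, toy_de_map):
        matrix = build_interaction_matrix(toy_exports, toy_de_map)
        paths = export_heatmaps(matrix, tmp_path)
        for metric, path in paths.items():
            df = pd.read_csv(path, sep="\t", index_col=0)
            view = matrix.metric_view(metric)
            assert np.array_equal(df.to_numpy(), view.to_numpy())

    def test_empty_de_list_zeroes_overlap_and_fc(self, tmp_path, toy_exports):
        matrix = build_interaction_matrix(toy_exports, {})
        assert (matrix.metric_view("percent_overlap").to_numpy() == 0).all()
        assert (matrix.metric_view("cumulative_abs_fc").to_numpy() == 0).all()

    def test_relevance_blocked_row_order(self, toy_exports, toy_de_map):
        relevance = {"hsa-mir-1": "unsubstantiated", "hsa-mir-2": "gbm_relevant",
                     "hsa-mir-3": "gbm_relevant"}
        matrix = build_interaction_matrix(toy_exports, toy_de_map,
                                          relevance=relevance)
        assert matrix.mirna_order == ["hsa-mir-2", "hsa-mir-3", "hsa-mir-1"]
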