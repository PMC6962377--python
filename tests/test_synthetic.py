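"""Synthetic-data generators: ground truth, reproducibility, distributions."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from mechanomir.presets import ConditionPreset, MixtureSpec, preset_names
from mechanomir.synthetic import (
    generate_ar_sample,
    generate_expression_set,
    generate_pathway_db,
    generate_wound_pair,
    load_mirna_panel,
    load_mrna_panel,
    mirna_relevance_annotation,
)
from mechanomir.interaction import classify_pathway


def _preset_with_mixture(mix):
    return ConditionPreset(
        name="test", cell_line="X", pressure=0.0,
        wound_closure_ctrl=0.5, wound_closure_exp=0.5,
        elongated_fraction=0.5, mixture=mix,
    )


class TestARSample:
    def test_degenerate_component_collapses_to_ar_2(self):
        """mu=0, sigma -> 0+ makes every draw exp(0)=1, i.e. AR = 2."""
        mix = MixtureSpec(weights=(1.0,), mus=(0.0,), sigmas=(1e-9,))
        ars = generate_ar_sample(_preset_with_mixture(mix), 5, seed=0)
        assert ars == pytest.approx(np.full(5, 2.0), abs=1e-6)

    def test_support_and_reproducibility(self):
        a1 = generate_ar_sample("LN229-23Pa", 1000, seed=3)
        a2 = generate_ar_sample("LN229-23Pa", 1000, seed=3)
        a3 = generate_ar_sample("LN229-23Pa", 1000, seed=4)
        assert np.array_equal(a1, a2)
        assert not np.array_equal(a1, a3)
        assert a1.min() > 1.0

    def test_elongated_fraction_of_sample(self):
        """The 23 Pa sample reproduces ~39.1% elongated within binomial error."""
        ars = generate_ar_sample("LN229-23Pa", 2000, seed=11)
        frac = np.mean(ars >= 2.0)
        # 4 sigma binomial band around the preset's exact 0.391
        assert frac == pytest.approx(0.391, abs=4 * np.sqrt(0.391 * 0.609 / 2000))

    @pytest.mark.parametrize("name", preset_names())
    def test_empirical_cdf_converges_to_mixture_cdf(self, name):
        """KS distance to the analytic mixture CDF < 0.03 at n = 10^4."""
        from mechanomir.presets import get_preset

        p = get_preset(name)
        ars = generate_ar_sample(p, 10_000, seed=5)

        def cdf(x):
            x = np.asarray(x, dtype=float)
            out = np.zeros_like(x)
            for w, mu, s in zip(p.mixture.weights, p.mixture.mus, p.mixture.sigmas):
                with np.errstate(divide="ignore"):
                    z = (np.log(np.maximum(x - 1.0, 1e-300)) - mu) / s
                out += w * stats.norm.cdf(z)
            return out

        d = stats.kstest(ars, cdf).statistic
        assert d < 0.03

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            generate_ar_sample("LN229-23Pa", 0)
        from mechanomir.presets import PresetError

        with pytest.raises(PresetError):
            generate_ar_sample("nope", 10)


class TestWoundPair:
    @pytest.mark.parametrize("closure,expected_ratio", [(0.0, 1.0), (1.0, 0.0)])
    def test_extreme_closures(self, closure, expected_ratio):
        pair = generate_wound_pair(gap_width=300, closure=closure, texture_seed=0,
                                   image_shape=(200, 300))
        assert pair.true_area_final == pair.true_area_initial * expected_ratio

    def test_closure_is_exact_up_to_pixel_rounding(self):
        pair = generate_wound_pair(gap_width=500, closure=0.570, texture_seed=0,
                                   image_shape=(400, 500))
        ratio = pair.true_area_final / pair.true_area_initial
        h = pair.image_initial.shape[0]
        assert ratio == pytest.approx(0.430, abs=h / pair.true_area_initial)
        assert pair.image_initial.shape == pair.image_final.shape
        assert pair.image_initial.dtype == np.uint16

    def test_closure_out_of_range(self):
        with pytest.raises(ValueError):
            generate_wound_pair(closure=-0.1)
        with pytest.raises(ValueError):
            generate_wound_pair(gap_width=0)


class TestExpressionSet:
    def _brute_force_de_count(self, records: pd.DataFrame) -> int:
        """Independent re-scan of the emitted table, no shared code path."""
        n = 0
        for _, row in records.iterrows():
            if (row["p_value"] < 0.05 and row["fdr"] < 0.05
                    and abs(row["fold_change"]) > 2.0):
                n += 1
        return n

    def test_truth_count_matches_brute_force_rescan(self):
        es = generate_expression_set(200, 30, seed=8)
        assert len(es.truth_de_ids) == 30
        assert self._brute_force_de_count(es.records) == 30
        # truth ids are exactly the passing ids
        passing = {
            r.feature_id for r in es.records.itertuples()
            if r.p_value < 0.05 and r.fdr < 0.05 and abs(r.fold_change) > 2
        }
        assert passing == set(es.truth_de_ids)

    def test_zero_de(self):
        es = generate_expression_set(100, 0, seed=1)
        assert self._brute_force_de_count(es.records) == 0
        assert es.truth_de_ids == frozenset()

    def test_feature_types_mixed(self):
        es = generate_expression_set(500, 50, seed=2, mirna_fraction=0.2)
        counts = es.records["feature_type"].value_counts()
        assert set(counts.index) <= {"coding", "precursor_mirna"}
        assert counts["precursor_mirna"] > 0

    def test_preconditions(self):
        with pytest.raises(ValueError):
            generate_expression_set(10, 20)
        with pytest.raises(ValueError):
            generate_expression_set(10, 2, fc_range=(1.5, 3.0))


class TestFixturePanels:
    def test_mirna_panel_is_the_27_mirna_table(self):
        panel = load_mirna_panel()
        assert len(panel) == 27
        assert (panel["feature_type"] == "precursor_mirna").all()
        assert (panel["fold_change"].abs() > 2).all()
        assert panel["gbm_relevant"].sum() == 11
        fc = dict(zip(panel["feature_id"], panel["fold_change"]))
        assert fc["mir-548-AJ2"] == pytest.approx(-2.16)
        assert fc["let-7i"] == pytest.approx(-3.35)
        assert fc["mir-6787"] == pytest.approx(4.95)

    def test_mrna_panel_values(self):
        panel = load_mrna_panel()
        rec = panel.set_index("feature_id")
        assert rec.loc["STC1", "fold_change"] == pytest.approx(12.79)
        assert rec.loc["STC1", "fdr"] == pytest.approx(0.0002)
        assert rec.loc["FOXN2", "fold_change"] == pytest.approx(-2.63)
        assert (rec["fold_change"].abs() > 2).all()

    def test_relevance_annotation_two_classes(self):
        ann = mirna_relevance_annotation()
        assert len(ann) == 27
        assert set(ann.values()) == {"gbm_relevant", "unsubstantiated"}


class TestPathwayDB:
    def test_classifier_round_trip(self):
        db = generate_pathway_db(1, ["hsa-mir-1"], 5, seed=0)
        assert len(db.truth_groups) == 7
        for name, group in db.truth_groups.items():
            assert classify_pathway(name) == group

    def test_node_count_by_enumeration(self):
        db = generate_pathway_db(
            3, ["m1", "m2", "m3"], 5, seed=1, pathways_per_mirna=2
        )
        assert len(db.exports) == 6  # 3 miRNAs x 2 pathways
        assert (db.exports["enrichment_p"] < 0.05).all()
        assert db.exports["targets"].map(len).eq(5).all()

    def test_empty_mirna_list_rejected(self):
        with pytest.raises(ValueError):
            generate_pathway_db(1, [], 5)

    def test_reproducible(self):
        d1 = generate_pathway_db(2, ["m1", "m2"], 4, seed=9)
        d2 = generate_pathway_db(2, ["m1", "m2"], 4, seed=9)
        pd.testing.assert_frame_equal(d1.exports, d2.exports)
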