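import numpy as np
import pandas as pd
import pytest

from tada.gene_model import (
    GeneParams,
    GeneRecord,
    InvalidParameterError,
    StudyDesign,
    category_fractions_from_sibling_counts,
    compute_rates,
    frame_to_records,
    preprocess_counts,
    records_to_frame,
    scale_mutation_rate,
)
from conftest import make_record


class TestComputeRates:
    def test_zero_exposure_gives_zero_rates(self):
        with pytest.warns(UserWarning, match="no samples"):
            design = StudyDesign(n_trios=0, n_cases=0, n_controls=0, categories=("LoF",))
        r = compute_rates(GeneParams(gamma=1.0, q=1e-3, mu=1e-6), design)
        assert r.r_dn == r.r_case_arm == r.r_ctrl_arm == 0.0

    def test_null_symmetry_of_arms(self):
        # under gamma = 1 the transmitted and nontransmitted arms are exchangeable
        design = StudyDesign(n_trios=500, categories=("LoF",))
        r = compute_rates(GeneParams(gamma=1.0, q=3.7e-4, mu=1e-6), design)
        assert r.r_case_arm == pytest.approx(r.r_ctrl_arm)
        assert r.e1 == r.e0 == 1000

    def test_asd_scale_arithmetic(self, asd_design):
        r = compute_rates(GeneParams(gamma=20.0, q=5e-5, mu=1e-6), asd_design)
        assert r.r_dn == pytest.approx(2 * 932 * 1e-6 * 20)
        assert r.e1 == 3734 and r.e0 == 3604

    @pytest.mark.parametrize("factor", [2.0, 5.0])
    def test_rates_linear_in_parameters(self, factor, trio_design):
        base = compute_rates(GeneParams(gamma=3.0, q=1e-4, mu=1e-6), trio_design)
        mu_scaled = compute_rates(GeneParams(gamma=3.0, q=1e-4, mu=factor * 1e-6), trio_design)
        q_scaled = compute_rates(GeneParams(gamma=3.0, q=factor * 1e-4, mu=1e-6), trio_design)
        n_scaled = compute_rates(
            GeneParams(gamma=3.0, q=1e-4, mu=1e-6),
            StudyDesign(n_trios=int(factor * 1000), categories=("LoF",)),
        )
        assert mu_scaled.r_dn == pytest.approx(factor * base.r_dn)
        assert q_scaled.r_case_arm == pytest.approx(factor * base.r_case_arm)
        assert q_scaled.r_ctrl_arm == pytest.approx(factor * base.r_ctrl_arm)
        assert n_scaled.r_dn == pytest.approx(factor * base.r_dn)

    def test_invalid_mu_rejected(self, trio_design):
        with pytest.raises(InvalidParameterError):
            compute_rates(GeneParams(gamma=1.0, q=1e-3, mu=0.0), trio_design)

    def test_large_q_warns(self):
        with pytest.warns(UserWarning, match="rare-variant"):
            GeneParams(gamma=1.0, q=0.2, mu=1e-6)


class TestMutationRateScaling:
    def test_lof_fraction_from_sibling_counts(self):
        # 34 LoF among 461 de novo SNVs in unaffected siblings
        assert scale_mutation_rate(1e-5, "LoF") == pytest.approx(7.375e-7, rel=1e-3)

    def test_zero_total_rate(self):
        assert scale_mutation_rate(0.0, "LoF") == 0.0

    def test_fractions_exceeding_one_rejected(self):
        with pytest.raises(InvalidParameterError, match="> 1"):
            scale_mutation_rate(1e-5, "LoF", {"LoF": 0.5, "Mis3": 0.6})

    def test_unknown_category_lists_known(self):
        with pytest.raises(KeyError, match="LoF"):
            scale_mutation_rate(1e-5, "Mis3", {"LoF": 0.1})

    def test_fractions_from_counts(self):
        fr = category_fractions_from_sibling_counts({"LoF": 34, "Mis3": 100}, 461)
        assert fr["LoF"] == pytest.approx(34 / 461)
        assert fr["Mis3"] == pytest.approx(100 / 461)


class TestPreprocess:
    def _table(self, rows):
        return pd.DataFrame(rows, columns=["gene", "category", "origin", "frequency", "individual"])

    def test_control_lof_filter_drops_gene(self, trio_design):
        rows = [("A", "LoF", "control", 0.0, f"c{i}") for i in range(11)]
        rows += [("B", "LoF", "denovo", 0.0, "t1")]
        recs = preprocess_counts(self._table(rows), trio_design)
        assert [r.gene_id for r in recs] == ["B"]

    def test_common_variants_excluded(self, trio_design):
        rows = [
            ("A", "LoF", "denovo", 0.02, "t1"),
            ("A", "LoF", "denovo", 0.001, "t2"),
        ]
        recs = preprocess_counts(self._table(rows), trio_design, freq_threshold=0.01)
        assert recs[0].x_dn["LoF"] == 1

    def test_denovo_counting(self, trio_design):
        rows = [("G", "LoF", "denovo", 0.0, f"t{i}") for i in range(3)]
        recs = preprocess_counts(self._table(rows), trio_design)
        assert recs[0].x_dn["LoF"] == 3

    def test_carrier_collapse_per_individual(self, trio_design):
        # two qualifying case variants in the same person count once
        rows = [
            ("G", "LoF", "case", 0.0, "p1"),
            ("G", "LoF", "case", 0.0, "p1"),
            ("G", "LoF", "case", 0.0, "p2"),
        ]
        recs = preprocess_counts(self._table(rows), trio_design)
        assert recs[0].x_case["LoF"] == 2

    def test_unknown_origin_rejected(self, trio_design):
        rows = [("G", "LoF", "sibling", 0.0, "s1")]
        with pytest.raises(ValueError, match="origin"):
            preprocess_counts(self._table(rows), trio_design)

    def test_empty_table_warns(self, trio_design):
        with pytest.warns(UserWarning, match="empty"):
            out = preprocess_counts(self._table([]), trio_design)
        assert out == []


class TestRecords:
    def test_round_trip(self):
        recs = [make_record("A", dn=2, case=1), make_record("B", trans=3, mu=2e-6)]
        back = frame_to_records(records_to_frame(recs))
        assert [r.gene_id for r in back] == ["A", "B"]
        assert back[0].x_dn["LoF"] == 2 and back[1].x_t["LoF"] == 3

    def test_pseudo_counts_are_derived(self):
        rec = make_record(dn=1, trans=2, nontrans=1, case=4, ctrl=3)
        assert rec.x1("LoF") == 6 and rec.x0("LoF") == 4

    def test_duplicate_gene_category_rejected(self):
        frame = records_to_frame([make_record("A", dn=1)])
        dup = pd.concat([frame, frame], ignore_index=True)
        with pytest.raises(ValueError, match="duplicate"):
            frame_to_records(dup)

    def test_negative_count_rejected(self):
        with pytest.raises(InvalidParameterError):
            GeneRecord("A", mu={"LoF": 1e-6}, x_dn={"LoF": -1})
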