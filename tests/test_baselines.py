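"""Baseline tests: multiplicity rule, Poisson de novo test, Fisher machinery,
and the de-novo-only Bayes analysis."""

import math

import numpy as np
import pytest
from scipy import stats

from tada.baselines import (
    baseline_table,
    denovo_test_pvalue,
    fisher_combine,
    meta_test_pvalue,
    multiplicity_test,
    tada_denovo,
    transmission_cc_pvalue,
)
from tada.bayes import Hyperparameters
from tada.datasets import load_asd_top_genes
from tada.gene_model import StudyDesign, frame_to_records
from conftest import make_record


class TestMultiplicity:
    @pytest.mark.parametrize("x,c,expected", [(2, 2, True), (1, 2, False), (3, 3, True)])
    def test_threshold_rule(self, x, c, expected):
        assert multiplicity_test(x, c) is expected

    def test_published_double_hit_genes(self):
        # the five genes found by requiring two de novo LoF events in 932 trios
        table = load_asd_top_genes()
        hits = table[table["dn"].apply(multiplicity_test)]
        assert len(hits) == 5
        assert set(hits["gene"]) == {"KATNAL2", "CHD8", "DYRK1A", "SCN2A", "POGZ"}

    def test_invalid_threshold(self):
        with pytest.raises(ValueError):
            multiplicity_test(5, 1)


class TestDenovoTest:
    def test_zero_count_is_one(self, trio_design):
        assert denovo_test_pvalue(0, 1e-6, trio_design) == 1.0

    def test_against_summation_oracle(self):
        # P(X >= x) by explicit term-by-term summation of the Poisson pmf
        design = StudyDesign(n_trios=500, categories=("LoF",))
        for x, mu in [(2, 1e-6), (1, 1e-4), (3, 1e-6), (5, 1e-5), (1, 1e-7)]:
            rate = 2 * 500 * mu
            oracle = 1.0 - sum(
                np.exp(-rate) * rate**j / math.factorial(j) for j in range(x)
            )
            assert denovo_test_pvalue(x, mu, design) == pytest.approx(
                oracle, abs=1e-12
            )

    def test_worked_values(self):
        d1 = StudyDesign(n_trios=500, categories=("LoF",))
        # closed form 1 - exp(-0.001) * 1.001
        assert denovo_test_pvalue(2, 1e-6, d1) == pytest.approx(4.99667e-7, rel=1e-4)
        assert denovo_test_pvalue(1, 1e-4, d1) == pytest.approx(0.095163, rel=1e-4)


class TestFisherExact:
    def test_matches_scipy_fisher_exact(self):
        # independent route: scipy's 2x2 exact test, alternative='greater'
        for x1, x0, e1, e0 in [(4, 0, 2000, 2000), (1, 3, 2000, 1800), (0, 2, 500, 500)]:
            mine = transmission_cc_pvalue(x1, x0, (e1, e0))
            table = [[x1, e1 - x1], [x0, e0 - x0]]
            ref = stats.fisher_exact(table, alternative="greater")[1]
            assert mine == pytest.approx(ref, rel=1e-9)

    def test_brute_force_hypergeometric_enumeration(self):
        # sum the hypergeometric pmf over the tail by hand
        x1, x0, e1, e0 = 4, 0, 2000, 2000
        total, draws = e1 + e0, x1 + x0
        oracle = sum(
            stats.hypergeom.pmf(j, total, draws, e1) for j in range(x1, draws + 1)
        )
        assert transmission_cc_pvalue(x1, x0, (e1, e0)) == pytest.approx(
            oracle, abs=1e-12
        )

    def test_no_signal_symmetry(self):
        assert transmission_cc_pvalue(3, 3, (2000, 2000)) >= 0.5

    def test_zero_case_count_is_one(self):
        assert transmission_cc_pvalue(0, 5, (2000, 2000)) == 1.0

    def test_count_exceeding_exposure_rejected(self):
        with pytest.raises(ValueError):
            transmission_cc_pvalue(10, 0, (5, 100))


class TestFisherCombine:
    def test_all_ones(self):
        assert fisher_combine([1.0, 1.0]) == pytest.approx(1.0)

    def test_closed_form_two_pvalues(self):
        # chi-square df 4 upper tail: exp(-x/2) (1 + x/2), x = -2 sum log p
        x = -2 * (np.log(0.05) + np.log(0.05))
        closed = np.exp(-x / 2) * (1 + x / 2)
        assert fisher_combine([0.05, 0.05]) == pytest.approx(closed, rel=1e-12)
        assert fisher_combine([0.05, 0.05]) == pytest.approx(0.01747, rel=1e-3)

    @pytest.mark.parametrize("p", [0.001, 0.05, 0.3, 0.9])
    def test_uninformative_partner_penalizes(self, p):
        assert fisher_combine([p, 1.0]) > p

    def test_zero_rejected(self):
        with pytest.raises(ValueError):
            fisher_combine([0.0, 0.5])


class TestMetaTest:
    def test_penalization_with_no_denovo(self, asd_design):
        # a gene with x_dn = 0 is penalized relative to its inherited evidence
        p_cc = transmission_cc_pvalue(
            6, 0, (int(asd_design.exposure_case), int(asd_design.exposure_control))
        )
        p_meta = meta_test_pvalue(0, 6, 0, 1e-6, asd_design)
        assert p_meta >= p_cc


class TestTadaDenovo:
    def test_monotone_in_denovo_count(self, trio_design, default_hyper):
        recs = [make_record("A", dn=1), make_record("B", dn=2)]
        res = tada_denovo(recs, trio_design, {"LoF": default_hyper}, B=20_000, seed=0)
        bf = res.set_index("gene")["log10_bf_total"]
        assert bf["B"] > bf["A"]

    def test_closed_form_matches_mc_integration(self, trio_design, default_hyper, rng):
        # oracle: average the Poisson pmf over relative-risk draws
        recs = [make_record("A", dn=2, mu=2e-6)]
        res = tada_denovo(recs, trio_design, {"LoF": default_hyper}, B=20_000, seed=0)
        a = 2 * 1000 * 2e-6
        g = rng.gamma(20.0, 1.0, size=1_000_000)
        mc_bf = stats.poisson.pmf(2, a * g).mean() / stats.poisson.pmf(2, a)
        assert 10 ** res["log10_bf_total"].iloc[0] == pytest.approx(mc_bf, rel=5e-3)

    def test_null_calibration(self, null_genome, trio_design, default_hyper):
        recs = frame_to_records(null_genome.counts)
        res = tada_denovo(recs, trio_design, {"LoF": default_hyper}, B=100_000, seed=2)
        ks = stats.kstest(res["p"], "uniform")
        assert ks.pvalue > 0.01


class TestBaselineTable:
    def test_columns_and_size(self, trio_design, null_genome):
        recs = frame_to_records(null_genome.counts)[:50]
        tab = baseline_table(recs, trio_design)
        assert list(tab.columns) == ["gene", "multiplicity", "p_denovo", "p_cc", "p_meta"]
        assert len(tab) == 50
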