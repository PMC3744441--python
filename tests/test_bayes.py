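"""Checks of the marginal likelihoods and Bayes factors against independent
integration oracles, plus their qualitative (monotonicity, limit) behavior."""

import numpy as np
import pytest

from tada.bayes import (
    Hyperparameters,
    approx_bayes_factor,
    bayes_factor_gene,
    combine_categories,
    log10_bf_arrays,
    marginal_casecontrol,
    marginal_denovo,
)
from tada.gene_model import StudyDesign
from conftest import make_record


def mc_denovo_marginal(x, a, gamma_mean, beta, n_draws, rng):
    """Monte-Carlo oracle: E_gamma[Poisson(x; a*gamma)] under the Gamma prior."""
    from scipy import stats

    g = rng.gamma(gamma_mean * beta, 1.0 / beta, size=n_draws)
    return float(stats.poisson.pmf(x, a * g).mean())


def mc_cc_h0_marginal(x1, x0, e1, e0, rho, nu, n_draws, rng):
    """Monte-Carlo oracle: E_q[Poisson(x1; e1 q) Poisson(x0; e0 q)]."""
    from scipy import stats

    q = rng.gamma(rho, 1.0 / nu, size=n_draws)
    return float((stats.poisson.pmf(x1, e1 * q) * stats.poisson.pmf(x0, e0 * q)).mean())


class TestDenovoMarginal:
    def test_h0_zero_count_is_poisson_at_zero(self, trio_design, default_hyper):
        val = marginal_denovo(0, 1e-6, trio_design, default_hyper, "H0")
        assert val == pytest.approx(np.exp(-2 * 1000 * 1e-6))

    def test_single_count_against_mc_oracle(self, rng):
        # 2*N*mu = 0.001, mean relative risk 20, precision 1
        design = StudyDesign(n_trios=500, categories=("LoF",))
        h = Hyperparameters(gamma_mean=20.0, beta=1.0)
        closed = marginal_denovo(1, 1e-6, design, h, "H1")
        assert closed == pytest.approx(0.019583, rel=1e-3)
        mc = mc_denovo_marginal(1, 0.001, 20.0, 1.0, 2_000_000, rng)
        assert closed == pytest.approx(mc, rel=2e-3)
        bf = closed / marginal_denovo(1, 1e-6, design, h, "H0")
        assert bf == pytest.approx(19.6, rel=1e-2)

    def test_degenerate_prior_limit_is_poisson(self, trio_design):
        from scipy import stats

        h = Hyperparameters(gamma_mean=20.0, beta=1e6)
        val = marginal_denovo(2, 1e-6, trio_design, h, "H1")
        assert val == pytest.approx(stats.poisson.pmf(2, 2 * 1000 * 1e-6 * 20), rel=1e-3)


class TestCaseControlMarginal:
    def test_empty_data_is_one(self, default_hyper):
        assert marginal_casecontrol(0, 0, (0.0, 0.0), default_hyper, "H0") == 1.0
        assert marginal_casecontrol(0, 0, (0.0, 0.0), default_hyper, "H1") == 1.0

    def test_h0_closed_form_against_mc_oracle(self, rng, default_hyper):
        closed = marginal_casecontrol(1, 0, (1000.0, 1000.0), default_hyper, "H0")
        mc = mc_cc_h0_marginal(
            1, 0, 1000.0, 1000.0, default_hyper.rho0, default_hyper.nu0, 4_000_000, rng
        )
        assert closed == pytest.approx(mc, rel=5e-3)

    def test_h1_likelihood_ratio_increases_in_x1(self, asd_design, default_hyper):
        e = (asd_design.exposure_case, asd_design.exposure_control)
        ratios = [
            marginal_casecontrol(x1, 1, e, default_hyper, "H1")
            / marginal_casecontrol(x1, 1, e, default_hyper, "H0")
            for x1 in range(6)
        ]
        assert np.all(np.diff(ratios) > 0)


class TestBayesFactors:
    def test_monotone_in_counts(self, asd_design, default_hyper):
        x_dn = np.arange(5)
        lb, _, _ = log10_bf_arrays(x_dn, np.zeros(5), np.zeros(5), np.full(5, 1e-6),
                                   asd_design, default_hyper)
        assert np.all(np.diff(lb) > 0)
        x1 = np.arange(5)
        lb, _, _ = log10_bf_arrays(np.zeros(5), x1, np.zeros(5), np.full(5, 1e-6),
                                   asd_design, default_hyper)
        assert np.all(np.diff(lb) > 0)
        x0 = np.arange(5)
        lb, _, _ = log10_bf_arrays(np.zeros(5), np.full(5, 2), x0, np.full(5, 1e-6),
                                   asd_design, default_hyper)
        assert np.all(np.diff(lb) < 0)

    def test_denovo_bf_direction_at_small_rates(self, trio_design, default_hyper):
        # a single observed de novo event is evidence for risk; none, against
        lb, lb_dn, _ = log10_bf_arrays([0, 1, 2], [0] * 3, [0] * 3, [4e-7] * 3,
                                       trio_design, default_hyper)
        assert lb_dn[0] < 0 < lb_dn[1] < lb_dn[2]

    def test_joint_vs_factorized_agree(self, asd_design, default_hyper, rng):
        n = 200
        mu = 1e-6 * np.exp(rng.normal(0, 1, n))
        x_dn = rng.poisson(0.01, n)
        x1 = rng.poisson(1.0, n)
        x0 = rng.poisson(1.0, n)
        lb_j, _, _ = log10_bf_arrays(x_dn, x1, x0, mu, asd_design, default_hyper, joint=True)
        lb_f, _, _ = log10_bf_arrays(x_dn, x1, x0, mu, asd_design, default_hyper, joint=False)
        assert np.corrcoef(lb_j, lb_f)[0, 1] > 0.99
        assert np.max(np.abs(lb_j - lb_f)) < 1.0

    def test_published_gene_ordering(self, asd_design, default_hyper):
        # a gene with de novo + case-control support dominates one with only
        # two transmitted variants
        katnal2 = make_record("KATNAL2", dn=2, trans=1, case=4)
        lmcd1 = make_record("LMCD1", trans=2)
        bf_k = bayes_factor_gene(katnal2, asd_design, default_hyper)
        bf_l = bayes_factor_gene(lmcd1, asd_design, default_hyper)
        assert bf_k.log10_bf_total > bf_l.log10_bf_total

    def test_no_information_limit(self, default_hyper):
        # tiny mu, matched q priors, zero counts: essentially no evidence
        design = StudyDesign(n_trios=10, categories=("LoF",))
        h = Hyperparameters(rho1=0.5, nu1=50_000.0, rho0=0.5, nu0=50_000.0)
        rec = make_record(mu=1e-10)
        bf = bayes_factor_gene(rec, design, h)
        assert abs(bf.log10_bf_total) < 0.01


class TestCategoryCombination:
    def test_full_weight_is_plain_product(self):
        h = {"LoF": Hyperparameters(w=1.0), "Mis3": Hyperparameters(w=1.0)}
        total = combine_categories({"LoF": 2.0, "Mis3": 1.0}, h)
        assert total == pytest.approx(3.0)

    def test_zero_weight_silences_category(self):
        h = {"LoF": Hyperparameters(w=1.0), "Mis3": Hyperparameters(w=0.0)}
        total = combine_categories({"LoF": 2.0, "Mis3": 5.0}, h)
        assert total == pytest.approx(2.0)

    def test_intermediate_weight_shrinks_toward_one(self):
        h = {"Mis3": Hyperparameters(w=0.5)}
        total = float(combine_categories({"Mis3": 2.0}, h))
        # 0.5 * 100 + 0.5 = 50.5
        assert 10 ** total == pytest.approx(50.5)


class TestApproxBayesFactor:
    def test_no_data_limit_uses_prior_means(self, default_hyper):
        with pytest.warns(UserWarning, match="no samples"):
            design = StudyDesign(n_trios=0, n_cases=0, n_controls=0, categories=("LoF",))
        rec = make_record()
        assert approx_bayes_factor(rec, design, default_hyper) == pytest.approx(1.0)

    def test_prior_weight_formula(self):
        # nu = exposure / 4 puts weight 0.20 on the prior mean
        nu = 1000.0 / 4.0
        exposure = 1000.0
        assert nu / (nu + exposure) == pytest.approx(0.20)
        h = Hyperparameters(rho0=nu * 1e-3, nu0=nu, rho1=nu * 1e-3, nu1=nu)
        design = StudyDesign(n_trios=250, categories=("LoF",))  # e1 + e0 = 1000
        rec = make_record(trans=2)
        x, e = 2.0, 1000.0
        expected_q = 0.2 * 1e-3 + 0.8 * (x / e)
        got = (h.rho0 + x) / (h.nu0 + e)
        assert got == pytest.approx(expected_q)
        assert approx_bayes_factor(rec, design, h) > 0

    def test_sign_agrees_with_exact_bf(self, asd_design, default_hyper, rng):
        n = 100
        agree = 0
        for _ in range(n):
            rec = make_record(
                dn=int(rng.poisson(0.1)),
                trans=int(rng.poisson(0.5)),
                nontrans=int(rng.poisson(0.5)),
                case=int(rng.poisson(0.5)),
                ctrl=int(rng.poisson(0.5)),
                mu=float(1e-6 * np.exp(rng.normal())),
            )
            exact = bayes_factor_gene(rec, asd_design, default_hyper).log10_bf_total
            approx = np.log10(approx_bayes_factor(rec, asd_design, default_hyper))
            agree += (exact > 0) == (approx > 0)
        assert agree / n >= 0.9
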