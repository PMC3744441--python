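"""Power and false-discovery experiments for the competing gene tests.

Two experiment styles mirror how gene-discovery methods are evaluated:

* per-gene power — replicate a single gene's data at fixed (gamma, q, mu)
  and measure the fraction of replicates reaching a fixed type-I error
  (the Bayes test converts its null pool into the matching threshold);
* genome-wide discoveries — simulate a full genome with known truth and
  count true discoveries at an oracle-calibrated false-discovery proportion
  (the threshold is chosen against the simulated truth, as one can only do
  in simulation; real-data analyses use Benjamini-Hochberg instead).

Also here: the analytic expected-discovery/FDR curves of the simple
multiplicity rule, and the sensitivity of a single gene's p-value to the
assumed mutation rate and mean relative risk.
"""

from __future__ import annotations

from dataclasses import replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from . import baselines, bayes, significance
from .architecture import _rr_quadrature
from .bayes import Hyperparameters
from .gene_model import GeneParams, GeneRecord, StudyDesign
from .simulate import SimConfig, simulate_genome

__all__ = [
    "per_gene_power",
    "genomewide_experiment",
    "oracle_fdr_threshold",
    "multiplicity_study",
    "sensitivity_analysis",
]

TESTS = ("denovo", "meta", "tada")


def _simulate_replicates(
    params: GeneParams, design: StudyDesign, n_reps: int, rng: np.random.Generator
):
    """Replicate counts (x_dn, x1, x0) of one gene at fixed parameters."""
    N, N1, N0 = design.n_trios, design.n_cases, design.n_controls
    x_dn = rng.poisson(2.0 * N * params.mu * params.gamma, size=n_reps)
    x_t = rng.poisson(2.0 * N * params.q * params.gamma, size=n_reps)
    x_nt = rng.poisson(2.0 * N * params.q, size=n_reps)
    x_case = rng.poisson(2.0 * N1 * params.q * params.gamma, size=n_reps)
    x_ctrl = rng.poisson(2.0 * N0 * params.q, size=n_reps)
    return x_dn, x_t + x_case, x_nt + x_ctrl


def _single_gene_null_pool(
    mu: float,
    design: StudyDesign,
    hyper: Hyperparameters,
    B: int,
    rng: np.random.Generator,
) -> np.ndarray:
    """Null log10-BF pool for one gene (its own mu), q from the H0 prior."""
    e1, e0 = design.exposure_case, design.exposure_control
    x_dn = rng.poisson(2.0 * design.n_trios * mu, size=B)
    q = rng.gamma(hyper.rho0, 1.0 / hyper.nu0, size=B)
    x1 = rng.poisson(e1 * q)
    x0 = rng.poisson(e0 * q)
    lb, _, _ = bayes.log10_bf_arrays(x_dn, x1, x0, np.full(B, mu), design, hyper)
    lb.sort()
    return lb


def per_gene_power(
    test: str,
    params: GeneParams,
    design: StudyDesign,
    alpha: float = 0.001,
    n_reps: int = 10_000,
    seed: int = 0,
    hyper: Hyperparameters | None = None,
    null_pool_size: int = 200_000,
) -> tuple[float, float]:
    """Power of one test at type-I error ``alpha``, with Monte-Carlo error.

    Returns ``(power, mc_error)`` where the error is the binomial standard
    error over ``n_reps`` replicates.  The Bayes test derives its rejection
    threshold from its own per-gene null pool.
    """
    if test not in TESTS:
        raise ValueError(f"unknown test {test!r}; choose from {TESTS}")
    if n_reps < 1000:
        raise ValueError("n_reps must be >= 1000 for a stable power estimate")
    rng = np.random.default_rng(seed)
    x_dn, x1, x0 = _simulate_replicates(params, design, n_reps, rng)

    if test == "denovo":
        p = baselines.denovo_test_pvalue(x_dn, params.mu, design)
    elif test == "meta":
        p = baselines.meta_test_pvalue(x_dn, x1, x0, params.mu, design)
    else:
        if hyper is None:
            hyper = Hyperparameters()
        pool = _single_gene_null_pool(params.mu, design, hyper, null_pool_size, rng)
        lb, _, _ = bayes.log10_bf_arrays(
            x_dn, x1, x0, np.full(n_reps, params.mu), design, hyper
        )
        p = significance.empirical_pvalue(lb, pool)
    power = float(np.mean(p <= alpha))
    return power, float(np.sqrt(power * (1.0 - power) / n_reps))


def oracle_fdr_threshold(pvalues, is_risk, fdr_target: float):
    """Largest p cutoff whose realized false-discovery proportion <= target.

    Returns ``(n_true_discoveries, realized_fdp, cutoff_rank)``; all zero
    when no cutoff achieves the target.
    """
    p = np.asarray(pvalues, dtype=float)
    risk = np.asarray(is_risk, dtype=bool)
    order = np.argsort(p, kind="mergesort")
    false_cum = np.cumsum(~risk[order])
    n = np.arange(1, p.size + 1)
    fdp = false_cum / n
    ok = np.flatnonzero(fdp <= fdr_target)
    if ok.size == 0:
        return 0, 0.0, 0
    i = int(ok[-1])
    return int(n[i] - false_cum[i]), float(fdp[i]), i + 1


def genomewide_experiment(
    sim_config: SimConfig,
    hyper: Mapping[str, Hyperparameters] | Hyperparameters,
    fdr_target: float = 0.10,
    seed: int = 0,
    tests: Sequence[str] = TESTS,
    null_pool_size: int = 200_000,
    category: str = "LoF",
) -> pd.DataFrame:
    """True discoveries per test on one simulated genome at oracle FDR.

    The Bayes test always runs with the supplied ``hyper`` (the analyst's
    priors), however the genome was generated — robustness to parameter
    mismatch is part of what the experiment measures.
    """
    if isinstance(hyper, Hyperparameters):
        hyper = {category: hyper}
    genome = simulate_genome(sim_config, seed, category=category)
    design = sim_config.design
    is_risk = genome.truth["is_risk"].to_numpy()
    mu = genome.counts["mu"].to_numpy()
    x_dn = genome.counts["dn"].to_numpy()
    x1 = (genome.counts["trans"] + genome.counts["case"]).to_numpy()
    x0 = (genome.counts["nontrans"] + genome.counts["control"]).to_numpy()

    from .gene_model import frame_to_records  # local: avoids cycle at import

    records = frame_to_records(genome.counts)
    rows = []
    for test in tests:
        if test == "denovo":
            p = baselines.denovo_test_pvalue(x_dn, mu, design)
        elif test == "meta":
            p = baselines.meta_test_pvalue(x_dn, x1, x0, mu, design)
        elif test == "tada":
            pool = significance.null_bf_pool(
                records, design, hyper, B=null_pool_size, seed=seed + 1
            )
            lb, _, _ = bayes.log10_bf_arrays(x_dn, x1, x0, mu, design, hyper[category])
            p = significance.empirical_pvalue(lb, pool)
        else:
            raise ValueError(f"unknown test {test!r}")
        n_true, fdp, rank = oracle_fdr_threshold(p, is_risk, fdr_target)
        rows.append(
            {
                "test": test,
                "seed": seed,
                "n_true_discoveries": n_true,
                "realized_fdp": fdp,
                "n_called": rank,
            }
        )
    return pd.DataFrame(rows)


def multiplicity_study(
    k: float,
    m: int,
    gamma_mean: float,
    mu_by_gene,
    n_grid: Sequence[int],
    c: int = 2,
    rr_cv: float = 1.0,
) -> pd.DataFrame:
    """Analytic expected discoveries and FDR of the multiplicity rule vs N.

    For each sample size N: every gene is a risk gene with probability
    ``k/m``; a risk gene's de novo count mixes Poisson(2 N mu gamma) over the
    relative-risk distribution; the rule calls a gene at >= ``c`` events.
    """
    if c not in (2, 3):
        raise ValueError("multiplicity threshold c must be 2 or 3")
    mu = np.asarray(mu_by_gene, dtype=float)
    g, wq = _rr_quadrature(gamma_mean, rr_cv)
    frac = k / m
    rows = []
    for N in n_grid:
        a = 2.0 * N * mu
        p_null = stats.poisson.sf(c - 1, a)
        p_risk = stats.poisson.sf(c - 1, np.outer(a, g)) @ wq
        e_true = frac * p_risk.sum()
        e_false = (1.0 - frac) * p_null.sum()
        total = e_true + e_false
        rows.append(
            {
                "N": N,
                "c": c,
                "expected_true": e_true,
                "expected_false": e_false,
                "expected_discoveries": total,
                "fdr": e_false / total if total > 0 else 0.0,
            }
        )
    return pd.DataFrame(rows)


def sensitivity_analysis(
    record: GeneRecord,
    design: StudyDesign,
    hyper: Hyperparameters,
    mu_factors: Sequence[float] = (0.5, 1.0, 2.0),
    gamma_means: Sequence[float] = (10.0, 15.0, 20.0),
    category: str = "LoF",
    seed: int = 0,
    null_pool_size: int = 100_000,
) -> pd.DataFrame:
    """TADA p-value of one gene across mutation-rate and prior-mean scans.

    Each grid point rescales the gene's mutation rate by ``mu_factor`` and
    replaces the prior mean relative risk; the null pool is regenerated with
    the same seed so the scan isolates the parameter effect.
    """
    if min(mu_factors) < 0.5 or max(mu_factors) > 2.0:
        raise ValueError("mutation-rate factors must lie in [0.5, 2]")
    if min(gamma_means) < 10.0 or max(gamma_means) > 20.0:
        raise ValueError("gamma_mean scan must lie in [10, 20]")
    x_dn = record.x_dn.get(category, 0)
    x1 = record.x1(category)
    x0 = record.x0(category)
    mu0 = record.mu[category]
    rows = []
    for gm in gamma_means:
        h = replace(hyper, gamma_mean=gm)
        for f in mu_factors:
            mu = f * mu0
            rng = np.random.default_rng(seed)
            pool = _single_gene_null_pool(mu, design, h, null_pool_size, rng)
            lb, _, _ = bayes.log10_bf_arrays([x_dn], [x1], [x0], [mu], design, h)
            p = significance.empirical_pvalue(float(lb[0]), pool)
            rows.append(
                {"gamma_mean": gm, "mu_factor": f, "log10_bf": float(lb[0]), "p": p}
            )
    return pd.DataFrame(rows)
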