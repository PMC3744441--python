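"""Genome-wide synthetic data under the rare-variant dominant model.

The generator emulates the assumed architecture of a disorder like autism:
``m`` genes of which ``k`` are risk genes; risk genes carry a relative risk
drawn from a Gamma distribution with mean ``gamma_mean`` and a rarer damaging
"allele" (mean frequency ``q1_mean``) than null genes (``q0_mean``), because
large-effect alleles are held down by selection.  Counts are then Poisson
draws at the model rates: de novo 2*N*mu*gamma, transmitted 2*N*q*gamma,
nontransmitted 2*N*q, case 2*N1*q*gamma, control 2*N0*q.

In ``mutation_selection`` mode the frequency of a risk gene is not drawn
independently but set inversely proportional to its sampled risk,
``q = c * mu / gamma``, with the constant solved from the configured mean
values — a one-parameter mutation-selection balance.

Every gene owns a counter-based random substream keyed by (seed, gene index),
so a subset of genes reproduces exactly the counts it had in the full genome.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Literal

import numpy as np
import pandas as pd

from .gene_model import RARE_Q_MAX, StudyDesign

__all__ = [
    "SimConfig",
    "SimGenome",
    "sample_gene_params",
    "generate_genome_counts",
    "simulate_genome",
    "simulate_sibling_cohort",
]


@dataclass(frozen=True)
class SimConfig:
    """Study conditions for the synthetic genome.

    Defaults are the estimated architecture of ASD: 1,000 risk genes among
    18,000, mean relative risk 20 (Gamma with precision ``gamma_beta`` = 1),
    null allele-frequency mean 1e-3 and risk-gene mean 5e-5 (Gamma with shape
    0.5), and a log-normal LoF mutation-rate spectrum with mean ~1.6e-6 per
    chromosome per generation (median 1e-6, sigma 1 on the natural log),
    consistent with ~34 LoF de novo events per ~590 sibling exomes.
    """

    m: int = 18_000
    k: int = 1_000
    design: StudyDesign = field(
        default_factory=lambda: StudyDesign(n_trios=1000, categories=("LoF",))
    )
    gamma_mean: float = 20.0
    gamma_beta: float = 1.0
    q1_mean: float = 5e-5
    q1_shape: float = 0.5
    q0_mean: float = 1e-3
    q0_shape: float = 0.5
    mu_mode: Literal["lognormal", "constant"] = "lognormal"
    mu_median: float = 1e-6
    mu_sigma: float = 1.0
    mu_table: tuple[float, ...] | None = None
    mode: Literal["independent", "mutation_selection"] = "independent"

    def __post_init__(self) -> None:
        if not (0 <= self.k <= self.m):
            raise ValueError(f"need 0 <= k <= m, got k={self.k}, m={self.m}")
        for name in ("gamma_mean", "gamma_beta", "q1_mean", "q1_shape", "q0_mean", "q0_shape", "mu_median", "mu_sigma"):
            if not (getattr(self, name) > 0):
                raise ValueError(f"{name} must be positive")
        if self.mu_table is not None and len(self.mu_table) != self.m:
            raise ValueError("mu_table length must equal m")


@dataclass
class SimGenome:
    """Simulated truth and counts, one category, one row per gene."""

    config: SimConfig
    seed: int
    truth: pd.DataFrame  # gene, is_risk, gamma, q, mu
    counts: pd.DataFrame  # gene table (long format, category column)


def _gene_rng(seed: int, index: int) -> np.random.Generator:
    """Per-gene substream, independent of gene ordering and subsetting."""
    return np.random.default_rng(np.random.SeedSequence(seed, spawn_key=(index,)))


def sample_gene_params(config: SimConfig, seed: int) -> pd.DataFrame:
    """Draw per-gene (is_risk, gamma, q, mu) according to the configuration."""
    rng = np.random.default_rng(np.random.SeedSequence(seed, spawn_key=(2**31,)))
    m, k = config.m, config.k
    is_risk = np.zeros(m, dtype=bool)
    is_risk[rng.choice(m, size=k, replace=False)] = True

    if config.mu_table is not None:
        mu = np.asarray(config.mu_table, dtype=float)
    elif config.mu_mode == "constant":
        mu = np.full(m, config.mu_median)
    else:
        mu = config.mu_median * np.exp(rng.normal(0.0, config.mu_sigma, size=m))

    gamma = np.ones(m)
    shape_g = config.gamma_mean * config.gamma_beta
    gamma[is_risk] = rng.gamma(shape_g, 1.0 / config.gamma_beta, size=k)

    q = rng.gamma(config.q0_shape, config.q0_mean / config.q0_shape, size=m)
    if config.mode == "independent":
        q[is_risk] = rng.gamma(config.q1_shape, config.q1_mean / config.q1_shape, size=k)
    else:
        # mutation-selection balance: q = c * mu / gamma, with c solved from
        # the configured means so E[q] matches q1_mean at the mean mu/gamma
        mu_mean = float(np.mean(mu))
        c = config.q1_mean * config.gamma_mean / mu_mean
        q_ms = c * mu[is_risk] / gamma[is_risk]
        if np.any(q_ms > RARE_Q_MAX):
            warnings.warn(
                "mutation-selection frequencies clamped at the rare-variant cap",
                stacklevel=2,
            )
            q_ms = np.minimum(q_ms, RARE_Q_MAX)
        q[is_risk] = q_ms

    genes = np.array([f"G{i:05d}" for i in range(m)])
    return pd.DataFrame(
        {"gene": genes, "is_risk": is_risk, "gamma": gamma, "q": q, "mu": mu}
    )


def generate_genome_counts(
    params: pd.DataFrame,
    design: StudyDesign,
    seed: int,
    category: str = "LoF",
) -> pd.DataFrame:
    """Poisson counts for every gene at the model rates (long gene table).

    Each gene draws from its own substream keyed by (seed, row index).
    """
    n = len(params)
    N, N1, N0 = design.n_trios, design.n_cases, design.n_controls
    rows = np.empty((n, 5), dtype=np.int64)
    mu = params["mu"].to_numpy()
    gam = params["gamma"].to_numpy()
    q = params["q"].to_numpy()
    for i in range(n):
        rng = _gene_rng(seed, i)
        rates = np.array(
            [
                2.0 * N * mu[i] * gam[i],
                2.0 * N * q[i] * gam[i],
                2.0 * N * q[i],
                2.0 * N1 * q[i] * gam[i],
                2.0 * N0 * q[i],
            ]
        )
        rows[i] = rng.poisson(rates)
    return pd.DataFrame(
        {
            "gene": params["gene"].to_numpy(),
            "category": category,
            "mu": mu,
            "dn": rows[:, 0],
            "trans": rows[:, 1],
            "nontrans": rows[:, 2],
            "case": rows[:, 3],
            "control": rows[:, 4],
        }
    )


def simulate_genome(config: SimConfig, seed: int, category: str = "LoF") -> SimGenome:
    """Sample parameters and generate counts in one call."""
    params = sample_gene_params(config, seed)
    counts = generate_genome_counts(params, config.design, seed, category=category)
    return SimGenome(config=config, seed=seed, truth=params, counts=counts)


def simulate_sibling_cohort(
    config: SimConfig, seed: int, n_siblings: int | None = None
) -> pd.DataFrame:
    """De novo counts in unaffected siblings (gamma = 1 everywhere).

    The contrast of proband vs sibling totals estimates the de novo
    fold-enrichment lambda.
    """
    n_sib = n_siblings if n_siblings is not None else config.design.n_trios
    params = sample_gene_params(config, seed)
    rng = np.random.default_rng(np.random.SeedSequence(seed, spawn_key=(2**31 + 1,)))
    dn = rng.poisson(2.0 * n_sib * params["mu"].to_numpy())
    return pd.DataFrame({"gene": params["gene"], "mu": params["mu"], "dn": dn})
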