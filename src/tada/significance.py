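"""Null-simulation p-values for Bayes factors, FDR control and diagnostics.

A Bayes factor has no universal significance scale, so its p-value is taken
against a simulated genome-wide null: replicate genes are drawn uniformly
from the analyzed gene list (keeping the empirical mutation-rate mix), an
allele frequency is drawn from the fitted H0 prior, counts are generated from
the null Poisson rates, and the resulting total Bayes factors form the
reference pool.  Multiple testing is handled with Benjamini-Hochberg
q-values, and a median-based genomic-control factor diagnoses inflation.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from . import bayes
from .bayes import Hyperparameters
from .ebayes import category_arrays
from .gene_model import GeneRecord, StudyDesign

__all__ = [
    "TestResult",
    "null_bf_pool",
    "empirical_pvalue",
    "bh_adjust",
    "genomic_control",
    "test_genes",
]

DEFAULT_POOL_SIZE = 1_000_000
_CHUNK = 200_000


@dataclass(frozen=True)
class TestResult:
    gene_id: str
    log10_bf_total: float
    p_value: float
    q_value: float
    baselines: dict[str, float] | None = None


def null_bf_pool(
    records: Sequence[GeneRecord],
    design: StudyDesign,
    hyper: Mapping[str, Hyperparameters],
    B: int = DEFAULT_POOL_SIZE,
    seed: int = 0,
    denovo_only: bool = False,
    joint: bool = True,
    gene_index: int | None = None,
) -> np.ndarray:
    """Sorted pool of log10 total Bayes factors simulated under H0.

    Each replicate draws a gene uniformly from ``records`` (or uses the fixed
    ``gene_index`` for a per-gene null), draws q from the H0 prior of each
    category, generates Poisson counts at the null rates with that gene's
    mutation rates, and evaluates the same Bayes factor that is applied to
    the observed data.
    """
    if B < 10_000:
        warnings.warn(
            f"null pool of {B} replicates limits p-value resolution to {1/(1+B):.2e}",
            stacklevel=2,
        )
    rng = np.random.default_rng(seed)
    cats = [c for c in design.categories if c in hyper]
    mu_by_cat = {}
    for cat in cats:
        mu_c, *_ = category_arrays(records, cat)
        if mu_c.size == 0:
            raise ValueError(f"no records carry category {cat!r}")
        mu_by_cat[cat] = mu_c

    n_genes = len(mu_by_cat[cats[0]])
    e1, e0 = design.exposure_case, design.exposure_control
    out = np.empty(B)
    done = 0
    while done < B:
        n = min(_CHUNK, B - done)
        if gene_index is None:
            idx = rng.integers(0, n_genes, size=n)
        else:
            idx = np.full(n, gene_index)
        lb_by_cat: dict[str, np.ndarray] = {}
        for cat in cats:
            h = hyper[cat]
            mu = mu_by_cat[cat][idx]
            x_dn = rng.poisson(2.0 * design.n_trios * mu)
            if denovo_only:
                x1 = np.zeros(n)
                x0 = np.zeros(n)
            else:
                q = rng.gamma(h.rho0, 1.0 / h.nu0, size=n)
                x1 = rng.poisson(e1 * q)
                x0 = rng.poisson(e0 * q)
            lb, _, _ = bayes.log10_bf_arrays(
                x_dn, x1, x0, mu, design, h, joint=joint, denovo_only=denovo_only
            )
            lb_by_cat[cat] = lb
        out[done : done + n] = bayes.combine_categories(
            lb_by_cat, {c: hyper[c] for c in cats}
        )
        done += n
    out.sort()
    return out


def empirical_pvalue(log10_bf, pool: np.ndarray):
    """p = (1 + #{pool >= observed}) / (1 + |pool|), ties counted as >=.

    ``pool`` must be sorted ascending.  Scalar in, scalar out.
    """
    obs = np.asarray(log10_bf, dtype=float)
    n_ge = pool.size - np.searchsorted(pool, obs, side="left")
    p = (1.0 + n_ge) / (1.0 + pool.size)
    return float(p) if np.isscalar(log10_bf) else p


def bh_adjust(pvalues) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values."""
    p = np.asarray(pvalues, dtype=float)
    if np.isnan(p).any():
        raise ValueError("NaN p-value passed to BH adjustment")
    if np.any((p <= 0) | (p > 1)):
        raise ValueError("p-values must lie in (0, 1]")
    if p.size == 0:
        return p.copy()
    return multipletests(p, method="fdr_bh")[1]


def genomic_control(pvalues) -> float:
    """Median-based inflation factor lambda of a 1-df chi-square conversion.

    p-values are mapped to chi-square(1) quantiles; lambda is the ratio of
    their median to the null median (0.4549...).  Values near 1 indicate no
    systematic inflation (e.g. from population stratification).
    """
    p = np.asarray(pvalues, dtype=float)
    if p.size < 100:
        warnings.warn(
            f"genomic control on only {p.size} p-values is unstable", stacklevel=2
        )
    if np.any(p == 0):
        floor = np.min(p[p > 0]) if np.any(p > 0) else np.finfo(float).tiny
        warnings.warn(f"zero p-values clamped to {floor:g}", stacklevel=2)
        p = np.where(p == 0, floor, p)
    chi = stats.chi2.isf(p, df=1)
    return float(np.median(chi) / stats.chi2.isf(0.5, df=1))


def test_genes(
    records: Sequence[GeneRecord],
    design: StudyDesign,
    hyper: Mapping[str, Hyperparameters],
    pool: np.ndarray | None = None,
    B: int = DEFAULT_POOL_SIZE,
    seed: int = 0,
    joint: bool = True,
    denovo_only: bool = False,
) -> pd.DataFrame:
    """Per-gene Bayes factors, null-simulation p-values and BH q-values."""
    if pool is None:
        pool = null_bf_pool(
            records, design, hyper, B=B, seed=seed, joint=joint, denovo_only=denovo_only
        )
    cats = [c for c in design.categories if c in hyper]
    ids = None
    lb_by_cat: dict[str, np.ndarray] = {}
    parts: dict[str, np.ndarray] = {}
    for cat in cats:
        mu, x_dn, x1, x0, ids_c = category_arrays(records, cat)
        if denovo_only:
            x1 = np.zeros_like(x1)
            x0 = np.zeros_like(x0)
        lb, lb_dn, lb_cc = bayes.log10_bf_arrays(
            x_dn, x1, x0, mu, design, hyper[cat], joint=joint, denovo_only=denovo_only
        )
        lb_by_cat[cat] = lb
        parts[f"log10_bf_{cat}"] = lb
        parts[f"log10_bf_dn_{cat}"] = lb_dn
        if ids is None:
            ids = ids_c
        elif ids_c != ids:
            raise ValueError("categories cover different gene sets; align the table first")
    total = np.asarray(
        bayes.combine_categories(lb_by_cat, {c: hyper[c] for c in cats}), dtype=float
    )
    p = empirical_pvalue(total, pool)
    q = bh_adjust(p)
    frame = pd.DataFrame({"gene": ids, "log10_bf_total": total, **parts, "p": p, "q": q})
    return frame.sort_values("p", kind="mergesort").reset_index(drop=True)
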