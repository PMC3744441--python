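"""Comparison tests: multiplicity, de novo Poisson, meta (Fisher), TADA-Denovo.

These are the tests the hierarchical-Bayes analysis is measured against:

* the multiplicity rule — call a gene when it sustains >= C independent de
  novo events;
* the De Novo Test — a per-gene Poisson tail on the de novo count, which
  adapts the multiplicity idea to gene-specific mutation rates;
* the Meta test — a one-sided Fisher exact test on the pseudo case/control
  counts combined with the De Novo p-value by Fisher's method;
* TADA-Denovo — the Bayes machinery restricted to de novo counts, where the
  relative-risk integral is conjugate and closed-form.
"""

from __future__ import annotations

from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from . import bayes, significance
from .bayes import Hyperparameters
from .ebayes import category_arrays
from .gene_model import GeneRecord, StudyDesign

__all__ = [
    "multiplicity_test",
    "denovo_test_pvalue",
    "transmission_cc_pvalue",
    "fisher_combine",
    "meta_test_pvalue",
    "tada_denovo",
]


def multiplicity_test(x_dn: int, c_threshold: int = 2) -> bool:
    """True iff the gene sustains at least ``c_threshold`` de novo events."""
    if c_threshold < 2:
        raise ValueError("multiplicity threshold must be >= 2")
    return x_dn >= c_threshold


def denovo_test_pvalue(x_dn, mu, design: StudyDesign):
    """Upper-tail Poisson p-value P(X >= x_dn) with X ~ Poisson(2 N mu)."""
    rate = 2.0 * design.n_trios * np.asarray(mu, dtype=float)
    x = np.asarray(x_dn)
    p = stats.poisson.sf(x - 1, rate)
    p = np.where(x <= 0, 1.0, p)
    return float(p) if np.isscalar(x_dn) else p


def transmission_cc_pvalue(x1, x0, exposures: tuple[int, int]):
    """One-sided Fisher exact p for excess carriers in the pseudo-case arm.

    The 2x2 table is [[x1, e1 - x1], [x0, e0 - x0]] on chromosome-count
    exposures; the p-value is the hypergeometric tail P(X >= x1) conditional
    on the margins.  Vectorized over counts.
    """
    e1, e0 = int(exposures[0]), int(exposures[1])
    x1a = np.asarray(x1, dtype=np.int64)
    x0a = np.asarray(x0, dtype=np.int64)
    if np.any(x1a > e1) or np.any(x0a > e0):
        raise ValueError("carrier count exceeds chromosome exposure")
    p = stats.hypergeom.sf(x1a - 1, e1 + e0, x1a + x0a, e1)
    return float(p) if np.isscalar(x1) else p


def fisher_combine(pvalues) -> float | np.ndarray:
    """Fisher's method: -2 sum(log p) against chi-square with 2k df.

    Accepts a sequence of k p-values (scalar result) or a (n, k) array
    (vectorized over rows).
    """
    p = np.asarray(pvalues, dtype=float)
    if np.any(p <= 0) or np.any(p > 1):
        raise ValueError("p-values must lie in (0, 1]; floor zeros before combining")
    stat = -2.0 * np.sum(np.log(p), axis=-1)
    k = p.shape[-1]
    out = stats.chi2.sf(stat, df=2 * k)
    return float(out) if p.ndim == 1 else out


def meta_test_pvalue(x_dn, x1, x0, mu, design: StudyDesign):
    """De novo and inherited/case-control evidence combined by Fisher's method.

    Two p-values per gene: the De Novo Poisson tail (floored at the smallest
    positive float) and the one-sided Fisher exact on the pooled pseudo
    case/control table.
    """
    p_dn = np.atleast_1d(denovo_test_pvalue(x_dn, mu, design))
    p_cc = np.atleast_1d(
        transmission_cc_pvalue(x1, x0, (int(design.exposure_case), int(design.exposure_control)))
    )
    p_dn = np.clip(p_dn, np.finfo(float).tiny, 1.0)
    out = fisher_combine(np.column_stack([p_dn, p_cc]))
    return float(out[0]) if np.isscalar(x_dn) else out


def tada_denovo(
    records: Sequence[GeneRecord],
    design: StudyDesign,
    hyper: Mapping[str, Hyperparameters],
    seed: int = 0,
    B: int = significance.DEFAULT_POOL_SIZE,
) -> pd.DataFrame:
    """The de-novo-only Bayes analysis: closed-form BFs plus null p-values.

    Equivalent to the full analysis with all inherited and case-control
    counts zeroed; useful when only trio de novo data exist.
    """
    return significance.test_genes(
        records, design, hyper, B=B, seed=seed, denovo_only=True
    )


def baseline_table(
    records: Sequence[GeneRecord],
    design: StudyDesign,
    category: str = "LoF",
    c_threshold: int = 2,
) -> pd.DataFrame:
    """Per-gene p-values of the baseline tests for one category."""
    mu, x_dn, x1, x0, ids = category_arrays(records, category)
    p_dn = denovo_test_pvalue(x_dn, mu, design)
    p_cc = transmission_cc_pvalue(
        x1, x0, (int(design.exposure_case), int(design.exposure_control))
    )
    p_meta = meta_test_pvalue(x_dn, x1, x0, mu, design)
    return pd.DataFrame(
        {
            "gene": ids,
            "multiplicity": x_dn >= c_threshold,
            "p_denovo": np.atleast_1d(p_dn),
            "p_cc": np.atleast_1d(p_cc),
            "p_meta": np.atleast_1d(p_meta),
        }
    )
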