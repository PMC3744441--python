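"""Genetic-architecture estimation from de novo enrichment and recurrence.

Two observable summaries of trio de novo data constrain the architecture of
a disorder:

* the fold-enrichment ``lambda`` of de novo events in probands relative to
  unaffected siblings.  If ``k`` of ``m`` genes are risk genes with mean
  relative risk ``gamma_mean`` (and comparable mutation rates), the expected
  enrichment is ``lambda = 1 + k (gamma_mean - 1) / m``, giving the inverse
  relationship ``k = m (lambda - 1) / (gamma_mean - 1)``: many genes of weak
  effect and few genes of strong effect are equally compatible with a given
  enrichment;
* the number of multi-hit genes (>= 2 independent de novo events), whose
  expectation as a function of ``k`` breaks that degeneracy.  Heterogeneity
  of mutation rates and relative risks raises the expected multi-hit count
  at fixed totals (a Jensen's-inequality effect), so assuming uniform rates
  underestimates ``k``.

The plausible range of ``k`` inverts the multi-hit curve at a band around
the observed count; within that range, the hierarchical-Bayes marginal
likelihood profiles over ``k`` (through ``pi = k/m``) to pick the most
likely value.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from numpy.polynomial.legendre import leggauss
from scipy import stats

from .ebayes import fit_hyperparameters
from .gene_model import GeneRecord, StudyDesign

__all__ = [
    "ArchitectureEstimate",
    "enrichment_to_k",
    "enrichment_from_k",
    "expected_multihit",
    "k_interval",
    "refine_k_hb",
]


@dataclass(frozen=True)
class ArchitectureEstimate:
    k: float
    gamma_mean: float
    k_range: tuple[float, float]
    m: int
    lambda_enrich: float


def enrichment_to_k(m: int, lambda_enrich: float, gamma_mean: float) -> float:
    """Number of risk genes implied by a de novo fold-enrichment.

    ``k = m (lambda - 1) / (gamma_mean - 1)`` under the equal-mutation-rate
    mixture; exact inverse of :func:`enrichment_from_k`.
    """
    if gamma_mean <= 1:
        raise ValueError("gamma_mean must exceed 1")
    if lambda_enrich < 1:
        raise ValueError("fold-enrichment must be >= 1")
    return m * (lambda_enrich - 1.0) / (gamma_mean - 1.0)


def enrichment_from_k(m: int, k: float, gamma_mean: float) -> float:
    """Expected proband/sibling de novo fold-enrichment for (k, gamma_mean)."""
    return 1.0 + k * (gamma_mean - 1.0) / m


def _rr_quadrature(gamma_mean: float, cv: float, n: int = 64):
    """Nodes/weights for E over gamma ~ Gamma(mean gamma_mean, CV cv)."""
    shape = 1.0 / cv**2
    rate = shape / gamma_mean
    lo = max(stats.gamma.ppf(1e-10, shape, scale=1.0 / rate), 1e-12)
    hi = stats.gamma.isf(1e-10, shape, scale=1.0 / rate)
    x, w = leggauss(n)
    u = 0.5 * (np.log(hi) - np.log(lo)) * x + 0.5 * (np.log(hi) + np.log(lo))
    g = np.exp(u)
    wq = w * 0.5 * (np.log(hi) - np.log(lo)) * stats.gamma.pdf(g, shape, scale=1.0 / rate) * g
    return g, wq / wq.sum()


def _p_multihit(rate):
    """P(X >= 2) for X ~ Poisson(rate)."""
    return -np.expm1(-rate) - rate * np.exp(-rate)


def expected_multihit(
    k: float,
    mu_by_gene: Sequence[float] | np.ndarray,
    n_trios: int,
    gamma_mean: float = 20.0,
    rr_cv: float = 1.0,
    n_mc: int | None = None,
    seed: int = 0,
) -> float:
    """Expected number of genes with >= 2 de novo events in ``n_trios`` trios.

    Each gene is a risk gene with probability ``k/m``; risk genes mix the
    Poisson rate ``2 N mu gamma`` over the relative-risk distribution
    (Gamma, mean ``gamma_mean``, coefficient of variation ``rr_cv``).  The
    gamma-expectation uses quadrature by default; ``n_mc`` switches to Monte
    Carlo with ``seed`` (for cross-checks).
    """
    mu = np.asarray(mu_by_gene, dtype=float)
    if np.any(mu <= 0):
        raise ValueError("mutation rates must be positive")
    m = mu.size
    if not (0 <= k <= m):
        raise ValueError("need 0 <= k <= m")
    a = 2.0 * n_trios * mu
    p_null = _p_multihit(a)
    if k == 0:
        return float(p_null.sum())
    if n_mc is None:
        g, wq = _rr_quadrature(gamma_mean, rr_cv)
        p_risk = _p_multihit(np.outer(a, g)) @ wq
    else:
        rng = np.random.default_rng(seed)
        shape = 1.0 / rr_cv**2
        g = rng.gamma(shape, gamma_mean / shape, size=n_mc)
        # common gamma draws across genes; the expectation is per gene
        p_risk = np.array([_p_multihit(ai * g).mean() for ai in a])
    frac = k / m
    return float(np.sum(frac * p_risk + (1.0 - frac) * p_null))


def k_interval(
    observed_multihit: int,
    band: tuple[float, float],
    mu_by_gene,
    n_trios: int,
    m: int | None = None,
    lambda_enrich: float = 2.0,
    rr_cv: float = 1.0,
    tol: float = 1.0,
) -> tuple[float, float]:
    """Plausible range of k from a band around the observed multi-hit count.

    Along the curve the mean relative risk is tied to ``k`` through the
    enrichment identity (``gamma_mean = 1 + m (lambda - 1) / k``).  The curve
    is unimodal: for very small ``k`` the implied relative risk is so large
    that each of the few risk genes is almost surely multi-hit (the curve
    rises roughly like ``k``), while past the peak additional risk genes
    spread a fixed amount of total risk thinner and the expectation falls.
    Inference happens on the decreasing branch — the architecture question
    is "how many genes could share this much signal" — so the peak is
    located on a coarse grid and the band endpoints are inverted there by
    bisection to one gene.  A band endpoint above the attainable maximum is
    clamped to the peak with a warning; a band entirely outside the curve
    range is an error.
    """
    mu = np.asarray(mu_by_gene, dtype=float)
    m = mu.size if m is None else m
    lo_band, hi_band = min(band), max(band)

    def curve(k: float) -> float:
        gm = 1.0 + m * (lambda_enrich - 1.0) / max(k, 1e-9)
        return expected_multihit(k, mu, n_trios, gamma_mean=gm, rr_cv=rr_cv)

    grid = np.unique(np.geomspace(1.0, float(m), 48))
    vals = np.array([curve(k) for k in grid])
    i_peak = int(np.argmax(vals))
    k_min, k_max = float(grid[i_peak]), float(m)
    c_max, c_min = vals[i_peak], curve(k_max)
    if lo_band > c_max or hi_band < c_min:
        raise ValueError(
            f"band {band} outside the attainable multi-hit range [{c_min:.3g}, {c_max:.3g}]"
        )
    if hi_band > c_max:
        warnings.warn(
            f"band endpoint {hi_band:g} exceeds the curve maximum {c_max:.3g}; "
            "clamped to the peak",
            stacklevel=2,
        )
        hi_band = c_max

    def invert(target: float) -> float:
        lo, hi = k_min, k_max
        while hi - lo > tol:
            mid = 0.5 * (lo + hi)
            if curve(mid) > target:
                lo = mid
            else:
                hi = mid
        return 0.5 * (lo + hi)

    # decreasing branch: the upper band endpoint maps to the lower k
    return (invert(hi_band), invert(lo_band))


def refine_k_hb(
    records: Sequence[GeneRecord],
    design: StudyDesign,
    k_grid: Sequence[float],
    m: int,
    category: str = "LoF",
    n_starts: int = 5,
    seed: int = 0,
) -> tuple[float, list[dict]]:
    """Profile the hierarchical-Bayes marginal likelihood over k.

    For each candidate ``k`` the mixture weight is ``pi = k/m`` and the prior
    parameters are refitted; the ``k`` with the highest maximized marginal
    log-likelihood wins.  Returns (k_hat, profile) where profile rows carry
    k, loglik and convergence.
    """
    if len(k_grid) == 0:
        raise ValueError("empty k grid")
    profile: list[dict] = []
    for k in k_grid:
        try:
            fit = fit_hyperparameters(
                records,
                design,
                pi=float(k) / m,
                category=category,
                n_starts=n_starts,
                seed=seed,
            )
        except RuntimeError as exc:
            warnings.warn(f"fit failed at k={k}: {exc}", stacklevel=2)
            continue
        if not fit.converged:
            warnings.warn(f"fit at k={k} did not converge; excluded", stacklevel=2)
            continue
        profile.append({"k": float(k), "loglik": fit.loglik, "hyper": fit.hyper})
    if not profile:
        raise RuntimeError("no converged fits on the k grid")
    best = max(profile, key=lambda row: row["loglik"])
    return best["k"], profile
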