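"""Marginal likelihoods and gene Bayes factors.

Evidence for a gene being a risk gene is the Bayes factor

    BF = P(x_dn, x1, x0 | H1) / P(x_dn, x1, x0 | H0)

where under the alternative H1 the relative risk gamma follows a
Gamma(gamma_mean * beta, beta) prior (mean ``gamma_mean``; ``beta`` acts as a
precision / pseudo-count) and the allele frequency q follows Gamma(rho1, nu1);
under the null H0 gamma = 1 and q ~ Gamma(rho0, nu0).

The q integrals are conjugate (Poisson counts with exposure-scaled rates
against a Gamma prior) and are evaluated in closed form.  The gamma integral
couples the de novo Poisson term with the pseudo-case arm; it is evaluated by
Gauss-Legendre quadrature on log(gamma) over the central prior mass, with the
node count doubled until the result is stable.  All computation is in log
space; Bayes factors are reported as log10.

With de novo counts only the gamma integral is itself conjugate and the H1
marginal is the negative-binomial closed form, used by the de-novo-only test.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal, Mapping

import numpy as np
from numpy.polynomial.legendre import leggauss
from scipy import stats
from scipy.special import gammaln, logsumexp, xlogy

from .gene_model import GeneRecord, InvalidParameterError, StudyDesign

__all__ = [
    "Hyperparameters",
    "BayesFactorResult",
    "marginal_denovo",
    "marginal_casecontrol",
    "bayes_factor_gene",
    "approx_bayes_factor",
    "combine_categories",
    "log10_bf_arrays",
]

LN10 = np.log(10.0)

#: Tail mass excluded on each side of the relative-risk prior when building
#: quadrature nodes.
_QUAD_TAIL = 1e-10
_QUAD_START = 32
_QUAD_MAX = 256


@dataclass(frozen=True)
class Hyperparameters:
    """Prior (hyper)parameters of the hierarchical model for one category.

    gamma_mean
        Mean relative risk of risk genes (> 1).
    beta
        Rate / precision of the Gamma prior on gamma; shape is
        ``gamma_mean * beta`` so the prior mean is ``gamma_mean`` and larger
        ``beta`` concentrates the prior.
    rho1, nu1
        Shape and rate of the Gamma prior on q under H1 (risk genes).
    rho0, nu0
        Shape and rate of the Gamma prior on q under H0.
    pi
        Prior fraction of risk genes (shared across categories).
    w
        Probability that a variant of this category is truly damaging; the
        category Bayes factor is shrunk as ``w * BF + (1 - w)``.  Use 1 for
        LoF, < 1 for predicted-damaging missense.
    """

    gamma_mean: float = 20.0
    beta: float = 1.0
    rho1: float = 0.5
    nu1: float = 10_000.0
    rho0: float = 0.5
    nu0: float = 500.0
    pi: float = 1000.0 / 18000.0
    w: float = 1.0

    def __post_init__(self) -> None:
        for name in ("gamma_mean", "beta", "rho1", "nu1", "rho0", "nu0"):
            if not (getattr(self, name) > 0):
                raise InvalidParameterError(f"{name} must be positive")
        if not (0 < self.pi < 1):
            raise InvalidParameterError(f"pi must be in (0,1), got {self.pi!r}")
        if not (0 <= self.w <= 1):
            raise InvalidParameterError(f"w must be in [0,1], got {self.w!r}")
        for rho, nu in ((self.rho1, self.nu1), (self.rho0, self.nu0)):
            mean = rho / nu
            if not (0 < mean < 0.05):
                raise InvalidParameterError(
                    f"q prior mean rho/nu = {mean:g} outside the rare-variant range (0, 0.05)"
                )

    @property
    def q1_mean(self) -> float:
        return self.rho1 / self.nu1

    @property
    def q0_mean(self) -> float:
        return self.rho0 / self.nu0


@dataclass(frozen=True)
class BayesFactorResult:
    """Per-gene Bayes factors on the log10 scale.

    ``log10_bf_category`` holds the unadjusted per-category BF;
    ``log10_bf_total`` is the product over categories after the
    damaging-fraction adjustment of each category's ``w``.
    """

    gene_id: str
    log10_bf_dn: dict[str, float]
    log10_bf_cc: dict[str, float]
    log10_bf_category: dict[str, float]
    log10_bf_total: float

    @property
    def bf_total(self) -> float:
        return float(10.0 ** self.log10_bf_total)


# ---------------------------------------------------------------------------
# quadrature over the relative-risk prior


def _gl_nodes(gamma_mean: float, beta: float, n: int):
    """Gauss-Legendre nodes/log-weights for integrating f(gamma) against the
    Gamma(gamma_mean*beta, beta) prior, on the log-gamma axis."""
    shape = gamma_mean * beta
    lo = stats.gamma.ppf(_QUAD_TAIL, shape, scale=1.0 / beta)
    hi = stats.gamma.isf(_QUAD_TAIL, shape, scale=1.0 / beta)
    lo = max(lo, 1e-12)
    ulo, uhi = np.log(lo), np.log(hi)
    x, w = leggauss(n)
    u = 0.5 * (uhi - ulo) * x + 0.5 * (uhi + ulo)
    g = np.exp(u)
    # d gamma = gamma du; absorb prior density and Jacobian into the weights
    logw = (
        np.log(w)
        + np.log(0.5 * (uhi - ulo))
        + stats.gamma.logpdf(g, shape, scale=1.0 / beta)
        + u
    )
    return g, logw


def _log_cc_closed(x1, x0, e1, e0, rho, nu):
    """Log marginal of the two Poisson arms with a shared Gamma(rho, nu) q.

    e1 may be gamma-scaled.  Shapes broadcast.
    """
    s = rho + x0 + x1
    return (
        gammaln(s)
        - gammaln(rho)
        - gammaln(x0 + 1.0)
        - gammaln(x1 + 1.0)
        + xlogy(x0, e0)
        + xlogy(x1, e1)
        + rho * np.log(nu)
        - s * np.log(nu + e0 + e1)
    )


def _log_pois(x, rate):
    return xlogy(x, rate) - rate - gammaln(x + 1.0)


def _log_nb_denovo(x, a, gamma_mean, beta):
    """Closed-form H1 de novo marginal: Gamma-mixed Poisson(a * gamma)."""
    s = gamma_mean * beta
    return (
        gammaln(s + x)
        - gammaln(s)
        - gammaln(x + 1.0)
        + xlogy(x, a / (a + beta))
        + s * np.log(beta / (a + beta))
    )


def _h1_log_marginal(
    x_dn,
    x1,
    x0,
    a,
    e1,
    e0,
    hyper: Hyperparameters,
    include_dn: bool = True,
    include_cc: bool = True,
    rtol: float = 1e-6,
    nodes: int | None = None,
):
    """Joint H1 log marginal over the shared gamma for arrays of genes.

    ``nodes`` forces a single fixed-order evaluation (used inside the
    optimizer where the adaptive doubling would triple the cost); otherwise
    the order doubles until the result is stable to ``rtol``.
    """
    x_dn = np.asarray(x_dn, dtype=float)
    x1 = np.asarray(x1, dtype=float)
    x0 = np.asarray(x0, dtype=float)
    a = np.asarray(a, dtype=float)

    cc_const = 0.0
    if include_cc:
        s1 = hyper.rho1 + x0 + x1
        cc_const = (
            gammaln(s1)
            - gammaln(hyper.rho1)
            - gammaln(x0 + 1.0)
            - gammaln(x1 + 1.0)
            + xlogy(x0, e0)
            + xlogy(x1, e1)
            + hyper.rho1 * np.log(hyper.nu1)
        )
    dn_const = 0.0
    if include_dn:
        dn_const = xlogy(x_dn, a) - gammaln(x_dn + 1.0)

    def _eval(n: int):
        g, logw = _gl_nodes(hyper.gamma_mean, hyper.beta, n)
        lg = np.log(g)
        terms = logw[None, :] + np.zeros((x_dn.size, n))
        if include_dn:
            terms = terms + dn_const[..., None] + np.outer(x_dn, lg) - np.outer(a, g)
        if include_cc:
            terms = (
                terms
                + cc_const[..., None]
                + np.outer(x1, lg)
                - np.outer(s1, np.log(hyper.nu1 + e0 + e1 * g))
            )
        return logsumexp(terms, axis=1)

    if nodes is not None:
        return _eval(int(nodes))

    n = _QUAD_START
    prev = _eval(n)
    while n < _QUAD_MAX:
        n *= 2
        cur = _eval(n)
        err = np.max(np.abs(cur - prev))
        prev = cur
        if err < rtol:
            return cur
    raise RuntimeError(
        f"gamma quadrature did not stabilize at {n} nodes "
        f"(last log-change {err:.2e}; gamma_mean={hyper.gamma_mean:g}, beta={hyper.beta:g})"
    )


# ---------------------------------------------------------------------------
# public marginals (per spec contracts; scalar or array friendly)


def marginal_denovo(
    x_dn,
    mu,
    design: StudyDesign,
    hyper: Hyperparameters,
    model: Literal["H0", "H1"] = "H0",
) -> float | np.ndarray:
    """Marginal likelihood of the de novo count under H0 or H1.

    H0 is Poisson with rate ``2 N mu``; H1 mixes the Poisson rate over the
    Gamma relative-risk prior, giving a negative-binomial-type closed form.
    """
    a = 2.0 * design.n_trios * np.asarray(mu, dtype=float)
    x = np.asarray(x_dn, dtype=float)
    if model == "H0":
        out = np.exp(_log_pois(x, a))
    else:
        out = np.exp(_log_nb_denovo(x, a, hyper.gamma_mean, hyper.beta))
    return float(out) if np.isscalar(x_dn) else out


def marginal_casecontrol(
    x1,
    x0,
    exposures: tuple[float, float],
    hyper: Hyperparameters,
    model: Literal["H0", "H1"] = "H0",
) -> float | np.ndarray:
    """Marginal likelihood of the pseudo case/control counts.

    The shared allele frequency is integrated conjugately; under H1 the
    case-arm exposure is additionally scaled by gamma, integrated against its
    Gamma prior by quadrature.
    """
    e1, e0 = exposures
    if e1 == 0 and e0 == 0:
        if np.any(np.asarray(x1) > 0) or np.any(np.asarray(x0) > 0):
            raise InvalidParameterError("nonzero counts with zero exposure")
        return 1.0 if np.isscalar(x1) else np.ones(np.shape(x1))
    if model == "H0":
        out = np.exp(_log_cc_closed(np.asarray(x1, float), np.asarray(x0, float), e1, e0, hyper.rho0, hyper.nu0))
    else:
        out = np.exp(
            _h1_log_marginal(
                np.atleast_1d(np.asarray(x1, float) * 0.0),
                np.atleast_1d(x1),
                np.atleast_1d(x0),
                np.atleast_1d(np.asarray(x1, float) * 0.0),
                e1,
                e0,
                hyper,
                include_dn=False,
            )
        )
    return float(np.squeeze(out)) if np.isscalar(x1) else np.reshape(out, np.shape(x1))


# ---------------------------------------------------------------------------
# vectorized Bayes factors


def log10_bf_arrays(
    x_dn,
    x1,
    x0,
    mu,
    design: StudyDesign,
    hyper: Hyperparameters,
    joint: bool = True,
    denovo_only: bool = False,
):
    """Per-gene log10 Bayes factors for aligned count/rate arrays.

    Returns ``(log10_bf, log10_bf_dn, log10_bf_cc)``.  With ``joint`` the de
    novo and case-control terms share one gamma integral (the model's single
    integral over gamma); otherwise the two streams are integrated
    independently and the BF factorizes (the de-novo-only / fast path).
    """
    x_dn = np.asarray(x_dn, dtype=float)
    x1 = np.asarray(x1, dtype=float)
    x0 = np.asarray(x0, dtype=float)
    a = 2.0 * design.n_trios * np.asarray(mu, dtype=float)
    e1, e0 = design.exposure_case, design.exposure_control

    log_bf_dn = _log_nb_denovo(x_dn, a, hyper.gamma_mean, hyper.beta) - _log_pois(x_dn, a)
    if denovo_only:
        lb = log_bf_dn / LN10
        return lb, lb, np.zeros_like(lb)

    log_h0_cc = _log_cc_closed(x1, x0, e1, e0, hyper.rho0, hyper.nu0)
    if joint:
        log_h1 = _h1_log_marginal(x_dn, x1, x0, a, e1, e0, hyper)
        log_h0 = _log_pois(x_dn, a) + log_h0_cc
        log_bf = log_h1 - log_h0
        log_h1_cc = _h1_log_marginal(x_dn, x1, x0, a, e1, e0, hyper, include_dn=False)
        log_bf_cc = log_h1_cc - log_h0_cc
    else:
        log_h1_cc = _h1_log_marginal(x_dn, x1, x0, a, e1, e0, hyper, include_dn=False)
        log_bf_cc = log_h1_cc - log_h0_cc
        log_bf = log_bf_dn + log_bf_cc
    return log_bf / LN10, log_bf_dn / LN10, log_bf_cc / LN10


def combine_categories(
    log10_bf_by_cat: Mapping[str, float | np.ndarray],
    hyper_by_cat: Mapping[str, Hyperparameters],
):
    """Total log10 BF: product over categories after damaging-fraction shrink.

    Each category's BF is replaced by ``w * BF + (1 - w)`` — a mixture with an
    evidence-free component for variants of the category that do not damage
    the protein — and the adjusted BFs multiply.
    """
    total = 0.0
    for cat, l10 in log10_bf_by_cat.items():
        w = hyper_by_cat[cat].w
        lb = np.asarray(l10, dtype=float) * LN10
        if w >= 1.0:
            adj = lb
        elif w <= 0.0:
            adj = np.zeros_like(lb)
        else:
            adj = np.logaddexp(np.log(w) + lb, np.log1p(-w))
        total = total + adj / LN10
    return total


def bayes_factor_gene(
    rec: GeneRecord,
    design: StudyDesign,
    hyper: Mapping[str, Hyperparameters] | Hyperparameters,
    joint: bool = True,
) -> BayesFactorResult:
    """Bayes factors of one gene, per category and combined."""
    if isinstance(hyper, Hyperparameters):
        hyper = {cat: hyper for cat in design.categories}
    bf_dn: dict[str, float] = {}
    bf_cc: dict[str, float] = {}
    bf_cat: dict[str, float] = {}
    for cat in design.categories:
        if cat not in rec.mu or not np.isfinite(rec.mu[cat]):
            # no usable data for this category: no evidence either way
            bf_dn[cat] = bf_cc[cat] = bf_cat[cat] = 0.0
            continue
        lb, lb_dn, lb_cc = log10_bf_arrays(
            [rec.x_dn.get(cat, 0)],
            [rec.x1(cat)],
            [rec.x0(cat)],
            [rec.mu[cat]],
            design,
            hyper[cat],
            joint=joint,
        )
        bf_dn[cat] = float(lb_dn[0])
        bf_cc[cat] = float(lb_cc[0])
        bf_cat[cat] = float(lb[0])
    present = {c: h for c, h in hyper.items() if c in bf_cat}
    total = float(combine_categories(bf_cat, present))
    return BayesFactorResult(
        gene_id=rec.gene_id,
        log10_bf_dn=bf_dn,
        log10_bf_cc=bf_cc,
        log10_bf_category=bf_cat,
        log10_bf_total=total,
    )


def approx_bayes_factor(
    rec: GeneRecord,
    design: StudyDesign,
    hyper: Hyperparameters,
    category: str = "LoF",
) -> float:
    """Plug-in approximation to the gene Bayes factor (likelihood-ratio form).

    Instead of integrating gamma and q out, the likelihood ratio is evaluated
    at Bayesian posterior-mean estimates.  Each estimate is a weighted average
    of the count-based estimate and the prior mean, the prior receiving weight
    ``nu / (nu + exposure)``; with no data the estimates collapse to the prior
    means, with abundant data to the maximum-likelihood estimates.
    """
    x_dn = rec.x_dn.get(category, 0)
    x1 = rec.x1(category)
    x0 = rec.x0(category)
    a = 2.0 * design.n_trios * rec.mu[category]
    e1, e0 = design.exposure_case, design.exposure_control

    gamma_hat = (hyper.gamma_mean * hyper.beta + x_dn) / (hyper.beta + a)
    q1_hat = (hyper.rho1 + x1 + x0) / (hyper.nu1 + e1 * gamma_hat + e0)
    q0_hat = (hyper.rho0 + x1 + x0) / (hyper.nu0 + e1 + e0)

    log_h1 = (
        _log_pois(x_dn, a * gamma_hat)
        + _log_pois(x1, e1 * q1_hat * gamma_hat)
        + _log_pois(x0, e0 * q1_hat)
    )
    log_h0 = (
        _log_pois(x_dn, a) + _log_pois(x1, e1 * q0_hat) + _log_pois(x0, e0 * q0_hat)
    )
    return float(np.exp(log_h1 - log_h0))
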