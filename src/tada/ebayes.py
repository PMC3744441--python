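"""Empirical-Bayes estimation of the prior (hyper)parameters.

The hierarchical model treats each gene as a draw from a two-component
mixture: with probability ``pi`` it is a risk gene (H1), otherwise null (H0).
The marginal likelihood of the whole gene table,

    L(hyper) = prod_i [ pi * P(d_i | H1, hyper) + (1 - pi) * P(d_i | H0, hyper) ],

is maximized over the six prior parameters (gamma_mean, beta, rho1, nu1,
rho0, nu0) with ``pi`` held fixed at its externally estimated value.  Each
mutation category is fitted independently.

The optimizer works on log-reparameterized coordinates — (log gamma_mean,
log beta, log prior means of q, log prior shapes) — so the flat directions of
the likelihood (notably beta) are bounded multiplicatively and rescaling the
raw parameters does not change the optimum.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import optimize

from . import bayes
from .bayes import Hyperparameters
from .gene_model import GeneRecord, StudyDesign

__all__ = ["FitResult", "mixture_loglik", "fit_hyperparameters", "category_arrays"]

# box bounds on the natural scale: gamma_mean, beta, q means, q shapes
BOUNDS = {
    "gamma_mean": (1.1, 500.0),
    "beta": (1e-3, 1e3),
    "q_mean": (1e-7, 0.049),
    "q_shape": (1e-2, 1e3),
}

_FIT_NODES = 32  # fixed quadrature order inside the optimizer


@dataclass
class FitResult:
    """Outcome of one empirical-Bayes fit."""

    hyper: Hyperparameters
    loglik: float
    converged: bool
    n_starts: int
    trace: list[dict] = field(default_factory=list)


def category_arrays(records: Sequence[GeneRecord], category: str):
    """Aligned (mu, x_dn, x1, x0, gene_ids) arrays for one category."""
    recs = [r for r in records if category in r.mu]
    mu = np.array([r.mu[category] for r in recs], dtype=float)
    x_dn = np.array([r.x_dn.get(category, 0) for r in recs], dtype=float)
    x1 = np.array([r.x1(category) for r in recs], dtype=float)
    x0 = np.array([r.x0(category) for r in recs], dtype=float)
    ids = [r.gene_id for r in recs]
    return mu, x_dn, x1, x0, ids


def _mixture_loglik_arrays(
    mu, x_dn, x1, x0, design: StudyDesign, hyper: Hyperparameters, nodes=None
) -> np.ndarray:
    a = 2.0 * design.n_trios * mu
    e1, e0 = design.exposure_case, design.exposure_control
    log_h0 = bayes._log_pois(x_dn, a) + bayes._log_cc_closed(
        x1, x0, e1, e0, hyper.rho0, hyper.nu0
    )
    log_h1 = bayes._h1_log_marginal(x_dn, x1, x0, a, e1, e0, hyper, nodes=nodes)
    if hyper.pi <= 0:
        return log_h0
    return np.logaddexp(np.log(hyper.pi) + log_h1, np.log1p(-hyper.pi) + log_h0)


def mixture_loglik(
    records: Sequence[GeneRecord],
    design: StudyDesign,
    hyper: Hyperparameters,
    category: str = "LoF",
) -> float:
    """Marginal log-likelihood of all genes under the two-component mixture."""
    mu, x_dn, x1, x0, ids = category_arrays(records, category)
    terms = _mixture_loglik_arrays(mu, x_dn, x1, x0, design, hyper)
    bad = ~np.isfinite(terms)
    if bad.any():
        raise FloatingPointError(
            f"non-finite mixture likelihood for gene {ids[int(np.flatnonzero(bad)[0])]!r}"
        )
    return float(terms.sum())


def _theta_to_hyper(theta: np.ndarray, pi: float, w: float) -> Hyperparameters:
    g, b, m1, r1, m0, r0 = np.exp(theta)
    return Hyperparameters(
        gamma_mean=g, beta=b, rho1=r1, nu1=r1 / m1, rho0=r0, nu0=r0 / m0, pi=pi, w=w
    )


def _log_bounds():
    lo = np.log(
        [
            BOUNDS["gamma_mean"][0],
            BOUNDS["beta"][0],
            BOUNDS["q_mean"][0],
            BOUNDS["q_shape"][0],
            BOUNDS["q_mean"][0],
            BOUNDS["q_shape"][0],
        ]
    )
    hi = np.log(
        [
            BOUNDS["gamma_mean"][1],
            BOUNDS["beta"][1],
            BOUNDS["q_mean"][1],
            BOUNDS["q_shape"][1],
            BOUNDS["q_mean"][1],
            BOUNDS["q_shape"][1],
        ]
    )
    return lo, hi


def _initial_theta(mu, x_dn, x1, x0, design: StudyDesign, pi: float) -> np.ndarray:
    """Moment-based starting point."""
    a = 2.0 * design.n_trios * mu
    e1, e0 = design.exposure_case, design.exposure_control
    exposure = e1 + e0
    if exposure > 0:
        q0 = (x1.sum() + x0.sum()) / (mu.size * exposure)
    else:
        q0 = 1e-3
    q0 = float(np.clip(q0, 2e-7, 0.04))
    q1 = float(np.clip(q0 * 0.3, 1.5e-7, 0.04))
    if a.sum() > 0:
        lam = max(x_dn.mean() / a.mean(), 1.0)
        g = 1.0 + (lam - 1.0) / pi
    else:
        g = 10.0
    g = float(np.clip(g, 1.5, 400.0))
    return np.log([g, 1.0, q1, 0.5, q0, 0.5])


def fit_hyperparameters(
    records: Sequence[GeneRecord],
    design: StudyDesign,
    pi: float = 1000.0 / 18000.0,
    category: str = "LoF",
    w: float = 1.0,
    n_starts: int = 5,
    seed: int = 0,
    gtol: float = 1e-8,
    maxiter: int = 400,
) -> FitResult:
    """Maximize the mixture marginal likelihood over the prior parameters.

    Multi-start L-BFGS-B on the log-parameters; the first start is a
    moment-based initial point, the remainder jitter it multiplicatively.
    Returns the best converged optimum (or the best point overall if no start
    reports convergence, flagged accordingly).
    """
    if len(records) < 2:
        raise ValueError("need at least 2 gene records to fit hyperparameters")
    mu, x_dn, x1, x0, _ = category_arrays(records, category)
    if mu.size < 2:
        raise ValueError(f"fewer than 2 records carry category {category!r}")

    lo, hi = _log_bounds()
    theta0 = np.clip(_initial_theta(mu, x_dn, x1, x0, design, pi), lo, hi)
    rng = np.random.default_rng(seed)

    def objective(theta: np.ndarray) -> float:
        hyper = _theta_to_hyper(np.clip(theta, lo, hi), pi, w)
        terms = _mixture_loglik_arrays(
            mu, x_dn, x1, x0, design, hyper, nodes=_FIT_NODES
        )
        val = terms.sum()
        if not np.isfinite(val):
            return 1e12
        return -float(val)

    trace: list[dict] = []
    best = None
    for s in range(n_starts):
        start = theta0 if s == 0 else np.clip(
            theta0 + rng.normal(scale=0.7, size=theta0.size), lo, hi
        )
        try:
            res = optimize.minimize(
                objective,
                start,
                method="L-BFGS-B",
                bounds=list(zip(lo, hi)),
                options={"maxiter": maxiter, "ftol": gtol, "gtol": gtol},
            )
        except Exception as exc:  # noqa: BLE001 - recorded, other starts continue
            trace.append({"start": s, "error": repr(exc)})
            continue
        trace.append(
            {
                "start": s,
                "theta0": start.tolist(),
                "theta": res.x.tolist(),
                "neg_loglik": float(res.fun),
                "success": bool(res.success),
                "nit": int(res.nit),
            }
        )
        if best is None or res.fun < best.fun:
            best = res
    if best is None:
        raise RuntimeError(f"all {n_starts} optimizer starts failed: {trace}")

    hyper = _theta_to_hyper(np.clip(best.x, lo, hi), pi, w)
    # final log-likelihood with the adaptive (full-accuracy) quadrature
    loglik = float(
        _mixture_loglik_arrays(mu, x_dn, x1, x0, design, hyper).sum()
    )
    converged = bool(best.success)
    if not converged:
        warnings.warn("no optimizer start reported convergence", stacklevel=2)
    return FitResult(
        hyper=hyper, loglik=loglik, converged=converged, n_starts=n_starts, trace=trace
    )
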