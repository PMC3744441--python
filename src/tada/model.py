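"""Model/Results interface over the hierarchical-Bayes association test.

``TADA`` is constructed from a gene table and a study design; ``fit()``
estimates the prior parameters per mutation category by empirical Bayes and
returns a ``TADAResults`` carrying those estimates, the marginal
log-likelihoods and convergence diagnostics.  Per-gene inference (Bayes
factors, null-simulation p-values, q-values) hangs off the results object.

    >>> model = TADA.from_dataframe(gene_table, n_trios=1000)
    >>> res = model.fit(seed=1)
    >>> print(res.summary())
    >>> table = res.gene_results(seed=1, null_pool_size=100_000)
"""

from __future__ import annotations

from typing import Mapping, Sequence

import pandas as pd

from . import ebayes, significance
from .bayes import Hyperparameters, bayes_factor_gene
from .ebayes import FitResult
from .gene_model import GeneRecord, StudyDesign, frame_to_records

__all__ = ["TADA", "TADAResults"]


class TADA:
    """Gene-level rare-variant association model.

    Parameters
    ----------
    records
        Per-gene count records (one per gene, with per-category counts and
        mutation rates).
    design
        Trio / case / control sample sizes and the category list.
    pi
        Prior fraction of risk genes, held fixed during fitting.
    w_mis
        Probability that a predicted-damaging missense variant is truly
        damaging; applied to every category except ``LoF``.
    """

    def __init__(
        self,
        records: Sequence[GeneRecord],
        design: StudyDesign,
        pi: float = 1000.0 / 18000.0,
        w_mis: float = 0.5,
    ) -> None:
        if len(records) == 0:
            raise ValueError("no gene records supplied")
        self.records = list(records)
        self.design = design
        self.pi = float(pi)
        self.w_mis = float(w_mis)

    @classmethod
    def from_dataframe(
        cls,
        frame: pd.DataFrame,
        n_trios: int = 0,
        n_cases: int = 0,
        n_controls: int = 0,
        **kwargs,
    ) -> "TADA":
        """Build from a long gene table (gene, category, mu, counts...)."""
        cats = tuple(pd.unique(frame["category"]))
        design = StudyDesign(
            n_trios=n_trios, n_cases=n_cases, n_controls=n_controls, categories=cats
        )
        return cls(frame_to_records(frame), design, **kwargs)

    def loglike(self, hyper: Mapping[str, Hyperparameters]) -> float:
        """Mixture marginal log-likelihood summed over categories."""
        return sum(
            ebayes.mixture_loglik(self.records, self.design, hyper[cat], category=cat)
            for cat in self.design.categories
            if cat in hyper
        )

    def fit(self, n_starts: int = 5, seed: int = 0, **fit_kwargs) -> "TADAResults":
        """Empirical-Bayes fit of the prior parameters, per category."""
        fits: dict[str, FitResult] = {}
        for i, cat in enumerate(self.design.categories):
            w = 1.0 if cat == "LoF" else self.w_mis
            fits[cat] = ebayes.fit_hyperparameters(
                self.records,
                self.design,
                pi=self.pi,
                category=cat,
                w=w,
                n_starts=n_starts,
                seed=seed + i,
                **fit_kwargs,
            )
        return TADAResults(self, fits)


class TADAResults:
    """Fitted priors plus per-gene inference."""

    def __init__(self, model: TADA, fits: Mapping[str, FitResult]) -> None:
        self.model = model
        self.fits = dict(fits)
        self.hyperparameters: dict[str, Hyperparameters] = {
            cat: fit.hyper for cat, fit in fits.items()
        }
        self.loglik = float(sum(fit.loglik for fit in fits.values()))
        self.converged = all(fit.converged for fit in fits.values())

    def bayes_factors(self, joint: bool = True) -> pd.DataFrame:
        """Per-gene log10 Bayes factors (per category and combined)."""
        rows = []
        for rec in self.model.records:
            bf = bayes_factor_gene(rec, self.model.design, self.hyperparameters, joint=joint)
            row = {"gene": rec.gene_id, "log10_bf_total": bf.log10_bf_total}
            for cat, v in bf.log10_bf_category.items():
                row[f"log10_bf_{cat}"] = v
            rows.append(row)
        return pd.DataFrame(rows)

    def gene_results(
        self,
        null_pool_size: int = significance.DEFAULT_POOL_SIZE,
        seed: int = 0,
        joint: bool = True,
    ) -> pd.DataFrame:
        """Bayes factors with null-simulation p-values and BH q-values."""
        return significance.test_genes(
            self.model.records,
            self.model.design,
            self.hyperparameters,
            B=null_pool_size,
            seed=seed,
            joint=joint,
        )

    def summary(self) -> str:
        """Plain-text summary of the fitted priors, statsmodels style."""
        d = self.model.design
        lines = [
            "Hierarchical-Bayes rare-variant association (TADA)",
            "=" * 58,
            f"Genes: {len(self.model.records):>6}    Trios: {d.n_trios}   "
            f"Cases: {d.n_cases}   Controls: {d.n_controls}",
            f"pi (risk-gene fraction, fixed): {self.model.pi:.4f}",
            f"Marginal log-likelihood: {self.loglik:.3f}   converged: {self.converged}",
            "-" * 58,
            f"{'category':<10}{'gamma_mean':>11}{'beta':>9}{'E[q|H1]':>11}{'E[q|H0]':>11}{'w':>6}",
        ]
        for cat, h in self.hyperparameters.items():
            lines.append(
                f"{cat:<10}{h.gamma_mean:>11.3f}{h.beta:>9.3f}"
                f"{h.q1_mean:>11.3e}{h.q0_mean:>11.3e}{h.w:>6.2f}"
            )
        lines.append("=" * 58)
        return "\n".join(lines)

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return f"<TADAResults: {len(self.model.records)} genes, loglik={self.loglik:.2f}>"
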