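"""Domain types and the Poisson rate model for rare-variant counts.

The unit of analysis is a gene with, per mutation category (e.g. loss-of-
function "LoF" and probably-damaging missense "Mis3"), a per-chromosome
mutation rate ``mu`` and five observed counts: de novo events in trios,
transmitted and nontransmitted variants in parents, and carrier counts in
cases and controls.  Under a dominant, rare-variant model all counts are
approximately Poisson with rates that are simple functions of three
gene-level parameters: the mutation rate ``mu``, the relative risk ``gamma``
of the damaging "allele", and its population frequency ``q``.

Transmitted/nontransmitted counts behave like case-control data from ``N``
pseudo-cases and ``N`` pseudo-controls, so both sources are pooled into a
pseudo-case count ``x1 = case + transmitted`` with chromosome exposure
``e1 = 2(N1 + N)`` and a pseudo-control count ``x0 = control + nontransmitted``
with exposure ``e0 = 2(N0 + N)``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

__all__ = [
    "StudyDesign",
    "GeneParams",
    "RateSet",
    "GeneRecord",
    "DEFAULT_CATEGORIES",
    "LOF_SIBLING_FRACTION",
    "compute_rates",
    "scale_mutation_rate",
    "category_fractions_from_sibling_counts",
    "preprocess_counts",
    "records_to_frame",
    "frame_to_records",
    "GENE_TABLE_COLUMNS",
]

DEFAULT_CATEGORIES = ("LoF", "Mis3")

#: Fraction of single-nucleotide de novo events that are loss-of-function,
#: estimated from unaffected-sibling exomes (34 LoF among 461 SNVs).
LOF_SIBLING_FRACTION = 34.0 / 461.0

#: Canonical gene-table columns, one row per gene x category.
GENE_TABLE_COLUMNS = ["gene", "category", "mu", "dn", "trans", "nontrans", "case", "control"]

VALID_ORIGINS = ("denovo", "transmitted", "nontransmitted", "case", "control")

#: q above this leaves the rare-variant regime where the Poisson
#: approximations (and the two-"allele" collapse) are justified.
RARE_Q_MAX = 0.05


class InvalidParameterError(ValueError):
    """Raised when a model parameter violates its domain."""


@dataclass(frozen=True)
class StudyDesign:
    """Sample sizes of the study: N trios, N1 cases, N0 controls."""

    n_trios: int = 0
    n_cases: int = 0
    n_controls: int = 0
    categories: tuple[str, ...] = DEFAULT_CATEGORIES

    def __post_init__(self) -> None:
        for name in ("n_trios", "n_cases", "n_controls"):
            v = getattr(self, name)
            if int(v) != v or v < 0:
                raise InvalidParameterError(f"{name} must be a nonnegative integer, got {v!r}")
        if self.n_trios + self.n_cases + self.n_controls <= 0:
            warnings.warn(
                "study has no samples (N = N1 = N0 = 0); all rates will be zero",
                stacklevel=2,
            )
        cats = tuple(self.categories)
        if not cats or len(set(cats)) != len(cats):
            raise InvalidParameterError(f"categories must be nonempty and unique, got {cats!r}")
        object.__setattr__(self, "categories", cats)

    @property
    def exposure_case(self) -> float:
        """Pseudo-case chromosome exposure e1 = 2(N1 + N)."""
        return 2.0 * (self.n_cases + self.n_trios)

    @property
    def exposure_control(self) -> float:
        """Pseudo-control chromosome exposure e0 = 2(N0 + N)."""
        return 2.0 * (self.n_controls + self.n_trios)


@dataclass(frozen=True)
class GeneParams:
    """Gene-level parameters: relative risk, allele frequency, mutation rate."""

    gamma: float
    q: float
    mu: float

    def __post_init__(self) -> None:
        if not (self.mu > 0) or not np.isfinite(self.mu):
            raise InvalidParameterError(f"mutation rate must be positive, got {self.mu!r}")
        if not (self.gamma >= 0) or not np.isfinite(self.gamma):
            raise InvalidParameterError(f"relative risk must be >= 0, got {self.gamma!r}")
        if not (0 < self.q):
            raise InvalidParameterError(f"allele frequency must be in (0, {RARE_Q_MAX}], got {self.q!r}")
        if self.q > RARE_Q_MAX:
            warnings.warn(
                f"q = {self.q:g} exceeds {RARE_Q_MAX}; the rare-variant Poisson "
                "approximation is unreliable",
                stacklevel=2,
            )


@dataclass(frozen=True)
class RateSet:
    """Poisson rates for the three count classes plus the arm exposures."""

    r_dn: float
    r_case_arm: float
    r_ctrl_arm: float
    e1: float
    e0: float


def compute_rates(params: GeneParams, design: StudyDesign) -> RateSet:
    """Poisson rates of the observable counts for one gene.

    De novo events arise at rate ``2 N mu gamma`` (two chromosomes per child,
    ascertainment through the affected child multiplying the mutation rate by
    the relative risk).  The pooled pseudo-case arm carries rate
    ``e1 * q * gamma`` and the pseudo-control arm ``e0 * q`` with chromosome
    exposures ``e1 = 2(N1+N)`` and ``e0 = 2(N0+N)``; both are first-order in
    ``q``.
    """
    e1 = design.exposure_case
    e0 = design.exposure_control
    return RateSet(
        r_dn=2.0 * design.n_trios * params.mu * params.gamma,
        r_case_arm=e1 * params.q * params.gamma,
        r_ctrl_arm=e0 * params.q,
        e1=e1,
        e0=e0,
    )


def scale_mutation_rate(
    mu_total: float,
    category: str,
    fractions: Mapping[str, float] | None = None,
) -> float:
    """Per-category mutation rate: total gene rate times the category fraction.

    Category fractions are the proportions of de novo events of each class
    among all de novo SNVs, estimated from unaffected siblings; the default
    supplies only the LoF fraction (34/461).  Fractions must be in [0, 1]
    and sum to at most 1.
    """
    if mu_total < 0:
        raise InvalidParameterError(f"mu_total must be >= 0, got {mu_total!r}")
    if fractions is None:
        fractions = {"LoF": LOF_SIBLING_FRACTION}
    for cat, f in fractions.items():
        if not (0.0 <= f <= 1.0):
            raise InvalidParameterError(f"fraction for {cat!r} outside [0, 1]: {f!r}")
    if sum(fractions.values()) > 1.0 + 1e-12:
        raise InvalidParameterError(
            f"category fractions sum to {sum(fractions.values()):g} > 1"
        )
    if category not in fractions:
        raise KeyError(
            f"unknown category {category!r}; known categories: {sorted(fractions)}"
        )
    return mu_total * fractions[category]


def category_fractions_from_sibling_counts(
    category_counts: Mapping[str, int], total_snvs: int
) -> dict[str, float]:
    """Turn sibling de novo event counts per category into rate fractions."""
    if total_snvs <= 0:
        raise InvalidParameterError("total_snvs must be positive")
    fr = {c: n / total_snvs for c, n in category_counts.items()}
    if sum(fr.values()) > 1.0 + 1e-12:
        raise InvalidParameterError("category counts exceed the SNV total")
    return fr


@dataclass
class GeneRecord:
    """Observed per-category counts and mutation rates for one gene.

    All per-category mappings share the same keys.  The pseudo-case and
    pseudo-control counts are derived, never stored.
    """

    gene_id: str
    mu: dict[str, float] = field(default_factory=dict)
    x_dn: dict[str, int] = field(default_factory=dict)
    x_t: dict[str, int] = field(default_factory=dict)
    x_nt: dict[str, int] = field(default_factory=dict)
    x_case: dict[str, int] = field(default_factory=dict)
    x_ctrl: dict[str, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for name in ("x_dn", "x_t", "x_nt", "x_case", "x_ctrl"):
            for cat, v in getattr(self, name).items():
                if int(v) != v or v < 0:
                    raise InvalidParameterError(
                        f"{self.gene_id}: {name}[{cat}] must be a nonnegative integer, got {v!r}"
                    )
        for cat, m in self.mu.items():
            if not (m > 0) or not np.isfinite(m):
                raise InvalidParameterError(
                    f"{self.gene_id}: mu[{cat}] must be positive, got {m!r}"
                )

    @property
    def categories(self) -> tuple[str, ...]:
        return tuple(self.mu)

    def x1(self, category: str) -> int:
        """Pseudo-case count: case carriers plus transmitted variants."""
        return int(self.x_case.get(category, 0) + self.x_t.get(category, 0))

    def x0(self, category: str) -> int:
        """Pseudo-control count: control carriers plus nontransmitted variants."""
        return int(self.x_ctrl.get(category, 0) + self.x_nt.get(category, 0))


def records_to_frame(records: Iterable[GeneRecord]) -> pd.DataFrame:
    """Long gene table (one row per gene x category) from records."""
    rows = []
    for rec in records:
        for cat in rec.categories:
            rows.append(
                {
                    "gene": rec.gene_id,
                    "category": cat,
                    "mu": rec.mu[cat],
                    "dn": rec.x_dn.get(cat, 0),
                    "trans": rec.x_t.get(cat, 0),
                    "nontrans": rec.x_nt.get(cat, 0),
                    "case": rec.x_case.get(cat, 0),
                    "control": rec.x_ctrl.get(cat, 0),
                }
            )
    return pd.DataFrame(rows, columns=GENE_TABLE_COLUMNS)


def frame_to_records(frame: pd.DataFrame) -> list[GeneRecord]:
    """Records from a long gene table; validates duplicates and domains."""
    missing = [c for c in GENE_TABLE_COLUMNS if c not in frame.columns]
    if missing:
        raise ValueError(f"gene table missing columns: {missing}")
    dup = frame.duplicated(subset=["gene", "category"])
    if dup.any():
        i = int(np.flatnonzero(dup.to_numpy())[0])
        row = frame.iloc[i]
        raise ValueError(
            f"duplicate (gene, category) = ({row['gene']!r}, {row['category']!r}) at row {i}"
        )
    out: list[GeneRecord] = []
    for gene, grp in frame.groupby("gene", sort=False):
        rec = GeneRecord(gene_id=str(gene))
        for _, row in grp.iterrows():
            cat = str(row["category"])
            rec.mu[cat] = float(row["mu"])
            rec.x_dn[cat] = int(row["dn"])
            rec.x_t[cat] = int(row["trans"])
            rec.x_nt[cat] = int(row["nontrans"])
            rec.x_case[cat] = int(row["case"])
            rec.x_ctrl[cat] = int(row["control"])
        rec.__post_init__()
        out.append(rec)
    return out


def preprocess_counts(
    variant_table: pd.DataFrame,
    design: StudyDesign,
    freq_threshold: float = 0.01,
    control_lof_max: int = 10,
    mu_table: Mapping[str, Mapping[str, float]] | None = None,
    lof_category: str = "LoF",
) -> list[GeneRecord]:
    """Aggregate a variant-level table into per-gene count records.

    Rows carry ``gene``, ``category``, ``origin`` (one of ``denovo``,
    ``transmitted``, ``nontransmitted``, ``case``, ``control``), an optional
    population ``frequency`` and an optional ``individual`` id.  Variants at
    population frequency >= ``freq_threshold`` are dropped (common variants
    carry no rare-variant signal and violate the model), and genes with more
    than ``control_lof_max`` LoF events among controls are removed outright
    (such genes tolerate truncation and are implausible dominant risk genes).
    When an ``individual`` column is present, multiple qualifying inherited or
    case-control variants in one individual and gene collapse to a single
    carrier count, matching the two-"allele" model.

    ``mu_table`` maps gene -> category -> mutation rate; genes without a rate
    receive NaN and must be completed before analysis.
    """
    required = {"gene", "category", "origin"}
    missing = required - set(variant_table.columns)
    if missing:
        raise ValueError(f"variant table missing columns: {sorted(missing)}")
    if len(variant_table) == 0:
        warnings.warn("empty variant table; no records produced", stacklevel=2)
        return []
    bad = set(variant_table["origin"]) - set(VALID_ORIGINS)
    if bad:
        raise ValueError(f"unknown origin labels {sorted(bad)}; valid: {VALID_ORIGINS}")

    tab = variant_table
    if "frequency" in tab.columns:
        freq = tab["frequency"].fillna(0.0)
        tab = tab.loc[freq < freq_threshold]

    # collapse to one count per carrier individual for non-de-novo origins
    if "individual" in tab.columns:
        dn = tab[tab["origin"] == "denovo"]
        other = tab[tab["origin"] != "denovo"].drop_duplicates(
            subset=["gene", "category", "origin", "individual"]
        )
        tab = pd.concat([dn, other], ignore_index=True)

    counts = (
        tab.groupby(["gene", "category", "origin"]).size().unstack("origin", fill_value=0)
    )
    for origin in VALID_ORIGINS:
        if origin not in counts.columns:
            counts[origin] = 0

    ctrl_lof = counts.xs(lof_category, level="category")["control"] if (
        lof_category in counts.index.get_level_values("category")
    ) else pd.Series(dtype=int)
    drop_genes = set(ctrl_lof[ctrl_lof > control_lof_max].index)

    records: list[GeneRecord] = []
    for gene, grp in counts.groupby(level="gene", sort=True):
        if gene in drop_genes:
            continue
        rec = GeneRecord(gene_id=str(gene))
        for (_, cat), row in grp.iterrows():
            mu = np.nan
            if mu_table is not None:
                mu = float(mu_table.get(gene, {}).get(cat, np.nan))
            rec.mu[cat] = mu
            rec.x_dn[cat] = int(row["denovo"])
            rec.x_t[cat] = int(row["transmitted"])
            rec.x_nt[cat] = int(row["nontransmitted"])
            rec.x_case[cat] = int(row["case"])
            rec.x_ctrl[cat] = int(row["control"])
        records.append(rec)
    return records
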