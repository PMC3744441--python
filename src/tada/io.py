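"""Table and configuration I/O plus the end-to-end analysis pipeline.

The on-disk interchange format is a long TSV gene table — one row per gene
and mutation category with columns ``gene category mu dn trans nontrans case
control`` — and a YAML configuration with a versioned schema.  The pipeline
mirrors a real-data workflow: per-category empirical-Bayes fit, per-gene
Bayes factors combined across categories, null-simulation p-values,
Benjamini-Hochberg q-values and a genomic-control diagnostic.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict
from pathlib import Path
from typing import Any, Mapping

import numpy as np
import pandas as pd
import yaml

from . import __version__, baselines, ebayes, significance
from .bayes import Hyperparameters
from .gene_model import GENE_TABLE_COLUMNS, GeneRecord, StudyDesign, frame_to_records

logger = logging.getLogger("tada")

__all__ = [
    "read_gene_table",
    "write_gene_table",
    "load_config",
    "default_config",
    "run_full_analysis",
]

_CONFIG_SCHEMA_VERSION = 1

_DEFAULT_CONFIG: dict[str, Any] = {
    "schema_version": _CONFIG_SCHEMA_VERSION,
    "design": {"n_trios": 0, "n_cases": 0, "n_controls": 0},
    "categories": ["LoF"],
    "pi": 1000.0 / 18000.0,
    "w_mis": 0.5,
    "joint": True,
    "null_pool_size": significance.DEFAULT_POOL_SIZE,
    "freq_threshold": 0.01,
    "control_lof_max": 10,
    "n_starts": 5,
}


def default_config(**overrides: Any) -> dict[str, Any]:
    """A fresh configuration dict with defaults, optionally overridden."""
    cfg = {k: (dict(v) if isinstance(v, dict) else v) for k, v in _DEFAULT_CONFIG.items()}
    for key, val in overrides.items():
        if key not in cfg:
            raise KeyError(f"unknown config key {key!r}; valid keys: {sorted(cfg)}")
        cfg[key] = val
    return cfg


def load_config(path: str | Path) -> dict[str, Any]:
    """Load and validate a YAML configuration against the schema."""
    raw = yaml.safe_load(Path(path).read_text())
    if not isinstance(raw, dict):
        raise ValueError(f"config {path} does not contain a mapping")
    unknown = set(raw) - set(_DEFAULT_CONFIG)
    if unknown:
        raise ValueError(f"unknown config keys {sorted(unknown)}; valid: {sorted(_DEFAULT_CONFIG)}")
    version = raw.get("schema_version", _CONFIG_SCHEMA_VERSION)
    if version != _CONFIG_SCHEMA_VERSION:
        raise ValueError(f"unsupported config schema version {version!r}")
    if "design" in raw:
        bad = set(raw["design"]) - {"n_trios", "n_cases", "n_controls"}
        if bad:
            raise ValueError(f"unknown design keys {sorted(bad)}")
    cfg = default_config()
    for key, val in raw.items():
        if isinstance(cfg.get(key), dict) and isinstance(val, dict):
            cfg[key].update(val)
        else:
            cfg[key] = val
    return cfg


def design_from_config(config: Mapping[str, Any]) -> StudyDesign:
    d = config["design"]
    return StudyDesign(
        n_trios=d.get("n_trios", 0),
        n_cases=d.get("n_cases", 0),
        n_controls=d.get("n_controls", 0),
        categories=tuple(config["categories"]),
    )


def read_gene_table(path: str | Path) -> list[GeneRecord]:
    """Read a long TSV gene table into validated records.

    Errors name the offending row (1-based, excluding the header).
    """
    frame = pd.read_csv(path, sep="\t")
    missing = [c for c in GENE_TABLE_COLUMNS if c not in frame.columns]
    if missing:
        raise ValueError(f"{path}: missing columns {missing}")
    counts = frame[["dn", "trans", "nontrans", "case", "control"]]
    neg = (counts.to_numpy() < 0).any(axis=1)
    if neg.any():
        raise ValueError(f"{path}: negative count at row {int(np.flatnonzero(neg)[0]) + 1}")
    try:
        return frame_to_records(frame)
    except ValueError as exc:
        raise ValueError(f"{path}: {exc}") from exc


def write_gene_table(frame_or_records, path: str | Path) -> None:
    if isinstance(frame_or_records, pd.DataFrame):
        frame = frame_or_records
    else:
        from .gene_model import records_to_frame

        frame = records_to_frame(frame_or_records)
    frame.to_csv(path, sep="\t", index=False)


def _hash_bytes(data: bytes) -> str:
    return hashlib.sha256(data).hexdigest()[:16]


def run_full_analysis(
    gene_table: pd.DataFrame | str | Path,
    config: Mapping[str, Any],
    seed: int = 0,
) -> tuple[pd.DataFrame, dict[str, Any]]:
    """Fit, test and adjust: the whole gene-discovery pipeline.

    Returns ``(results, summary)``: a per-gene results frame sorted by
    p-value and a JSON-ready summary carrying the fitted priors, the
    genomic-control factor, gene counts at q-value thresholds 0.1/0.2/0.3
    and provenance (version, seed, config and input hashes).
    """
    if isinstance(gene_table, (str, Path)):
        records = read_gene_table(gene_table)
        input_hash = _hash_bytes(Path(gene_table).read_bytes())
    else:
        records = frame_to_records(gene_table)
        input_hash = _hash_bytes(gene_table.to_csv(index=False).encode())
    config_hash = _hash_bytes(json.dumps(dict(config), sort_keys=True, default=str).encode())
    logger.info(
        "run_full_analysis version=%s seed=%d config_hash=%s input_hash=%s",
        __version__,
        seed,
        config_hash,
        input_hash,
    )

    design = design_from_config(config)
    pi = float(config["pi"])
    w_mis = float(config["w_mis"])
    hyper: dict[str, Hyperparameters] = {}
    fits: dict[str, Any] = {}
    for i, cat in enumerate(design.categories):
        w = 1.0 if cat == "LoF" else w_mis
        fit = ebayes.fit_hyperparameters(
            records,
            design,
            pi=pi,
            category=cat,
            w=w,
            n_starts=int(config["n_starts"]),
            seed=seed + i,
        )
        hyper[cat] = fit.hyper
        fits[cat] = {"loglik": fit.loglik, "converged": fit.converged, **asdict(fit.hyper)}

    results = significance.test_genes(
        records,
        design,
        hyper,
        B=int(config["null_pool_size"]),
        seed=seed + 1000,
        joint=bool(config["joint"]),
    )

    # attach observed counts and the de novo baseline p for the report
    first_cat = design.categories[0]
    mu, x_dn, x1, x0, ids = ebayes.category_arrays(records, first_cat)
    extras = pd.DataFrame(
        {
            "gene": ids,
            f"dn_{first_cat}": x_dn.astype(int),
            f"case_trans_{first_cat}": x1.astype(int),
            f"control_nontrans_{first_cat}": x0.astype(int),
            "p_denovo": baselines.denovo_test_pvalue(x_dn, mu, design),
        }
    )
    results = results.merge(extras, on="gene", how="left")

    lam = significance.genomic_control(results["p"].to_numpy())
    summary = {
        "version": __version__,
        "seed": seed,
        "config_hash": config_hash,
        "input_hash": input_hash,
        "n_genes": int(results["gene"].nunique()),
        "lambda_gc": lam,
        "hyperparameters": fits,
        "n_at_q": {
            str(t): int((results["q"] < t).sum()) for t in (0.1, 0.2, 0.3)
        },
        "top_genes": results.head(20)["gene"].tolist(),
    }
    return results, summary
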