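"""End-to-end orchestration: discovery and validation runs with manifests.

A discovery run executes pairing -> encoding -> reversal testing -> LASSO
selection -> Cox refit -> scoring -> evaluation and writes every stage's
output in its documented TSV/JSON dialect, plus a manifest recording the
config, seed, package version and content hashes so reruns are verifiable.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time as _time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np

from . import __version__
from .expression_io import (
    ClinicalTable,
    CohortBundle,
    ExpressionMatrix,
    ValidationError,
    read_clinical,
    read_expression,
    write_clinical,
    write_expression,
)
from .evaluation import DEFAULT_HORIZONS, calibration, evaluate_cohort
from .pair_encoding import (
    DEFAULT_LOG10_THRESHOLD,
    PairIndicatorMatrix,
    encode_pairs,
    results_to_frame,
    reversal_test,
    select_reversed_pairs,
)
from .regulator_pairing import GenePair, PairCatalog, build_pair_catalog, load_regulators
from .signature_fit import PairSignature, cox_refit, lasso_cox_select, risk_score
from .synthetic_data import SyntheticConfig, generate_cohort, recovery_report

log = logging.getLogger("mrgps")


@dataclass
class RunConfig:
    """Configuration of one discovery run."""

    seed: int
    expression_path: str | None = None
    clinical_path: str | None = None
    synthetic: SyntheticConfig | None = None
    r_min: float = 0.5
    p_max: float = 0.01
    log10_fisher_threshold: float = DEFAULT_LOG10_THRESHOLD
    folds: int = 10
    horizons: tuple[float, ...] = DEFAULT_HORIZONS
    group1: str = "LGG"
    group2: str = "GBM"
    outdir: str = "mrgps_run"

    def __post_init__(self) -> None:
        if self.synthetic is None:
            if not self.expression_path:
                raise ValidationError("config needs expression_path or synthetic block")
            if not self.clinical_path:
                raise ValidationError("config needs clinical_path or synthetic block")
        if not (0 <= self.r_min < 1):
            raise ValidationError("r_min must be in [0, 1)")
        if not (0 < self.p_max <= 1):
            raise ValidationError("p_max must be in (0, 1]")
        if self.log10_fisher_threshold > 0:
            raise ValidationError("log10_fisher_threshold must be <= 0")

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        if self.synthetic is not None:
            d["synthetic"] = dataclasses.asdict(self.synthetic)
        return d


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _stage(name: str):
    class _Timer:
        def __enter__(self):
            self.t0 = _time.perf_counter()
            log.info("stage %s: start", name)
            return self

        def __exit__(self, exc_type, exc, tb):
            dt = _time.perf_counter() - self.t0
            if exc is not None:
                log.error("stage %s: failed after %.2fs: %s", name, dt, exc)
                raise RuntimeError(f"stage {name!r} failed: {exc}") from exc
            log.info("stage %s: done in %.2fs", name, dt)

    return _Timer()


def run_discovery(config: RunConfig) -> dict:
    """Full discovery pipeline; returns a summary dict and writes artifacts."""
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)

    truth = None
    with _stage("load"):
        if config.synthetic is not None:
            expr, clinical, truth = generate_cohort(config.synthetic)
            write_expression(expr, outdir / "expression.tsv")
            write_clinical(clinical, outdir / "clinical.tsv")
        else:
            expr = read_expression(config.expression_path)
            clinical = read_clinical(config.clinical_path)
        CohortBundle(expr, clinical)

    tumor_ids = [
        s for s, g in zip(clinical.sample_ids, clinical.grade)
        if g in (config.group1, config.group2)
    ]
    tumor_clin = clinical.subset(tumor_ids)

    with _stage("pairs"):
        catalog = build_pair_catalog(expr, load_regulators(), config.r_min, config.p_max)
        catalog.write(outdir / "catalog.tsv")
    with _stage("encode"):
        indicators = encode_pairs(expr, catalog)
        tumor_ind = PairIndicatorMatrix(
            indicators.pairs, tumor_ids,
            indicators.to_frame()[tumor_ids].to_numpy(),
        )
        indicators.write(outdir / "indicators.tsv")
    with _stage("reversal-test"):
        results = reversal_test(
            tumor_ind, tumor_clin, config.group1, config.group2,
            config.log10_fisher_threshold,
        )
        results_to_frame(results).to_csv(outdir / "reversal_test.tsv", sep="\t", index=False)
        selected = select_reversed_pairs(results, config.log10_fisher_threshold)
        if not selected:
            raise RuntimeError("no reversed pairs passed the Fisher threshold")
        candidate_ind = tumor_ind.subset_pairs([r.pair for r in selected])
    with _stage("lasso"):
        chosen = lasso_cox_select(
            candidate_ind, tumor_clin, folds=config.folds, seed=config.seed
        )
        if not chosen:
            raise RuntimeError("LASSO selected no pairs")
    with _stage("refit"):
        signature = cox_refit(chosen, candidate_ind, tumor_clin)
        signature.save(outdir / "signature.json")
    with _stage("score"):
        scores = risk_score(signature, tumor_ind)
        scores.write(outdir / "scores.tsv")
    with _stage("evaluate"):
        metrics = evaluate_cohort(scores, tumor_clin, config.horizons)
        cal = calibration(signature, tumor_ind, tumor_clin, horizon=config.horizons[-1])
        metrics["calibration"] = cal.table.to_dict("records")
        if truth is not None:
            rec = recovery_report(truth, [r.pair for r in selected], signature)
            metrics["recovery"] = {
                "precision": rec.precision,
                "recall": rec.recall,
                "mean_abs_coef_error": rec.mean_abs_coef_error,
            }
        (outdir / "metrics.json").write_text(json.dumps(metrics, indent=2, default=float))

    manifest = {
        "package_version": __version__,
        "seed": config.seed,
        "config": config.to_dict(),
        "artifacts": {
            p.name: _sha256(p)
            for p in sorted(outdir.iterdir())
            if p.suffix in (".tsv", ".json") and p.name != "manifest.json"
        },
    }
    manifest["manifest_hash"] = hashlib.sha256(
        json.dumps(manifest, sort_keys=True).encode()
    ).hexdigest()
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return {
        "signature": signature,
        "scores": scores,
        "metrics": metrics,
        "manifest": manifest,
        "n_catalog_pairs": len(catalog),
        "n_selected_pairs": len(selected),
    }


def encode_signature_pairs(
    expr: ExpressionMatrix, signature: PairSignature
) -> PairIndicatorMatrix:
    """Indicator matrix for just the signature's pairs (all genes required)."""
    gene_index = {g: i for i, g in enumerate(expr.gene_ids)}
    rows = []
    for m, g in signature.pairs:
        for gene in (m, g):
            if gene not in gene_index:
                raise KeyError(
                    f"signature gene {gene!r} missing from validation cohort"
                )
        rows.append(
            np.where(expr.values[gene_index[m]] >= expr.values[gene_index[g]], 1, -1)
        )
    return PairIndicatorMatrix(signature.pairs, list(expr.sample_ids), np.array(rows))


def run_validate(
    signature: PairSignature,
    expr: ExpressionMatrix,
    clinical: ClinicalTable,
    horizons: Sequence[float] = DEFAULT_HORIZONS,
) -> dict:
    """Score a cohort with a fixed signature and compute the metric suite."""
    with _stage("validate-encode"):
        indicators = encode_signature_pairs(expr, signature)
    with _stage("validate-score"):
        scores = risk_score(signature, indicators)
    with _stage("validate-evaluate"):
        metrics = evaluate_cohort(scores, clinical, horizons)
        cal = calibration(signature, indicators, clinical, horizon=horizons[-1])
        metrics["calibration"] = cal.table.to_dict("records")
    metrics["n_samples"] = len(scores.sample_ids)
    return metrics
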