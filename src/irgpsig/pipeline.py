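"""End-to-end orchestration: discovery on a training cohort, validation on
external cohorts.

Discovery runs the full chain: survival exclusion -> train/test split ->
immune-gene intersection -> pair enumeration and scoring -> prevalence
filter (train OR test) -> log-rank/FDR prescreen (train only) -> repeated
CV-lasso selection -> final signature and training stratification report.
All intermediate artifacts are plain TSV so any stage can be inspected or
replaced, and the master seed fans out to per-stage seeds by fixed offsets
so stages can be rerun in isolation reproducibly.
"""
from __future__ import annotations

import dataclasses
import json
import logging
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from . import evaluation, io_formats, lasso_cox, pairs, prescreen, risk
from .containers import (
    ExpressionMatrix,
    IndicatorMatrix,
    SignatureModel,
    SurvivalCohort,
)
from .synthetic import split_cohort

log = logging.getLogger(__name__)

# fixed per-stage seed offsets from the master seed
SEED_SPLIT = 11
SEED_SELECTION = 101


@dataclasses.dataclass
class RunConfig:
    """Configuration for a discovery or validation run."""

    expression: str
    clinical: str
    outdir: str
    immune_genes: str | None = None
    signature: str | None = None
    split_fraction: float = 0.6
    min_months: float = 1.0
    filter_threshold: float = 0.9
    fdr_cut: float = 0.01
    iterations: int = 1000
    folds: int = 10
    lambda_rule: str = "min"
    final_rule: str = "modal_support"
    dichotomize_rule: str = "median"
    horizons: tuple[float, ...] = evaluation.DEFAULT_HORIZONS
    covariates: tuple[str, ...] = ("age", "sex", "stage")
    seed: int = 0

    @classmethod
    def from_file(cls, path: str | Path, **overrides) -> "RunConfig":
        """Parse a flat ``key = value`` config file."""
        values: dict[str, object] = {}
        with open(path) as fh:
            for lineno, line in enumerate(fh, 1):
                line = line.strip()
                if not line or line.startswith("#"):
                    continue
                if "=" not in line:
                    raise ValueError(f"{path}:{lineno}: expected 'key = value'")
                key, _, val = line.partition("=")
                values[key.strip()] = val.strip()
        values.update({k: v for k, v in overrides.items() if v is not None})
        field_types = {f.name: f.type for f in dataclasses.fields(cls)}
        parsed: dict[str, object] = {}
        for key, val in values.items():
            if key not in field_types:
                raise ValueError(f"unknown config key {key!r}")
            if key in ("horizons", "covariates") and isinstance(val, str):
                items = [v.strip() for v in val.split(",") if v.strip()]
                parsed[key] = (
                    tuple(float(v) for v in items)
                    if key == "horizons"
                    else tuple(items)
                )
            elif key in ("split_fraction", "min_months", "filter_threshold", "fdr_cut") and isinstance(val, str):
                parsed[key] = float(val)
            elif key in ("iterations", "folds", "seed") and isinstance(val, str):
                parsed[key] = int(val)
            else:
                parsed[key] = val
        return cls(**parsed)


def _load_inputs(config: RunConfig) -> tuple[ExpressionMatrix, SurvivalCohort]:
    for attr in ("expression", "clinical"):
        path = Path(getattr(config, attr))
        if not path.exists():
            raise FileNotFoundError(f"{attr} file not found: {path}")
    expr = io_formats.read_expression_table(config.expression)
    cohort = io_formats.read_clinical_table(config.clinical)
    common = [p for p in cohort.patient_ids if p in set(expr.sample_ids)]
    dropped = len(cohort) - len(common)
    if dropped:
        log.info("[load] %d clinical patients lack expression data", dropped)
    if not common:
        raise ValueError("no patients shared between expression and clinical tables")
    return expr.subset_samples(common), cohort.subset(common)


def _indicator_for(
    expr: ExpressionMatrix, pair_list: Sequence
) -> IndicatorMatrix:
    return pairs.score_pairs(expr, pair_list)


def run_discovery(config: RunConfig) -> tuple[SignatureModel, dict]:
    """Train a pair signature end to end; returns (signature, reports).

    Writes signature.tsv, tally.tsv, screen.tsv, train_scores.tsv and
    report.json into ``config.outdir``.
    """
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    expr, cohort = _load_inputs(config)
    log.info("[load] %d genes x %d patients", *expr.shape)

    cohort = io_formats.apply_survival_exclusion(cohort, config.min_months)
    expr = expr.subset_samples(cohort.patient_ids)
    log.info("[exclude] %d patients retained", len(cohort))

    (expr_tr, coh_tr), (expr_te, coh_te) = split_cohort(
        expr, cohort, config.split_fraction, seed=config.seed + SEED_SPLIT
    )
    log.info("[split] train=%d test=%d", len(coh_tr), len(coh_te))

    gene_lists = [expr.gene_ids]
    immune = (
        io_formats.read_gene_list(config.immune_genes)
        if config.immune_genes
        else expr.gene_ids
    )
    genes = pairs.common_genes(gene_lists, immune)
    all_pairs = pairs.enumerate_pairs(genes)
    log.info("[pairs] %d genes -> %d pairs", len(genes), len(all_pairs))

    ind_tr = _indicator_for(expr_tr, all_pairs)
    ind_te = _indicator_for(expr_te, all_pairs)
    kept = pairs.prevalence_filter(ind_tr, ind_te, config.filter_threshold)
    if not kept:
        raise ValueError("prevalence filter removed every pair")
    log.info("[filter] %d/%d pairs kept", len(kept), len(all_pairs))
    ind_tr = ind_tr.subset_pairs(kept)
    ind_te = ind_te.subset_pairs(kept)

    screened = prescreen.select_prognostic_pairs(ind_tr, coh_tr, config.fdr_cut)
    if not screened:
        raise ValueError(f"no pairs pass the FDR < {config.fdr_cut} screen")
    screen_df = pd.DataFrame(
        {
            "gene_a": [r.pair.gene_a for r in screened],
            "gene_b": [r.pair.gene_b for r in screened],
            "chi_square": [r.chi_square for r in screened],
            "p": [r.p_value for r in screened],
            "q": [r.q_value for r in screened],
        }
    )
    screen_df.to_csv(outdir / "screen.tsv", sep="\t", index=False)
    log.info("[prescreen] %d prognostic pairs", len(screened))

    sel_pairs = [r.pair for r in screened]
    ind_sel = ind_tr.subset_pairs(sel_pairs)
    ind_sel = ind_sel.subset_samples(coh_tr.patient_ids)
    X = ind_sel.values.T.astype(float)
    tally = lasso_cox.repeated_selection(
        X,
        coh_tr.time,
        coh_tr.event,
        iterations=config.iterations,
        base_seed=config.seed + SEED_SELECTION,
        n_folds=config.folds,
        rule=config.lambda_rule,
    )
    tally_df = pd.DataFrame(
        sorted(tally.size_counts.items()), columns=["model_size", "count"]
    )
    tally_df.to_csv(outdir / "tally.tsv", sep="\t", index=False)
    sizes_df = pd.DataFrame(
        {
            "seed": [r.seed for r in tally.records],
            "lambda": [r.lambda_star for r in tally.records],
            "size": [r.size for r in tally.records],
        }
    )
    sizes_df.to_csv(outdir / "iteration_sizes.tsv", sep="\t", index=False)

    signature = lasso_cox.choose_final_signature(
        tally, X, coh_tr.time, coh_tr.event, sel_pairs, rule=config.final_rule
    )
    io_formats.write_signature(signature, outdir / "signature.tsv")
    log.info("[signature] %d pairs, cutoff %.4f", len(signature), signature.cutoff)

    train_report = _stratification_report(
        signature, expr_tr, coh_tr, config, cohort_name="train"
    )
    train_report["scores"].to_csv(outdir / "train_scores.tsv", sep="\t")
    reports = {
        "n_pairs_total": len(all_pairs),
        "n_pairs_filtered": len(kept),
        "n_pairs_prognostic": len(screened),
        "size_counts": tally.size_counts,
        "signature_size": len(signature),
        "train": {k: v for k, v in train_report.items() if k != "scores"},
    }
    with open(outdir / "report.json", "w") as fh:
        json.dump(reports, fh, indent=2, default=str)
    return signature, reports


def _stratification_report(
    signature: SignatureModel,
    expr: ExpressionMatrix,
    cohort: SurvivalCohort,
    config: RunConfig,
    cohort_name: str = "cohort",
) -> dict:
    missing = [g for g in signature.genes if g not in set(expr.gene_ids)]
    if missing:
        raise KeyError(
            f"signature genes absent from {cohort_name} expression: {missing}"
        )
    ind = pairs.score_pairs(expr, signature.pairs)
    scores = risk.risk_score(signature, ind)
    scores = scores.loc[cohort.patient_ids]
    if config.dichotomize_rule == "median":
        profile = risk.dichotomize(scores, rule="median")
    else:
        profile = risk.dichotomize(scores, rule="fixed", cutoff=signature.cutoff)
    comparison = risk.km_group_comparison(profile, cohort)
    report: dict = {
        "n": len(cohort),
        "cutoff": profile.cutoff,
        "logrank_p": comparison.logrank_p,
        "hazard_ratio": comparison.hazard_ratio,
        "hr_ci": [comparison.hr_ci_low, comparison.hr_ci_high],
        "n_low": comparison.n_low,
        "n_high": comparison.n_high,
        "c_index": evaluation.harrell_cindex(
            scores.to_numpy(), cohort.time, cohort.event
        ).c_index,
        "scores": profile.to_frame(),
    }
    for h in config.horizons:
        try:
            report[f"auc_{int(h)}m"] = evaluation.time_dependent_roc(
                scores.to_numpy(), cohort.time, cohort.event, h
            ).auc
        except ValueError as exc:
            log.info("[evaluate] AUC at %s months unavailable: %s", h, exc)
            report[f"auc_{int(h)}m"] = None
    available = [c for c in config.covariates if c in cohort.data.columns]
    skipped = [c for c in config.covariates if c not in cohort.data.columns]
    if skipped:
        log.info("[cox] covariates unavailable in %s: %s", cohort_name, skipped)
    if available:
        try:
            cox = risk.multivariable_cox(profile, cohort, available)
            report["multivariable"] = cox.table.to_dict(orient="index")
        except (ValueError, KeyError) as exc:
            log.warning("[cox] multivariable model failed: %s", exc)
            report["multivariable"] = None
    return report


def run_validation(
    config: RunConfig, signature: SignatureModel | None = None
) -> dict:
    """Score an external cohort with a frozen signature and evaluate it."""
    if signature is None:
        if not config.signature:
            raise ValueError("validation needs a signature (file or object)")
        signature = io_formats.read_signature(config.signature)
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    expr, cohort = _load_inputs(config)
    cohort = io_formats.apply_survival_exclusion(cohort, config.min_months)
    expr = expr.subset_samples(cohort.patient_ids)
    report = _stratification_report(
        signature, expr, cohort, config, cohort_name="validation"
    )
    report["scores"].to_csv(outdir / "validation_scores.tsv", sep="\t")
    out = {k: v for k, v in report.items() if k != "scores"}
    with open(outdir / "validation_report.json", "w") as fh:
        json.dump(out, fh, indent=2, default=str)
    return report
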