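"""Readers/writers for expression, clinical and signature tables.

All on-disk formats are plain tab-separated text:

* expression: first column = gene/probe identifier, header row = sample ids,
  cells = decimal numbers;
* clinical: columns ``patient_id``, ``time_months``, ``event``, then any
  covariates (unknown covariates pass through untouched);
* signature: header ``gene_a``, ``gene_b``, ``coefficient``.

Ingestion applies the standard aggregation rules for redundant measurements:
probes mapping to the same gene symbol are averaged per sample, and multiple
samples from one patient are averaged per gene.
"""
from __future__ import annotations

import logging
from importlib import resources
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

from .containers import (
    ExpressionMatrix,
    GenePair,
    SignatureModel,
    SurvivalCohort,
    normalize_symbol,
)

log = logging.getLogger(__name__)

_COEF_FMT = "%.17g"  # round-trips any float64 exactly


def read_expression_table(
    path: str | Path,
    probe_to_gene_map: Mapping[str, str] | None = None,
) -> ExpressionMatrix:
    """Read a genes/probes x samples TSV and collapse duplicate rows by mean.

    If ``probe_to_gene_map`` is given, row identifiers are first mapped to
    gene symbols (unmapped probes are dropped with a log message).  Rows that
    then share a gene symbol are replaced by their arithmetic mean per sample.
    Duplicate sample ids and non-numeric cells are hard errors.
    """
    path = Path(path)
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
    sample_ids = header[1:]
    seen: set[str] = set()
    for s in sample_ids:
        if s in seen:
            raise ValueError(f"duplicate sample id {s!r} in {path}")
        seen.add(s)

    df = pd.read_csv(path, sep="\t", index_col=0, dtype=str)
    df.columns = sample_ids
    numeric = df.apply(pd.to_numeric, errors="coerce")
    bad = numeric.isna() & df.notna()
    if bad.to_numpy().any():
        r, c = np.argwhere(bad.to_numpy())[0]
        raise ValueError(
            f"non-numeric expression value {df.iat[r, c]!r} at row "
            f"{df.index[r]!r}, column {df.columns[c]!r} in {path}"
        )
    if numeric.isna().to_numpy().any():
        r, c = np.argwhere(numeric.isna().to_numpy())[0]
        raise ValueError(
            f"missing expression value at row {df.index[r]!r}, "
            f"column {df.columns[c]!r} in {path}"
        )

    ids = [str(i) for i in numeric.index]
    if probe_to_gene_map is not None:
        mapping = {str(k): normalize_symbol(v) for k, v in probe_to_gene_map.items()}
        keep = [i for i, probe in enumerate(ids) if probe in mapping]
        if len(keep) < len(ids):
            log.info(
                "dropping %d probes without a gene mapping", len(ids) - len(keep)
            )
        numeric = numeric.iloc[keep]
        symbols = [mapping[ids[i]] for i in keep]
    else:
        symbols = [normalize_symbol(i) for i in ids]
    numeric.index = pd.Index(symbols, name="gene")

    if numeric.index.duplicated().any():
        numeric = numeric.groupby(level=0, sort=False).mean()
    return ExpressionMatrix(numeric)


def write_expression_table(matrix: ExpressionMatrix, path: str | Path) -> None:
    matrix.data.to_csv(path, sep="\t", index_label="gene", float_format=_COEF_FMT)


def collapse_patient_samples(
    matrix: ExpressionMatrix, sample_to_patient: Mapping[str, str]
) -> ExpressionMatrix:
    """Average multi-sample patients so the result has one column per patient.

    Every sample id must map to a patient id; an unmapped sample is a hard
    error (silently dropping measurements would bias the per-gene means).
    """
    unmapped = [s for s in matrix.sample_ids if s not in sample_to_patient]
    if unmapped:
        raise ValueError(f"samples without a patient mapping: {unmapped[:5]}")
    patients = [str(sample_to_patient[s]) for s in matrix.sample_ids]
    collapsed = matrix.data.T.groupby(pd.Index(patients, name="patient"), sort=False)
    return ExpressionMatrix(collapsed.mean().T)


def apply_survival_exclusion(
    cohort: SurvivalCohort, min_months: float = 1.0
) -> SurvivalCohort:
    """Drop patients followed for less than ``min_months``; keep time >= cutoff.

    Short-follow-up patients carry almost no outcome information and their
    deaths are often perioperative; the boundary is inclusive (exactly one
    month is retained).
    """
    keep = cohort.data["time"] >= min_months
    n_removed = int((~keep).sum())
    if n_removed:
        log.info(
            "excluded %d/%d patients with survival time < %g months",
            n_removed,
            len(cohort),
            min_months,
        )
    if not keep.any():
        raise ValueError(
            f"no patients remain after excluding survival time < {min_months} months"
        )
    return SurvivalCohort(cohort.data.loc[keep])


def read_clinical_table(path: str | Path) -> SurvivalCohort:
    """Read a clinical TSV into a :class:`SurvivalCohort`.

    Requires columns ``patient_id``, ``time_months`` and ``event``; all other
    columns are kept as covariates (missing values allowed and preserved).
    """
    df = pd.read_csv(path, sep="\t", dtype={"patient_id": str})
    for col in ("patient_id", "time_months", "event"):
        if col not in df.columns:
            raise ValueError(f"clinical table {path} missing column {col!r}")
    df = df.set_index("patient_id").rename(
        columns={"time_months": "time"}
    )
    return SurvivalCohort(df)


def write_clinical_table(cohort: SurvivalCohort, path: str | Path) -> None:
    out = cohort.data.rename(columns={"time": "time_months"})
    out.to_csv(path, sep="\t", index_label="patient_id", float_format=_COEF_FMT)


def read_signature(path: str | Path) -> SignatureModel:
    """Read a (gene_a, gene_b, coefficient) TSV into a :class:`SignatureModel`."""
    path = Path(path)
    pairs: list[GenePair] = []
    coefs: list[float] = []
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if header[:3] != ["gene_a", "gene_b", "coefficient"]:
            raise ValueError(
                f"{path}: expected header gene_a/gene_b/coefficient, got {header[:3]}"
            )
        for lineno, line in enumerate(fh, start=2):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValueError(f"{path}:{lineno}: expected 3 columns, got {len(fields)}")
            try:
                pair = GenePair.make(fields[0], fields[1])
                coef = float(fields[2])
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: {exc}") from exc
            if pair in pairs:
                raise ValueError(f"{path}:{lineno}: duplicate pair {pair}")
            pairs.append(pair)
            coefs.append(coef)
    if not pairs:
        raise ValueError(f"{path}: signature file contains no pairs")
    return SignatureModel(pairs, np.array(coefs))


def write_signature(model: SignatureModel, path: str | Path) -> None:
    """Write a signature TSV; coefficients keep full float precision."""
    with open(path, "w") as fh:
        fh.write("gene_a\tgene_b\tcoefficient\n")
        for pair, coef in zip(model.pairs, model.coefficients):
            fh.write(f"{pair.gene_a}\t{pair.gene_b}\t{_COEF_FMT % coef}\n")


def read_gene_list(path: str | Path) -> list[str]:
    """Read one gene symbol per line; blank lines and '#' comments ignored."""
    symbols = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if line and not line.startswith("#"):
                symbols.append(normalize_symbol(line))
    if not symbols:
        raise ValueError(f"empty gene list {path}")
    return symbols


def load_packaged_signature() -> SignatureModel:
    """The packaged 33-pair hepatocellular-carcinoma immune signature.

    Shipped as a TSV data file inside the package; 33 gene pairs over 54
    distinct immune gene symbols with the published coefficients.
    """
    ref = resources.files("irgpsig").joinpath("data/hcc_irgp33.tsv")
    with resources.as_file(ref) as p:
        return read_signature(p)
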