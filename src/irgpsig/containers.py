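"""Core data containers shared across the pipeline.

The central objects are an expression matrix (genes x samples), a survival
cohort (per-patient time-to-event records), a binary gene-pair indicator
matrix, and a sparse pair signature with coefficients.  All containers
validate their invariants on construction so downstream stages can assume
clean inputs.
"""
from __future__ import annotations

import dataclasses
from typing import NamedTuple, Sequence

import numpy as np
import pandas as pd


def normalize_symbol(symbol: str) -> str:
    """Uppercase and strip a gene symbol; hyphens are preserved (HLA-A)."""
    return str(symbol).strip().upper()


class GenePair(NamedTuple):
    """An ordered gene pair; the indicator asks "is gene_a higher than gene_b".

    Canonical enumeration emits each unordered pair once with ``gene_a``
    lexicographically before ``gene_b``; the model coefficient sign absorbs
    directionality.
    """

    gene_a: str
    gene_b: str

    def __str__(self) -> str:
        return f"{self.gene_a}>{self.gene_b}"

    @classmethod
    def make(cls, gene_a: str, gene_b: str) -> "GenePair":
        a, b = normalize_symbol(gene_a), normalize_symbol(gene_b)
        if a == b:
            raise ValueError(f"gene pair with identical genes: {a}")
        return cls(a, b)


class ExpressionMatrix:
    """Genes x samples numeric matrix with unique ids and no missing values."""

    def __init__(self, data: pd.DataFrame):
        if data.index.duplicated().any():
            dups = data.index[data.index.duplicated()].unique().tolist()
            raise ValueError(f"duplicate gene ids: {dups[:5]}")
        if data.columns.duplicated().any():
            dups = data.columns[data.columns.duplicated()].unique().tolist()
            raise ValueError(f"duplicate sample ids: {dups[:5]}")
        values = data.to_numpy()
        if not np.issubdtype(values.dtype, np.number):
            raise ValueError("expression matrix contains non-numeric values")
        if np.isnan(values.astype(float)).any():
            r, c = np.argwhere(np.isnan(values.astype(float)))[0]
            raise ValueError(
                f"missing expression value at gene {data.index[r]!r}, "
                f"sample {data.columns[c]!r}"
            )
        self.data = data.astype(float)
        self.data.index = self.data.index.astype(str).rename("gene")
        self.data.columns = self.data.columns.astype(str).rename(None)

    @property
    def gene_ids(self) -> list[str]:
        return self.data.index.tolist()

    @property
    def sample_ids(self) -> list[str]:
        return self.data.columns.tolist()

    @property
    def values(self) -> np.ndarray:
        return self.data.to_numpy()

    @property
    def shape(self) -> tuple[int, int]:
        return self.data.shape

    def subset_samples(self, sample_ids: Sequence[str]) -> "ExpressionMatrix":
        missing = [s for s in sample_ids if s not in self.data.columns]
        if missing:
            raise KeyError(f"samples not in matrix: {missing[:5]}")
        return ExpressionMatrix(self.data.loc[:, list(sample_ids)])


class SurvivalCohort:
    """Per-patient survival records: time (months), event flag, covariates.

    ``data`` is indexed by patient id and must contain columns ``time`` and
    ``event``; every other column is treated as a covariate and may contain
    missing values (NaN).
    """

    REQUIRED = ("time", "event")

    def __init__(self, data: pd.DataFrame):
        for col in self.REQUIRED:
            if col not in data.columns:
                raise ValueError(f"clinical table missing column {col!r}")
        if data.index.duplicated().any():
            dups = data.index[data.index.duplicated()].unique().tolist()
            raise ValueError(f"duplicate patient ids: {dups[:5]}")
        time = pd.to_numeric(data["time"], errors="raise").astype(float)
        event = pd.to_numeric(data["event"], errors="raise")
        if (time <= 0).any() or time.isna().any():
            bad = data.index[(time <= 0) | time.isna()].tolist()
            raise ValueError(f"non-positive or missing survival time for {bad[:5]}")
        if not event.isin([0, 1]).all():
            bad = data.index[~event.isin([0, 1])].tolist()
            raise ValueError(f"event flag not in {{0,1}} for {bad[:5]}")
        self.data = data.copy()
        self.data.index = self.data.index.astype(str)
        self.data["time"] = time.to_numpy()
        self.data["event"] = event.astype(int).to_numpy()

    @property
    def patient_ids(self) -> list[str]:
        return self.data.index.tolist()

    @property
    def time(self) -> np.ndarray:
        return self.data["time"].to_numpy(dtype=float)

    @property
    def event(self) -> np.ndarray:
        return self.data["event"].to_numpy(dtype=int)

    @property
    def covariate_names(self) -> list[str]:
        return [c for c in self.data.columns if c not in self.REQUIRED]

    def __len__(self) -> int:
        return len(self.data)

    def subset(self, patient_ids: Sequence[str]) -> "SurvivalCohort":
        missing = [p for p in patient_ids if p not in self.data.index]
        if missing:
            raise KeyError(f"patients not in cohort: {missing[:5]}")
        return SurvivalCohort(self.data.loc[list(patient_ids)])


@dataclasses.dataclass
class IndicatorMatrix:
    """Pairs x samples binary matrix of within-sample ordering indicators."""

    pairs: list[GenePair]
    sample_ids: list[str]
    values: np.ndarray  # (n_pairs, n_samples), uint8 of {0,1}

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.uint8)
        if self.values.shape != (len(self.pairs), len(self.sample_ids)):
            raise ValueError(
                f"indicator shape {self.values.shape} does not match "
                f"{len(self.pairs)} pairs x {len(self.sample_ids)} samples"
            )
        if len(set(self.pairs)) != len(self.pairs):
            raise ValueError("duplicate pairs in indicator matrix")
        if self.values.size and self.values.max() > 1:
            raise ValueError("indicator entries must be 0 or 1")

    @property
    def n_pairs(self) -> int:
        return len(self.pairs)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.values,
            index=[str(p) for p in self.pairs],
            columns=self.sample_ids,
        )

    def subset_samples(self, sample_ids: Sequence[str]) -> "IndicatorMatrix":
        pos = {s: i for i, s in enumerate(self.sample_ids)}
        missing = [s for s in sample_ids if s not in pos]
        if missing:
            raise KeyError(f"samples not in indicator matrix: {missing[:5]}")
        idx = [pos[s] for s in sample_ids]
        return IndicatorMatrix(list(self.pairs), list(sample_ids), self.values[:, idx])

    def subset_pairs(self, pairs: Sequence[GenePair]) -> "IndicatorMatrix":
        pos = {p: i for i, p in enumerate(self.pairs)}
        missing = [p for p in pairs if p not in pos]
        if missing:
            raise KeyError(f"pairs not in indicator matrix: {missing[:5]}")
        idx = [pos[p] for p in pairs]
        return IndicatorMatrix(list(pairs), list(self.sample_ids), self.values[idx])


@dataclasses.dataclass
class SignatureModel:
    """A sparse gene-pair risk signature: score(s) = sum_k coef_k * indicator_k(s).

    ``cutoff`` is the training-cohort median risk score when available; it is
    the dichotomization threshold for the fixed-cutoff rule.
    """

    pairs: list[GenePair]
    coefficients: np.ndarray
    cutoff: float | None = None

    def __post_init__(self) -> None:
        self.coefficients = np.asarray(self.coefficients, dtype=float)
        if len(self.pairs) != len(self.coefficients):
            raise ValueError("pairs and coefficients length mismatch")
        if len(set(self.pairs)) != len(self.pairs):
            raise ValueError("duplicate pairs in signature")
        if len(self.coefficients) and (self.coefficients == 0).any():
            raise ValueError("signature must not store zero coefficients")

    @property
    def genes(self) -> list[str]:
        seen: dict[str, None] = {}
        for p in self.pairs:
            seen.setdefault(p.gene_a)
            seen.setdefault(p.gene_b)
        return list(seen)

    def __len__(self) -> int:
        return len(self.pairs)
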