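"""Gene-pair feature construction: the core of the method.

A gene pair (a, b) scores 1 in a sample when gene a's expression strictly
exceeds gene b's in that same sample, else 0.  Because the comparison is
within-sample, the resulting binary features are invariant to any strictly
increasing per-sample transform (log, scaling, affine shifts), which is what
makes pair signatures portable across platforms without normalization.

Pairs that are nearly constant in a cohort (same value in more than 90% of
samples by default) carry little information and are filtered out before any
survival testing.
"""
from __future__ import annotations

import dataclasses
import itertools
from typing import Sequence

import numpy as np

from .containers import ExpressionMatrix, GenePair, IndicatorMatrix, normalize_symbol


def common_genes(
    gene_lists: Sequence[Sequence[str]], immune_list: Sequence[str]
) -> list[str]:
    """Intersect dataset gene lists with the immune gene list, sorted.

    Raises if fewer than one dataset list is given or the intersection is
    empty (no pairs could be formed).
    """
    if not gene_lists:
        raise ValueError("need at least one dataset gene list")
    common = {normalize_symbol(g) for g in immune_list}
    for lst in gene_lists:
        common &= {normalize_symbol(g) for g in lst}
    if not common:
        raise ValueError("no genes common to all datasets and the immune list")
    return sorted(common)


def enumerate_pairs(genes: Sequence[str]) -> list[GenePair]:
    """All n(n-1)/2 unordered pairs in canonical (lexicographic) order."""
    symbols = [normalize_symbol(g) for g in genes]
    if len(set(symbols)) != len(symbols):
        from collections import Counter

        dups = sorted(s for s, c in Counter(symbols).items() if c > 1)
        raise ValueError(f"duplicate gene symbols: {dups[:5]}")
    if len(symbols) < 2:
        raise ValueError("need at least two genes to form pairs")
    return [GenePair(a, b) for a, b in itertools.combinations(sorted(symbols), 2)]


def score_pairs(matrix: ExpressionMatrix, pairs: Sequence[GenePair]) -> IndicatorMatrix:
    """Binary pair indicators: 1 iff expr(gene_a) > expr(gene_b), ties score 0."""
    row = {g: i for i, g in enumerate(matrix.gene_ids)}
    missing = sorted({g for p in pairs for g in p if g not in row})
    if missing:
        raise KeyError(f"genes absent from expression matrix: {missing[:10]}")
    ia = np.fromiter((row[p.gene_a] for p in pairs), dtype=np.intp, count=len(pairs))
    ib = np.fromiter((row[p.gene_b] for p in pairs), dtype=np.intp, count=len(pairs))
    x = matrix.values
    values = (x[ia] > x[ib]).astype(np.uint8)
    return IndicatorMatrix(list(pairs), matrix.sample_ids, values)


@dataclasses.dataclass
class PairPrevalence:
    pair: GenePair
    fraction_ones_train: float
    fraction_ones_test: float


def prevalence_filter(
    ind_train: IndicatorMatrix,
    ind_test: IndicatorMatrix,
    threshold: float = 0.90,
) -> list[GenePair]:
    """Keep pairs whose indicator is not near-constant in either split.

    A pair is discarded iff its majority value (0 or 1) covers strictly more
    than ``threshold`` of the samples in the training split OR in the testing
    split; kept pairs are returned in input order.
    """
    if ind_train.pairs != ind_test.pairs:
        raise ValueError("train and test indicator matrices list different pairs")
    keep = np.ones(ind_train.n_pairs, dtype=bool)
    for ind in (ind_train, ind_test):
        frac1 = ind.values.mean(axis=1)
        keep &= np.maximum(frac1, 1.0 - frac1) <= threshold
    return [p for p, k in zip(ind_train.pairs, keep) if k]


def pair_prevalences(
    ind_train: IndicatorMatrix, ind_test: IndicatorMatrix
) -> list[PairPrevalence]:
    """Per-pair fraction of ones in each split (diagnostic companion to the filter)."""
    if ind_train.pairs != ind_test.pairs:
        raise ValueError("train and test indicator matrices list different pairs")
    f_tr = ind_train.values.mean(axis=1)
    f_te = ind_test.values.mean(axis=1)
    return [
        PairPrevalence(p, float(a), float(b))
        for p, a, b in zip(ind_train.pairs, f_tr, f_te)
    ]
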