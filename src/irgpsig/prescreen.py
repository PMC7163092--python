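"""Per-pair log-rank screening with Benjamini-Hochberg FDR control.

Each binary pair indicator splits the cohort into two groups; the standard
one-degree-of-freedom log-rank statistic (hypergeometric variance at each
distinct event time, which handles tied event times natively) tests whether
the groups' survival differs.  Benjamini-Hochberg adjustment across all
testable pairs then selects the prognostic ones at a chosen FDR.
"""
from __future__ import annotations

import dataclasses
import logging
from typing import Sequence

import numpy as np
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .containers import GenePair, IndicatorMatrix, SurvivalCohort

log = logging.getLogger(__name__)


@dataclasses.dataclass
class LogRankResult:
    pair: GenePair
    chi_square: float
    p_value: float
    q_value: float
    n_group0: int
    n_group1: int


def _logrank_bulk(
    time: np.ndarray, event: np.ndarray, groups: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Vectorized 1-df log-rank over many binary groupings.

    ``groups`` is (n_tests, n_patients) of {0,1}.  Returns (chi_square,
    variance) arrays; callers turn zero variance into skips or errors.
    """
    time = np.asarray(time, dtype=float)
    event = np.asarray(event, dtype=int)
    groups = np.asarray(groups, dtype=float)
    evt_times = np.unique(time[event == 1])
    # at-risk and death incidence matrices, (n_times, n_patients)
    at_risk = time[None, :] >= evt_times[:, None]
    deaths = (time[None, :] == evt_times[:, None]) & (event[None, :] == 1)
    n_k = at_risk.sum(axis=1).astype(float)
    d_k = deaths.sum(axis=1).astype(float)
    n1 = at_risk @ groups.T  # (n_times, n_tests)
    d1 = deaths @ groups.T
    obs = d1.sum(axis=0)
    exp = (d_k[:, None] * n1 / n_k[:, None]).sum(axis=0)
    with np.errstate(divide="ignore", invalid="ignore"):
        frac = n1 / n_k[:, None]
        v_k = d_k[:, None] * frac * (1.0 - frac) * (
            (n_k[:, None] - d_k[:, None]) / np.maximum(n_k[:, None] - 1.0, 1.0)
        )
    var = v_k.sum(axis=0)
    with np.errstate(divide="ignore", invalid="ignore"):
        chi2 = np.where(var > 0, (obs - exp) ** 2 / var, np.nan)
    return chi2, var


def logrank_two_group(
    time: Sequence[float], event: Sequence[int], group: Sequence[int]
) -> tuple[float, float]:
    """Two-group log-rank test; returns (chi_square, p_value).

    Requires both groups non-empty, at least one event overall, and nonzero
    hypergeometric variance.
    """
    time = np.asarray(time, dtype=float)
    event = np.asarray(event, dtype=int)
    group = np.asarray(group, dtype=int)
    if group.min() == group.max():
        raise ValueError("log-rank test needs two non-empty groups")
    if event.sum() == 0:
        raise ValueError("log-rank test needs at least one event")
    chi2, var = _logrank_bulk(time, event, group[None, :])
    if not var[0] > 0:
        raise ValueError("log-rank variance is zero (no informative event times)")
    p = float(stats.chi2.sf(chi2[0], df=1))
    return float(chi2[0]), p


def bh_fdr(p_values: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, order-preserving."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def select_prognostic_pairs(
    ind: IndicatorMatrix,
    cohort: SurvivalCohort,
    fdr_cut: float = 0.01,
) -> list[LogRankResult]:
    """Screen every pair by log-rank on its 0/1 indicator; keep q < ``fdr_cut``.

    Indicator samples must match cohort patients (any order).  Pairs whose
    indicator is constant in this cohort, or whose log-rank variance is zero,
    are skipped with a logged warning rather than erroring: they can occur
    legitimately when the prevalence filter was computed on other splits.
    Results are sorted by (q, p).
    """
    if set(ind.sample_ids) != set(cohort.patient_ids):
        raise ValueError("indicator samples and cohort patients do not match")
    ind = ind.subset_samples(cohort.patient_ids)
    time, event = cohort.time, cohort.event
    g = ind.values
    n1 = g.sum(axis=1)
    testable = (n1 > 0) & (n1 < g.shape[1])
    n_skip = int((~testable).sum())
    if n_skip:
        log.warning("skipping %d pairs with a constant indicator in this cohort", n_skip)
    # chunked to bound the (event-times x pairs) intermediates
    sub = g[testable]
    if sub.shape[0]:
        chunks = [
            _logrank_bulk(time, event, sub[i : i + 4096])
            for i in range(0, sub.shape[0], 4096)
        ]
        chi2 = np.concatenate([c for c, _ in chunks])
        var = np.concatenate([v for _, v in chunks])
    else:
        chi2 = var = np.empty(0)
    ok = var > 0
    if int((~ok).sum()):
        log.warning("skipping %d pairs with zero log-rank variance", int((~ok).sum()))
    idx = np.flatnonzero(testable)[ok]
    chi2 = chi2[ok]
    p = stats.chi2.sf(chi2, df=1)
    q = bh_fdr(p)
    results = [
        LogRankResult(
            pair=ind.pairs[i],
            chi_square=float(c),
            p_value=float(pv),
            q_value=float(qv),
            n_group0=int(g.shape[1] - n1[i]),
            n_group1=int(n1[i]),
        )
        for i, c, pv, qv in zip(idx, chi2, p, q)
    ]
    selected = [r for r in results if r.q_value < fdr_cut]
    selected.sort(key=lambda r: (r.q_value, r.p_value, r.pair))
    log.info(
        "log-rank screen: %d/%d pairs selected at FDR < %g",
        len(selected),
        len(results),
        fdr_cut,
    )
    return selected


def screen_all_pairs(
    ind: IndicatorMatrix, cohort: SurvivalCohort
) -> list[LogRankResult]:
    """Like :func:`select_prognostic_pairs` but returns every testable pair."""
    return select_prognostic_pairs(ind, cohort, fdr_cut=np.inf)
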