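"""Discrimination metrics for survival risk scores.

Harrell's concordance index follows the original convention: a pair of
patients (i, j) is usable when the earlier time is an observed event
(time_i < time_j, event_i = 1); tied risk scores contribute 1/2; pairs with
tied times are not usable.

The time-dependent ROC at horizon t uses the cumulative-case / dynamic-
control definition - cases are patients with an observed event by t,
controls are patients still at risk beyond t - with inverse-probability-of-
censoring weights from the Kaplan-Meier estimate of the censoring
distribution, so patients censored before the horizon contribute through
the reweighting of observed cases rather than being dropped informatively.
"""
from __future__ import annotations

import dataclasses
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from lifelines import KaplanMeierFitter

from .containers import SurvivalCohort


@dataclasses.dataclass
class ConcordanceResult:
    c_index: float
    n_concordant: int
    n_discordant: int
    n_tied_score: int
    n_usable_pairs: int


@dataclasses.dataclass
class TimeROC:
    horizon: float
    fpr: np.ndarray  # 1 - specificity, nondecreasing
    tpr: np.ndarray  # sensitivity, nondecreasing
    auc: float
    n_cases: int
    n_controls: int


def harrell_cindex(
    scores: Sequence[float], time: Sequence[float], event: Sequence[int]
) -> ConcordanceResult:
    """Harrell's c-index with 1/2 credit for score ties."""
    s = np.asarray(scores, dtype=float)
    t = np.asarray(time, dtype=float)
    e = np.asarray(event, dtype=int)
    # usable (i, j): t_i < t_j and event_i
    usable = (t[:, None] < t[None, :]) & (e[:, None] == 1)
    diff = s[:, None] - s[None, :]
    conc = int(np.sum(usable & (diff > 0)))
    disc = int(np.sum(usable & (diff < 0)))
    tied = int(np.sum(usable & (diff == 0)))
    n_usable = conc + disc + tied
    if n_usable == 0:
        raise ValueError("no usable patient pairs for concordance")
    c = (conc + 0.5 * tied) / n_usable
    return ConcordanceResult(float(c), conc, disc, tied, n_usable)


def _censoring_survival(time: np.ndarray, event: np.ndarray) -> KaplanMeierFitter:
    kmf = KaplanMeierFitter()
    kmf.fit(time, 1 - event)
    return kmf


def time_dependent_roc(
    scores: Sequence[float],
    time: Sequence[float],
    event: Sequence[int],
    horizon: float,
) -> TimeROC:
    """KM-weighted cumulative/dynamic ROC and AUC at a fixed horizon.

    Requires at least one observed event by the horizon and at least one
    patient still at risk beyond it.  With no censoring before the horizon
    this reduces exactly to the static ROC on the binary outcome
    "death by the horizon".
    """
    s = np.asarray(scores, dtype=float)
    t = np.asarray(time, dtype=float)
    e = np.asarray(event, dtype=int)
    cases = (t <= horizon) & (e == 1)
    controls = t > horizon
    if cases.sum() == 0:
        raise ValueError(f"no observed events by horizon {horizon}")
    if controls.sum() == 0:
        raise ValueError(f"no patients at risk beyond horizon {horizon}")

    km_c = _censoring_survival(t, e)
    # weight for a case observed at time u: 1 / G(u-)
    g_at = km_c.survival_function_at_times(t[cases] - 1e-9).to_numpy(dtype=float)
    g_floor = g_at[g_at > 0].min() if (g_at > 0).any() else 1.0
    w_case = 1.0 / np.maximum(g_at, g_floor * 1e-6)

    thresholds = np.unique(s)[::-1]
    s_case, s_ctrl = s[cases], s[controls]
    tpr = np.array(
        [w_case[s_case > c].sum() for c in thresholds] + [w_case.sum()]
    ) / w_case.sum()
    fpr = np.array(
        [(s_ctrl > c).sum() for c in thresholds] + [controls.sum()]
    ) / controls.sum()
    tpr = np.concatenate([[0.0], tpr])
    fpr = np.concatenate([[0.0], fpr])
    auc = float(np.trapezoid(tpr, fpr))
    return TimeROC(
        horizon=float(horizon),
        fpr=fpr,
        tpr=tpr,
        auc=auc,
        n_cases=int(cases.sum()),
        n_controls=int(controls.sum()),
    )


DEFAULT_HORIZONS = (12.0, 36.0, 60.0)  # 1-, 3- and 5-year survival, months


def compare_signatures(
    score_vectors: Mapping[str, Sequence[float]],
    cohort: SurvivalCohort,
    horizons: Sequence[float] = DEFAULT_HORIZONS,
) -> pd.DataFrame:
    """One row per named score vector: c-index plus AUC at each horizon.

    Rows are ordered by c-index, best first (name breaks exact ties, for
    determinism).  Horizons where the ROC is undefined yield NaN.
    """
    n = len(cohort)
    rows = []
    for name, scores in score_vectors.items():
        s = np.asarray(scores, dtype=float)
        if len(s) != n:
            raise ValueError(
                f"score vector {name!r} has length {len(s)}, cohort has {n}"
            )
        row: dict[str, object] = {"signature": name}
        row["c_index"] = harrell_cindex(s, cohort.time, cohort.event).c_index
        for h in horizons:
            try:
                row[f"auc_{int(h)}m"] = time_dependent_roc(
                    s, cohort.time, cohort.event, h
                ).auc
            except ValueError:
                row[f"auc_{int(h)}m"] = np.nan
        rows.append(row)
    out = pd.DataFrame(rows).sort_values(
        ["c_index", "signature"], ascending=[False, True]
    )
    return out.reset_index(drop=True)
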