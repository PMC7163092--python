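"""Risk scoring, median dichotomization and survival group comparison.

A patient's risk score is the signature-weighted sum of their pair
indicators.  Cohorts are split at their own median score (patients exactly
at the median go to the low-risk group), and the groups are compared by
log-rank test, Kaplan-Meier curves, univariate Cox hazard ratio, and
covariate-adjusted multivariable Cox models.  Cox fits use lifelines
(Breslow tie handling, Wald confidence intervals).
"""
from __future__ import annotations

import dataclasses
import logging
import warnings
from typing import Sequence

import numpy as np
import pandas as pd
from lifelines import CoxPHFitter, KaplanMeierFitter
from lifelines.exceptions import ConvergenceError as LifelinesConvergenceError

from .containers import IndicatorMatrix, SignatureModel, SurvivalCohort
from .prescreen import logrank_two_group

log = logging.getLogger(__name__)

AGE_CUT = 60  # years; standard elderly cutoff in the clinical tables


@dataclasses.dataclass
class RiskProfile:
    patient_ids: list[str]
    scores: np.ndarray
    group: np.ndarray  # "low"/"high" per patient
    cutoff: float

    @property
    def high_mask(self) -> np.ndarray:
        return self.group == "high"

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"risk_score": self.scores, "risk_group": self.group},
            index=pd.Index(self.patient_ids, name="patient_id"),
        )


@dataclasses.dataclass
class KMCurve:
    times: np.ndarray
    survival: np.ndarray
    ci_lower: np.ndarray
    ci_upper: np.ndarray


@dataclasses.dataclass
class GroupComparison:
    logrank_chi2: float
    logrank_p: float
    hazard_ratio: float
    hr_ci_low: float
    hr_ci_high: float
    n_low: int
    n_high: int
    km_low: KMCurve
    km_high: KMCurve


@dataclasses.dataclass
class CoxSummary:
    """Per-term hazard ratios with Wald CIs from a multivariable Cox fit."""

    table: pd.DataFrame  # index=term, columns=hr, ci_low, ci_high, p
    log_likelihood: float
    n_used: int
    n_dropped_missing: int
    separation_flag: bool = False


def risk_score(signature: SignatureModel, ind: IndicatorMatrix) -> pd.Series:
    """Per-sample signature score: sum_k coefficient_k * indicator_k."""
    pos = {p: i for i, p in enumerate(ind.pairs)}
    missing = [p for p in signature.pairs if p not in pos]
    if missing:
        raise KeyError(
            f"signature pairs absent from indicator matrix: "
            f"{[str(p) for p in missing[:5]]}"
        )
    idx = [pos[p] for p in signature.pairs]
    scores = signature.coefficients @ ind.values[idx].astype(float)
    return pd.Series(scores, index=ind.sample_ids, name="risk_score")


def dichotomize(
    scores: pd.Series,
    rule: str = "median",
    cutoff: float | None = None,
) -> RiskProfile:
    """Assign high/low risk groups; high iff score > cutoff.

    ``median`` uses the cohort's own median score; ``fixed`` uses the given
    ``cutoff`` (e.g. a frozen training median).  Scores exactly at the cutoff
    go to the low-risk group, which yields a deterministic near-even split
    for distinct scores.
    """
    if len(scores) < 2:
        raise ValueError("need at least two patients to stratify")
    if rule == "median":
        cut = float(np.median(scores.to_numpy()))
    elif rule == "fixed":
        if cutoff is None:
            raise ValueError("fixed-cutoff rule requires a cutoff value")
        cut = float(cutoff)
    else:
        raise ValueError(f"unknown dichotomization rule {rule!r}")
    values = scores.to_numpy(dtype=float)
    if np.all(values == values[0]):
        raise ValueError("all risk scores identical; no stratification possible")
    group = np.where(values > cut, "high", "low")
    if rule == "median" and (group == "high").sum() == 0:
        # coarse score distributions (few-pair signatures) can put a strict
        # majority exactly at the median; move the boundary into the high
        # group so both groups stay populated
        log.info("median equals the score majority; boundary scores go high")
        group = np.where(values >= cut, "high", "low")
    return RiskProfile(list(scores.index), values, group, cut)


def _km_curve(time: np.ndarray, event: np.ndarray) -> KMCurve:
    kmf = KaplanMeierFitter()
    kmf.fit(time, event)
    sf = kmf.survival_function_
    ci = kmf.confidence_interval_
    return KMCurve(
        times=sf.index.to_numpy(dtype=float),
        survival=sf.iloc[:, 0].to_numpy(),
        ci_lower=ci.iloc[:, 0].to_numpy(),
        ci_upper=ci.iloc[:, 1].to_numpy(),
    )


def km_group_comparison(
    profile: RiskProfile, cohort: SurvivalCohort
) -> GroupComparison:
    """Log-rank p, univariate Cox HR with 95% CI, and KM curves per group."""
    cohort = cohort.subset(profile.patient_ids)
    high = profile.high_mask
    if high.sum() == 0 or (~high).sum() == 0:
        raise ValueError("both risk groups must be non-empty")
    time, event = cohort.time, cohort.event
    chi2, p = logrank_two_group(time, event, high.astype(int))
    df = pd.DataFrame({"t": time, "e": event, "high": high.astype(float)})
    cph = CoxPHFitter()
    cph.fit(df, duration_col="t", event_col="e")
    s = cph.summary.loc["high"]
    return GroupComparison(
        logrank_chi2=chi2,
        logrank_p=p,
        hazard_ratio=float(s["exp(coef)"]),
        hr_ci_low=float(s["exp(coef) lower 95%"]),
        hr_ci_high=float(s["exp(coef) upper 95%"]),
        n_low=int((~high).sum()),
        n_high=int(high.sum()),
        km_low=_km_curve(time[~high], event[~high]),
        km_high=_km_curve(time[high], event[high]),
    )


def _encode_covariate(name: str, col: pd.Series) -> pd.Series | None:
    """Standard clinical encodings: age >= 60, stage III/IV, male sex.

    Unknown covariates pass through if numeric; non-numeric unknown columns
    are label-encoded only when binary.
    """
    if name == "age":
        return (pd.to_numeric(col, errors="coerce") >= AGE_CUT).astype(float).where(
            pd.to_numeric(col, errors="coerce").notna()
        )
    if name == "stage":
        mapping = {"I": 0.0, "II": 0.0, "III": 1.0, "IV": 1.0}
        return col.astype(str).str.strip().str.upper().map(mapping)
    if name == "sex":
        mapping = {"male": 1.0, "female": 0.0, "m": 1.0, "f": 0.0}
        return col.astype(str).str.strip().str.lower().map(mapping)
    numeric = pd.to_numeric(col, errors="coerce")
    if numeric.notna().any():
        return numeric
    levels = sorted(col.dropna().astype(str).unique())
    if len(levels) == 2:
        return col.astype(str).map({levels[0]: 0.0, levels[1]: 1.0})
    return None


def multivariable_cox(
    profile: RiskProfile,
    cohort: SurvivalCohort,
    covariates: Sequence[str] = ("age", "sex", "stage"),
) -> CoxSummary:
    """Cox model of risk group adjusted for clinical covariates.

    Age is dichotomized at 60, stage as I/II vs III/IV, sex as male vs
    female.  Patients with missing covariate values are dropped (logged).
    Rank-deficient designs raise; suspected separation (huge coefficients)
    sets a flag instead of failing.
    """
    cohort = cohort.subset(profile.patient_ids)
    absent = [c for c in covariates if c not in cohort.data.columns]
    if absent:
        raise KeyError(f"covariates not in cohort: {absent}")
    design = pd.DataFrame(index=cohort.data.index)
    design["risk_high"] = profile.high_mask.astype(float)
    for name in covariates:
        enc = _encode_covariate(name, cohort.data[name])
        if enc is None:
            raise ValueError(f"cannot encode covariate {name!r}")
        design[name] = enc.to_numpy(dtype=float)
    design["t"] = cohort.time
    design["e"] = cohort.event
    n0 = len(design)
    design = design.dropna()
    n_dropped = n0 - len(design)
    if n_dropped:
        log.info("dropped %d patients with missing covariates", n_dropped)
    terms = [c for c in design.columns if c not in ("t", "e")]
    x = design[terms].to_numpy()
    if np.linalg.matrix_rank(x - x.mean(axis=0)) < len(terms):
        raise ValueError("covariate design is rank deficient (collinear terms)")
    cph = CoxPHFitter()
    separation = False
    with warnings.catch_warnings(record=True) as caught:
        warnings.simplefilter("always")
        try:
            cph.fit(design, duration_col="t", event_col="e")
        except LifelinesConvergenceError as exc:
            raise ValueError(f"multivariable Cox did not converge: {exc}") from exc
        for w in caught:
            if "convergence" in str(w.message).lower() or "complete separation" in str(
                w.message
            ).lower():
                separation = True
    if np.any(np.abs(cph.params_) > 20):
        separation = True
    if separation:
        log.warning("possible separation: confidence intervals may be inflated")
    table = pd.DataFrame(
        {
            "hr": cph.summary["exp(coef)"],
            "ci_low": cph.summary["exp(coef) lower 95%"],
            "ci_high": cph.summary["exp(coef) upper 95%"],
            "p": cph.summary["p"],
        }
    )
    return CoxSummary(
        table=table,
        log_likelihood=float(cph.log_likelihood_),
        n_used=len(design),
        n_dropped_missing=n_dropped,
        separation_flag=separation,
    )


def subgroup_analysis(
    profile: RiskProfile,
    cohort: SurvivalCohort,
    stratifiers: Sequence[str],
) -> pd.DataFrame:
    """Per-stratum group comparison table.

    For every level of every stratifier the risk-group comparison is rerun on
    the restricted cohort; strata where a group is empty or the test is
    degenerate yield NA rows rather than errors.
    """
    cohort = cohort.subset(profile.patient_ids)
    unknown = [s for s in stratifiers if s not in cohort.data.columns]
    if unknown:
        raise KeyError(f"unknown stratifiers: {unknown}")
    prof_frame = profile.to_frame()
    rows = []
    for strat in stratifiers:
        col = cohort.data[strat]
        for level in sorted(col.dropna().astype(str).unique()):
            mask = col.astype(str) == level
            ids = cohort.data.index[mask].tolist()
            sub_prof = prof_frame.loc[ids]
            n_low = int((sub_prof["risk_group"] == "low").sum())
            n_high = int((sub_prof["risk_group"] == "high").sum())
            row = {
                "stratifier": strat,
                "level": level,
                "n_low": n_low,
                "n_high": n_high,
                "hr": np.nan,
                "ci_low": np.nan,
                "ci_high": np.nan,
                "logrank_p": np.nan,
            }
            if n_low > 0 and n_high > 0:
                sub = RiskProfile(
                    ids,
                    sub_prof["risk_score"].to_numpy(),
                    sub_prof["risk_group"].to_numpy(),
                    profile.cutoff,
                )
                try:
                    cmp_ = km_group_comparison(sub, cohort.subset(ids))
                    row.update(
                        hr=cmp_.hazard_ratio,
                        ci_low=cmp_.hr_ci_low,
                        ci_high=cmp_.hr_ci_high,
                        logrank_p=cmp_.logrank_p,
                    )
                except (ValueError, LifelinesConvergenceError) as exc:
                    log.info("stratum %s=%s degenerate: %s", strat, level, exc)
            rows.append(row)
    return pd.DataFrame(rows)
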