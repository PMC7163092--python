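"""Risk scoring, dichotomization and survival group comparisons."""
from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from irgpsig import (
    GenePair,
    IndicatorMatrix,
    SignatureModel,
    SurvivalCohort,
    dichotomize,
    km_group_comparison,
    load_packaged_signature,
    multivariable_cox,
    risk_score,
    subgroup_analysis,
)
from irgpsig.risk import RiskProfile

# independent hand-summation of the 33 packaged coefficients, frozen
PACKAGED_COEF_SUM = 1.822898


def _indicator_for_signature(sig, fill):
    values = np.full((len(sig.pairs), 4), fill, dtype=np.uint8)
    return IndicatorMatrix(list(sig.pairs), [f"S{j}" for j in range(4)], values)


class TestRiskScore:
    def test_all_zero_indicators_score_zero(self):
        sig = load_packaged_signature()
        scores = risk_score(sig, _indicator_for_signature(sig, 0))
        assert np.all(scores.to_numpy() == 0.0)

    def test_all_one_indicators_equal_coefficient_sum(self):
        sig = load_packaged_signature()
        scores = risk_score(sig, _indicator_for_signature(sig, 1))
        np.testing.assert_allclose(scores.to_numpy(), PACKAGED_COEF_SUM, atol=1e-9)

    def test_two_pair_arithmetic(self):
        sig = SignatureModel(
            [GenePair("A", "B"), GenePair("C", "D")], np.array([0.5, -0.25])
        )
        ind = IndicatorMatrix(
            list(sig.pairs), ["S1"], np.array([[1], [1]], dtype=np.uint8)
        )
        assert risk_score(sig, ind).iloc[0] == pytest.approx(0.25)

    def test_missing_pair_named(self):
        sig = SignatureModel([GenePair("A", "B")], np.array([1.0]))
        ind = IndicatorMatrix(
            [GenePair("C", "D")], ["S1"], np.array([[1]], dtype=np.uint8)
        )
        with pytest.raises(KeyError, match="A>B"):
            risk_score(sig, ind)

    def test_linear_in_coefficients(self):
        rng = np.random.default_rng(0)
        pairs = [GenePair(f"A{j}", f"B{j}") for j in range(5)]
        ind = IndicatorMatrix(
            pairs, [f"S{j}" for j in range(7)],
            (rng.random((5, 7)) < 0.5).astype(np.uint8),
        )
        coefs = rng.normal(size=5)
        base = risk_score(SignatureModel(pairs, coefs), ind).to_numpy()
        scaled = risk_score(SignatureModel(pairs, 3.0 * coefs), ind).to_numpy()
        np.testing.assert_allclose(scaled, 3.0 * base, atol=1e-12)


class TestDichotomize:
    def test_median_split_four_values(self):
        scores = pd.Series([1.0, 2.0, 3.0, 4.0], index=list("abcd"))
        prof = dichotomize(scores)
        assert list(prof.group) == ["low", "low", "high", "high"]

    def test_odd_cohort_near_even_split(self):
        rng = np.random.default_rng(1)
        scores = pd.Series(rng.permutation(207).astype(float),
                           index=[f"P{i}" for i in range(207)])
        prof = dichotomize(scores)
        sizes = {int((prof.group == "low").sum()), int((prof.group == "high").sum())}
        assert sizes == {103, 104}
        # the median patient goes to the low-risk group
        assert prof.group[np.argsort(scores.to_numpy())[103]] == "low"

    def test_fixed_cutoff(self):
        scores = pd.Series([-1.0, 1.0], index=["a", "b"])
        prof = dichotomize(scores, rule="fixed", cutoff=0.0)
        assert list(prof.group) == ["low", "high"]

    def test_identical_scores_rejected(self):
        with pytest.raises(ValueError, match="identical"):
            dichotomize(pd.Series([2.0, 2.0, 2.0], index=list("abc")))

    def test_median_split_sizes_property(self):
        rng = np.random.default_rng(2)
        for _ in range(200):
            n = int(rng.integers(2, 60))
            scores = pd.Series(
                rng.choice(10_000, size=n, replace=False).astype(float),
                index=[f"P{i}" for i in range(n)],
            )
            prof = dichotomize(scores)
            n_low = int((prof.group == "low").sum())
            n_high = n - n_low
            assert abs(n_low - n_high) <= 1


def _cohort_from_arrays(time, event, **covs):
    df = pd.DataFrame({"time": time, "event": event, **covs},
                      index=[f"P{i}" for i in range(len(time))])
    return SurvivalCohort(df)


def _profile(scores, ids=None, cutoff=None):
    s = np.asarray(scores, dtype=float)
    ids = ids or [f"P{i}" for i in range(len(s))]
    cut = float(np.median(s)) if cutoff is None else cutoff
    group = np.where(s > cut, "high", "low")
    return RiskProfile(ids, s, group, cut)


class TestKMGroupComparison:
    def test_identical_groups_null_result(self):
        time = [2, 4, 6, 8, 2, 4, 6, 8.0]
        event = [1, 1, 0, 1, 1, 1, 0, 1]
        prof = _profile([0, 0, 0, 0, 1, 1, 1, 1], cutoff=0.5)
        cohort = _cohort_from_arrays(time, event)
        cmp_ = km_group_comparison(prof, cohort)
        assert cmp_.logrank_p == pytest.approx(1.0)
        assert cmp_.hr_ci_low <= 1.0 <= cmp_.hr_ci_high

    def test_km_curve_matches_product_limit_hand_calc(self):
        # single group of 6: deaths at 3, 5, 12; censored at 8, 20, 30
        time = [3, 5, 8, 12, 20, 30.0]
        event = [1, 1, 0, 1, 0, 1]
        prof = _profile([0, 0, 0, 1, 1, 1], cutoff=0.5)
        cohort = _cohort_from_arrays(time, event)
        cmp_ = km_group_comparison(prof, cohort)
        # low group: deaths at 3 (3 at risk) then 5 (2 at risk): S = 2/3, 1/3,
        # unchanged at the censoring time 8
        np.testing.assert_allclose(cmp_.km_low.survival, [1.0, 2 / 3, 1 / 3, 1 / 3])
        # high group: death at 12 (3 at risk), censor 20, death 30 (1 at risk)
        np.testing.assert_allclose(cmp_.km_high.survival, [1.0, 2 / 3, 2 / 3, 0.0])

    def test_recovers_planted_group_hazard(self):
        log_hrs = []
        for seed in range(20):
            rng = np.random.default_rng(400 + seed)
            n = 400
            high = rng.random(n) < 0.5
            T = rng.exponential(1.0 / (0.02 * np.exp(1.5 * high)))
            C = rng.exponential(50.0, n)
            time, event = np.minimum(T, C), (T <= C).astype(int)
            prof = _profile(high.astype(float), cutoff=0.5)
            cmp_ = km_group_comparison(prof, _cohort_from_arrays(time, event))
            log_hrs.append(np.log(cmp_.hazard_ratio))
        assert np.mean(log_hrs) == pytest.approx(1.5, abs=0.35)

    def test_degenerate_group_rejected(self):
        prof = _profile([1.0, 2.0, 3.0], cutoff=0.0)  # everyone high
        with pytest.raises(ValueError, match="non-empty"):
            km_group_comparison(prof, _cohort_from_arrays([1, 2, 3.0], [1, 1, 1]))


class TestMultivariableCox:
    def _simulate(self, seed, n=500, beta_group=1.0, beta_stage=0.6):
        rng = np.random.default_rng(seed)
        high = rng.random(n) < 0.5
        stage34 = rng.random(n) < 0.3
        age = rng.integers(35, 85, n)
        sex = rng.choice(["male", "female"], n)
        lp = beta_group * high + beta_stage * stage34
        T = rng.exponential(1.0 / (0.02 * np.exp(lp)))
        C = rng.exponential(50.0, n)
        time, event = np.minimum(T, C), (T <= C).astype(int)
        cohort = _cohort_from_arrays(
            time, event,
            age=age, sex=sex,
            stage=np.where(stage34, "III", "I"),
        )
        return _profile(high.astype(float), cutoff=0.5), cohort

    def test_recovers_group_and_stage_effects(self):
        g_effects, s_effects = [], []
        for seed in range(20):
            prof, cohort = self._simulate(500 + seed)
            summary = multivariable_cox(prof, cohort)
            g_effects.append(np.log(summary.table.loc["risk_high", "hr"]))
            s_effects.append(np.log(summary.table.loc["stage", "hr"]))
        assert np.mean(g_effects) == pytest.approx(1.0, abs=0.3)
        assert np.mean(s_effects) == pytest.approx(0.6, abs=0.3)

    def test_null_covariates_keep_unit_hazard(self):
        covered = 0
        for seed in range(20):
            prof, cohort = self._simulate(600 + seed, beta_stage=0.0)
            t = multivariable_cox(prof, cohort).table
            ok = all(
                t.loc[term, "ci_low"] <= 1.0 <= t.loc[term, "ci_high"]
                for term in ("age", "sex", "stage")
            )
            covered += ok
        assert covered >= 15  # each CI covers ~95%; joint coverage is lower

    def test_collinear_covariate_rejected(self):
        prof, cohort = self._simulate(7)
        cohort.data["dup"] = prof.high_mask.astype(float)
        with pytest.raises(ValueError, match="rank deficient"):
            multivariable_cox(prof, cohort, covariates=("dup",))

    def test_missing_covariates_dropped_and_counted(self):
        prof, cohort = self._simulate(8, n=300)
        cohort.data.loc[cohort.data.index[:25], "stage"] = np.nan
        summary = multivariable_cox(prof, cohort)
        assert summary.n_dropped_missing == 25
        assert summary.n_used == 275


class TestSubgroupAnalysis:
    def test_single_level_reproduces_overall(self):
        rng = np.random.default_rng(9)
        n = 200
        high = rng.random(n) < 0.5
        T = rng.exponential(1.0 / (0.02 * np.exp(1.2 * high)))
        C = rng.exponential(50.0, n)
        time, event = np.minimum(T, C), (T <= C).astype(int)
        cohort = _cohort_from_arrays(time, event, onegrp=["all"] * n)
        prof = _profile(high.astype(float), cutoff=0.5)
        table = subgroup_analysis(prof, cohort, ["onegrp"])
        overall = km_group_comparison(prof, cohort)
        assert len(table) == 1
        assert table.loc[0, "hr"] == pytest.approx(overall.hazard_ratio)
        assert table.loc[0, "logrank_p"] == pytest.approx(overall.logrank_p)

    def test_homogeneous_effect_consistent_across_sexes(self):
        consistent = 0
        for seed in range(20):
            rng = np.random.default_rng(700 + seed)
            n = 400
            high = rng.random(n) < 0.5
            sex = rng.choice(["male", "female"], n)
            T = rng.exponential(1.0 / (0.02 * np.exp(1.2 * high)))
            C = rng.exponential(50.0, n)
            time, event = np.minimum(T, C), (T <= C).astype(int)
            cohort = _cohort_from_arrays(time, event, sex=sex)
            prof = _profile(high.astype(float), cutoff=0.5)
            t = subgroup_analysis(prof, cohort, ["sex"]).set_index("level")
            a, b = t.loc["male"], t.loc["female"]
            # homogeneity: log-HR difference within 1.96 * SE of the difference
            # (SE recovered from the Wald CIs)
            se_a = (np.log(a["ci_high"]) - np.log(a["ci_low"])) / (2 * 1.96)
            se_b = (np.log(b["ci_high"]) - np.log(b["ci_low"])) / (2 * 1.96)
            diff = abs(np.log(a["hr"]) - np.log(b["hr"]))
            if diff <= 1.96 * np.hypot(se_a, se_b):
                consistent += 1
        assert consistent >= 16  # >= 80% of seeds (true rate ~95%)

    def test_degenerate_stratum_gives_na_row(self):
        cohort = _cohort_from_arrays(
            [2, 4, 6.0], [1, 1, 1], grp=["x", "x", "x"]
        )
        prof = RiskProfile(
            cohort.patient_ids, np.array([1.0, 2.0, 3.0]),
            np.array(["low", "low", "low"]), 5.0,
        )
        table = subgroup_analysis(prof, cohort, ["grp"])
        assert len(table) == 1
        assert np.isnan(table.loc[0, "hr"])
        assert table.loc[0, "n_high"] == 0

    def test_unknown_stratifier_rejected(self, toy_cohort):
        prof = _profile([1, 2, 3, 4, 5, 6.0], ids=toy_cohort.patient_ids)
        with pytest.raises(KeyError, match="unknown stratifiers"):
            subgroup_analysis(prof, toy_cohort, ["nope"])
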