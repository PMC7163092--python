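"""Penalized Cox solver: closed forms, reference fits, KKT and selection."""
from __future__ import annotations

import numpy as np
import pandas as pd
import pytest
from lifelines import CoxPHFitter

from irgpsig import (
    cox_negative_partial_loglik,
    cv_choose_lambda,
    fit_l1_cox,
    repeated_selection,
)
from irgpsig.lasso_cox import (
    ConvergenceError,
    SelectionRecord,
    SelectionTally,
    check_kkt,
    choose_final_signature,
    kkt_violation,
    lambda_max,
)
from irgpsig.containers import GenePair

from conftest import random_survival


def naive_breslow_nll(beta, X, time, event):
    """Direct double-loop Breslow negative partial log-likelihood."""
    beta = np.asarray(beta, float)
    eta = np.asarray(X, float) @ beta
    ll = 0.0
    for u in sorted(set(np.asarray(time)[np.asarray(event) == 1])):
        at_risk = np.asarray(time) >= u
        dead = (np.asarray(time) == u) & (np.asarray(event) == 1)
        ll += eta[dead].sum() - dead.sum() * np.log(np.exp(eta[at_risk]).sum())
    return -ll


class TestPartialLikelihood:
    def test_zero_beta_closed_form(self):
        # three events at distinct times: log 3 + log 2 + log 1
        val = cox_negative_partial_loglik(
            np.zeros(1), np.zeros((3, 1)), [1.0, 2.0, 3.0], [1, 1, 1]
        )
        assert val == pytest.approx(np.log(3) + np.log(2), abs=1e-12)

    def test_two_patient_hand_value(self):
        # times (1,2), both events, X=(1,0), beta=0.5:
        # ll = [0.5 - log(e^0.5 + 1)] + [0 - log(1)]
        val = cox_negative_partial_loglik(
            [0.5], np.array([[1.0], [0.0]]), [1.0, 2.0], [1, 1]
        )
        assert val == pytest.approx(np.log(np.exp(0.5) + 1) - 0.5, abs=1e-12)

    def test_matches_naive_oracle_with_ties(self):
        rng = np.random.default_rng(5)
        X = rng.normal(size=(10, 3))
        time = np.array([1, 1, 2, 3, 3, 3, 4, 5, 6, 6], dtype=float)
        event = np.array([1, 0, 1, 1, 1, 0, 0, 1, 1, 1])
        beta = np.array([0.3, -0.7, 0.1])
        mine = cox_negative_partial_loglik(beta, X, time, event)
        assert mine == pytest.approx(naive_breslow_nll(beta, X, time, event), abs=1e-8)

    def test_no_events_rejected(self):
        with pytest.raises(ValueError, match="no events"):
            cox_negative_partial_loglik([0.0], np.zeros((2, 1)), [1, 2], [0, 0])


class TestFitL1Cox:
    def test_all_zero_at_lambda_max(self):
        X, time, event = random_survival(0, 150, 6, np.array([1.0, -1, 0.5, 0, 0, 0]))
        lmax = lambda_max(X, time, event)
        fit = fit_l1_cox(X, time, event, lmax * 1.000001)
        assert np.all(fit.coefficients == 0.0)
        assert check_kkt(X, time, event, fit.coefficients, lmax * 1.000001)

    def test_unpenalized_matches_lifelines(self):
        X, time, event = random_survival(
            1, 200, 5, np.array([1.0, -0.8, 0.5, 0.0, 0.0])
        )
        fit = fit_l1_cox(X, time, event, 0.0)
        df = pd.DataFrame(X, columns=[f"x{j}" for j in range(5)])
        df["t"], df["e"] = time, event
        ref = CoxPHFitter().fit(df, "t", "e").params_.to_numpy()
        np.testing.assert_allclose(fit.coefficients, ref, atol=1e-4)

    def test_recovers_planted_single_pair(self):
        rng = np.random.default_rng(2)
        n = 400
        X = (rng.random((n, 1)) < 0.5).astype(float)
        T = rng.exponential(1.0 / (0.03 * np.exp(1.5 * X[:, 0])))
        C = rng.exponential(40.0, n)
        time, event = np.minimum(T, C), (T <= C).astype(int)
        fit = fit_l1_cox(X, time, event, 0.01)
        assert fit.coefficients[0] == pytest.approx(1.5, abs=0.3)

    def test_kkt_certified_across_random_instances(self):
        rng = np.random.default_rng(10)
        for k in range(8):
            betas = np.zeros(8)
            betas[:2] = rng.normal(0, 1, 2)
            X, time, event = random_survival(100 + k, 120, 8, betas)
            lmax = lambda_max(X, time, event)
            for lam in (0.0, 0.1 * lmax, 0.5 * lmax):
                fit = fit_l1_cox(X, time, event, lam)
                assert kkt_violation(X, time, event, fit.coefficients, lam) <= 1e-4 * max(
                    1.0, lam
                )

    def test_negative_lambda_rejected(self):
        X, time, event = random_survival(3, 50, 2)
        with pytest.raises(ValueError, match="nonnegative"):
            fit_l1_cox(X, time, event, -0.1)


class TestCVChooseLambda:
    def test_deterministic_given_seed(self):
        X, time, event = random_survival(4, 100, 6, np.array([1.0, 0, 0, 0, 0, 0]))
        a, _ = cv_choose_lambda(X, time, event, seed=7)
        b, _ = cv_choose_lambda(X, time, event, seed=7)
        assert a == b

    def test_noise_design_keeps_penalty_high(self):
        sizes = []
        ratios = []
        for seed in range(20):
            X, time, event = random_survival(200 + seed, 120, 50)
            lam, _ = cv_choose_lambda(X, time, event, seed=seed)
            fit = fit_l1_cox(X, time, event, lam)
            sizes.append(len(fit.support))
            ratios.append(lam / lambda_max(X, time, event))
        # on pure noise the chosen penalty stays high and the model near-empty
        assert np.median(sizes) <= 1
        assert sum(s <= 3 for s in sizes) >= 16  # near-0 support in >= 80%
        assert np.median(ratios) > 0.5

    def test_strong_signal_support_contains_truth(self):
        hits = 0
        for seed in range(10):
            betas = np.array([1.5, -1.5, 0, 0, 0, 0, 0, 0, 0, 0])
            X, time, event = random_survival(300 + seed, 250, 10, betas)
            lam, _ = cv_choose_lambda(X, time, event, seed=seed)
            fit = fit_l1_cox(X, time, event, lam)
            if {0, 1} <= set(fit.support):
                hits += 1
        assert hits >= 9  # >= 90% of seeds

    def test_deviance_decreases_from_lambda_max(self):
        X, time, event = random_survival(5, 150, 5, np.array([1.2, -1.0, 0, 0, 0]))
        _, curve = cv_choose_lambda(X, time, event, seed=1)
        assert curve.mean_deviance.min() <= curve.mean_deviance[0]

    def test_unknown_rule_rejected(self):
        X, time, event = random_survival(6, 60, 3)
        with pytest.raises(ValueError, match="unknown lambda rule"):
            cv_choose_lambda(X, time, event, rule="2se")


class TestRepeatedSelection:
    def test_single_iteration_tally(self):
        X, time, event = random_survival(7, 80, 4, np.array([1.0, 0, 0, 0]))
        tally = repeated_selection(X, time, event, iterations=1, base_seed=3)
        assert len(tally) == 1
        assert sum(tally.size_counts.values()) == 1

    def test_deterministic_given_base_seed(self):
        X, time, event = random_survival(8, 100, 5, np.array([1.0, -1.0, 0, 0, 0]))
        t1 = repeated_selection(X, time, event, iterations=10, base_seed=11)
        t2 = repeated_selection(X, time, event, iterations=10, base_seed=11)
        assert [r.support for r in t1.records] == [r.support for r in t2.records]
        assert [r.lambda_star for r in t1.records] == [
            r.lambda_star for r in t2.records
        ]

    def test_planted_signal_modal_size_after_screen(self):
        # protocol order: univariate log-rank/FDR screen, then repeated lasso;
        # on the screened features the modal model size tracks the truth
        from irgpsig import bh_fdr, logrank_two_group

        rng = np.random.default_rng(9)
        n, p = 300, 23
        X = (rng.random((n, p)) < 0.5).astype(float)
        betas = np.zeros(p)
        betas[:3] = [1.5, 1.5, -1.5]
        T = rng.exponential(1.0 / (0.03 * np.exp(X @ betas)))
        C = rng.exponential(40.0, n)
        time, event = np.minimum(T, C), (T <= C).astype(int)
        pvals = [
            logrank_two_group(time, event, X[:, j].astype(int))[1] for j in range(p)
        ]
        keep = np.flatnonzero(bh_fdr(pvals) < 0.01)
        assert set(keep) >= {0, 1, 2}
        tally = repeated_selection(
            X[:, keep], time, event, iterations=50, base_seed=21
        )
        modal = max(tally.size_counts, key=lambda k: tally.size_counts[k])
        assert 2 <= modal <= 4


class TestChooseFinalSignature:
    def _pairs(self, p):
        return [GenePair(f"A{j:02d}", f"B{j:02d}") for j in range(p)]

    def test_modal_size_resolution(self):
        # frequency table {3: 424, 2: 300, 4: 276} -> modal size 3
        records = []
        seed = 0
        for size, count in [(3, 424), (2, 300), (4, 276)]:
            for _ in range(count):
                records.append(
                    SelectionRecord(seed, 0.05, tuple(range(size)), size, 10.0)
                )
                seed += 1
        tally = SelectionTally(records)
        X, time, event = random_survival(12, 200, 5, np.array([1.0, -1.0, 0.8, 0, 0]))
        sig = choose_final_signature(tally, X, time, event, self._pairs(5))
        assert len(sig) == 3
        assert [p.gene_a for p in sig.pairs] == ["A00", "A01", "A02"]

    def test_single_iteration_passthrough(self):
        X, time, event = random_survival(13, 150, 4, np.array([1.2, 0, 0, 0]))
        tally = repeated_selection(X, time, event, iterations=1, base_seed=5)
        sig = choose_final_signature(tally, X, time, event, self._pairs(4))
        assert set(sig.pairs) <= set(self._pairs(4))
        assert sig.cutoff is not None

    def test_empty_tally_rejected(self):
        X, time, event = random_survival(14, 50, 2)
        with pytest.raises(ValueError, match="empty selection tally"):
            choose_final_signature(SelectionTally([]), X, time, event, self._pairs(2))

    def test_signature_sign_matches_planted_effect(self):
        rng = np.random.default_rng(15)
        n = 350
        X = (rng.random((n, 6)) < 0.5).astype(float)
        betas = np.array([1.5, -1.5, 0, 0, 0, 0])
        T = rng.exponential(1.0 / (0.03 * np.exp(X @ betas)))
        C = rng.exponential(40.0, n)
        time, event = np.minimum(T, C), (T <= C).astype(int)
        tally = repeated_selection(X, time, event, iterations=20, base_seed=31)
        sig = choose_final_signature(tally, X, time, event, self._pairs(6))
        coef = dict(zip(sig.pairs, sig.coefficients))
        assert coef[GenePair("A00", "B00")] > 0
        assert coef[GenePair("A01", "B01")] < 0
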