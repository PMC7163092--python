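"""L1-penalized Cox regression and resampling-based model-size selection.

The estimator minimizes

    f(beta) = (1/n) * NLL(beta) + lambda * ||beta||_1

where NLL is the Breslow-tie negative Cox partial log-likelihood.  Fitting
uses the standard penalized IRLS scheme: at the current linear predictor the
partial likelihood is replaced by its diagonal quadratic approximation and
the resulting weighted lasso problem is solved by cyclic coordinate descent.
The IRLS/descent core is numba-compiled because model-size selection runs
thousands of warm-started regularization paths.  Every returned solution is
certified against the KKT conditions of the convex objective.

Model-size selection mirrors the repeated cross-validation protocol used for
pair signatures: many CV runs with fresh random folds, a tally of selected
support sizes, and a final refit of the modal support at the median selected
penalty.
"""
from __future__ import annotations

import dataclasses
import logging
import statistics
from collections import Counter
from typing import Sequence

import numpy as np
from numba import njit

from .containers import GenePair, SignatureModel

log = logging.getLogger(__name__)

N_LAMBDA = 100
LAMBDA_MIN_RATIO = 0.01
COEF_TOL = 1e-7
KKT_RTOL = 1e-4


class ConvergenceError(RuntimeError):
    pass


# ---------------------------------------------------------------------------
# Breslow partial-likelihood kernels (time-sorted frame)
# ---------------------------------------------------------------------------


@njit(cache=False)
def _rev_cumsum_exp(eta_s):  # pragma: no cover - numba
    """exp(eta - max) summed over the tail; returns (rev, max)."""
    n = eta_s.shape[0]
    m = eta_s[0]
    for i in range(1, n):
        if eta_s[i] > m:
            m = eta_s[i]
    rev = np.empty(n)
    acc = 0.0
    for i in range(n - 1, -1, -1):
        acc += np.exp(eta_s[i] - m)
        rev[i] = acc
    return rev, m


@njit(cache=False)
def _nll_sorted(eta_s, d_s, d_u, risk_start):  # pragma: no cover - numba
    rev, m = _rev_cumsum_exp(eta_s)
    s = 0.0
    for i in range(eta_s.shape[0]):
        s += d_s[i] * eta_s[i]
    for u in range(d_u.shape[0]):
        s -= d_u[u] * (np.log(rev[risk_start[u]]) + m)
    return -s


@njit(cache=False)
def _grad_hess_sorted(eta_s, d_s, d_u, risk_start, n_evt_le, g, h):  # pragma: no cover
    """Gradient/diagonal Hessian of the NLL w.r.t. the sorted linear predictor."""
    n = eta_s.shape[0]
    m_u = d_u.shape[0]
    rev, m = _rev_cumsum_exp(eta_s)
    a_cum = np.empty(m_u + 1)
    b_cum = np.empty(m_u + 1)
    a_cum[0] = 0.0
    b_cum[0] = 0.0
    for u in range(m_u):
        r = rev[risk_start[u]]
        a_cum[u + 1] = a_cum[u] + d_u[u] / r
        b_cum[u + 1] = b_cum[u] + d_u[u] / (r * r)
    for i in range(n):
        e = np.exp(eta_s[i] - m)
        a = a_cum[n_evt_le[i]]
        b = b_cum[n_evt_le[i]]
        # a_cum/b_cum carry exp(m)/exp(2m) scalings that cancel against e, e^2
        g[i] = -(d_s[i] - e * a)
        h[i] = e * a - e * e * b
    return m


@njit(cache=False)
def _grad_beta(Xst, eta, d_s, d_u, risk_start, n_evt_le, g_b):  # pragma: no cover
    """g_b <- X^T dNLL/deta / n in the time-sorted frame."""
    p, n = Xst.shape
    rev, m = _rev_cumsum_exp(eta)
    a_cum = np.empty(d_u.shape[0] + 1)
    a_cum[0] = 0.0
    for u in range(d_u.shape[0]):
        a_cum[u + 1] = a_cum[u] + d_u[u] / rev[risk_start[u]]
    for j in range(p):
        g_b[j] = 0.0
    for i in range(n):
        e = np.exp(eta[i] - m)
        gi = -(d_s[i] - e * a_cum[n_evt_le[i]])
        for j in range(p):
            g_b[j] += Xst[j, i] * gi
    for j in range(p):
        g_b[j] /= n


@njit(cache=False)
def _fit_one(Xst, d_s, d_u, risk_start, n_evt_le, lam, beta, eta, tol, max_outer):
    # pragma: no cover - numba
    """Proximal-Newton solver at one penalty, in place.

    ``Xst`` is (p, n) with patients time-sorted; ``beta``/``eta`` are updated
    in place.  Each outer iteration forms the exact Breslow Hessian on the
    working set (active coefficients plus KKT violators), solves the
    L1-penalized quadratic model by cyclic coordinate descent, and
    line-searches the resulting direction on the true objective.  Returns the
    outer iteration count, or a negative error code (-1: no convergence,
    -2: inner sweep budget exhausted).
    """
    p, n = Xst.shape
    m_u = d_u.shape[0]
    g_b = np.empty(p)
    obj = _nll_sorted(eta, d_s, d_u, risk_start) / n
    for j in range(p):
        obj += lam * abs(beta[j])
    kkt_tol = 1e-5 * max(1.0, lam)
    for outer in range(1, max_outer + 1):
        _grad_beta(Xst, eta, d_s, d_u, risk_start, n_evt_le, g_b)
        # working set: active coords plus penalty-exceeding gradients
        work = np.empty(p, np.int64)
        nw = 0
        for j in range(p):
            if beta[j] != 0.0 or abs(g_b[j]) > lam:
                work[nw] = j
                nw += 1
        if nw == 0:
            return outer  # zero vector satisfies KKT outright
        # exact Hessian of NLL/n restricted to the working set
        rev, mx = _rev_cumsum_exp(eta)
        Hn = np.zeros((nw, nw))
        cumW = 0.0
        cumS = np.zeros(nw)
        cumM = np.zeros((nw, nw))
        i = n - 1
        for u in range(m_u - 1, -1, -1):
            while i >= risk_start[u]:
                wi = np.exp(eta[i] - mx)
                for a in range(nw):
                    xa = Xst[work[a], i]
                    cumS[a] += wi * xa
                    for b in range(a, nw):
                        cumM[a, b] += wi * xa * Xst[work[b], i]
                cumW += wi
                i -= 1
            for a in range(nw):
                for b in range(a, nw):
                    Hn[a, b] += d_u[u] * (
                        cumM[a, b] / cumW - cumS[a] * cumS[b] / (cumW * cumW)
                    )
        for a in range(nw):
            for b in range(a + 1, nw):
                Hn[b, a] = Hn[a, b]
        for a in range(nw):
            for b in range(nw):
                Hn[a, b] /= n
            Hn[a, a] += 1e-12
        # CD on the L1-penalized quadratic model, in working coordinates
        z = np.empty(nw)
        r = np.empty(nw)  # gradient of the quadratic model at z
        for a in range(nw):
            z[a] = beta[work[a]]
            r[a] = g_b[work[a]]
        cd_ok = False
        for _sweep in range(10_000):
            maxc = 0.0
            for a in range(nw):
                aa = Hn[a, a]
                u_ = r[a] - aa * z[a]
                if -u_ > lam:
                    znew = (-u_ - lam) / aa
                elif -u_ < -lam:
                    znew = (-u_ + lam) / aa
                else:
                    znew = 0.0
                diff = znew - z[a]
                if diff != 0.0:
                    for b in range(nw):
                        r[b] += Hn[b, a] * diff
                    z[a] = znew
                    ad = abs(diff)
                    if ad > maxc:
                        maxc = ad
            if maxc < tol * 0.1:
                cd_ok = True
                break
        if not cd_ok:
            return -2
        # line search along the proximal-Newton direction
        dz = np.empty(nw)
        step_any = False
        for a in range(nw):
            dz[a] = z[a] - beta[work[a]]
            if dz[a] != 0.0:
                step_any = True
        step_max = 0.0
        if step_any:
            t = 1.0
            accepted = False
            for _half in range(40):
                eta_c = eta.copy()
                for a in range(nw):
                    da = t * dz[a]
                    if da != 0.0:
                        xj = Xst[work[a]]
                        for i2 in range(n):
                            eta_c[i2] += da * xj[i2]
                obj_c = _nll_sorted(eta_c, d_s, d_u, risk_start) / n
                for j in range(p):
                    obj_c += lam * abs(beta[j])
                for a in range(nw):
                    obj_c += lam * (abs(beta[work[a]] + t * dz[a]) - abs(beta[work[a]]))
                if obj_c <= obj + 1e-12:
                    for a in range(nw):
                        da = t * dz[a]
                        beta[work[a]] += da
                        if abs(da) > step_max:
                            step_max = abs(da)
                    for i2 in range(n):
                        eta[i2] = eta_c[i2]
                    obj = obj_c
                    accepted = True
                    break
                t *= 0.5
            if not accepted:
                step_max = 0.0  # numerically stationary
        if step_max < tol:
            # confirm global KKT before declaring victory
            _grad_beta(Xst, eta, d_s, d_u, risk_start, n_evt_le, g_b)
            ok = True
            for j in range(p):
                if beta[j] == 0.0:
                    if abs(g_b[j]) > lam + kkt_tol:
                        ok = False
                        break
                else:
                    s = 1.0 if beta[j] > 0 else -1.0
                    if abs(g_b[j] + lam * s) > kkt_tol:
                        ok = False
                        break
            if ok:
                return outer
    return -1


@njit(cache=False)
def _fit_path_nb(Xst, d_s, d_u, risk_start, n_evt_le, lambdas, tol, max_outer):
    # pragma: no cover - numba
    """Warm-started coefficient path over a descending lambda grid."""
    p = Xst.shape[0]
    coefs = np.zeros((lambdas.shape[0], p))
    beta = np.zeros(p)
    eta = np.zeros(Xst.shape[1])
    for li in range(lambdas.shape[0]):
        status = _fit_one(
            Xst, d_s, d_u, risk_start, n_evt_le, lambdas[li], beta, eta, tol, max_outer
        )
        if status < 0:
            return coefs, status
        coefs[li] = beta
    return coefs, 0


# ---------------------------------------------------------------------------
# survival-data bookkeeping
# ---------------------------------------------------------------------------


class _CoxData:
    """Time-sorted survival data plus per-event-time index structures."""

    def __init__(self, time: np.ndarray, event: np.ndarray):
        time = np.asarray(time, dtype=float)
        event = np.asarray(event, dtype=float)
        if time.shape != event.shape:
            raise ValueError("time and event length mismatch")
        if event.sum() == 0:
            raise ValueError("Cox partial likelihood undefined with no events")
        self.n = len(time)
        self.order = np.argsort(time, kind="stable")
        self.t = time[self.order]
        self.d = event[self.order]
        uniq = np.unique(self.t[self.d > 0])
        self.risk_start = np.searchsorted(self.t, uniq, side="left")
        self.d_u = np.zeros(len(uniq))
        is_evt = self.d > 0
        np.add.at(self.d_u, np.searchsorted(uniq, self.t[is_evt]), self.d[is_evt])
        self.n_evt_le = np.searchsorted(uniq, self.t, side="right")

    def sort_X(self, X: np.ndarray) -> np.ndarray:
        """(p, n) time-sorted transposed design for the numba kernels."""
        return np.ascontiguousarray(X[self.order].T)

    def nll(self, eta: np.ndarray) -> float:
        return float(
            _nll_sorted(
                np.ascontiguousarray(eta[self.order]), self.d, self.d_u, self.risk_start
            )
        )

    def grad_eta(self, eta: np.ndarray) -> np.ndarray:
        g = np.empty(self.n)
        h = np.empty(self.n)
        _grad_hess_sorted(
            np.ascontiguousarray(eta[self.order]),
            self.d,
            self.d_u,
            self.risk_start,
            self.n_evt_le,
            g,
            h,
        )
        out = np.empty(self.n)
        out[self.order] = g
        return out


def cox_negative_partial_loglik(
    beta: Sequence[float],
    X: np.ndarray,
    time: Sequence[float],
    event: Sequence[int],
) -> float:
    """Breslow-tie negative Cox partial log-likelihood at ``beta``.

    At ``beta = 0`` with distinct event times this reduces to the sum of the
    log risk-set sizes over events.
    """
    X = np.asarray(X, dtype=float)
    beta = np.asarray(beta, dtype=float)
    data = _CoxData(np.asarray(time, float), np.asarray(event, float))
    if X.shape != (data.n, len(beta)):
        raise ValueError(f"X shape {X.shape} incompatible with n={data.n}, p={len(beta)}")
    return data.nll(X @ beta)


def lambda_max(X: np.ndarray, time: Sequence[float], event: Sequence[int]) -> float:
    """Smallest penalty at which the all-zero solution is optimal."""
    X = np.asarray(X, dtype=float)
    data = _CoxData(np.asarray(time, float), np.asarray(event, float))
    g = data.grad_eta(np.zeros(data.n))
    return float(np.max(np.abs(X.T @ g)) / data.n)


# ---------------------------------------------------------------------------
# public fitting API
# ---------------------------------------------------------------------------


@dataclasses.dataclass
class PenalizedCoxFit:
    lam: float
    coefficients: np.ndarray
    n_outer_iter: int
    cv_curve: "CVCurve | None" = None

    @property
    def support(self) -> np.ndarray:
        return np.flatnonzero(self.coefficients)


@dataclasses.dataclass
class CVCurve:
    lambdas: np.ndarray
    mean_deviance: np.ndarray
    sd_deviance: np.ndarray


def kkt_violation(
    X: np.ndarray,
    time: Sequence[float],
    event: Sequence[int],
    beta: np.ndarray,
    lam: float,
) -> float:
    """Worst-case KKT residual on the gradient scale of NLL/n.

    Inactive coordinates require |g_j| <= lambda; active ones require
    g_j + lambda * sign(beta_j) = 0.
    """
    X = np.asarray(X, dtype=float)
    beta = np.asarray(beta, dtype=float)
    data = _CoxData(np.asarray(time, float), np.asarray(event, float))
    g = X.T @ data.grad_eta(X @ beta) / data.n
    inactive = beta == 0.0
    viol = 0.0
    if inactive.any():
        viol = max(viol, float(np.max(np.abs(g[inactive])) - lam))
    if (~inactive).any():
        viol = max(
            viol, float(np.max(np.abs(g[~inactive] + lam * np.sign(beta[~inactive]))))
        )
    return max(viol, 0.0)


def check_kkt(
    X: np.ndarray,
    time: Sequence[float],
    event: Sequence[int],
    beta: np.ndarray,
    lam: float,
    rtol: float = KKT_RTOL,
) -> bool:
    """True when ``beta`` satisfies the KKT conditions within tolerance."""
    return kkt_violation(X, time, event, beta, lam) <= rtol * max(1.0, lam)


def fit_l1_cox(
    X: np.ndarray,
    time: Sequence[float],
    event: Sequence[int],
    lam: float,
    beta0: np.ndarray | None = None,
    max_outer: int = 500,
) -> PenalizedCoxFit:
    """Fit the L1-penalized Cox model at a single penalty ``lam`` >= 0.

    The returned solution is KKT-certified; failure to converge or to satisfy
    the KKT conditions raises :class:`ConvergenceError`.
    """
    if lam < 0:
        raise ValueError("lambda must be nonnegative")
    X = np.asarray(X, dtype=float)
    data = _CoxData(np.asarray(time, float), np.asarray(event, float))
    if X.shape[0] != data.n:
        raise ValueError("X row count does not match survival data")
    Xst = data.sort_X(X)
    beta = np.zeros(X.shape[1]) if beta0 is None else np.asarray(beta0, float).copy()
    eta = np.ascontiguousarray((X @ beta)[data.order])
    status = _fit_one(
        Xst, data.d, data.d_u, data.risk_start, data.n_evt_le,
        float(lam), beta, eta, COEF_TOL, max_outer,
    )
    if status == -2:
        raise ConvergenceError("coordinate descent exhausted its sweep budget")
    if status == -1:
        raise ConvergenceError(
            f"L1-Cox did not converge in {max_outer} outer iterations (lambda={lam:g})"
        )
    if not check_kkt(X, time, event, beta, lam):
        raise ConvergenceError(
            f"solution at lambda={lam:g} failed KKT certification "
            f"(violation {kkt_violation(X, time, event, beta, lam):.3g})"
        )
    return PenalizedCoxFit(lam=float(lam), coefficients=beta, n_outer_iter=int(status))


def _lambda_path(lmax: float) -> np.ndarray:
    return np.geomspace(lmax, LAMBDA_MIN_RATIO * lmax, N_LAMBDA)


def _fit_path(X: np.ndarray, data: _CoxData, lambdas: np.ndarray) -> np.ndarray:
    coefs, status = _fit_path_nb(
        data.sort_X(X), data.d, data.d_u, data.risk_start, data.n_evt_le,
        np.asarray(lambdas, float), 1e-6, 200,
    )
    if status < 0:
        raise ConvergenceError(f"path fit failed with status {status}")
    return coefs


def _make_folds(
    time: np.ndarray, event: np.ndarray, n_folds: int, seed: int
) -> np.ndarray:
    """Random fold ids such that every fold and every train split has events."""
    n = len(time)
    if n_folds < 2 or n_folds > n:
        raise ValueError(f"n_folds={n_folds} invalid for n={n}")
    rng = np.random.default_rng(seed)
    for _ in range(10):
        fold_id = np.empty(n, dtype=int)
        perm = rng.permutation(n)
        for k, chunk in enumerate(np.array_split(perm, n_folds)):
            fold_id[chunk] = k
        ok = all(
            event[fold_id == k].sum() >= 1 and event[fold_id != k].sum() >= 2
            for k in range(n_folds)
        )
        if ok:
            return fold_id
    raise ValueError("could not build folds with events in every fold after 10 attempts")


def _cv_deviance(
    X: np.ndarray,
    time: np.ndarray,
    event: np.ndarray,
    lambdas: np.ndarray,
    fold_id: np.ndarray,
) -> tuple[np.ndarray, np.ndarray]:
    """Cross-validated partial-likelihood deviance per lambda.

    Verweij-van Houwelingen form: the fold-k contribution is twice the
    difference between the full-data NLL and the training-fold NLL, both at
    the training-fold solution.  This stays well-defined even when a held-out
    fold alone has too few events.
    """
    full = _CoxData(time, event)
    n_folds = int(fold_id.max()) + 1
    devs = np.zeros((n_folds, len(lambdas)))
    for k in range(n_folds):
        tr = fold_id != k
        data_tr = _CoxData(time[tr], event[tr])
        coefs = _fit_path(X[tr], data_tr, lambdas)
        etas = X @ coefs.T  # (n, n_lambda)
        for i in range(len(lambdas)):
            devs[k, i] = 2.0 * (full.nll(etas[:, i]) - data_tr.nll(etas[tr, i]))
    return devs.mean(axis=0), devs.std(axis=0, ddof=1)


def cv_choose_lambda(
    X: np.ndarray,
    time: Sequence[float],
    event: Sequence[int],
    n_folds: int = 10,
    seed: int = 0,
    rule: str = "min",
) -> tuple[float, CVCurve]:
    """Choose the penalty by K-fold cross-validated deviance.

    ``rule='min'`` takes the deviance-minimizing lambda; ``rule='1se'`` the
    largest lambda within one standard error of the minimum.  The path runs
    over 100 log-spaced values from lambda_max down to 0.01*lambda_max; fold
    assignment is deterministic given ``seed``.
    """
    X = np.asarray(X, dtype=float)
    time = np.asarray(time, dtype=float)
    event = np.asarray(event, dtype=float)
    lambdas = _lambda_path(lambda_max(X, time, event))
    fold_id = _make_folds(time, event, n_folds, seed)
    mean_dev, sd_dev = _cv_deviance(X, time, event, lambdas, fold_id)
    curve = CVCurve(lambdas, mean_dev, sd_dev)
    i_min = int(np.argmin(mean_dev))
    if rule == "min":
        i_star = i_min
    elif rule == "1se":
        se = sd_dev[i_min] / np.sqrt(n_folds)
        i_star = int(np.flatnonzero(mean_dev <= mean_dev[i_min] + se).min())
    else:
        raise ValueError(f"unknown lambda rule {rule!r}; use 'min' or '1se'")
    return float(lambdas[i_star]), curve


# ---------------------------------------------------------------------------
# repeated selection
# ---------------------------------------------------------------------------


@dataclasses.dataclass
class SelectionRecord:
    seed: int
    lambda_star: float
    support: tuple[int, ...]
    size: int
    cv_deviance: float


@dataclasses.dataclass
class SelectionTally:
    """Per-iteration CV-lasso outcomes and the model-size frequency table."""

    records: list[SelectionRecord]
    n_failed: int = 0

    @property
    def size_counts(self) -> dict[int, int]:
        return dict(sorted(Counter(r.size for r in self.records).items()))

    def __len__(self) -> int:
        return len(self.records)


def repeated_selection(
    X: np.ndarray,
    time: Sequence[float],
    event: Sequence[int],
    iterations: int = 1000,
    base_seed: int = 0,
    n_folds: int = 10,
    rule: str = "min",
) -> SelectionTally:
    """Run CV-tuned lasso ``iterations`` times with fresh random folds.

    Iteration ``i`` uses fold seed ``base_seed + i``.  The support recorded
    for an iteration is the nonzero set of the full-data path solution at
    that iteration's chosen lambda (the path does not change across
    iterations; only the folds, hence the chosen lambda, do).  More than 10%
    failed iterations aborts.
    """
    if iterations < 1:
        raise ValueError("iterations must be >= 1")
    X = np.asarray(X, dtype=float)
    time = np.asarray(time, dtype=float)
    event = np.asarray(event, dtype=float)
    data = _CoxData(time, event)
    lambdas = _lambda_path(lambda_max(X, time, event))
    full_path = _fit_path(X, data, lambdas)
    records: list[SelectionRecord] = []
    n_failed = 0
    for i in range(iterations):
        seed = base_seed + i
        try:
            fold_id = _make_folds(time, event, n_folds, seed)
            mean_dev, sd_dev = _cv_deviance(X, time, event, lambdas, fold_id)
            if rule == "min":
                i_star = int(np.argmin(mean_dev))
            elif rule == "1se":
                i_min = int(np.argmin(mean_dev))
                se = sd_dev[i_min] / np.sqrt(n_folds)
                i_star = int(np.flatnonzero(mean_dev <= mean_dev[i_min] + se).min())
            else:
                raise ValueError(f"unknown lambda rule {rule!r}")
            support = tuple(np.flatnonzero(full_path[i_star]).tolist())
            records.append(
                SelectionRecord(
                    seed=seed,
                    lambda_star=float(lambdas[i_star]),
                    support=support,
                    size=len(support),
                    cv_deviance=float(mean_dev[i_star]),
                )
            )
        except (ConvergenceError, ValueError) as exc:
            n_failed += 1
            log.warning("selection iteration %d failed: %s", i, exc)
    if n_failed > 0.1 * iterations:
        raise ConvergenceError(f"{n_failed}/{iterations} selection iterations failed")
    tally = SelectionTally(records, n_failed=n_failed)
    log.info("selection tally over %d iterations: %s", len(records), tally.size_counts)
    return tally


def choose_final_signature(
    tally: SelectionTally,
    X: np.ndarray,
    time: Sequence[float],
    event: Sequence[int],
    pairs: Sequence[GenePair],
    rule: str = "modal_support",
) -> SignatureModel:
    """Extract the final signature from a selection tally.

    ``modal_support`` (default): find the modal support size (ties broken
    toward the larger size), take the most frequent support set of that size
    (ties broken by best mean CV deviance, then lexicographically), and refit
    the L1-Cox model restricted to that support at the median chosen lambda
    of the matching iterations.  ``best_deviance`` instead takes the support
    of the single iteration with the lowest CV deviance.  The training-cohort
    median risk score is stored as the dichotomization cutoff.
    """
    if not tally.records:
        raise ValueError("empty selection tally")
    X = np.asarray(X, dtype=float)
    if rule == "best_deviance":
        best = min(tally.records, key=lambda r: (r.cv_deviance, r.support))
        support = best.support
        chosen_records = [r for r in tally.records if r.support == support]
    elif rule == "modal_support":
        counts = Counter(r.size for r in tally.records)
        top = max(counts.values())
        k_star = max(k for k, c in counts.items() if c == top)
        if sum(1 for c in counts.values() if c == top) > 1:
            log.info("model-size tie resolved toward larger size %d", k_star)
        at_k = [r for r in tally.records if r.size == k_star]
        sup_counts = Counter(r.support for r in at_k)
        top_sup = max(sup_counts.values())
        tied = [s for s, c in sup_counts.items() if c == top_sup]
        if len(tied) > 1:
            mean_dev = {
                s: float(np.mean([r.cv_deviance for r in at_k if r.support == s]))
                for s in tied
            }
            support = min(tied, key=lambda s: (mean_dev[s], s))
        else:
            support = tied[0]
        chosen_records = [r for r in at_k if r.support == support]
    else:
        raise ValueError(f"unknown final-model rule {rule!r}")

    if len(support) == 0:
        raise ValueError("selected support is empty; no signature can be formed")
    lam_med = float(statistics.median(r.lambda_star for r in chosen_records))
    cols = list(support)
    fit = fit_l1_cox(X[:, cols], time, event, lam_med)
    nonzero = np.flatnonzero(fit.coefficients)
    if len(nonzero) < len(cols):
        log.warning(
            "refit at lambda=%.4g zeroed %d of %d chosen pairs",
            lam_med,
            len(cols) - len(nonzero),
            len(cols),
        )
    if len(nonzero) == 0:
        raise ValueError("refit eliminated every chosen pair")
    kept_cols = [cols[j] for j in nonzero]
    kept_pairs = [pairs[c] for c in kept_cols]
    coefs = fit.coefficients[nonzero]
    scores = X[:, kept_cols] @ coefs
    return SignatureModel(kept_pairs, coefs, cutoff=float(np.median(scores)))
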