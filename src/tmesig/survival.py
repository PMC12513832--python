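"""Survival-analysis primitives.

Cox partial likelihood (Breslow/Efron ties), Newton-type unpenalized fits,
a sign-constrained L1-penalized Cox solver (IRLS outer loop with cyclic
coordinate descent on the weighted working response, soft-thresholding
followed by projection onto the sign orthant), cross-validated penalty
selection, Kaplan-Meier product-limit curves, one-/two-sided log-rank
tests and hazard ratios.

The sign constraint is the device that turns a penalized Cox fit into a
*directional* signature: ``nonnegative`` coefficients can only describe
risk-increasing (resistance) features, ``nonpositive`` only protective
(response) features.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Dict, Literal, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from numba import njit
from scipy import stats

__all__ = [
    "SurvivalData",
    "LassoConfig",
    "CoxFit",
    "CVResult",
    "cox_partial_loglik",
    "fit_cox",
    "fit_constrained_lasso_cox",
    "make_lambda_path",
    "cv_lambda",
    "km_estimate",
    "logrank_test",
    "hazard_ratio",
]

Sign = Literal["nonnegative", "nonpositive", "unconstrained"]
Ties = Literal["breslow", "efron"]

#: coefficients larger than this in absolute value indicate a monotone
#: likelihood (perfect separation); fits are capped here and flagged.
BETA_CAP = 20.0


# ---------------------------------------------------------------------------
# containers
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class SurvivalData:
    """Right-censored time-to-event data, time in months.

    event: 1 = progression/death, 0 = censored/progression-free.
    """

    time: np.ndarray
    event: np.ndarray
    patient_id: np.ndarray

    def __post_init__(self):
        t = np.asarray(self.time, dtype=float)
        e = np.asarray(self.event, dtype=np.int64)
        pid = np.asarray(self.patient_id)
        if t.shape != e.shape or t.shape != pid.shape:
            raise ValueError("time, event and patient_id must be aligned")
        if np.any(~np.isfinite(t)) or np.any(t <= 0):
            raise ValueError("times must be positive and finite")
        if not np.isin(e, [0, 1]).all():
            raise ValueError("event indicator must be 0 or 1")
        if len(set(pid.tolist())) != len(pid):
            raise ValueError("patient ids must be unique")
        object.__setattr__(self, "time", t)
        object.__setattr__(self, "event", e)
        object.__setattr__(self, "patient_id", pid)

    def __len__(self) -> int:
        return self.time.shape[0]

    @property
    def n_events(self) -> int:
        return int(self.event.sum())

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame, time="time", event="event",
                       patient_id="patient_id") -> "SurvivalData":
        missing = [c for c in (time, event, patient_id) if c not in df.columns]
        if missing:
            raise ValueError(f"missing required columns: {missing}")
        return cls(df[time].to_numpy(), df[event].to_numpy(),
                   df[patient_id].to_numpy())

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame({"patient_id": self.patient_id,
                             "time": self.time, "event": self.event})

    def subset(self, idx) -> "SurvivalData":
        return SurvivalData(self.time[idx], self.event[idx], self.patient_id[idx])


@dataclass
class LassoConfig:
    """Configuration for sign-constrained L1-penalized Cox regression."""

    sign: Sign = "unconstrained"
    lambda_path: Optional[np.ndarray] = None
    n_lambda: int = 40
    lambda_min_ratio: float = 0.01
    n_folds: int = 10
    standardize: bool = True
    ties: Ties = "breslow"
    max_iter: int = 1000
    tol: float = 1e-8
    seed: int = 0
    use_1se: bool = False

    def __post_init__(self):
        if self.lambda_path is not None:
            lp = np.asarray(self.lambda_path, dtype=float)
            if lp.ndim != 1 or np.any(lp <= 0) or np.any(np.diff(lp) >= 0):
                raise ValueError("lambda_path must be strictly decreasing and positive")
            self.lambda_path = lp
        if self.n_folds < 2:
            raise ValueError("n_folds must be at least 2")
        if self.sign not in ("nonnegative", "nonpositive", "unconstrained"):
            raise ValueError(f"unknown sign constraint: {self.sign}")


@dataclass
class CoxFit:
    coefficients: Dict[str, float]
    loglik: float
    se: Dict[str, float]
    converged: bool
    sign: Sign = "unconstrained"
    n: int = 0
    n_events: int = 0

    @property
    def beta(self) -> np.ndarray:
        return np.array(list(self.coefficients.values()), dtype=float)


@dataclass
class CVResult:
    lambda_path: np.ndarray
    mean_deviance: np.ndarray
    se_deviance: np.ndarray
    lambda_min: float
    lambda_1se: float
    fold_seed: int

    @property
    def selected(self) -> float:
        return self.lambda_min


# ---------------------------------------------------------------------------
# risk-set bookkeeping
# ---------------------------------------------------------------------------


def _sorted_structure(surv: SurvivalData):
    """Sort by ascending time; return order, sorted event vector and tie-group
    start offsets (tied times share a risk-set denominator)."""
    order = np.argsort(surv.time, kind="stable")
    t = surv.time[order]
    e = surv.event[order].astype(np.float64)
    # group starts: positions where time changes
    change = np.empty(t.shape[0], dtype=bool)
    change[0] = True
    change[1:] = t[1:] != t[:-1]
    starts = np.flatnonzero(change)
    tie_start = np.append(starts, t.shape[0]).astype(np.int64)
    return order, e, tie_start


# ---------------------------------------------------------------------------
# numba kernels (Breslow ties)
# ---------------------------------------------------------------------------


@njit(cache=True)
def _breslow_ll_grad_w(eta, event, tie_start):
    """Log partial likelihood, per-subject gradient and diagonal Hessian
    weights under Breslow tie handling.  Inputs are sorted by ascending time.
    """
    n = eta.shape[0]
    G = tie_start.shape[0] - 1
    shift = eta[0]
    for i in range(n):
        if eta[i] > shift:
            shift = eta[i]
    e = np.empty(n)
    for i in range(n):
        e[i] = np.exp(eta[i] - shift)
    # risk-set sums per tie group, accumulated from the last group backwards
    S = np.empty(G)
    acc = 0.0
    for g in range(G - 1, -1, -1):
        for i in range(tie_start[g], tie_start[g + 1]):
            acc += e[i]
        S[g] = acc
    ll = 0.0
    grad = np.empty(n)
    w = np.empty(n)
    A = 0.0  # sum over event groups so far of d/S
    B = 0.0  # sum of d/S^2
    for g in range(G):
        d = 0.0
        for i in range(tie_start[g], tie_start[g + 1]):
            d += event[i]
        if d > 0.0:
            A += d / S[g]
            B += d / (S[g] * S[g])
            ll += -d * (np.log(S[g]) + shift)
            for i in range(tie_start[g], tie_start[g + 1]):
                if event[i] > 0.0:
                    ll += eta[i]
        for i in range(tie_start[g], tie_start[g + 1]):
            grad[i] = event[i] - e[i] * A
            wi = e[i] * A - e[i] * e[i] * B
            w[i] = wi if wi > 1e-12 else 1e-12
    return ll, grad, w


@njit(cache=True)
def _cd_wls(X, w, r, beta, lam, sign_code, max_inner, tol):
    """Cyclic coordinate descent for the weighted least-squares subproblem

        min (1/2n) sum_i w_i (r_i + x_i beta_old - x_i beta)^2 + lam * |beta|_1

    subject to the sign orthant.  ``r`` holds current residuals z - X beta and
    is updated in place.  sign_code: 0 unconstrained, +1 nonneg, -1 nonpos.
    """
    n, p = X.shape
    denom = np.empty(p)
    for j in range(p):
        s = 0.0
        for i in range(n):
            s += w[i] * X[i, j] * X[i, j]
        denom[j] = s / n
    for _ in range(max_inner):
        max_delta = 0.0
        for j in range(p):
            if denom[j] <= 1e-14:
                continue
            rho = 0.0
            for i in range(n):
                rho += w[i] * X[i, j] * r[i]
            rho = rho / n + denom[j] * beta[j]
            # soft threshold
            if rho > lam:
                bnew = (rho - lam) / denom[j]
            elif rho < -lam:
                bnew = (rho + lam) / denom[j]
            else:
                bnew = 0.0
            # project onto sign orthant
            if sign_code > 0 and bnew < 0.0:
                bnew = 0.0
            elif sign_code < 0 and bnew > 0.0:
                bnew = 0.0
            diff = bnew - beta[j]
            if diff != 0.0:
                for i in range(n):
                    r[i] -= diff * X[i, j]
                beta[j] = bnew
                d2 = diff * diff * denom[j]
                if d2 > max_delta:
                    max_delta = d2
        if max_delta < tol:
            break
    return beta


@njit(cache=True)
def _pen_cox_fit(X, event, tie_start, lam, sign_code, beta, max_outer,
                 max_inner, tol):
    """One penalized Cox fit (Breslow) by IRLS + coordinate descent, warm
    started from ``beta`` (modified in place).  Returns (beta, loglik)."""
    n, p = X.shape
    eta = np.zeros(n)
    for i in range(n):
        s = 0.0
        for j in range(p):
            s += X[i, j] * beta[j]
        eta[i] = s
    ll_old = -1e300
    for _ in range(max_outer):
        ll, grad, w = _breslow_ll_grad_w(eta, event, tie_start)
        # working residual r = z - eta with z = eta + grad/w  =>  r = grad/w
        r = np.empty(n)
        for i in range(n):
            r[i] = grad[i] / w[i]
        beta = _cd_wls(X, w, r, beta, lam, sign_code, max_inner, tol)
        for i in range(n):
            s = 0.0
            for j in range(p):
                s += X[i, j] * beta[j]
            eta[i] = s
        if np.abs(ll - ll_old) < tol * (np.abs(ll) + 1.0):
            break
        ll_old = ll
    ll, grad, w = _breslow_ll_grad_w(eta, event, tie_start)
    return beta, ll


@njit(cache=True)
def _pen_cox_path(X, event, tie_start, lambdas, sign_code, max_outer,
                  max_inner, tol):
    """Warm-started path of penalized fits over a decreasing lambda grid."""
    p = X.shape[1]
    L = lambdas.shape[0]
    betas = np.zeros((L, p))
    beta = np.zeros(p)
    for li in range(L):
        beta, _ = _pen_cox_fit(X, event, tie_start, lambdas[li], sign_code,
                               beta, max_outer, max_inner, tol)
        betas[li] = beta
    return betas


_SIGN_CODE = {"unconstrained": 0, "nonnegative": 1, "nonpositive": -1}


# ---------------------------------------------------------------------------
# partial likelihood (reference implementation, Breslow & Efron)
# ---------------------------------------------------------------------------


def _as_matrix(X) -> Tuple[np.ndarray, list]:
    if isinstance(X, pd.DataFrame):
        return X.to_numpy(dtype=float), list(X.columns)
    arr = np.asarray(X, dtype=float)
    if arr.ndim == 1:
        arr = arr[:, None]
    return arr, [f"x{j}" for j in range(arr.shape[1])]


def cox_partial_loglik(beta, X, surv: SurvivalData, ties: Ties = "breslow") -> float:
    """Cox log partial likelihood at ``beta``.

    Invariant to adding a constant to any covariate column.  Raises if the
    data contain no events.
    """
    Xa, _ = _as_matrix(X)
    beta = np.asarray(beta, dtype=float)
    if not np.all(np.isfinite(Xa)):
        raise ValueError("covariate matrix contains non-finite values")
    if surv.n_events == 0:
        raise ValueError("no events")
    order, e, tie_start = _sorted_structure(surv)
    eta = Xa[order] @ beta
    shift = eta.max()
    ex = np.exp(eta - shift)
    G = len(tie_start) - 1
    # suffix sums of exp(eta) per group
    grp_sum = np.add.reduceat(ex, tie_start[:-1])
    S = np.cumsum(grp_sum[::-1])[::-1]
    if ties == "breslow":
        d = np.add.reduceat(e, tie_start[:-1])
        return float(eta[e > 0].sum() - d @ (np.log(S) + shift))
    if ties != "efron":
        raise ValueError(f"unknown tie method: {ties}")
    ll = 0.0
    for g in range(G):
        sl = slice(tie_start[g], tie_start[g + 1])
        ev = e[sl] > 0
        d = int(ev.sum())
        if d == 0:
            continue
        ll += eta[sl][ev].sum()
        T = ex[sl][ev].sum()
        for l in range(d):
            ll -= np.log(S[g] - (l / d) * T) + shift
    return float(ll)


def _grad_hess(beta, Xa, surv: SurvivalData, ties: Ties):
    """Gradient and full observed-information Hessian of the partial loglik."""
    order, e, tie_start = _sorted_structure(surv)
    Xs = Xa[order]
    n, p = Xs.shape
    eta = Xs @ beta
    shift = eta.max()
    ex = np.exp(eta - shift)
    exX = ex[:, None] * Xs
    exXX = np.einsum("i,ij,ik->ijk", ex, Xs, Xs)
    G = len(tie_start) - 1
    g0 = np.add.reduceat(ex, tie_start[:-1])
    g1 = np.add.reduceat(exX, tie_start[:-1], axis=0)
    g2 = np.add.reduceat(exXX, tie_start[:-1], axis=0)
    S0 = np.cumsum(g0[::-1])[::-1]
    S1 = np.cumsum(g1[::-1], axis=0)[::-1]
    S2 = np.cumsum(g2[::-1], axis=0)[::-1]
    U = np.zeros(p)
    H = np.zeros((p, p))
    ll = 0.0
    for g in range(G):
        sl = slice(tie_start[g], tie_start[g + 1])
        ev = e[sl] > 0
        d = int(ev.sum())
        if d == 0:
            continue
        xev = Xs[sl][ev]
        ll += eta[sl][ev].sum()
        U += xev.sum(axis=0)
        if ties == "breslow":
            ll -= d * (np.log(S0[g]) + shift)
            m1 = S1[g] / S0[g]
            U -= d * m1
            H += d * (S2[g] / S0[g] - np.outer(m1, m1))
        else:  # efron
            T0 = ex[sl][ev].sum()
            T1 = exX[sl][ev].sum(axis=0)
            T2 = exXX[sl][ev].sum(axis=0)
            for l in range(d):
                f = l / d
                s0 = S0[g] - f * T0
                s1 = S1[g] - f * T1
                s2 = S2[g] - f * T2
                ll -= np.log(s0) + shift
                m1 = s1 / s0
                U -= m1
                H += s2 / s0 - np.outer(m1, m1)
    return float(ll), U, H


def fit_cox(X, surv: SurvivalData, ties: Ties = "breslow",
            sign: Sign = "unconstrained", max_iter: int = 100,
            tol: float = 1e-9) -> CoxFit:
    """Unpenalized Cox proportional-hazards fit by Newton's method with
    step-halving.

    With a sign constraint the fit is obtained from the penalized solver at
    lambda=0 (projected coordinate descent); standard errors are then reported
    only for coefficients strictly inside the orthant.

    A monotone likelihood (perfect separation) is detected by coefficients
    escaping ``BETA_CAP``; the fit is capped there and flagged non-converged.
    """
    Xa, names = _as_matrix(X)
    n, p = Xa.shape
    if surv.n_events == 0:
        raise ValueError("no events")
    sds = Xa.std(axis=0)
    if np.any(sds == 0):
        bad = [names[j] for j in np.flatnonzero(sds == 0)]
        raise ValueError(f"constant columns: {bad}")
    if p >= surv.n_events:
        warnings.warn(
            f"{p} features for {surv.n_events} events; estimates may be unstable",
            stacklevel=2)

    if sign != "unconstrained":
        fit = fit_constrained_lasso_cox(
            Xa, surv, lam=0.0,
            config=LassoConfig(sign=sign, ties=ties, standardize=True, tol=tol))
        beta = fit.beta
        ll, U, H = _grad_hess(beta, Xa, surv, ties)
        se = np.full(p, np.nan)
        active = np.flatnonzero(beta != 0.0)
        if active.size:
            try:
                cov = np.linalg.inv(H[np.ix_(active, active)])
                se[active] = np.sqrt(np.clip(np.diag(cov), 0, None))
            except np.linalg.LinAlgError:
                pass
        return CoxFit(dict(zip(names, beta)), ll, dict(zip(names, se)),
                      fit.converged, sign, n, surv.n_events)

    # fit on standardized covariates for conditioning; the separation cap
    # applies to per-SD log hazard ratios, which are scale-free
    mu, sd = Xa.mean(axis=0), sds
    Xz = (Xa - mu) / sd
    beta = np.zeros(p)
    ll, U, H = _grad_hess(beta, Xz, surv, ties)
    converged = False
    for _ in range(max_iter):
        try:
            delta = np.linalg.solve(H, U)
        except np.linalg.LinAlgError:
            delta = np.linalg.lstsq(H, U, rcond=None)[0]
        step = 1.0
        for _ in range(30):
            cand = beta + step * delta
            ll_new = cox_partial_loglik(cand, Xz, surv, ties)
            if ll_new >= ll - 1e-9 * (abs(ll) + 1.0):
                break
            step *= 0.5
        beta = beta + step * delta
        if np.any(np.abs(beta) > BETA_CAP):
            beta = np.clip(beta, -BETA_CAP, BETA_CAP)
            ll, U, H = _grad_hess(beta, Xz, surv, ties)
            converged = False
            break
        ll, U, H = _grad_hess(beta, Xz, surv, ties)
        if np.max(np.abs(U)) <= tol * (abs(ll) + 1.0):
            converged = True
            break
    try:
        cov = np.linalg.inv(H)
        se_z = np.sqrt(np.clip(np.diag(cov), 0, None))
    except np.linalg.LinAlgError:
        se_z = np.full(p, np.nan)
    # monotone likelihood leaves a flat direction: per-SD SEs explode long
    # before the coefficient cap is reached
    if np.any(~np.isfinite(se_z)) or np.any(se_z > 100.0):
        converged = False
    return CoxFit(dict(zip(names, beta / sd)), ll,
                  dict(zip(names, se_z / sd)), converged, "unconstrained",
                  n, surv.n_events)


# ---------------------------------------------------------------------------
# penalized fits and cross-validation
# ---------------------------------------------------------------------------


def _prepare(X, surv, standardize):
    Xa, names = _as_matrix(X)
    if not np.all(np.isfinite(Xa)):
        raise ValueError("covariate matrix contains non-finite values")
    order, e, tie_start = _sorted_structure(surv)
    Xs = np.ascontiguousarray(Xa[order])
    if standardize:
        mu = Xs.mean(axis=0)
        sd = Xs.std(axis=0)
        sd = np.where(sd == 0, 1.0, sd)
        Xs = (Xs - mu) / sd
    else:
        sd = np.ones(Xs.shape[1])
    return Xs, e, tie_start, names, sd


def make_lambda_path(X, surv: SurvivalData, config: LassoConfig) -> np.ndarray:
    """glmnet-style geometric grid from the smallest lambda killing every
    coefficient down to lambda_min_ratio times that value, honoring the sign
    constraint when computing entry gradients."""
    if config.lambda_path is not None:
        return config.lambda_path
    Xs, e, tie_start, _, _ = _prepare(X, surv, config.standardize)
    n = Xs.shape[0]
    _, grad, _ = _breslow_ll_grad_w(np.zeros(n), e, tie_start)
    g = -(Xs.T @ grad) / n  # gradient of (1/n) * negative loglik at 0
    if config.sign == "nonnegative":
        entry = np.maximum(0.0, -g)
    elif config.sign == "nonpositive":
        entry = np.maximum(0.0, g)
    else:
        entry = np.abs(g)
    lam_max = float(entry.max())
    if lam_max <= 0:
        lam_max = 1e-3
    lam_max *= 1.000001
    return np.geomspace(lam_max, lam_max * config.lambda_min_ratio,
                        config.n_lambda)


def fit_constrained_lasso_cox(X, surv: SurvivalData, lam: float,
                              config: LassoConfig) -> CoxFit:
    """Sign-constrained L1-penalized Cox fit at a single penalty ``lam``.

    Minimizes -(1/n) * partial loglik + lam * sum_j |beta_j| subject to the
    configured orthant.  Coefficients are reported on the original covariate
    scale regardless of internal standardization.
    """
    if lam < 0 or not np.isfinite(lam):
        raise ValueError("lambda must be finite and non-negative")
    if config.ties != "breslow":
        raise NotImplementedError(
            "penalized fits support Breslow ties only; Efron is available "
            "for unpenalized fits")
    Xs, e, tie_start, names, sd = _prepare(X, surv, config.standardize)
    if surv.n_events == 0:
        raise ValueError("no events")
    p = Xs.shape[1]
    beta = np.zeros(p)
    beta, ll = _pen_cox_fit(Xs, e, tie_start, lam, _SIGN_CODE[config.sign],
                            beta, 100, config.max_iter, config.tol)
    beta_orig = beta / sd
    return CoxFit(dict(zip(names, beta_orig)), float(ll),
                  {nm: float("nan") for nm in names}, True, config.sign,
                  Xs.shape[0], surv.n_events)


def _breslow_ll_multi(etas: np.ndarray, e: np.ndarray,
                      tie_start: np.ndarray) -> np.ndarray:
    """Breslow log partial likelihood for many coefficient vectors at once;
    ``etas`` is (n, L) of linear predictors sorted by ascending time."""
    shift = etas.max(axis=0)
    ex = np.exp(etas - shift[None, :])
    grp = np.add.reduceat(ex, tie_start[:-1], axis=0)
    S = np.cumsum(grp[::-1], axis=0)[::-1]
    d = np.add.reduceat(e, tie_start[:-1])
    return (etas[e > 0].sum(axis=0)
            - d @ np.log(S) - d.sum() * shift)


def _stratified_event_folds(event: np.ndarray, n_folds: int,
                            rng: np.random.Generator) -> np.ndarray:
    """Fold assignment stratified by event status so every fold sees events."""
    n = event.shape[0]
    folds = np.empty(n, dtype=np.int64)
    for val in (1, 0):
        idx = np.flatnonzero(event == val)
        idx = rng.permutation(idx)
        folds[idx] = np.arange(idx.size) % n_folds
    return folds


def cv_lambda(X, surv: SurvivalData, config: LassoConfig) -> CVResult:
    """Select the L1 penalty by k-fold cross-validated partial-likelihood
    deviance (Verweij & van Houwelingen: fold deviance is -2 times the
    difference between the full-data and leave-fold-out log likelihoods at
    the fold-trained coefficients).  Folds are stratified by event status
    and seeded from ``config.seed``."""
    Xa, names = _as_matrix(X)
    n = Xa.shape[0]
    if config.n_folds > surv.n_events:
        raise ValueError(
            f"n_folds={config.n_folds} exceeds event count {surv.n_events}")
    lambdas = make_lambda_path(Xa, surv, config)
    rng = np.random.default_rng(config.seed)
    folds = _stratified_event_folds(surv.event, config.n_folds, rng)
    sign_code = _SIGN_CODE[config.sign]

    order_full, e_full, ts_full = _sorted_structure(surv)
    X_full_sorted = Xa[order_full]
    dev = np.zeros((config.n_folds, len(lambdas)))
    for k in range(config.n_folds):
        tr = folds != k
        surv_tr = surv.subset(tr)
        if surv_tr.n_events == 0:
            raise ValueError("training fold with zero events")
        Xs_tr, e_tr, ts_tr, _, sd_tr = _prepare(Xa[tr], surv_tr,
                                                config.standardize)
        betas = _pen_cox_path(Xs_tr, e_tr, ts_tr, lambdas, sign_code, 100,
                              config.max_iter, config.tol)
        betas_orig = betas / sd_tr[None, :]
        ll_full = _breslow_ll_multi(X_full_sorted @ betas_orig.T, e_full,
                                    ts_full)
        order_tr, e_tr_s, ts_tr_s = _sorted_structure(surv_tr)
        ll_tr = _breslow_ll_multi(Xa[tr][order_tr] @ betas_orig.T, e_tr_s,
                                  ts_tr_s)
        dev[k] = -2.0 * (ll_full - ll_tr)
    mean_dev = dev.mean(axis=0)
    se_dev = dev.std(axis=0, ddof=1) / np.sqrt(config.n_folds)
    i_min = int(np.argmin(mean_dev))
    lam_min = float(lambdas[i_min])
    # largest lambda within one SE of the minimum
    ok = mean_dev <= mean_dev[i_min] + se_dev[i_min]
    lam_1se = float(lambdas[np.flatnonzero(ok)[0]])
    return CVResult(lambdas, mean_dev, se_dev, lam_min, lam_1se, config.seed)


def select_lambda(X, surv: SurvivalData, config: LassoConfig) -> float:
    cv = cv_lambda(X, surv, config)
    return cv.lambda_1se if config.use_1se else cv.lambda_min


# ---------------------------------------------------------------------------
# Kaplan-Meier, log-rank, hazard ratio
# ---------------------------------------------------------------------------


def km_estimate(surv: SurvivalData, group=None) -> Dict[object, pd.DataFrame]:
    """Product-limit survival curves per group.

    Returns a mapping group label -> DataFrame(time, n_at_risk, n_events,
    survival) including the S(0)=1 anchor row.
    """
    if group is None:
        group = np.zeros(len(surv), dtype=int)
    group = np.asarray(group)
    out: Dict[object, pd.DataFrame] = {}
    for lab in pd.unique(group):
        m = group == lab
        if m.sum() == 0:
            raise ValueError(f"empty group {lab!r}")
        t, e = surv.time[m], surv.event[m]
        order = np.argsort(t, kind="stable")
        t, e = t[order], e[order]
        times = np.unique(t[e == 1])
        rows = [(0.0, int(m.sum()), 0, 1.0)]
        s = 1.0
        for tt in times:
            at_risk = int((t >= tt).sum())
            d = int(((t == tt) & (e == 1)).sum())
            s *= 1.0 - d / at_risk
            rows.append((float(tt), at_risk, d, s))
        out[lab] = pd.DataFrame(rows, columns=["time", "n_at_risk",
                                               "n_events", "survival"])
    return out


def logrank_test(surv: SurvivalData, group, sided: Literal["two", "one"] = "two",
                 direction=None) -> Tuple[float, float]:
    """Log-rank test between exactly two groups.

    Returns (statistic, p).  For ``sided="two"`` the statistic is the usual
    (O-E)^2/V chi-square on 1 df.  For ``sided="one"``, ``direction`` names
    the group hypothesized to be at *higher* risk (more events than
    expected); the statistic is the signed z for that group and
    p = Phi(-z), so an observed effect opposing the declared direction gives
    p >= 0.5.  The direction is a required explicit argument, never inferred
    from the data.
    """
    group = np.asarray(group)
    labs = pd.unique(group)
    if len(labs) != 2:
        raise ValueError(f"exactly 2 groups required, got {len(labs)}")
    for lab in labs:
        if (group == lab).sum() == 0:
            raise ValueError(f"empty group {lab!r}")
    if sided == "one":
        if direction is None:
            raise ValueError("one-sided test requires an explicit direction")
        if direction not in labs:
            raise ValueError(f"direction {direction!r} is not a group label")
        ref = direction
    else:
        ref = labs[0]
    in_ref = group == ref
    t, e = surv.time, surv.event
    times = np.unique(t[e == 1])
    O = E = V = 0.0
    for tt in times:
        at = t >= tt
        nj = at.sum()
        n1 = (at & in_ref).sum()
        dj = ((t == tt) & (e == 1)).sum()
        d1 = ((t == tt) & (e == 1) & in_ref).sum()
        O += d1
        E += dj * n1 / nj
        if nj > 1:
            V += dj * (n1 / nj) * (1 - n1 / nj) * (nj - dj) / (nj - 1)
    if V <= 0:
        return (0.0, 1.0)
    z = (O - E) / np.sqrt(V)
    if sided == "two":
        chi2 = z * z
        return (float(chi2), float(stats.chi2.sf(chi2, 1)))
    return (float(z), float(stats.norm.sf(z)))


def hazard_ratio(surv: SurvivalData, group_or_score,
                 ties: Ties = "breslow") -> Tuple[float, Tuple[float, float], float, bool]:
    """Univariable Cox hazard ratio.

    ``group_or_score`` is either a binary group vector (encoded 0/1 by sorted
    label; HR is for the second label vs the first) or a continuous score
    (HR per unit).  Returns (HR, (lo, hi), Wald p, stable) where ``stable``
    is False when a binary group has no events or the fit did not converge.
    """
    x = np.asarray(group_or_score)
    labs = pd.unique(x)
    stable = True
    if len(labs) == 2:
        labs_sorted = np.sort(labs)
        xv = (x == labs_sorted[1]).astype(float)
        for lv in (0.0, 1.0):
            if surv.event[xv == lv].sum() == 0:
                stable = False
    else:
        xv = x.astype(float)
    fit = fit_cox(xv[:, None], surv, ties=ties)
    b = fit.beta[0]
    se = list(fit.se.values())[0]
    hr = float(np.exp(b))
    ci = (float(np.exp(b - 1.96 * se)), float(np.exp(b + 1.96 * se)))
    p = float(2 * stats.norm.sf(abs(b) / se)) if se > 0 else float("nan")
    return hr, ci, p, stable and fit.converged
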