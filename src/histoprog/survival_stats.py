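"""Survival and comparison statistics.

Self-contained implementations of the estimators used throughout the
pipeline: Harrell's concordance index, Kaplan-Meier curves with the
log-rank test, Cox proportional-hazards regression (Newton-Raphson on
the Breslow partial likelihood), median risk-group stratification, and
the Mann-Whitney U test with exact small-sample p-values.

Conventions (used consistently across the package):

* Tied event times are handled with the Breslow approximation.
* All p-values are two-sided; the working significance level is 0.05.
* Censoring indicators are 1 for an observed event, 0 for censoring.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import stats as sps

__all__ = [
    "SurvivalData",
    "CoxFit",
    "KMCurve",
    "harrell_c",
    "km_curve",
    "logrank",
    "cox_fit",
    "median_split",
    "mann_whitney",
]


# ---------------------------------------------------------------------------
# Containers
# ---------------------------------------------------------------------------

@dataclass
class SurvivalData:
    """Right-censored survival outcomes.

    Parameters
    ----------
    times : array-like
        Positive follow-up times (months).
    events : array-like
        Event indicators, 1 = death observed, 0 = censored.
    """

    times: np.ndarray
    events: np.ndarray

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.events = np.asarray(self.events, dtype=int)
        if self.times.shape != self.events.shape:
            raise ValueError("times and events must have equal length")
        if self.times.ndim != 1:
            raise ValueError("times must be one-dimensional")
        if np.any(~np.isfinite(self.times)) or np.any(self.times <= 0):
            raise ValueError("times must be finite and > 0")
        if not np.all(np.isin(self.events, (0, 1))):
            raise ValueError("events must be 0/1")

    def __len__(self) -> int:
        return self.times.size


@dataclass
class CoxFit:
    """Result of a Cox proportional-hazards fit."""

    beta: np.ndarray
    se: np.ndarray
    hr: np.ndarray
    ci95: np.ndarray  # (p, 2) array of (low, high)
    wald_p: np.ndarray
    converged: bool
    n_iter: int
    loglik: float = float("nan")
    names: list = field(default_factory=list)


@dataclass
class KMCurve:
    """Product-limit survival curve."""

    times: np.ndarray
    survival: np.ndarray
    at_risk: np.ndarray


# ---------------------------------------------------------------------------
# Harrell's C
# ---------------------------------------------------------------------------

def harrell_c(surv: SurvivalData, scores) -> float:
    """Harrell's concordance index of a risk score against survival.

    A pair (i, j) is usable when ``times[i] < times[j]`` and subject i had
    an event; it is concordant when the shorter-lived subject has the
    higher score. Tied scores count 0.5.

    Returns C in [0, 1]; 0.5 is chance level.
    """
    scores = np.asarray(scores, dtype=float)
    if scores.shape != surv.times.shape:
        raise ValueError("scores length must match survival data")
    t, e, s = surv.times, surv.events, scores
    # Vectorized pair scan: usable (i, j) with t_i < t_j and e_i = 1.
    dt = t[:, None] < t[None, :]
    usable = dt & (e[:, None] == 1)
    n_usable = int(usable.sum())
    if n_usable == 0:
        raise ValueError("no usable pairs: concordance undefined")
    ds = s[:, None] - s[None, :]
    concordant = int((usable & (ds > 0)).sum())
    tied = int((usable & (ds == 0)).sum())
    return (concordant + 0.5 * tied) / n_usable


# ---------------------------------------------------------------------------
# Kaplan-Meier and log-rank
# ---------------------------------------------------------------------------

def km_curve(surv: SurvivalData) -> KMCurve:
    """Product-limit estimator of the survival function.

    Survival probabilities are reported at distinct event times; the
    curve starts at S(0) = 1 (prepended at time 0).
    """
    if len(surv) == 0:
        raise ValueError("empty survival data")
    order = np.argsort(surv.times, kind="stable")
    t, e = surv.times[order], surv.events[order]
    event_times = np.unique(t[e == 1])
    n = len(t)
    times_out = [0.0]
    surv_out = [1.0]
    at_risk_out = [n]
    s = 1.0
    for et in event_times:
        at_risk = int(np.sum(t >= et))
        d = int(np.sum((t == et) & (e == 1)))
        s *= 1.0 - d / at_risk
        times_out.append(float(et))
        surv_out.append(s)
        at_risk_out.append(at_risk)
    return KMCurve(np.array(times_out), np.array(surv_out), np.array(at_risk_out))


def logrank(surv_a: SurvivalData, surv_b: SurvivalData) -> tuple[float, float]:
    """Two-group log-rank test (1 df).

    Observed-minus-expected events in group A summed over distinct event
    times, with the hypergeometric variance. Returns (chi2, p).
    """
    if len(surv_a) == 0 and len(surv_b) == 0:
        raise ValueError("both groups empty")
    if len(surv_a) == 0 or len(surv_b) == 0:
        raise ValueError("each group needs at least one subject")
    t = np.concatenate([surv_a.times, surv_b.times])
    e = np.concatenate([surv_a.events, surv_b.events])
    g = np.concatenate([np.zeros(len(surv_a), int), np.ones(len(surv_b), int)])
    event_times = np.unique(t[e == 1])
    o_minus_e = 0.0
    var = 0.0
    for et in event_times:
        at_risk = t >= et
        n_tot = int(at_risk.sum())
        n_a = int((at_risk & (g == 0)).sum())
        d_tot = int(((t == et) & (e == 1)).sum())
        d_a = int(((t == et) & (e == 1) & (g == 0)).sum())
        if n_tot < 2:
            continue
        expected_a = d_tot * n_a / n_tot
        o_minus_e += d_a - expected_a
        var += (d_tot * (n_a / n_tot) * (1 - n_a / n_tot)
                * (n_tot - d_tot) / (n_tot - 1))
    if var <= 0:
        return 0.0, 1.0
    chi2 = o_minus_e ** 2 / var
    p = float(sps.chi2.sf(chi2, df=1))
    return float(chi2), p


# ---------------------------------------------------------------------------
# Cox regression
# ---------------------------------------------------------------------------

def _cox_loglik_grad_hess(beta, X, t, e):
    """Breslow log partial likelihood, gradient and observed information.

    Risk sets computed over subjects with time >= each event time; tied
    event times share one denominator (Breslow).
    """
    eta = X @ beta
    # guard against overflow during Newton steps
    eta = np.clip(eta, -500, 500)
    w = np.exp(eta)
    order = np.argsort(-t, kind="stable")  # decreasing time
    Xo, to, eo, wo = X[order], t[order], e[order], w[order]
    p = X.shape[1]
    ll = 0.0
    grad = np.zeros(p)
    info = np.zeros((p, p))
    # cumulative sums over the risk set, built from longest time down
    s0 = 0.0
    s1 = np.zeros(p)
    s2 = np.zeros((p, p))
    i = 0
    n = len(to)
    while i < n:
        # all subjects tied at this time enter the risk set together
        j = i
        while j < n and to[j] == to[i]:
            s0 += wo[j]
            s1 += wo[j] * Xo[j]
            s2 += wo[j] * np.outer(Xo[j], Xo[j])
            j += 1
        for k in range(i, j):
            if eo[k] == 1:
                xb = Xo[k] @ beta
                ll += xb - np.log(s0)
                mean = s1 / s0
                grad += Xo[k] - mean
                info += s2 / s0 - np.outer(mean, mean)
        i = j
    return ll, grad, info


def cox_fit(X, surv: SurvivalData, names=None, max_iter: int = 50,
            tol: float = 1e-8) -> CoxFit:
    """Cox proportional-hazards regression via Newton-Raphson.

    Breslow handling of ties; convergence when the max absolute score
    component drops below ``tol`` or after ``max_iter`` iterations.
    Standard errors come from the inverse observed information.
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    if X.shape[0] != len(surv):
        X = X.T
    if X.shape[0] != len(surv):
        raise ValueError("covariate matrix does not match survival data")
    n, p = X.shape
    if np.any(np.ptp(X, axis=0) == 0):
        raise ValueError("constant covariate: Cox model unidentifiable")
    if int(surv.events.sum()) < p:
        raise ValueError("fewer events than covariates")
    beta = np.zeros(p)
    converged = False
    n_iter = 0
    ll = -np.inf
    for n_iter in range(1, max_iter + 1):
        ll, grad, info = _cox_loglik_grad_hess(beta, X, surv.times, surv.events)
        if np.max(np.abs(grad)) < tol:
            converged = True
            break
        try:
            step = np.linalg.solve(info, grad)
        except np.linalg.LinAlgError:
            step = np.linalg.lstsq(info, grad, rcond=None)[0]
        # step-halving to keep the likelihood finite
        for _ in range(30):
            cand = beta + step
            ll_new = _cox_loglik_grad_hess(cand, X, surv.times, surv.events)[0]
            if np.isfinite(ll_new) and ll_new >= ll - 1e-12:
                break
            step = step / 2.0
        beta = beta + step
        if np.max(np.abs(step)) < 1e-10:  # stalled at machine precision
            converged = True
            break
    else:
        warnings.warn("cox_fit did not converge; partial results returned")
    if np.any(np.abs(beta) > 15):
        warnings.warn("possible separation: |beta| > 15")
    _, _, info = _cox_loglik_grad_hess(beta, X, surv.times, surv.events)
    try:
        cov = np.linalg.inv(info)
        se = np.sqrt(np.clip(np.diag(cov), 0, None))
    except np.linalg.LinAlgError:
        se = np.full(p, np.nan)
    hr = np.exp(beta)
    ci = np.column_stack([np.exp(beta - 1.96 * se), np.exp(beta + 1.96 * se)])
    with np.errstate(divide="ignore", invalid="ignore"):
        z = np.where(se > 0, beta / se, np.inf * np.sign(beta))
    wald_p = 2 * sps.norm.sf(np.abs(z))
    return CoxFit(beta=beta, se=se, hr=hr, ci95=ci, wald_p=wald_p,
                  converged=converged, n_iter=n_iter, loglik=float(ll),
                  names=list(names) if names is not None else
                  [f"x{i}" for i in range(p)])


# ---------------------------------------------------------------------------
# Median split
# ---------------------------------------------------------------------------

def median_split(scores) -> np.ndarray:
    """Stratify subjects into high/low risk groups at the median.

    Returns an integer array, 1 = high (strictly above the median),
    0 = low. Scores exactly equal to the median go to the low group, so
    group sizes differ by at most the number of median ties.
    """
    scores = np.asarray(scores, dtype=float)
    if scores.size < 2:
        raise ValueError("need at least 2 subjects to stratify")
    med = np.median(scores)
    labels = (scores > med).astype(int)
    if labels.sum() == 0:
        warnings.warn("all scores at or below the median; high group empty")
    return labels


# ---------------------------------------------------------------------------
# Mann-Whitney U
# ---------------------------------------------------------------------------

def _rank_sum_u(x: np.ndarray, y: np.ndarray) -> float:
    pooled = np.concatenate([x, y])
    ranks = sps.rankdata(pooled)
    r_x = ranks[: len(x)].sum()
    return r_x - len(x) * (len(x) + 1) / 2.0


def mann_whitney(x, y, exact_max_n: int = 20) -> tuple[float, float]:
    """Mann-Whitney U test, two-sided.

    U is the rank-sum statistic for ``x``. For small samples
    (``n + m <= exact_max_n``) the p-value is computed by full
    enumeration of group assignments of the pooled sample (valid under
    ties); otherwise the tie-corrected normal approximation is used.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("both samples must be non-empty")
    n, m = x.size, y.size
    u_obs = _rank_sum_u(x, y)
    mu = n * m / 2.0
    if n + m <= exact_max_n:
        pooled = np.concatenate([x, y])
        ranks = sps.rankdata(pooled)
        total = 0
        extreme = 0
        offset = n * (n + 1) / 2.0
        dev_obs = abs(u_obs - mu)
        for idx in itertools.combinations(range(n + m), n):
            u = ranks[list(idx)].sum() - offset
            total += 1
            if abs(u - mu) >= dev_obs - 1e-12:
                extreme += 1
        p = extreme / total
        return float(u_obs), float(min(1.0, p))
    # normal approximation with tie correction
    pooled = np.concatenate([x, y])
    _, counts = np.unique(pooled, return_counts=True)
    nm = n + m
    tie_term = np.sum(counts ** 3 - counts) / (nm * (nm - 1))
    sigma2 = n * m / 12.0 * (nm + 1 - tie_term)
    if sigma2 <= 0:
        return float(u_obs), 1.0
    z = (u_obs - mu - 0.5 * np.sign(u_obs - mu)) / np.sqrt(sigma2)
    p = float(2 * sps.norm.sf(abs(z)))
    return float(u_obs), min(1.0, p)
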