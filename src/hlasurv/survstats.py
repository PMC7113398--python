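"""Core survival statistics.

Kaplan-Meier product-limit estimation, the two-group log-rank test, Cox
proportional-hazards fitting by Newton-Raphson on the partial
likelihood (Efron tie correction by default, Breslow by flag), hazard
ratios for binary stratifications, and the two-sample mean test used by
the superallele screen.

The Cox fitter maximizes the partial likelihood

    l(beta) = sum_k [ s_k' beta - sum_{l=0}^{d_k-1} log(S0_k - (l/d_k) s0_k) ]

over distinct event times k with d_k tied deaths, risk-set sums S0/S1/S2
of exp(eta) and its covariate moments, and death-set sums s0/s1/s2 (the
(l/d_k) terms vanish under Breslow).  Convergence: max |score| < 1e-9 or
relative log-likelihood change < 1e-10, at most 100 iterations, with
step-halving.  Monotone likelihood (perfect separation) and constant
covariates raise explicit errors naming the covariate.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import stats

__all__ = [
    "KMCurve",
    "CoxFit",
    "GroupHR",
    "ConvergenceError",
    "km_estimate",
    "logrank_test",
    "fit_cox",
    "cox_score_chi2",
    "group_hazard_ratio",
    "welch_t_test",
]

_Z95 = 1.96  # normal multiplier for the 95% CI, as reported throughout


class ConvergenceError(RuntimeError):
    """Cox partial-likelihood maximization failed to converge."""


# ---------------------------------------------------------------------------
# Kaplan-Meier


@dataclass
class KMCurve:
    """Product-limit survival curve.

    ``event_times`` are the distinct times with at least one death;
    ``survival`` is S(t) just after each; ``at_risk`` the risk-set size
    just before each.  S(0) = 1 by construction.
    """

    event_times: np.ndarray
    survival: np.ndarray
    at_risk: np.ndarray
    n_events: np.ndarray

    def survival_at(self, t: float) -> float:
        """Right-continuous step-function value S(t)."""
        idx = np.searchsorted(self.event_times, t, side="right") - 1
        if idx < 0:
            return 1.0
        return float(self.survival[idx])

    def to_table(self):
        import pandas as pd

        return pd.DataFrame(
            {
                "time": self.event_times,
                "survival": self.survival,
                "at_risk": self.at_risk,
                "n_events": self.n_events,
            }
        )


def km_estimate(time: Sequence[float], event: Sequence[int]) -> KMCurve:
    """Kaplan-Meier estimate; censored times shrink risk sets without steps."""
    t = np.asarray(time, dtype=float)
    e = np.asarray(event, dtype=int)
    if t.size == 0:
        raise ValueError("km_estimate needs at least one sample")
    if np.any(~np.isfinite(t)) or np.any(t < 0):
        raise ValueError("times must be finite and non-negative")
    order = np.argsort(t, kind="mergesort")
    t, e = t[order], e[order]
    uniq = np.unique(t[e == 1])
    surv = []
    at_risk = []
    d_out = []
    s = 1.0
    for u in uniq:
        n_risk = int(np.sum(t >= u))
        d = int(np.sum((t == u) & (e == 1)))
        s *= 1.0 - d / n_risk
        surv.append(s)
        at_risk.append(n_risk)
        d_out.append(d)
    return KMCurve(
        event_times=uniq,
        survival=np.asarray(surv),
        at_risk=np.asarray(at_risk, dtype=int),
        n_events=np.asarray(d_out, dtype=int),
    )


# ---------------------------------------------------------------------------
# Log-rank


@dataclass
class LogrankResult:
    chi2: float
    p: float


def logrank_test(
    time: Sequence[float], event: Sequence[int], group: Sequence[int]
) -> LogrankResult:
    """Two-group log-rank test.

    At each distinct event time the observed deaths in group 1 are
    compared with their hypergeometric expectation given the pooled
    risk set; the squared sum over times, scaled by the summed
    variance, is chi-square with 1 df.  Zero total variance (e.g. no
    events) yields p = 1 with a warning.
    """
    t = np.asarray(time, dtype=float)
    e = np.asarray(event, dtype=int)
    g = np.asarray(group, dtype=int)
    if not (set(np.unique(g)) <= {0, 1}):
        raise ValueError("group labels must be binary 0/1")
    if np.sum(g == 1) == 0 or np.sum(g == 0) == 0:
        raise ValueError("both groups must be non-empty")
    o_minus_e = 0.0
    var = 0.0
    for u in np.unique(t[e == 1]):
        at_risk = t >= u
        n = int(at_risk.sum())
        n1 = int((at_risk & (g == 1)).sum())
        dying = (t == u) & (e == 1)
        d = int(dying.sum())
        d1 = int((dying & (g == 1)).sum())
        o_minus_e += d1 - d * n1 / n
        if n > 1:
            var += d * (n1 / n) * (1 - n1 / n) * (n - d) / (n - 1)
    if var <= 0:
        warnings.warn("log-rank variance is zero; returning p = 1", stacklevel=2)
        return LogrankResult(chi2=0.0, p=1.0)
    chi2 = o_minus_e**2 / var
    return LogrankResult(chi2=float(chi2), p=float(stats.chi2.sf(chi2, df=1)))


# ---------------------------------------------------------------------------
# Cox proportional hazards


@dataclass
class CoxFit:
    names: list[str]
    coef: np.ndarray
    se: np.ndarray
    loglik: float
    n: int
    n_events: int
    ties: str
    separated: bool = False  # monotone likelihood detected (beta drifting)

    @property
    def hr(self) -> np.ndarray:
        return np.exp(self.coef)

    @property
    def ci95(self) -> np.ndarray:
        lo = np.exp(np.clip(self.coef - _Z95 * self.se, -700, 700))
        hi = np.exp(np.clip(self.coef + _Z95 * self.se, -700, 700))
        return np.column_stack([lo, hi])

    @property
    def wald_p(self) -> np.ndarray:
        z = self.coef / self.se
        return 2 * stats.norm.sf(np.abs(z))


def _cox_groups(t: np.ndarray, e: np.ndarray):
    """Indices of tied-death groups and risk-set start positions (t sorted asc)."""
    groups = []
    uniq = np.unique(t[e == 1])
    for u in uniq:
        start = int(np.searchsorted(t, u, side="left"))
        death_idx = np.flatnonzero((t == u) & (e == 1))
        groups.append((start, death_idx))
    return groups


def _cox_loglik_grad_hess(beta, X, groups, ties):
    n, p = X.shape
    eta = X @ beta
    shift = eta.max()
    w = np.exp(eta - shift)  # common shift cancels in all ratios and in l(beta)
    wX = w[:, None] * X
    wXX = np.einsum("i,ij,ik->ijk", w, X, X)
    # suffix sums: risk set at sorted position s is rows s..n-1
    S0 = np.cumsum(w[::-1])[::-1]
    S1 = np.cumsum(wX[::-1], axis=0)[::-1]
    S2 = np.cumsum(wXX[::-1], axis=0)[::-1]
    ll = 0.0
    grad = np.zeros(p)
    hess = np.zeros((p, p))
    for start, death_idx in groups:
        d = len(death_idx)
        sx = X[death_idx].sum(axis=0)
        ll += float(eta[death_idx].sum() - d * shift)
        if ties == "efron" and d > 1:
            s0d = w[death_idx].sum()
            s1d = wX[death_idx].sum(axis=0)
            s2d = wXX[death_idx].sum(axis=0)
            frac = np.arange(d) / d
            denom = S0[start] - frac * s0d                     # (d,)
            num1 = S1[start][None, :] - frac[:, None] * s1d    # (d, p)
            num2 = S2[start][None, :, :] - frac[:, None, None] * s2d
            ll += float(-np.log(denom).sum())
            m = num1 / denom[:, None]
            grad += sx - m.sum(axis=0)
            hess += (num2 / denom[:, None, None]).sum(axis=0) - np.einsum("lj,lk->jk", m, m)
        else:  # Breslow, or untied group (corrections coincide)
            denom = S0[start]
            ll += float(-d * np.log(denom))
            m = S1[start] / denom
            grad += sx - d * m
            hess += d * (S2[start] / denom - np.outer(m, m))
    return ll, grad, hess


def fit_cox(
    time: Sequence[float],
    event: Sequence[int],
    X,
    names: Sequence[str] | None = None,
    ties: str = "efron",
    max_iter: int = 100,
    tol_score: float = 1e-9,
    tol_loglik: float = 1e-10,
    on_separation: str = "raise",
) -> CoxFit:
    """Fit a Cox proportional-hazards model by Newton-Raphson.

    Parameters
    ----------
    time, event
        Follow-up in months and event indicator (1 = death).
    X
        Covariate matrix (n x p).  Constant columns are rejected.
    ties
        ``"efron"`` (default) or ``"breslow"`` tie correction; they
        coincide on tie-free data.
    on_separation
        A monotone partial likelihood (some |beta| drifting beyond 15,
        i.e. perfect separation) raises :class:`ConvergenceError`
        naming the covariate (default) or, with ``"return"``, yields
        the flagged fit — the coefficient is then effectively a lower
        bound with an uninformative CI.
    """
    t = np.asarray(time, dtype=float)
    e = np.asarray(event, dtype=int)
    X = np.asarray(X, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    n, p = X.shape
    if names is None:
        names = [f"x{j}" for j in range(p)]
    names = list(names)
    if ties not in ("efron", "breslow"):
        raise ValueError(f"unknown tie correction {ties!r}")
    if on_separation not in ("raise", "return"):
        raise ValueError(f"unknown separation policy {on_separation!r}")
    if t.shape[0] != n or e.shape[0] != n:
        raise ValueError("time, event and X must share their first dimension")
    if e.sum() < 1:
        raise ValueError("at least one event is required")
    ptp = X.max(axis=0) - X.min(axis=0)
    if np.any(ptp == 0):
        bad = names[int(np.argmax(ptp == 0))]
        raise ValueError(f"covariate {bad!r} is constant")

    order = np.argsort(t, kind="mergesort")
    t, e, X = t[order], e[order], X[order]
    groups = _cox_groups(t, e)

    # center covariates for numerical stability; beta is unaffected
    mu = X.mean(axis=0)
    Xc = X - mu

    beta = np.zeros(p)
    ll, grad, hess = _cox_loglik_grad_hess(beta, Xc, groups, ties)
    converged = False
    separated = False
    for _ in range(max_iter):
        try:
            delta = np.linalg.solve(hess, grad)
        except np.linalg.LinAlgError as exc:
            raise ConvergenceError(f"singular information matrix: {exc}") from exc
        step = 1.0
        while True:
            beta_new = beta + step * delta
            ll_new, grad_new, hess_new = _cox_loglik_grad_hess(beta_new, Xc, groups, ties)
            if np.isfinite(ll_new) and (ll_new >= ll or step <= 1 / 1024):
                break
            step /= 2
        rel_change = abs(ll_new - ll) / max(abs(ll), 1.0)
        beta, grad, hess = beta_new, grad_new, hess_new
        ll = ll_new
        if not separated and np.any(np.abs(beta) > 15):
            separated = True
            if on_separation == "raise":
                bad = names[int(np.argmax(np.abs(beta)))]
                raise ConvergenceError(
                    f"monotone likelihood: covariate {bad!r} separates events perfectly"
                )
        if np.max(np.abs(grad)) < tol_score or rel_change < tol_loglik:
            converged = True
            break
    if not converged:
        bad = names[int(np.argmax(np.abs(grad)))]
        raise ConvergenceError(
            f"no convergence in {max_iter} iterations (largest score on {bad!r})"
        )
    cov = np.linalg.inv(hess)
    se = np.sqrt(np.diag(cov))
    return CoxFit(
        names=names,
        coef=beta,
        se=se,
        loglik=float(ll),
        n=n,
        n_events=int(e.sum()),
        ties=ties,
        separated=separated,
    )


def cox_score_chi2(time, event, x, ties: str = "breslow") -> float:
    """Cox score-test statistic at beta = 0 (one covariate or several).

    For a single binary covariate on tie-free data this equals the
    log-rank chi-square exactly.
    """
    t = np.asarray(time, dtype=float)
    e = np.asarray(event, dtype=int)
    X = np.asarray(x, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    order = np.argsort(t, kind="mergesort")
    t, e, X = t[order], e[order], X[order]
    groups = _cox_groups(t, e)
    Xc = X - X.mean(axis=0)
    _, grad, hess = _cox_loglik_grad_hess(np.zeros(X.shape[1]), Xc, groups, ties)
    return float(grad @ np.linalg.solve(hess, grad))


# ---------------------------------------------------------------------------
# Group hazard ratio


@dataclass
class GroupHR:
    """Hazard ratio of a binary stratification, oriented high vs low.

    hr > 1 means the designated high-risk group dies faster.  ``p`` is
    the log-rank p-value; the Wald p of the Cox coefficient is kept as
    ``wald_p``.
    """

    hr: float
    ci95: tuple[float, float]
    p: float
    n_high: int
    n_low: int
    wald_p: float
    separated: bool = False  # monotone likelihood: hr is a runaway bound

    def inverted(self) -> "GroupHR":
        lo, hi = self.ci95
        return GroupHR(
            hr=1 / self.hr,
            ci95=(1 / hi, 1 / lo),
            p=self.p,
            n_high=self.n_low,
            n_low=self.n_high,
            wald_p=self.wald_p,
            separated=self.separated,
        )


def group_hazard_ratio(
    time, event, high_mask, ties: str = "efron", on_separation: str = "raise"
) -> GroupHR:
    """Cox HR (with 95% CI) and log-rank p for a high-vs-low split."""
    high = np.asarray(high_mask, dtype=bool)
    n_high = int(high.sum())
    n_low = int((~high).sum())
    if n_high == 0 or n_low == 0:
        raise ValueError("both groups must be non-empty")
    fit = fit_cox(
        time, event, high.astype(float), names=["high_risk"], ties=ties,
        on_separation=on_separation,
    )
    lr = logrank_test(time, event, high.astype(int))
    return GroupHR(
        hr=float(fit.hr[0]),
        ci95=(float(fit.ci95[0, 0]), float(fit.ci95[0, 1])),
        p=lr.p,
        n_high=n_high,
        n_low=n_low,
        wald_p=float(fit.wald_p[0]),
        separated=fit.separated,
    )


# ---------------------------------------------------------------------------
# Two-sample mean test (screening)


@dataclass
class TTestResult:
    t: float
    df: float
    p: float


def welch_t_test(x, y, equal_var: bool = False) -> TTestResult:
    """Two-sided two-sample t-test, unequal-variance (Welch) by default."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size < 2 or y.size < 2:
        raise ValueError("both samples need at least two observations")
    vx, vy = x.var(ddof=1), y.var(ddof=1)
    if vx == 0 and vy == 0:
        raise ValueError("both samples are constant; t-test undefined")
    res = stats.ttest_ind(x, y, equal_var=equal_var)
    if equal_var:
        df = x.size + y.size - 2
    else:
        a, b = vx / x.size, vy / y.size
        df = (a + b) ** 2 / (a**2 / (x.size - 1) + b**2 / (y.size - 1))
    return TTestResult(t=float(res.statistic), df=float(df), p=float(res.pvalue))
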