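"""Survival and contingency statistics for validating risk stratification.

Group comparisons: Pearson chi-square (Yates continuity correction for 2x2
tables only), Fisher's exact test, and the Mann-Whitney U test. Survival:
Kaplan-Meier curves, the log-rank test, and Cox proportional-hazards
regression (unpenalized Newton-Raphson with Breslow tie handling — the same
convention as the training loss — and an L1-penalized proximal-gradient
variant for small-event-count cohorts).

All-zero rows/columns (empty categories) are dropped before chi-square
testing: expected counts of zero make the statistic undefined.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import List, Optional, Sequence, Tuple

import numpy as np
from scipy import stats as sps
from lifelines import KaplanMeierFitter
from lifelines.statistics import logrank_test as _ll_logrank

COEF_CAP = 20.0  # |coef| cap flagging monotone likelihood (perfect separation)


# ---------------------------------------------------------------------------
# contingency tables
# ---------------------------------------------------------------------------

@dataclass
class ContingencyTable:
    counts: np.ndarray
    rows: Sequence[str] = ()
    cols: Sequence[str] = ()

    def __post_init__(self):
        self.counts = np.asarray(self.counts, dtype=int)
        if self.counts.ndim != 2 or self.counts.sum() <= 0:
            raise ValueError("contingency table must be 2-D with positive total")
        if (self.counts < 0).any():
            raise ValueError("counts must be nonnegative")


def _drop_empty(counts: np.ndarray) -> np.ndarray:
    counts = counts[counts.sum(axis=1) > 0][:, counts.sum(axis=0) > 0]
    return counts


def pearson_chi2(table: ContingencyTable, yates: bool = False
                 ) -> Tuple[float, int, float]:
    """Pearson chi-square after dropping all-zero rows/columns.

    Yates' 0.5 continuity correction applies to 2x2 tables only.
    Returns (statistic, degrees of freedom, p).
    """
    counts = _drop_empty(table.counts)
    if counts.shape[0] < 2 or counts.shape[1] < 2:
        raise ValueError("table degenerate after dropping empty categories")
    correction = yates and counts.shape == (2, 2)
    stat, p, dof, _ = sps.chi2_contingency(counts, correction=correction)
    return float(stat), int(dof), float(p)


def fisher_exact(table) -> float:
    """Two-sided Fisher's exact test for a 2x2 table."""
    counts = np.asarray(table.counts if isinstance(table, ContingencyTable) else table,
                        dtype=int)
    if counts.shape != (2, 2):
        raise ValueError("Fisher's exact test requires a 2x2 table")
    return float(sps.fisher_exact(counts, alternative="two-sided")[1])


def mann_whitney(x, y) -> Tuple[float, float]:
    """Two-sided Mann-Whitney U, normal approximation with tie and
    continuity corrections. Returns (U of the first sample, p)."""
    x, y = np.asarray(x, dtype=float), np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("both samples must be nonempty")
    if np.unique(np.concatenate([x, y])).size == 1:
        return float(x.size * y.size / 2.0), 1.0
    res = sps.mannwhitneyu(x, y, alternative="two-sided",
                           use_continuity=True, method="asymptotic")
    return float(res.statistic), float(res.pvalue)


# ---------------------------------------------------------------------------
# Kaplan-Meier and log-rank
# ---------------------------------------------------------------------------

@dataclass
class KMCurve:
    times: np.ndarray      # sorted observed times (0 prepended)
    survival: np.ndarray   # nonincreasing step values, S(0) = 1
    at_risk: np.ndarray
    events: np.ndarray

    def survival_at(self, t: float) -> float:
        idx = np.searchsorted(self.times, t, side="right") - 1
        return float(self.survival[max(idx, 0)])


def km_fit(times, events) -> KMCurve:
    """Kaplan-Meier product-limit estimate."""
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=bool)
    if times.size == 0:
        raise ValueError("need at least one subject")
    kmf = KaplanMeierFitter()
    kmf.fit(times, event_observed=events)
    grid = np.asarray(kmf.survival_function_.index, dtype=float)
    surv = kmf.survival_function_.iloc[:, 0].to_numpy()
    tbl = kmf.event_table
    return KMCurve(
        times=grid,
        survival=surv,
        at_risk=tbl["at_risk"].to_numpy(),
        events=tbl["observed"].to_numpy(),
    )


def logrank_test(times_a, events_a, times_b, events_b) -> Tuple[float, float]:
    """Two-group log-rank test; returns (chi-square statistic, p)."""
    ea = np.asarray(events_a, dtype=bool)
    eb = np.asarray(events_b, dtype=bool)
    if len(np.atleast_1d(times_a)) == 0 or len(np.atleast_1d(times_b)) == 0:
        raise ValueError("both groups must be nonempty")
    if not (ea.any() or eb.any()):
        raise ValueError("log-rank test undefined with no events")
    res = _ll_logrank(times_a, times_b, event_observed_A=ea, event_observed_B=eb)
    return float(res.test_statistic), float(res.p_value)


# ---------------------------------------------------------------------------
# Cox proportional hazards
# ---------------------------------------------------------------------------

@dataclass
class CoxFit:
    coefficients: np.ndarray
    hazard_ratios: np.ndarray
    ci_lower: Optional[np.ndarray]
    ci_upper: Optional[np.ndarray]
    p_values: Optional[np.ndarray]
    se: Optional[np.ndarray]
    converged: bool
    separation: bool = False
    penalty: float = 0.0
    log_likelihood: Optional[float] = None


def _breslow_loglik_grad_hess(beta, x, times, events):
    """Breslow partial log-likelihood with analytic gradient and Hessian."""
    eta = x @ beta
    eta = np.clip(eta, -500, 500)
    w = np.exp(eta)
    ll, grad = 0.0, np.zeros_like(beta)
    hess = np.zeros((len(beta), len(beta)))
    ev_times = np.unique(times[events])
    for t in ev_times:
        in_risk = times >= t
        d_idx = events & (times == t)
        d = int(d_idx.sum())
        s0 = w[in_risk].sum()
        s1 = w[in_risk] @ x[in_risk]
        s2 = (w[in_risk, None] * x[in_risk]).T @ x[in_risk]
        xbar = s1 / s0
        ll += eta[d_idx].sum() - d * np.log(s0)
        grad += x[d_idx].sum(axis=0) - d * xbar
        hess -= d * (s2 / s0 - np.outer(xbar, xbar))
    return ll, grad, hess


def cox_fit(times, events, covariates, l1_penalty: float = 0.0,
            tol: float = 1e-8, max_iter: int = 100) -> CoxFit:
    """Cox PH regression (Breslow ties).

    Unpenalized: Newton-Raphson with Wald SEs from the inverse observed
    information; hazard ratios and 95% CIs per covariate. Non-convergence or
    monotone likelihood (coefficients running away; capped at +/-20) is
    flagged on the result rather than raised.

    `l1_penalty > 0`: proximal-gradient (ISTA) fit of the lasso-penalized
    partial likelihood; no standard errors are reported.
    """
    x = np.atleast_2d(np.asarray(covariates, dtype=float))
    if x.shape[0] != len(np.asarray(times)):
        x = x.T
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=bool)
    if not events.any():
        raise ValueError("Cox fit requires at least one event")
    n, p = x.shape
    if l1_penalty == 0.0:
        if np.any(x.std(axis=0) == 0):
            raise ValueError("constant covariate in unpenalized Cox fit")

    if l1_penalty > 0.0:
        beta = _cox_lasso(x, times, events, l1_penalty)
        ll = _breslow_loglik_grad_hess(beta, x, times, events)[0]
        return CoxFit(
            coefficients=beta, hazard_ratios=np.exp(beta),
            ci_lower=None, ci_upper=None, p_values=None, se=None,
            converged=True, penalty=l1_penalty, log_likelihood=ll,
        )

    beta = np.zeros(p)
    converged = separation = False
    for _ in range(max_iter):
        ll, grad, hess = _breslow_loglik_grad_hess(beta, x, times, events)
        try:
            step = np.linalg.solve(hess, grad)
        except np.linalg.LinAlgError:
            separation = True
            break
        new_beta = beta - step
        if np.any(np.abs(new_beta) > COEF_CAP):
            separation = True
            beta = np.clip(new_beta, -COEF_CAP, COEF_CAP)
            break
        if np.max(np.abs(new_beta - beta)) < tol:
            beta = new_beta
            converged = True
            break
        beta = new_beta
    ll, grad, hess = _breslow_loglik_grad_hess(beta, x, times, events)
    info = -hess
    try:
        cov = np.linalg.inv(info)
        se = np.sqrt(np.maximum(np.diag(cov), 0.0))
    except np.linalg.LinAlgError:
        se = np.full(p, np.nan)
    z = np.divide(beta, se, out=np.zeros_like(beta), where=se > 0)
    pvals = 2.0 * sps.norm.sf(np.abs(z))
    with np.errstate(over="ignore"):  # separated fits have unbounded CIs
        ci_lo, ci_hi = np.exp(beta - 1.96 * se), np.exp(beta + 1.96 * se)
    return CoxFit(
        coefficients=beta,
        hazard_ratios=np.exp(beta),
        ci_lower=ci_lo,
        ci_upper=ci_hi,
        p_values=pvals,
        se=se,
        converged=converged,
        separation=separation,
        log_likelihood=ll,
    )


def _cox_lasso(x, times, events, penalty, max_iter: int = 2000, tol: float = 1e-7):
    """ISTA with backtracking on the mean negative partial log-likelihood."""
    n, p = x.shape
    beta = np.zeros(p)
    step = 1.0

    def f(b):
        return -_breslow_loglik_grad_hess(b, x, times, events)[0] / n

    fb = f(beta)
    for _ in range(max_iter):
        _, grad, _ = _breslow_loglik_grad_hess(beta, x, times, events)
        grad = -grad / n
        while True:
            cand = beta - step * grad
            cand = np.sign(cand) * np.maximum(np.abs(cand) - step * penalty, 0.0)
            fc = f(cand)
            diff = cand - beta
            if fc <= fb + grad @ diff + (diff @ diff) / (2 * step) + 1e-12:
                break
            step *= 0.5
            if step < 1e-12:
                break
        if np.max(np.abs(cand - beta)) < tol:
            beta = cand
            break
        beta, fb = cand, fc
        step = min(step * 1.5, 10.0)
    return beta


def cox_l1_path(times, events, covariates, penalties: Sequence[float]) -> List[CoxFit]:
    """Lasso-Cox coefficient path over a grid of regularization strengths."""
    return [cox_fit(times, events, covariates, l1_penalty=lam) for lam in penalties]


# ---------------------------------------------------------------------------
# report generators (group-comparison and HR tables)
# ---------------------------------------------------------------------------

def group_comparison_table(df, group_col: str,
                           categorical: Sequence[str] = (),
                           continuous: Sequence[str] = ()):
    """Per-variable comparison of two groups (chi-square / Mann-Whitney).

    Categorical variables use Pearson chi-square with Yates correction when
    the (empty-category-dropped) table is 2x2; continuous variables use the
    Mann-Whitney U test. Returns a tidy DataFrame (variable, test, p_value).
    """
    import pandas as pd

    groups = sorted(df[group_col].dropna().unique())
    if len(groups) != 2:
        raise ValueError("group comparison requires exactly two groups")
    rows = []
    for var in categorical:
        sub = df[[group_col, var]].dropna()
        counts = pd.crosstab(sub[group_col], sub[var]).to_numpy()
        try:
            table = ContingencyTable(counts)
            dropped = _drop_empty(table.counts)
            stat, dof, p = pearson_chi2(table, yates=dropped.shape == (2, 2))
            test = "pearson_chi2" + ("_yates" if dropped.shape == (2, 2) else "")
        except ValueError:
            p, test = np.nan, "undefined"
        rows.append({"variable": var, "test": test, "p_value": p})
    for var in continuous:
        sub = df[[group_col, var]].dropna()
        x = sub.loc[sub[group_col] == groups[0], var].to_numpy(dtype=float)
        y = sub.loc[sub[group_col] == groups[1], var].to_numpy(dtype=float)
        _, p = mann_whitney(x, y)
        rows.append({"variable": var, "test": "mann_whitney", "p_value": p})
    return pd.DataFrame(rows)


def cox_table(df, time_col: str, event_col: str,
              covariate_cols: Sequence[str],
              multivariable: Optional[Sequence[str]] = None):
    """Univariable (and optional multivariable) Cox HR table.

    Each covariate must already be numeric (e.g. 0/1 indicators). Returns a
    DataFrame with hazard ratios, 95% CIs, and Wald p-values, mirroring the
    usual clinical-paper layout.
    """
    import pandas as pd

    t = df[time_col].to_numpy(dtype=float)
    e = df[event_col].to_numpy(dtype=bool)
    rows = []
    for var in covariate_cols:
        x = df[[var]].to_numpy(dtype=float)
        fit = cox_fit(t, e, x)
        rows.append({
            "variable": var, "analysis": "univariable",
            "HR": fit.hazard_ratios[0],
            "CI_lower": fit.ci_lower[0], "CI_upper": fit.ci_upper[0],
            "p_value": fit.p_values[0],
        })
    if multivariable:
        x = df[list(multivariable)].to_numpy(dtype=float)
        fit = cox_fit(t, e, x)
        for j, var in enumerate(multivariable):
            rows.append({
                "variable": var, "analysis": "multivariable",
                "HR": fit.hazard_ratios[j],
                "CI_lower": fit.ci_lower[j], "CI_upper": fit.ci_upper[j],
                "p_value": fit.p_values[j],
            })
    return pd.DataFrame(rows)
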