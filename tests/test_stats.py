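"""Contingency tests, Mann-Whitney, Kaplan-Meier, log-rank, Cox regression."""

import numpy as np
import pandas as pd
import pytest

from graphsurv.stats import (
    ContingencyTable, cox_fit, cox_l1_path, cox_table, fisher_exact,
    group_comparison_table, km_fit, logrank_test, mann_whitney, pearson_chi2,
)


# ---------------------------------------------------------------------------
# chi-square
# ---------------------------------------------------------------------------

def test_chi2_equals_textbook_formula(rng):
    counts = rng.integers(1, 40, (3, 4))
    stat, dof, _ = pearson_chi2(ContingencyTable(counts))
    expected = counts.sum(1, keepdims=True) * counts.sum(0) / counts.sum()
    assert stat == pytest.approx((((counts - expected) ** 2) / expected).sum())
    assert dof == 6


def test_chi2_drops_all_zero_categories():
    # 2x4 table whose last column is empty reduces to 2x3
    counts = np.array([[7, 1, 5, 0], [58, 2, 7, 0]])
    stat, dof, p = pearson_chi2(ContingencyTable(counts))
    assert dof == 2
    stat2, _, p2 = pearson_chi2(ContingencyTable(counts[:, :3]))
    assert (stat, p) == (stat2, p2)


def test_yates_correction_only_on_2x2():
    t22 = ContingencyTable(np.array([[5, 8], [51, 16]]))
    stat_y, _, p_y = pearson_chi2(t22, yates=True)
    stat_n, _, p_n = pearson_chi2(t22, yates=False)
    assert stat_y < stat_n  # correction shrinks the statistic
    t23 = ContingencyTable(np.array([[6, 3, 4], [54, 13, 0]]))
    assert pearson_chi2(t23, yates=True) == pearson_chi2(t23, yates=False)


def test_chi2_degenerate_table_raises():
    with pytest.raises(ValueError):
        pearson_chi2(ContingencyTable(np.array([[3, 0], [5, 0]])))


# ---------------------------------------------------------------------------
# Fisher's exact test
# ---------------------------------------------------------------------------

@pytest.mark.parametrize("table,expected", [
    ([[1, 0], [0, 1]], 1.0),          # both tables with these margins are extreme
    ([[5, 0], [0, 5]], 2 / 252),      # hypergeometric enumeration
    ([[2, 3], [0, 0]], 1.0),          # zero margin: single possible table
])
def test_fisher_exact_enumeration_values(table, expected):
    assert fisher_exact(table) == pytest.approx(expected)


def test_fisher_requires_2x2():
    with pytest.raises(ValueError):
        fisher_exact(np.ones((2, 3), dtype=int))


# ---------------------------------------------------------------------------
# Mann-Whitney
# ---------------------------------------------------------------------------

def test_mann_whitney_identical_samples():
    u, p = mann_whitney([1.0, 2.0, 3.0, 4.0], [1.0, 2.0, 3.0, 4.0])
    assert p == pytest.approx(1.0)


def test_mann_whitney_extreme_separation_u_zero():
    u, p = mann_whitney([1, 2, 3], [10, 11, 12])
    assert u == 0.0


def test_mann_whitney_all_tied_returns_p_one():
    u, p = mann_whitney([2.0, 2.0], [2.0, 2.0, 2.0])
    assert p == 1.0


def test_mann_whitney_u_matches_pair_count_oracle(rng):
    x = rng.normal(0, 1, 8)
    y = rng.normal(0.5, 1, 8)
    u, _ = mann_whitney(x, y)
    oracle = sum(1.0 if xi > yj else 0.5 if xi == yj else 0.0
                 for xi in x for yj in y)
    assert u == pytest.approx(oracle)


# ---------------------------------------------------------------------------
# Kaplan-Meier and log-rank
# ---------------------------------------------------------------------------

def test_km_no_censoring_is_empirical_survival():
    km = km_fit([1.0, 2.0, 3.0], [1, 1, 1])
    assert km.survival_at(0.5) == 1.0
    assert km.survival_at(1.0) == pytest.approx(2 / 3)
    assert km.survival_at(2.0) == pytest.approx(1 / 3)
    assert km.survival_at(3.0) == pytest.approx(0.0)


def test_km_censoring_keeps_curve_above_empirical(rng):
    t = rng.uniform(1, 10, 20)
    e = rng.random(20) > 0.5
    if not e.any():
        e[0] = True
    km = km_fit(t, e)
    assert km.survival[0] == 1.0
    assert np.all(np.diff(km.survival) <= 1e-12)


def logrank_oracle(ta, ea, tb, eb):
    """Hand hypergeometric O-E / V computation."""
    ta, tb = np.asarray(ta, float), np.asarray(tb, float)
    ea, eb = np.asarray(ea, bool), np.asarray(eb, bool)
    times = np.unique(np.concatenate([ta[ea], tb[eb]]))
    o_minus_e = v = 0.0
    for t in times:
        na = (ta >= t).sum()
        nb = (tb >= t).sum()
        da = (ea & (ta == t)).sum()
        db = (eb & (tb == t)).sum()
        n, d = na + nb, da + db
        o_minus_e += da - d * na / n
        if n > 1:
            v += d * (na / n) * (nb / n) * (n - d) / (n - 1)
    return o_minus_e**2 / v


def test_logrank_identical_groups_is_null():
    stat, p = logrank_test([1, 2, 3], [1, 1, 1], [1, 2, 3], [1, 1, 1])
    assert stat == pytest.approx(0.0, abs=1e-12)
    assert p == pytest.approx(1.0)


def test_logrank_symmetric_and_matches_hand_oracle():
    ta, ea = [1.0, 3.0, 5.0], [1, 1, 0]
    tb, eb = [2.0, 4.0, 6.0], [1, 1, 1]
    stat, p = logrank_test(ta, ea, tb, eb)
    stat_sym, p_sym = logrank_test(tb, eb, ta, ea)
    assert stat == pytest.approx(stat_sym)
    assert p == pytest.approx(p_sym)
    assert stat >= 0
    assert stat == pytest.approx(logrank_oracle(ta, ea, tb, eb), rel=1e-6)


def test_logrank_requires_events():
    with pytest.raises(ValueError):
        logrank_test([1, 2], [0, 0], [3, 4], [0, 0])


# ---------------------------------------------------------------------------
# Cox regression
# ---------------------------------------------------------------------------

def test_cox_closed_form_two_events():
    # events at t=1 (x=1, full risk set) and t=2 (x=0, risk set {x=0,x=1}):
    # score equation gives exp(beta) = sqrt(2)
    fit = cox_fit([1, 2, 3, 4], [1, 1, 0, 0], [[1], [0], [1], [0]])
    assert fit.converged
    assert fit.coefficients[0] == pytest.approx(0.5 * np.log(2), abs=1e-8)


def test_cox_hr_recovery_binary_covariate(rng):
    n = 500
    x = (rng.random(n) < 0.5).astype(float)
    t = rng.exponential(1.0 / (0.05 * 3.0**x))
    c = rng.exponential(30.0, n)
    time, event = np.minimum(t, c), t <= c
    fit = cox_fit(time, event, x[:, None])
    assert 2.4 <= fit.hazard_ratios[0] <= 3.75
    assert fit.ci_lower[0] < fit.hazard_ratios[0] < fit.ci_upper[0]
    assert fit.hazard_ratios[0] == pytest.approx(np.exp(fit.coefficients[0]))


def test_cox_matches_lifelines_on_tie_free_data(rng):
    n = 80
    x = rng.normal(0, 1, (n, 2))
    beta = np.array([0.8, -0.5])
    t = rng.exponential(1 / (0.1 * np.exp(x @ beta)))
    c = rng.exponential(12, n)
    time, event = np.minimum(t, c), t <= c
    fit = cox_fit(time, event, x)
    from lifelines import CoxPHFitter
    df = pd.DataFrame({"t": time, "e": event.astype(int),
                       "x0": x[:, 0], "x1": x[:, 1]})
    cph = CoxPHFitter().fit(df, "t", "e")
    assert np.allclose(fit.coefficients, cph.params_.values, atol=1e-4)
    assert np.allclose(fit.se, cph.standard_errors_.values, atol=1e-4)


def test_cox_separation_flagged_not_raised():
    # the only event is on x=1 while x=0 subjects always outlive: monotone PL
    fit = cox_fit([1, 2, 3], [1, 0, 0], [[1], [0], [0]])
    assert fit.separation
    assert np.abs(fit.coefficients[0]) <= 20.0


def test_cox_constant_covariate_rejected_unpenalized():
    with pytest.raises(ValueError):
        cox_fit([1, 2, 3], [1, 1, 0], [[1], [1], [1]])


def test_lasso_zero_covariate_stays_zero(rng):
    n = 60
    x = rng.normal(0, 1, (n, 1))
    t = rng.exponential(1 / (0.1 * np.exp(0.8 * x[:, 0])))
    e = np.ones(n, dtype=bool)
    xz = np.hstack([x, np.zeros((n, 1))])
    fit = cox_fit(t, e, xz, l1_penalty=0.05)
    assert fit.coefficients[1] == 0.0
    assert fit.coefficients[0] != 0.0


def test_lasso_path_shrinks_monotonically(rng):
    n = 80
    x = rng.normal(0, 1, (n, 1))
    t = rng.exponential(1 / (0.1 * np.exp(1.0 * x[:, 0])))
    e = np.ones(n, dtype=bool)
    path = cox_l1_path(t, e, x, [0.0, 0.05, 0.2, 1.0])
    mags = [abs(f.coefficients[0]) for f in path]
    assert all(a >= b - 1e-8 for a, b in zip(mags, mags[1:]))
    assert mags[-1] == pytest.approx(0.0, abs=1e-6)


def test_cox_sign_agrees_with_group_survival_ordering(rng):
    # group 1 dies faster => positive coefficient
    t0 = rng.exponential(20.0, 40)
    t1 = rng.exponential(5.0, 40)
    times = np.concatenate([t0, t1])
    x = np.concatenate([np.zeros(40), np.ones(40)])[:, None]
    fit = cox_fit(times, np.ones(80, bool), x)
    assert fit.coefficients[0] > 0


# ---------------------------------------------------------------------------
# report generators
# ---------------------------------------------------------------------------

def test_group_comparison_and_cox_tables(rng):
    n = 60
    df = pd.DataFrame({
        "risk_group": np.where(rng.random(n) < 0.3, "high", "low"),
        "stage": rng.choice(["I", "II", "III"], n),
        "marker": rng.normal(30, 10, n),
        "time_months": rng.uniform(1, 60, n),
        "event": rng.random(n) < 0.4,
    })
    cmp_table = group_comparison_table(df, "risk_group",
                                       categorical=["stage"], continuous=["marker"])
    assert set(cmp_table.variable) == {"stage", "marker"}
    assert ((cmp_table.p_value >= 0) & (cmp_table.p_value <= 1)).all()

    df["high"] = (df.risk_group == "high").astype(float)
    tbl = cox_table(df, "time_months", "event", ["high"], multivariable=["high"])
    assert len(tbl) == 2
    assert (tbl.HR > 0).all()
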