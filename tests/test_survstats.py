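"""Survival-statistic oracles and properties.

Brute-force risk-set enumeration oracles are written independently of
the implementation and frozen here; `lifelines` serves as an external
cross-check on larger inputs.
"""

import itertools

import numpy as np
import pytest

from hlasurv.survstats import (
    ConvergenceError,
    cox_score_chi2,
    fit_cox,
    group_hazard_ratio,
    km_estimate,
    logrank_test,
    welch_t_test,
)

# ---------------------------------------------------------------------------
# independent oracles


def km_oracle(times, events, t):
    """S(t) by direct product over death times, no shared code."""
    s = 1.0
    for u in sorted({ti for ti, ei in zip(times, events) if ei == 1}):
        if u > t:
            break
        n_risk = sum(1 for ti in times if ti >= u)
        d = sum(1 for ti, ei in zip(times, events) if ti == u and ei == 1)
        s *= 1 - d / n_risk
    return s


def logrank_oracle(times, events, groups):
    """Chi-square from an explicit O/E/V table over pooled risk sets."""
    num = 0.0
    var = 0.0
    for u in sorted({ti for ti, ei in zip(times, events) if ei == 1}):
        risk = [(ti, gi) for ti, gi in zip(times, groups) if ti >= u]
        n = len(risk)
        n1 = sum(1 for _, gi in risk if gi == 1)
        d = sum(1 for ti, ei in zip(times, events) if ti == u and ei == 1)
        d1 = sum(1 for ti, ei, gi in zip(times, events, groups) if ti == u and ei == 1 and gi == 1)
        num += d1 - d * n1 / n
        if n > 1:
            var += d * n1 * (n - n1) * (n - d) / (n * n * (n - 1))
    return num * num / var


# ---------------------------------------------------------------------------
# Kaplan-Meier


def test_km_no_censoring_equals_empirical_survival():
    times = [1.0, 2.0, 3.0, 4.0]
    km = km_estimate(times, [1, 1, 1, 1])
    assert km.survival_at(2.0) == pytest.approx(0.5)
    for t in times:
        emp = np.mean(np.asarray(times) > t)
        assert km.survival_at(t) == pytest.approx(emp)


def test_km_all_censored_is_flat_one():
    km = km_estimate([3.0, 5.0, 9.0], [0, 0, 0])
    assert km.event_times.size == 0
    assert km.survival_at(100.0) == 1.0


def test_km_matches_risk_set_enumeration_oracle():
    times = [2.0, 3.0, 3.0, 5.0, 8.0, 11.0]
    events = [1, 1, 0, 1, 0, 1]
    km = km_estimate(times, events)
    for t in [1.0, 2.0, 3.0, 5.0, 8.0, 11.0, 20.0]:
        assert km.survival_at(t) == pytest.approx(km_oracle(times, events, t))
    assert (np.diff(km.survival) <= 0).all()
    assert (np.diff(km.at_risk) <= 0).all()


def test_km_rejects_empty():
    with pytest.raises(ValueError):
        km_estimate([], [])


# ---------------------------------------------------------------------------
# log-rank


def test_logrank_identical_groups_gives_p_one():
    times = [1.0, 2.0, 3.0, 4.0] * 2
    events = [1, 1, 0, 1] * 2
    groups = [0, 0, 0, 0, 1, 1, 1, 1]
    res = logrank_test(times, events, groups)
    assert res.chi2 == pytest.approx(0.0, abs=1e-12)
    assert res.p == pytest.approx(1.0)


def test_logrank_matches_enumeration_oracle_eight_patients():
    times = [1.0, 2.0, 2.0, 4.0, 5.0, 7.0, 9.0, 12.0]
    events = [1, 1, 0, 1, 1, 0, 1, 1]
    groups = [1, 0, 1, 1, 0, 0, 0, 1]
    res = logrank_test(times, events, groups)
    assert res.chi2 == pytest.approx(logrank_oracle(times, events, groups))


def test_logrank_zero_events_warns_p_one():
    with pytest.warns(UserWarning, match="variance"):
        res = logrank_test([1.0, 2.0, 3.0, 4.0], [0, 0, 0, 0], [0, 0, 1, 1])
    assert res.p == 1.0


def test_logrank_invariant_under_monotone_time_transform(rng):
    t = rng.exponential(10, 60)
    e = rng.integers(0, 2, 60)
    e[0] = 1
    g = rng.integers(0, 2, 60)
    g[:2] = [0, 1]
    a = logrank_test(t, e, g)
    b = logrank_test(t**2, e, g)  # rank-preserving
    assert a.chi2 == pytest.approx(b.chi2)


def test_logrank_calibration_under_null(rng):
    """Rejection rate at alpha=0.05 stays near 0.05 for exchangeable groups."""
    reps, hits = 1000, 0
    for _ in range(reps):
        t = rng.exponential(1.0, 80)
        e = (rng.random(80) < 0.8).astype(int)
        g = np.zeros(80, dtype=int)
        g[:40] = 1
        if logrank_test(t, e, g).p < 0.05:
            hits += 1
    assert abs(hits / reps - 0.05) < 0.02


# ---------------------------------------------------------------------------
# Cox


def test_cox_matches_lifelines_with_ties(rng):
    lifelines = pytest.importorskip("lifelines")
    import pandas as pd

    n = 300
    X = np.column_stack([rng.integers(0, 2, n), rng.normal(size=n)])
    t = np.round(50 * rng.exponential(size=n) / np.exp(0.6 * X[:, 0] - 0.3 * X[:, 1])) + 1
    c = rng.exponential(60, n)
    time = np.minimum(t, c)
    event = (t <= c).astype(int)
    fit = fit_cox(time, event, X)
    df = pd.DataFrame({"T": time, "E": event, "a": X[:, 0], "b": X[:, 1]})
    ref = lifelines.CoxPHFitter().fit(df, "T", "E")
    np.testing.assert_allclose(fit.coef, ref.params_.to_numpy(), atol=1e-6)
    np.testing.assert_allclose(fit.se, ref.standard_errors_.to_numpy(), atol=1e-6)
    assert fit.loglik == pytest.approx(ref.log_likelihood_, abs=1e-6)


def test_cox_efron_equals_breslow_without_ties(rng):
    n = 120
    x = rng.normal(size=(n, 2))
    t = rng.exponential(1.0, n) / np.exp(0.5 * x[:, 0])
    e = np.ones(n, dtype=int)
    f1 = fit_cox(t, e, x, ties="efron")
    f2 = fit_cox(t, e, x, ties="breslow")
    np.testing.assert_allclose(f1.coef, f2.coef, atol=1e-9)
    np.testing.assert_allclose(f1.se, f2.se, atol=1e-9)


def test_cox_recovers_log_rate_ratio_two(rng):
    """Two-group exponential with rate ratio 2: beta-hat near ln 2."""
    n = 2000
    x = (rng.random(n) < 0.5).astype(float)
    t = rng.exponential(1.0, n) / np.exp(np.log(2) * x)
    fit = fit_cox(t, np.ones(n, dtype=int), x)
    assert abs(fit.coef[0] - np.log(2)) < 0.1


def test_cox_score_test_equals_logrank_chi2(rng):
    n = 150
    x = (rng.random(n) < 0.4).astype(float)
    t = rng.exponential(1.0, n) / np.exp(0.5 * x)  # continuous -> tie-free
    c = rng.exponential(2.0, n)
    time, event = np.minimum(t, c), (t <= c).astype(int)
    lr = logrank_test(time, event, x.astype(int))
    assert cox_score_chi2(time, event, x) == pytest.approx(lr.chi2, rel=1e-10)


def test_cox_constant_covariate_rejected(rng):
    with pytest.raises(ValueError, match="constant"):
        fit_cox(rng.exponential(1, 30), np.ones(30, int), np.ones((30, 1)), names=["flat"])


def test_cox_perfect_separation_raises():
    # all deaths in one group, all censored in the other, disjoint time ranges
    t = np.concatenate([np.linspace(1, 2, 20), np.linspace(10, 12, 20)])
    e = np.concatenate([np.ones(20, int), np.zeros(20, int)])
    x = np.concatenate([np.ones(20), np.zeros(20)])
    with pytest.raises(ConvergenceError):
        fit_cox(t, e, x, names=["sep"])


def test_cox_hr_ci_ordering(rng):
    n = 400
    x = (rng.random(n) < 0.5).astype(float)
    t = rng.exponential(1.0, n) / np.exp(0.6 * x)
    fit = fit_cox(t, np.ones(n, int), x)
    lo, hi = fit.ci95[0]
    assert lo < fit.hr[0] < hi
    assert fit.hr[0] > 0


# ---------------------------------------------------------------------------
# group hazard ratio


def test_group_hr_mask_swap_inverts(rng):
    n = 200
    high = rng.random(n) < 0.4
    t = rng.exponential(1.0, n) / np.exp(0.8 * high)
    e = np.ones(n, int)
    a = group_hazard_ratio(t, e, high)
    b = group_hazard_ratio(t, e, ~high)
    assert b.hr == pytest.approx(1 / a.hr, rel=1e-6)
    assert b.ci95[0] == pytest.approx(1 / a.ci95[1], rel=1e-6)
    assert b.ci95[1] == pytest.approx(1 / a.ci95[0], rel=1e-6)
    assert (a.n_high, a.n_low) == (b.n_low, b.n_high)
    assert a.p == b.p


def test_group_hr_requires_both_groups(rng):
    t = rng.exponential(1.0, 10)
    with pytest.raises(ValueError):
        group_hazard_ratio(t, np.ones(10, int), np.ones(10, bool))


# ---------------------------------------------------------------------------
# two-sample t


def test_t_test_identical_samples():
    x = np.array([1.0, 2.0, 3.0, 4.0])
    res = welch_t_test(x, x.copy())
    assert res.t == pytest.approx(0.0)
    assert res.p == pytest.approx(1.0)


def test_t_test_zero_variance_rejected():
    with pytest.raises(ValueError, match="constant"):
        welch_t_test([1.0, 1.0, 1.0], [2.0, 2.0])


def test_t_test_near_exact_permutation_oracle():
    """Pooled-variance p agrees with the exact permutation distribution."""
    x = [8.1, 9.4, 7.7, 8.9, 9.9]
    y = [6.2, 7.0, 5.8, 6.9, 7.5]
    combined = x + y
    obs = abs(welch_t_test(x, y, equal_var=True).t)
    count = total = 0
    for idx in itertools.combinations(range(10), 5):
        xs = [combined[i] for i in idx]
        ys = [combined[i] for i in range(10) if i not in idx]
        total += 1
        if abs(welch_t_test(xs, ys, equal_var=True).t) >= obs - 1e-12:
            count += 1
    p_perm = count / total
    p_t = welch_t_test(x, y, equal_var=True).p
    assert abs(p_t - p_perm) < 0.05


def test_welch_df_between_min_and_sum():
    res = welch_t_test([1.0, 2.0, 3.0], [10.0, 30.0, 20.0, 40.0])
    assert 2 <= res.df <= 5
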