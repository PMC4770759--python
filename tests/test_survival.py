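"""Survival machinery against hand-written oracles: transplant censoring,
Kaplan-Meier product limit, log-rank O-E/V, and the Efron partial
likelihood."""

import numpy as np
import pandas as pd
import pytest

from mrnasig.survival import (
    NOT_REACHED,
    CoxFitError,
    apply_hsct_censoring,
    cox_fit,
    km_estimate,
    logrank_test,
    univariate_cox,
)


def _clin(times, events, **extra):
    n = len(times)
    df = pd.DataFrame({
        "os_time": times, "os_event": events,
        "response": ["other"] * n, "treated_intensively": [True] * n,
    }, index=[f"s{i}" for i in range(n)])
    for k, v in extra.items():
        df[k] = v
    return df


# ---------------------------------------------------------------------------
# oracles

def efron_loglik_oracle(beta, times, events, x):
    """Efron partial log-likelihood written directly from its definition."""
    times, events, x = map(np.asarray, (times, events, x))
    ll = 0.0
    for t in np.unique(times[events == 1]):
        tied = (times == t) & (events == 1)
        risk = times >= t
        d = tied.sum()
        s_risk = np.exp(beta * x[risk]).sum()
        s_tie = np.exp(beta * x[tied]).sum()
        ll += beta * x[tied].sum()
        for ell in range(d):
            ll -= np.log(s_risk - (ell / d) * s_tie)
    return ll


def logrank_oracle(times, events, groups):
    """Two-group log-rank chi-square from the O-E / V definition."""
    times, events, groups = map(np.asarray, (times, events, groups))
    labels = np.unique(groups)
    o_minus_e = 0.0
    var = 0.0
    for t in np.unique(times[events == 1]):
        at_risk = times >= t
        n = at_risk.sum()
        n1 = (at_risk & (groups == labels[0])).sum()
        d = ((times == t) & (events == 1)).sum()
        d1 = ((times == t) & (events == 1) & (groups == labels[0])).sum()
        o_minus_e += d1 - d * n1 / n
        if n > 1:
            var += d * (n1 / n) * (1 - n1 / n) * (n - d) / (n - 1)
    return o_minus_e ** 2 / var


# ---------------------------------------------------------------------------


class TestHsctCensoring:
    def test_no_transplants_identity(self):
        clin = _clin([5.0, 10.0], [1, 0])
        out = apply_hsct_censoring(clin)
        pd.testing.assert_frame_equal(out, clin)

    def test_transplant_truncates_and_censors(self):
        clin = _clin([20.0, 15.0], [1, 1], hsct_time=[6.0, np.nan])
        out = apply_hsct_censoring(clin)
        assert out.loc["s0", "os_time"] == 6.0
        assert out.loc["s0", "os_event"] == 0
        assert out.loc["s1", "os_time"] == 15.0 and out.loc["s1", "os_event"] == 1

    def test_event_accounting(self):
        rng = np.random.default_rng(3)
        t = rng.uniform(1, 30, 50)
        e = rng.integers(0, 2, 50)
        hsct = np.where(rng.uniform(size=50) < 0.3, t * rng.uniform(0.2, 1.0, 50), np.nan)
        clin = _clin(t, e, hsct_time=hsct)
        out = apply_hsct_censoring(clin)
        lost = int(clin.loc[~np.isnan(hsct), "os_event"].sum())
        assert out["os_event"].sum() == clin["os_event"].sum() - lost

    def test_hsct_after_death_rejected(self):
        clin = _clin([5.0], [1], hsct_time=[9.0])
        with pytest.raises(ValueError, match="hsct"):
            apply_hsct_censoring(clin)


class TestKaplanMeier:
    def test_no_events_flat_median_not_reached(self):
        km = km_estimate([3.0, 5.0, 8.0], [0, 0, 0])
        df = next(iter(km.values()))
        assert (df["survival"] == 1.0).all()
        assert df.attrs["median"] == NOT_REACHED

    def test_hand_computed_product_limit(self):
        km = km_estimate([1.0, 2.0, 3.0], [1, 1, 1])
        df = next(iter(km.values()))
        steps = df.set_index("time")["survival"]
        assert steps.loc[1.0] == pytest.approx(2 / 3)
        assert steps.loc[2.0] == pytest.approx(1 / 3)
        assert steps.loc[3.0] == pytest.approx(0.0)
        assert df.attrs["median"] == 2.0

    def test_censoring_tail_keeps_curve_flat(self):
        km = km_estimate([1.0, 2.0, 5.0, 9.0], [1, 1, 0, 0])
        df = next(iter(km.values()))
        after = df[df["time"] >= 2.0]["survival"]
        assert (after == after.iloc[0]).all()

    def test_curve_monotone_from_one(self, small_cohort):
        _, clinical, _ = small_cohort
        km = km_estimate(clinical["os_time"], clinical["os_event"])
        s = next(iter(km.values()))["survival"].to_numpy()
        assert s[0] == 1.0
        assert (np.diff(s) <= 1e-12).all()


class TestLogrank:
    def test_identical_groups_statistic_zero(self):
        t = [2.0, 4.0, 6.0, 8.0]
        e = [1, 0, 1, 1]
        chi, p = logrank_test(t + t, e + e, [0] * 4 + [1] * 4)
        assert chi == pytest.approx(0.0, abs=1e-12)
        assert p == pytest.approx(1.0)

    def test_matches_hand_oracle_six_subjects(self):
        times = [1.0, 3.0, 4.0, 5.0, 7.0, 9.0]
        events = [1, 1, 0, 1, 1, 1]
        groups = [0, 0, 0, 1, 1, 1]
        chi, p = logrank_test(times, events, groups)
        assert chi == pytest.approx(logrank_oracle(times, events, groups), rel=1e-10)

    def test_symmetric_in_group_labels(self):
        rng = np.random.default_rng(9)
        t = rng.exponential(10, 30)
        e = rng.integers(0, 2, 30)
        e[0] = 1
        g = rng.integers(0, 2, 30)
        assert logrank_test(t, e, g) == logrank_test(t, e, 1 - g)

    def test_zero_events_rejected(self):
        with pytest.raises(ValueError, match="zero events"):
            logrank_test([1.0, 2.0], [0, 0], [0, 1])


class TestCoxFit:
    def test_univariate_matches_grid_search_oracle_with_ties(self):
        # 8 subjects, tied event times, binary covariate
        times = [2.0, 2.0, 3.0, 5.0, 5.0, 7.0, 8.0, 9.0]
        events = [1, 1, 1, 0, 1, 1, 0, 1]
        x = np.array([1, 0, 1, 1, 0, 1, 0, 0], dtype=float)
        grid = np.linspace(-3, 3, 60001)
        lls = [efron_loglik_oracle(b, times, events, x) for b in grid]
        beta_star = grid[int(np.argmax(lls))]
        fit = univariate_cox(times, events, x)
        assert fit.coef == pytest.approx(beta_star, abs=1e-4)

    def test_library_route_agrees_with_newton_route(self):
        rng = np.random.default_rng(4)
        n = 60
        x = rng.standard_normal(n)
        t = rng.exponential(1 / (0.05 * np.exp(0.5 * x)))
        e = (t < rng.uniform(0, 40, n)).astype(int)
        t = np.minimum(t, 40.0)
        clin = _clin(t, e, cov=x)
        table = cox_fit(clin, ["cov"])
        fast = univariate_cox(t, e, x)
        assert table.loc["cov", "coef"] == pytest.approx(fast.coef, abs=1e-6)
        assert table.loc["cov", "se"] == pytest.approx(fast.se, abs=1e-6)
        assert table.loc["cov", "p"] == pytest.approx(fast.p, rel=1e-4)
        assert table.loc["cov", "hr"] == pytest.approx(np.exp(fast.coef))
        lo, hi = fast.ci
        assert table.loc["cov", "ci_low"] == pytest.approx(lo, rel=1e-4)
        assert table.loc["cov", "ci_high"] == pytest.approx(hi, rel=1e-4)

    def test_multivariate_fit_reports_all_covariates(self, small_cohort):
        _, clinical, truth = small_cohort
        clin = clinical[clinical["treated_intensively"]].copy()
        clin["factor"] = truth.latent_factor[
            clinical["treated_intensively"].to_numpy()]
        table = cox_fit(clin, ["factor", "age", "NPM1"])
        assert list(table.index) == ["factor", "age", "NPM1"]
        assert np.isfinite(table.attrs["log_likelihood"])
        assert ((table["ci_low"] <= table["hr"]) & (table["hr"] <= table["ci_high"])).all()

    def test_score_test_approximates_logrank_large_n(self):
        rng = np.random.default_rng(12)
        n = 2000
        g = rng.integers(0, 2, n)
        t = rng.exponential(1 / (0.04 * np.exp(0.3 * g)))
        c = rng.uniform(0, 50, n)
        e = (t <= c).astype(int)
        t = np.minimum(t, c)
        chi_lr, _ = logrank_test(t, e, g)
        fit = univariate_cox(t, e, g.astype(float))
        chi_wald = (fit.coef / fit.se) ** 2
        assert abs(chi_wald - chi_lr) / chi_lr < 0.05

    def test_degenerate_inputs_raise(self):
        with pytest.raises(CoxFitError):
            univariate_cox([1.0, 2.0, 3.0], [1, 0, 0], [0.0, 1.0, 2.0])
        with pytest.raises(CoxFitError, match="constant"):
            univariate_cox([1.0, 2.0, 3.0], [1, 1, 1], [1.0, 1.0, 1.0])
        clin = _clin([1.0, 2.0], [1, 0], cov=[np.nan, 1.0])
        with pytest.raises(ValueError, match="missing"):
            cox_fit(clin, ["cov"])
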