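"""Survival machinery: transplant censoring, Kaplan-Meier, log-rank, and
Cox proportional-hazards fitting.

The general (possibly multivariate) Cox fit, the Kaplan-Meier estimator and
the log-rank test are delegated to lifelines. A dedicated single-covariate
Newton solver on the Efron partial likelihood (:func:`univariate_cox`) is
provided for the per-probe survival screen and the permutation null, where
tens of thousands of fits per run make a heavier fitter impractical; the two
routes agree to numerical precision and are cross-checked in the test suite.

Conventions: Efron handling of tied event times; Wald-based P-values and
confidence intervals (CI = exp(coef +/- 1.96 se)); medians reported as the
first time the survival curve drops to 0.5 or below, with "not reached"
as a distinguished token.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from lifelines import CoxPHFitter, KaplanMeierFitter
from lifelines.statistics import multivariate_logrank_test
from scipy import stats

from .containers import validate_clinical

__all__ = [
    "apply_hsct_censoring",
    "km_estimate",
    "logrank_test",
    "cox_fit",
    "univariate_cox",
    "CoxFitError",
    "UnivariateCoxResult",
    "NOT_REACHED",
]

NOT_REACHED = "not reached"

Z_95 = stats.norm.ppf(0.975)


class CoxFitError(RuntimeError):
    """Raised when a proportional-hazards fit fails to converge or separates."""


# ---------------------------------------------------------------------------
# transplant censoring


def apply_hsct_censoring(clinical: pd.DataFrame) -> pd.DataFrame:
    """Censor transplanted patients at the day of stem-cell infusion.

    For samples with a non-missing ``hsct_time``, overall survival is
    truncated to the transplant time and the event indicator cleared.
    Other samples (and all other columns) are unchanged; the input is not
    mutated.
    """
    validate_clinical(clinical)
    out = clinical.copy()
    if "hsct_time" not in out.columns:
        return out
    has = out["hsct_time"].notna()
    out.loc[has, "os_time"] = out.loc[has, "hsct_time"]
    out.loc[has, "os_event"] = 0
    return out


# ---------------------------------------------------------------------------
# Kaplan-Meier and log-rank


def km_estimate(times, events, groups=None) -> dict[str, pd.DataFrame]:
    """Product-limit survival estimate per group.

    Returns a dict mapping group label to a DataFrame with columns
    ``time``, ``survival``, ``at_risk`` and attrs ``median`` (a float, or
    the string ``"not reached"`` when the curve never drops to 0.5).
    """
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=int)
    if groups is None:
        groups = np.zeros(len(times), dtype=int)
    groups = np.asarray(groups)
    out: dict[str, pd.DataFrame] = {}
    for g in pd.unique(groups):
        mask = groups == g
        if mask.sum() == 0:
            raise ValueError(f"empty group {g!r}")
        kmf = KaplanMeierFitter()
        kmf.fit(times[mask], events[mask])
        surv = kmf.survival_function_.iloc[:, 0]
        at_risk = kmf.event_table["at_risk"].reindex(surv.index).ffill()
        df = pd.DataFrame({"time": surv.index, "survival": surv.to_numpy(),
                           "at_risk": at_risk.to_numpy()})
        med = kmf.median_survival_time_
        df.attrs["median"] = NOT_REACHED if np.isinf(med) else float(med)
        out[g] = df
    return out


def logrank_test(times, events, groups) -> tuple[float, float]:
    """Standard (unweighted) log-rank test across >=2 groups.

    Returns ``(chi_square, p_value)``. Requires at least one event.
    """
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=int)
    groups = np.asarray(groups)
    if len(pd.unique(groups)) < 2:
        raise ValueError("logrank_test requires at least 2 groups")
    if events.sum() == 0:
        raise ValueError("logrank_test undefined with zero events")
    res = multivariate_logrank_test(times, groups, events)
    return float(res.test_statistic), float(res.p_value)


# ---------------------------------------------------------------------------
# Cox fitting (lifelines route)


def cox_fit(clinical: pd.DataFrame, covariates: list[str],
            time_col: str = "os_time", event_col: str = "os_event") -> pd.DataFrame:
    """Cox proportional-hazards fit (Efron ties) on named covariates.

    Returns a DataFrame indexed by covariate with columns ``coef``, ``se``,
    ``hr``, ``ci_low``, ``ci_high``, ``p`` and attrs ``log_likelihood``.
    Supports a single covariate (the univariate screen) or several (the
    multivariate survival model).
    """
    cols = [time_col, event_col] + list(covariates)
    data = clinical[cols]
    if data.isna().any().any():
        missing = data.columns[data.isna().any()].tolist()
        raise ValueError(f"missing values in columns {missing}; drop or impute first")
    if data[event_col].sum() < 2:
        raise CoxFitError("fewer than 2 events; Cox fit not identifiable")
    cph = CoxPHFitter()
    try:
        cph.fit(data, duration_col=time_col, event_col=event_col)
    except Exception as exc:  # convergence / separation surfaced explicitly
        raise CoxFitError(f"Cox fit failed: {exc}") from exc
    summ = cph.summary
    out = pd.DataFrame(
        {
            "coef": summ["coef"],
            "se": summ["se(coef)"],
            "hr": np.exp(summ["coef"]),
            "ci_low": np.exp(summ["coef"] - Z_95 * summ["se(coef)"]),
            "ci_high": np.exp(summ["coef"] + Z_95 * summ["se(coef)"]),
            "p": summ["p"],
        }
    )
    out.index.name = "covariate"
    out.attrs["log_likelihood"] = float(cph.log_likelihood_)
    return out


# ---------------------------------------------------------------------------
# Fast single-covariate Cox (Efron partial likelihood, Newton iterations)


@dataclass(frozen=True)
class UnivariateCoxResult:
    coef: float
    se: float
    p: float

    @property
    def hr(self) -> float:
        return float(np.exp(self.coef))

    @property
    def ci(self) -> tuple[float, float]:
        return (float(np.exp(self.coef - Z_95 * self.se)),
                float(np.exp(self.coef + Z_95 * self.se)))


def _efron_loglik_terms(beta, x_sorted, event_groups, risk_starts):
    """Log-likelihood, gradient and Hessian of the Efron partial likelihood.

    ``x_sorted`` is the covariate sorted by ascending time; ``event_groups``
    lists, per distinct event time, the positions of the tied events;
    ``risk_starts`` the first index of the risk set (all with time >= t).
    With no tied events (every group a singleton) the Efron and Breslow
    forms coincide and everything vectorizes.
    """
    eta = beta * x_sorted
    w = np.exp(eta)
    # suffix sums over the (time-ascending) array give risk-set sums
    s0 = np.cumsum(w[::-1])[::-1]
    s1 = np.cumsum((w * x_sorted)[::-1])[::-1]
    s2 = np.cumsum((w * x_sorted ** 2)[::-1])[::-1]
    if isinstance(event_groups, np.ndarray):  # tie-free fast path
        starts = risk_starts
        r1 = s1[starts] / s0[starts]
        ll = eta[event_groups].sum() - np.log(s0[starts]).sum()
        grad = x_sorted[event_groups].sum() - r1.sum()
        hess = -(s2[starts] / s0[starts] - r1 ** 2).sum()
        return ll, grad, hess
    ll = grad = hess = 0.0
    for idx, start in zip(event_groups, risk_starts):
        d = len(idx)
        xw, ww = x_sorted[idx], w[idx]
        t0, t1, t2 = ww.sum(), (ww * xw).sum(), (ww * xw ** 2).sum()
        ll += eta[idx].sum()
        frac = np.arange(d) / d
        a0 = s0[start] - frac * t0
        a1 = s1[start] - frac * t1
        a2 = s2[start] - frac * t2
        ll -= np.log(a0).sum()
        grad += xw.sum() - (a1 / a0).sum()
        hess -= (a2 / a0 - (a1 / a0) ** 2).sum()
    return ll, grad, hess


def _prepare(times, events):
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=int)
    order = np.argsort(times, kind="mergesort")
    t, e = times[order], events[order]
    event_groups, risk_starts = [], []
    i = 0
    n = len(t)
    while i < n:
        j = i
        while j < n and t[j] == t[i]:
            j += 1
        idx = np.arange(i, j)[e[i:j] == 1]
        if idx.size:
            event_groups.append(idx)
            risk_starts.append(i)
        i = j
    if all(len(g) == 1 for g in event_groups):
        return (order, np.array([g[0] for g in event_groups], dtype=np.intp),
                np.asarray(risk_starts, dtype=np.intp))
    return order, event_groups, risk_starts


def univariate_cox(times, events, x, max_iter: int = 50, tol: float = 1e-9) -> UnivariateCoxResult:
    """Single-covariate Cox fit by Newton's method on the Efron partial
    likelihood. Returns coefficient, standard error and two-sided Wald P.

    Raises :class:`CoxFitError` on non-convergence or separation (diverging
    coefficient / vanishing information).
    """
    x = np.asarray(x, dtype=float)
    events = np.asarray(events, dtype=int)
    if events.sum() < 2:
        raise CoxFitError("fewer than 2 events; Cox fit not identifiable")
    order, event_groups, risk_starts = _prepare(times, events)
    xs = x[order]
    if np.ptp(xs) == 0:
        raise CoxFitError("constant covariate")
    beta = 0.0
    for _ in range(max_iter):
        ll, grad, hess = _efron_loglik_terms(beta, xs, event_groups, risk_starts)
        if not np.isfinite(ll) or hess >= -1e-12:
            raise CoxFitError("degenerate information in Cox fit")
        step = -grad / hess
        # step-halving keeps the likelihood finite and increasing
        new = beta + step
        for _ in range(30):
            ll_new, _, _ = _efron_loglik_terms(new, xs, event_groups, risk_starts)
            if np.isfinite(ll_new) and ll_new >= ll - 1e-12:
                break
            new = (beta + new) / 2.0
        if abs(new - beta) < tol:
            beta = new
            break
        beta = new
    else:
        raise CoxFitError("Newton iteration did not converge")
    if abs(beta) > 50:
        raise CoxFitError("coefficient diverged (likely separation)")
    _, _, hess = _efron_loglik_terms(beta, xs, event_groups, risk_starts)
    se = float(np.sqrt(-1.0 / hess))
    z = beta / se
    p = float(2.0 * stats.norm.sf(abs(z)))
    return UnivariateCoxResult(coef=float(beta), se=se, p=p)
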