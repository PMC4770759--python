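"""Association tests between risk-score groups and clinical/molecular
features: 2x2 chi-square (uncorrected Pearson), Fisher's exact test, and
the Mann-Whitney rank-sum test for continuous variables.

The Pearson test deliberately omits the Yates continuity correction —
that convention reproduces published CN-AML score-vs-mutation tables,
whereas corrected values do not. Mutation variables may have per-variable
denominators (not every patient is assayed for every gene); build each
2x2 table from the counts actually observed for that variable.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

from .containers import warn

__all__ = ["chisq_2x2", "fisher_2x2", "mann_whitney", "association_table"]


def _as_table(t) -> np.ndarray:
    arr = np.asarray(t, dtype=float)
    if arr.shape != (2, 2):
        raise ValueError("expected a 2x2 table")
    if (arr < 0).any():
        raise ValueError("counts must be non-negative")
    if arr.sum() == 0:
        raise ValueError("empty table")
    return arr


def chisq_2x2(table) -> tuple[float, float]:
    """Pearson chi-square on a 2x2 table, 1 df, no continuity correction.

    Returns ``(statistic, two_sided_p)``. A zero row or column margin
    leaves the statistic undefined and raises.
    """
    arr = _as_table(table)
    if (arr.sum(axis=0) == 0).any() or (arr.sum(axis=1) == 0).any():
        raise ValueError("chi-square undefined: zero margin")
    stat, p, _, _ = stats.chi2_contingency(arr, correction=False)
    return float(stat), float(p)


def fisher_2x2(table) -> float:
    """Fisher's exact two-sided P (sum of tables as or less probable)."""
    arr = _as_table(table).astype(int)
    _, p = stats.fisher_exact(arr, alternative="two-sided")
    return float(p)


def mann_whitney(values, groups) -> tuple[float, float]:
    """Mann-Whitney rank-sum test, two-sided.

    Exact null distribution for small tie-free samples; otherwise the
    normal approximation with tie correction (no continuity correction,
    so identical groups give P = 1 exactly). ``groups`` is a two-level
    label vector aligned with ``values``. Returns ``(U, two_sided_p)``;
    an all-tied input gives P = 1 with a warning rather than a
    degenerate division.
    """
    values = np.asarray(values, dtype=float)
    groups = np.asarray(groups)
    labels = pd.unique(groups)
    if len(labels) != 2:
        raise ValueError("mann_whitney requires exactly 2 groups")
    a = values[groups == labels[0]]
    b = values[groups == labels[1]]
    if a.size == 0 or b.size == 0:
        raise ValueError("both groups must be non-empty")
    if np.ptp(values) == 0:
        warn("mann_whitney: all values tied; P = 1")
        return float(a.size * b.size / 2.0), 1.0
    res = stats.mannwhitneyu(a, b, alternative="two-sided",
                             method="auto", use_continuity=False)
    return float(res.statistic), float(res.pvalue)


def association_table(clinical: pd.DataFrame, groups: pd.Series,
                      binary_vars: list[str] | None = None,
                      continuous_vars: list[str] | None = None) -> pd.DataFrame:
    """Score-group association report over named clinical variables.

    ``groups`` maps sample id -> "low"/"high" (median-split labels).
    Binary variables get the uncorrected chi-square (with Fisher alongside);
    continuous variables get the Mann-Whitney test and per-group medians.
    Samples missing a variable are excluded from that variable's test
    (per-variable denominators).
    """
    groups = groups.reindex(clinical.index)
    if groups.isna().any():
        raise ValueError("every clinical sample needs a group label")
    low = groups == "low"
    high = groups == "high"
    rows = []
    for var in binary_vars or []:
        v = clinical[var]
        ok = v.notna()
        tab = np.array([
            [int(((v == 1) & low & ok).sum()), int(((v == 0) & low & ok).sum())],
            [int(((v == 1) & high & ok).sum()), int(((v == 0) & high & ok).sum())],
        ])
        try:
            stat, p = chisq_2x2(tab)  # rows = groups, cols = present/absent
        except ValueError:
            stat, p = np.nan, np.nan
        rows.append({"variable": var, "kind": "binary",
                     "n_low": int((low & ok).sum()), "n_high": int((high & ok).sum()),
                     "low_pos": int(tab[0, 0]), "high_pos": int(tab[1, 0]),
                     "statistic": stat, "p": p, "fisher_p": fisher_2x2(tab)})
    for var in continuous_vars or []:
        v = clinical[var]
        ok = v.notna()
        u, p = mann_whitney(v[ok].to_numpy(), groups[ok].to_numpy())
        rows.append({"variable": var, "kind": "continuous",
                     "n_low": int((low & ok).sum()), "n_high": int((high & ok).sum()),
                     "low_pos": float(v[low & ok].median()),
                     "high_pos": float(v[high & ok].median()),
                     "statistic": u, "p": p, "fisher_p": np.nan})
    return pd.DataFrame(rows).set_index("variable")
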