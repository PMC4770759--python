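"""Two-stage signature discovery.

Stage 1 — response-associated differential expression: per-probe
equal-variance two-sided Student t-test between the refractory (PR) and
remission (GR) groups, with a fold-change gate on the log2 mean
difference.

Stage 2 — survival filtering: for each stage-1 probe, a univariate Cox
proportional-hazards fit of overall survival on the probe's standardized
(z) expression among intensively treated patients; probes with Wald
P < 0.01 form the signature.

No multiple-testing correction is applied at either stage; the whole
scoring system is instead validated globally against a random-gene-set
permutation null (see :mod:`mrnasig.permutation`).
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

from .containers import ExpressionMatrix, ZMatrix
from .survival import CoxFitError, univariate_cox

__all__ = ["differential_expression", "cox_filter"]


def differential_expression(
    expr: ExpressionMatrix,
    group_a,
    group_b,
    p_thresh: float = 0.05,
    fold_thresh: float = 2.0,
) -> pd.DataFrame:
    """Per-probe Student t-test between two sample groups on log2 values.

    Parameters
    ----------
    group_a, group_b : sample-id collections
        Disjoint subsets of the matrix columns, each of size >= 2. In the
        discovery use ``group_a`` is the poor-response (PR) group, so a
        positive mean difference means up-regulated in PR.
    p_thresh, fold_thresh : float
        A probe is ``selected`` when its two-sided P is below ``p_thresh``
        AND its absolute log2 mean difference exceeds ``log2(fold_thresh)``.

    Returns
    -------
    DataFrame indexed by probe with columns ``mean_diff`` (log2,
    group_a - group_b), ``fold_change`` (= 2**|mean_diff|), ``t``, ``p``,
    ``direction`` ("up"/"down" in group_a) and boolean ``selected``.
    """
    group_a, group_b = list(group_a), list(group_b)
    overlap = set(group_a) & set(group_b)
    if overlap:
        raise ValueError(f"groups overlap: {sorted(overlap)[:5]}")
    for name, g in (("group_a", group_a), ("group_b", group_b)):
        if len(g) < 2:
            raise ValueError(f"{name} needs at least 2 samples")
        missing = set(g) - set(expr.sample_ids)
        if missing:
            raise ValueError(f"{name} contains unknown samples: {sorted(missing)[:5]}")

    a = expr.values[group_a].to_numpy()
    b = expr.values[group_b].to_numpy()
    t, p = stats.ttest_ind(a, b, axis=1, equal_var=True)
    diff = a.mean(axis=1) - b.mean(axis=1)
    log_gate = np.log2(fold_thresh)
    out = pd.DataFrame(
        {
            "mean_diff": diff,
            "fold_change": 2.0 ** np.abs(diff),
            "t": t,
            "p": p,
            "direction": np.where(diff >= 0, "up", "down"),
            "selected": (p < p_thresh) & (np.abs(diff) > log_gate),
        },
        index=expr.values.index.rename("probe_id"),
    )
    out.attrs["n_selected"] = int(out["selected"].sum())
    out.attrs["all_up_in_group_a"] = bool((out.loc[out["selected"], "direction"] == "up").all())
    return out


def cox_filter(
    de: pd.DataFrame,
    zexpr: ZMatrix,
    clinical: pd.DataFrame,
    p_thresh: float = 0.01,
    time_col: str = "os_time",
    event_col: str = "os_event",
) -> pd.DataFrame:
    """Survival filter: univariate Cox of OS on each DE-selected probe.

    ``clinical`` should already be restricted to the intensively treated
    samples (and transplant-censored if applicable); its index must be a
    subset of the z-matrix samples. Probes whose Wald P falls below
    ``p_thresh`` are retained.

    Returns the signature table, ordered by probe id: ``gene``, ``coef``,
    ``hr``, ``ci_low``, ``ci_high``, ``cox_p``, plus the DE columns
    ``mean_diff`` and ``de_p``. Probes whose fit fails (e.g. separation)
    are dropped.
    """
    if clinical[event_col].sum() < 2:
        raise CoxFitError("fewer than 2 events in the survival subset")
    samples = [s for s in clinical.index if s in set(zexpr.sample_ids)]
    if len(samples) != len(clinical):
        missing = set(clinical.index) - set(zexpr.sample_ids)
        raise ValueError(f"clinical samples missing from expression: {sorted(missing)[:5]}")
    times = clinical.loc[samples, time_col].to_numpy()
    events = clinical.loc[samples, event_col].to_numpy()

    rows = []
    for probe in de.index[de["selected"]]:
        x = zexpr.values.loc[probe, samples].to_numpy()
        try:
            fit = univariate_cox(times, events, x)
        except CoxFitError:
            continue
        if fit.p < p_thresh:
            lo, hi = fit.ci
            rows.append(
                {
                    "probe_id": probe,
                    "gene": zexpr.gene_of(probe),
                    "coef": fit.coef,
                    "hr": fit.hr,
                    "ci_low": lo,
                    "ci_high": hi,
                    "cox_p": fit.p,
                    "mean_diff": de.loc[probe, "mean_diff"],
                    "de_p": de.loc[probe, "p"],
                }
            )
    cols = ["probe_id", "gene", "coef", "hr", "ci_low", "ci_high", "cox_p", "mean_diff", "de_p"]
    sig = pd.DataFrame(rows, columns=cols).set_index("probe_id").sort_index()
    return sig
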