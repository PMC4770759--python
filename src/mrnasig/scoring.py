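"""Equal-weight z-score risk scoring and cohort groupings.

The risk score of a patient is the unweighted sum of their z-values over
the signature probes (or genes, for a collapsed external cohort). Because
each z-row has zero mean, the cohort mean score is ~0 by construction.
Scores are standardized *within* each cohort, so they are comparable only
within a cohort, never across cohorts.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .containers import ExpressionMatrix, ZMatrix, warn

__all__ = ["compute_risk_score", "split_by_median", "extreme_groups", "map_signature"]


def compute_risk_score(zexpr: ZMatrix, signature: pd.DataFrame) -> pd.DataFrame:
    """Per-sample sum of z-values over the signature rows.

    ``signature`` is indexed by probe (or gene) id as produced by
    :func:`mrnasig.discovery.cox_filter` or :func:`map_signature`; any
    index-like of row ids also works.

    Returns a DataFrame indexed by sample with a single ``score`` column;
    use :func:`split_by_median` / :func:`extreme_groups` to add groupings.
    """
    ids = list(signature.index if isinstance(signature, pd.DataFrame) else signature)
    if not ids:
        raise ValueError("empty signature: nothing to score")
    missing = [i for i in ids if i not in zexpr.values.index]
    if missing:
        raise KeyError(f"signature members absent from matrix: {missing[:5]}"
                       " (collapse/map the signature first)")
    score = zexpr.values.loc[ids].sum(axis=0)
    # rename_axis (not .name assignment) so the matrix's shared column
    # Index object is never mutated
    return pd.DataFrame({"score": score}).rename_axis("sample_id")


def split_by_median(scores: pd.DataFrame) -> pd.DataFrame:
    """Median dichotomization: score > median -> "high", <= median -> "low".

    For an even cohort with distinct scores this yields equal halves. With
    all scores tied everyone lands in "low" and a warning is emitted.
    """
    if len(scores) < 2:
        raise ValueError("median split requires at least 2 samples")
    out = scores.copy()
    med = out["score"].median()
    out["median_group"] = np.where(out["score"] > med, "high", "low")
    if (out["median_group"] == "low").all():
        warn("split_by_median: all scores at or below the median; everyone 'low'")
    return out


def extreme_groups(scores: pd.DataFrame, k_sd: float = 1.0) -> pd.DataFrame:
    """Mean +/- k_sd tails: high_risk above, low_risk below, middle otherwise."""
    if len(scores) < 3:
        raise ValueError("extreme_groups requires at least 3 samples")
    out = scores.copy()
    m = out["score"].mean()
    s = out["score"].std(ddof=1)
    out["extreme_group"] = np.select(
        [out["score"] > m + k_sd * s, out["score"] < m - k_sd * s],
        ["high_risk", "low_risk"],
        default="middle",
    )
    return out


def map_signature(signature: pd.DataFrame, target: ExpressionMatrix) -> pd.DataFrame:
    """Transfer a signature to a gene-level target cohort by gene symbol.

    The target must be collapsed to one row per gene (its index holds gene
    symbols). Signature members whose gene symbol is absent are dropped with
    a warning — matching is exact, never fuzzy; supply an alias table
    upstream if symbols differ between platforms.

    Returns the signature subset re-indexed by gene symbol, with the
    original probe id kept in a ``source_probe`` column.
    """
    if "gene" not in signature.columns:
        raise ValueError("signature table must carry a 'gene' column")
    present = signature["gene"].isin(target.values.index)
    dropped = signature.loc[~present, "gene"].tolist()
    if dropped:
        warn(f"map_signature: {len(dropped)} signature genes not in target: {dropped}")
    mapped = signature.loc[present].copy()
    if mapped.empty:
        raise ValueError("no signature genes could be mapped to the target cohort")
    mapped["source_probe"] = mapped.index
    mapped = mapped.set_index("gene", drop=False)
    mapped.index.name = "gene_id"
    return mapped
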