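"""Expression preprocessing: log2 transform, quantile normalization,
CV-based probe collapsing, and per-probe z-standardization.

Two processing paths are supported, mirroring common microarray practice:
discovery-style data stays at probe level after log2 + quantile
normalization, while external validation-style data is additionally
collapsed to one "most informative" probe per gene (largest coefficient of
variation) before standardization.

Standard-deviation convention: the sample (n-1) denominator is used
everywhere, including in the coefficient of variation.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .containers import ExpressionMatrix, ZMatrix, warn

__all__ = ["log2_transform", "quantile_normalize", "collapse_probes_by_cv", "z_transform"]


def log2_transform(raw: ExpressionMatrix, offset: float = 0.0) -> ExpressionMatrix:
    """Element-wise ``log2(raw + offset)``; metadata preserved.

    Raises if any cell is non-positive after the offset, naming the
    offending probe/sample.
    """
    if offset < 0:
        raise ValueError("offset must be non-negative")
    arr = raw.values.to_numpy() + offset
    if (arr <= 0).any():
        i, j = np.argwhere(arr <= 0)[0]
        raise ValueError(
            f"non-positive value after offset at probe {raw.values.index[i]!r}, "
            f"sample {raw.values.columns[j]!r}: {arr[i, j]!r}"
        )
    out = pd.DataFrame(np.log2(arr), index=raw.values.index, columns=raw.values.columns)
    return ExpressionMatrix(out, raw.probe_to_gene)


def quantile_normalize(expr: ExpressionMatrix) -> ExpressionMatrix:
    """Quantile-normalize columns to a shared reference distribution.

    The reference is the mean across samples of the per-rank sorted values;
    every sample column then carries exactly that sorted vector, placed in
    its original rank order. Ties within a column receive the mean of the
    reference values over the tied ranks.
    """
    arr = expr.values.to_numpy(dtype=float)
    n_probes, n_samples = arr.shape
    if n_samples < 2:
        warn("quantile_normalize: single sample, returning input unchanged")
        return ExpressionMatrix(expr.values.copy(), expr.probe_to_gene)

    reference = np.sort(arr, axis=0).mean(axis=1)
    out = np.empty_like(arr)
    for j in range(n_samples):
        order = np.argsort(arr[:, j], kind="mergesort")
        col = np.empty(n_probes)
        col[order] = reference
        # average reference values over groups of tied input values
        s = pd.Series(col).groupby(pd.Series(arr[:, j])).transform("mean")
        out[:, j] = s.to_numpy()
    res = pd.DataFrame(out, index=expr.values.index, columns=expr.values.columns)
    return ExpressionMatrix(res, expr.probe_to_gene)


def collapse_probes_by_cv(expr: ExpressionMatrix) -> ExpressionMatrix:
    """Collapse to one row per gene: the probe with the largest CV.

    CV is the per-probe standard deviation (ddof=1) divided by the
    per-probe mean. Probes without gene annotation are dropped; a gene
    whose probes all have zero mean (CV undefined) is excluded with a
    warning. The returned matrix is indexed by gene symbol and its
    annotation maps each gene to the winning probe id.
    """
    if not expr.probe_to_gene:
        raise ValueError("collapse_probes_by_cv requires probe_to_gene annotation")
    values = expr.values
    annotated = [p for p in values.index if p in expr.probe_to_gene]
    if not annotated:
        raise ValueError("no annotated probes to collapse")
    sub = values.loc[annotated]
    means = sub.mean(axis=1)
    sds = sub.std(axis=1, ddof=1)
    genes = pd.Series({p: expr.probe_to_gene[p] for p in annotated})

    rows, gene_to_probe = [], {}
    for gene, probes in genes.groupby(genes).groups.items():
        m = means.loc[probes]
        defined = m != 0
        if not defined.any():
            warn(f"collapse_probes_by_cv: gene {gene!r} has zero-mean probes only; excluded")
            continue
        cv = sds.loc[probes][defined] / m[defined]
        winner = cv.idxmax()
        rows.append(pd.Series(sub.loc[winner], name=gene))
        gene_to_probe[gene] = winner
    out = pd.DataFrame(rows)
    out.index.name = "gene"
    return ExpressionMatrix(out.sort_index(), gene_to_probe)


def z_transform(expr: ExpressionMatrix) -> ZMatrix:
    """Standardize each probe row: subtract the mean, divide by the sd.

    Zero-variance rows become all zeros (with a warning) rather than NaN.
    """
    if expr.shape[1] < 2:
        raise ValueError("z_transform requires at least 2 samples")
    arr = expr.values.to_numpy(dtype=float)
    means = arr.mean(axis=1, keepdims=True)
    sds = arr.std(axis=1, ddof=1, keepdims=True)
    zero = sds[:, 0] == 0
    if zero.any():
        names = list(expr.values.index[zero][:5])
        warn(f"z_transform: {int(zero.sum())} zero-variance probes set to 0 (e.g. {names})")
    sds[sds == 0] = 1.0
    z = (arr - means) / sds
    out = pd.DataFrame(z, index=expr.values.index, columns=expr.values.columns)
    return ZMatrix(out, expr.probe_to_gene, zero_variance_probes=list(expr.values.index[zero]))
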