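"""Gene-set enrichment by the weighted running-sum (GSEA-style) statistic
with gene-permutation significance.

Genes are ranked by the signed t statistic of differential expression
between two groups (up in the first group at the top). Walking down the
ranked list, the running sum increments by ``|metric|^p / sum(|metric|^p
over set members)`` at each set member and decrements by ``1/(N - |set|)``
elsewhere; the enrichment score (ES) is the signed extremum and the
leading edge is the set members at or before it. Significance comes from
random same-size gene sets drawn from the ranked universe (gene
permutation, not phenotype permutation), one-sided on the observed ES
sign by default.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .containers import ExpressionMatrix
from .discovery import differential_expression

__all__ = ["EnrichmentResult", "rank_genes", "enrichment_score", "enrichment_p", "read_gmt"]


@dataclass
class EnrichmentResult:
    es: float
    running_sum: np.ndarray
    leading_edge: list[str]
    empirical_p: float | None = None
    n_perm: int = 0
    null_es: np.ndarray | None = field(default=None, repr=False)

    @property
    def p_label(self) -> str:
        if self.empirical_p is None:
            raise ValueError("no permutation P computed")
        if self.empirical_p == 0.0:
            return f"< {1.0 / self.n_perm:g}"
        return f"{self.empirical_p:.4g}"


def rank_genes(expr: ExpressionMatrix, group_a, group_b) -> pd.Series:
    """Rank genes by signed t statistic, descending (up in group_a first).

    Returns a Series: index = gene/probe ids in rank order, values = t.
    """
    de = differential_expression(expr, group_a, group_b, p_thresh=1.0, fold_thresh=1.0)
    return de["t"].sort_values(ascending=False, kind="mergesort")


def _running_sum(ranked: pd.Series, gene_set, p: float) -> tuple[np.ndarray, np.ndarray]:
    genes = ranked.index.to_numpy()
    metric = ranked.to_numpy(dtype=float)
    in_set = np.isin(genes, list(gene_set))
    if not in_set.any():
        raise ValueError("gene set does not intersect the ranked list")
    n = len(genes)
    n_hit = int(in_set.sum())
    if n_hit == n:
        raise ValueError("gene set covers the whole ranked list")
    w = np.abs(metric) ** p
    hit_total = w[in_set].sum()
    if hit_total == 0:
        # all hit metrics are exactly 0 (possible only with p > 0): fall
        # back to equal hit increments, the p = 0 convention
        w = np.ones(n)
        hit_total = float(n_hit)
    steps = np.where(in_set, w / hit_total, -1.0 / (n - n_hit))
    return np.cumsum(steps), in_set


def enrichment_score(ranked: pd.Series, gene_set, p: float = 1.0) -> EnrichmentResult:
    """Enrichment score and running-sum curve for one gene set (no P)."""
    rs, in_set = _running_sum(ranked, gene_set, p)
    i_max = int(np.argmax(rs))
    i_min = int(np.argmin(rs))
    es = rs[i_max] if rs[i_max] >= -rs[i_min] else rs[i_min]
    genes = ranked.index.to_numpy()
    if es >= 0:
        lead = genes[: i_max + 1][in_set[: i_max + 1]]
    else:
        lead = genes[i_min:][in_set[i_min:]]
    return EnrichmentResult(es=float(es), running_sum=rs, leading_edge=list(lead))


def enrichment_p(
    ranked: pd.Series,
    gene_set,
    n_perm: int = 2000,
    seed: int = 0,
    p: float = 1.0,
    two_sided: bool = False,
) -> EnrichmentResult:
    """Gene-permutation significance of the enrichment score.

    Null sets are random same-size draws from the ranked universe. By
    default the P is one-sided on the observed ES sign (fraction of null
    ES at least as extreme on that side); ``two_sided=True`` compares
    absolute values instead.
    """
    obs = enrichment_score(ranked, gene_set, p=p)
    genes = ranked.index.to_numpy()
    size = int(np.isin(genes, list(gene_set)).sum())
    rng = np.random.default_rng(seed)
    null = np.empty(n_perm)
    for i in range(n_perm):
        rand = rng.choice(genes, size=size, replace=False)
        null[i] = enrichment_score(ranked, rand, p=p).es
    if two_sided:
        pval = float(np.mean(np.abs(null) >= abs(obs.es)))
    elif obs.es >= 0:
        pval = float(np.mean(null >= obs.es))
    else:
        pval = float(np.mean(null <= obs.es))
    return EnrichmentResult(es=obs.es, running_sum=obs.running_sum,
                            leading_edge=obs.leading_edge, empirical_p=pval,
                            n_perm=n_perm, null_es=null)


def read_gmt(path) -> dict[str, list[str]]:
    """Read gene sets from a GMT file: name <tab> description <tab> genes..."""
    sets: dict[str, list[str]] = {}
    with open(path) as fh:
        for line in fh:
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 3 or not parts[0]:
                continue
            sets[parts[0]] = [g for g in parts[2:] if g]
    return sets
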