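"""Model/Results interface over the discovery pipeline.

:class:`SignatureModel` holds a cohort (expression + clinical) and the
discovery thresholds; :meth:`SignatureModel.fit` runs the two-stage
selection plus scoring and survival analysis and returns a
:class:`SignatureResults` carrying the signature table (per-probe hazard
ratios with confidence intervals), the per-sample risk scores and
groupings, the Kaplan-Meier/log-rank comparison of the median split, and
the univariate Cox fit of overall survival on the continuous score.
Permutation validation, association reports, extreme-group differential
expression, enrichment and external-cohort transfer hang off the results
object.

Analysis populations follow the discovery design: associations use all
samples; survival analyses use only the intensively treated subset, with
transplanted patients censored at the day of stem-cell infusion.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .association import association_table
from .containers import ExpressionMatrix, ZMatrix, validate_clinical
from .discovery import cox_filter, differential_expression
from .enrichment import enrichment_p, rank_genes
from .permutation import PermutationResult, permutation_null
from .preprocess import collapse_probes_by_cv, z_transform
from .scoring import compute_risk_score, extreme_groups, map_signature, split_by_median
from .survival import apply_hsct_censoring, cox_fit, km_estimate, logrank_test

__all__ = ["SignatureModel", "SignatureResults", "score_external_cohort"]


class SignatureModel:
    """Prognostic-signature discovery model for one cohort.

    Parameters
    ----------
    expression : ExpressionMatrix
        Probe-level log2 expression (already normalized).
    clinical : pandas.DataFrame
        Per-sample clinical table (see
        :data:`mrnasig.containers.CLINICAL_REQUIRED_COLUMNS`).
    de_p, fold, cox_p : float
        Stage thresholds: t-test P, fold change, and univariate Cox P.
    """

    def __init__(self, expression: ExpressionMatrix, clinical: pd.DataFrame,
                 de_p: float = 0.05, fold: float = 2.0, cox_p: float = 0.01):
        for name, v in (("de_p", de_p), ("cox_p", cox_p)):
            if not 0 < v < 1:
                raise ValueError(f"{name} must be in (0, 1)")
        validate_clinical(clinical)
        missing = set(clinical.index) - set(expression.sample_ids)
        if missing:
            raise ValueError(f"clinical samples absent from expression: {sorted(missing)[:5]}")
        self.expression = expression
        self.clinical = clinical
        self.de_p = de_p
        self.fold = fold
        self.cox_p = cox_p

    @classmethod
    def from_synthetic(cls, config=None, **kwargs):
        """Build the model from a synthetic cohort; also returns the truth.

        Returns ``(model, ground_truth)``.
        """
        from .cohort import CohortConfig, generate_cohort

        if config is None:
            config = CohortConfig(**{k: v for k, v in kwargs.items()
                                     if k in CohortConfig.__dataclass_fields__})
            kwargs = {k: v for k, v in kwargs.items()
                      if k not in CohortConfig.__dataclass_fields__}
        expr, clinical, truth = generate_cohort(config)
        return cls(expr, clinical, **kwargs), truth

    # -- population helpers ------------------------------------------------
    def survival_subset(self) -> pd.DataFrame:
        """Treated patients, transplant-censored: the survival population."""
        treated = self.clinical[self.clinical["treated_intensively"].astype(bool)]
        return apply_hsct_censoring(treated)

    def response_groups(self) -> tuple[list[str], list[str]]:
        """(PR sample ids, GR sample ids) for the differential stage."""
        pr = self.clinical.index[self.clinical["response"] == "PR"].tolist()
        gr = self.clinical.index[self.clinical["response"] == "GR"].tolist()
        return pr, gr

    def fit(self) -> "SignatureResults":
        """Run discovery: DE -> Cox filter -> score -> groups -> survival."""
        zexpr = z_transform(self.expression)
        pr, gr = self.response_groups()
        de = differential_expression(self.expression, pr, gr,
                                     p_thresh=self.de_p, fold_thresh=self.fold)
        surv = self.survival_subset()
        signature = cox_filter(de, zexpr, surv, p_thresh=self.cox_p)
        if signature.empty:
            scores = None
        else:
            scores = compute_risk_score(zexpr, signature)
            scores = extreme_groups(split_by_median(scores))
        return SignatureResults(self, zexpr, de, signature, scores)


class SignatureResults:
    """Fitted discovery results; see :class:`SignatureModel`."""

    def __init__(self, model: SignatureModel, zexpr: ZMatrix, de: pd.DataFrame,
                 signature: pd.DataFrame, scores: pd.DataFrame | None):
        self.model = model
        self.zexpr = zexpr
        self.de = de
        self.signature = signature
        self.scores = scores
        self._survival = model.survival_subset()
        self.km = None
        self.logrank = None
        self.score_cox = None
        if scores is not None:
            sub = self._survival
            labels = scores.loc[sub.index, "median_group"]
            self.km = km_estimate(sub["os_time"], sub["os_event"], labels)
            if sub["os_event"].sum() > 0 and labels.nunique() > 1:
                self.logrank = logrank_test(sub["os_time"], sub["os_event"], labels)
            tab = sub.copy()
            tab["mrna_score"] = scores.loc[sub.index, "score"]
            self.score_cox = cox_fit(tab, ["mrna_score"])

    # -- diagnostics & downstream analyses --------------------------------
    @property
    def n_selected_probes(self) -> int:
        return int(self.de.attrs["n_selected"])

    def permutation_test(self, n_iter: int = 10_000, seed: int = 0) -> PermutationResult:
        """Random-gene-set null for the fitted score (see
        :func:`mrnasig.permutation.permutation_null`)."""
        if self.signature.empty:
            raise ValueError("empty signature; nothing to validate")
        return permutation_null(self.zexpr, self._survival, self.signature,
                                n_iter=n_iter, seed=seed)

    def associations(self, binary_vars=None, continuous_vars=None) -> pd.DataFrame:
        """Score-group vs clinical/mutation associations over all samples."""
        if self.scores is None:
            raise ValueError("no scores fitted")
        if binary_vars is None:
            skip = {"os_time", "os_event", "dfs_time", "dfs_event", "response",
                    "treated_intensively", "hsct_time", "age"}
            binary_vars = [c for c in self.model.clinical.columns
                           if c not in skip and
                           self.model.clinical[c].dropna().isin([0, 1]).all()]
        if continuous_vars is None:
            continuous_vars = [c for c in ("age",) if c in self.model.clinical.columns]
        return association_table(self.model.clinical, self.scores["median_group"],
                                 binary_vars=binary_vars, continuous_vars=continuous_vars)

    def multivariate_cox(self, covariates: list[str]) -> pd.DataFrame:
        """Multivariate Cox of OS on the score plus named covariates."""
        tab = self._survival.copy()
        tab["mrna_score"] = self.scores.loc[tab.index, "score"]
        return cox_fit(tab, ["mrna_score"] + list(covariates))

    def extreme_group_de(self, p_thresh: float | None = None,
                         fold_thresh: float | None = None) -> pd.DataFrame:
        """Differential expression between the mean +/- 1 SD score tails."""
        if self.scores is None:
            raise ValueError("no scores fitted")
        hi = self.scores.index[self.scores["extreme_group"] == "high_risk"].tolist()
        lo = self.scores.index[self.scores["extreme_group"] == "low_risk"].tolist()
        return differential_expression(
            self.model.expression, hi, lo,
            p_thresh=self.de_p if p_thresh is None else p_thresh,
            fold_thresh=self.fold if fold_thresh is None else fold_thresh,
        )

    # convenience passthroughs used by extreme_group_de defaults
    de_p = property(lambda self: self.model.de_p)
    fold = property(lambda self: self.model.fold)

    def enrich(self, gene_set, n_perm: int = 2000, seed: int = 0, weight: float = 1.0):
        """Running-sum enrichment of a gene set in the extreme-group ranking.

        The ranking is probe-level; set membership is resolved through the
        probe->gene annotation so ``gene_set`` holds gene symbols.
        """
        hi = self.scores.index[self.scores["extreme_group"] == "high_risk"].tolist()
        lo = self.scores.index[self.scores["extreme_group"] == "low_risk"].tolist()
        ranked = rank_genes(self.model.expression, hi, lo)
        gene_of = self.model.expression.gene_of
        ranked.index = pd.Index([gene_of(p) or p for p in ranked.index])
        return enrichment_p(ranked, gene_set, n_perm=n_perm, seed=seed, p=weight)

    def score_external(self, expression: ExpressionMatrix, clinical: pd.DataFrame):
        """Transfer the fitted signature to an external cohort."""
        return score_external_cohort(self.signature, expression, clinical)

    def summary(self) -> str:
        """Plain-text summary table of the fit."""
        lines = ["Prognostic signature discovery", "=" * 34]
        pr, gr = self.model.response_groups()
        n = len(self.model.clinical)
        lines.append(f"Samples: {n} (treated {int(self.model.clinical['treated_intensively'].sum())}, "
                     f"PR {len(pr)}, GR {len(gr)})")
        lines.append(f"Stage 1 (t-test P < {self.model.de_p}, fold > {self.model.fold}): "
                     f"{self.n_selected_probes} probes selected"
                     + (" (all up-regulated in PR)" if self.de.attrs["all_up_in_group_a"] else ""))
        lines.append(f"Stage 2 (univariate Cox P < {self.model.cox_p}): "
                     f"{len(self.signature)} probes in signature")
        if not self.signature.empty:
            lines.append("")
            tab = self.signature[["gene", "cox_p", "hr", "ci_low", "ci_high"]].copy()
            lines.append(tab.to_string(float_format=lambda v: f"{v:.3g}"))
        if self.logrank is not None:
            chi, p = self.logrank
            meds = {g: df.attrs["median"] for g, df in self.km.items()}
            med_str = ", ".join(f"{g}: {m if isinstance(m, str) else f'{m:.1f} mo'}"
                                for g, m in sorted(meds.items()))
            lines.append("")
            lines.append(f"Median-split log-rank: chi2 = {chi:.3f}, P = {p:.3g}")
            lines.append(f"Median OS ({med_str})")
        if self.score_cox is not None:
            row = self.score_cox.loc["mrna_score"]
            lines.append(f"Cox on continuous score: HR {row['hr']:.3f} per unit "
                         f"(95% CI {row['ci_low']:.3f}-{row['ci_high']:.3f}), P = {row['p']:.3g}")
        return "\n".join(lines)

    def plot_km(self, ax=None):  # pragma: no cover - thin plotting shim
        """Step plot of the median-split Kaplan-Meier curves."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        for g, df in (self.km or {}).items():
            ax.step(df["time"], df["survival"], where="post", label=str(g))
        ax.set_xlabel("months")
        ax.set_ylabel("overall survival")
        ax.set_ylim(0, 1.02)
        ax.legend(title="score group")
        return ax


def score_external_cohort(signature: pd.DataFrame, expression: ExpressionMatrix,
                          clinical: pd.DataFrame) -> dict:
    """Validate a signature on an external probe-level cohort.

    Pipeline: collapse probes to genes by CV -> z-transform -> match the
    signature by gene symbol -> equal-weight score -> per-cohort median
    split -> Kaplan-Meier + log-rank + univariate Cox on the continuous
    score.

    Returns a dict with keys ``scores``, ``mapped_signature``, ``km``,
    ``logrank`` (chi2, P), and ``cox`` (a one-row table: HR, CI, P).
    """
    validate_clinical(clinical)
    collapsed = collapse_probes_by_cv(expression)
    zexpr = z_transform(collapsed)
    mapped = map_signature(signature, collapsed)
    scores = split_by_median(compute_risk_score(zexpr, mapped))
    sub = apply_hsct_censoring(clinical)
    labels = scores.loc[sub.index, "median_group"]
    km = km_estimate(sub["os_time"], sub["os_event"], labels)
    logrank = logrank_test(sub["os_time"], sub["os_event"], labels)
    tab = sub.copy()
    tab["mrna_score"] = scores.loc[sub.index, "score"]
    cox = cox_fit(tab, ["mrna_score"])
    return {"scores": scores, "mapped_signature": mapped, "km": km,
            "logrank": logrank, "cox": cox}
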