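"""Core data containers: expression matrices and the clinical table contract.

An :class:`ExpressionMatrix` is a probe x sample matrix of log2-scale
intensities with an optional probe->gene annotation. A :class:`ZMatrix` is the
same shape after per-probe standardization (row mean 0, row sd 1). Clinical
data travels as a plain :class:`pandas.DataFrame` validated by
:func:`validate_clinical`; the required columns are documented there.
"""

from __future__ import annotations

import io
import warnings
from typing import Mapping

import numpy as np
import pandas as pd

__all__ = [
    "ExpressionMatrix",
    "ZMatrix",
    "validate_clinical",
    "read_expression_tsv",
    "read_annotation_tsv",
    "CLINICAL_REQUIRED_COLUMNS",
]

#: Columns every clinical table must carry. ``response`` takes values
#: ``"GR"`` (continuous complete remission), ``"PR"`` (refractory to
#: induction) or ``"other"``; ``treated_intensively`` is a boolean flag
#: selecting the subset eligible for survival analysis.
CLINICAL_REQUIRED_COLUMNS = (
    "os_time",
    "os_event",
    "response",
    "treated_intensively",
)


class ExpressionMatrix:
    """Probe x sample expression matrix on log2 scale.

    Parameters
    ----------
    values : pandas.DataFrame
        Rows indexed by unique probe ids, columns by unique sample ids.
    probe_to_gene : mapping, optional
        Partial map from probe id to gene symbol. Probes absent from the
        map are treated as unannotated.
    """

    def __init__(self, values: pd.DataFrame, probe_to_gene: Mapping[str, str] | None = None):
        if values.index.has_duplicates:
            raise ValueError("duplicate probe ids in expression matrix")
        if values.columns.has_duplicates:
            raise ValueError("duplicate sample ids in expression matrix")
        self.values = values.astype(float)
        if probe_to_gene is None:
            probe_to_gene = {}
        self.probe_to_gene = dict(probe_to_gene)

    # -- basic protocol ----------------------------------------------------
    @property
    def probe_ids(self) -> pd.Index:
        return self.values.index

    @property
    def sample_ids(self) -> pd.Index:
        return self.values.columns

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        n_ann = sum(1 for p in self.probe_ids if p in self.probe_to_gene)
        return (
            f"<{type(self).__name__} {self.shape[0]} probes x "
            f"{self.shape[1]} samples ({n_ann} annotated)>"
        )

    def gene_of(self, probe_id: str) -> str | None:
        return self.probe_to_gene.get(probe_id)

    def subset_samples(self, sample_ids) -> "ExpressionMatrix":
        return type(self)(self.values[list(sample_ids)], self.probe_to_gene)

    def subset_probes(self, probe_ids) -> "ExpressionMatrix":
        return type(self)(self.values.loc[list(probe_ids)], self.probe_to_gene)

    def require_finite(self) -> None:
        if not np.isfinite(self.values.to_numpy()).all():
            bad = np.argwhere(~np.isfinite(self.values.to_numpy()))[0]
            raise ValueError(
                "non-finite expression value at probe "
                f"{self.values.index[bad[0]]!r}, sample {self.values.columns[bad[1]]!r}"
            )

    # -- I/O ---------------------------------------------------------------
    def to_tsv(self, path) -> None:
        """Write the probe x sample TSV with a header row of sample ids."""
        self.values.to_csv(path, sep="\t", index_label="probe_id")

    def annotation_to_tsv(self, path) -> None:
        pd.Series(self.probe_to_gene, name="gene").rename_axis("probe_id").to_csv(path, sep="\t")


class ZMatrix(ExpressionMatrix):
    """Per-probe standardized expression: row mean 0, row sd 1 (ddof=1).

    Rows of originally zero variance are all-zero and are listed in
    ``zero_variance_probes``.
    """

    def __init__(self, values, probe_to_gene=None, zero_variance_probes=()):
        super().__init__(values, probe_to_gene)
        self.zero_variance_probes = list(zero_variance_probes)
        self._check_standardized()

    def _check_standardized(self, tol: float = 1e-9) -> None:
        arr = self.values.to_numpy()
        means = arr.mean(axis=1)
        sds = arr.std(axis=1, ddof=1)
        nonzero = ~np.isin(self.values.index, self.zero_variance_probes)
        if np.abs(means).max(initial=0.0) > tol:
            raise ValueError("ZMatrix rows must have zero mean")
        if nonzero.any() and np.abs(sds[nonzero] - 1.0).max() > tol:
            raise ValueError("ZMatrix rows must have unit standard deviation")


def validate_clinical(clinical: pd.DataFrame) -> pd.DataFrame:
    """Validate the per-sample clinical table contract.

    Checks required columns, non-negative times, events coded 0/1, and that
    transplant times never exceed the recorded survival time.
    """
    missing = [c for c in CLINICAL_REQUIRED_COLUMNS if c not in clinical.columns]
    if missing:
        raise ValueError(f"clinical table missing required columns: {missing}")
    if (clinical["os_time"] < 0).any():
        raise ValueError("negative os_time in clinical table")
    if not clinical["os_event"].isin([0, 1]).all():
        raise ValueError("os_event must be coded 0/1")
    if "hsct_time" in clinical.columns:
        has = clinical["hsct_time"].notna()
        if (clinical.loc[has, "hsct_time"] > clinical.loc[has, "os_time"]).any():
            raise ValueError("hsct_time exceeds os_time for some samples")
    bad = ~clinical["response"].isin(["GR", "PR", "other"])
    if bad.any():
        raise ValueError(f"unknown response labels: {sorted(clinical.loc[bad, 'response'].unique())}")
    return clinical


def read_expression_tsv(path, annotation_path=None) -> ExpressionMatrix:
    """Read a probe x sample TSV (first column probe ids, header sample ids).

    Lines starting with ``!`` (the GEO series-matrix comment convention) are
    skipped, as are the ``!series_matrix_table_begin/end`` sentinels.
    """
    with open(path) as fh:
        lines = [ln for ln in fh if not ln.startswith("!")]
    df = pd.read_csv(io.StringIO("".join(lines)), sep="\t", index_col=0)
    df.index = df.index.astype(str)
    annot = read_annotation_tsv(annotation_path) if annotation_path is not None else None
    return ExpressionMatrix(df, annot)


def read_annotation_tsv(path) -> dict[str, str]:
    """Read a two-column probe->gene annotation TSV (header optional)."""
    df = pd.read_csv(path, sep="\t", dtype=str, comment="!")
    if df.shape[1] < 2:
        raise ValueError("annotation file must have two columns: probe_id, gene")
    probe_col, gene_col = df.columns[:2]
    df = df.dropna(subset=[gene_col])
    return dict(zip(df[probe_col].astype(str), df[gene_col].astype(str)))


def warn(message: str) -> None:
    """Emit a package-namespaced UserWarning (single funnel for modules)."""
    warnings.warn(message, UserWarning, stacklevel=3)
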