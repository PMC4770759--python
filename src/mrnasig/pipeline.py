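"""End-to-end discovery runs with on-disk artifacts and a run manifest.

`run_discovery` wires the stages together — preprocess, differential
expression, survival filter, risk scoring, median split, Kaplan-Meier /
log-rank, Cox on the continuous score, the random-gene-set permutation
test, and extreme-group differential expression — and writes every table
to the output directory together with a manifest recording the
configuration, the master seed and package versions. A master seed fans
out to per-stage seeds through fixed labels, so reruns with the same seed
are byte-identical.
"""

from __future__ import annotations

import json
import platform
import zlib
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .cohort import CohortConfig, generate_cohort
from .containers import ExpressionMatrix
from .model import SignatureModel, score_external_cohort

__all__ = ["PipelineConfig", "run_discovery", "stage_seed"]


@dataclass(frozen=True)
class PipelineConfig:
    """Thresholds, iteration counts and the master seed for a full run."""

    de_p: float = 0.05
    fold: float = 2.0
    cox_p: float = 0.01
    n_iter_permutation: int = 10_000
    n_perm_enrichment: int = 2000
    seed: int = 0
    cohort: CohortConfig | None = None  # synthetic input when no files given
    outdir: str | Path = "mrnasig_run"

    def __post_init__(self):
        for name in ("de_p", "cox_p"):
            v = getattr(self, name)
            if not 0 < v < 1:
                raise ValueError(f"{name} must be in (0, 1)")


def stage_seed(master: int, label: str) -> int:
    """Derive a per-stage seed from the master seed and a fixed label."""
    child = np.random.SeedSequence(master, spawn_key=(zlib.crc32(label.encode()),))
    return int(child.generate_state(1)[0] & 0x7FFFFFFF)


def _write_km(km: dict, path: Path) -> None:
    frames = []
    for g, df in km.items():
        d = df.copy()
        d.insert(0, "group", g)
        d["median"] = df.attrs["median"]
        frames.append(d)
    pd.concat(frames, ignore_index=True).to_csv(path, index=False)


def run_discovery(config: PipelineConfig,
                  expression: ExpressionMatrix | None = None,
                  clinical: pd.DataFrame | None = None) -> dict:
    """Run the whole discovery pipeline and write artifacts.

    With no explicit inputs, a synthetic cohort is generated from
    ``config.cohort`` (re-seeded from the master seed). Returns a dict of
    in-memory results (model, results, permutation, extreme-group DE,
    ground truth when synthetic).
    """
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    truth = None
    if expression is None or clinical is None:
        cohort_cfg = config.cohort or CohortConfig()
        cohort_cfg = type(cohort_cfg)(**{**asdict_cohort(cohort_cfg),
                                         "seed": stage_seed(config.seed, "cohort")})
        expression, clinical, truth = generate_cohort(cohort_cfg)
        expression.to_tsv(outdir / "expression.tsv")
        expression.annotation_to_tsv(outdir / "annotation.tsv")
        clinical.to_csv(outdir / "clinical.csv")

    model = SignatureModel(expression, clinical, de_p=config.de_p,
                           fold=config.fold, cox_p=config.cox_p)
    results = model.fit()

    results.de.to_csv(outdir / "differential_expression.tsv", sep="\t")
    results.signature.to_csv(outdir / "signature.tsv", sep="\t")

    perm = None
    extreme_de = None
    if results.scores is not None and not results.signature.empty:
        results.scores.to_csv(outdir / "risk_scores.csv")
        _write_km(results.km, outdir / "km_curves.csv")
        results.score_cox.to_csv(outdir / "score_cox.csv")
        with open(outdir / "logrank.json", "w") as fh:
            json.dump({"chi_square": results.logrank[0], "p": results.logrank[1]}, fh, indent=2)
        perm = results.permutation_test(n_iter=config.n_iter_permutation,
                                        seed=stage_seed(config.seed, "permutation"))
        with open(outdir / "permutation.json", "w") as fh:
            json.dump({"observed_cox_p": perm.observed_stat,
                       "empirical_p": perm.empirical_p,
                       "label": perm.label, "n_iter": perm.n_iter}, fh, indent=2)
        np.savetxt(outdir / "permutation_null.tsv", perm.null_stats, fmt="%.6g")
        extreme_de = results.extreme_group_de()
        extreme_de.to_csv(outdir / "extreme_group_de.tsv", sep="\t")
        assoc = results.associations()
        assoc.to_csv(outdir / "associations.csv")

    manifest = {
        "package": "mrnasig",
        "version": __version__,
        "python": platform.python_version(),
        "seed": config.seed,
        "thresholds": {"de_p": config.de_p, "fold": config.fold, "cox_p": config.cox_p},
        "n_iter_permutation": config.n_iter_permutation,
        "synthetic": truth is not None,
        "n_samples": int(expression.shape[1]),
        "n_probes": int(expression.shape[0]),
        "n_selected_probes": results.n_selected_probes,
        "n_signature": int(len(results.signature)),
    }
    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)

    return {"model": model, "results": results, "permutation": perm,
            "extreme_de": extreme_de, "truth": truth, "outdir": outdir}


def asdict_cohort(cfg: CohortConfig) -> dict:
    d = asdict(cfg)
    d["mutation_spec"] = tuple(tuple(m) for m in d["mutation_spec"])
    return d


def validate_external(signature_path, expression: ExpressionMatrix,
                      clinical: pd.DataFrame, outdir: str | Path) -> dict:
    """Score an external cohort from a saved signature table; write report."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    signature = pd.read_csv(signature_path, sep="\t", index_col=0)
    report = score_external_cohort(signature, expression, clinical)
    report["scores"].to_csv(outdir / "external_scores.csv")
    _write_km(report["km"], outdir / "external_km.csv")
    report["cox"].to_csv(outdir / "external_cox.csv")
    with open(outdir / "external_logrank.json", "w") as fh:
        json.dump({"chi_square": report["logrank"][0], "p": report["logrank"][1]}, fh, indent=2)
    return report
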