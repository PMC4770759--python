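"""Model/Results interface, end-to-end pipeline runs, external transfer,
CLI wiring."""

import hashlib
import json
from pathlib import Path

import numpy as np
import pandas as pd
import pytest
from click.testing import CliRunner

from mrnasig import CohortConfig, SignatureModel, generate_cohort, score_external_cohort
from mrnasig.cli import main as cli_main
from mrnasig.containers import read_expression_tsv
from mrnasig.pipeline import PipelineConfig, run_discovery


class TestSignatureModel:
    def test_fit_populates_results(self, default_fit):
        model, truth, results = default_fit
        assert results.n_selected_probes > 0
        assert len(results.signature) > 0
        assert results.scores is not None
        assert set(results.scores.columns) >= {"score", "median_group", "extreme_group"}
        assert results.logrank is not None and results.logrank[1] < 0.05
        hr = results.score_cox.loc["mrna_score", "hr"]
        assert hr > 1.0  # higher score, higher hazard

    def test_summary_mentions_key_quantities(self, default_fit):
        _, _, results = default_fit
        text = results.summary()
        assert "probes selected" in text
        assert "log-rank" in text
        assert "HR" in text

    def test_bad_thresholds_rejected(self, small_cohort):
        expr, clinical, _ = small_cohort
        with pytest.raises(ValueError):
            SignatureModel(expr, clinical, de_p=1.5)

    def test_multivariate_cox_includes_score(self, default_fit):
        _, _, results = default_fit
        table = results.multivariate_cox(["age", "NPM1", "FLT3_ITD"])
        assert list(table.index) == ["mrna_score", "age", "NPM1", "FLT3_ITD"]

    def test_associations_report_mutations(self, default_fit):
        _, _, results = default_fit
        table = results.associations()
        assert {"NPM1", "FLT3_ITD", "ASXL1"} <= set(table.index)
        assert "age" in table.index
        assert table["p"].between(0, 1).all()

    def test_extreme_group_de_and_enrichment(self, default_fit):
        _, truth, results = default_fit
        de = results.extreme_group_de()
        # the planted block separates the score tails by construction
        planted = [p for p in truth.signature_probe_ids if p in de.index]
        assert de.loc[planted, "selected"].mean() > 0.5
        sig_genes = [results.model.expression.gene_of(p)
                     for p in truth.signature_probe_ids]
        enr = results.enrich(sig_genes, n_perm=100, seed=2)
        assert enr.es > 0
        assert enr.empirical_p <= 0.05


class TestExternalTransfer:
    def test_signature_transfers_to_fresh_cohort(self, default_fit):
        _, _, results = default_fit
        expr, clinical, _ = generate_cohort(CohortConfig(seed=77, n_probes=800))
        report = score_external_cohort(results.signature, expr, clinical)
        assert len(report["mapped_signature"]) == len(results.signature)
        assert report["logrank"][1] < 0.05
        assert report["cox"].loc["mrna_score", "hr"] > 1.0

    def test_absent_genes_hard_error(self, default_fit):
        _, _, results = default_fit
        expr, clinical, _ = generate_cohort(
            CohortConfig(seed=78, n_probes=300, n_signature=2))
        # rename all genes so nothing matches
        expr.probe_to_gene = {p: f"X_{g}" for p, g in expr.probe_to_gene.items()}
        with pytest.raises(ValueError, match="no signature genes"):
            with pytest.warns(UserWarning):
                score_external_cohort(results.signature, expr, clinical)

    def test_report_schema(self, default_fit):
        _, _, results = default_fit
        expr, clinical, _ = generate_cohort(CohortConfig(seed=79, n_probes=600))
        report = score_external_cohort(results.signature, expr, clinical)
        assert {"hr", "ci_low", "ci_high", "p"} <= set(report["cox"].columns)
        assert set(report["km"]) == {"low", "high"}


def _hash_dir(path: Path) -> dict:
    return {f.name: hashlib.sha256(f.read_bytes()).hexdigest()
            for f in sorted(path.iterdir()) if f.is_file()}


class TestPipeline:
    def test_run_all_byte_identical_across_reruns(self, tmp_path):
        cohort = CohortConfig(n_samples=80, n_probes=250, seed=0)
        hashes = []
        for sub in ("a", "b"):
            cfg = PipelineConfig(seed=123, n_iter_permutation=40,
                                 cohort=cohort, outdir=tmp_path / sub)
            run_discovery(cfg)
            hashes.append(_hash_dir(tmp_path / sub))
        assert hashes[0] == hashes[1]

    def test_manifest_and_artifacts_written(self, tmp_path):
        cfg = PipelineConfig(seed=5, n_iter_permutation=30,
                             cohort=CohortConfig(n_samples=80, n_probes=250, seed=0),
                             outdir=tmp_path / "run")
        out = run_discovery(cfg)
        manifest = json.loads((tmp_path / "run" / "manifest.json").read_text())
        assert manifest["seed"] == 5
        assert manifest["n_signature"] == len(out["results"].signature)
        for name in ("expression.tsv", "clinical.csv", "signature.tsv",
                     "risk_scores.csv", "km_curves.csv", "permutation.json"):
            assert (tmp_path / "run" / name).exists()

    def test_inputs_not_mutated_by_run(self, tmp_path):
        expr, clinical, _ = generate_cohort(CohortConfig(n_samples=80, n_probes=250, seed=1))
        before = (expr.values.copy(), clinical.copy())
        cfg = PipelineConfig(seed=9, n_iter_permutation=20, outdir=tmp_path / "r")
        run_discovery(cfg, expr, clinical)
        pd.testing.assert_frame_equal(expr.values, before[0])
        pd.testing.assert_frame_equal(clinical, before[1])

    def test_roundtrip_expression_io(self, tmp_path, tiny_expr):
        p = tmp_path / "e.tsv"
        a = tmp_path / "a.tsv"
        tiny_expr.to_tsv(p)
        tiny_expr.annotation_to_tsv(a)
        # prepend GEO-style comment lines; the reader must skip them
        p.write_text("!Series_title\ttest\n" + p.read_text())
        back = read_expression_tsv(p, a)
        pd.testing.assert_frame_equal(back.values, tiny_expr.values, check_names=False)
        assert back.probe_to_gene == tiny_expr.probe_to_gene


class TestCli:
    def test_simulate_discover_validate_chain(self, tmp_path):
        runner = CliRunner()
        sim = runner.invoke(cli_main, [
            "simulate", "--n-samples", "120", "--n-probes", "250",
            "--seed", "4", "--outdir", str(tmp_path / "cohort")])
        assert sim.exit_code == 0, sim.output
        disc = runner.invoke(cli_main, [
            "discover",
            "--expression", str(tmp_path / "cohort" / "expression.tsv"),
            "--annotation", str(tmp_path / "cohort" / "annotation.tsv"),
            "--clinical", str(tmp_path / "cohort" / "clinical.csv"),
            "--n-iter", "30", "--seed", "4", "--outdir", str(tmp_path / "run")])
        assert disc.exit_code == 0, disc.output
        assert "Permutation empirical P" in disc.output
        val = runner.invoke(cli_main, [
            "validate", "--signature", str(tmp_path / "run" / "signature.tsv"),
            "--expression", str(tmp_path / "cohort" / "expression.tsv"),
            "--annotation", str(tmp_path / "cohort" / "annotation.tsv"),
            "--clinical", str(tmp_path / "cohort" / "clinical.csv"),
            "--outdir", str(tmp_path / "val")])
        assert val.exit_code == 0, val.output
        assert "log-rank" in val.output

    def test_associate_counts_mode(self):
        runner = CliRunner()
        res = runner.invoke(cli_main, ["associate", "--counts", "47", "32", "31", "48"])
        assert res.exit_code == 0
        assert "P = 0.0109" in res.output
        assert "statistic = 6.4821" in res.output
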