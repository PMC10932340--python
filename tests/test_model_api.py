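"""Model/Results facade and the command-line interface."""

import json

import numpy as np
import pandas as pd
import pytest
from click.testing import CliRunner

from vfipred.cli import main as cli_main
from vfipred.model import PathogenicityModel, SeverityModel


@pytest.fixture(scope="module")
def small_fit(gene, pathogenicity_data):
    """A deliberately small protocol run exercising the full fit path."""
    model = PathogenicityModel.from_gene(
        gene, pathogenicity_data, candidates=("logistic_regression", "naive_bayes")
    )
    results = model.fit(repeats=2, n_draws=2, patience=2, seed=3)
    return model, results


class TestPathogenicityFacade:
    def test_report_shape_invariants(self, small_fit):
        _, results = small_fit
        report = results.ensemble_report
        assert len(report.per_split) == report.folds * report.repeats
        assert report.predictions.notna().sum(axis=1).eq(report.repeats).all()
        ba = (report.per_split["sensitivity"] + report.per_split["specificity"]) / 2
        assert np.allclose(report.per_split["balanced_accuracy"], ba)

    def test_summary_mentions_members_and_metrics(self, small_fit):
        _, results = small_fit
        text = results.summary()
        assert "ensemble (soft vote)" in text
        assert "AUC-ROC" in text
        for cfg in results.member_configs:
            assert cfg.algorithm in text

    def test_selected_features_nonempty_and_from_matrix(self, small_fit):
        model, results = small_fit
        for cfg in results.member_configs:
            assert len(cfg.selected_features) >= 1
            assert set(cfg.selected_features) <= set(model.dataset.X.columns)

    def test_error_map_flags_are_ratios(self, small_fit):
        _, results = small_fit
        em = results.error_map()
        assert ((em["error_rate"] >= 0) & (em["error_rate"] <= 1)).all()
        assert (em["flagged"] == (em["error_rate"] > 0.5)).all()

    def test_evaluate_test_returns_quartet(self, small_fit):
        _, results = small_fit
        metrics = results.evaluate_test()
        assert set(metrics) == {"auc_roc", "balanced_accuracy", "sensitivity", "specificity"}
        assert metrics["auc_roc"] > 0.8  # strong-signal preset generalizes

    def test_predictions_are_probabilities(self, small_fit):
        model, results = small_fit
        p = results.predict_proba(model.dataset.train_X)
        assert (p >= 0).all() and (p <= 1).all()


@pytest.fixture(scope="module")
def sev_fit(gene, severity_data):
    model = SeverityModel.from_gene(
        gene, severity_data, candidates=("logistic_regression",)
    )
    results = model.fit(repeats=2, n_draws=2, patience=2, seed=5)
    return model, results


class TestSeverityFacade:
    def test_threshold_in_open_interval(self, sev_fit):
        _, results = sev_fit
        assert 0.0 < results.threshold < 1.0

    def test_predictions_use_optimized_threshold(self, sev_fit):
        model, results = sev_fit
        scores = results.predict_proba(model.dataset.train_X)
        pred = results.predict(model.dataset.train_X)
        assert np.array_equal(pred, (scores >= results.threshold).astype(int))

    def test_no_endpoint_features_in_matrix(self, sev_fit):
        model, _ = sev_fit
        assert not any(
            c.startswith(("initial_aa_", "final_aa_")) for c in model.dataset.X.columns
        )

    def test_summary_reports_threshold(self, sev_fit):
        _, results = sev_fit
        assert "threshold" in results.summary()


def _reduced_feature_csv(src, dst, n_rows=150):
    """Cut a featurize output down to a handful of columns for fast training."""
    frame = pd.read_csv(src)
    keep = ["variant", "label", "split", "vfi", "plddt", "conservation_entropy",
            "p_to_np", "selectivity_filter", "calmodulin_interaction"]
    small = frame[keep]
    train = small[small["split"] == "train"].groupby("label").head(n_rows // 2)
    test = small[small["split"] == "test"].groupby("label").head(20)
    pd.concat([train, test]).to_csv(dst, index=False)


@pytest.fixture(scope="module")
def workdir(tmp_path_factory):
    return tmp_path_factory.mktemp("cli")


class TestCli:
    def test_full_command_chain(self, workdir):
        runner = CliRunner()
        fx = workdir / "fx"
        r = runner.invoke(cli_main, ["make-fixtures", "--seed", "7", "--out-dir", str(fx)])
        assert r.exit_code == 0, r.output
        assert (fx / "manifest.json").exists()

        profile = workdir / "profile.tsv"
        r = runner.invoke(cli_main, [
            "compute-vfi", "--alleles", str(fx / "alleles.tsv"),
            "--cds", str(fx / "cds.fasta"), "--sigma", "2", "--out", str(profile),
        ])
        assert r.exit_code == 0, r.output
        table = pd.read_csv(profile, sep="\t")
        assert list(table.columns) == ["position", "f", "F", "vfi", "window31"]
        assert len(table) == 872

        features = workdir / "features.csv"
        r = runner.invoke(cli_main, [
            "featurize", "--data", str(fx / "labels_pathogenicity.csv"),
            "--profile", str(profile), "--plddt", str(fx / "plddt.json"),
            "--msa", str(fx / "msa.fasta"), "--secondary", str(fx / "secondary.txt"),
            "--domains", str(fx / "domains.tsv"), "--out", str(features),
        ])
        assert r.exit_code == 0, r.output

        small = workdir / "small.csv"
        _reduced_feature_csv(features, small)
        config = workdir / "config.yaml"
        config.write_text(
            "repeats: 2\nn_draws: 2\npatience: 2\ncandidates: [logistic_regression]\n"
        )
        bundle = workdir / "model.bundle"
        r = runner.invoke(cli_main, [
            "train", "--features", str(small), "--config", str(config),
            "--seed", "1", "--out", str(bundle),
        ])
        assert r.exit_code == 0, r.output
        assert bundle.exists() and (workdir / "model.cv.json").exists()

        preds = workdir / "preds.csv"
        r = runner.invoke(cli_main, ["predict", "--model", str(bundle), "--in", str(small), "--out", str(preds)])
        assert r.exit_code == 0, r.output
        out = pd.read_csv(preds)
        assert {"score", "predicted"} <= set(out.columns)

        ev = workdir / "eval"
        r = runner.invoke(cli_main, ["evaluate", "--model", str(bundle), "--in", str(small), "--out-dir", str(ev)])
        assert r.exit_code == 0, r.output
        metrics = json.loads((ev / "metrics.json").read_text())
        assert set(metrics) == {"auc_roc", "balanced_accuracy", "sensitivity", "specificity"}

        ex = workdir / "explain"
        r = runner.invoke(cli_main, ["explain", "--model", str(bundle), "--in", str(small), "--out-dir", str(ex), "--seed", "0"])
        assert r.exit_code == 0, r.output
        summary = pd.read_csv(ex / "shap_summary.csv")
        assert "vfi" in summary["feature"].tolist()

    def test_compute_vfi_idempotent(self, workdir):
        runner = CliRunner()
        fx = workdir / "fx"
        out1, out2 = workdir / "p1.tsv", workdir / "p2.tsv"
        for out in (out1, out2):
            r = runner.invoke(cli_main, [
                "compute-vfi", "--alleles", str(fx / "alleles.tsv"),
                "--cds", str(fx / "cds.fasta"), "--out", str(out),
            ])
            assert r.exit_code == 0
        assert out1.read_bytes() == out2.read_bytes()

    def test_validation_error_exit_code(self, workdir):
        runner = CliRunner()
        fx = workdir / "fx"
        r = runner.invoke(cli_main, [
            "compute-vfi", "--alleles", str(fx / "alleles.tsv"),
            "--cds", str(fx / "cds.fasta"), "--alpha", "banana",
            "--out", str(workdir / "x.tsv"),
        ])
        assert r.exit_code == 2

    def test_data_error_exit_code(self, workdir, tmp_path):
        bad = tmp_path / "bad.tsv"
        bad.write_text("variant\tallele_count\ttotal_alleles\tsource\nG2G\t1\t10\tv2\n")
        runner = CliRunner()
        fx = workdir / "fx"
        r = runner.invoke(cli_main, [
            "compute-vfi", "--alleles", str(bad),
            "--cds", str(fx / "cds.fasta"), "--out", str(tmp_path / "x.tsv"),
        ])
        assert r.exit_code == 3
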