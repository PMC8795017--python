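"""Model/results objects, experiment orchestration and the CLI."""

import json

import numpy as np
import pandas as pd
import pytest
import yaml
from click.testing import CliRunner

from otoradiomics.cli import main as cli_main
from otoradiomics.evaluation import make_split
from otoradiomics.mlp import MLPConfig
from otoradiomics.model import RadiomicsClassifier
from otoradiomics.pipeline import ExperimentConfig, run_experiment

SMALL_COHORT = {
    "n_patients": {"A": 5, "B": 5, "C": 5, "D": 3},
    "n_controls": {"A": 5, "B": 5, "C": 5, "D": 3},
}


@pytest.fixture(scope="module")
def small_report(tmp_path_factory):
    out = tmp_path_factory.mktemp("exp")
    cfg = ExperimentConfig(
        synthetic=SMALL_COHORT,
        seed=21,
        out_dir=str(out),
        bootstrap_reps=100,
        crossval_k=3,
        mlp={"patience": 10, "max_epochs": 200},
    )
    return run_experiment(cfg)


def test_experiment_outputs_complete(small_report):
    out = small_report.out_dir
    for name in (
        "features.csv",
        "contributions.csv",
        "metrics.json",
        "predictions.csv",
        "roc_test.csv",
        "manifest.json",
        "summary.txt",
    ):
        assert (out / name).exists(), name
    features = pd.read_csv(out / "features.csv")
    assert features.shape == (36, 3 + 812)
    metrics = json.loads((out / "metrics.json").read_text())
    assert set(metrics) == {"train", "test", "crossval_mean"}
    assert 0 <= metrics["test"]["accuracy_pct"] <= 100
    manifest = json.loads((out / "manifest.json").read_text())
    assert manifest["n_features"] == 812
    assert manifest["stage_seeds"]["cohort"] == 21


def test_rerun_identical_config_identical_outputs(small_report, tmp_path):
    cfg = ExperimentConfig(
        synthetic=SMALL_COHORT,
        seed=21,
        out_dir=str(tmp_path),
        bootstrap_reps=100,
        crossval_k=3,
        mlp={"patience": 10, "max_epochs": 200},
    )
    rerun = run_experiment(cfg)
    pd.testing.assert_frame_equal(small_report.feature_table, rerun.feature_table)
    assert (small_report.out_dir / "metrics.json").read_text() == (
        tmp_path / "metrics.json"
    ).read_text()


def test_summary_mentions_key_quantities(small_report):
    text = small_report.results.summary()
    assert "812" in text and "components: 10" in text
    assert "Training cohort" in text and "Test cohort" in text


def test_results_predict_on_new_rows(small_report):
    table = small_report.feature_table
    proba = small_report.results.predict_proba(table.head(5))
    assert proba.shape == (5,)
    assert np.all((proba >= 0) & (proba <= 1))


def test_too_few_training_rows_for_pca(small_report):
    table = small_report.feature_table.head(8)
    clf = RadiomicsClassifier(table, n_components=10, mlp_config=MLPConfig())
    with pytest.raises(ValueError, match="fewer rows"):
        clf.fit(None, bootstrap_reps=0)


def test_config_roundtrip(tmp_path):
    cfg = ExperimentConfig(synthetic=SMALL_COHORT, seed=3, crossval_k=5)
    path = tmp_path / "cfg.yaml"
    cfg.to_yaml(path)
    again = ExperimentConfig.from_yaml(path)
    assert again == cfg


def test_config_unknown_key_rejected(tmp_path):
    path = tmp_path / "bad.yaml"
    path.write_text(yaml.safe_dump({"not_a_key": 1}))
    with pytest.raises(ValueError, match="unknown config keys"):
        ExperimentConfig.from_yaml(path)


def test_cli_simulate_and_extract(tmp_path):
    runner = CliRunner()
    cohort_yaml = tmp_path / "cohort.yaml"
    cohort_yaml.write_text(
        yaml.safe_dump({"n_patients": {"A": 1}, "n_controls": {"A": 1}})
    )
    res = runner.invoke(
        cli_main,
        ["simulate", "--config", str(cohort_yaml), "--seed", "1", "--out", str(tmp_path / "c")],
    )
    assert res.exit_code == 0, res.output
    cohort = pd.read_csv(tmp_path / "c" / "cohort.csv")
    assert len(cohort) == 2

    row_csv = tmp_path / "row.csv"
    res = runner.invoke(
        cli_main,
        [
            "extract",
            "--image", cohort["image_path"][0],
            "--mask", cohort["mask_path"][0],
            "--out", str(row_csv),
        ],
    )
    assert res.exit_code == 0, res.output
    row = pd.read_csv(row_csv)
    assert row.shape == (1, 813)  # id + 812 features


def test_cli_evaluate(tmp_path):
    truth = pd.DataFrame({"id": list("abcdef"), "label": ["patient"] * 3 + ["control"] * 3})
    pred = pd.DataFrame({"id": list("abcdef"), "proba_patient": [0.9, 0.8, 0.4, 0.2, 0.1, 0.6]})
    truth.to_csv(tmp_path / "t.csv", index=False)
    pred.to_csv(tmp_path / "p.csv", index=False)
    runner = CliRunner()
    res = runner.invoke(
        cli_main,
        ["evaluate", "--pred", str(tmp_path / "p.csv"), "--truth", str(tmp_path / "t.csv")],
    )
    assert res.exit_code == 0, res.output
    payload = json.loads(res.output)
    assert payload["accuracy_pct"] == pytest.approx(100 * 4 / 6)


def test_cli_unknown_flag_nonzero_exit():
    res = CliRunner().invoke(cli_main, ["run", "--bogus"])
    assert res.exit_code != 0
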