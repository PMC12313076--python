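"""Configuration, dataset I/O, seed derivation and CLI behaviour."""

import json

import numpy as np
import pytest
from click.testing import CliRunner

from ctgaug.cli import main
from ctgaug.fixtures import FixtureConfig, generate_dataset
from ctgaug.interface import (
    RunConfig,
    compare_reports,
    config_hash,
    derive_seed,
    prepare_model_matrices,
    read_dataset,
    run_all,
    write_dataset,
)


@pytest.fixture
def tiny_run_config():
    from ctgaug.began import BeganConfig
    from ctgaug.classifier import TrainConfig
    from ctgaug.representation import AutoencoderConfig

    return RunConfig(
        seed=1,
        task="multiclass",
        fixture=FixtureConfig(
            train_counts={"normal": 60, "suspicious": 10, "pathological": 8},
            test_counts={"normal": 25, "suspicious": 4, "pathological": 3},
        ),
        began=BeganConfig(latent_dim=4, hidden_width=8, max_epochs=2,
                          convergence_threshold=0.0),
        autoencoder=AutoencoderConfig(code_dim=6, hidden_width=10, epochs=3),
        train=TrainConfig(epochs=3),
        models=("dnn", "g_dnn_ae"),
        runs=1,
        multiclass_minor=10,
    )


class TestSeedDerivation:
    def test_stable_and_stage_dependent(self):
        assert derive_seed(1, "began") == derive_seed(1, "began")
        assert derive_seed(1, "began") != derive_seed(1, "autoencoder")
        assert derive_seed(1, "began") != derive_seed(2, "began")
        assert 0 <= derive_seed(123456, "x") < 2 ** 31


class TestRunConfigSerialization:
    def test_yaml_round_trip(self, tiny_run_config, tmp_path):
        path = tmp_path / "config.yaml"
        tiny_run_config.to_yaml(path)
        back = RunConfig.from_yaml(path)
        assert back == tiny_run_config
        assert config_hash(back) == config_hash(tiny_run_config)

    def test_hash_changes_with_config(self, tiny_run_config):
        other = RunConfig(seed=tiny_run_config.seed + 1)
        assert config_hash(tiny_run_config) != config_hash(other)


class TestDatasetIO:
    def test_round_trip_identity(self, tmp_path):
        split = generate_dataset(FixtureConfig(
            train_counts={"normal": 10, "suspicious": 5, "pathological": 5},
            test_counts={"normal": 4, "suspicious": 2, "pathological": 1},
            seed=3))
        path = tmp_path / "dataset.csv"
        write_dataset(split, path)
        back = read_dataset(path)
        assert back.train == split.train
        assert back.validation == split.validation
        assert back.test == split.test

    def test_unknown_label_names_row(self, tmp_path):
        split = generate_dataset(FixtureConfig(
            train_counts={"normal": 2}, test_counts={}, seed=0))
        path = tmp_path / "dataset.csv"
        write_dataset(split, path)
        text = path.read_text().replace("normal", "ambiguous", 1)
        path.write_text(text)
        with pytest.raises(ValueError, match="line 2.*ambiguous"):
            read_dataset(path)

    def test_unknown_column_rejected(self, tmp_path):
        path = tmp_path / "dataset.csv"
        path.write_text("bp_systolic,extra\n1,2\n")
        with pytest.raises(ValueError, match="unknown columns"):
            read_dataset(path)

    def test_header_only_file_gives_empty_dataset(self, tmp_path):
        from ctgaug.interface import DATASET_COLUMNS
        path = tmp_path / "dataset.csv"
        path.write_text(",".join(DATASET_COLUMNS) + "\n")
        split = read_dataset(path)
        assert split.train == [] and split.test == []


class TestPrepareModelMatrices:
    def test_shapes_and_finiteness(self, small_split):
        x_train, y_train, x_val, y_val, x_test, y_test, columns = \
            prepare_model_matrices(small_split)
        assert x_train.shape[1] == len(columns) == 14
        assert np.isfinite(x_train).all() and np.isfinite(x_test).all()
        assert x_train.shape[0] == len(y_train) == len(small_split.train)
        assert x_test.shape[0] == len(small_split.test)

    def test_onehot_block_untouched(self, small_matrices):
        x_train, columns = small_matrices[0], small_matrices[-1]
        onehot_idx = [i for i, c in enumerate(columns)
                      if c.startswith("deceleration_")]
        assert set(np.unique(x_train[:, onehot_idx])) <= {0.0, 1.0}


class TestPipeline:
    def test_run_all_deterministic(self, tiny_run_config, tmp_path):
        run_all(tiny_run_config, tmp_path / "a")
        run_all(tiny_run_config, tmp_path / "b")
        a = (tmp_path / "a" / "metrics.json").read_bytes()
        b = (tmp_path / "b" / "metrics.json").read_bytes()
        assert a == b

    def test_compare_refuses_mismatched_partitions(self, tiny_run_config,
                                                   tmp_path):
        from dataclasses import replace
        run_all(tiny_run_config, tmp_path / "a")
        other = replace(tiny_run_config, seed=tiny_run_config.seed + 1)
        run_all(other, tmp_path / "b")
        with pytest.raises(ValueError, match="not comparable"):
            compare_reports(tmp_path / "a" / "metrics.json",
                            tmp_path / "b" / "metrics.json")


class TestCli:
    def test_generate_data_writes_expected_rows(self, tiny_run_config, tmp_path):
        config_path = tmp_path / "config.yaml"
        tiny_run_config.to_yaml(config_path)
        runner = CliRunner()
        result = runner.invoke(main, ["generate-data", "--config",
                                      str(config_path), "--output-dir",
                                      str(tmp_path / "out")])
        assert result.exit_code == 0, result.output
        assert "wrote 110 records" in result.output
        n_lines = sum(1 for _ in open(tmp_path / "out" / "dataset.csv"))
        assert n_lines == 111  # header + records

    def test_default_config_generates_full_cohort(self, tmp_path):
        runner = CliRunner()
        result = runner.invoke(main, ["generate-data", "--output-dir",
                                      str(tmp_path / "out"), "--seed", "1"])
        assert result.exit_code == 0, result.output
        assert "wrote 42000 records" in result.output

    def test_train_clf_without_encoder_exits_one(self, tiny_run_config, tmp_path):
        config_path = tmp_path / "config.yaml"
        tiny_run_config.to_yaml(config_path)
        out = tmp_path / "out"
        runner = CliRunner()
        for verb in (["generate-data"], ["preprocess"]):
            result = runner.invoke(main, verb + ["--config", str(config_path),
                                                 "--output-dir", str(out)])
            assert result.exit_code == 0, result.output
        result = runner.invoke(main, ["train-clf", "--model", "g_dnn_ae",
                                      "--config", str(config_path),
                                      "--output-dir", str(out)])
        assert result.exit_code == 1
        assert "encoder" in result.output

    def test_unknown_flag_exits_two(self):
        result = CliRunner().invoke(main, ["generate-data", "--bogus"])
        assert result.exit_code == 2

    def test_stage_verbs_compose_into_pipeline(self, tiny_run_config, tmp_path):
        """generate-data -> preprocess -> train-gan -> augment -> train-ae ->
        train-clf -> evaluate -> compare, on a tiny configuration."""
        config_path = tmp_path / "config.yaml"
        tiny_run_config.to_yaml(config_path)
        out = tmp_path / "out"
        runner = CliRunner()
        common = ["--config", str(config_path), "--output-dir", str(out)]
        for verb in (["generate-data"], ["preprocess"],
                     ["train-gan", "--mode", "multiclass"], ["augment"],
                     ["train-ae"],
                     ["train-clf", "--model", "g_dnn_ae"],
                     ["train-clf", "--model", "dnn"]):
            result = runner.invoke(main, verb + common)
            assert result.exit_code == 0, f"{verb}: {result.output}"
        pred = out / "predictions_g_dnn_ae_multiclass.csv"
        result = runner.invoke(main, ["evaluate", "--predictions", str(pred)]
                               + common)
        assert result.exit_code == 0, result.output
        assert pred.with_suffix(".report.json").exists()
        result = runner.invoke(main, [
            "compare", str(pred), str(out / "predictions_dnn_multiclass.csv"),
            "--resamples", "200"])
        assert result.exit_code == 0, result.output
        payload = json.loads(result.output)
        assert "mcnemar" in payload and "bootstrap_accuracy_diff_ci" in payload
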