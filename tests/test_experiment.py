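"""Experiment orchestration: configs, summaries, serialization, CLI."""

import json

import numpy as np
import pandas as pd
import pytest
from click.testing import CliRunner

import neuroplast as npl
from neuroplast.cli import main as cli_main
from neuroplast.plasticity import ExperimentResult, IterationRecord


def _result_from_accuracies(acc_by_replicate, gamma=0.2):
    """Hand-build an ExperimentResult with given retrained accuracies."""
    replicates = []
    for accs in acc_by_replicate:
        records = [
            IterationRecord(
                iteration=i + 1,
                injured_fraction=npl.cumulative_injured_fraction(gamma, i + 1),
                accuracy_injured=a / 2,
                accuracy_retrained=a,
            )
            for i, a in enumerate(accs)
        ]
        replicates.append(records)
    baseline = IterationRecord(0, 0.0, 0.9, 0.9)
    return ExperimentResult(
        baseline=baseline, replicates=replicates,
        seeds=tuple(range(len(acc_by_replicate))),
        schedule=npl.InjurySchedule(gamma, len(acc_by_replicate[0])),
        retrain_config=npl.TrainingConfig(),
        readout_config=npl.ReadoutConfig(rdm=False),
    )


class TestInjuryPercentLabels:
    def test_odd_iteration_labels_for_default_schedule(self):
        labels = npl.injury_percent_labels(0.2, range(1, 16, 2))
        assert labels == [20.0, 48.8, 67.2, 79.0, 86.6, 91.4, 94.5, 96.5]

    def test_labels_match_cumulative_fraction_exactly(self):
        for gamma in (0.1, 0.2, 0.5):
            for n in range(1, 12):
                label = npl.injury_percent_labels(gamma, [n])[0]
                assert label == round(
                    100 * npl.cumulative_injured_fraction(gamma, n), 1
                )


class TestSummarize:
    def test_hand_arithmetic_two_replicates(self):
        res = _result_from_accuracies([[0.8, 0.6], [0.6, 0.4]])
        table = npl.summarize(res)
        row = table[(table.metric == "accuracy") & (table.phase == "retrained")
                    & (table.iteration == 1)].iloc[0]
        assert row["mean"] == pytest.approx(0.7)
        assert row["sd"] == pytest.approx(np.std([0.8, 0.6], ddof=1))
        assert row["n_replicates"] == 2
        assert row["injury_percent"] == 20.0

    def test_single_replicate_sd_zero(self):
        res = _result_from_accuracies([[0.8, 0.6]])
        table = npl.summarize(res)
        assert (table["sd"] == 0.0).all()

    def test_mixed_schedules_rejected(self):
        a = _result_from_accuracies([[0.8, 0.6]], gamma=0.2)
        b = _result_from_accuracies([[0.8, 0.6]], gamma=0.3)
        with pytest.raises(ValueError, match="mixed"):
            npl.summarize([a, b])

    def test_pooling_across_results(self):
        a = _result_from_accuracies([[0.8, 0.6]])
        b = _result_from_accuracies([[0.6, 0.4]])
        table = npl.summarize([a, b])
        row = table[(table.metric == "accuracy") & (table.phase == "retrained")
                    & (table.iteration == 1)].iloc[0]
        assert row["mean"] == pytest.approx(0.7)
        assert row["n_replicates"] == 2


class TestRunConfig:
    def test_yaml_roundtrip(self, tmp_path):
        cfg = npl.RunConfig(
            stimulus_spec=npl.StimulusSpec(n_classes=4, image_size=16, seed=9),
            network_spec=npl.NetworkSpec.desk_scale(n_classes=4,
                                                    input_shape=(3, 16, 16)),
            schedule=npl.InjurySchedule(0.25, 4),
            readout=npl.ReadoutConfig(rdm=True, predictivity=True,
                                      rdm_stimuli_per_class=5),
            compress_target=2.0,
            seeds=(3, 4),
        )
        path = cfg.to_yaml(tmp_path / "cfg.yaml")
        loaded = npl.RunConfig.from_yaml(path)
        assert loaded == cfg

    def test_class_count_mismatch_rejected(self, tiny_dataset):
        with pytest.raises(ValueError, match="classes"):
            npl.DegenerationExperiment(
                tiny_dataset,
                network_spec=npl.NetworkSpec.desk_scale(n_classes=7,
                                                        input_shape=(3, 16, 16)),
            )


@pytest.fixture(scope="module")
def fitted(tiny_dataset, tiny_net_spec):
    exp = npl.DegenerationExperiment(
        tiny_dataset, network_spec=tiny_net_spec,
        schedule=npl.InjurySchedule(0.2, 2),
        baseline_config=npl.TrainingConfig(epochs=4, seed=0),
        retrain_config=npl.TrainingConfig(epochs=1),
        readout=npl.ReadoutConfig(rdm=True, rdm_stimuli_per_class=6),
    )
    return exp.fit(seeds=(0, 1))


class TestDegenerationResultsObject:
    def test_zero_iteration_run_is_baseline_only(self, tiny_dataset, tiny_net_spec):
        exp = npl.DegenerationExperiment(
            tiny_dataset, network_spec=tiny_net_spec,
            schedule=npl.InjurySchedule(0.2, 0),
            baseline_config=npl.TrainingConfig(epochs=1, seed=0),
            readout=npl.ReadoutConfig(rdm=False),
        )
        res = exp.fit(seeds=(0,))
        assert res.result.replicates == [[]]
        assert "0% (healthy)" in res.summary().columns

    def test_summary_table_layout(self, fitted):
        # default layout: healthy column + odd iterations (here just 1)
        table = fitted.summary()
        assert list(table.columns) == ["0% (healthy)", "20%"]
        assert ("accuracy", "retrained") in table.index
        # explicit iteration selection includes iteration 2 (36% cumulative)
        full = fitted.summary(iterations=(0, 1, 2))
        assert list(full.columns) == ["0% (healthy)", "20%", "36%"]

    def test_save_writes_csv_json_deterministically(self, fitted, tmp_path,
                                                    tiny_dataset, tiny_net_spec):
        paths = fitted.save(tmp_path / "run")
        df = pd.read_csv(paths["results"])
        assert {"replicate", "iteration", "metric", "phase", "value"} <= set(df.columns)
        manifest = json.loads(paths["manifest"].read_text())
        assert manifest["schedule"]["gamma"] == 0.2
        # identical config + seeds -> byte-identical results CSV
        exp2 = npl.DegenerationExperiment(
            tiny_dataset, network_spec=tiny_net_spec,
            schedule=npl.InjurySchedule(0.2, 2),
            baseline_config=npl.TrainingConfig(epochs=4, seed=0),
            retrain_config=npl.TrainingConfig(epochs=1),
            readout=npl.ReadoutConfig(rdm=True, rdm_stimuli_per_class=6),
        )
        paths2 = exp2.fit(seeds=(0, 1)).save(tmp_path / "run2")
        assert paths["results"].read_bytes() == paths2["results"].read_bytes()

    def test_plot_decline_returns_axis(self, fitted):
        import matplotlib

        matplotlib.use("Agg")
        ax = fitted.plot_decline()
        assert len(ax.lines) >= 2


class TestCLI:
    def test_generate_data_and_report_pipeline(self, tmp_path):
        runner = CliRunner()
        out = runner.invoke(cli_main, [
            "generate-data", "--n-classes", "3", "--image-size", "8",
            "--train-per-class", "2", "--test-per-class", "2",
            "--seed", "0", "--out", str(tmp_path / "data"),
        ])
        assert out.exit_code == 0, out.output
        assert (tmp_path / "data" / "manifest.csv").exists()

    def test_injure_and_report(self, tmp_path):
        cfg = npl.RunConfig(
            stimulus_spec=npl.StimulusSpec(
                n_classes=3, image_size=8, samples_per_class_train=8,
                samples_per_class_test=4, seed=0),
            network_spec=npl.NetworkSpec(
                blocks=(npl.ConvBlock(4, pool=True),), hidden=(),
                n_classes=3, input_shape=(3, 8, 8)),
            schedule=npl.InjurySchedule(0.3, 1),
            baseline_config=npl.TrainingConfig(epochs=1, seed=0),
            retrain_config=npl.TrainingConfig(epochs=1),
            readout=npl.ReadoutConfig(rdm=False),
            seeds=(0,),
            output_dir=str(tmp_path / "run"),
        )
        cfg.to_yaml(tmp_path / "cfg.yaml")
        runner = CliRunner()
        out = runner.invoke(cli_main, ["injure", "--config",
                                       str(tmp_path / "cfg.yaml")])
        assert out.exit_code == 0, out.output
        out = runner.invoke(cli_main, ["report", str(tmp_path / "run")])
        assert out.exit_code == 0, out.output
        assert "accuracy" in out.output
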